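# Methods

## Model and statistic

`snpfoldscan` treats an RNA molecule as a Boltzmann ensemble of
pseudoknot-free secondary structures.  The probability that positions i
and j pair, P(i,j), is computed by inside/outside dynamic programming
over the standard loop decomposition (hairpins, stacks, bulges/internal
loops, multiloops), and the structural effect of a mutation set is the
difference between the wild-type and mutant probability matrices,
summarized per sequence interval:

* **distance** d(i,j) = sqrt(Σ (ΔP)²) over pairs with *both* endpoints in
  [i, j], maximized;
* **correlation** r(i,j) = Pearson correlation of the two probability
  vectors over cells where max(P_wt, P_mut) ≥ a floor (default 0.01),
  minimized; intervals with fewer than 3 qualifying cells or zero
  variance are unscorable.

Restricting to self-contained pairs makes d monotone non-decreasing
under interval inclusion.  A direct consequence is that the unnormalized
d is maximized by (one of) the largest admissible intervals whenever the
probability change is nonzero everywhere, so with the distance measure
the reported "local region" tends to the whole folding region; genuine
localization comes from the correlation measure and from Mode 2's
fixed-length first pass.  We kept d unnormalized because the P-value
calibration is invariant to any monotone rescaling shared by foreground
and null, and the monotonicity gives clean invariants to test.

Scores are converted to empirical P-values against null tables: N scores
of the same statistic for one uniform random substitution (position
uniform, alternative base uniform over the three others) in an i.i.d.
random sequence, stratified by (length, GC) with nearest-bin lookup and
clamping outside the grid.  The add-one estimator
p = (1 + #{null at least as extreme}) / (N + 1) keeps p in
[1/(N+1), 1].  Mononucleotide i.i.d. nulls are a deliberate choice;
dinucleotide-preserving shuffles are out of scope.

## Energy model

The internal model ships its own tables (kcal/mol, 37 °C,
kT = 0.6163): sequence-dependent stacking energies for the 21 distinct
stacked combinations of {AU, UA, CG, GC, GU, UG} (rotationally
consistent, wobble-on-wobble destabilized), hairpin initiation by loop
size with Jacobson–Stockmayer log extrapolation beyond size 9, bulge and
internal-loop initiation by size with a capped asymmetry penalty of
0.5 kcal/mol per unpaired-base difference, and a linear multiloop model
a + b·branches + c·unpaired with (3.4, 0.4, 0.1).  Minimum hairpin size
h = 3; interior loops are capped at 30 unpaired bases, in the DP and in
the enumeration oracle alike, so the two define the *same* ensemble.
Dangling ends, coaxial stacking, terminal-mismatch and tetraloop bonuses
are intentionally absent: the model is self-contained and exactly
testable, not a Turner-2004 reimplementation.  Where published numbers
produced with Turner parameters matter, the pluggable backend interface
substitutes the Vienna RNA package's fold (see `snpfoldscan.vienna`);
all property tests and the calibration pipeline run on the internal
model.

## Algorithms and numerical choices

* **Inside/outside.**  Inside arrays (pair-closed, multiloop helpers,
  exterior prefix/suffix) are filled over increasing span; pair
  probabilities propagate over decreasing span, each pair pushing its
  mass to the pairs it can directly enclose.  Outer pairs with
  probability below 1e-15 are not propagated; every pushed term is
  bounded by the outer probability, so the truncation error per cell is
  below n²·1e-15 — orders of magnitude under the 1e-9 oracle tolerance.
  Kernels are numba-jitted plain loops and run (slower) without JIT.
* **Exhaustive oracle.**  All pair sets on ≤14 nt are enumerated and
  scored by explicit loop decomposition through a separate code path;
  DP probabilities, partition function and MFE are required to agree to
  1e-9 (observed: ~1e-15).  14 nt is enough to exercise multiloops.
* **Local folding** averages each pair's probability over every sliding
  window (width W, stride 1, truncated to the sequence if W > n)
  containing both partners and zeroes pairs with span ≥ L.  With W and L
  covering the sequence this reduces *exactly* to the global fold, which
  is asserted.  Folding inside a window is unconstrained; the span
  cutoff applies to the averaged output.
* **Interval scans** use the inclusion–exclusion recurrence
  T[i,j] = T[i+1,j] + T[i,j−1] − T[i+1,j−1] + A[i,j] on per-cell
  summands (squared differences; for correlation the five moment sums
  and the qualifying-cell count), so all O(n²) intervals cost O(n²).
  Tie-breaking is deterministic: best score, then shortest interval,
  then smallest start.  A brute-force per-interval oracle (guarded at
  80 nt) must agree exactly.
* **MFE structures** (display only) use the min-plus analogue of the
  inside recursion with a leftmost-first traceback at tolerance 1e-6.
* **Degenerate inputs.**  Sequences too short to close a hairpin fold
  to the open chain (all-zero matrix, d = 0, p = 1).  A correlation scan
  with no scorable interval raises in the scan API; the mode runners
  convert it to the weakest result (r = 1) so screens never abort.
  Folding regions shorter than `min_len` clamp the minimum interval
  length to the region.

## Modes and defaults

| knob | default | why |
| --- | --- | --- |
| flank | 200 nt | region = variant span ±flank, truncated at the ends |
| min_len | 50 nt | shortest reportable local region |
| window W / span L | 200 / 120 nt | local-fold averaging window and max pair span |
| fixed_len | 120 nt | Mode 2 step-1 window, matched to L |
| prob_floor | 0.01 | correlation cells must clear this in one allele |
| screen / report cutoff | 0.2 / 0.05 | Mode 3: permissive screen, standard significance |

Mode 3 evaluates all 3n substitutions with Mode 2, confirms candidates
at p ≤ 0.2 with Mode 1, reports p < 0.05 sorted by P-value then
position; with screen cutoff 1 it reduces exactly to Mode 1 on every
substitution (asserted).  The stratum for P-value lookup uses the
wild-type folding region's length and GC.  Inputs over 1000 nt only
warn: the cost is the user's choice.  CLI-level flank ranges (Mode 1:
100–800; Modes 2/3: 200–800 in steps of 50) mirror common server-style
guidance; the library accepts any positive flank.

## Synthetic data and what passing tests show

The null generator draws i.i.d. bases with P(G)=P(C)=gc/2 and one
uniform substitution — exactly the population the background tables
describe, so calibration tests are a closed loop: fresh null scores
against a same-stratum table give uniform P-values (KS-checked), and the
Mode 3 screen of a fresh random 100-nt sequence against N = 500 tables
reports about 5% of 300 substitutions at p < 0.05.  Because all 300
substitutions share one wild-type structure, the significant fraction of
a *single* sequence is overdispersed relative to binomial (pilot spread
of several percentage points across sequences); the calibration
experiment sizes (length 100, N = 500, one sequence) were chosen to keep
the full recomputation to a few minutes on one CPU.  Real transcripts
are not i.i.d.: composition bias, repeats and evolved structure mean
these tests certify the statistics, not biological accuracy.  Null
tables record measure, mode, folding parameters, N, seed and model
identifier, and regenerate bit-identically from their metadata.

## Known limitations

* The internal energy model's simplifications shift absolute energies
  and probabilities relative to Turner-parameter engines; published
  P-values from those engines reproduce only through the compatibility
  backend (and remain stochastic through table sampling).
* Unnormalized d localizes weakly (see above).
* No pseudoknots, no indels, no temperature scans, no dinucleotide-
  preserving nulls, no tail extrapolation below p = 1/(N+1).
* Local folding refolds every window from scratch (O(n·W³)); fine to a
  few hundred nt, not tuned for chromosome-scale scans.
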