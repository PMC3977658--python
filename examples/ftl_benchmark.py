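"""Published worked example: IRE-disrupting SNP in the FTL 5'UTR.

The U22G substitution in the iron-responsive element of the human
Ferritin light chain (FTL) mRNA 5'UTR is experimentally known to disrupt
the IRE hairpin, and the double mutant U22G-G14C to restore it.  The
published analysis (global fold of region 1-222, 200-nt flank, Turner
energies) reports P = 0.0518 for U22G, P = 0.3464 for U22G-G14C, and a
disrupted local region of 15-64.

The FTL mRNA (RefSeq NM_000146.3) is not redistributable with this
package: download it yourself (e.g. from NCBI E-utilities) and pass the
FASTA path.  Folding uses the Vienna compatibility backend so energies
match the published parameterization; P-values remain stochastic through
null-table sampling, so expect agreement to within a few hundredths.

Usage:
    python examples/ftl_benchmark.py NM_000146.3.fa [N_per_stratum]
"""

import sys

import snpfoldscan as sfs
from snpfoldscan.vienna import ViennaBackend

if len(sys.argv) < 2:
    sys.exit(__doc__)

fasta_path = sys.argv[1]
N = int(sys.argv[2]) if len(sys.argv) > 2 else 1000

seq = sfs.read_fasta(open(fasta_path).read())[0]
print(f"loaded {seq.id}: {len(seq)} nt")

params = sfs.ModeParams(measure=sfs.DISTANCE, flank=200, min_len=50,
                        backend=ViennaBackend())

# null table matched to the folding region the 200-nt flank produces
region, _ = sfs.extract_folding_region(
    seq, sfs.parse_mutation_spec("U22G")[0], params.flank
)
table = sfs.build_background_table(
    sfs.mode1_score_fn(params), sfs.DISTANCE, "mode1",
    N=N, seed=1,
    length_bins=[len(region)], gc_bins=[round(region.gc_fraction, 2)],
)

for spec, published in [("U22G", 0.0518), ("U22G-G14C", 0.3464)]:
    (ms,) = sfs.parse_mutation_spec(spec)
    res = sfs.run_mode1(seq, ms, params, table)
    print(f"{spec:>10}: region {res.w_start}-{res.w_end}, local "
          f"{res.local_start}-{res.local_end}, d = {res.score:.4f}, "
          f"P = {res.p_value:.4f}  (published P = {published})")
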