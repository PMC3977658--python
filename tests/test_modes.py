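"""Mode orchestration: region extraction, the three runners, determinism."""

import numpy as np
import pytest

import snpfoldscan as sfs
from snpfoldscan.modes import all_substitutions


def snp_at(seq, pos, alt=None):
    ref = seq.bases[pos - 1]
    if alt is None:
        alt = next(b for b in "ACGU" if b != ref)
    return sfs.MutationSet((sfs.Mutation(pos, ref, alt),))


class TestExtractFoldingRegion:
    def test_snp_near_start_truncates_at_one(self, rng):
        seq = sfs.random_sequence(300, 0.5, rng)
        region, offset = sfs.extract_folding_region(seq, snp_at(seq, 22), 200)
        assert offset == 0
        assert (offset + 1, offset + len(region)) == (1, 222)

    def test_interior_snp_gets_symmetric_flanks(self, rng):
        seq = sfs.random_sequence(1000, 0.5, rng)
        region, offset = sfs.extract_folding_region(seq, snp_at(seq, 300), 200)
        assert (offset + 1, offset + len(region)) == (100, 500)

    def test_flank_covering_sequence_returns_whole(self, rng):
        seq = sfs.random_sequence(80, 0.5, rng)
        region, offset = sfs.extract_folding_region(seq, snp_at(seq, 40), 200)
        assert offset == 0 and len(region) == 80

    def test_compound_mutant_region_covers_all_positions(self, rng):
        seq = sfs.random_sequence(600, 0.5, rng)
        ms = sfs.MutationSet(
            (
                sfs.Mutation(100, seq.bases[99], next(b for b in "ACGU" if b != seq.bases[99])),
                sfs.Mutation(450, seq.bases[449], next(b for b in "ACGU" if b != seq.bases[449])),
            )
        )
        region, offset = sfs.extract_folding_region(seq, ms, 50)
        assert (offset + 1, offset + len(region)) == (50, 500)

    def test_region_content_matches_slice(self, rng):
        seq = sfs.random_sequence(100, 0.5, rng)
        region, offset = sfs.extract_folding_region(seq, snp_at(seq, 60), 20)
        assert region.bases == seq.bases[39:80]


class TestMode1:
    def test_result_fields_and_coordinates(self, small_tables, rng):
        params, tables = small_tables
        seq = sfs.random_sequence(60, 0.5, rng, "m1")
        res = sfs.run_mode1(seq, snp_at(seq, 30), params, tables["mode1"])
        assert res.mode == 1
        assert res.w_start <= res.local_start <= res.local_end <= res.w_end
        assert res.w_start <= 30 <= res.w_end
        assert 0 < res.p_value <= 1

    def test_structurally_silent_mutation_scores_zero(self, small_tables):
        params, tables = small_tables
        # a pure-A context with one U: neither allele can form any pair
        bases = "A" * 30 + "U" + "A" * 29
        seq = sfs.RnaSequence("silent", bases.replace("U", "C", 1))
        ms = snp_at(seq, 31)  # C31A keeps the sequence unpairable
        assert seq.bases[30] == "C"
        res = sfs.run_mode1(seq, sfs.MutationSet((sfs.Mutation(31, "C", "A"),)),
                            params, tables["mode1"])
        assert res.score == 0.0
        assert res.p_value == 1.0

    def test_correlation_measure_reports_r(self, small_tables, rng):
        params, tables = small_tables
        corr_params = sfs.ModeParams(measure=sfs.CORRELATION, min_len=20)
        corr_table = sfs.BackgroundTable(
            measure=sfs.CORRELATION, mode="mode1", samples_per_stratum=9,
            seed=0, model="toy",
        )
        corr_table.strata[(60, 0.5)] = np.linspace(0.1, 0.9, 9)
        seq = sfs.random_sequence(60, 0.6, rng, "m1c")
        res = sfs.run_mode1(seq, snp_at(seq, 30), corr_params, corr_table)
        assert res.measure == sfs.CORRELATION
        assert -1.0 <= res.score <= 1.0


class TestMode2:
    def test_same_neighborhood_as_mode1_on_planted_disruption(self, small_tables, rng):
        """A substitution inside the only stable hairpin of a long random
        context must be localized near that hairpin by both modes."""
        params, tables = small_tables
        # AU-rich context folds weakly; plant a strong GC hairpin at 121-150
        rng2 = np.random.default_rng(77)
        context = "".join(rng2.choice(["A", "U"], 300, p=[0.7, 0.3]))
        stem = "GGCGGCGGCGGC" + "AAAA" + "GCCGCCGCCGCC"
        bases = context[:120] + stem + context[150:300]
        seq = sfs.RnaSequence("planted", bases[:300])
        pos = 126  # inside the 5' stem arm
        ms = sfs.MutationSet((sfs.Mutation(pos, seq.bases[pos - 1], "A"),))
        p2 = sfs.ModeParams(min_len=20, fixed_len=60, window=100, max_span=80,
                            flank=200)
        res2 = sfs.run_mode2(seq, ms, p2, tables["mode2"])
        assert res2.mode == 2
        assert res2.local_start <= pos <= res2.local_end
        res1 = sfs.run_mode1(seq, ms, p2, tables["mode1"])
        assert res1.local_start <= pos <= res1.local_end

    def test_identical_alleles_impossible_but_silent_scores_zero(self, small_tables):
        params, tables = small_tables
        seq = sfs.RnaSequence("s2", "A" * 40 + "C" + "A" * 39)
        res = sfs.run_mode2(seq, sfs.MutationSet((sfs.Mutation(41, "C", "G"),)),
                            params, tables["mode2"])
        assert res.score == 0.0 and res.p_value == 1.0


class TestMode3:
    def test_tiny_input_runs_and_respects_bounds(self, small_tables):
        params, tables = small_tables
        seq = sfs.RnaSequence("tiny", "GGGCAAAAGC")
        results = sfs.run_mode3(seq, params, tables)
        assert len(results) <= 30
        N = tables["mode1"].samples_per_stratum
        for r in results:
            assert 1 / (N + 1) <= r.p_value <= 1.0
            assert r.mode == 3

    def test_screen_cutoff_one_equals_mode1_on_every_substitution(self, small_tables, rng):
        params, tables = small_tables
        seq = sfs.random_sequence(30, 0.6, rng, "m3")
        open_params = sfs.ModeParams(
            min_len=params.min_len, fixed_len=params.fixed_len,
            screen_cutoff=1.0, report_cutoff=1.0,
        )
        screened = sfs.run_mode3(seq, open_params, tables)
        direct = [
            sfs.run_mode1(seq, ms, open_params, tables["mode1"])
            for ms in all_substitutions(seq)
        ]
        # report_cutoff=1.0 excludes p==1 rows (strict inequality)
        expected = sorted(
            (r for r in direct if r.p_value < 1.0),
            key=lambda r: (r.p_value, r.local_start, r.label),
        )
        assert [(r.label, r.score, r.p_value) for r in screened] == [
            (r.label, r.score, r.p_value) for r in expected
        ]

    def test_sorted_by_pvalue_then_position(self, small_tables, rng):
        params, tables = small_tables
        seq = sfs.random_sequence(40, 0.6, rng, "m3s")
        loose = sfs.ModeParams(min_len=20, fixed_len=30,
                               screen_cutoff=1.0, report_cutoff=0.9)
        results = sfs.run_mode3(seq, loose, tables)
        keys = [(r.p_value, r.local_start, r.label) for r in results]
        assert keys == sorted(keys)

    def test_soft_cap_warns_but_runs(self, small_tables):
        _, tables = small_tables
        seq = sfs.RnaSequence("long", "A" * 1001)
        # tiny folding windows keep the 3x1001 screens affordable
        cheap = sfs.ModeParams(flank=5, min_len=5, window=10, max_span=8,
                               fixed_len=8, screen_cutoff=0.01)
        warnings_seen = []
        results = sfs.run_mode3(seq, cheap, tables, warn=warnings_seen.append)
        assert warnings_seen and "1000" in warnings_seen[0]
        assert isinstance(results, list)

    def test_determinism_across_runs(self, small_tables, rng):
        params, tables = small_tables
        seq = sfs.random_sequence(25, 0.6, rng, "det")
        loose = sfs.ModeParams(min_len=15, fixed_len=20,
                               screen_cutoff=1.0, report_cutoff=1.0)
        a = sfs.run_mode3(seq, loose, tables)
        b = sfs.run_mode3(seq, loose, tables)
        assert a == b
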