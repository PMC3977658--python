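"""Null-model generation, empirical P-values, table persistence."""

import io

import numpy as np
import pytest

import snpfoldscan as sfs
from snpfoldscan.background import (
    TableFormatError,
    random_substitution,
    table_to_text,
)


def toy_score(wt, mut):
    """Cheap substitution-effect stand-in: Hamming-weighted GC shift."""
    return abs(wt.gc_fraction - mut.gc_fraction) * len(wt) + sum(
        a != b for a, b in zip(wt.bases, mut.bases)
    )


class TestRandomSequence:
    def test_gc_zero_is_au_only(self, rng):
        seq = sfs.random_sequence(200, 0.0, rng)
        assert set(seq.bases) <= {"A", "U"}

    def test_gc_one_is_gc_only(self, rng):
        seq = sfs.random_sequence(200, 1.0, rng)
        assert set(seq.bases) <= {"G", "C"}

    def test_gc_fraction_within_binomial_bound(self, rng):
        # 3 sigma for n=10000, p=0.6 is ~0.015
        seq = sfs.random_sequence(10000, 0.6, rng)
        assert abs(seq.gc_fraction - 0.6) < 0.015

    def test_random_substitution_changes_exactly_one_base(self, rng):
        seq = sfs.random_sequence(50, 0.5, rng)
        mut = random_substitution(seq, rng)
        assert sum(a != b for a, b in zip(seq.bases, mut.bases)) == 1


class TestSampleNullScores:
    def test_deterministic_under_fixed_seed(self):
        a = sfs.sample_null_scores(30, 0.5, 25, toy_score, np.random.default_rng(5))
        b = sfs.sample_null_scores(30, 0.5, 25, toy_score, np.random.default_rng(5))
        assert np.array_equal(a, b)

    def test_nonnegative_distance_scores_from_real_statistic(self):
        params = sfs.ModeParams(min_len=15)
        scores = sfs.sample_null_scores(
            40, 0.5, 10, sfs.mode1_score_fn(params), np.random.default_rng(3)
        )
        assert np.all(scores >= 0.0)

    def test_distribution_is_nondegenerate(self):
        params = sfs.ModeParams(min_len=20)
        scores = sfs.sample_null_scores(
            60, 0.5, 40, sfs.mode1_score_fn(params), np.random.default_rng(9)
        )
        assert len(np.unique(scores)) >= 10


class TestEmpiricalPvalue:
    @pytest.fixture()
    def toy_table(self):
        t = sfs.BackgroundTable(
            measure=sfs.DISTANCE, mode="mode1", samples_per_stratum=10,
            seed=0, model="toy",
        )
        t.strata[(100, 0.5)] = np.arange(1.0, 11.0)  # {1..10}
        return t

    def test_hand_counted_example(self, toy_table):
        # six null values >= 5 -> (1+6)/11
        assert sfs.empirical_pvalue(5.0, 100, 0.5, toy_table) == pytest.approx(7 / 11)

    def test_score_zero_gives_p_one(self, toy_table):
        assert sfs.empirical_pvalue(0.0, 100, 0.5, toy_table) == 1.0

    def test_score_above_all_nulls_gives_floor(self, toy_table):
        assert sfs.empirical_pvalue(99.0, 100, 0.5, toy_table) == pytest.approx(1 / 11)

    def test_monotone_nonincreasing_in_score(self, toy_table):
        ps = [sfs.empirical_pvalue(s, 100, 0.5, toy_table) for s in np.linspace(0, 12, 40)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        assert all(1 / 11 <= p <= 1 for p in ps)

    def test_correlation_measure_counts_lower_tail(self):
        t = sfs.BackgroundTable(
            measure=sfs.CORRELATION, mode="mode1", samples_per_stratum=4,
            seed=0, model="toy",
        )
        t.strata[(100, 0.5)] = np.array([0.2, 0.5, 0.8, 0.95])
        # two null values <= 0.6 -> (1+2)/5
        assert sfs.empirical_pvalue(0.6, 100, 0.5, t) == pytest.approx(3 / 5)

    def test_nearest_bin_lookup_clamps_outside_grid(self, toy_table):
        toy_table.strata[(200, 0.5)] = np.arange(11.0, 21.0)
        # length 1000 clamps to the 200 bin: all nulls >= 12 > observed
        assert sfs.empirical_pvalue(1.0, 1000, 0.5, toy_table) == 1.0
        # length 40 clamps to the 100 bin
        assert sfs.empirical_pvalue(99.0, 40, 0.5, toy_table) == pytest.approx(1 / 11)


class TestBuildAndPersist:
    @pytest.fixture(scope="class")
    def table(self):
        return sfs.build_background_table(
            toy_score, sfs.DISTANCE, "mode1", N=20, seed=42,
            length_bins=[30, 60], gc_bins=[0.4, 0.6],
            params={"min_len": 10},
        )

    def test_one_sorted_stratum_per_grid_cell(self, table):
        assert set(table.strata) == {(30, 0.4), (30, 0.6), (60, 0.4), (60, 0.6)}
        for scores in table.strata.values():
            assert len(scores) == 20
            assert np.all(np.diff(scores) >= 0)

    def test_regeneration_with_same_seed_is_identical(self, table):
        again = sfs.build_background_table(
            toy_score, sfs.DISTANCE, "mode1", N=20, seed=42,
            length_bins=[30, 60], gc_bins=[0.4, 0.6],
            params={"min_len": 10},
        )
        assert table_to_text(again) == table_to_text(table)

    def test_different_seed_differs(self, table):
        other = sfs.build_background_table(
            toy_score, sfs.DISTANCE, "mode1", N=20, seed=43,
            length_bins=[30, 60], gc_bins=[0.4, 0.6],
        )
        assert any(
            not np.array_equal(other.strata[k], table.strata[k])
            for k in table.strata
        )

    def test_save_load_save_round_trips_bytes(self, table, tmp_path):
        p1 = tmp_path / "a.tsv"
        p2 = tmp_path / "b.tsv"
        sfs.save_table(table, p1)
        loaded = sfs.load_table(p1)
        sfs.save_table(loaded, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert loaded.params == table.params
        assert loaded.seed == table.seed

    def test_wrong_magic_rejected(self):
        with pytest.raises(TableFormatError, match="magic"):
            sfs.load_table(io.StringIO("# SOMETHING-ELSE v9\n"))

    def test_truncated_file_rejected(self, table, tmp_path):
        p = tmp_path / "t.tsv"
        sfs.save_table(table, p)
        lines = p.read_text().splitlines()
        p.write_text("\n".join(lines[:-3]) + "\n")
        with pytest.raises(TableFormatError, match="truncated"):
            sfs.load_table(p)

    def test_longer_strata_have_larger_mean_distance_scores(self):
        # diagnostic: more sequence means more difference mass to accumulate
        params = sfs.ModeParams(min_len=15)
        fn = sfs.mode1_score_fn(params)
        t = sfs.build_background_table(
            fn, sfs.DISTANCE, "mode1", N=25, seed=7,
            length_bins=[30, 90], gc_bins=[0.5],
        )
        assert t.strata[(90, 0.5)].mean() > t.strata[(30, 0.5)].mean()


class TestCalibrationUniformity:
    def test_fresh_null_scores_give_uniform_pvalues(self):
        """P-values of fresh null draws against a same-stratum table must be
        uniform: KS statistic below the 1% critical value, and the p<0.05
        fraction close to 0.05."""
        from scipy import stats

        params = sfs.ModeParams(min_len=20)
        score = sfs.mode1_score_fn(params)
        t = sfs.build_background_table(
            score, sfs.DISTANCE, "mode1", N=400, seed=17,
            length_bins=[60], gc_bins=[0.5],
        )
        rng = np.random.default_rng(18)
        M = 1000
        pvals = np.empty(M)
        for k in range(M):
            wt = sfs.random_sequence(60, 0.5, rng)
            mut = random_substitution(wt, rng)
            pvals[k] = sfs.empirical_pvalue(score(wt, mut), 60, 0.5, t)
        # discrete support: compare against the achievable uniform grid
        ks = stats.kstest(pvals, "uniform").statistic
        # 1% critical value ~ 1.63 / sqrt(M), plus discreteness allowance 1/(N+1)
        assert ks < 1.63 / np.sqrt(M) + 1 / 401
        frac = float(np.mean(pvals < 0.05))
        assert abs(frac - 0.05) <= 0.02
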