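import numpy as np
import pandas as pd
import pytest

import brainstates as bs
from brainstates.errors import StatsError


def make_fo_table(n_subjects, session_effect=0.0, run_effect=0.0, interaction=0.0,
                  subject_sd=0.03, noise_sd=0.05, seed=0, runs=(1, 3)):
    """Tidy measure table from a known additive generative model."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        intercept = 0.25 + rng.normal(0, subject_sd)
        for session in ("placebo", "drug"):
            for run in runs:
                is_drug = session == "drug"
                is_late = run == runs[1]
                value = (intercept
                         + session_effect * is_drug
                         + run_effect * is_late
                         + interaction * is_drug * is_late
                         + rng.normal(0, noise_sd))
                rows.append({"subject": f"s{i}", "session": session, "run": run,
                             "condition": "rest", "measure": "fo", "state": 1,
                             "value": value})
    return pd.DataFrame(rows)


class TestKsNormality:
    def test_normal_sample_not_rejected(self):
        x = np.random.default_rng(0).normal(size=10000)
        stat, p = bs.ks_normality(x)
        assert 0 <= stat <= 1
        assert p > 0.05

    def test_exponential_sample_rejected(self):
        x = np.random.default_rng(1).exponential(size=10000)
        _, p = bs.ks_normality(x)
        assert p < 0.001

    def test_degenerate_inputs(self):
        with pytest.raises(StatsError):
            bs.ks_normality([1.0, 1.0, 1.0, 1.0, 1.0])
        with pytest.raises(StatsError):
            bs.ks_normality([1.0, 2.0])


class TestPairedT:
    def test_identical_vectors_rejected(self):
        with pytest.raises(StatsError):
            bs.paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_closed_form_value(self):
        # differences (1, 2, 3): t = mean/(sd/sqrt(3)) = 2*sqrt(3)
        t, p = bs.paired_t([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(2 * np.sqrt(3), abs=1e-12)
        assert p == pytest.approx(0.0742, abs=5e-4)

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=10), rng.normal(size=10)
        t1, p1 = bs.paired_t(x, y)
        t2, p2 = bs.paired_t(y, x)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)


class TestPermutationPaired:
    def test_equal_conditions_give_p_one(self):
        x = np.random.default_rng(3).normal(size=8)
        res = bs.permutation_paired(x, x + 0.0, n_perm=500, seed=0)
        assert res.observed == 0.0 and res.p_value == 1.0

    def test_overwhelming_effect_hits_floor(self):
        rng = np.random.default_rng(4)
        b = rng.normal(size=12)
        res = bs.permutation_paired(b + 10, b + rng.normal(0, 0.1, 12), n_perm=10000, seed=0)
        # every sign-flip except (near-)identity is dominated, so p sits
        # within a few re-draws of the 1/(n_perm+1) floor
        assert res.p_value >= 1 / 10001
        assert res.p_value < 1e-3

    def test_shift_invariance(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=10), rng.normal(size=10)
        r1 = bs.permutation_paired(a, b, n_perm=999, seed=7)
        r2 = bs.permutation_paired(a + 42.0, b + 42.0, n_perm=999, seed=7)
        assert r1.p_value == r2.p_value
        assert r1.observed == pytest.approx(r2.observed)

    def test_seed_reproducibility_and_floor(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=9), rng.normal(size=9)
        r1 = bs.permutation_paired(a, b, n_perm=1000, seed=3)
        r2 = bs.permutation_paired(a, b, n_perm=1000, seed=3)
        assert r1.p_value == r2.p_value
        assert r1.p_value >= 1 / 1001

    def test_missing_pairs_dropped_and_counted(self):
        a = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        b = np.array([1.5, 1.0, 2.0, np.nan, 4.0])
        res = bs.permutation_paired(a, b, n_perm=200, seed=0)
        assert res.n_pairs == 3 and res.n_dropped == 2

    def test_too_few_pairs_rejected(self):
        with pytest.raises(StatsError):
            bs.permutation_paired([1.0, 2.0], [0.0, 1.0], n_perm=200, seed=0)

    def test_t_statistic_variant(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(1, 1, 10), rng.normal(0, 1, 10)
        res = bs.permutation_paired(a, b, n_perm=2000, seed=0, statistic="t")
        assert res.statistic == "t"
        assert 0 < res.p_value <= 1


class TestPermutationDiffOfDiffs:
    def test_identical_differences_give_p_one(self):
        d = np.random.default_rng(8).normal(size=10)
        res = bs.permutation_diff_of_diffs(d, d.copy(), n_perm=300, seed=0)
        assert res.p_value == 1.0

    def test_session_swap_negates_statistic(self):
        rng = np.random.default_rng(9)
        d1, d2 = rng.normal(0.05, 0.02, 12), rng.normal(0.0, 0.02, 12)
        r12 = bs.permutation_diff_of_diffs(d1, d2, n_perm=2000, seed=1)
        r21 = bs.permutation_diff_of_diffs(d2, d1, n_perm=2000, seed=1)
        assert r12.observed == pytest.approx(-r21.observed)
        assert r12.p_value == r21.p_value


class TestMlm:
    def test_zero_noise_recovers_planted_constants(self):
        table = make_fo_table(8, session_effect=0.2, run_effect=0.1, interaction=0.05,
                              subject_sd=0.0, noise_sd=0.0, seed=0)
        res = bs.fit_mlm(table, "fo", 1)
        assert res.structure == "degenerate"
        assert res.effect_difference("session") == pytest.approx(
            -(0.2 + 0.05 / 2), abs=1e-8)  # placebo - drug, averaged over runs
        # cell means reproduce the generative table exactly
        mm = res.marginal_means.set_index(["session", "run"])["mean"]
        assert mm.loc[("drug", "3")] - mm.loc[("placebo", "1")] == pytest.approx(0.35, abs=1e-8)

    def test_planted_session_effect_detected(self):
        table = make_fo_table(15, session_effect=0.15, noise_sd=0.05, seed=1)
        res = bs.fit_mlm(table, "fo", 1)
        assert res.effects["session"].p < 0.01
        # recovered marginal drug-placebo difference close to delta
        assert -res.effect_difference("session") == pytest.approx(0.15, abs=0.05)
        assert res.effects["run"].p > 0.01

    def test_missing_cells_tolerated(self):
        table = make_fo_table(10, session_effect=0.1, seed=2)
        table.loc[table.sample(5, random_state=0).index, "value"] = np.nan
        res = bs.fit_mlm(table, "fo", 1)
        assert res.n_dropped == 5
        assert np.isfinite(res.effects["session"].F)

    def test_single_subject_rejected(self):
        table = make_fo_table(1, seed=3)
        with pytest.raises(StatsError):
            bs.fit_mlm(table, "fo", 1)

    def test_all_missing_rejected(self):
        table = make_fo_table(5, seed=4)
        table["value"] = np.nan
        with pytest.raises(StatsError):
            bs.fit_mlm(table, "fo", 1)

    def test_results_table_layout(self):
        table = make_fo_table(8, seed=5)
        res = bs.fit_mlm(table, "fo", 1)
        tidy = bs.stats.mlm_results_table([res])
        assert set(tidy["effect"]) == {"session", "run", "session:run"}
        assert ((tidy["p"] >= 0) & (tidy["p"] <= 1)).all()
        assert (tidy["F"] >= 0).all()


class TestBhAdjust:
    def test_monotone_and_bounded(self):
        p = [0.001, 0.01, 0.04, 0.2, 0.9]
        adj = bs.bh_adjust(p)
        assert np.all(adj >= p)
        assert np.all(adj <= 1)
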