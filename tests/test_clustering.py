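import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import brainstates as bs
from brainstates.errors import FitError, ValidationError


def best_permutation_accuracy(pred, true, k):
    """Brute-force label matching over all k! permutations."""
    best = 0.0
    for perm in itertools.permutations(range(1, k + 1)):
        mapping = np.array([0] + list(perm))
        best = max(best, float((mapping[pred] == true).mean()))
    return best


def planted_clouds(k, n_per, p, separation, noise_sd, seed):
    cents = bs.make_centroids(k, p, separation, seed)
    rng = np.random.default_rng(seed + 1)
    true = np.repeat(np.arange(1, k + 1), n_per)
    x = cents[true - 1] + rng.normal(0, noise_sd, size=(k * n_per, p))
    return x, true


class TestMaxFeasibleK:
    @pytest.mark.parametrize("T,expected", [(217, 14), (17, 4), (5, 2), (226, 15), (100, 9)])
    def test_values(self, T, expected):
        assert bs.max_feasible_k(T) == expected

    def test_too_short_run(self):
        with pytest.raises(ValidationError):
            bs.max_feasible_k(4)

    @given(T=st.integers(5, 100000))
    @settings(max_examples=200, deadline=None)
    def test_defining_inequality(self, T):
        k = bs.max_feasible_k(T)
        assert k >= 2
        assert k * k < T and (k + 1) ** 2 >= T


class TestFitStates:
    def test_recovers_well_separated_clouds(self):
        x, true = planted_clouds(4, 100, 20, separation=10, noise_sd=0.01, seed=7)
        model = bs.fit_states(x, 4, n_init=5, seed=1)
        assert best_permutation_accuracy(model.labels, true, 4) == 1.0

    def test_two_point_data_perfect_fit(self):
        x = np.repeat([[0.0, 0.0], [5.0, 5.0]], 10, axis=0)
        model = bs.fit_states(x, 2, n_init=2, seed=0)
        assert model.wss == pytest.approx(0.0, abs=1e-12)
        assert model.variance_explained == pytest.approx(1.0)

    def test_deterministic_for_fixed_seed(self):
        x, _ = planted_clouds(3, 50, 10, separation=5, noise_sd=0.5, seed=2)
        a = bs.fit_states(x, 3, n_init=4, seed=9)
        b = bs.fit_states(x, 3, n_init=4, seed=9)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.centroids, b.centroids)

    def test_variance_decomposition(self, small_concat):
        model = bs.fit_states(small_concat, 3, n_init=2, seed=0, compute_silhouette=False)
        x = small_concat.data
        tss = float(((x - x.mean(axis=0)) ** 2).sum())
        assert model.wss + model.bss == pytest.approx(tss, rel=1e-6)
        assert model.variance_explained == pytest.approx(model.bss / tss, rel=1e-9)

    def test_ve_nondecreasing_in_k(self):
        x, _ = planted_clouds(3, 80, 10, separation=6, noise_sd=1.0, seed=4)
        ves = [bs.fit_states(x, k, n_init=20, seed=0, compute_silhouette=False).variance_explained
               for k in range(2, 7)]
        assert all(b >= a - 1e-3 for a, b in zip(ves, ves[1:]))

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(FitError):
            bs.fit_states(np.random.default_rng(0).normal(size=(3, 2)), 4, n_init=1, seed=0)

    def test_degenerate_data_rejected(self):
        with pytest.raises(FitError, match="identical"):
            bs.fit_states(np.ones((50, 3)), 2, n_init=1, seed=0)


class TestChooseK:
    def test_injected_ve_profile(self):
        chosen, warn = bs.choose_k([2, 3, 4, 5], [0.30, 0.50, 0.505, 0.506], threshold=0.01)
        assert chosen == 3 and not warn

    def test_all_gains_below_threshold_warns(self):
        chosen, warn = bs.choose_k([2, 3, 4], [0.30, 0.301, 0.302], threshold=0.5)
        assert chosen == 2 and warn

    def test_non_contiguous_range_rejected(self):
        with pytest.raises(ValidationError):
            bs.choose_k([2, 4, 5], [0.1, 0.2, 0.3])


class TestKSelectionScan:
    def test_recovers_planted_k(self):
        x, _ = planted_clouds(4, 750, 20, separation=8, noise_sd=0.5, seed=3)
        report = bs.k_selection_scan(x, range(2, 9), threshold=0.01, n_init=3, seed=42,
                                     compute_silhouette=False)
        assert report.chosen_k == 4 and not report.warning

    def test_noise_only_hits_warning_branch(self):
        x = np.random.default_rng(5).normal(size=(400, 10))
        with pytest.warns(UserWarning, match="below threshold"):
            report = bs.k_selection_scan(x, range(2, 5), threshold=0.5, n_init=2, seed=0,
                                         compute_silhouette=False)
        assert report.chosen_k == 2 and report.warning

    def test_report_serialization(self, tmp_path, small_concat):
        report = bs.k_selection_scan(small_concat, range(2, 5), n_init=2, seed=0,
                                     compute_silhouette=False)
        report.to_tsv(tmp_path / "scan.tsv")
        report.to_json(tmp_path / "scan.json")
        assert (tmp_path / "scan.tsv").read_text().startswith("k\t")
        assert '"chosen_k"' in (tmp_path / "scan.json").read_text()


class TestCanonicalOrder:
    def _model_with_labels(self, labels, k):
        labels = np.asarray(labels)
        cents = np.arange(k * 2, dtype=float).reshape(k, 2)
        return bs.StateModel(k=k, centroids=cents, labels=labels, wss=1.0, bss=1.0,
                             variance_explained=0.5, silhouette=0.0, seed=0, n_init=1)

    def test_relabels_by_descending_occupancy(self):
        model = self._model_with_labels([3] * 5 + [1] * 3 + [2] * 2, k=3)
        ordered = bs.canonical_order(model)
        counts = np.bincount(ordered.labels, minlength=4)[1:]
        assert list(counts) == [5, 3, 2]
        # centroid rows follow their states
        np.testing.assert_array_equal(ordered.centroids[0], model.centroids[2])

    def test_ties_keep_original_index_order(self):
        model = self._model_with_labels([1, 2, 3, 1, 2, 3], k=3)
        ordered = bs.canonical_order(model)
        np.testing.assert_array_equal(ordered.labels, model.labels)

    def test_idempotent(self):
        model = self._model_with_labels([2, 2, 2, 1, 3, 3], k=3)
        once = bs.canonical_order(model)
        twice = bs.canonical_order(once)
        np.testing.assert_array_equal(once.labels, twice.labels)
        np.testing.assert_array_equal(once.centroids, twice.centroids)


class TestAbsenceAudit:
    def _seq(self, labels, subject="s1", session="placebo", run=1):
        return bs.StateSequence(np.asarray(labels), subject, session, run, "rest")

    def test_counts_absent_states(self):
        audit = bs.absence_audit([self._seq([1, 1, 2, 2])], k=4)
        assert audit.total == 2

    def test_full_coverage_zero_absent(self):
        audit = bs.absence_audit([self._seq([1, 2, 3, 4, 2, 1])], k=4)
        assert audit.total == 0

    def test_confined_chain_aggregate(self):
        # a chain that never leaves states {1, 2}: 2 absent per run
        rng = np.random.default_rng(0)
        seqs = [self._seq(rng.integers(1, 3, size=50), subject=f"s{i}", run=1 + i % 3)
                for i in range(10)]
        audit = bs.absence_audit(seqs, k=4)
        assert (audit.per_run["n_absent"] == 2).all()
        assert audit.total == 20

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValidationError, match="outside"):
            bs.absence_audit([self._seq([1, 5])], k=4)
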