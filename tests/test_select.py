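import numpy as np
import pytest

import nirfm as nf
from nirfm.plsda import cv_misclassification
from nirfm.select import _spa_chain, exhaustive_best_subset


def _labeled(X, labels, start=1000.0, step=10.0):
    X = np.asarray(X, dtype=float)
    grid = nf.WavelengthGrid(start + step * np.arange(X.shape[1]))
    return nf.SpectraSet(grid, X, np.asarray(labels, dtype=int))


def _separable_small(rng, n=40, J=8, informative=(2, 5)):
    labels = rng.permutation(np.array([0] * (n // 2) + [1] * (n - n // 2)))
    X = rng.normal(0.0, 1.0, size=(n, J))
    for j in informative:
        X[:, j] += 6.0 * labels
    return _labeled(X, labels)


class TestVipScores:
    def test_equal_weights_give_unit_scores(self):
        # rank-one X along an equal-weight direction: every variable matters equally
        rng = np.random.default_rng(3)
        t = np.linspace(-1, 1, 20)
        w = np.ones(5) / np.sqrt(5)
        X = np.outer(t, w)
        labels = (t > 0).astype(int)
        S = _labeled(X, labels)
        m = nf.fit_plsda(S, n_lv=1)
        scores = nf.vip_scores(m).scores
        np.testing.assert_allclose(scores, 1.0, atol=1e-8)

    @pytest.mark.parametrize("n_lv", [1, 2, 4])
    def test_mean_square_identity(self, n_lv, rng):
        S = _separable_small(rng, n=30, J=10)
        m = nf.fit_plsda(S, n_lv=n_lv)
        v = nf.vip_scores(m)
        assert np.mean(v.scores**2) == pytest.approx(1.0, abs=1e-8)

    def test_informative_variables_score_above_noise(self, rng):
        S = _separable_small(rng, n=60, J=12, informative=(3, 7))
        m = nf.fit_plsda(S, n_lv=2)
        scores = nf.vip_scores(m).scores
        noise = np.delete(scores, [3, 7])
        assert scores[3] > 1.0 and scores[7] > 1.0
        assert np.median(noise) < 1.0
        assert min(scores[3], scores[7]) > np.median(noise)


class TestWrcSelect:
    def test_single_spike_is_selected(self):
        rng = np.random.default_rng(0)
        n, J = 40, 60
        labels = rng.permutation(np.array([0] * 20 + [1] * 20))
        X = rng.normal(0.0, 0.05, size=(n, J))
        X[:, 42] += 2.0 * labels
        m = nf.fit_plsda(_labeled(X, labels), n_lv=1, autoscale=True)
        sel = nf.wrc_select(m, k=1)
        assert sel.selected_indices.tolist() == [42]

    def test_minimum_separation_enforced(self, demo_split):
        cal, _ = demo_split
        m = nf.fit_plsda(cal, n_lv=5, autoscale=True)
        sel = nf.wrc_select(m, k=5, min_separation=30.0)
        wl = np.sort(sel.selected_wavelengths)
        assert np.all(np.diff(wl) >= 30.0)

    def test_two_planted_bands_recovered(self, small_two_band_spectra):
        S = small_two_band_spectra
        m = nf.fit_plsda(S, n_lv=1, autoscale=True)
        sel = nf.wrc_select(m, k=2)
        for center in (1450.0, 1940.0):
            offsets = np.abs(sel.selected_wavelengths - center)
            spacing = float(S.grid.spacing[0])
            assert offsets.min() <= 3 * spacing, center

    def test_unscaled_model_rejected(self, rng):
        S = _separable_small(rng)
        with pytest.raises(ValueError):
            nf.wrc_select(nf.fit_plsda(S, n_lv=2), k=2)


class TestVipSelect:
    def test_low_cutoff_keeps_everything(self, rng):
        S = _separable_small(rng, n=30, J=6)
        sel = nf.vip_select(S, cutoffs=np.array([1e-6]), folds=5, seed=0)
        assert sel.n_selected == 6
        assert sel.criterion_trace[0]["n_vars"] == 6

    def test_default_grid_traces_eight_cutoffs(self, demo_selections):
        trace = demo_selections["vip"].criterion_trace
        assert len(trace) == 8
        assert trace[0]["cutoff"] == pytest.approx(0.8)
        assert trace[-1]["cutoff"] == pytest.approx(1.5)

    def test_winner_maximises_accuracy_then_size(self, demo_selections):
        trace = [r for r in demo_selections["vip"].criterion_trace if not r["skipped"]]
        best_acc = max(r["cv_accuracy_pct"] for r in trace)
        winners = [r for r in trace if r["cv_accuracy_pct"] == best_acc]
        assert demo_selections["vip"].n_selected == min(r["n_vars"] for r in winners)


class TestSfsSelect:
    def test_stops_at_zero_error_with_one_variable(self, rng):
        S = _separable_small(rng, n=40, J=8, informative=(4,))
        sel = nf.sfs_select(S, max_features=5, folds=5, seed=0)
        assert sel.n_selected == 1
        assert sel.selected_indices.tolist() == [4]
        assert sel.criterion_trace[-1]["cv_error"] == 0.0

    def test_each_step_is_the_candidate_minimum(self, rng):
        """Greedy additions equal an exhaustive scan over candidates."""
        labels = rng.permutation(np.array([0] * 15 + [1] * 15))
        X = rng.normal(0.0, 1.0, size=(30, 8))
        X[:, 3] += 1.0 * labels  # weakly informative: forces several steps
        S = _labeled(X, labels)
        sel = nf.sfs_select(S, max_features=3, folds=5, seed=2)
        chosen: list[int] = []
        for step in sel.criterion_trace:
            errors = {}
            for j in range(S.n_wavelengths):
                if j in chosen:
                    continue
                errors[j] = cv_misclassification(
                    S.absorbance[:, chosen + [j]], S.labels,
                    min(len(chosen) + 1, 5), 5, 2,
                )[0]
            assert step["cv_error"] == pytest.approx(min(errors.values()))
            chosen.append(step["added_index"])

    def test_deterministic_for_fixed_seed(self, rng):
        S = _separable_small(rng, n=30, J=10, informative=(1,))
        a = nf.sfs_select(S, max_features=4, folds=5, seed=9)
        b = nf.sfs_select(S, max_features=4, folds=5, seed=9)
        assert a.selected_indices.tolist() == b.selected_indices.tolist()
        assert a.criterion_trace == b.criterion_trace


class TestSpaSelect:
    def test_orthogonal_pair_beats_duplicate(self):
        # two orthogonal columns and an exact duplicate of the first:
        # the projection criterion must pick the orthogonal pair
        t = np.linspace(-1, 1, 24)
        u = np.sin(np.pi * t)
        X = np.column_stack([t, u, t])
        labels = (t > 0).astype(int)
        Xc = X - X.mean(axis=0)
        chain = _spa_chain(Xc, 0, 2)
        assert set(chain) == {0, 1}

    def test_min_vars_lower_bound(self, rng):
        S = _separable_small(rng, n=20, J=6)
        with pytest.raises(ValueError):
            nf.spa_select(S, min_vars=1, max_vars=1)

    def test_chain_residual_norm_is_stepwise_maximal(self, rng):
        X = rng.normal(size=(18, 12))
        Xc = X - X.mean(axis=0)
        chain = _spa_chain(Xc, 4, 5)
        R = Xc.copy()
        for step, j in enumerate(chain):
            if step > 0:
                norms = np.linalg.norm(R, axis=0)
                norms[chain[:step]] = -1.0
                assert np.linalg.norm(R[:, j]) == pytest.approx(norms.max())
            u = R[:, j] / np.linalg.norm(R[:, j])
            R = R - np.outer(u, u @ R)

    def test_winner_has_minimal_cv_error(self, rng):
        S = _separable_small(rng, n=30, J=9, informative=(2, 6))
        sel = nf.spa_select(S, min_vars=2, max_vars=4, folds=5, seed=1)
        best = min(r["cv_error"] for r in sel.criterion_trace)
        winner = [
            r for r in sel.criterion_trace
            if sorted(r["subset"]) == sel.selected_indices.tolist()
        ]
        assert winner and winner[0]["cv_error"] == best


class TestIplsSelect:
    def test_unit_width_intervals_are_single_wavelengths(self, rng):
        S = _separable_small(rng, n=30, J=8, informative=(3,))
        sel = nf.ipls_select(S, interval_width=1, folds=5, seed=0)
        assert sel.n_selected == len(sel.criterion_trace)

    def test_informative_interval_chosen_first(self, rng):
        labels = rng.permutation(np.array([0] * 15 + [1] * 15))
        X = rng.normal(0.0, 1.0, size=(30, 12))
        X[:, 7] += 6.0 * labels
        S = _labeled(X, labels)
        sel = nf.ipls_select(S, interval_width=3, folds=5, seed=1)
        first = sel.criterion_trace[0]
        assert first["interval"] == 7 // 3
        # oracle: exhaustive scan over all first intervals
        errors = []
        for lo in range(0, 12, 3):
            cols = list(range(lo, min(lo + 3, 12)))
            errors.append(cv_misclassification(
                S.absorbance[:, cols], S.labels, min(len(cols), 5), 5, 1
            )[0])
        assert first["cv_error"] == pytest.approx(min(errors))

    def test_trace_errors_strictly_decrease(self, rng):
        S = _separable_small(rng, n=40, J=16, informative=(5, 11))
        sel = nf.ipls_select(S, interval_width=2, folds=5, seed=3)
        errs = [r["cv_error"] for r in sel.criterion_trace]
        assert all(b < a for a, b in zip(errs, errs[1:]))


class TestGreedyVsExhaustive:
    def test_selectors_match_brute_force_on_tiny_instance(self, rng):
        """On a 10-variable problem the greedy winners reach the exhaustive
        optimum of the CV criterion at their selected size."""
        S = _separable_small(rng, n=30, J=10, informative=(4, 8))
        spa = nf.spa_select(S, min_vars=2, max_vars=2, folds=5, seed=0)
        _, best_err = exhaustive_best_subset(S, 2, folds=5, seed=0)
        spa_err = min(r["cv_error"] for r in spa.criterion_trace if r["n_vars"] == 2)
        assert spa_err == pytest.approx(best_err)


class TestRefitWithBands:
    def test_full_selection_equals_full_model(self, rng):
        S = _separable_small(rng, n=60, J=6, informative=(1, 4))
        all_sel = nf.SelectionResult(
            method="vip",
            selected_indices=np.arange(6),
            selected_wavelengths=S.grid.values,
        )
        rep = nf.refit_with_bands(S, all_sel, test_fraction=0.5, folds=5, seed=3)
        cal, test = nf.stratified_split(S, 0.5, 3)
        n_lv = nf.choose_n_lv(cal, max_lv=5, folds=5, seed=3)
        full = nf.evaluate_model(nf.fit_plsda(cal, n_lv=n_lv), test, "test")
        assert rep.counts == full.counts

    def test_planted_band_selection_reaches_100(self, small_two_band_spectra):
        S = small_two_band_spectra
        idx = [S.grid.nearest_index(1450), S.grid.nearest_index(1940)]
        sel = nf.SelectionResult(
            method="wrc",
            selected_indices=np.array(idx),
            selected_wavelengths=S.grid.values[idx],
        )
        rep = nf.refit_with_bands(S, sel, test_fraction=0.5, folds=5, seed=1)
        assert rep.accuracy == 100.0

    def test_report_consistent_with_counts(self, small_two_band_spectra):
        S = small_two_band_spectra
        sel = nf.SelectionResult(
            method="sfs",
            selected_indices=np.array([S.grid.nearest_index(1940)]),
            selected_wavelengths=np.array([1940.0]),
        )
        rep = nf.refit_with_bands(S, sel, test_fraction=0.5, folds=5, seed=1)
        m = nf.metrics(rep.counts)
        assert rep.accuracy == pytest.approx(m.accuracy)

    def test_empty_selection_rejected(self, rng):
        S = _separable_small(rng)
        empty = nf.SelectionResult(
            method="sfs", selected_indices=np.array([], dtype=int),
            selected_wavelengths=np.array([]),
        )
        with pytest.raises(ValueError):
            nf.refit_with_bands(S, empty)
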