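"""Variational-Bayes Gaussian HMM: closed forms, recovery, and invariants."""

import numpy as np
import pandas as pd
import pytest

from brainstates import (
    CohortConfig,
    VBGaussianHMM,
    concatenate,
    fit_hmm,
    fit_pca,
    make_ground_truth,
    project,
    scan_states,
    select_n_states,
    simulate_cohort,
    standardize,
    state_maps,
)
from brainstates.hmm import SelectionResult, hard_assign, match_states
from brainstates.preprocessing import CohortPCA


def _accuracy(perm, posterior, true_paths, subjects):
    accs = [
        (perm[np.asarray(p)] == true_paths[s.subject_id]).mean()
        for s, p in zip(subjects, posterior.paths)
    ]
    return float(np.mean(accs))


class TestFit:
    def test_single_state_closed_form(self, rng):
        x = rng.standard_normal((300, 4)) + 2.0
        model = VBGaussianHMM(n_states=1, n_restarts=1, random_state=0).fit(
            x, lengths=[150, 150]
        )
        np.testing.assert_allclose(model.transmat_, [[1.0]])
        np.testing.assert_allclose(model.means_[0], x.mean(axis=0), atol=1e-6)
        gamma = model.predict_proba(x, lengths=[150, 150])
        np.testing.assert_allclose(gamma, 1.0)

    def test_recovery_on_three_state_cohort(self, small_cohort, small_projected):
        _, truth, cohort = small_cohort
        z, lengths, pca = small_projected
        model, post = fit_hmm(z, lengths, n_states=3, n_restarts=3, random_state=0)
        maps = state_maps(model, pca)
        corr = np.array([[np.corrcoef(t, e)[0, 1] for e in maps]
                         for t in truth.roi_means])
        perm = match_states(truth.roi_means, maps)
        matched = np.array([corr[perm[k], k] for k in range(3)])
        assert matched.mean() >= 0.95
        assert _accuracy(perm, post, cohort.true_paths, cohort.subjects) >= 0.90

    def test_free_energy_monotone_on_every_restart(self, small_projected):
        z, lengths, _ = small_projected
        model = VBGaussianHMM(n_states=3, n_restarts=10, random_state=1).fit(
            z, lengths
        )
        for trace in model.all_free_energy_traces_:
            diffs = np.diff(trace)
            assert np.all(diffs <= np.abs(trace[:-1]) * 1e-8 + 1e-8)

    def test_transition_and_posterior_rows_are_simplex(self, small_projected):
        z, lengths, _ = small_projected
        model = VBGaussianHMM(n_states=3, n_restarts=2, random_state=2).fit(z, lengths)
        np.testing.assert_allclose(model.transmat_.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(model.transmat_ >= 0)
        gamma = model.predict_proba(z, lengths)
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(gamma >= 0)

    def test_label_permutation_leaves_free_energy_unchanged(self, small_projected):
        z, lengths, _ = small_projected
        model = VBGaussianHMM(n_states=3, n_restarts=2, random_state=3).fit(z, lengths)
        f = model.free_energy(z, lengths)
        permuted = model.permute_states([2, 0, 1])
        f_perm = permuted.free_energy(z, lengths)
        assert f_perm == pytest.approx(f, rel=1e-8)

    def test_near_zero_noise_two_state_paths_exact(self):
        cfg = CohortConfig(n_per_group=2, T=100, R=6, n_states=2,
                           noise_scale=0.05, state_separation=40.0, seed=4)
        truth = make_ground_truth(cfg)
        cohort = simulate_cohort(truth, cfg)
        stacked, spans = concatenate([standardize(s) for s in cohort.subjects])
        pca = fit_pca(stacked)
        z = project(stacked, pca)
        model, post = fit_hmm(z, [b - a for a, b in spans], 2, n_restarts=2,
                              random_state=0)
        perm = match_states(truth.roi_means, state_maps(model, pca))
        acc = _accuracy(perm, post, cohort.true_paths, cohort.subjects)
        assert acc >= 0.99

    def test_vb_means_agree_with_independent_em_implementation(self, small_projected):
        """Maximum-likelihood EM (hmmlearn) lands on the same state means."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        z, lengths, _ = small_projected
        model = VBGaussianHMM(n_states=3, n_restarts=3, random_state=0).fit(z, lengths)
        em = best = None
        for rs in range(4):  # EM needs restarts against local optima too
            cand = hmmlearn.GaussianHMM(n_components=3, covariance_type="full",
                                        n_iter=300, tol=1e-4, random_state=rs)
            cand.fit(z, lengths=lengths)
            score = cand.score(z, lengths=lengths)
            if best is None or score > best:
                em, best = cand, score
        perm = match_states(em.means_, model.means_)
        dists = [np.linalg.norm(em.means_[perm[k]] - model.means_[k])
                 for k in range(3)]
        assert max(dists) <= 0.1

    def test_invalid_inputs_rejected(self, rng):
        x = rng.standard_normal((20, 3))
        with pytest.raises(ValueError, match="finite"):
            VBGaussianHMM(n_states=2).fit(np.full((10, 2), np.nan))
        with pytest.raises(ValueError, match="lengths"):
            VBGaussianHMM(n_states=2).fit(x, lengths=[5, 5])

    def test_sklearn_param_interface(self):
        model = VBGaussianHMM(n_states=4, tol=1e-4)
        assert model.get_params()["n_states"] == 4
        model.set_params(n_states=2)
        assert model.n_states == 2


class TestHardAssign:
    def test_simple_argmax(self):
        assert hard_assign(np.array([[0.2, 0.5, 0.3]])).tolist() == [1]

    def test_tie_breaks_to_lowest_index(self):
        assert hard_assign(np.array([[0.5, 0.5]])).tolist() == [0]

    def test_agrees_with_row_scan_oracle(self, rng):
        mat = rng.random((200, 6))
        mat /= mat.sum(axis=1, keepdims=True)
        expected = [max(range(6), key=lambda k: (row[k], -k)) for row in mat]
        assert hard_assign(mat).tolist() == expected

    def test_invalid_rows_rejected(self):
        with pytest.raises(ValueError, match="probability"):
            hard_assign(np.array([[0.9, 0.9]]))


class TestStateMaps:
    def _identity_pca(self, r):
        t = CohortPCA(n_components=r)
        t.center_ = np.zeros(r)
        t.loadings_ = np.eye(r)
        t.explained_variance_ratio_ = np.full(r, 1.0 / r)
        t.n_components_ = r
        return t

    def test_identity_transform_returns_means(self, rng):
        x = rng.standard_normal((200, 3))
        model = VBGaussianHMM(n_states=1, n_restarts=1, random_state=0).fit(x)
        maps = state_maps(model, self._identity_pca(3))
        np.testing.assert_allclose(maps, model.means_, atol=1e-12)

    def test_zero_mean_returns_center(self, rng):
        x = rng.standard_normal((100, 4))
        pca = fit_pca(x, n_components=2)
        model = VBGaussianHMM(n_states=1, n_restarts=1, random_state=0).fit(
            rng.standard_normal((50, 2))
        )
        # a zero component vector back-projects onto the PCA center
        model.means_ = np.zeros((1, 2))
        np.testing.assert_allclose(state_maps(model, pca)[0], pca.center_, atol=1e-12)

    def test_dimension_mismatch_rejected(self, rng, small_projected):
        _, _, pca = small_projected
        x = rng.standard_normal((50, 2))
        model = VBGaussianHMM(n_states=1, n_restarts=1, random_state=0).fit(x)
        with pytest.raises(ValueError, match="components"):
            state_maps(model, pca)

    def test_sign_pattern_recovered(self, small_cohort, small_projected):
        _, truth, _ = small_cohort
        z, lengths, pca = small_projected
        model, _ = fit_hmm(z, lengths, 3, n_restarts=3, random_state=0)
        maps = state_maps(model, pca)
        perm = match_states(truth.roi_means, maps)
        strong = np.abs(truth.roi_means) > 0.5
        agree = total = 0
        for est_k in range(3):
            true_k = perm[est_k]
            cells = strong[true_k]
            agree += (np.sign(maps[est_k][cells])
                      == np.sign(truth.roi_means[true_k][cells])).sum()
            total += cells.sum()
        assert total > 0 and agree / total >= 0.90


class TestScanSelect:
    def test_scan_single_state_range(self, small_projected):
        z, lengths, _ = small_projected
        scan = scan_states(z, lengths, [1], n_restarts=1, random_state=0)
        assert len(scan) == 1
        assert scan["median_fo"].iloc[0] == pytest.approx(1.0)

    def test_rule_on_frozen_sequence(self):
        scan = pd.DataFrame({
            "K": [2, 3, 4, 5, 6],
            "median_fo": [0.30, 0.15, 0.10, 0.099, 0.098],
            "free_energy": [-1.0, -2.0, -3.0, -4.0, -5.0],
            "failed": [False] * 5,
        })
        sel = select_n_states(scan, epsilon=0.05)
        assert sel.n_states == 4
        assert sel.plateau_found
        assert sel.free_energy_monotone

    def test_geometric_decay_has_no_plateau(self):
        ks = list(range(2, 10))
        scan = pd.DataFrame({
            "K": ks,
            "median_fo": [0.5 * 0.5 ** i for i in range(len(ks))],
            "free_energy": [-float(i) for i in range(len(ks))],
            "failed": [False] * len(ks),
        })
        sel = select_n_states(scan, epsilon=0.05)
        assert not sel.plateau_found
        assert sel.n_states == ks[-1]

    def test_needs_three_scanned_values(self):
        scan = pd.DataFrame({"K": [2, 3], "median_fo": [0.5, 0.3],
                             "free_energy": [0.0, -1.0], "failed": [False, False]})
        with pytest.raises(ValueError, match="at least 3"):
            select_n_states(scan)

    def test_invalid_k_range_rejected(self, small_projected):
        z, lengths, _ = small_projected
        with pytest.raises(ValueError, match="ascending"):
            scan_states(z, lengths, [3, 2], n_restarts=1)

    def test_selection_result_shape(self):
        sel = SelectionResult(n_states=3, plateau_found=True, free_energy_monotone=False)
        assert sel.n_states == 3
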