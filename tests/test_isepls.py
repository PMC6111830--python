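"""PLS1 engine, LOO cross-validation, elimination loop, NLV selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hyperchla import (SpectrumSet, first_derivative, importance,
                       ise_eliminate, jaggedness, loo_predictions, loo_rmse,
                       pls_fit, pls_predict, run_ise_pls, select_final_nlv,
                       select_nlv_by_rmse)
from hyperchla.isepls import _rescale01

from conftest import preprocess_rl


def random_problem(n, p, seed=0, noise=1.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + noise * rng.normal(size=n)
    return X, y


class TestPLSFit:
    def test_single_predictor_equals_ols_slope(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20)
        y = 2.5 * x + rng.normal(size=20)
        m = pls_fit(x[:, None], y, 1)
        xc = x - x.mean()
        slope = (xc @ (y - y.mean())) / (xc @ xc)
        assert m.beta[0] == pytest.approx(slope, rel=1e-10)

    @given(st.integers(0, 500))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_full_rank_equals_least_squares(self, seed):
        X, y = random_problem(12, 5, seed)
        m = pls_fit(X, y, 5)
        beta = np.linalg.lstsq(X - X.mean(0), y - y.mean(), rcond=None)[0]
        np.testing.assert_allclose(m.beta, beta, rtol=1e-8, atol=1e-10)

    def test_matches_reference_pls_implementation(self):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, y = random_problem(25, 12, seed=7)
        for nlv in (1, 3, 6):
            ref = sklearn.PLSRegression(n_components=nlv, scale=False).fit(X, y)
            m = pls_fit(X, y, nlv)
            np.testing.assert_allclose(m.beta, ref.coef_.ravel(), atol=1e-8)

    def test_centering_contract(self):
        X, y = random_problem(15, 8, seed=3)
        m = pls_fit(X, y, 4)
        np.testing.assert_allclose(pls_predict(m, X),
                                   m.y_mean + (X - m.x_mean) @ m.beta)

    def test_constant_y_rejected(self):
        X, _ = random_problem(10, 4)
        with pytest.raises(ValueError, match="zero variance"):
            pls_fit(X, np.ones(10), 2)

    def test_infeasible_nlv_rejected(self):
        X, y = random_problem(6, 4)
        with pytest.raises(ValueError, match="exceeds"):
            pls_fit(X, y, 6)


class TestPLSPredict:
    def test_exact_fit_reproduces_training_response(self):
        X, y = random_problem(10, 9, seed=2, noise=0.0)
        m = pls_fit(X, y, 9)
        np.testing.assert_allclose(pls_predict(m, X), y, atol=1e-8)

    def test_mean_spectrum_predicts_mean_response(self):
        X, y = random_problem(12, 6, seed=4)
        m = pls_fit(X, y, 3)
        assert pls_predict(m, m.x_mean[None, :])[0] == pytest.approx(m.y_mean)

    def test_column_mismatch_rejected(self):
        X, y = random_problem(12, 6, seed=4)
        m = pls_fit(X, y, 3)
        with pytest.raises(ValueError, match="columns"):
            pls_predict(m, X[:, :5])


class TestLOO:
    def test_hand_arithmetic_rmse(self):
        # RMSE of residuals (3, 4) over n=2: sqrt(25/2)
        from hyperchla.isepls import _rmse
        assert _rmse(np.zeros(2), np.array([3.0, 4.0])) == pytest.approx(
            np.sqrt(12.5))

    @given(st.integers(0, 200))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_matches_brute_force_refits(self, seed):
        X, y = random_problem(10, 8, seed)
        for nlv in (1, 3, 5):
            got = loo_rmse(X, y, nlv)
            brute = np.array([
                pls_predict(pls_fit(np.delete(X, i, 0), np.delete(y, i), nlv),
                            X[i][None, :])[0]
                for i in range(10)
            ])
            np.testing.assert_allclose(got.y_pred, brute, atol=1e-9)
            assert got.rmse == pytest.approx(
                np.sqrt(np.mean((y - brute) ** 2)), rel=1e-9)

    def test_nested_predictions_consistent(self):
        # column j of the multi-NLV matrix equals a fixed-nlv LOO run
        X, y = random_problem(12, 9, seed=9)
        all_preds = loo_predictions(X, y, 5)
        for nlv in (1, 2, 5):
            np.testing.assert_allclose(all_preds[:, nlv - 1],
                                       loo_rmse(X, y, nlv).y_pred, atol=1e-10)

    def test_perfect_predictions_zero_rmse(self):
        X, y = random_problem(12, 4, seed=1, noise=0.0)
        res = loo_rmse(X, y, 4)
        assert res.rmse < 1e-8 and res.r2 > 1 - 1e-12


class TestNLVSelection:
    def test_rank_two_structure_selects_two(self):
        rng = np.random.default_rng(3)
        T = rng.normal(size=(30, 2))
        X = T @ rng.normal(size=(2, 12))
        y = T @ np.array([2.0, -1.0])
        assert select_nlv_by_rmse(X, y, 6) == 2

    def test_single_candidate(self):
        X, y = random_problem(10, 5)
        assert select_nlv_by_rmse(X, y, 1) == 1

    def test_deterministic(self):
        X, y = random_problem(15, 10, seed=5)
        assert select_nlv_by_rmse(X, y, 8) == select_nlv_by_rmse(X, y, 8)


class TestImportance:
    def test_equal_products_split_evenly(self):
        # orthogonal columns; column 2 has twice the sd but half the
        # coefficient, so the |beta| s importance products tie at 0.5/0.5
        X = np.array([[1.0, 2.0], [-1.0, -2.0], [1.0, -2.0], [-1.0, 2.0]])
        y = X @ np.array([1.0, 0.5])
        m = pls_fit(X, y, 2)
        z = importance(m, X).z
        np.testing.assert_allclose(z, [0.5, 0.5], rtol=1e-8)

    @given(st.integers(0, 300))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_normalisation(self, seed):
        X, y = random_problem(12, 7, seed)
        m = pls_fit(X, y, 3)
        z = importance(m, X).z
        assert z.sum() == pytest.approx(1.0)
        assert np.all(z >= 0)

    def test_constant_column_has_zero_importance(self):
        X, y = random_problem(12, 4, seed=6)
        X = np.column_stack([X, np.full(12, 3.0)])
        m = pls_fit(X, y, 3)
        assert importance(m, X).z[-1] == 0.0


class TestEliminate:
    def test_sparse_noiseless_recovery(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 50))
        y = 2 * X[:, 5] - 1.5 * X[:, 20] + 0.7 * X[:, 33]
        model, trace = ise_eliminate(X, y, max_nlv=8)
        assert trace.rmses[trace.best_cycle] < 1e-8
        assert model.band_mask.sum() <= 50
        assert all(model.band_mask[i] for i in (5, 20, 33))

    def test_trace_decreases_by_one(self):
        X, y = random_problem(15, 20, seed=2)
        _, trace = ise_eliminate(X, y, max_nlv=4)
        counts = trace.retained_counts
        assert counts[0] == 20 and counts[-1] == 2
        assert all(a - b == 1 for a, b in zip(counts, counts[1:]))

    def test_best_cycle_is_global_minimum(self):
        X, y = random_problem(15, 20, seed=12)
        _, trace = ise_eliminate(X, y, max_nlv=4)
        assert trace.rmses[trace.best_cycle] == min(trace.rmses)
        # never worse than the full-band model (cycle 0)
        assert trace.rmses[trace.best_cycle] <= trace.rmses[0]

    def test_importance_normalised_every_cycle(self):
        X, y = random_problem(20, 15, seed=4)
        _, trace = ise_eliminate(X, y, max_nlv=5)
        for mask, nlv in zip(trace.masks, trace.nlvs):
            m = pls_fit(X[:, mask], y, nlv)
            assert importance(m, X[:, mask]).z.sum() == pytest.approx(1.0)


class TestJaggedness:
    def test_examples(self):
        assert jaggedness(np.array([2.0, 2.0, 2.0])) == 0.0
        assert jaggedness(np.array([0.0, 1.0, 0.0])) == 2.0
        assert jaggedness(np.array([0.0, 0.0, 1.0])) == 1.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            jaggedness(np.array([1.0]))


class TestFinalNLV:
    def test_rescaling_example(self):
        scaled, degen = _rescale01(np.array([2.0, 4.0, 6.0]))
        np.testing.assert_allclose(scaled, [0.0, 0.5, 1.0])
        assert not degen

    def test_dominant_candidate_wins(self):
        sel = None
        for seed in range(20):
            X, y = random_problem(15, 8, seed)
            sel = select_final_nlv(X, y, max_nlv=5)
            both_min = (np.argmin(sel.rmse_cv) == np.argmin(sel.jaggedness))
            if both_min:
                assert sel.chosen_nlv == sel.candidates[np.argmin(sel.rmse_cv)]
        assert sel is not None

    @given(st.integers(0, 200))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_matches_brute_force_enumeration(self, seed):
        X, y = random_problem(15, 8, seed)
        sel = select_final_nlv(X, y, max_nlv=5)
        rm = np.array([loo_rmse(X, y, j).rmse for j in range(1, 6)])
        J = np.array([jaggedness(pls_fit(X, y, j).beta) for j in range(1, 6)])
        rr = (rm - rm.min()) / (rm.max() - rm.min())
        jr = (J - J.min()) / (J.max() - J.min())
        assert sel.chosen_nlv == 1 + int(np.argmin(rr + jr))
        assert np.all((sel.rmse_r >= 0) & (sel.rmse_r <= 1))
        assert np.all((sel.jaggedness_r >= 0) & (sel.jaggedness_r <= 1))


class TestRunPipeline:
    def test_fdr_input_accepted_and_percentage_convention(self, coarse_params):
        from hyperchla import generate_dataset
        ds = generate_dataset(coarse_params)
        rl = preprocess_rl(ds.spectra)
        fdr = first_derivative(rl)
        res = run_ise_pls(fdr, ds.chl)
        assert res.summary["dataset"] == "FDR"
        n_sel = res.summary["n_selected_bands"]
        assert res.summary["selected_band_percentage"] == pytest.approx(
            round(100.0 * n_sel / fdr.n_bands, 1))
        assert res.wavelengths.size == n_sel

    def test_noise_monotonicity_of_final_rmse(self, coarse_params):
        # decreasing sensor noise should not degrade the final LOO RMSE
        # (matched seeds; small slack for sampling error)
        from dataclasses import replace
        from hyperchla import generate_dataset
        rmses = []
        for mult in (0.0, 0.02, 0.06):
            p = replace(coarse_params, noise_sd_multiplicative=mult,
                        noise_sd_additive=mult * 5e-3)
            ds = generate_dataset(p)
            res = run_ise_pls(preprocess_rl(ds.spectra), ds.chl)
            rmses.append(res.summary["validation_rmse"])
        assert rmses[0] <= rmses[1] * 1.10
        assert rmses[1] <= rmses[2] * 1.10
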