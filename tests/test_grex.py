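"""cis-window extraction, Elastic-Net / DPR oracles, CV regimes, imputation."""

import numpy as np
import pandas as pd
import pytest

import twaskit as tk
from twaskit.grex import (
    EqtlWeightSet,
    _standardize,
    _to_dosage_scale,
    evaluate_cv,
    extract_cis_window,
    fit_dpr,
    fit_enet,
    frame_to_weights,
    impute_grex,
    weights_to_frame,
)

from conftest import make_panel


# ---------------------------------------------------------------------------
# cis-window extraction
# ---------------------------------------------------------------------------

class TestCisWindow:
    GENE = {"gene_id": "G1", "chrom": "1", "start": 2_000_000, "end": 2_010_000}

    def make(self, positions, dosages=None, n=20):
        rng = np.random.default_rng(0)
        d = (
            dosages
            if dosages is not None
            else rng.binomial(2, 0.3, size=(n, len(positions))).astype(float)
        )
        return make_panel(d, pos=list(positions))

    def test_window_boundaries_inclusive(self):
        panel = self.make([999_999, 1_000_000, 3_010_000, 3_010_001])
        window, X = extract_cis_window(panel, self.GENE)
        assert window.variant_ids == ["v2", "v3"]
        assert window.window_start == 1_000_000
        assert window.window_end == 3_010_000

    def test_high_missing_variant_excluded(self):
        rng = np.random.default_rng(1)
        d = rng.binomial(2, 0.4, size=(20, 2)).astype(float)
        d[:6, 1] = np.nan  # missing rate 0.3 > 0.2
        panel = self.make([2_000_100, 2_000_200], dosages=d)
        window, X = extract_cis_window(panel, self.GENE)
        assert window.variant_ids == ["v1"]

    def test_remaining_missing_mean_imputed(self):
        d = np.array([[0.0], [1.0], [2.0], [np.nan], [1.0]])
        panel = self.make([2_000_100], dosages=d)
        _, X = extract_cis_window(panel, self.GENE)
        assert X[3, 0] == pytest.approx(1.0)

    def test_zero_survivors_marks_untrainable(self):
        panel = self.make([10, 20])  # far outside the window
        window, X = extract_cis_window(panel, self.GENE)
        assert window.variant_ids == [] and X.shape[1] == 0


# ---------------------------------------------------------------------------
# Elastic-Net
# ---------------------------------------------------------------------------

class TestElasticNet:
    def test_unpenalized_limit_matches_ols(self):
        rng = np.random.default_rng(0)
        X = rng.binomial(2, 0.3, size=(40, 5)).astype(float)
        e = X @ rng.normal(size=5) + rng.normal(size=40) * 0.1
        ws = fit_enet(X, e, lam=0.0)
        Xc = X - X.mean(axis=0)
        ols, *_ = np.linalg.lstsq(Xc, e - e.mean(), rcond=None)
        np.testing.assert_allclose(ws.weights, ols, atol=1e-8)

    @staticmethod
    def orthonormal_standardized_design(n=64, p=6, seed=1):
        """Columns with zero mean, unit std and X'X = nI.

        QR of a centered matrix keeps columns orthogonal to the ones vector,
        so fit_enet's internal standardization leaves the design unchanged.
        """
        rng = np.random.default_rng(seed)
        M = rng.normal(size=(n, p))
        M -= M.mean(axis=0)
        Q, _ = np.linalg.qr(M)
        return Q * np.sqrt(n)

    def test_lasso_soft_threshold_on_orthonormal_design(self):
        """α=1 on an orthonormal design gives sign(b)·max(|b|−λ, 0)."""
        n, p = 64, 6
        X = self.orthonormal_standardized_design(n, p)
        b = np.array([2.0, -1.5, 0.8, 0.1, -0.05, 0.0])
        e = X @ b
        lam = 0.3
        ws = fit_enet(X, e, lam=lam, l1_ratio=1.0)
        univariate = X.T @ (e - e.mean()) / n  # per-column OLS coefficient
        expected = np.sign(univariate) * np.maximum(np.abs(univariate) - lam, 0.0)
        np.testing.assert_allclose(ws.weights, expected, atol=1e-6)

    def test_pure_noise_selects_heavy_penalty(self):
        rng = np.random.default_rng(0)
        X = rng.binomial(2, 0.3, size=(8, 50)).astype(float)
        e = rng.normal(size=8)
        ws = fit_enet(X, e, seed=0)
        assert np.abs(ws.weights).max() < 0.05  # near-all-zero
        assert ws.penalty["lambda"] > 0.5  # CV pushed λ toward the grid top

    def test_alpha_cv_mode_searches_grid(self):
        rng = np.random.default_rng(2)
        X = rng.binomial(2, 0.3, size=(30, 8)).astype(float)
        e = X @ rng.normal(size=8) * 0.5 + rng.normal(size=30)
        ws = fit_enet(X, e, alpha_mode="cv", seed=0)
        assert 0.1 <= ws.penalty["alpha"] <= 0.9

    def test_fold_reduction_warns_below_n(self):
        rng = np.random.default_rng(3)
        X = rng.binomial(2, 0.4, size=(4, 3)).astype(float)
        e = rng.normal(size=4)
        with pytest.warns(UserWarning, match="reducing CV folds"):
            fit_enet(X, e, n_folds=5, seed=0)


# ---------------------------------------------------------------------------
# DPR
# ---------------------------------------------------------------------------

class TestDpr:
    def test_k1_collapses_to_ridge_at_fitted_ratio(self):
        rng = np.random.default_rng(5)
        n, p = 50, 10
        X = rng.binomial(2, 0.3, size=(n, p)).astype(float)
        e = X @ (rng.normal(size=p) * 0.3) + rng.normal(size=n)
        ws = fit_dpr(X, e, K=1, seed=0)
        lam = ws.penalty["sigma_e2"] * ws.penalty["prior_precision_mean"]
        Xs, _, sd = _standardize(X)
        ridge = np.linalg.solve(
            Xs.T @ Xs + lam * np.eye(p), Xs.T @ (e - e.mean())
        )
        np.testing.assert_allclose(ws.weights, _to_dosage_scale(ridge, sd), atol=1e-8)

    def test_pure_noise_shrinks_below_tenth_of_ols(self):
        rng = np.random.default_rng(7)
        n, p = 50, 10
        X = rng.binomial(2, 0.3, size=(n, p)).astype(float)
        e = rng.standard_normal(n)
        ws = fit_dpr(X, e, seed=0)
        Xs, _, sd = _standardize(X)
        ols, *_ = np.linalg.lstsq(Xs, e - e.mean(), rcond=None)
        w_std = ws.weights * np.where(sd > 0, sd, 1.0)
        assert np.linalg.norm(w_std) < 0.1 * np.linalg.norm(ols)

    def test_row_duplication_near_invariance(self):
        """Stacking the data twice preserves the weight profile (corr, scale)."""
        rng = np.random.default_rng(6)
        X = rng.binomial(2, 0.3, size=(50, 10)).astype(float)
        e = X @ (rng.normal(size=10) * 0.3) + rng.normal(size=50) * 0.5
        ws1 = fit_dpr(X, e, seed=0)
        ws2 = fit_dpr(np.vstack([X, X]), np.concatenate([e, e]), seed=0)
        assert np.corrcoef(ws1.weights, ws2.weights)[0, 1] > 0.99
        ratio = np.linalg.norm(ws2.weights) / np.linalg.norm(ws1.weights)
        assert 0.9 < ratio < 1.1

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(8)
        X = rng.binomial(2, 0.3, size=(20, 15)).astype(float)
        e = rng.normal(size=20)
        w1 = fit_dpr(X, e, seed=3).weights
        w2 = fit_dpr(X, e, seed=3).weights
        np.testing.assert_array_equal(w1, w2)

    def test_nonconvergence_flagged_not_raised(self):
        rng = np.random.default_rng(9)
        X = rng.binomial(2, 0.3, size=(10, 20)).astype(float)
        e = rng.normal(size=10)
        ws = fit_dpr(X, e, max_iter=2, seed=0)
        assert ws.penalty["converged"] is False
        assert np.all(np.isfinite(ws.weights))


# ---------------------------------------------------------------------------
# evaluate_cv
# ---------------------------------------------------------------------------

class TestEvaluateCv:
    def test_perfect_signal_nocv_r2_one(self):
        rng = np.random.default_rng(0)
        X = rng.binomial(2, 0.4, size=(30, 4)).astype(float)
        e = X @ np.array([1.0, -0.5, 0.25, 2.0])
        fitter = lambda Xa, ea: fit_enet(Xa, ea, lam=0.0)
        r2 = evaluate_cv(fitter, X, e, mode="nocv")
        assert r2 == pytest.approx(1.0, abs=1e-10)

    def test_null_cv_r2_near_zero(self):
        rng = np.random.default_rng(1)
        X = rng.binomial(2, 0.3, size=(500, 10)).astype(float)
        e = rng.normal(size=500)
        fitter = lambda Xa, ea: fit_enet(Xa, ea, lam=0.0)
        r2 = evaluate_cv(fitter, X, e, mode="cv5", seed=0)
        assert r2 < 0.05

    def test_in_sample_optimism_dominates_cv(self):
        """nocv R² ≥ cv5 R² for nearly all simulated genes."""
        rng = np.random.default_rng(2)
        wins = 0
        trials = 40
        for _ in range(trials):
            X = rng.binomial(2, 0.3, size=(30, 8)).astype(float)
            e = X @ (rng.normal(size=8) * 0.2) + rng.normal(size=30)
            fitter = lambda Xa, ea: fit_enet(Xa, ea, lam=0.05)
            nocv = evaluate_cv(fitter, X, e, mode="nocv")
            cv5 = evaluate_cv(fitter, X, e, mode="cv5", seed=1)
            wins += nocv >= cv5
        assert wins >= 0.95 * trials

    def test_loto_mode_runs(self):
        rng = np.random.default_rng(3)
        X = rng.binomial(2, 0.3, size=(8, 5)).astype(float)
        e = rng.normal(size=8)
        fitter = lambda Xa, ea: fit_dpr(Xa, ea, seed=0)
        r2 = evaluate_cv(fitter, X, e, mode="loto")
        assert 0.0 <= r2 <= 1.0

    def test_zero_variance_predictions_convention(self):
        X = np.zeros((10, 3))
        X[:, 0] = np.arange(10) % 2  # some variance in X but fit gives zeros
        e = np.random.default_rng(4).normal(size=10)
        fitter = lambda Xa, ea: EqtlWeightSet(
            gene_id="g", variant_ids=["a", "b", "c"], weights=np.zeros(3),
            model="ENET", cv_mode="nocv",
        )
        assert evaluate_cv(fitter, X, e, mode="nocv") == 0.0


# ---------------------------------------------------------------------------
# impute_grex
# ---------------------------------------------------------------------------

class TestImputeGrex:
    def panel(self):
        d = np.array(
            [[0.0, 1, 2], [1, 1, 0], [2, 0, 1], [0, 2, 2]], dtype=float
        )
        return make_panel(d)

    def ws(self, weights, gene="G1", vids=("v1", "v2", "v3")):
        return EqtlWeightSet(
            gene_id=gene, variant_ids=list(vids),
            weights=np.asarray(weights, float), model="DPR", cv_mode="nocv",
        )

    def test_zero_weights_zero_grex(self):
        grex = impute_grex([self.ws([0, 0, 0])], self.panel())
        assert np.allclose(grex.loc["G1"], 0.0)

    def test_single_unit_weight_reproduces_dosage(self):
        grex = impute_grex([self.ws([1.0], vids=["v2"])], self.panel())
        np.testing.assert_array_equal(
            grex.loc["G1"].to_numpy(), self.panel().dosages[:, 1]
        )

    def test_hand_computed_matrix_product(self):
        w1 = self.ws([0.5, -1.0, 0.0], gene="G1")
        w2 = self.ws([0.0, 2.0, 1.0], gene="G2")
        grex = impute_grex([w1, w2], self.panel())
        D = self.panel().dosages
        np.testing.assert_allclose(grex.loc["G1"], D @ [0.5, -1.0, 0.0])
        np.testing.assert_allclose(grex.loc["G2"], D @ [0.0, 2.0, 1.0])

    def test_linearity_in_weights(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=3)
        b = rng.normal(size=3)
        panel = self.panel()
        g_a = impute_grex([self.ws(a)], panel)
        g_b = impute_grex([self.ws(b)], panel)
        g_ab = impute_grex([self.ws(a + b)], panel)
        np.testing.assert_allclose(
            g_ab.to_numpy(), g_a.to_numpy() + g_b.to_numpy(), atol=1e-12
        )

    def test_missing_variant_dropped_with_warning(self):
        ws = self.ws([1.0, 1.0], vids=["v1", "absent"])
        with pytest.warns(UserWarning, match="absent"):
            grex = impute_grex([ws], self.panel())
        np.testing.assert_array_equal(
            grex.loc["G1"].to_numpy(), self.panel().dosages[:, 0]
        )

    def test_gene_with_all_variants_missing_excluded(self):
        ws = self.ws([1.0], vids=["nowhere"])
        with pytest.warns(UserWarning):
            grex = impute_grex([ws], self.panel())
        assert grex.empty

    def test_missing_test_dosage_mean_imputed(self):
        d = np.array([[0.0], [2.0], [np.nan], [1.0]])
        panel = make_panel(d)
        grex = impute_grex([self.ws([1.0], vids=["v1"])], panel)
        assert grex.loc["G1"].iloc[2] == pytest.approx(1.0)

    def test_weights_frame_round_trip(self):
        rng = np.random.default_rng(1)
        cfg = tk.SimulationConfig(
            n_ref=20, n_test=10, n_genes=2, snps_per_gene=5, he2=0.3, seed=2
        )
        ref, test, ann = tk.simulate_panel(cfg)
        expr, _ = tk.simulate_expression(ref, ann, cfg)
        ws = tk.train_all_genes(ref, expr, ann, model="DPR", seed=0)
        frame = weights_to_frame(ws)
        back = frame_to_weights(frame)
        g1 = impute_grex(ws, test)
        g2 = impute_grex(back, test)
        pd.testing.assert_frame_equal(g1, g2)


# ---------------------------------------------------------------------------
# Cross-model parameter recovery and coverage direction
# ---------------------------------------------------------------------------

def test_orientation_flip_between_panels_is_corrected():
    """A variant whose minor allele differs between panels imputes correctly."""
    variants = pd.DataFrame(
        {
            "variant_id": ["v1"], "chrom": ["1"], "pos": [100],
            "ref": ["A"], "alt": ["G"], "minor_allele": ["A"],  # flipped vs ref
        }
    )
    panel_test = tk.GenotypePanel(
        sample_ids=["s1", "s2"], variants=variants,
        dosages=np.array([[0.0], [2.0]]),
    )
    ws = EqtlWeightSet(
        gene_id="G1", variant_ids=["v1"], weights=np.array([1.0]),
        model="DPR", cv_mode="nocv",
        variants=pd.DataFrame(
            {"variant_id": ["v1"], "chrom": ["1"], "pos": [100],
             "minor_allele": ["G"]}
        ),
    )
    grex = impute_grex([ws], panel_test)
    # test dosage counts allele A; weight is per G allele → flipped to 2−d
    np.testing.assert_array_equal(grex.loc["G1"].to_numpy(), [2.0, 0.0])
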