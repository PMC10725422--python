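"""Stage 1 of the TWAS: per-gene cis-eQTL weight training and GReX imputation.

The expression-imputation model is E_g = X_train·w + ε over the SNPs within
±1 Mb of the gene body.  Two weight estimators are provided:

* Elastic-Net — (1/2n)‖e − Xw‖² + λ[(1−α)/2‖w‖² + α‖w‖₁], with λ chosen by
  k-fold CV over a log-spaced grid and α either fixed at 0.5 or grid-searched.
* Dirichlet-process regression (DPR) — a nonparametric Bayesian shrinkage
  model: effect sizes follow a scale mixture of normals whose mixing measure
  carries a truncated stick-breaking Dirichlet-process prior, fitted by
  coordinate-ascent variational inference.  Posterior-mean weights adapt the
  shrinkage profile to the (unknown) cis effect-size distribution, which is
  why it keeps more genes "predictable" than the Elastic-Net at very small
  reference sizes.

Imputation is the linear map GReX = X_test·ŵ on minor-allele dosages; weights
are trained on standardized columns and returned on the dosage scale so the
two stages compose.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln

from .genotypes import GenotypePanel, hwe_exact_test

logger = logging.getLogger(__name__)

CIS_FLANK = 1_000_000
USABLE_WEIGHT_EPS = 1e-8


@dataclass
class CisWindow:
    """±1 Mb cis window of one gene and its surviving member variants."""

    gene_id: str
    chrom: str
    window_start: int
    window_end: int
    variant_ids: list[str]


@dataclass
class EqtlWeightSet:
    """Trained cis-SNP weights for one gene, on the dosage scale."""

    gene_id: str
    variant_ids: list[str]
    weights: np.ndarray
    model: str  # "ENET" | "DPR"
    cv_mode: str  # "cv5" | "nocv"
    training_r2: float = np.nan
    penalty: dict = field(default_factory=dict)
    variants: pd.DataFrame | None = None  # chrom/pos/minor_allele metadata

    @property
    def usable(self) -> bool:
        """True when at least one weight is meaningfully nonzero."""
        return bool(len(self.weights)) and bool(
            (np.abs(self.weights) > USABLE_WEIGHT_EPS).any()
        )


# ---------------------------------------------------------------------------
# cis-window extraction
# ---------------------------------------------------------------------------

def extract_cis_window(
    panel: GenotypePanel,
    gene: pd.Series | dict,
    max_missing_rate: float = 0.2,
    maf_min: float = 0.01,
    hwe_alpha: float = 1e-4,
) -> tuple[CisWindow, np.ndarray]:
    """Cis-SNP dosages for one gene with training-time exclusions applied.

    The window is [max(1, start − 1 Mb), end + 1 Mb], 1-based inclusive on
    both ends.  SNPs with missing rate > 0.2, MAF < 0.01 or HWE exact-test
    p < 1e-4 are excluded from training; remaining missing dosages are
    mean-imputed per variant.  A gene with zero surviving cis-SNPs yields an
    empty window (untrainable), not an exception.
    """
    g = gene if isinstance(gene, dict) else gene.to_dict()
    chrom = str(g["chrom"])
    window_start = max(1, int(g["start"]) - CIS_FLANK)
    window_end = int(g["end"]) + CIS_FLANK

    v = panel.variants
    in_window = (
        (v["chrom"].astype(str) == chrom)
        & (v["pos"] >= window_start)
        & (v["pos"] <= window_end)
    ).to_numpy()
    idx = np.flatnonzero(in_window)
    X = panel.dosages[:, idx]

    keep = np.ones(len(idx), dtype=bool)
    n = panel.n_samples
    for j in range(len(idx)):
        col = X[:, j]
        obs = ~np.isnan(col)
        n_obs = int(obs.sum())
        if n - n_obs > max_missing_rate * n:
            keep[j] = False
            continue
        if n_obs == 0:
            keep[j] = False
            continue
        freq = np.nansum(col) / (2.0 * n_obs)
        maf = min(freq, 1.0 - freq)
        if maf < maf_min:
            keep[j] = False
            continue
        counts = (int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))
        if hwe_exact_test(*counts) < hwe_alpha:
            keep[j] = False
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.debug(
            "extract_cis_window(%s): excluded %d of %d cis-SNPs",
            g.get("gene_id", "?"),
            n_excluded,
            len(idx),
        )

    idx = idx[keep]
    X = panel.dosages[:, idx].copy()
    if X.size:
        col_mean = np.nanmean(X, axis=0)
        nan_pos = np.isnan(X)
        X[nan_pos] = np.take(col_mean, np.where(nan_pos)[1])
    window = CisWindow(
        gene_id=str(g["gene_id"]),
        chrom=chrom,
        window_start=window_start,
        window_end=window_end,
        variant_ids=v.loc[idx, "variant_id"].tolist(),
    )
    return window, X


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center and unit-scale columns; zero-variance columns stay zero."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    safe_sd = np.where(sd > 0, sd, 1.0)
    return (X - mean) / safe_sd, mean, sd


def _to_dosage_scale(w_std: np.ndarray, sd: np.ndarray) -> np.ndarray:
    return np.where(sd > 0, w_std / np.where(sd > 0, sd, 1.0), 0.0)


# ---------------------------------------------------------------------------
# Elastic-Net
# ---------------------------------------------------------------------------

ALPHA_GRID = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)


def fit_enet(
    X: np.ndarray,
    e: np.ndarray,
    gene_id: str = "",
    variant_ids: list[str] | None = None,
    alpha_mode: str = "fixed0.5",
    n_folds: int = 5,
    lam: float | None = None,
    l1_ratio: float | None = None,
    seed: int = 0,
) -> EqtlWeightSet:
    """Elastic-Net cis-eQTL weights.

    λ is selected by ``n_folds``-fold CV (mean-squared-error criterion) over
    scikit-learn's log-spaced grid unless ``lam`` pins it; α is 0.5 under
    ``fixed0.5``, grid-searched over {0.1, …, 0.9} under ``cv``, or pinned by
    ``l1_ratio`` (e.g. 1.0 for the lasso limit).  Columns are standardized
    internally and weights returned on the dosage scale.  ``lam=0`` reduces
    to ordinary least squares.
    """
    from sklearn.exceptions import ConvergenceWarning
    from sklearn.linear_model import ElasticNet, ElasticNetCV

    X = np.asarray(X, float)
    e = np.asarray(e, float)
    n, p = X.shape
    if n != len(e):
        raise ValueError("X rows and e length disagree")
    if n < 3:
        raise ValueError("need at least 3 samples to fit")
    Xs, _, sd = _standardize(X)
    ec = e - e.mean()

    if l1_ratio is not None:
        l1_ratios = [float(l1_ratio)]
    elif alpha_mode == "fixed0.5":
        l1_ratios = [0.5]
    elif alpha_mode == "cv":
        l1_ratios = list(ALPHA_GRID)
    else:
        raise ValueError(f"unknown alpha_mode {alpha_mode!r}")

    if lam is not None:
        if lam == 0:
            w_std, *_ = np.linalg.lstsq(Xs, ec, rcond=None)
            chosen = {"lambda": 0.0, "alpha": None}
        else:
            model = ElasticNet(
                alpha=lam, l1_ratio=l1_ratios[0], fit_intercept=True, max_iter=50_000
            )
            model.fit(Xs, ec)
            w_std = model.coef_
            chosen = {"lambda": float(lam), "alpha": l1_ratios[0]}
    else:
        folds = min(n_folds, n)
        if folds < n_folds:
            warnings.warn(
                f"only {n} samples: reducing CV folds from {n_folds} to {folds}"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model = ElasticNetCV(
                l1_ratio=l1_ratios,
                alphas=100,  # size of the log-spaced λ grid
                cv=folds,
                fit_intercept=True,
                max_iter=50_000,
                random_state=seed,
            )
            model.fit(Xs, ec)
        w_std = model.coef_
        chosen = {"lambda": float(model.alpha_), "alpha": float(model.l1_ratio_)}

    weights = _to_dosage_scale(np.asarray(w_std, float), sd)
    return EqtlWeightSet(
        gene_id=gene_id,
        variant_ids=variant_ids or [f"v{j}" for j in range(p)],
        weights=weights,
        model="ENET",
        cv_mode="cv5",
        penalty=chosen,
    )


# ---------------------------------------------------------------------------
# Dirichlet-process regression (variational)
# ---------------------------------------------------------------------------

def _psd_inv(A: np.ndarray) -> np.ndarray:
    """Inverse of a symmetric PSD matrix with escalating diagonal jitter."""
    scale = max(float(np.trace(A)) / len(A), 1.0)
    for jitter in (0.0, 1e-10, 1e-8, 1e-6, 1e-4):
        try:
            L = np.linalg.cholesky(A + jitter * scale * np.eye(len(A)))
            Linv = np.linalg.inv(L)
            return Linv.T @ Linv
        except np.linalg.LinAlgError:
            continue
    return np.linalg.pinv(A)


def fit_dpr(
    X: np.ndarray,
    e: np.ndarray,
    gene_id: str = "",
    variant_ids: list[str] | None = None,
    K: int = 4,
    tol: float = 1e-4,
    max_iter: int = 1000,
    seed: int = 0,
    dp_alpha: float = 1.0,
    ig_a: float = 1.0,
    ig_b: float = 1e-8,
) -> EqtlWeightSet:
    """Posterior-mean cis-eQTL weights under a DP scale-mixture prior.

    Model: e | w ~ N(Xw, σ_e²I); w_j | z_j=k ~ N(0, σ_k²); z_j ~ Cat(π(v))
    with truncated stick-breaking v_k ~ Beta(1, ``dp_alpha``) over ``K``
    components and an inverse-gamma(``ig_a``, ``ig_b``) base on each σ_k².
    Mean-field coordinate-ascent VI with a full-covariance Gaussian factor
    for w; σ_e² is point-updated.  Convergence when the relative change of
    the evidence lower bound falls below ``tol``; component responsibilities
    are initialized from a seeded Dirichlet draw, so the fit is deterministic
    given the seed.  With K=1 the posterior mean is exactly ridge regression
    at the fitted variance ratio.
    """
    X = np.asarray(X, float)
    e = np.asarray(e, float)
    n, p = X.shape
    if n != len(e):
        raise ValueError("X rows and e length disagree")
    if n < 3:
        raise ValueError("need at least 3 samples to fit")

    Xs, _, sd = _standardize(X)
    ec = e - e.mean()
    rng = np.random.default_rng(seed)

    XtX = Xs.T @ Xs
    Xte = Xs.T @ ec
    ete = float(ec @ ec)
    var_e = max(ete / n, 1e-12)

    # seeded initialization
    r = rng.dirichlet(np.ones(K), size=p)  # responsibilities q(z_j)
    sigma_e2 = var_e
    # spread initial component scales over decades around var(e)/p
    base = max(var_e / max(p, 1), 1e-10)
    e_inv_sigma2 = 1.0 / (base * np.logspace(-1, 1, K))  # E[1/σ_k²]
    e_log_sigma2 = -np.log(e_inv_sigma2)

    elbo_prev = -np.inf
    converged = False
    n_iter = 0
    I_p = np.eye(p)
    for n_iter in range(1, max_iter + 1):
        # q(w) = N(mu, Sigma)
        prior_prec = r @ e_inv_sigma2  # per-coordinate E[1/σ²_{z_j}]
        A = XtX / sigma_e2 + np.diag(prior_prec)
        Sigma = _psd_inv(A)
        mu = Sigma @ (Xte / sigma_e2)
        Ew2 = mu**2 + np.diag(Sigma)

        # q(σ_k²) inverse-gamma
        Nk = r.sum(axis=0)
        a_k = ig_a + 0.5 * Nk
        b_k = ig_b + 0.5 * (r * Ew2[:, None]).sum(axis=0)
        e_inv_sigma2 = a_k / b_k
        e_log_sigma2 = np.log(b_k) - digamma(a_k)

        # q(v_k) Beta (stick-breaking weights)
        if K > 1:
            tail = Nk[::-1].cumsum()[::-1]  # Σ_{l>=k} N_l
            g1 = 1.0 + Nk[:-1]
            g2 = dp_alpha + tail[1:]
            e_log_v = digamma(g1) - digamma(g1 + g2)
            e_log_1mv = digamma(g2) - digamma(g1 + g2)
            e_log_pi = np.concatenate([e_log_v, [0.0]])
            e_log_pi[1:] += np.cumsum(e_log_1mv)
        else:
            e_log_pi = np.zeros(1)

        # q(z)
        log_r = (
            e_log_pi[None, :]
            - 0.5 * e_log_sigma2[None, :]
            - 0.5 * Ew2[:, None] * e_inv_sigma2[None, :]
        )
        log_r -= log_r.max(axis=1, keepdims=True)
        r = np.exp(log_r)
        r /= r.sum(axis=1, keepdims=True)

        # MAP update of the noise variance under the same weak inverse-gamma
        # prior; keeps σ_e² bounded away from 0 when p ≥ n (interpolation)
        resid2 = ete - 2.0 * mu @ Xte + float(mu @ XtX @ mu) + float(np.sum(XtX * Sigma))
        sigma_e2 = max((ig_b + 0.5 * resid2) / (ig_a + 0.5 * n + 1.0), 1e-12)

        # ELBO (constants in the fixed hyperpriors dropped)
        sign, logdet = np.linalg.slogdet(Sigma)
        ll = -0.5 * n * np.log(2 * np.pi * sigma_e2) - 0.5 * resid2 / sigma_e2
        prior_w = (
            -0.5 * (r * (e_log_sigma2[None, :] + Ew2[:, None] * e_inv_sigma2[None, :])).sum()
            - 0.5 * p * np.log(2 * np.pi)
        )
        prior_z = float((r * e_log_pi[None, :]).sum())
        prior_sigma = float(
            np.sum(-(ig_a + 1.0) * e_log_sigma2 - ig_b * e_inv_sigma2)
        )
        ent_w = 0.5 * (logdet + p * (1.0 + np.log(2 * np.pi)))
        with np.errstate(divide="ignore", invalid="ignore"):
            ent_z = -float(np.nansum(r * np.log(np.where(r > 0, r, 1.0))))
        ent_sigma = float(
            np.sum(a_k + np.log(b_k) + gammaln(a_k) - (1.0 + a_k) * digamma(a_k))
        )
        elbo = ll + prior_w + prior_z + prior_sigma + ent_w + ent_z + ent_sigma
        if np.isfinite(elbo_prev):
            denom = max(abs(elbo_prev), 1.0)
            if abs(elbo - elbo_prev) / denom < tol:
                converged = True
                break
        elbo_prev = elbo

    if not converged:
        logger.warning("fit_dpr(%s): not converged after %d iterations", gene_id, n_iter)

    # refresh q(w) so the returned weights are consistent with the final
    # variational parameters (and, at K=1, exactly ridge at the fitted ratio)
    prior_prec = r @ e_inv_sigma2
    Sigma = _psd_inv(XtX / sigma_e2 + np.diag(prior_prec))
    mu = Sigma @ (Xte / sigma_e2)

    weights = _to_dosage_scale(mu, sd)
    return EqtlWeightSet(
        gene_id=gene_id,
        variant_ids=variant_ids or [f"v{j}" for j in range(p)],
        weights=weights,
        model="DPR",
        cv_mode="nocv",
        penalty={
            "K": K,
            "n_iter": n_iter,
            "converged": converged,
            "sigma_e2": float(sigma_e2),
            "prior_precision_mean": float(np.mean(r @ e_inv_sigma2)),
        },
    )


# ---------------------------------------------------------------------------
# Training-accuracy evaluation
# ---------------------------------------------------------------------------

def _squared_pearson(y: np.ndarray, yhat: np.ndarray) -> float:
    if np.std(yhat) == 0 or np.std(y) == 0:
        logger.debug("zero-variance predictions; training R² = 0 by convention")
        return 0.0
    return float(np.corrcoef(y, yhat)[0, 1] ** 2)


def evaluate_cv(
    model_fitter,
    X: np.ndarray,
    e: np.ndarray,
    mode: str = "cv5",
    n_folds: int = 5,
    seed: int = 0,
) -> float:
    """Training R² of a weight fitter under a chosen regime.

    ``cv5`` — squared Pearson correlation between observed expression and
    out-of-fold predictions from seeded k-fold splits.  ``nocv`` — squared
    correlation with in-sample fitted values after fitting on all samples.
    ``loto`` — rotational leave-two-out out-of-fold predictions (an
    alternative small-n regime some pipelines use).  ``model_fitter(X, e)``
    must return an :class:`EqtlWeightSet`.
    """
    from sklearn.model_selection import KFold

    X = np.asarray(X, float)
    e = np.asarray(e, float)
    n = len(e)
    if mode == "nocv":
        ws = model_fitter(X, e)
        return _squared_pearson(e, X @ ws.weights)
    if mode == "cv5":
        folds = min(n_folds, n)
        if folds < 2:
            raise ValueError("cv5 requires at least 2 samples")
        preds = np.zeros(n)
        kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
        for train_idx, test_idx in kf.split(X):
            ws = model_fitter(X[train_idx], e[train_idx])
            preds[test_idx] = X[test_idx] @ ws.weights
        return _squared_pearson(e, preds)
    if mode == "loto":
        if n < 3:
            raise ValueError("loto requires at least 3 samples")
        preds = np.zeros(n)
        counts = np.zeros(n)
        for start in range(0, n, 2):
            test_idx = np.arange(start, min(start + 2, n))
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            ws = model_fitter(X[train_idx], e[train_idx])
            preds[test_idx] += X[test_idx] @ ws.weights
            counts[test_idx] += 1
        preds /= np.maximum(counts, 1)
        return _squared_pearson(e, preds)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# GReX imputation
# ---------------------------------------------------------------------------

def impute_grex(
    weight_sets: list[EqtlWeightSet], panel_test: GenotypePanel
) -> pd.DataFrame:
    """GReX = X_test·ŵ per gene; genes × test samples.

    Weight variants absent from the test panel are dropped with a warning;
    a gene losing all its variants is excluded (reported).  Test missing
    dosages are mean-imputed from the test panel; dosage orientation is
    aligned by the recorded minor allele (a flipped variant contributes
    2 − d).
    """
    vid_index = {v: i for i, v in enumerate(panel_test.variants["variant_id"])}
    test_minor = dict(
        zip(panel_test.variants["variant_id"], panel_test.variants["minor_allele"])
    )
    D = panel_test.dosages.copy()
    if D.size:
        col_mean = np.nanmean(
            np.where(np.isnan(D), np.nan, D), axis=0
        )
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        nan_pos = np.isnan(D)
        D[nan_pos] = np.take(col_mean, np.where(nan_pos)[1])

    rows = []
    gene_ids = []
    n_dropped_total = 0
    for ws in weight_sets:
        weight_minor = None
        if ws.variants is not None and "minor_allele" in ws.variants.columns:
            weight_minor = dict(
                zip(ws.variants["variant_id"], ws.variants["minor_allele"])
            )
        cols = []
        w_kept = []
        n_dropped = 0
        for vid, w in zip(ws.variant_ids, ws.weights):
            j = vid_index.get(vid)
            if j is None:
                n_dropped += 1
                continue
            col = D[:, j]
            if weight_minor is not None and weight_minor[vid] != test_minor[vid]:
                col = 2.0 - col  # opposite orientation in the test panel
            cols.append(col)
            w_kept.append(w)
        if n_dropped:
            n_dropped_total += n_dropped
            warnings.warn(
                f"gene {ws.gene_id}: {n_dropped} weight variant(s) absent from "
                "test panel, dropped"
            )
        if not cols:
            logger.info("gene %s: all weight variants dropped; excluded", ws.gene_id)
            continue
        rows.append(np.column_stack(cols) @ np.asarray(w_kept))
        gene_ids.append(ws.gene_id)
    out = pd.DataFrame(
        np.array(rows) if rows else np.empty((0, panel_test.n_samples)),
        index=gene_ids,
        columns=panel_test.sample_ids,
    )
    out.index.name = "gene_id"
    return out


# ---------------------------------------------------------------------------
# Whole-panel training driver and weight I/O
# ---------------------------------------------------------------------------

def train_gene(
    panel_ref: GenotypePanel,
    expression: pd.DataFrame,
    gene: pd.Series | dict,
    model: str = "DPR",
    cv_mode: str = "nocv",
    seed: int = 0,
    **fit_kwargs,
) -> EqtlWeightSet | None:
    """Train one gene's weight set; None when the gene is untrainable."""
    g = gene if isinstance(gene, dict) else gene.to_dict()
    gene_id = str(g["gene_id"])
    if gene_id not in expression.index:
        return None
    window, X = extract_cis_window(panel_ref, g)
    if not window.variant_ids:
        return None
    e = expression.loc[gene_id].to_numpy(float)

    if model.upper() == "ENET":
        fitter = lambda Xa, ea: fit_enet(Xa, ea, seed=seed, **fit_kwargs)
    elif model.upper() == "DPR":
        fitter = lambda Xa, ea: fit_dpr(Xa, ea, seed=seed, **fit_kwargs)
    else:
        raise ValueError(f"unknown model {model!r}")

    ws = fitter(X, e)
    ws.gene_id = gene_id
    ws.variant_ids = window.variant_ids
    ws.cv_mode = cv_mode
    ws.training_r2 = evaluate_cv(fitter, X, e, mode=cv_mode, seed=seed)
    meta = panel_ref.variants.set_index("variant_id").loc[
        window.variant_ids, ["chrom", "pos", "minor_allele"]
    ]
    ws.variants = meta.reset_index()
    return ws


def train_all_genes(
    panel_ref: GenotypePanel,
    expression: pd.DataFrame,
    annotation: pd.DataFrame,
    model: str = "DPR",
    cv_mode: str = "nocv",
    seed: int = 0,
    **fit_kwargs,
) -> list[EqtlWeightSet]:
    out = []
    for _, gene in annotation.iterrows():
        ws = train_gene(
            panel_ref, expression, gene, model=model, cv_mode=cv_mode, seed=seed,
            **fit_kwargs,
        )
        if ws is not None:
            out.append(ws)
    return out


def weights_to_frame(weight_sets: list[EqtlWeightSet]) -> pd.DataFrame:
    """Long-format weight table, the exchange format between train and impute."""
    rows = []
    for ws in weight_sets:
        meta = (
            ws.variants.set_index("variant_id")
            if ws.variants is not None
            else None
        )
        for vid, w in zip(ws.variant_ids, ws.weights):
            chrom = pos = minor = None
            if meta is not None and vid in meta.index:
                chrom = meta.at[vid, "chrom"]
                pos = meta.at[vid, "pos"]
                minor = meta.at[vid, "minor_allele"]
            rows.append(
                {
                    "gene_id": ws.gene_id,
                    "variant_id": vid,
                    "chrom": chrom,
                    "pos": pos,
                    "minor_allele": minor,
                    "weight": w,
                    "model": ws.model,
                    "cv_mode": ws.cv_mode,
                    "training_r2": ws.training_r2,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "variant_id", "chrom", "pos", "minor_allele",
            "weight", "model", "cv_mode", "training_r2",
        ],
    )


def frame_to_weights(frame: pd.DataFrame) -> list[EqtlWeightSet]:
    """Inverse of :func:`weights_to_frame`."""
    out = []
    for gene_id, grp in frame.groupby("gene_id", sort=False):
        out.append(
            EqtlWeightSet(
                gene_id=gene_id,
                variant_ids=grp["variant_id"].tolist(),
                weights=grp["weight"].to_numpy(float),
                model=str(grp["model"].iloc[0]),
                cv_mode=str(grp["cv_mode"].iloc[0]),
                training_r2=float(grp["training_r2"].iloc[0]),
                variants=grp[["variant_id", "chrom", "pos", "minor_allele"]].reset_index(
                    drop=True
                ),
            )
        )
    return out
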