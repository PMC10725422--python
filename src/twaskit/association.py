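"""Stage 2: single-SNP GWAS and gene-level TWAS scans.

Both scans fit per-unit fixed-effect linear models with stratification
covariates — the first two coordinates of a classical MDS on genome-wide
identity-by-state distances — plus age at first calving (AFC) and birth
weight (bwt):

    GWAS:  y = β₀ + x·β₁ + C₁β₂ + C₂β₃ + AFC·β₄ + bwt·β₅ + e
    TWAS:  y = ηC + β·GReX_g + e        (identity link, H₀: β = 0)

Inference is a two-sided t-test on the unit coefficient with n − q degrees
of freedom.  Multiple-testing helpers (Bonferroni threshold, Benjamini-
Hochberg step-up) and the genomic-inflation factor λ_GC round out the scan
toolkit.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotypes import GenotypePanel

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Population stratification: IBS distances + classical MDS
# ---------------------------------------------------------------------------

def ibs_matrix(panel: GenotypePanel) -> np.ndarray:
    """Pairwise identity-by-state: mean of (2 − |d_i − d_j|)/2 over variants
    non-missing in both samples."""
    D = panel.dosages
    n = panel.n_samples
    valid = (~np.isnan(D)).astype(float)
    # indicator decomposition: |a-b| over {0,1,2} = (N01+N10+N12+N21) + 2(N02+N20)
    I = [np.where(np.nan_to_num(D, nan=-1.0) == g, 1.0, 0.0) for g in (0.0, 1.0, 2.0)]
    absdiff = (
        I[0] @ I[1].T + I[1] @ I[0].T + I[1] @ I[2].T + I[2] @ I[1].T
        + 2.0 * (I[0] @ I[2].T + I[2] @ I[0].T)
    )
    counts = valid @ valid.T
    with np.errstate(invalid="ignore", divide="ignore"):
        ibs = (2.0 * counts - absdiff) / (2.0 * counts)
    ibs[counts == 0] = np.nan
    return ibs


def compute_ibs_mds(panel: GenotypePanel, k: int = 2) -> pd.DataFrame:
    """Top-k classical (Torgerson) MDS coordinates of 1 − IBS distances.

    The squared-distance matrix is double-centered and eigendecomposed;
    coordinates are eigenvector columns scaled by the root eigenvalues.
    Sign convention: each component's largest-magnitude loading is positive.
    Fewer than k components are returned (with a warning) when positive
    eigenvalues run out.
    """
    if panel.n_samples < 3:
        raise ValueError("MDS needs at least 3 samples")
    dist = 1.0 - ibs_matrix(panel)
    dist = np.nan_to_num(dist, nan=0.0)
    np.fill_diagonal(dist, 0.0)
    n = dist.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (dist**2) @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > max(eigval.max(), 0) * 1e-12
    n_pos = int(pos.sum())
    k_eff = min(k, n_pos)
    if k_eff < k:
        warnings.warn(
            f"only {k_eff} positive MDS eigenvalue(s); returning {k_eff} components"
        )
    coords = np.zeros((n, k_eff))
    for c in range(k_eff):
        v = eigvec[:, c] * np.sqrt(eigval[c])
        if len(v) and v[np.argmax(np.abs(v))] < 0:
            v = -v
        coords[:, c] = v
    return pd.DataFrame(
        coords,
        index=panel.sample_ids,
        columns=[f"C{c + 1}" for c in range(k_eff)],
    )


# ---------------------------------------------------------------------------
# Per-unit linear-model scan core
# ---------------------------------------------------------------------------

def _drop_collinear(Z: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Greedily drop covariate columns until the design has full rank."""
    keep = list(range(Z.shape[1]))
    rank = np.linalg.matrix_rank(Z)
    while len(keep) > rank:
        for j in range(len(keep) - 1, 0, -1):  # never drop the intercept
            trial = keep[:j] + keep[j + 1:]
            if np.linalg.matrix_rank(Z[:, trial]) == rank:
                warnings.warn(f"dropping collinear covariate column {names[keep[j]]!r}")
                keep = trial
                break
        else:  # pragma: no cover - intercept-only designs are full rank
            break
    return Z[:, keep], [names[j] for j in keep]


def _scan(
    units: np.ndarray,
    unit_ids: list[str],
    chroms: list,
    positions: list,
    y: np.ndarray,
    covars: np.ndarray,
    covar_names: list[str],
) -> pd.DataFrame:
    """Shared per-unit OLS + t-test engine; units is (n_samples, n_units)."""
    n = len(y)
    Z = np.column_stack([np.ones(n), covars]) if covars.size else np.ones((n, 1))
    Z, _ = _drop_collinear(Z, ["intercept"] + covar_names)
    q = Z.shape[1] + 1  # + the unit column
    df = n - q
    if df < 1:
        raise ValueError(f"not enough samples ({n}) for {q} model parameters")

    # project out covariates once (Frisch–Waugh): the unit coefficient,
    # its SE and t are identical to the full multiple regression
    Qz, _ = np.linalg.qr(Z)
    y_r = y - Qz @ (Qz.T @ y)
    U_r = units - Qz @ (Qz.T @ units)

    uu = (U_r**2).sum(axis=0)
    zero_var = uu <= 1e-12 * n
    uu_safe = np.where(zero_var, 1.0, uu)
    beta = (U_r * y_r[:, None]).sum(axis=0) / uu_safe
    resid2 = (y_r**2).sum() - beta**2 * uu_safe
    resid2 = np.maximum(resid2, 0.0)
    sigma2 = resid2 / df
    se = np.sqrt(sigma2 / uu_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    pvals = 2.0 * sps.t.sf(np.abs(tstat), df)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)

    beta = np.where(zero_var, 0.0, beta)
    se = np.where(zero_var, np.nan, se)
    pvals = np.where(zero_var, 1.0, pvals)
    if zero_var.any():
        logger.info("%d zero-variance unit(s) flagged with p = 1", int(zero_var.sum()))

    out = pd.DataFrame(
        {
            "unit_id": unit_ids,
            "chrom": chroms,
            "pos": positions,
            "beta": beta,
            "se": se,
            "p": pvals,
            "zero_variance": zero_var,
        }
    )
    out = out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    out["p_bh"] = bh_adjust(out["p"].to_numpy())
    return out


def _align_pheno_covars(
    sample_ids: list[str],
    pheno: pd.DataFrame,
    covars: pd.DataFrame | None,
    trait: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Listwise-complete y, covariate matrix and sample mask, in panel order."""
    ph = pheno.set_index("sample_id")
    missing_samples = [s for s in sample_ids if s not in ph.index]
    if missing_samples:
        raise ValueError(f"phenotypes missing for samples: {missing_samples[:5]}...")
    cols = [trait] + [c for c in ("AFC", "bwt") if c in ph.columns]
    tab = ph.loc[list(sample_ids), cols].astype(float)
    covar_names = cols[1:]
    if covars is not None:
        cv = covars.loc[list(sample_ids)].astype(float)
        tab = pd.concat([tab, cv], axis=1)
        covar_names = covar_names + list(cv.columns)
    ok = ~tab.isna().any(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("dropping %d sample(s) with missing trait/covariates", n_dropped)
    tab = tab.loc[ok]
    y = tab[trait].to_numpy()
    C = tab[covar_names].to_numpy() if covar_names else np.empty((len(tab), 0))
    return y, C, ok.to_numpy(), covar_names


def gwas_scan(
    panel: GenotypePanel,
    pheno: pd.DataFrame,
    covars: pd.DataFrame | None,
    trait: str = "trait",
) -> pd.DataFrame:
    """Per-SNP additive-model scan with covariates.

    Missing dosages are mean-imputed for the scan; samples missing the trait
    or any covariate are dropped listwise.  Returns records sorted by
    (chrom, pos) with beta, se, p and BH-adjusted p.
    """
    y, C, mask, names = _align_pheno_covars(panel.sample_ids, pheno, covars, trait)
    D = panel.dosages[mask]
    if D.size:
        col_mean = np.nanmean(np.where(np.isnan(D), np.nan, D), axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        nan_pos = np.isnan(D)
        D[nan_pos] = np.take(col_mean, np.where(nan_pos)[1])
    return _scan(
        D,
        panel.variants["variant_id"].tolist(),
        panel.variants["chrom"].tolist(),
        panel.variants["pos"].tolist(),
        y,
        C,
        names,
    )


def twas_scan(
    grex: pd.DataFrame,
    pheno: pd.DataFrame,
    covars: pd.DataFrame | None,
    trait: str = "trait",
    annotation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-gene scan of phenotype on imputed GReX with covariates.

    ``grex`` is genes × samples.  Gene positions are reported at the gene
    midpoint when an annotation is supplied (for plotting); a constant GReX
    column (all weights zero) is flagged with p = 1.
    """
    sample_ids = list(grex.columns)
    y, C, mask, names = _align_pheno_covars(sample_ids, pheno, covars, trait)
    units = grex.to_numpy(float).T[mask]
    gene_ids = list(grex.index)
    if annotation is not None:
        ann = annotation.set_index("gene_id")
        chroms = [ann.at[g, "chrom"] if g in ann.index else "NA" for g in gene_ids]
        positions = [
            int((ann.at[g, "start"] + ann.at[g, "end"]) // 2) if g in ann.index else 0
            for g in gene_ids
        ]
    else:
        chroms = ["NA"] * len(gene_ids)
        positions = list(range(len(gene_ids)))
    return _scan(units, gene_ids, chroms, positions, y, C, names)


# ---------------------------------------------------------------------------
# Multiple testing and diagnostics
# ---------------------------------------------------------------------------

def bonferroni_threshold(alpha: float, m: int) -> float:
    """Genome-wide significance threshold alpha / m."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("number of tests must be at least 1")
    return alpha / m


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    nan_idx = np.flatnonzero(np.isnan(p))
    if len(nan_idx):
        raise ValueError(f"NaN p-value at index {nan_idx[0]}")
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def genomic_inflation(p_values) -> tuple[float, pd.DataFrame]:
    """Genomic-inflation factor λ_GC plus a QQ table.

    λ_GC is the median of the 1-d.f. χ² quantiles implied by the p-values,
    divided by the null χ²₁ median (≈ 0.4549).  The QQ table pairs expected
    and observed −log₁₀ p for plotting.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size < 10:
        raise ValueError("need at least 10 p-values for a stable λ_GC")
    if (p <= 0).any():
        warnings.warn("p = 0 entries clamped to the smallest positive float")
        p = np.clip(p, np.finfo(float).tiny, None)
    chi2 = sps.chi2.isf(p, df=1)
    lam = float(np.median(chi2) / sps.chi2.ppf(0.5, df=1))
    m = p.size
    obs = np.sort(p)
    expected = (np.arange(1, m + 1) - 0.5) / m
    qq = pd.DataFrame(
        {
            "expected_neglog10p": -np.log10(expected),
            "observed_neglog10p": -np.log10(obs),
        }
    )
    return lam, qq
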