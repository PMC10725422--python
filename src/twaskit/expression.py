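"""Expression normalization and confounder residualization.

Produces the continuous, approximately homoskedastic expression matrix the
cis-eQTL training model assumes: raw counts are scaled by median-of-ratios
size factors and log2-transformed, then each gene is residualized on
production-level (high/low yield) and collection-batch indicators.  A
pre-normalized matrix (e.g. an rLog table produced elsewhere) can be passed
straight to :func:`residualize`.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (genes × samples counts).

    Only genes with all-positive counts enter the geometric-mean reference.
    Raises if a sample has no positive ratio (undefined size factor).
    """
    if counts.shape[1] < 2:
        raise ValueError("size factor estimation needs at least 2 samples")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    positive = counts[(counts > 0).all(axis=1)]
    if positive.empty:
        raise ValueError("no gene with all-positive counts; size factors undefined")
    log_geo_mean = np.log(positive).mean(axis=1)
    ratios = np.log(positive).sub(log_geo_mean, axis=0)
    sf = np.exp(ratios.median(axis=0))
    bad = sf[~np.isfinite(sf) | (sf <= 0)]
    if len(bad):
        raise ValueError(f"undefined size factor for sample(s): {list(bad.index)}")
    return sf


def normalize_expression(raw_counts: pd.DataFrame) -> pd.DataFrame:
    """Size-factor-scaled log2 expression: log2(count / sf + 1).

    Genes with any zero count are kept in the output but excluded from
    size-factor estimation; an all-zero gene comes out as a row of zeros.
    """
    zero_samples = raw_counts.columns[(raw_counts == 0).all(axis=0)]
    if len(zero_samples):
        raise ValueError(
            f"sample(s) with all-zero counts: {list(zero_samples)}; "
            "size factor undefined"
        )
    sf = size_factors(raw_counts)
    normed = np.log2(raw_counts.div(sf, axis=1) + 1.0)
    normed.index.name = raw_counts.index.name or "gene_id"
    return normed


def _factor_design(factors: pd.DataFrame, sample_ids) -> np.ndarray:
    """Intercept + treatment-coded indicators for production level and batch.

    Rank-deficient designs (e.g. a factor confounded with another) are
    handled downstream by least squares on the column space; redundant
    columns are detected and logged here.
    """
    f = factors.set_index("sample_id").loc[list(sample_ids)]
    cols = [np.ones(len(f))]
    for name in ("production_level", "batch"):
        if name not in f.columns:
            continue
        levels = sorted(f[name].astype(str).unique())
        for lv in levels[1:]:  # first level is the baseline
            cols.append((f[name].astype(str) == lv).to_numpy(float))
    design = np.column_stack(cols)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        logger.info(
            "factor design rank-deficient (rank %d of %d columns); "
            "redundant columns absorbed by least squares",
            rank,
            design.shape[1],
        )
    return design


def residualize(expr: pd.DataFrame, factors: pd.DataFrame) -> pd.DataFrame:
    """Replace each gene's expression by residuals on the factor design.

    The design holds an intercept plus production-level and batch indicators,
    so residuals have zero mean per gene and are orthogonal to every factor
    column.  Idempotent.
    """
    missing = set(expr.columns) - set(factors["sample_id"])
    if missing:
        raise ValueError(f"factors missing for samples: {sorted(missing)}")
    design = _factor_design(factors, expr.columns)
    Y = expr.to_numpy(float).T  # samples × genes
    coef, *_ = np.linalg.lstsq(design, Y, rcond=None)
    resid = Y - design @ coef
    out = pd.DataFrame(resid.T, index=expr.index, columns=expr.columns)
    out.index.name = expr.index.name
    return out
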