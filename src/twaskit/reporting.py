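"""Comparison products of the GWAS/TWAS scans.

Plot-ready Manhattan tables, ranked top-hit tables with ±20 kb gene
neighborhoods, ±1.5 Mb TWAS hit windows, method-overlap (Venn) counts and
extreme-weight SNP extraction.  Everything is emitted as tables; rendering
is left to the caller.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .association import bh_adjust
from .grex import EqtlWeightSet

CHROM_GAP = 1_000_000
TOP_HIT_FLANK = 20_000
TWAS_WINDOW_HALF_WIDTH = 1_500_000


def _chrom_sort_key(c) -> tuple:
    s = str(c).replace("chr", "")
    return (0, int(s)) if s.isdigit() else (1, s)


def manhattan_table(results: pd.DataFrame, bonferroni_line: float) -> pd.DataFrame:
    """Cumulative-coordinate table for a Manhattan plot.

    Adds −log₁₀ p, a genome-wide cumulative coordinate (chromosomes laid end
    to end with a 1 Mb gap) and an above-threshold flag; the threshold is
    carried in ``df.attrs['bonferroni_line']``.
    """
    if results.empty:
        raise ValueError("empty association results")
    out = results.copy()
    out["neglog10p"] = -np.log10(out["p"])
    chroms = sorted(out["chrom"].unique(), key=_chrom_sort_key)
    offset = 0
    offsets = {}
    for c in chroms:
        offsets[c] = offset
        offset += int(out.loc[out["chrom"] == c, "pos"].max()) + CHROM_GAP
    out["cum_pos"] = out.apply(lambda r: offsets[r["chrom"]] + r["pos"], axis=1)
    out["above_threshold"] = out["p"] < bonferroni_line
    out.attrs["bonferroni_line"] = bonferroni_line
    return out


def annotate_neighbors(
    chrom, pos: int, annotation: pd.DataFrame, flank: int = TOP_HIT_FLANK
) -> list[str]:
    """Genes whose flanked interval [start − flank, end + flank] covers pos."""
    ann = annotation[annotation["chrom"].astype(str) == str(chrom)]
    hit = ann[(ann["start"] - flank <= pos) & (pos <= ann["end"] + flank)]
    return hit["gene_id"].tolist()


def top_hits(
    results: pd.DataFrame,
    n: int = 10,
    annotation: pd.DataFrame | None = None,
    flank: int = TOP_HIT_FLANK,
    fdr_scope: str = "all",
) -> pd.DataFrame:
    """Lowest-n-p units with neighbor genes and BH-adjusted p-values.

    ``fdr_scope='all'`` (default) reports the BH adjustment computed over the
    full result set; ``'top'`` re-adjusts within the selected top-n only — a
    statistically unusual convention retained as an opt-in to mirror
    top-ten-SNP FDR tables some studies print.  Ties in p are broken by
    (chrom, pos).
    """
    if results.empty:
        raise ValueError("empty association results")
    if fdr_scope not in ("all", "top"):
        raise ValueError("fdr_scope must be 'all' or 'top'")
    ranked = results.sort_values(
        ["p", "chrom", "pos"], kind="mergesort"
    ).head(n).copy()
    if fdr_scope == "top":
        ranked["p_bh"] = bh_adjust(ranked["p"].to_numpy())
    elif "p_bh" not in ranked.columns:
        ranked["p_bh"] = bh_adjust(results["p"].to_numpy())[ranked.index]
    if annotation is not None:
        known_chroms = set(annotation["chrom"].astype(str))
        missing = set(ranked["chrom"].astype(str)) - known_chroms
        if missing:
            import warnings

            warnings.warn(f"annotation lacks chromosome(s): {sorted(missing)}")
        ranked["neighbor_genes"] = [
            ",".join(annotate_neighbors(r.chrom, r.pos, annotation, flank))
            for r in ranked.itertuples()
        ]
    return ranked.reset_index(drop=True)


def twas_hit_window_genes(
    hit_gene_id: str,
    annotation: pd.DataFrame,
    half_width: int = TWAS_WINDOW_HALF_WIDTH,
) -> list[str]:
    """Genes whose midpoint lies within ±half_width of the hit gene midpoint.

    Same chromosome only; boundary inclusive; the hit gene itself included.
    """
    ann = annotation.copy()
    ann["midpoint"] = (ann["start"] + ann["end"]) // 2
    row = ann[ann["gene_id"] == hit_gene_id]
    if row.empty:
        raise ValueError(f"hit gene {hit_gene_id!r} not in annotation")
    chrom = str(row["chrom"].iloc[0])
    mid = int(row["midpoint"].iloc[0])
    sel = ann[
        (ann["chrom"].astype(str) == chrom)
        & (ann["midpoint"] >= mid - half_width)
        & (ann["midpoint"] <= mid + half_width)
    ]
    return sel["gene_id"].tolist()


def shared_gene_counts(top_lists: dict[str, set | list]) -> pd.DataFrame:
    """Venn-region cardinalities for a family of named gene sets.

    Each region is identified by the subset of set names whose members it
    belongs to exclusively; all 2^k − 1 regions are reported, plus pairwise
    intersection sizes for convenience.
    """
    if len(top_lists) < 2:
        raise ValueError("need at least 2 named sets")
    sets = {k: set(v) for k, v in top_lists.items()}
    names = list(sets)
    rows = []
    for r in range(1, len(names) + 1):
        for members in combinations(names, r):
            inside = set.intersection(*(sets[m] for m in members))
            outside = set().union(*(sets[m] for m in names if m not in members)) if r < len(names) else set()
            rows.append(
                {
                    "region": "&".join(members),
                    "n_sets": r,
                    "intersection_size": len(inside),
                    "exclusive_size": len(inside - outside),
                }
            )
    return pd.DataFrame(rows)


def top_weight_snps(weights: EqtlWeightSet) -> dict[str, tuple[str, float] | None]:
    """Most positive and most negative weight variants of one gene model.

    Ties are broken by genomic position (earlier wins) when position metadata
    is available, else by variant order.  All-zero weights yield empty slots.
    """
    w = np.asarray(weights.weights, float)
    if len(w) == 0 or not weights.usable:
        import warnings

        warnings.warn(f"gene {weights.gene_id}: no nonzero weights")
        return {"most_positive": None, "most_negative": None}

    if weights.variants is not None and "pos" in weights.variants.columns:
        pos = weights.variants.set_index("variant_id").loc[
            weights.variant_ids, "pos"
        ].to_numpy()
    else:
        pos = np.arange(len(w))

    def _pick(candidates: np.ndarray) -> tuple[str, float]:
        best = candidates[np.argsort(pos[candidates], kind="mergesort")[0]]
        return weights.variant_ids[best], float(w[best])

    out: dict[str, tuple[str, float] | None] = {
        "most_positive": None,
        "most_negative": None,
    }
    pos_idx = np.flatnonzero(w == w.max())
    neg_idx = np.flatnonzero(w == w.min())
    if w.max() > 0:
        out["most_positive"] = _pick(pos_idx)
    if w.min() < 0:
        out["most_negative"] = _pick(neg_idx)
    return out
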