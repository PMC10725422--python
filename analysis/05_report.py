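#!/usr/bin/env python
"""Comparison products: Manhattan tables, top-10 hits, windows, overlaps.

For the GWAS and each TWAS model: a plot-ready Manhattan table and a top-10
table with BH-adjusted p-values and genes within ±20 kb of each hit.  For
the best TWAS gene: all genes whose midpoint lies within ±1.5 Mb (the
candidate window exported for pathway enrichment) and its extreme-weight
cis-SNPs.  Finally, the method-overlap (Venn) counts of the top-10 neighbor
gene sets across all methods.

Writes tables under results/report/.
"""

from pathlib import Path

import pandas as pd

import twaskit as tk
from twaskit.grex import frame_to_weights

ROOT = Path(__file__).resolve().parents[1] / "results"
MODELS = ["dpr_nocv", "dpr_cv5", "enet_nocv", "enet_cv5"]


def main() -> None:
    out = ROOT / "report"
    out.mkdir(parents=True, exist_ok=True)
    ann = tk.read_annotation(ROOT / "data" / "genes.tsv")

    top_gene_sets: dict[str, set] = {}

    scans = [("gwas", ROOT / "assoc" / "gwas.tsv")] + [
        (f"twas_{tag}", ROOT / "assoc" / f"twas_{tag}.tsv") for tag in MODELS
    ]
    for name, path in scans:
        res = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        line = tk.bonferroni_threshold(0.05, len(res))
        tk.manhattan_table(res, line).to_csv(
            out / f"manhattan_{name}.tsv", sep="\t", index=False, float_format="%.6g"
        )
        top = tk.top_hits(res, n=10, annotation=ann)
        top.to_csv(out / f"top10_{name}.tsv", sep="\t", index=False, float_format="%.6g")
        neighbors = set()
        for cell in top["neighbor_genes"]:
            neighbors.update(g for g in str(cell).split(",") if g and g != "nan")
        if name.startswith("twas"):
            neighbors.update(top["unit_id"])
        top_gene_sets[name] = neighbors
        print(f"{name}: top hit {top['unit_id'].iloc[0]} "
              f"(p = {top['p'].iloc[0]:.3g}, BH = {top['p_bh'].iloc[0]:.3g})")

    # candidate window and extreme-weight SNPs around the lead DPR TWAS gene
    lead = pd.read_csv(out / "top10_twas_dpr_nocv.tsv", sep="\t")["unit_id"].iloc[0]
    window_genes = tk.twas_hit_window_genes(lead, ann)
    pd.DataFrame({"gene_id": window_genes}).to_csv(
        out / "lead_gene_window.tsv", sep="\t", index=False
    )
    print(f"lead TWAS gene {lead}: {len(window_genes)} genes within ±1.5 Mb")

    weights = frame_to_weights(
        pd.read_csv(ROOT / "train" / "weights_dpr_nocv.tsv", sep="\t",
                    dtype={"chrom": str})
    )
    lead_ws = next(ws for ws in weights if ws.gene_id == lead)
    extremes = tk.top_weight_snps(lead_ws)
    rows = [
        {"direction": d, "variant_id": v[0], "weight": v[1]}
        for d, v in extremes.items()
        if v is not None
    ]
    pd.DataFrame(rows).to_csv(
        out / "lead_gene_extreme_weight_snps.tsv", sep="\t", index=False,
        float_format="%.6g",
    )
    for row in rows:
        print(f"  {row['direction']}: {row['variant_id']} ({row['weight']:+.4f})")

    venn = tk.shared_gene_counts(top_gene_sets)
    venn.to_csv(out / "method_overlap.tsv", sep="\t", index=False)
    gwas_vs_dpr = venn.set_index("region").at["gwas&twas_dpr_nocv", "intersection_size"]
    print(f"genes shared between GWAS and DPR-TWAS top-10 neighborhoods: {gwas_vs_dpr}")


if __name__ == "__main__":
    main()
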