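"""End-to-end driver: simulate → QC → train → impute → scan → report.

One call reproduces the whole study design on synthetic data and writes the
result tables as TSV.  Deterministic: the same config and seed produce
byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .association import (
    bonferroni_threshold,
    compute_ibs_mds,
    gwas_scan,
    twas_scan,
)
from .genotypes import QcProfile, apply_qc_profile
from .grex import impute_grex, train_all_genes, weights_to_frame
from .reporting import top_hits
from .simulate import (
    SimulationConfig,
    assign_sample_factors,
    simulate_expression,
    simulate_panel,
    simulate_phenotypes,
)
from .expression import residualize

FLOAT_FORMAT = "%.10g"


def run_pipeline(
    config: SimulationConfig,
    out_dir: str | Path,
    model: str = "DPR",
    cv_mode: str = "nocv",
    alpha: float = 0.05,
) -> dict[str, Path]:
    """Run the full two-stage study on one simulated dataset.

    Writes ``weights.tsv``, ``grex.tsv``, ``twas.tsv``, ``gwas.tsv``,
    ``twas_top10.tsv``, ``gwas_top10.tsv`` and ``qc_report.tsv`` under
    ``out_dir`` and returns the path map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    panel_ref, panel_test, annotation = simulate_panel(config)
    expr, truths = simulate_expression(panel_ref, annotation, config)
    factors = assign_sample_factors(config, panel_ref.sample_ids)
    expr = residualize(expr, factors)
    pheno = simulate_phenotypes(truths, panel_test, config)

    ref_qc, _ = apply_qc_profile(panel_ref, QcProfile.set1())
    test_set2, report = apply_qc_profile(panel_test, QcProfile.set2())

    weight_sets = train_all_genes(
        panel_ref=ref_qc,
        expression=expr,
        annotation=annotation,
        model=model,
        cv_mode=cv_mode,
        seed=config.seed,
    )
    grex = impute_grex(weight_sets, panel_test)

    covars = compute_ibs_mds(test_set2, k=2)
    twas = twas_scan(grex, pheno, covars, trait="trait", annotation=annotation)
    gwas = gwas_scan(test_set2, pheno, covars, trait="trait")

    twas["bonferroni_significant"] = twas["p"] < bonferroni_threshold(alpha, len(twas))
    gwas["bonferroni_significant"] = gwas["p"] < bonferroni_threshold(alpha, len(gwas))

    paths = {
        "weights": out / "weights.tsv",
        "grex": out / "grex.tsv",
        "twas": out / "twas.tsv",
        "gwas": out / "gwas.tsv",
        "twas_top10": out / "twas_top10.tsv",
        "gwas_top10": out / "gwas_top10.tsv",
        "qc_report": out / "qc_report.tsv",
    }
    weights_to_frame(weight_sets).to_csv(
        paths["weights"], sep="\t", index=False, float_format=FLOAT_FORMAT
    )
    grex.to_csv(paths["grex"], sep="\t", float_format=FLOAT_FORMAT)
    twas.to_csv(paths["twas"], sep="\t", index=False, float_format=FLOAT_FORMAT)
    gwas.to_csv(paths["gwas"], sep="\t", index=False, float_format=FLOAT_FORMAT)
    top_hits(twas, n=10, annotation=annotation).to_csv(
        paths["twas_top10"], sep="\t", index=False, float_format=FLOAT_FORMAT
    )
    top_hits(gwas, n=10, annotation=annotation).to_csv(
        paths["gwas_top10"], sep="\t", index=False, float_format=FLOAT_FORMAT
    )
    report.to_frame().to_csv(paths["qc_report"], sep="\t", index=False)
    return paths
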