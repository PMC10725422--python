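"""Synthetic genotype / expression / phenotype generator.

Emulates the data structure of a small-herd dairy TWAS: a reference panel
with both genotypes and mammary-transcriptome expression (default 8 animals),
a larger genotyped-only test panel (default 136), biallelic SNPs in
Hardy-Weinberg proportions with a configurable MAF spectrum and missingness,
per-gene cis architecture E_g = X·w + ε with configurable expression
heritability, and quantitative phenotypes driven by genetically regulated
expression (GReX) plus age-at-first-calving and birth-weight covariates.

Defaults mirror the study design the package targets: 8 reference / 136 test
samples and expression heritability within the 0.04–0.2 band where TWAS is
expected to out-power single-SNP GWAS.  Everything is deterministic under a
fixed seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypePanel

GENE_LENGTH = 10_000
CIS_FLANK = 1_000_000
# gene spacing > 2*CIS_FLANK + GENE_LENGTH keeps ±1 Mb windows disjoint
GENE_SPACING = 2 * CIS_FLANK + GENE_LENGTH + 90_000


@dataclass
class SimulationConfig:
    """All knobs of the generator; one config + seed fixes every output bit.

    ``he2`` is the fraction of per-gene expression variance explained by
    cis-genotypes; ``pi_causal`` the fraction of cis-SNPs per gene with a
    nonzero weight.  ``beta_trait`` (trait units per expression unit) may be
    a scalar, applied to every gene, or a per-gene sequence.  AFC is in
    months, birth weight in kg; their phenotype effects are in trait units
    per unit covariate.
    """

    n_ref: int = 8
    n_test: int = 136
    n_genes: int = 20
    snps_per_gene: int = 20
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    he2: float = 0.15
    pi_causal: float = 0.25
    beta_trait: float | Sequence[float] = 0.5
    covariate_effects: tuple[float, float] = (-5.0, 10.0)  # (AFC, bwt)
    afc_mean: float = 40.0
    afc_sd: float = 4.0
    bwt_mean: float = 33.0
    bwt_sd: float = 3.0
    batch_effect_sd: float = 0.0
    n_batches: int = 2
    noise_sd: float = 1.0
    n_chromosomes: int = 2
    overlap_windows: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range {self.maf_range} must lie in (0, 0.5]")
        if not 0.0 <= self.he2 < 1.0:
            raise ValueError("he2 must be in [0, 1)")
        if not 0.0 < self.pi_causal <= 1.0:
            raise ValueError("pi_causal must be in (0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_ref < 2:
            raise ValueError("n_ref must be at least 2")
        if self.snps_per_gene < 1:
            raise ValueError("snps_per_gene must be at least 1")
        if self.n_genes < 0:
            raise ValueError("n_genes must be nonnegative")

    def beta_vector(self) -> np.ndarray:
        b = np.asarray(self.beta_trait, dtype=float)
        if b.ndim == 0:
            return np.full(self.n_genes, float(b))
        if b.shape != (self.n_genes,):
            raise ValueError("beta_trait sequence length must equal n_genes")
        return b


@dataclass
class TruthRecord:
    """Generative ground truth for one gene."""

    gene_id: str
    variant_ids: list[str]
    true_weights: np.ndarray  # dosage-scale effect sizes, post he2-scaling
    causal_flag: np.ndarray  # bool per cis-SNP
    true_grex_ref: np.ndarray  # per reference sample
    raw_weight_scale: float  # multiplier mapping unscaled N(0,1) draws to true_weights
    minor_alleles: list[str] = field(default_factory=list)  # dosage orientation of true_weights


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    """Independent deterministic stream per simulation stage."""
    h = hashlib.sha256(f"{config.seed}:{stream}".encode()).digest()
    return np.random.default_rng(int.from_bytes(h[:4], "little"))


def make_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Gene coordinates on 1–2 synthetic chromosomes.

    By default genes are spaced so that their ±1 Mb cis windows do not
    overlap; ``overlap_windows`` packs them closer for stress tests.
    """
    spacing = GENE_SPACING if not config.overlap_windows else CIS_FLANK // 2
    rows = []
    per_chrom = -(-config.n_genes // max(config.n_chromosomes, 1)) if config.n_genes else 0
    for g in range(config.n_genes):
        chrom = f"{g // per_chrom + 1}" if per_chrom else "1"
        rank = g % per_chrom if per_chrom else 0
        start = CIS_FLANK + 1 + rank * spacing
        rows.append(
            {
                "gene_id": f"G{g + 1:04d}",
                "chrom": chrom,
                "start": start,
                "end": start + GENE_LENGTH - 1,
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def _simulate_dosages(
    rng: np.random.Generator, n: int, freqs: np.ndarray
) -> np.ndarray:
    """HWE genotypes: two independent allele draws per sample and site."""
    return rng.binomial(2, freqs[None, :], size=(n, len(freqs))).astype(float)


def simulate_panel(
    config: SimulationConfig,
) -> tuple[GenotypePanel, GenotypePanel, pd.DataFrame]:
    """Simulate reference and test genotype panels sharing one variant list.

    Each gene carries ``snps_per_gene`` biallelic SNPs placed uniformly in its
    ±1 Mb cis window; per-variant allele frequencies are uniform on
    ``maf_range`` and genotypes are two independent allele draws (HWE).
    Missing entries are masked at ``missing_rate`` independently per panel.
    Dosages count the simulated minor allele (the alternate allele, whose
    population frequency is ≤ 0.5 by construction).
    """
    ann = make_annotation(config)
    rng = _rng(config, "panel")
    bases = np.array(["A", "C", "G", "T"])

    var_rows = []
    freqs = []
    for rec in ann.itertuples():
        window_start = max(1, rec.start - CIS_FLANK)
        window_end = rec.end + CIS_FLANK
        pos = np.sort(
            rng.choice(
                np.arange(window_start, window_end + 1),
                size=config.snps_per_gene,
                replace=False,
            )
        )
        for j, p in enumerate(pos):
            ref, alt = rng.choice(4, size=2, replace=False)
            var_rows.append(
                {
                    "variant_id": f"{rec.gene_id}_snp{j + 1:03d}",
                    "chrom": rec.chrom,
                    "pos": int(p),
                    "ref": bases[ref],
                    "alt": bases[alt],
                }
            )
        freqs.append(rng.uniform(config.maf_range[0], config.maf_range[1], config.snps_per_gene))
    variants = pd.DataFrame(
        var_rows, columns=["variant_id", "chrom", "pos", "ref", "alt"]
    )
    if len(variants):
        variants["minor_allele"] = variants["alt"]
        order = variants.sort_values(["chrom", "pos"], kind="mergesort").index.to_numpy()
    else:
        variants["minor_allele"] = pd.Series(dtype=str)
        order = np.array([], dtype=int)
    freq = np.concatenate(freqs) if freqs else np.array([])
    variants = variants.loc[order].reset_index(drop=True)
    freq = freq[order] if len(order) else freq

    panels = []
    for tag, n in (("ref", config.n_ref), ("test", config.n_test)):
        complete = _simulate_dosages(_rng(config, f"dosage-{tag}"), n, freq)
        dosages = complete.copy()
        if config.missing_rate > 0:
            mask = _rng(config, f"missing-{tag}").random(dosages.shape) < config.missing_rate
            dosages[mask] = np.nan
        # orient to each panel's own empirical minor allele, exactly as the
        # VCF reader would (ties at 0.5 -> alternate allele is minor)
        pv = variants.copy()
        if len(pv):
            import warnings as _warnings

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", RuntimeWarning)
                alt_freq = np.nanmean(dosages, axis=0) / 2.0
            minor_is_alt = ~(alt_freq > 0.5)
            minor_is_alt[np.isnan(alt_freq)] = True
            dosages = np.where(minor_is_alt[None, :], dosages, 2.0 - dosages)
            complete = np.where(minor_is_alt[None, :], complete, 2.0 - complete)
            pv["minor_allele"] = np.where(minor_is_alt, pv["alt"], pv["ref"])
        panels.append(
            GenotypePanel(
                sample_ids=[f"{tag}{s + 1:03d}" for s in range(n)],
                variants=pv,
                dosages=dosages,
                complete_dosages=complete,
            )
        )
    return panels[0], panels[1], ann


def assign_sample_factors(config: SimulationConfig, sample_ids: list[str]) -> pd.DataFrame:
    """Production-level and batch labels for the reference samples.

    Mirrors a herd split into high and low yielders plus a collection-batch
    label; deterministic round-robin assignment.
    """
    n = len(sample_ids)
    production = ["high" if i < (n + 1) // 2 else "low" for i in range(n)]
    batch = [f"b{i % config.n_batches + 1}" for i in range(n)]
    return pd.DataFrame(
        {"sample_id": sample_ids, "production_level": production, "batch": batch}
    )


def simulate_expression(
    panel_ref: GenotypePanel,
    annotation: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, list[TruthRecord]]:
    """Per-gene expression E_g = X·w + ε with variance fraction he2 genetic.

    For each gene, ``round(pi_causal · snps_per_gene)`` cis-SNPs get standard
    normal raw weights, rescaled so the empirical variance of X·w across the
    reference panel is ``he2`` of a unit total; noise makes up the rest.  An
    optional per-(gene, batch) shift of scale ``batch_effect_sd`` is added.
    Ground-truth dosages (pre-missingness) drive the generative step.

    Returns an expression matrix (genes × samples) and per-gene truth records.
    """
    rng = _rng(config, "expression")
    X_all = (
        panel_ref.complete_dosages
        if panel_ref.complete_dosages is not None
        else panel_ref.dosages
    )
    factors = assign_sample_factors(config, panel_ref.sample_ids)
    batch_codes = factors["batch"].to_numpy()

    expr_rows = []
    truths: list[TruthRecord] = []
    for rec in annotation.itertuples():
        in_gene = panel_ref.variants["variant_id"].str.startswith(f"{rec.gene_id}_")
        idx = np.flatnonzero(in_gene.to_numpy())
        if len(idx) == 0:
            raise ValueError(f"gene {rec.gene_id} has zero cis-SNPs in the panel")
        X = X_all[:, idx]
        p = len(idx)
        n_causal = int(round(config.pi_causal * p))
        causal = np.zeros(p, dtype=bool)
        causal[rng.choice(p, size=n_causal, replace=False)] = True
        w_raw = np.where(causal, rng.standard_normal(p), 0.0)
        scale = 0.0
        if config.he2 > 0 and n_causal > 0:
            g_raw = X @ w_raw
            var_raw = g_raw.var()
            if var_raw > 0:
                scale = np.sqrt(config.he2 / var_raw)
        w = w_raw * scale
        if scale == 0.0:
            w = np.zeros(p)
            causal = causal & (scale != 0.0)
        genetic = X @ w
        noise = rng.standard_normal(X.shape[0]) * np.sqrt(max(1.0 - config.he2, 0.0))
        e = genetic + noise
        if config.batch_effect_sd > 0:
            shifts = {
                b: rng.normal(0.0, config.batch_effect_sd)
                for b in sorted(set(batch_codes))
            }
            e = e + np.array([shifts[b] for b in batch_codes])
        expr_rows.append(e)
        truths.append(
            TruthRecord(
                gene_id=rec.gene_id,
                variant_ids=panel_ref.variants.loc[idx, "variant_id"].tolist(),
                true_weights=w,
                causal_flag=causal,
                true_grex_ref=genetic,
                raw_weight_scale=float(scale),
                minor_alleles=panel_ref.variants.loc[idx, "minor_allele"].tolist(),
            )
        )
    expr = pd.DataFrame(
        np.array(expr_rows) if expr_rows else np.empty((0, panel_ref.n_samples)),
        index=annotation["gene_id"].tolist(),
        columns=panel_ref.sample_ids,
    )
    expr.index.name = "gene_id"
    return expr, truths


def true_grex_matrix(
    truths: list[TruthRecord], panel: GenotypePanel
) -> pd.DataFrame:
    """Ground-truth GReX (X·w_true) of a panel, genes × samples."""
    X_all = panel.complete_dosages if panel.complete_dosages is not None else panel.dosages
    vid_index = {v: i for i, v in enumerate(panel.variants["variant_id"])}
    panel_minor = dict(
        zip(panel.variants["variant_id"], panel.variants["minor_allele"])
    )
    rows = []
    for t in truths:
        try:
            idx = [vid_index[v] for v in t.variant_ids]
        except KeyError as exc:
            raise ValueError(
                f"gene {t.gene_id}: variant {exc.args[0]} absent from panel"
            ) from exc
        X = X_all[:, idx]
        X = np.where(np.isnan(X), np.nanmean(X, axis=0), X)
        if t.minor_alleles:  # align dosage orientation to the truth's
            flip = np.array(
                [panel_minor[v] != m for v, m in zip(t.variant_ids, t.minor_alleles)]
            )
            X = np.where(flip[None, :], 2.0 - X, X)
        rows.append(X @ t.true_weights)
    out = pd.DataFrame(
        np.array(rows) if rows else np.empty((0, panel.n_samples)),
        index=[t.gene_id for t in truths],
        columns=panel.sample_ids,
    )
    out.index.name = "gene_id"
    return out


def simulate_phenotypes(
    truths: list[TruthRecord],
    panel_test: GenotypePanel,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Quantitative trait for the test panel.

    y = Σ_g β_g · GReX_g(test) + β_AFC·AFC + β_bwt·bwt + N(0, noise_sd²),
    with AFC and birth weight drawn from the configured normals.  Reference
    samples carry expression, not traits, so only test samples get phenotypes.
    """
    if not truths:
        raise ValueError("at least one gene truth record required")
    beta = config.beta_vector()
    if len(beta) != len(truths):
        raise ValueError(
            f"beta_trait length {len(beta)} does not match {len(truths)} genes"
        )
    grex = true_grex_matrix(truths, panel_test)
    rng = _rng(config, "phenotype")
    n = panel_test.n_samples
    afc = rng.normal(config.afc_mean, config.afc_sd, n)
    bwt = rng.normal(config.bwt_mean, config.bwt_sd, n)
    genetic = beta @ grex.to_numpy()
    c_afc, c_bwt = config.covariate_effects
    y = genetic + c_afc * afc + c_bwt * bwt + rng.normal(0.0, config.noise_sd, n)
    return pd.DataFrame(
        {
            "sample_id": panel_test.sample_ids,
            "trait": y,
            "AFC": afc,
            "bwt": bwt,
        }
    )


# ---------------------------------------------------------------------------
# Fixture output
# ---------------------------------------------------------------------------

_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Write a panel as a minimal VCF 4.2 with GT fields.

    Genotypes are emitted as unphased alt-allele counts, reconstructed from
    the minor-allele dosages via the stored orientation; missing dosage
    becomes ``./.``.  Output bytes are a pure function of the panel.
    """
    path = Path(path)
    gt_for_alt = {0: "0/0", 1: "0/1", 2: "1/1"}
    lines = [_VCF_HEADER]
    contigs = list(dict.fromkeys(panel.variants["chrom"].astype(str)))
    for c in contigs:
        lines.append(f"##contig=<ID={c}>\n")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(panel.sample_ids)
        + "\n"
    )
    minor_is_alt = (
        panel.variants["minor_allele"].to_numpy() == panel.variants["alt"].to_numpy()
    )
    for j, rec in enumerate(panel.variants.itertuples()):
        dos = panel.dosages[:, j]
        alt_counts = dos if minor_is_alt[j] else 2.0 - dos
        gts = "\t".join(
            "./." if np.isnan(a) else gt_for_alt[int(a)] for a in alt_counts
        )
        lines.append(
            f"{rec.chrom}\t{rec.pos}\t{rec.variant_id}\t{rec.ref}\t{rec.alt}"
            f"\t.\tPASS\t.\tGT\t{gts}\n"
        )
    path.write_text("".join(lines))


def write_fixtures(
    panel_ref: GenotypePanel,
    panel_test: GenotypePanel,
    annotation: pd.DataFrame,
    expression: pd.DataFrame,
    phenotypes: pd.DataFrame,
    out_dir: str | Path,
    factors: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Emit the full fixture set as plain-text files.

    Returns a name → path mapping for: reference/test VCFs, annotation TSV
    (1-based inclusive coordinates), expression TSV (genes × samples),
    phenotype TSV and, when given, a sample-factors TSV.  Byte-identical
    across runs for identical inputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf_ref": out / "ref.vcf",
        "vcf_test": out / "test.vcf",
        "annotation": out / "genes.tsv",
        "expression": out / "expression.tsv",
        "phenotypes": out / "phenotypes.tsv",
    }
    write_vcf(panel_ref, paths["vcf_ref"])
    write_vcf(panel_test, paths["vcf_test"])
    annotation.to_csv(paths["annotation"], sep="\t", index=False)
    expression.to_csv(paths["expression"], sep="\t", float_format="%.10g")
    phenotypes.to_csv(paths["phenotypes"], sep="\t", index=False, float_format="%.10g")
    if factors is not None:
        paths["factors"] = out / "factors.tsv"
        factors.to_csv(paths["factors"], sep="\t", index=False)
    return paths


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a gene annotation TSV (gene_id, chrom, start, end)."""
    ann = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"gene_id", "chrom", "start", "end"}
    if not required.issubset(ann.columns):
        raise ValueError(f"annotation must have columns {sorted(required)}")
    return ann
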