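"""Genotype panels, VCF input, and variant quality control.

The panel container codes genotypes as minor-allele counts in {0, 1, 2}
(``nan`` for missing), the coding the expression-imputation and association
models assume.  The minor allele is defined per variant from the panel's own
allele frequency; a tie at 0.5 is broken toward the alternate allele.  Two QC
profiles mirror standard GWAS/TWAS practice: a permissive set for cis-eQTL
training (call rate, Hardy-Weinberg, MAF) and a stricter set for single-SNP
scans that adds an LD r² prune and a higher MAF floor.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "ref", "alt", "minor_allele"]


@dataclass
class GenotypePanel:
    """Samples × variants dosage matrix with variant metadata.

    Parameters
    ----------
    sample_ids
        Sample identifiers, one per dosage-matrix row.
    variants
        DataFrame with columns ``variant_id, chrom, pos, ref, alt,
        minor_allele`` sorted by (chrom, pos).  ``minor_allele`` holds the
        base string of the allele being counted by ``dosages``.
    dosages
        Float array of shape (n_samples, n_variants); minor-allele counts in
        {0, 1, 2} with ``nan`` marking missing genotypes.
    complete_dosages
        Optional ground-truth matrix without missingness; populated by the
        simulator only and never by file readers.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray
    complete_dosages: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table missing columns: {missing}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset_variants(self, mask_or_ids) -> "GenotypePanel":
        """Return a panel restricted to a boolean mask or list of variant ids."""
        if isinstance(mask_or_ids, (pd.Series, np.ndarray, list)) and len(
            mask_or_ids
        ) == self.n_variants and np.asarray(mask_or_ids).dtype == bool:
            mask = np.asarray(mask_or_ids, dtype=bool)
        else:
            wanted = set(mask_or_ids)
            mask = self.variants["variant_id"].isin(wanted).to_numpy()
        complete = (
            self.complete_dosages[:, mask]
            if self.complete_dosages is not None
            else None
        )
        return GenotypePanel(
            sample_ids=list(self.sample_ids),
            variants=self.variants.loc[mask].reset_index(drop=True),
            dosages=self.dosages[:, mask],
            complete_dosages=complete,
        )


@dataclass(frozen=True)
class QcProfile:
    """Thresholds for one variant-QC pass.

    ``min_call_rate`` is a strict lower bound (a variant at exactly the
    boundary fails).  ``hwe_alpha`` removes variants with exact-test
    p < hwe_alpha; ``maf_min`` removes variants with MAF < maf_min.
    ``ld_r2_max`` enables greedy LD pruning when set.
    """

    name: str
    min_call_rate: float | None = None
    hwe_alpha: float | None = None
    maf_min: float | None = None
    ld_r2_max: float | None = None
    ld_window: int = 50
    ld_step: int = 5
    autosomes_plus_x_only: bool = True

    def __post_init__(self) -> None:
        for attr in ("min_call_rate", "hwe_alpha", "maf_min", "ld_r2_max"):
            v = getattr(self, attr)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{attr}={v} outside [0, 1]")

    @staticmethod
    def set1() -> "QcProfile":
        """TWAS variant set: call rate > 95%, HWE p ≥ 1e-4, MAF ≥ 0.01."""
        return QcProfile("set1", min_call_rate=0.95, hwe_alpha=1e-4, maf_min=0.01)

    @staticmethod
    def set2() -> "QcProfile":
        """GWAS variant set: adds MAF > 0.05 and an LD prune at r² < 0.8."""
        return QcProfile(
            "set2", min_call_rate=0.95, hwe_alpha=1e-4, maf_min=0.05, ld_r2_max=0.8
        )

    @staticmethod
    def twas_train() -> "QcProfile":
        """Per-gene training exclusions: missing rate ≤ 0.2, MAF ≥ 0.01, HWE."""
        return QcProfile("twas_train", min_call_rate=0.8, hwe_alpha=1e-4, maf_min=0.01)


@dataclass
class QcReport:
    """Per-rule removal accounting for one `apply_qc_profile` run."""

    profile: str
    n_input: int
    rows: list[tuple[str, int, int]] = field(default_factory=list)

    def add(self, rule: str, removed: int, remaining: int) -> None:
        self.rows.append((rule, removed, remaining))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["rule", "removed", "remaining"])

    @property
    def n_output(self) -> int:
        return self.rows[-1][2] if self.rows else self.n_input


# ---------------------------------------------------------------------------
# VCF input
# ---------------------------------------------------------------------------

_BASES = {"A", "C", "G", "T"}


def _is_snp(ref: str, alts: Sequence[str]) -> bool:
    return (
        len(alts) == 1
        and len(ref) == 1
        and len(alts[0]) == 1
        and ref.upper() in _BASES
        and alts[0].upper() in _BASES
    )


def read_genotypes(vcf_path: str) -> GenotypePanel:
    """Read a VCF into a :class:`GenotypePanel` of minor-allele dosages.

    Multi-allelic sites and indels are excluded (counts logged).  Dosages are
    recoded so each variant counts its minor allele, determined from this
    panel's non-missing allele frequency; at an alternate-allele frequency of
    exactly 0.5 the alternate allele is taken as minor.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(vcf_path), gts012=True)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise ValueError(f"cannot parse VCF {vcf_path}: {exc}") from exc

    sample_ids = list(vcf.samples)
    rows: list[dict] = []
    dosage_cols: list[np.ndarray] = []
    n_skipped = 0
    for rec in vcf:
        if not _is_snp(rec.REF, rec.ALT):
            n_skipped += 1
            continue
        # gts012: 0/1/2 alt counts, 3 = missing
        alt_counts = np.asarray(rec.gt_types, dtype=float)
        alt_counts[alt_counts == 3] = np.nan
        rows.append(
            {
                "variant_id": rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}",
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": rec.ALT[0],
            }
        )
        dosage_cols.append(alt_counts)
    if n_skipped:
        logger.info("read_genotypes: excluded %d non-biallelic-SNP sites", n_skipped)

    variants = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "ref", "alt"])
    if not len(variants):
        variants["minor_allele"] = pd.Series(dtype=str)
        return GenotypePanel(sample_ids, variants, np.empty((len(sample_ids), 0)))

    alt_dosages = np.column_stack(dosage_cols)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-missing columns
        alt_freq = np.nanmean(alt_dosages, axis=0) / 2.0
    minor_is_alt = ~(alt_freq > 0.5)  # ties at 0.5 -> alternate allele is minor
    minor_is_alt[np.isnan(alt_freq)] = True
    dosages = np.where(minor_is_alt[None, :], alt_dosages, 2.0 - alt_dosages)
    variants["minor_allele"] = np.where(
        minor_is_alt, variants["alt"], variants["ref"]
    )
    order = variants.sort_values(["chrom", "pos"], kind="mergesort").index.to_numpy()
    variants = variants.loc[order].reset_index(drop=True)
    return GenotypePanel(sample_ids, variants, dosages[:, order])


# ---------------------------------------------------------------------------
# Per-variant statistics
# ---------------------------------------------------------------------------

def allele_stats(panel: GenotypePanel) -> pd.DataFrame:
    """Per-variant MAF, call rate and genotype counts.

    MAF is computed over non-missing alleles.  Genotype counts are
    (hom_major, het, hom_minor) of non-missing genotypes.  A variant with all
    genotypes missing gets ``maf = nan`` (it fails any call-rate filter).
    """
    if panel.n_samples < 1:
        raise ValueError("allele_stats requires at least one sample")
    d = panel.dosages
    obs = ~np.isnan(d)
    n_obs = obs.sum(axis=0)
    call_rate = n_obs / panel.n_samples
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        minor_freq = np.nansum(d, axis=0) / (2.0 * n_obs)
    minor_freq = np.where(n_obs == 0, np.nan, minor_freq)
    # dosage counts the minor allele, so frequency may exceed 0.5 only through
    # sampling noise after orientation; fold for safety
    maf = np.minimum(minor_freq, 1.0 - minor_freq)
    hom_major = np.nansum(d == 0, axis=0)
    het = np.nansum(d == 1, axis=0)
    hom_minor = np.nansum(d == 2, axis=0)
    return pd.DataFrame(
        {
            "variant_id": panel.variants["variant_id"].to_numpy(),
            "maf": maf,
            "call_rate": call_rate,
            "hom_major": hom_major.astype(int),
            "het": het.astype(int),
            "hom_minor": hom_minor.astype(int),
        }
    )


@lru_cache(maxsize=100_000)
def _het_probabilities(n: int, n_minor: int) -> np.ndarray:
    """Null probabilities of each valid heterozygote count.

    For ``n`` genotyped diploids carrying ``n_minor`` minor alleles, the
    heterozygote count under Hardy-Weinberg ranges over values of the same
    parity as ``n_minor`` up to ``min(n_minor, 2n - n_minor)``.  Probabilities
    are built by the standard two-term recurrence from the midpoint, then
    normalised; index i corresponds to het = parity + 2*i.
    """
    n_major = 2 * n - n_minor
    het_max = min(n_minor, n_major)
    parity = n_minor % 2
    hets = np.arange(parity, het_max + 1, 2)
    if len(hets) == 0:
        return np.ones(1)
    # start at the modal mid het and recurse outward (numerically stable)
    mid = int(round(n_minor * n_major / (2.0 * n - 1.0))) if n > 0 else 0
    if mid % 2 != parity:
        mid += 1
    mid = min(max(mid, parity), het_max)
    probs = np.zeros(len(hets))
    i_mid = (mid - parity) // 2
    probs[i_mid] = 1.0
    # downward: P(h-2)/P(h) = h(h-1) / ((hom_minor+1)(hom_major+1)) * 1/4
    for i in range(i_mid, 0, -1):
        h = hets[i]
        hom_minor = (n_minor - h) // 2
        hom_major = (n_major - h) // 2
        probs[i - 1] = probs[i] * h * (h - 1) / (4.0 * (hom_minor + 1) * (hom_major + 1))
    # upward: P(h+2)/P(h) = 4 hom_minor * hom_major / ((h+2)(h+1))
    for i in range(i_mid, len(hets) - 1):
        h = hets[i]
        hom_minor = (n_minor - h) // 2
        hom_major = (n_major - h) // 2
        probs[i + 1] = probs[i] * 4.0 * hom_minor * hom_major / ((h + 2.0) * (h + 1.0))
    return probs / probs.sum()


def hwe_exact_test(hom_major: int, het: int, hom_minor: int) -> float:
    """Exact two-sided Hardy-Weinberg test p-value.

    Sums null probabilities of all heterozygote configurations (same allele
    counts and parity) whose probability does not exceed that of the observed
    configuration.  A monomorphic site returns p = 1 by convention.
    """
    if min(hom_major, het, hom_minor) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = hom_major + het + hom_minor
    if n < 1:
        raise ValueError("at least one genotyped sample required")
    n_minor = het + 2 * hom_minor
    n_major = het + 2 * hom_major
    if n_minor > n_major:  # orient to the minor allele
        n_minor, n_major = n_major, n_minor
    if n_minor == 0:
        logger.debug("hwe_exact_test: monomorphic site, p = 1 by convention")
        return 1.0
    probs = _het_probabilities(n, n_minor)
    i_obs = (het - (n_minor % 2)) // 2
    p_obs = probs[i_obs]
    p = float(probs[probs <= p_obs * (1.0 + 1e-10)].sum())
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def ld_prune(
    panel: GenotypePanel,
    r2_max: float = 0.8,
    window: int = 50,
    step: int = 5,
) -> list[str]:
    """Greedy sliding-window LD prune; returns retained variant ids.

    Within each window of ``window`` variants (advanced by ``step``), every
    pair with squared Pearson correlation of dosages exceeding ``r2_max``
    drops the member with the lower MAF; at equal MAF the later position is
    dropped.  Zero-variance variants are treated as uncorrelated (r² = 0) and
    logged.  Missing dosages are mean-imputed for the correlation only.
    """
    if panel.n_variants < 1:
        raise ValueError("ld_prune requires at least one variant")
    d = panel.dosages.copy()
    col_mean = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    nan_mask = np.isnan(d)
    d[nan_mask] = np.take(col_mean, np.where(nan_mask)[1])
    sd = d.std(axis=0)
    zero_var = sd == 0
    if zero_var.any():
        logger.info("ld_prune: %d zero-variance variants treated as r²=0", zero_var.sum())
    stats = allele_stats(panel)
    maf = np.nan_to_num(stats["maf"].to_numpy(), nan=-1.0)
    p = panel.n_variants
    keep = np.ones(p, dtype=bool)
    z = d - d.mean(axis=0)
    norms = np.sqrt((z**2).sum(axis=0))
    start = 0
    while True:
        end = min(start + window, p)
        idx = np.arange(start, end)
        idx = idx[keep[idx] & ~zero_var[idx]]
        if len(idx) > 1:
            zc = z[:, idx]
            nrm = norms[idx]
            corr = (zc.T @ zc) / np.outer(nrm, nrm)
            r2 = corr**2
            for a in range(len(idx)):
                if not keep[idx[a]]:
                    continue
                for b in range(a + 1, len(idx)):
                    if not keep[idx[b]]:
                        continue
                    if r2[a, b] > r2_max:
                        ia, ib = idx[a], idx[b]
                        if maf[ia] < maf[ib]:
                            keep[ia] = False
                            break  # variant a gone; stop scanning its pairs
                        else:  # equal MAF -> drop the later position (b)
                            keep[ib] = False
        if end >= p:
            break
        start += step
    return panel.variants.loc[keep, "variant_id"].tolist()


# ---------------------------------------------------------------------------
# QC profile application
# ---------------------------------------------------------------------------

def apply_qc_profile(
    panel: GenotypePanel, profile: QcProfile
) -> tuple[GenotypePanel, QcReport]:
    """Filter a panel through one QC profile.

    Rules fire in a fixed order — site type, call rate, HWE, MAF, optional LD
    prune — and the report records the count removed by each.  An empty
    surviving set is returned as a valid empty panel with a warning.
    """
    report = QcReport(profile.name, panel.n_variants)
    current = panel

    def _apply(rule: str, mask: np.ndarray) -> None:
        nonlocal current
        removed = int((~mask).sum())
        current = current.subset_variants(mask)
        report.add(rule, removed, current.n_variants)

    # site type: panels are biallelic SNPs by construction; the chromosome
    # class rule drops contigs outside autosomes + X when requested
    if profile.autosomes_plus_x_only:
        chroms = current.variants["chrom"].astype(str)
        ok = chroms.str.replace("chr", "", regex=False).str.fullmatch(r"\d+|X").to_numpy()
        _apply("site_type", ok)
    else:
        _apply("site_type", np.ones(current.n_variants, dtype=bool))

    stats = allele_stats(current) if current.n_variants else None
    if profile.min_call_rate is not None and current.n_variants:
        _apply("call_rate", stats["call_rate"].to_numpy() > profile.min_call_rate)
        stats = allele_stats(current) if current.n_variants else None
    if profile.hwe_alpha is not None and current.n_variants:
        pvals = np.array(
            [
                hwe_exact_test(r.hom_major, r.het, r.hom_minor)
                for r in stats.itertuples()
            ]
        )
        _apply("hwe", pvals >= profile.hwe_alpha)
        stats = allele_stats(current) if current.n_variants else None
    if profile.maf_min is not None and current.n_variants:
        maf = np.nan_to_num(stats["maf"].to_numpy(), nan=-1.0)
        _apply("maf", maf >= profile.maf_min)
    if profile.ld_r2_max is not None and current.n_variants:
        kept = set(
            ld_prune(
                current,
                r2_max=profile.ld_r2_max,
                window=profile.ld_window,
                step=profile.ld_step,
            )
        )
        _apply("ld_prune", current.variants["variant_id"].isin(kept).to_numpy())

    if current.n_variants == 0:
        warnings.warn(f"QC profile {profile.name} removed all variants")
    return current, report
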