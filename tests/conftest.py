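import numpy as np
import pandas as pd
import pytest

from twaskit import GenotypePanel, SimulationConfig


def make_panel(dosages, chrom="1", start_pos=100, sample_prefix="s", pos=None):
    """Panel from a raw dosage matrix (helper for hand-built fixtures)."""
    dosages = np.asarray(dosages, dtype=float)
    n, p = dosages.shape
    positions = pos if pos is not None else [start_pos + 10 * j for j in range(p)]
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{j + 1}" for j in range(p)],
            "chrom": [chrom] * p,
            "pos": positions,
            "ref": ["A"] * p,
            "alt": ["G"] * p,
            "minor_allele": ["G"] * p,
        }
    )
    return GenotypePanel(
        sample_ids=[f"{sample_prefix}{i + 1}" for i in range(n)],
        variants=variants,
        dosages=dosages,
    )


@pytest.fixture
def small_config():
    return SimulationConfig(
        n_ref=8, n_test=40, n_genes=3, snps_per_gene=8, seed=7, missing_rate=0.05
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def hwe_enumeration_oracle(hom_major: int, het: int, hom_minor: int) -> float:
    """Direct enumeration of the exact HWE test via the log-gamma formula.

    P(het = h | n, m) = 2^h n! m! (2n−m)! / (n_AA! n_Aa! n_aa! (2n)!),
    summed over all configurations at most as probable as the observed one.
    Independent of the recurrence used by the implementation.
    """
    from scipy.special import gammaln

    n = hom_major + het + hom_minor
    m = het + 2 * hom_minor
    M = 2 * n
    if m > M - m:
        m = M - m
    if m == 0:
        return 1.0
    hets = np.arange(m % 2, min(m, M - m) + 1, 2)
    hom_min = (m - hets) // 2
    hom_maj = (M - m - hets) // 2
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        + gammaln(m + 1)
        + gammaln(M - m + 1)
        - gammaln(hom_maj + 1)
        - gammaln(hets + 1)
        - gammaln(hom_min + 1)
        - gammaln(M + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[np.where(hets == het)[0][0]]
    return float(min(probs[probs <= p_obs * (1.0 + 1e-10)].sum(), 1.0))


def bh_stepup_oracle(p):
    """Brute-force Benjamini-Hochberg step-up by its definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    for rank_pos, idx in enumerate(order):
        i = rank_pos + 1
        candidates = [m * p[order[j]] / (j + 1) for j in range(rank_pos, m)]
        adjusted[idx] = min(1.0, min(candidates))
    return adjusted
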