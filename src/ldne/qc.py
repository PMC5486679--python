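"""Marker quality control: call rate, minor allele frequency, and an exact
Hardy-Weinberg test, applied as three sequential filters.

The three per-SNP statistics are computed once on the input matrix;
individuals are never filtered.  Comparisons are ``>=`` for call rate and
MAF and ``>`` for the HWE p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "QcThresholds",
    "QcReport",
    "snp_call_rate",
    "minor_allele_freq",
    "hwe_exact_test",
    "hwe_chisq_test",
    "apply_qc_filters",
]


@dataclass(frozen=True)
class QcThresholds:
    """Marker-QC cutoffs: SNPs are kept when call rate >= `min_call_rate`,
    MAF >= `min_maf` and HWE p > `min_hwe_p`."""

    min_call_rate: float = 0.95
    min_maf: float = 0.05
    min_hwe_p: float = 1e-5

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "min_maf", "min_hwe_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class QcReport:
    """Attrition bookkeeping for one QC run."""

    n_input: int
    removed_call_rate: int
    removed_maf: int
    removed_hwe: int
    surviving_ids: list[str]
    snp_stats: pd.DataFrame = field(repr=False)

    @property
    def n_surviving(self) -> int:
        return len(self.surviving_ids)

    def __post_init__(self) -> None:
        removed = self.removed_call_rate + self.removed_maf + self.removed_hwe
        assert removed + self.n_surviving == self.n_input


def snp_call_rate(genotype_column: np.ndarray) -> float:
    """Fraction of individuals with a non-missing call at one SNP."""
    col = np.asarray(genotype_column)
    if col.size == 0:
        raise ValueError("call rate undefined for an empty genotype column")
    return float((col != MISSING).sum() / col.size)


def minor_allele_freq(genotype_column: np.ndarray) -> float:
    """MAF from allele-B dosage codes; raises if every call is missing."""
    col = np.asarray(genotype_column)
    called = col[col != MISSING]
    if called.size == 0:
        raise ValueError("MAF undefined: no non-missing genotypes")
    p = called.sum() / (2 * called.size)
    return float(min(p, 1.0 - p))


def _hwe_weights(n: int, n_rare: int) -> tuple[np.ndarray, list[int]]:
    """Integer weights of the conditional distribution of the heterozygote
    count given the allele counts (n diploids, ``n_rare`` copies of the rarer
    allele).  Weight of het count h is  n! / (n_hom_rare! h! n_hom_common!) * 2^h.
    Exact integer arithmetic so ties are resolved without rounding."""
    hs = list(range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2))
    import math

    weights = []
    for h in hs:
        hom_rare = (n_rare - h) // 2
        hom_common = n - hom_rare - h
        w = (
            math.factorial(n)
            // (math.factorial(hom_rare) * math.factorial(h) * math.factorial(hom_common))
        ) * (2**h)
        weights.append(w)
    return np.array(weights, dtype=object), hs


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value.

    Conditional on the observed allele counts, the p-value sums the
    probabilities of every heterozygote count whose conditional probability
    is less than or equal to that of the observed count (ties included).
    Computed in exact integer arithmetic; p is in (0, 1].
    """
    counts = (n_aa, n_ab, n_bb)
    if any(c < 0 for c in counts):
        raise ValueError(f"negative genotype counts: {counts}")
    n = sum(counts)
    if n < 1:
        raise ValueError("at least one genotype is required")
    n_b = 2 * n_bb + n_ab
    n_rare = min(n_b, 2 * n - n_b)
    weights, hs = _hwe_weights(n, n_rare)
    w_obs = weights[hs.index(n_ab)]
    num = sum(int(w) for w in weights if w <= w_obs)
    den = sum(int(w) for w in weights)
    return num / den


def hwe_chisq_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """One-degree-of-freedom chi-square HWE test (no continuity correction);
    offered as an alternative to the exact test."""
    counts = np.array([n_aa, n_ab, n_bb], dtype=float)
    if (counts < 0).any():
        raise ValueError("negative genotype counts")
    n = counts.sum()
    if n < 1:
        raise ValueError("at least one genotype is required")
    p = (2 * n_bb + n_ab) / (2 * n)
    expected = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    if p in (0.0, 1.0):
        return 1.0
    x2 = float(((counts - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(x2, df=1))


def _snp_statistics(genotypes: GenotypeMatrix, hwe_method: str) -> pd.DataFrame:
    codes = genotypes.codes
    n, m = codes.shape
    called = codes != MISSING
    call_rate = called.sum(axis=0) / n
    n_bb = (codes == 2).sum(axis=0)
    n_ab = (codes == 1).sum(axis=0)
    n_aa = (codes == 0).sum(axis=0)
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2 * n_bb + n_ab) / (2 * n_called)
    maf = np.where(n_called > 0, np.minimum(p, 1 - p), np.nan)

    test = hwe_exact_test if hwe_method == "exact" else hwe_chisq_test
    hwe_p = np.empty(m)
    cache: dict[tuple[int, int, int], float] = {}
    for j in range(m):
        key = (int(n_aa[j]), int(n_ab[j]), int(n_bb[j]))
        if key not in cache:
            cache[key] = test(*key) if sum(key) >= 1 else np.nan
        hwe_p[j] = cache[key]
    return pd.DataFrame(
        {"call_rate": call_rate, "maf": maf, "hwe_p": hwe_p}
    )


def apply_qc_filters(
    genotypes: GenotypeMatrix,
    snp_map: pd.DataFrame,
    thresholds: QcThresholds = QcThresholds(),
    hwe_method: str = "exact",
) -> tuple[GenotypeMatrix, pd.DataFrame, QcReport]:
    """Apply the three marker filters in order: call rate, MAF, HWE.

    Each filter acts on the survivors of the previous one, but all three
    per-SNP statistics are computed once on the input matrix and never
    recomputed between steps, so the surviving set is order-independent
    while the per-step removal counts reflect the stated order.
    SNPs with every call missing have undefined MAF/HWE and are removed by
    the call-rate step whenever its threshold is positive; with a zero
    threshold they are removed by the MAF step (MAF undefined).
    """
    stats_df = _snp_statistics(genotypes, hwe_method)
    stats_df.insert(0, "snp_id", snp_map["snp_id"].to_numpy())

    cr = stats_df["call_rate"].to_numpy()
    maf = stats_df["maf"].to_numpy()
    hwe = stats_df["hwe_p"].to_numpy()

    pass_cr = cr >= thresholds.min_call_rate
    pass_maf = np.where(np.isnan(maf), False, maf >= thresholds.min_maf)
    pass_hwe = np.where(np.isnan(hwe), False, hwe > thresholds.min_hwe_p)

    removed_cr = int((~pass_cr).sum())
    removed_maf = int((pass_cr & ~pass_maf).sum())
    removed_hwe = int((pass_cr & pass_maf & ~pass_hwe).sum())
    keep = pass_cr & pass_maf & pass_hwe

    stats_df["pass_call_rate"] = pass_cr
    stats_df["pass_maf"] = pass_maf
    stats_df["pass_hwe"] = pass_hwe
    stats_df["retained"] = keep

    if not keep.any():
        warnings.warn("no SNPs survive QC; returning an empty panel", stacklevel=2)

    filtered = GenotypeMatrix(genotypes.codes[:, keep], genotypes.samples.copy())
    filtered_map = snp_map.loc[keep].reset_index(drop=True)
    report = QcReport(
        n_input=genotypes.n_snps,
        removed_call_rate=removed_cr,
        removed_maf=removed_maf,
        removed_hwe=removed_hwe,
        surviving_ids=snp_map.loc[keep, "snp_id"].tolist(),
        snp_stats=stats_df,
    )
    return filtered, filtered_map, report
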