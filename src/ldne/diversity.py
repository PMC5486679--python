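"""Panel diversity statistics: polymorphism, expected heterozygosity and
method-of-moments inbreeding coefficients."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "DiversitySummary",
    "allele_frequencies",
    "expected_heterozygosity",
    "proportion_polymorphic",
    "inbreeding_coefficient",
    "diversity_summary",
]


@dataclass
class DiversitySummary:
    """Panel-level diversity: P_N (proportion polymorphic at the stated MAF
    threshold), mean expected heterozygosity H_E, and the mean and
    per-individual excess-homozygosity inbreeding coefficient F."""

    p_n: float
    h_e: float
    f_mean: float
    f_per_individual: np.ndarray
    maf_threshold: float


def allele_frequencies(genotypes: GenotypeMatrix) -> np.ndarray:
    """Per-SNP allele-B frequency from non-missing calls (NaN if all missing)."""
    codes = genotypes.codes
    called = codes != MISSING
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(codes == MISSING, 0, codes).sum(axis=0) / (2 * n_called)
    return np.where(n_called > 0, p, np.nan)


def expected_heterozygosity(freqs: np.ndarray) -> float:
    """Mean gene diversity over loci: mean of 2p(1-p)."""
    p = np.asarray(freqs, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no allele frequencies supplied")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("allele frequencies must lie in [0, 1]")
    return float(np.mean(2 * p * (1 - p)))


def proportion_polymorphic(maf_list: np.ndarray, threshold: float = 0.05) -> float:
    """Fraction of loci with MAF >= *threshold*.

    The threshold is exposed because P_N has no universal definition; the
    default matches the usual chip QC MAF cut.
    """
    maf = np.asarray(maf_list, dtype=float)
    maf = maf[~np.isnan(maf)]
    if maf.size == 0:
        raise ValueError("no MAF values supplied")
    return float((maf >= threshold).mean())


def inbreeding_coefficient(
    genotype_row: np.ndarray,
    allele_freqs: np.ndarray,
    unbiased: bool = False,
) -> float:
    """Excess-homozygosity F for one individual.

    F = (O_hom - E_hom) / (L - E_hom) over the individual's called loci with
    0 < p < 1, where O_hom counts observed homozygotes and
    E_hom = sum over loci of 1 - 2p(1-p).  With ``unbiased=True`` the
    heterozygosity term carries the small-sample factor 2n/(2n-1) applied to
    2p(1-p) (the correction common QC tools use); the plain estimator is the
    default for transparency.  NaN when no informative loci remain.
    """
    g = np.asarray(genotype_row)
    p = np.asarray(allele_freqs, dtype=float)
    if g.shape != p.shape:
        raise ValueError("genotype row and allele frequency lengths differ")
    informative = (g != MISSING) & ~np.isnan(p) & (p > 0) & (p < 1)
    if not informative.any():
        return float("nan")
    g_i, p_i = g[informative], p[informative]
    het_term = 2 * p_i * (1 - p_i)
    if unbiased:
        n2 = 2 * informative.sum()
        het_term = het_term * n2 / (n2 - 1)
    o_hom = float((g_i != 1).sum())
    e_hom = float(np.sum(1 - het_term))
    l_called = float(g_i.size)
    if l_called == e_hom:
        return float("nan")
    return (o_hom - e_hom) / (l_called - e_hom)


def diversity_summary(
    genotypes: GenotypeMatrix,
    maf_threshold: float = 0.05,
    unbiased: bool = False,
) -> DiversitySummary:
    """P_N, H_E and per-individual F for a genotype panel."""
    p = allele_frequencies(genotypes)
    maf = np.minimum(p, 1 - p)
    f = np.array(
        [
            inbreeding_coefficient(genotypes.codes[i], p, unbiased=unbiased)
            for i in range(genotypes.n_individuals)
        ]
    )
    return DiversitySummary(
        p_n=proportion_polymorphic(maf, threshold=maf_threshold),
        h_e=expected_heterozygosity(p),
        f_mean=float(np.nanmean(f)) if np.isfinite(f).any() else float("nan"),
        f_per_individual=f,
        maf_threshold=maf_threshold,
    )
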