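"""Pairwise r² between unphased SNP genotypes and distance-binned LD decay.

Because chip genotypes are unphased, two-locus haplotype frequencies are
estimated by an EM algorithm: every genotype pair is phase-resolved except
the double heterozygote, whose copies are split between the coupling
(A1B1/A2B2) and repulsion (A1B2/A2B1) phases by iterated expected fractions.
r² is then D² / (pA1 pA2 pB1 pB2) with D = p11 p22 - p12 p21.

Within a chromosome, only pairs with 0 < distance <= 10 Mb (configurable)
are evaluated.  Individuals missing either genotype are dropped per pair
(pairwise-complete), so the per-pair sample size varies.  Results stream:
binning accumulates running sums and never holds all pairs in memory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "DEFAULT_BIN_EDGES_BP",
    "HaplotypeFreqs",
    "LdPair",
    "MonomorphicLocusError",
    "em_haplotype_freqs",
    "two_locus_loglik",
    "r_squared",
    "pairwise_ld",
    "bin_ld",
    "LdScanStats",
]

#: canonical decay-curve bin edges: 0-10 kb, 10-25 kb, ..., 5-10 Mb
DEFAULT_BIN_EDGES_BP: tuple[int, ...] = (
    0, 10_000, 25_000, 50_000, 100_000, 500_000, 1_000_000, 5_000_000, 10_000_000,
)

EM_TOL = 1e-10
EM_MAX_ITER = 1000


class MonomorphicLocusError(ValueError):
    """r² is undefined when either locus is monomorphic in the individuals used."""


@dataclass(frozen=True)
class HaplotypeFreqs:
    """Two-locus haplotype frequencies (A1B1, A1B2, A2B1, A2B2)."""

    p11: float
    p12: float
    p21: float
    p22: float

    def __post_init__(self) -> None:
        ps = (self.p11, self.p12, self.p21, self.p22)
        if any(p < -1e-12 for p in ps):
            raise ValueError(f"negative haplotype frequency: {ps}")
        if abs(sum(ps) - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies sum to {sum(ps)}, not 1")

    @property
    def pA1(self) -> float:
        return self.p11 + self.p12

    @property
    def pA2(self) -> float:
        return self.p21 + self.p22

    @property
    def pB1(self) -> float:
        return self.p11 + self.p21

    @property
    def pB2(self) -> float:
        return self.p12 + self.p22

    @property
    def d(self) -> float:
        """Gametic disequilibrium D = p11 p22 - p12 p21."""
        return self.p11 * self.p22 - self.p12 * self.p21


class LdPair(NamedTuple):
    """One SNP pair's LD record."""

    chrom: str
    snp_i: str
    snp_j: str
    distance_bp: int
    r2: float
    n_used: int


@dataclass
class LdScanStats:
    """Side counters filled in by :func:`pairwise_ld`."""

    n_pairs: int = 0
    n_skipped_monomorphic: int = 0


def _check_table(table: np.ndarray) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.shape != (3, 3):
        raise ValueError(f"expected a 3x3 genotype count table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("negative counts in genotype table")
    if t.sum() < 1:
        raise ValueError("empty genotype table")
    return t


def _batch_loglik(t, p11, p12, p21, p22):
    """Observed-data log-likelihood per table (phase summed out), vectorized."""
    probs = np.stack(
        [
            p11**2, 2 * p11 * p12, p12**2,
            2 * p11 * p21, 2 * (p11 * p22 + p12 * p21), 2 * p12 * p22,
            p21**2, 2 * p21 * p22, p22**2,
        ],
        axis=-1,
    )
    counts = t.reshape(t.shape[0], 9)
    logp = np.where(probs > 0, np.log(np.where(probs > 0, probs, 1.0)), -np.inf)
    # mask cells with zero count BEFORE multiplying so 0 * -inf never arises
    return (counts * np.where(counts > 0, logp, 0.0)).sum(axis=1)


def _em_iterate(k11, k12, k21, k22, dh, n2, p11, p12, p21, p22, tol, max_iter):
    for _ in range(max_iter):
        num = p11 * p22
        den = num + p12 * p21
        w = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.5)
        c11 = (k11 + w * dh) / n2
        c12 = (k12 + (1 - w) * dh) / n2
        c21 = (k21 + (1 - w) * dh) / n2
        c22 = (k22 + w * dh) / n2
        delta = np.max(
            np.abs(np.stack([c11 - p11, c12 - p12, c21 - p21, c22 - p22]))
        )
        p11, p12, p21, p22 = c11, c12, c21, c22
        if delta < tol:
            break
    return p11, p12, p21, p22


def _em_core(tables: np.ndarray, tol: float = EM_TOL, max_iter: int = EM_MAX_ITER):
    """Vectorized EM over a batch of 3x3 genotype count tables.

    Returns (p11, p12, p21, p22, pA1, pB1) arrays.  All cells except the
    double heterozygote contribute fixed haplotype counts; the double-het
    count Dh is split by the coupling fraction w = p11 p22 / (p11 p22 + p12 p21).

    The double-het likelihood can be multimodal, so EM runs from three
    deterministic starts — the linkage-equilibrium product and the two ends
    of the feasible p11 interval (maximum coupling / maximum repulsion) —
    and the fixed point with the highest observed-data likelihood wins.
    Exact likelihood ties are broken toward the linkage-equilibrium start,
    keeping the output deterministic with no random restarts.
    """
    t = tables.astype(float)
    n2 = 2.0 * t.sum(axis=(1, 2))
    k11 = 2 * t[:, 0, 0] + t[:, 0, 1] + t[:, 1, 0]
    k12 = 2 * t[:, 0, 2] + t[:, 0, 1] + t[:, 1, 2]
    k21 = 2 * t[:, 2, 0] + t[:, 2, 1] + t[:, 1, 0]
    k22 = 2 * t[:, 2, 2] + t[:, 2, 1] + t[:, 1, 2]
    dh = t[:, 1, 1]

    pA1 = (k11 + k12 + dh) / n2
    pB1 = (k11 + k21 + dh) / n2
    lo = np.maximum(0.0, pA1 + pB1 - 1.0)
    hi = np.minimum(pA1, pB1)
    starts = [pA1 * pB1, lo + 0.999 * (hi - lo), lo + 0.001 * (hi - lo)]

    best = None
    best_ll = np.full(t.shape[0], -np.inf)
    for s11 in starts:
        p11 = s11
        p12 = pA1 - p11
        p21 = pB1 - p11
        p22 = 1.0 - pA1 - pB1 + p11
        p11, p12, p21, p22 = _em_iterate(
            k11, k12, k21, k22, dh, n2, p11, p12, p21, p22, tol, max_iter
        )
        ll = _batch_loglik(t, p11, p12, p21, p22)
        if best is None:
            best = (p11, p12, p21, p22)
            best_ll = ll
        else:
            better = ll > best_ll + 1e-12
            best = tuple(np.where(better, new, old) for new, old in
                         zip((p11, p12, p21, p22), best))
            best_ll = np.where(better, ll, best_ll)
    p11, p12, p21, p22 = best
    return p11, p12, p21, p22, pA1, pB1


def two_locus_loglik(table: np.ndarray, h: HaplotypeFreqs) -> float:
    """Observed-data log-likelihood of a 3x3 genotype table under random
    union of gametes with haplotype frequencies *h* (phase summed out)."""
    t = _check_table(table)
    hap = np.array([[h.p11, h.p12], [h.p21, h.p22]])  # [A allele][B allele]
    ll = 0.0
    for ga in range(3):
        for gb in range(3):
            if t[ga, gb] == 0:
                continue
            prob = 0.0
            # paternal/maternal haplotypes (a1,b1) and (a2,b2)
            for a1 in range(2):
                for b1 in range(2):
                    for a2 in range(2):
                        for b2 in range(2):
                            if a1 + a2 == ga and b1 + b2 == gb:
                                prob += hap[a1, b1] * hap[a2, b2]
            if prob <= 0:
                return -math.inf
            ll += t[ga, gb] * math.log(prob)
    return ll


def em_haplotype_freqs(
    table: np.ndarray,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
    return_trace: bool = False,
) -> HaplotypeFreqs | tuple[HaplotypeFreqs, np.ndarray]:
    """Maximum-likelihood haplotype frequencies from a 3x3 genotype table.

    The table is indexed ``[genotype at locus A, genotype at locus B]`` with
    genotypes coded as allele-2 dosage.  With *return_trace* the EM runs from
    the linkage-equilibrium start only and its per-iteration log-likelihoods
    are returned as well (used to verify that each EM step is monotone).
    """
    t = _check_table(table)[None, :, :]
    if not return_trace:
        p11, p12, p21, p22, _, _ = _em_core(t, tol, max_iter)
        return HaplotypeFreqs(float(p11[0]), float(p12[0]), float(p21[0]), float(p22[0]))

    # scalar EM with a log-likelihood trace, from the same independence start
    p11, p12, p21, p22, _, _ = _em_core(t, max_iter=0)
    cur = HaplotypeFreqs(float(p11[0]), float(p12[0]), float(p21[0]), float(p22[0]))
    trace = [two_locus_loglik(table, cur)]
    for _ in range(max_iter):
        nxt = _em_single_step(table, cur)
        delta = max(
            abs(nxt.p11 - cur.p11), abs(nxt.p12 - cur.p12),
            abs(nxt.p21 - cur.p21), abs(nxt.p22 - cur.p22),
        )
        cur = nxt
        trace.append(two_locus_loglik(table, cur))
        if delta < tol:
            break
    return cur, np.asarray(trace)


def _em_single_step(table: np.ndarray, h: HaplotypeFreqs) -> HaplotypeFreqs:
    t = _check_table(table)
    n2 = 2.0 * t.sum()
    k11 = 2 * t[0, 0] + t[0, 1] + t[1, 0]
    k12 = 2 * t[0, 2] + t[0, 1] + t[1, 2]
    k21 = 2 * t[2, 0] + t[2, 1] + t[1, 0]
    k22 = 2 * t[2, 2] + t[2, 1] + t[1, 2]
    dh = t[1, 1]
    num = h.p11 * h.p22
    den = num + h.p12 * h.p21
    w = num / den if den > 0 else 0.5
    return HaplotypeFreqs(
        (k11 + w * dh) / n2,
        (k12 + (1 - w) * dh) / n2,
        (k21 + (1 - w) * dh) / n2,
        (k22 + w * dh) / n2,
    )


def r_squared(h: HaplotypeFreqs) -> float:
    """Squared allelic correlation r² = D² / (pA1 pA2 pB1 pB2), clipped to [0, 1]."""
    den = h.pA1 * h.pA2 * h.pB1 * h.pB2
    if den <= 0:
        raise MonomorphicLocusError(
            "r^2 undefined: at least one locus is monomorphic"
        )
    return float(np.clip(h.d**2 / den, 0.0, 1.0))


def _pair_tables(gi: np.ndarray, gj: np.ndarray) -> np.ndarray:
    """3x3 count tables for one anchor column ``gi`` against columns ``gj``,
    restricted per pair to individuals called at both loci."""
    valid = (gi != MISSING)[:, None] & (gj != MISSING)
    tables = np.empty((gj.shape[1], 3, 3), dtype=np.int64)
    for a in range(3):
        ma = (gi == a)[:, None] & valid
        for b in range(3):
            tables[:, a, b] = (ma & (gj == b)).sum(axis=0)
    return tables


def pairwise_ld(
    genotypes: GenotypeMatrix,
    snp_map: pd.DataFrame,
    max_distance_bp: int = 10_000_000,
    stats: LdScanStats | None = None,
) -> Iterator[LdPair]:
    """Stream r² for every within-chromosome SNP pair up to *max_distance_bp*.

    Pairs where either locus is monomorphic among the pairwise-complete
    individuals are skipped and counted in *stats*.  EM runs vectorized over
    one anchor SNP's window at a time, so memory stays proportional to the
    window, not to the total pair count.
    """
    codes = genotypes.codes
    chroms = snp_map["chrom"].to_numpy()
    pos = snp_map["physical_pos"].to_numpy(dtype=np.int64)
    ids = snp_map["snp_id"].to_numpy()

    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        cpos = pos[idx]
        order = np.argsort(cpos, kind="stable")
        idx, cpos = idx[order], cpos[order]
        for a in range(len(idx) - 1):
            hi = np.searchsorted(cpos, cpos[a] + max_distance_bp, side="right")
            js = idx[a + 1 : hi]
            if js.size == 0:
                continue
            dist = cpos[a + 1 : hi] - cpos[a]
            nonzero = dist > 0
            js, dist = js[nonzero], dist[nonzero]
            if js.size == 0:
                continue
            tables = _pair_tables(codes[:, idx[a]], codes[:, js])
            n_used = tables.sum(axis=(1, 2))
            p11, p12, p21, p22, pA1, pB1 = _em_core(tables)
            denom = pA1 * (1 - pA1) * pB1 * (1 - pB1)
            ok = (denom > 0) & (n_used > 0)
            d = p11 * p22 - p12 * p21
            r2 = np.zeros(len(js))
            r2[ok] = np.clip(d[ok] ** 2 / denom[ok], 0.0, 1.0)
            if stats is not None:
                stats.n_pairs += int(ok.sum())
                stats.n_skipped_monomorphic += int((~ok).sum())
            anchor_id = ids[idx[a]]
            for j, dbp, ok_j, r2_j, nu in zip(js, dist, ok, r2, n_used):
                if not ok_j:
                    continue
                yield LdPair(str(chrom), str(anchor_id), str(ids[j]),
                             int(dbp), float(r2_j), int(nu))


class _BinAccum:
    """Streaming mean/SD accumulator per (scope, bin)."""

    __slots__ = ("n", "s1", "s2")

    def __init__(self) -> None:
        self.n = 0
        self.s1 = 0.0
        self.s2 = 0.0

    def add(self, x: float) -> None:
        self.n += 1
        self.s1 += x
        self.s2 += x * x

    def summary(self) -> tuple[float, float, float]:
        mean = self.s1 / self.n
        if self.n > 1:
            var = max(self.s2 / self.n - mean * mean, 0.0) * self.n / (self.n - 1)
            sd = math.sqrt(var)
            se = sd / math.sqrt(self.n)
        else:
            sd = se = float("nan")
        return mean, sd, se


def bin_ld(
    pairs: Iterable[LdPair],
    bin_edges_bp: Sequence[int] = DEFAULT_BIN_EDGES_BP,
    scope: str = "both",
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Distance-binned LD decay summaries.

    Each pair goes to the unique bin with ``lower < distance <= upper``
    (half-open on the left, so a pair at exactly 10 kb falls in the 0-10 kb
    bin).  Pairs beyond the last edge are counted as unbinned in the
    ``n_unbinned`` DataFrame attribute.

    scope:
        ``"genome"`` - one row per bin pooled over chromosomes;
        ``"chromosome"`` - one row per chromosome per bin;
        ``"both"`` - tuple ``(genome, per_chromosome)`` from a single pass.
    """
    edges = np.asarray(bin_edges_bp, dtype=np.int64)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing with >= 2 values")
    if scope not in ("genome", "chromosome", "both"):
        raise ValueError(f"unknown scope {scope!r}")

    per_chrom: dict[tuple[str, int], _BinAccum] = {}
    chrom_order: list[str] = []
    n_unbinned = 0
    for pair in pairs:
        k = int(np.searchsorted(edges, pair.distance_bp, side="left")) - 1
        if pair.distance_bp <= edges[0] or k >= len(edges) - 1:
            n_unbinned += 1
            continue
        if pair.chrom not in chrom_order:
            chrom_order.append(pair.chrom)
        per_chrom.setdefault((pair.chrom, k), _BinAccum()).add(pair.r2)

    def rows_for(scope_label: str, keys: list[tuple[str, int]]) -> pd.DataFrame:
        recs = []
        for chrom_label, bins in keys_grouped(keys):
            for k in range(len(edges) - 1):
                acc = bins.get(k)
                rec = {
                    "scope": chrom_label,
                    "bin_lo_bp": int(edges[k]),
                    "bin_hi_bp": int(edges[k + 1]),
                    "n_pairs": 0,
                    "mean_r2": float("nan"),
                    "sd_r2": float("nan"),
                    "se_r2": float("nan"),
                }
                if acc is not None and acc.n > 0:
                    mean, sd, se = acc.summary()
                    rec.update(n_pairs=acc.n, mean_r2=mean, sd_r2=sd, se_r2=se)
                recs.append(rec)
        return pd.DataFrame(recs)

    def keys_grouped(keys):
        if keys == ["genome"]:
            pooled: dict[int, _BinAccum] = {}
            for (chrom, k), acc in per_chrom.items():
                tgt = pooled.setdefault(k, _BinAccum())
                tgt.n += acc.n
                tgt.s1 += acc.s1
                tgt.s2 += acc.s2
            return [("genome", pooled)]
        return [
            (chrom, {k: acc for (c, k), acc in per_chrom.items() if c == chrom})
            for chrom in chrom_order
        ]

    genome = rows_for("genome", ["genome"])
    genome.attrs["n_unbinned"] = n_unbinned
    chrom = rows_for("chromosome", list(per_chrom))
    chrom.attrs["n_unbinned"] = n_unbinned
    if scope == "genome":
        return genome
    if scope == "chromosome":
        return chrom
    return genome, chrom
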