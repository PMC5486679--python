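"""Effective population size from binned LD via Sved's relationship.

Sved's equation links expected LD at genetic distance c (Morgans) to the
effective population size Ne and the experimental sample size n:

    E(r²) = 1 / (alpha + k Ne c) + 1/n

with k = 4 for autosomes (2 for the X) and alpha = 1 without mutation or
2 with mutation.  Inverting for Ne:

    Ne = 1 / ((r² - 1/n) k c) - alpha / (k c)

An estimate at genetic distance c refers to the population roughly
t = 1/(2c) generations in the past, so a trajectory over distance bins is a
trajectory over time.  Physical distance converts to genetic distance at a
configurable rate, 1 cM/Mb by default (100 kb ~ 0.1 cM).

Each bin's c is taken from its UPPER edge (the convention that pairs the
10-25 kb bin with c = 0.00025 and t = 2000 generations); this choice affects
every estimate and is deliberately prominent here.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "expected_r2",
    "ne_from_r2",
    "generations_from_c",
    "ne_trajectory",
]

#: smallest upper bin edge (bp, at 1 cM/Mb) of the conventional generation grid
STANDARD_GRID_MIN_C = 0.00025


def expected_r2(
    ne: float, c: float, n: float = math.inf, k: float = 4.0, alpha: float = 2.0
) -> float:
    """Sved's expectation 1/(alpha + k Ne c) + 1/n.

    *n* is the diploid sample size; ``n = inf`` drops the sampling term.
    """
    if ne <= 0 or c <= 0:
        raise ValueError(f"ne and c must be positive, got ne={ne}, c={c}")
    if n < 1:
        raise ValueError(f"sample size must be >= 1 (or inf), got {n}")
    return 1.0 / (alpha + k * ne * c) + (0.0 if math.isinf(n) else 1.0 / n)


def ne_from_r2(
    r2: float, n: float, c: float, k: float = 4.0, alpha: float = 2.0
) -> float:
    """Invert Sved's equation for Ne; NaN (not an exception) at the pole.

    Defined only when r² exceeds the sampling floor 1/n; otherwise the
    drift signal is indistinguishable from sampling noise and NaN is
    returned as the "undefined" flag.
    """
    if not 0.0 <= r2 <= 1.0:
        raise ValueError(f"r2 must lie in [0, 1], got {r2}")
    if c <= 0:
        raise ValueError(f"genetic distance c must be positive, got {c}")
    if n < 1:
        raise ValueError(f"sample size must be >= 1 (or inf), got {n}")
    adj = r2 - (0.0 if math.isinf(n) else 1.0 / n)
    if adj <= 0:
        return float("nan")
    return 1.0 / (adj * k * c) - alpha / (k * c)


def generations_from_c(c: float) -> float:
    """Generations before present to which an estimate at distance c refers: 1/(2c)."""
    if c <= 0:
        raise ValueError(f"genetic distance c must be positive, got {c}")
    return 1.0 / (2.0 * c)


def ne_trajectory(
    bin_summaries: pd.DataFrame,
    n: float,
    cm_per_mb: float = 1.0,
    k: float = 4.0,
    alpha: float = 2.0,
    use_chromosome_count: bool = False,
) -> pd.DataFrame:
    """Sved-inverted Ne for every distance bin of a decay table.

    Parameters
    ----------
    bin_summaries:
        Output of :func:`ldne.ld.bin_ld` (any scope): needs columns
        ``scope, bin_lo_bp, bin_hi_bp, mean_r2, n_pairs``.
    n:
        Number of genotyped diploid individuals entering the 1/n term.
    cm_per_mb:
        Physical-to-genetic conversion; c (Morgans) = upper edge in Mb
        times cm_per_mb / 100.
    use_chromosome_count:
        When True the sampling term uses 2n chromosomes instead of n
        individuals (sensitivity analysis).

    Returns one row per input bin with c, generations = 1/(2c), the bin's
    arithmetic-mean r², and the Ne estimate (NaN when the bin is empty or
    its mean r² does not exceed 1/n).  ``standard_grid`` is False for bins
    finer than the conventional 25 kb-and-up generation grid.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    n_eff = 2 * n if use_chromosome_count else n
    rows = []
    for row in bin_summaries.itertuples(index=False):
        c = row.bin_hi_bp / 1e6 * cm_per_mb / 100.0
        rec = {
            "scope": row.scope,
            "bin_lo_bp": row.bin_lo_bp,
            "bin_hi_bp": row.bin_hi_bp,
            "c_morgans": c,
            "generations": generations_from_c(c),
            "r2_used": row.mean_r2,
            "n_pairs": row.n_pairs,
            "n": n_eff,
            "k": k,
            "alpha": alpha,
            "standard_grid": c >= STANDARD_GRID_MIN_C - 1e-15,
        }
        if row.n_pairs == 0 or not np.isfinite(row.mean_r2):
            rec["ne"] = float("nan")
        else:
            rec["ne"] = ne_from_r2(float(row.mean_r2), n_eff, c, k=k, alpha=alpha)
        rows.append(rec)
    return pd.DataFrame(rows)
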