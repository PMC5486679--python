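"""Synthetic SNP-chip panels with known demography.

The generator emulates a 50K-chip-like panel: a handful of autosomes with
biallelic SNPs at roughly chip-like spacing, a configurable minimum MAF
(crude chip ascertainment), configurable missingness, and LD decay produced
by a neutral model with a known effective population size, so every
downstream stage (QC, r², decay binning, Sved inversion) can be validated
against truth.

Two engines are available:

``coalescent``
    msprime ancestry + binary mutations (the default; fast at chromosome
    scale, supports piecewise-constant Ne epochs).
``forward``
    an explicit diploid Wright-Fisher population iterated for a burn-in of
    at least 4 Ne generations from intermediate-frequency standing
    variation, with per-interval Haldane recombination and no mutation.
    Slower, but has no coalescent machinery at all and handles the
    degenerate regimes (zero recombination, tiny populations) transparently.

Physical scale maps to genetic scale at ``recomb_rate`` cM/Mb (default 1,
i.e. 100 kb ~ 0.1 cM), matching the conversion used when LD decay is turned
into an Ne trajectory.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import msprime
import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, default_samples, validate_snp_map

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "SimulationError",
    "simulate_population",
    "inject_missingness",
    "replicate_pair_r2",
    "write_truth",
]


class SimulationError(RuntimeError):
    """Raised when a simulation cannot satisfy its configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Panel-generation parameters.

    ``ne_true`` is either a constant size or a list of
    ``(generations_before_present, size)`` epochs, most recent first, where
    the first entry must start at generation 0.  ``maf_floor`` drops sites
    whose sample MAF falls below the floor before thinning (ascertainment);
    ``missing_rate`` is applied to the final genotype calls.
    """

    n_individuals: int
    n_chromosomes: int
    chrom_length_bp: int
    target_n_snps: int
    recomb_rate: float = 1.0  # cM per Mb
    ne_true: float | Sequence[tuple[float, float]] = 500.0
    missing_rate: float = 0.0
    maf_floor: float = 0.0
    seed: int = 1
    engine: str = "coalescent"
    mutation_rate: float | None = None  # per bp per generation; None = auto

    def __post_init__(self) -> None:
        for name in ("n_individuals", "n_chromosomes", "chrom_length_bp", "target_n_snps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.recomb_rate < 0:
            raise ValueError("recomb_rate must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.maf_floor < 0.5:
            raise ValueError("maf_floor must lie in [0, 0.5)")
        if self.engine not in ("coalescent", "forward"):
            raise ValueError(f"unknown engine {self.engine!r}")
        sizes = self.epochs()
        if any(s <= 0 for _, s in sizes):
            raise ValueError("all effective population sizes must be positive")
        if sizes[0][0] != 0:
            raise ValueError("the first Ne epoch must start at generation 0")

    def epochs(self) -> list[tuple[float, float]]:
        """Ne history as (time_before_present, size) pairs, present first."""
        if isinstance(self.ne_true, (int, float)):
            return [(0.0, float(self.ne_true))]
        return [(float(t), float(s)) for t, s in self.ne_true]

    @property
    def current_ne(self) -> float:
        return self.epochs()[0][1]


@dataclass
class SimulatedDataset:
    """Genotypes + map + the truth record that produced them."""

    genotypes: GenotypeMatrix
    snp_map: pd.DataFrame
    truth: SimulationConfig

    def __post_init__(self) -> None:
        for _, grp in self.snp_map.groupby("chrom", sort=False):
            pos = grp["physical_pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("map positions must be strictly increasing per chromosome")

    def copy(self) -> "SimulatedDataset":
        return SimulatedDataset(self.genotypes.copy(), self.snp_map.copy(), self.truth)


def _recomb_per_bp(cm_per_mb: float) -> float:
    return cm_per_mb * 1e-8


def _auto_mutation_rate(config: SimulationConfig) -> float:
    """Rate aimed at ~5x the per-chromosome SNP target before ascertainment,
    using the expected number of segregating sites under the standard
    coalescent (Watterson) at the current Ne."""
    n_hap = 2 * config.n_individuals
    a = np.sum(1.0 / np.arange(1, n_hap))
    ne = config.current_ne
    return 5.0 * config.target_n_snps / (4.0 * ne * config.chrom_length_bp * a)


def _coalescent_chromosome(
    config: SimulationConfig, seed_pair: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """One chromosome of diploid dosages (individuals x sites) + positions."""
    epochs = config.epochs()
    demography = msprime.Demography()
    demography.add_population(name="pop", initial_size=epochs[0][1])
    for t, size in epochs[1:]:
        demography.add_population_parameters_change(time=t, initial_size=size)
    ts = msprime.sim_ancestry(
        samples=config.n_individuals,
        demography=demography,
        sequence_length=config.chrom_length_bp,
        recombination_rate=_recomb_per_bp(config.recomb_rate),
        random_seed=seed_pair[0],
        discrete_genome=True,
    )
    mu = config.mutation_rate or _auto_mutation_rate(config)
    ts = msprime.sim_mutations(
        ts, rate=mu, random_seed=seed_pair[1], model=msprime.BinaryMutationModel()
    )
    hap = ts.genotype_matrix()  # sites x haplotypes, values 0/1
    pos = ts.sites_position.astype(np.int64) + 1  # 1-based bp
    dip = (hap[:, ::2] + hap[:, 1::2]).T.astype(np.int8)  # individuals x sites
    return dip, pos


def _forward_chromosome(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Pure-forward Wright-Fisher engine for one chromosome.

    Constant Ne only.  Loci start as independent standing variation at
    frequency 1/2 and drift (with recombination, without mutation) for a
    burn-in of 4 Ne generations, which is ample for the two-locus
    correlation structure to reach its drift shape.
    """
    epochs = config.epochs()
    if len(epochs) > 1:
        raise SimulationError("the forward engine supports constant Ne only")
    ne = int(round(epochs[0][1]))
    if config.n_individuals > ne:
        raise SimulationError(
            f"forward engine samples without replacement: n_individuals "
            f"({config.n_individuals}) exceeds ne_true ({ne})"
        )
    n_loci = max(3 * config.target_n_snps, config.target_n_snps + 8)
    if n_loci > config.chrom_length_bp:
        raise SimulationError("chromosome too short for the requested SNP count")
    pos = np.sort(rng.choice(config.chrom_length_bp, size=n_loci, replace=False)) + 1
    d_morgans = np.diff(pos) * _recomb_per_bp(config.recomb_rate)
    rec_prob = 0.5 * (1.0 - np.exp(-2.0 * d_morgans))  # Haldane map function

    n_hap = 2 * ne
    hap = (rng.random((n_hap, n_loci)) < 0.5).astype(np.int8)
    generations = 4 * ne
    for _ in range(generations):
        parents = rng.integers(0, ne, size=n_hap)
        h1 = hap[2 * parents]
        h2 = hap[2 * parents + 1]
        start = rng.random(n_hap) < 0.5
        crossings = rng.random((n_hap, n_loci - 1)) < rec_prob
        selector = np.empty((n_hap, n_loci), dtype=bool)
        selector[:, 0] = start
        np.logical_xor.accumulate(crossings, axis=1, out=crossings)
        selector[:, 1:] = start[:, None] ^ crossings
        hap = np.where(selector, h2, h1)

    chosen = rng.permutation(ne)[: config.n_individuals]
    cols = np.empty(2 * config.n_individuals, dtype=np.int64)
    cols[0::2], cols[1::2] = 2 * chosen, 2 * chosen + 1
    sampled = hap[cols]
    dip = (sampled[0::2] + sampled[1::2]).astype(np.int8)
    return dip, pos.astype(np.int64)


def simulate_population(config: SimulationConfig) -> SimulatedDataset:
    """Generate a diploid panel under *config*; deterministic given the seed.

    Monomorphic sites and sites below ``maf_floor`` are dropped, then sites
    are thinned to ``target_n_snps`` per chromosome by seeded uniform
    subsampling.  A shortfall of polymorphic sites raises
    :class:`SimulationError` naming the deficit.
    """
    ss = np.random.SeedSequence(config.seed)
    child_seeds = ss.spawn(config.n_chromosomes + 1)
    missing_rng = np.random.default_rng(child_seeds[-1])

    dips, maps = [], []
    for ci in range(config.n_chromosomes):
        rng = np.random.default_rng(child_seeds[ci])
        if config.engine == "coalescent":
            pair = tuple(int(s) for s in rng.integers(1, 2**31, size=2))
            dip, pos = _coalescent_chromosome(config, pair)
        else:
            dip, pos = _forward_chromosome(config, rng)

        freq = dip.sum(axis=0) / (2 * config.n_individuals)
        maf = np.minimum(freq, 1 - freq)
        keep = maf > 0 if config.maf_floor == 0 else maf >= config.maf_floor
        dip, pos = dip[:, keep], pos[keep]
        if dip.shape[1] < config.target_n_snps:
            raise SimulationError(
                f"chromosome {ci + 1}: only {dip.shape[1]} usable polymorphic sites "
                f"for a target of {config.target_n_snps} "
                f"(shortfall {config.target_n_snps - dip.shape[1]}); "
                "increase chrom_length_bp or mutation_rate, or lower maf_floor/target"
            )
        pick = np.sort(rng.choice(dip.shape[1], size=config.target_n_snps, replace=False))
        dip, pos = dip[:, pick], pos[pick]

        chrom = str(ci + 1)
        maps.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "snp_id": [f"snp{ci + 1}_{k + 1}" for k in range(len(pos))],
                    "genetic_pos": pos / 1e6 * config.recomb_rate,  # cM
                    "physical_pos": pos,
                    "allele_a": "A",
                    "allele_b": "G",
                }
            )
        )
        dips.append(dip)

    codes = np.concatenate(dips, axis=1)
    snp_map = validate_snp_map(pd.concat(maps, ignore_index=True))
    genotypes = GenotypeMatrix(codes, default_samples(config.n_individuals))
    dataset = SimulatedDataset(genotypes, snp_map, truth=config)
    if config.missing_rate > 0:
        dataset = inject_missingness(
            dataset, config.missing_rate, seed=int(missing_rng.integers(1, 2**31))
        )
    return dataset


def inject_missingness(
    dataset: SimulatedDataset, rate: float, seed: int
) -> SimulatedDataset:
    """Return a copy with each genotype independently set missing with
    probability *rate* (the map is untouched)."""
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"missing rate must lie in [0, 1), got {rate}")
    out = dataset.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    mask = rng.random(out.genotypes.codes.shape) < rate
    out.genotypes.codes[mask] = MISSING
    return out


def write_truth(dataset: SimulatedDataset, path: str | Path) -> Path:
    """Write the truth record as a JSON sidecar next to the PED/MAP files."""
    path = Path(path)
    rec = dataclasses.asdict(dataset.truth)
    if not isinstance(rec["ne_true"], (int, float)):
        rec["ne_true"] = [list(e) for e in dataset.truth.epochs()]
    path.write_text(json.dumps(rec, indent=2, sort_keys=True) + "\n")
    return path


def replicate_pair_r2(
    ne: int,
    c: float,
    n: int,
    n_replicates: int = 2000,
    seed: int = 1,
    maf_min: float = 0.05,
    burn_in: int | None = None,
) -> np.ndarray:
    """r² from independent two-locus Wright-Fisher replicates at distance c.

    Each replicate evolves the exact WF Markov chain on the four haplotype
    counts of a population of *ne* diploids (deterministic recombination at
    Haldane probability, multinomial drift) for ``burn_in`` generations
    (default 4 Ne) from linkage equilibrium at frequency 1/2, then samples
    *n* diploids without replacement, pairs gametes at random, and computes
    EM-based genotype r².  Replicates where either locus ends monomorphic or
    below ``maf_min`` in the sample are discarded, mirroring chip
    ascertainment.  Returns the retained r² values (possibly fewer than
    requested if drift fixes too many replicates).

    This is the generator's calibration experiment against Sved's
    E(r²) = 1/(2 + 4 Ne c) + 1/n; see the methods note for the accuracy
    actually attained (the relationship is approximate, not exact).
    """
    if ne <= 0 or c <= 0 or n < 1:
        raise ValueError("ne, c must be positive and n >= 1")
    rng = np.random.default_rng(seed)
    gens = 4 * ne if burn_in is None else burn_in
    # drift fixes most replicates during burn-in; oversample accordingly
    n_chains = int(n_replicates * 40)
    counts = rng.multinomial(2 * ne, np.full((n_chains, 4), 0.25))
    rec = 0.5 * (1.0 - np.exp(-2.0 * c))
    sign = np.array([1.0, -1.0, -1.0, 1.0])
    for _ in range(gens):
        f = counts / (2.0 * ne)
        d = f[:, 0] * f[:, 3] - f[:, 1] * f[:, 2]
        p = f - np.outer(d, sign) * rec
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        counts = rng.multinomial(2 * ne, p)

    from .ld import _em_core  # deferred to avoid an import cycle

    tables = []
    for k in range(n_chains):
        if len(tables) >= n_replicates:
            break
        hap_counts = rng.multivariate_hypergeometric(counts[k], 2 * n)
        haps = np.repeat(np.arange(4), hap_counts)
        rng.shuffle(haps)
        ga = (haps >= 2).astype(np.int8)  # allele 2 at locus A
        gb = (haps % 2).astype(np.int8)  # allele 2 at locus B
        da = ga[0::2] + ga[1::2]
        db = gb[0::2] + gb[1::2]
        fa = da.sum() / (2 * n)
        fb = db.sum() / (2 * n)
        if min(fa, 1 - fa) < maf_min or min(fb, 1 - fb) < maf_min:
            continue
        table = np.zeros((3, 3), dtype=np.int64)
        np.add.at(table, (da, db), 1)
        tables.append(table)

    if not tables:
        return np.empty(0)
    batch = np.stack(tables)
    p11, p12, p21, p22, pa, pb = _em_core(batch)
    denom = pa * (1 - pa) * pb * (1 - pb)
    d = p11 * p22 - p12 * p21
    return np.clip(d**2 / denom, 0.0, 1.0)
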