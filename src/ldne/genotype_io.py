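"""Read/write PLINK text genotype formats and summarize marker maps.

Genotypes are held as an individuals x loci matrix of allele-B dosage codes
(0, 1, 2) with ``-1`` marking a missing call.  The marker map is a pandas
DataFrame with one row per SNP, sorted by chromosome and physical position.

Coordinates are 1-based base pairs; Mb = 10^6 bp and kb = 10^3 bp throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "MAP_COLUMNS",
    "GenotypeMatrix",
    "PedParseError",
    "read_ped_map",
    "write_ped_map",
    "read_vcf",
    "summarize_map",
    "genome_totals",
    "validate_snp_map",
]

logger = logging.getLogger(__name__)

#: genotype code for a missing call
MISSING: int = -1

#: required columns of a SNP map frame
MAP_COLUMNS = ("chrom", "snp_id", "genetic_pos", "physical_pos", "allele_a", "allele_b")


class PedParseError(ValueError):
    """Raised for malformed PED/MAP input; the message carries the line number."""


@dataclass
class GenotypeMatrix:
    """Diploid genotypes for a panel of individuals.

    Attributes
    ----------
    codes:
        ``(n_individuals, n_snps)`` int8 array; entry = count of allele B
        (0, 1 or 2), or :data:`MISSING`.
    samples:
        One row per individual with the six PLINK pedigree columns
        (``fid iid father mother sex phenotype``).
    """

    codes: np.ndarray
    samples: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D individuals x SNPs array")
        bad = ~np.isin(self.codes, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError(f"{bad.sum()} genotype codes outside {{0,1,2,{MISSING}}}")
        if self.samples is None:
            n = self.codes.shape[0]
            self.samples = default_samples(n)
        if len(self.samples) != self.codes.shape[0]:
            raise ValueError("sample table length does not match genotype rows")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.codes.copy(), self.samples.copy())


def default_samples(n: int) -> pd.DataFrame:
    """Placeholder pedigree table for *n* individuals."""
    return pd.DataFrame(
        {
            "fid": [f"F{i+1}" for i in range(n)],
            "iid": [f"I{i+1}" for i in range(n)],
            "father": ["0"] * n,
            "mother": ["0"] * n,
            "sex": ["0"] * n,
            "phenotype": ["-9"] * n,
        }
    )


def validate_snp_map(snp_map: pd.DataFrame) -> pd.DataFrame:
    """Check map invariants; returns the (possibly flagged) frame.

    Positions must be >= 1 and sorted within each chromosome.  Duplicate
    physical positions are allowed but flagged in a boolean
    ``duplicate_pos`` column and logged.
    """
    missing_cols = [c for c in MAP_COLUMNS if c not in snp_map.columns]
    if missing_cols:
        raise ValueError(f"snp map missing columns: {missing_cols}")
    if (snp_map["physical_pos"] < 1).any():
        raise ValueError("physical positions must be >= 1 (1-based bp)")
    for chrom, grp in snp_map.groupby("chrom", sort=False):
        pos = grp["physical_pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"map not sorted by position within chromosome {chrom}")
    dup = snp_map.duplicated(subset=["chrom", "physical_pos"], keep=False)
    snp_map = snp_map.copy()
    snp_map["duplicate_pos"] = dup.to_numpy()
    if dup.any():
        logger.warning("%d SNPs share a physical position with another SNP", int(dup.sum()))
    return snp_map


def _read_map(map_path: Path) -> pd.DataFrame:
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 4:
                raise PedParseError(
                    f"{map_path}:{lineno}: expected 4 MAP columns, found {len(tok)}"
                )
            rows.append((tok[0], tok[1], float(tok[2]), int(tok[3])))
    frame = pd.DataFrame(rows, columns=["chrom", "snp_id", "genetic_pos", "physical_pos"])
    return frame


def read_ped_map(
    ped_path: str | Path,
    map_path: str | Path,
    alleles: Mapping[str, tuple[str, str]] | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Parse PLINK text PED/MAP files into a genotype matrix and SNP map.

    Allele B (the counted allele) is the lexicographically second allele
    observed at each SNP unless *alleles* supplies an explicit
    ``snp_id -> (allele_a, allele_b)`` mapping.  ``0 0`` is a missing call.
    Malformed rows raise :class:`PedParseError` naming the offending line.
    """
    ped_path, map_path = Path(ped_path), Path(map_path)
    snp_map = _read_map(map_path)
    m = len(snp_map)

    sample_rows: list[tuple[str, ...]] = []
    allele_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 6 + 2 * m:
                raise PedParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} fields "
                    f"(6 + 2x{m} SNPs from {map_path.name}), found {len(tok)}"
                )
            sample_rows.append(tuple(tok[:6]))
            allele_rows.append(np.array(tok[6:], dtype="U8").reshape(m, 2))

    n = len(sample_rows)
    samples = pd.DataFrame(
        sample_rows, columns=["fid", "iid", "father", "mother", "sex", "phenotype"]
    )
    codes = np.full((n, m), MISSING, dtype=np.int8)
    allele_a = np.empty(m, dtype=object)
    allele_b = np.empty(m, dtype=object)
    calls = np.stack(allele_rows, axis=0) if n else np.empty((0, m, 2), dtype="U8")

    for j in range(m):
        col = calls[:, j, :] if n else np.empty((0, 2), dtype="U8")
        called = ~np.any(col == "0", axis=1) if n else np.zeros(0, bool)
        observed = sorted(set(col[called].ravel().tolist()))
        if len(observed) > 2:
            raise PedParseError(
                f"{ped_path}: SNP {snp_map['snp_id'].iat[j]} (column {j + 1}) has "
                f"{len(observed)} alleles: {observed}"
            )
        snp_id = snp_map["snp_id"].iat[j]
        if alleles is not None and snp_id in alleles:
            a, b = alleles[snp_id]
        else:
            a = observed[0] if observed else "0"
            b = observed[1] if len(observed) > 1 else "0"
        allele_a[j], allele_b[j] = a, b
        if n:
            codes[called, j] = (col[called] == b).sum(axis=1)

    snp_map = snp_map.assign(allele_a=allele_a, allele_b=allele_b)
    snp_map = validate_snp_map(snp_map)
    return GenotypeMatrix(codes, samples), snp_map


def write_ped_map(
    genotypes: GenotypeMatrix, snp_map: pd.DataFrame, out_prefix: str | Path
) -> tuple[Path, Path]:
    """Write space-delimited PED/MAP files; inverse of :func:`read_ped_map`.

    Missing genotypes are written as ``0 0``.  Returns the two paths.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    ped_path = out_prefix.with_suffix(".ped")
    map_path = out_prefix.with_suffix(".map")

    with open(map_path, "w") as fh:
        for row in snp_map.itertuples(index=False):
            gpos = row.genetic_pos
            gpos_s = repr(float(gpos)) if gpos else "0"
            fh.write(f"{row.chrom} {row.snp_id} {gpos_s} {int(row.physical_pos)}\n")

    a = snp_map["allele_a"].to_numpy(dtype=object)
    b = snp_map["allele_b"].to_numpy(dtype=object)
    with open(ped_path, "w") as fh:
        for i in range(genotypes.n_individuals):
            lead = " ".join(str(v) for v in genotypes.samples.iloc[i])
            parts = [lead]
            row = genotypes.codes[i]
            for j, g in enumerate(row):
                if g == MISSING:
                    parts.append("0 0")
                elif g == 0:
                    parts.append(f"{a[j]} {a[j]}")
                elif g == 1:
                    parts.append(f"{a[j]} {b[j]}")
                else:
                    parts.append(f"{b[j]} {b[j]}")
            fh.write(" ".join(parts) + "\n")
    return ped_path, map_path


def read_vcf(vcf_path: str | Path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read biallelic SNPs from a VCF into the same containers as PED/MAP.

    Non-biallelic or non-SNP records are skipped and counted in the log.
    Requires :mod:`cyvcf2`.
    """
    from cyvcf2 import VCF  # deferred: optional ingestion path

    vcf = VCF(str(vcf_path), gts012=True)
    samples = default_samples(len(vcf.samples))
    samples["iid"] = vcf.samples
    rows, cols, skipped = [], [], 0
    for var in vcf:
        if not var.is_snp or len(var.ALT) != 1:
            skipped += 1
            continue
        rows.append((var.CHROM, var.ID or f"{var.CHROM}:{var.POS}", 0.0, var.POS,
                     var.REF, var.ALT[0]))
        g = var.gt_types.astype(np.int8)  # 0,1,2 and 3 = unknown
        g[g == 3] = MISSING
        cols.append(g)
    if skipped:
        logger.info("skipped %d non-biallelic/non-SNP VCF records", skipped)
    snp_map = pd.DataFrame(rows, columns=list(MAP_COLUMNS))
    codes = np.stack(cols, axis=1) if cols else np.empty((len(vcf.samples), 0), np.int8)
    return GenotypeMatrix(codes, samples), validate_snp_map(snp_map)


def summarize_map(
    snp_map: pd.DataFrame,
    chrom_lengths: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-chromosome marker-density summary plus genome totals.

    For each chromosome: SNP count, length in Mb (the supplied assembly
    length if given, else the last SNP position), mean inter-SNP interval
    defined as length / n_snps, and the longest/shortest adjacent-SNP gaps.
    Chromosomes with a single SNP report undefined (NaN) intervals.

    Returns ``(rows, totals)`` where *totals* has the summed length, summed
    SNP count and mean chromosome length.
    """
    if len(snp_map) == 0:
        raise ValueError("empty SNP map")
    rows = []
    for chrom, grp in snp_map.groupby("chrom", sort=False):
        pos = np.sort(grp["physical_pos"].to_numpy(dtype=float))
        n = len(pos)
        if chrom_lengths is not None and chrom in chrom_lengths:
            length_mb = float(chrom_lengths[chrom])
        else:
            length_mb = pos[-1] / 1e6
        if n >= 2:
            gaps = np.diff(pos)
            longest_mb = gaps.max() / 1e6
            shortest_kb = gaps.min() / 1e3
        else:
            longest_mb = np.nan
            shortest_kb = np.nan
        rows.append(
            {
                "chromosome": chrom,
                "length_mb": length_mb,
                "n_snps": n,
                "mean_interval_mb": length_mb / n,
                "longest_interval_mb": longest_mb,
                "shortest_interval_kb": shortest_kb,
            }
        )
    frame = pd.DataFrame(rows)
    return frame, genome_totals(frame)


def genome_totals(summary_rows: pd.DataFrame) -> dict[str, float]:
    """Genome-level aggregates of a per-chromosome summary table.

    Works on any frame with ``length_mb`` and ``n_snps`` columns, so printed
    reference tables can be aggregated the same way as computed ones.
    """
    return {
        "total_length_mb": float(summary_rows["length_mb"].sum()),
        "total_snps": int(summary_rows["n_snps"].sum()),
        "mean_length_mb": float(summary_rows["length_mb"].mean()),
        "longest_chromosome_mb": float(summary_rows["length_mb"].max()),
        "shortest_chromosome_mb": float(summary_rows["length_mb"].min()),
    }
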