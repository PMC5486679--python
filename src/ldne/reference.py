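"""Published reference inputs used by examples and the analysis summary.

``OVINE_SNP50_AUTOSOME_SUMMARY`` is the per-autosome marker summary of an
Ovine SNP50 BeadChip panel after QC in a cohort of 635 Chinese Merino
(Xinjiang type) ewes: 26 autosomes with assembly length (Mb) and the number
of SNPs retained.  It serves as a worked input for the map-aggregation
operations (the genotypes themselves are not public).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "OVINE_SNP50_AUTOSOME_SUMMARY",
    "REFERENCE_SAMPLE_SIZE",
    "reference_map_summary",
]

#: diploid sample size of the reference cohort
REFERENCE_SAMPLE_SIZE = 635

_ROWS = [
    # chromosome, length (Mb), SNPs after QC
    ("1", 299.637, 5180),
    ("2", 263.109, 4856),
    ("3", 242.770, 4409),
    ("4", 127.202, 2375),
    ("5", 116.343, 2089),
    ("6", 129.054, 2295),
    ("7", 108.923, 1952),
    ("8", 97.814, 1827),
    ("9", 100.791, 1884),
    ("10", 94.128, 1621),
    ("11", 66.878, 1048),
    ("12", 86.402, 1507),
    ("13", 89.063, 1492),
    ("14", 69.303, 1014),
    ("15", 90.000, 1481),
    ("16", 77.051, 1372),
    ("17", 78.614, 1254),
    ("18", 72.434, 1239),
    ("19", 64.803, 1104),
    ("20", 55.394, 983),
    ("21", 55.476, 781),
    ("22", 55.747, 960),
    ("23", 66.685, 998),
    ("24", 44.851, 648),
    ("25", 48.288, 885),
    ("26", 50.044, 808),
]

OVINE_SNP50_AUTOSOME_SUMMARY: pd.DataFrame = pd.DataFrame(
    _ROWS, columns=["chromosome", "length_mb", "n_snps"]
)


def reference_map_summary() -> pd.DataFrame:
    """Copy of the reference table with the mean SNP interval (length/n) added."""
    df = OVINE_SNP50_AUTOSOME_SUMMARY.copy()
    df["mean_interval_mb"] = df["length_mb"] / df["n_snps"]
    return df
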