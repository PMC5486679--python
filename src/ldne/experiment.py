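"""Pipeline orchestration and the sample-size subsampling experiment.

``run_pipeline`` drives the full analysis from a TOML config: input (PED/MAP
files or a simulation block), marker QC, pairwise r² with distance binning,
Sved Ne trajectories, diversity statistics, and optionally the subsampling
experiment in which LD is re-estimated on random individual subsets of
several sizes and the short-range r² values are compared by one-way ANOVA
with least-significant-difference (LSD) pairwise tests.

QC is computed once on the full panel and the surviving SNP set is reused
for every subsample: re-running MAF-driven QC per subset would change the
marker set with sample size and confound the comparison.
"""

from __future__ import annotations

import shutil
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import __version__
from .diversity import diversity_summary
from .genotype_io import GenotypeMatrix, read_ped_map, summarize_map
from .ld import DEFAULT_BIN_EDGES_BP, LdScanStats, bin_ld, pairwise_ld
from .ne import ne_trajectory
from .qc import QcThresholds, apply_qc_filters
from .simulate import SimulationConfig, simulate_population

__all__ = [
    "SubsampleResult",
    "AnovaResult",
    "PipelineError",
    "subsample_ld",
    "one_way_anova_lsd",
    "run_pipeline",
]

#: distance window whose mean r² summarizes each subsample (short-range LD)
FOCUS_WINDOW_BP = (0, 50_000)


@dataclass
class SubsampleResult:
    """LD of one random individual subset."""

    sample_size: int
    seed: int
    bins_genome: pd.DataFrame
    focus_mean_r2: float
    focus_r2: np.ndarray = field(repr=False)

    @property
    def focus_n_pairs(self) -> int:
        return len(self.focus_r2)


@dataclass
class AnovaResult:
    """One-way ANOVA with LSD pairwise comparisons and letter grouping."""

    group_means: pd.Series
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    lsd: pd.DataFrame
    letters: dict[str, str]
    alpha: float = 0.05


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def subsample_ld(
    genotypes: GenotypeMatrix,
    snp_map: pd.DataFrame,
    sizes: Sequence[int | None] = (30, 50, 100, 200, 400, None),
    seed: int = 1,
    max_distance_bp: int = 10_000_000,
    bin_edges_bp: Sequence[int] = DEFAULT_BIN_EDGES_BP,
) -> list[SubsampleResult]:
    """Re-estimate binned LD on random individual subsets of each size.

    ``None`` (or the full panel size) means all individuals.  Subsets are
    drawn without replacement with a generator seeded per size from *seed*,
    so results are reproducible and subsets of different sizes independent.
    The input should already be QC'd; no per-subset QC is applied.
    """
    n_panel = genotypes.n_individuals
    results = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(sizes))
    for size, child in zip(sizes, children):
        eff = n_panel if size is None else int(size)
        if eff > n_panel:
            raise ValueError(f"subsample size {eff} exceeds panel size {n_panel}")
        rng = np.random.default_rng(child)
        if eff == n_panel:
            rows = np.arange(n_panel)
        else:
            rows = np.sort(rng.choice(n_panel, size=eff, replace=False))
        sub = GenotypeMatrix(
            genotypes.codes[rows], genotypes.samples.iloc[rows].reset_index(drop=True)
        )
        focus: list[float] = []

        def tap(pairs: Iterable):
            lo, hi = FOCUS_WINDOW_BP
            for p in pairs:
                if lo < p.distance_bp <= hi:
                    focus.append(p.r2)
                yield p

        bins = bin_ld(
            tap(pairwise_ld(sub, snp_map, max_distance_bp=max_distance_bp)),
            bin_edges_bp=bin_edges_bp,
            scope="genome",
        )
        focus_arr = np.asarray(focus)
        results.append(
            SubsampleResult(
                sample_size=eff,
                seed=seed,
                bins_genome=bins,
                focus_mean_r2=float(focus_arr.mean()) if focus_arr.size else float("nan"),
                focus_r2=focus_arr,
            )
        )
    return results


def one_way_anova_lsd(
    groups: dict[str, np.ndarray], alpha: float = 0.05
) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA plus Fisher's LSD comparisons.

    F is computed from between/within sums of squares; each pair of groups
    is then compared with a two-sided t test using the pooled within-group
    mean square.  Groups whose means are not significantly different share a
    lower-case letter (computed with the standard line algorithm on the
    means sorted in descending order).
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    names = list(groups)
    data = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in data.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has fewer than 2 values")

    sizes = {k: v.size for k, v in data.items()}
    n_total = sum(sizes.values())
    grand = sum(v.sum() for v in data.values()) / n_total
    means = pd.Series({k: v.mean() for k, v in data.items()})
    ss_between = sum(sizes[k] * (means[k] - grand) ** 2 for k in names)
    ss_within = sum(((data[k] - means[k]) ** 2).sum() for k in names)
    df_between = len(names) - 1
    df_within = n_total - len(names)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0:
        f_stat = 0.0 if ms_between == 0 else float("inf")
    else:
        f_stat = ms_between / ms_within
    p_value = float(sps.f.sf(f_stat, df_between, df_within)) if np.isfinite(f_stat) else 0.0

    rows = []
    nonsig: set[tuple[str, str]] = set()
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            se = np.sqrt(ms_within * (1 / sizes[a] + 1 / sizes[b]))
            diff = means[a] - means[b]
            t = diff / se if se > 0 else (0.0 if diff == 0 else np.inf)
            p = float(2 * sps.t.sf(abs(t), df_within)) if np.isfinite(t) else 0.0
            sig = p < alpha
            if not sig:
                nonsig.add((a, b))
                nonsig.add((b, a))
            rows.append(
                {"group_a": a, "group_b": b, "mean_diff": diff, "se": se,
                 "t": t, "p": p, "significant": sig}
            )
    lsd = pd.DataFrame(rows)
    letters = _letter_display(means, nonsig)
    return AnovaResult(
        group_means=means,
        f_statistic=float(f_stat),
        df_between=df_between,
        df_within=df_within,
        p_value=p_value,
        lsd=lsd,
        letters=letters,
        alpha=alpha,
    )


def _letter_display(means: pd.Series, nonsig: set[tuple[str, str]]) -> dict[str, str]:
    """Compact letter display: maximal runs of mutually comparable means
    (sorted descending) that contain no significant pair share a letter."""
    order = list(means.sort_values(ascending=False).index)
    k = len(order)

    def compatible(i: int, j: int) -> bool:
        for a in range(i, j + 1):
            for b in range(a + 1, j + 1):
                if (order[a], order[b]) not in nonsig:
                    return False
        return True

    lines: list[tuple[int, int]] = []
    for i in range(k):
        j = i
        while j + 1 < k and compatible(i, j + 1):
            j += 1
        if not any(lo <= i and j <= hi for lo, hi in lines):
            lines.append((i, j))
    letters = {name: "" for name in order}
    for letter_idx, (lo, hi) in enumerate(lines):
        letter = chr(ord("a") + letter_idx)
        for name in order[lo : hi + 1]:
            letters[name] += letter
    return letters


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.10g"


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def _load_config(config_path: str | Path) -> dict:
    with open(config_path, "rb") as fh:
        return tomllib.load(fh)


def run_pipeline(config_path: str | Path) -> Path:
    """End-to-end run from a TOML config; returns the output directory.

    The config needs an ``[input]`` table (``ped``/``map`` paths) or a
    ``[simulation]`` table, an ``[output] dir``, and optional ``[qc]``,
    ``[ld]``, ``[ne]`` and ``[subsample]`` tables.  Fixed seeds make the run
    byte-reproducible.  On a stage failure the output directory is removed
    and :class:`PipelineError` names the stage.
    """
    cfg = _load_config(config_path)
    if "output" not in cfg or "dir" not in cfg["output"]:
        raise PipelineError("config", "missing [output] table with a 'dir' key")
    out_dir = Path(cfg["output"]["dir"])
    out_dir.mkdir(parents=True, exist_ok=True)

    log_lines = [f"ldne {__version__}"]

    def fail(stage: str, exc: Exception):
        shutil.rmtree(out_dir, ignore_errors=True)
        raise PipelineError(stage, str(exc)) from exc

    # --- input -------------------------------------------------------------
    try:
        if "simulation" in cfg:
            sim_cfg = SimulationConfig(**cfg["simulation"])
            dataset = simulate_population(sim_cfg)
            genotypes, snp_map = dataset.genotypes, dataset.snp_map
            log_lines.append(f"simulated panel: {sim_cfg}")
        elif "input" in cfg:
            for key in ("ped", "map"):
                if key not in cfg["input"]:
                    raise ValueError(f"[input] table is missing the {key!r} key")
            genotypes, snp_map = read_ped_map(cfg["input"]["ped"], cfg["input"]["map"])
            log_lines.append(f"read panel: {cfg['input']['ped']}")
        else:
            raise ValueError("config needs an [input] or [simulation] table")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage boundary
        fail("input", exc)

    log_lines.append(
        f"panel: {genotypes.n_individuals} individuals x {genotypes.n_snps} SNPs"
    )

    try:
        map_rows, totals = summarize_map(snp_map)
        _write(map_rows, out_dir / "map_summary.tsv")
        _write(pd.DataFrame([totals]), out_dir / "map_totals.tsv")
    except Exception as exc:
        fail("map_summary", exc)

    # --- qc ----------------------------------------------------------------
    try:
        thr = QcThresholds(**cfg.get("qc", {}))
        genotypes_qc, map_qc, report = apply_qc_filters(genotypes, snp_map, thr)
        _write(report.snp_stats, out_dir / "qc_snp_stats.tsv")
        _write(
            pd.DataFrame(
                [
                    {
                        "n_input": report.n_input,
                        "removed_call_rate": report.removed_call_rate,
                        "removed_maf": report.removed_maf,
                        "removed_hwe": report.removed_hwe,
                        "n_surviving": report.n_surviving,
                    }
                ]
            ),
            out_dir / "qc_report.tsv",
        )
        log_lines.append(
            f"qc: {report.n_input} -> {report.n_surviving} SNPs "
            f"(call rate {report.removed_call_rate}, maf {report.removed_maf}, "
            f"hwe {report.removed_hwe})"
        )
    except Exception as exc:
        fail("qc", exc)

    # --- ld ----------------------------------------------------------------
    try:
        ld_cfg = cfg.get("ld", {})
        max_dist = int(ld_cfg.get("max_distance_bp", 10_000_000))
        edges = list(ld_cfg.get("bin_edges_bp", DEFAULT_BIN_EDGES_BP))
        scan = LdScanStats()
        genome_bins, chrom_bins = bin_ld(
            pairwise_ld(genotypes_qc, map_qc, max_distance_bp=max_dist, stats=scan),
            bin_edges_bp=edges,
            scope="both",
        )
        _write(genome_bins, out_dir / "ld_bins_genome.tsv")
        _write(chrom_bins, out_dir / "ld_bins_chromosome.tsv")
        log_lines.append(
            f"ld: {scan.n_pairs} pairs <= {max_dist} bp "
            f"({scan.n_skipped_monomorphic} skipped monomorphic)"
        )
    except Exception as exc:
        fail("ld", exc)

    # --- ne ----------------------------------------------------------------
    try:
        ne_cfg = cfg.get("ne", {})
        n_for_ne = ne_cfg.get("n", genotypes_qc.n_individuals)
        kwargs = dict(
            n=n_for_ne,
            cm_per_mb=ne_cfg.get("cm_per_mb", 1.0),
            k=ne_cfg.get("k", 4.0),
            alpha=ne_cfg.get("alpha", 2.0),
        )
        _write(ne_trajectory(genome_bins, **kwargs), out_dir / "ne_genome.tsv")
        _write(ne_trajectory(chrom_bins, **kwargs), out_dir / "ne_chromosome.tsv")
    except Exception as exc:
        fail("ne", exc)

    # --- diversity ---------------------------------------------------------
    try:
        div = diversity_summary(genotypes_qc)
        _write(
            pd.DataFrame(
                [
                    {
                        "p_n": div.p_n,
                        "h_e": div.h_e,
                        "f_mean": div.f_mean,
                        "maf_threshold": div.maf_threshold,
                    }
                ]
            ),
            out_dir / "diversity.tsv",
        )
        _write(
            pd.DataFrame(
                {"iid": genotypes_qc.samples["iid"], "f": div.f_per_individual}
            ),
            out_dir / "inbreeding_individual.tsv",
        )
    except Exception as exc:
        fail("diversity", exc)

    # --- subsample experiment (optional) ------------------------------------
    if "subsample" in cfg:
        try:
            sub_cfg = cfg["subsample"]
            sizes = [None if s in ("all", 0) else int(s) for s in sub_cfg["sizes"]]
            results = subsample_ld(
                genotypes_qc,
                map_qc,
                sizes=sizes,
                seed=int(sub_cfg.get("seed", 1)),
                max_distance_bp=int(sub_cfg.get("max_distance_bp", 10_000_000)),
            )
            _write(
                pd.DataFrame(
                    [
                        {
                            "sample_size": r.sample_size,
                            "focus_lo_bp": FOCUS_WINDOW_BP[0],
                            "focus_hi_bp": FOCUS_WINDOW_BP[1],
                            "focus_mean_r2": r.focus_mean_r2,
                            "focus_n_pairs": r.focus_n_pairs,
                        }
                        for r in results
                    ]
                ),
                out_dir / "subsample_summary.tsv",
            )
            groups = {
                str(r.sample_size): r.focus_r2 for r in results if r.focus_n_pairs >= 2
            }
            if len(groups) >= 2:
                anova = one_way_anova_lsd(groups)
                _write(anova.lsd, out_dir / "subsample_lsd.tsv")
                _write(
                    pd.DataFrame(
                        [
                            {
                                "group": g,
                                "mean_r2": anova.group_means[g],
                                "letters": anova.letters[g],
                            }
                            for g in anova.group_means.index
                        ]
                    ).assign(
                        f=anova.f_statistic,
                        df_between=anova.df_between,
                        df_within=anova.df_within,
                        p=anova.p_value,
                    ),
                    out_dir / "subsample_anova.tsv",
                )
                log_lines.append(
                    f"subsample anova: F={anova.f_statistic:.4g} p={anova.p_value:.4g}"
                )
        except Exception as exc:
            fail("subsample", exc)

    (out_dir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return out_dir
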