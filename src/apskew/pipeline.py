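"""End-to-end report pipeline: normalize -> filter -> skew -> peaks -> enrich.

Wires the stage modules together under a single configuration and a
single seed, writing one result TSV per stage plus a machine-readable
run log. Re-running with the same configuration and seed reproduces
every TSV byte for byte.
"""

from __future__ import annotations

import json
import logging

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chip_signal import mean_normalize, order_by_skew, scale01_per_factor, window_matrix
from .peak_analysis import (
    CLASSES,
    classify_peaks,
    fisher_one_tailed,
    overlap_contingency,
    reproducible_peaks,
)
from .preprocess import apply_normalization, fit_no_intercept, scale_to_depth
from .regions import RegionCatalog, filter_by_peaks, filter_by_signal, load_catalog
from .skew import build_null, compare_groups, score_regions, signal_pair
from .tracks_io import (
    CoverageTrack,
    GenomeTable,
    read_bed,
    read_bedgraph,
    read_genome_table,
    read_wiggle,
    write_wiggle,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_report", "read_track"]

#: float formatting used for every result TSV (determinism + stable diffs)
_FLOAT_FMT = "%.6g"


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def read_track(path, genome: GenomeTable, label: str = "") -> CoverageTrack:
    """Read a coverage track, dispatching on file extension.

    ``.bedgraph``/``.bdg`` are parsed as bedGraph, anything else as
    wiggle.
    """
    suffix = Path(path).suffix.lower()
    if suffix in (".bedgraph", ".bdg"):
        return read_bedgraph(path, genome, label=label)
    return read_wiggle(path, genome, label=label)


@dataclass
class PipelineConfig:
    """Paths and parameters for :func:`run_report`.

    Required: genome plus the three coverage tracks. Peak/TF/ChIP paths
    are optional; stages without inputs are skipped (and logged).
    """

    genome: str
    anterior_track: str
    posterior_track: str
    whole_track: str
    catalog: str | None = None
    region_peak_beds: list[str] = field(default_factory=list)
    peaks_rep1: str | None = None
    peaks_rep2: str | None = None
    peaks_merged: str | None = None
    exclusion_bed: str | None = None
    tf_beds: dict[str, str] = field(default_factory=dict)
    chip_tracks: dict[str, str] = field(default_factory=dict)
    out_dir: str = "apskew_report"
    bin_size: int = 1000
    min_signal: float = 200.0
    k: int = 10
    tolerance: float = 0.05
    max_tries: int = 50_000
    alpha: float = 0.05
    chip_window: int = 3000
    null_max_rois: int = 500
    depth_scale: bool = False
    mapped_reads: dict[str, int] = field(default_factory=dict)
    target_reads: int = 10_000_000
    seed: int = 0
    make_plots: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.bin_size < 1 or self.k < 1 or self.tolerance < 0:
            raise ValueError("bin_size >= 1, k >= 1, tolerance >= 0 required")

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        return cls(**raw)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_report(config: PipelineConfig) -> dict:
    """Run every configured stage; returns the run log dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "apskew_version": __version__,
        "seed": config.seed,
        "parameters": {
            "bin_size": config.bin_size,
            "min_signal": config.min_signal,
            "k": config.k,
            "tolerance": config.tolerance,
            "alpha": config.alpha,
            "chip_window": config.chip_window,
        },
        "stages": {},
    }
    rng = np.random.default_rng(config.seed)

    stage = "load"
    try:
        genome = read_genome_table(config.genome)
        anterior = read_track(config.anterior_track, genome, label="anterior")
        posterior = read_track(config.posterior_track, genome, label="posterior")
        whole = read_track(config.whole_track, genome, label="whole")
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
    log["stages"][stage] = {
        "chromosomes": len(genome),
        "totals": {t.label: t.total() for t in (anterior, posterior, whole)},
    }

    stage = "normalize"
    try:
        if config.depth_scale:
            for name in ("anterior", "posterior", "whole"):
                if name not in config.mapped_reads:
                    raise ValueError(f"depth_scale set but mapped_reads[{name!r}] missing")
            anterior = scale_to_depth(anterior, config.mapped_reads["anterior"], config.target_reads)
            posterior = scale_to_depth(
                posterior, config.mapped_reads["posterior"], config.target_reads
            )
            whole = scale_to_depth(whole, config.mapped_reads["whole"], config.target_reads)
        fit_ant = fit_no_intercept(anterior, whole, bin_size=config.bin_size)
        fit_post = fit_no_intercept(posterior, whole, bin_size=config.bin_size)
        anterior = apply_normalization(anterior, fit_ant)
        posterior = apply_normalization(posterior, fit_post)
        fits = pd.DataFrame(
            [
                {"sample": "anterior", **asdict(fit_ant)},
                {"sample": "posterior", **asdict(fit_post)},
            ]
        )
        _write_tsv(fits, out / "normalization_fits.tsv")
        write_wiggle(anterior, out / "anterior.norm.wig")
        write_wiggle(posterior, out / "posterior.norm.wig")
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
    log["stages"][stage] = {
        "slope_anterior": fit_ant.slope,
        "slope_posterior": fit_post.slope,
        "r_squared_anterior": fit_ant.r_squared,
        "r_squared_posterior": fit_post.r_squared,
    }

    exclusion = None
    if config.exclusion_bed:
        exclusion = read_bed(config.exclusion_bed, genome)

    catalog: RegionCatalog | None = None
    if config.catalog:
        stage = "regions"
        try:
            catalog = load_catalog(config.catalog, genome)
            n0 = len(catalog)
            if config.region_peak_beds:
                peak_sets = [read_bed(p, genome) for p in config.region_peak_beds]
                catalog = filter_by_peaks(catalog, peak_sets)
            n1 = len(catalog)
            catalog = filter_by_signal(catalog, whole, min_signal=config.min_signal)
            n2 = len(catalog)
        except Exception as exc:
            raise PipelineError(stage, exc) from exc
        log["stages"][stage] = {"loaded": n0, "after_peak_filter": n1, "after_signal_filter": n2}

    null = None
    skew_df = None
    if catalog is not None and len(catalog) > 0:
        stage = "skew"
        try:
            rois = list(catalog)
            null = build_null(
                rois,
                anterior,
                posterior,
                whole,
                exclusion=exclusion,
                k=config.k,
                tolerance=config.tolerance,
                max_tries=config.max_tries,
                rng_seed=rng,
            )
            pairs = [signal_pair(r, anterior, posterior, whole) for r in rois]
            skew_df = score_regions(pairs, null)
            _write_tsv(skew_df, out / "skew_results.tsv")
            by_class = {
                cls: sub["positional_skew"].tolist()
                for cls, sub in skew_df[~skew_df["degenerate"]].groupby("class")
                if len(sub) >= 2
            }
            if len(by_class) >= 2:
                comparison = compare_groups(by_class)
                _write_tsv(comparison.tukey, out / "group_tukey.tsv")
                _write_tsv(comparison.ttests, out / "group_ttests.tsv")
                log.setdefault("stages", {})["group_comparison"] = {
                    "anova_f": comparison.anova_f,
                    "anova_p": comparison.anova_p,
                }
        except Exception as exc:
            raise PipelineError(stage, exc) from exc
        log["stages"][stage] = {
            "n_regions": len(catalog),
            "null_mu": null.mu,
            "null_sigma": null.sigma,
            "null_n": int(null.rand_skews.size),
            "n_significant": int(skew_df["significant"].sum()),
        }

    peak_table = None
    repro = None
    if config.peaks_rep1 and config.peaks_rep2 and config.peaks_merged:
        stage = "peaks"
        try:
            rep1 = read_bed(config.peaks_rep1, genome)
            rep2 = read_bed(config.peaks_rep2, genome)
            merged = read_bed(config.peaks_merged, genome)
            repro = reproducible_peaks(rep1, rep2, merged)
            peak_null = null
            if peak_null is None:
                rois = repro
                if len(rois) > config.null_max_rois:
                    idx = rng.choice(len(rois), size=config.null_max_rois, replace=False)
                    rois = [rois[i] for i in sorted(idx)]
                peak_null = build_null(
                    rois,
                    anterior,
                    posterior,
                    whole,
                    exclusion=exclusion,
                    k=config.k,
                    tolerance=config.tolerance,
                    max_tries=config.max_tries,
                    rng_seed=rng,
                )
            peak_table = classify_peaks(repro, anterior, posterior, peak_null)
            _write_tsv(peak_table.table, out / "peak_classes.tsv")
        except Exception as exc:
            raise PipelineError(stage, exc) from exc
        log["stages"][stage] = {
            "rep1": len(rep1),
            "rep2": len(rep2),
            "merged": len(merged),
            "reproducible": len(repro),
            "class_counts": peak_table.counts(),
        }

    if config.tf_beds and peak_table is not None:
        stage = "enrich"
        try:
            rows = []
            for tf_name, tf_path in config.tf_beds.items():
                tf_peaks = read_bed(tf_path, genome)
                for cls in CLASSES:
                    class_peaks = peak_table.peaks_in_class(cls)
                    if not class_peaks:
                        continue
                    table = overlap_contingency(class_peaks, tf_peaks, repro)
                    enr = fisher_one_tailed(table, "enrichment")
                    dep = fisher_one_tailed(table, "depletion")
                    rows.append(
                        {
                            "tf": tf_name,
                            "class": cls,
                            "a": table.a,
                            "b": table.b,
                            "c": table.c,
                            "d": table.d,
                            "odds_ratio": enr.odds_ratio,
                            "p_enrichment": enr.p_one_tailed,
                            "p_depletion": dep.p_one_tailed,
                        }
                    )
            _write_tsv(pd.DataFrame(rows), out / "enrichment.tsv")
        except Exception as exc:
            raise PipelineError(stage, exc) from exc
        log["stages"][stage] = {"n_tests": len(rows)}

    if config.chip_tracks and catalog is not None and skew_df is not None:
        stage = "chipmat"
        try:
            tracks = {
                name: mean_normalize(read_track(path, genome, label=name))
                for name, path in config.chip_tracks.items()
            }
            regions = [r for r in catalog]
            matrix = window_matrix(
                tracks, regions, window=config.chip_window, scaling="mean_normalized"
            )
            matrix = scale01_per_factor(matrix)
            skews = dict(zip(skew_df["name"], skew_df["positional_skew"]))
            matrix = order_by_skew(matrix, skews)
            matrix.to_tsv(out / "chip_matrix.tsv")
        except Exception as exc:
            raise PipelineError(stage, exc) from exc
        log["stages"][stage] = {"n_regions": len(matrix.values), "n_factors": len(matrix.factors)}

    if config.make_plots and skew_df is not None:
        stage = "plots"
        try:
            _skew_barplot(skew_df, out / "skew_barplot.png")
        except Exception as exc:  # plotting must never sink the run
            logger.warning("plotting failed: %s", exc)

    log_path = out / "run_log.json"
    with open(log_path, "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return log


def _skew_barplot(skew_df: pd.DataFrame, path: Path) -> None:
    """Per-region positional skew bars, significant regions starred."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = skew_df[~skew_df["degenerate"]].sort_values(
        ["positional_skew", "name"], ascending=[False, True]
    )
    colors = df["positional_skew"].map(lambda s: "#e08214" if s > 0 else "#5aa2cc")
    fig, ax = plt.subplots(figsize=(max(6, 0.12 * len(df)), 4))
    ax.bar(range(len(df)), df["positional_skew"], color=list(colors))
    for i, (skew, sig) in enumerate(zip(df["positional_skew"], df["significant"])):
        if sig:
            ax.annotate("*", (i, skew), ha="center", fontsize=8)
    ax.set_ylabel("positional skew")
    ax.set_xlabel("regions (sorted)")
    ax.set_ylim(-1.05, 1.05)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
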