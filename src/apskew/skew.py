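"""Accessibility skew statistics and the signal-matched random-region null.

The central quantity is the positional skew score of a region,

    skew = (X_anterior - X_posterior) / (X_anterior + X_posterior),

where X is the normalized per-region accessibility signal in each
embryo half: +1 means all signal anterior, -1 all posterior, 0 equal.
The accessibility skew score is the same ratio oriented by the half in
which the region is expected to be active, so positive values mean
"more accessible where active".

Significance of a region's skew is assessed against random genomic
regions matched to it in length and total reference signal (drawn
outside an exclusion mask of genes and annotated regulatory regions).
The positional skews of the matched regions pool into an approximately
normal null; a region's z-score against that null yields a two-tailed
normal p-value, called significant at p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .regions import Region, _IntervalIndex
from .tracks_io import CoverageTrack, Interval

__all__ = [
    "RegionSignalPair",
    "SkewResult",
    "NullModel",
    "MatchError",
    "positional_skew",
    "accessibility_skew",
    "accessibility_skew_for_region",
    "draw_matched_regions",
    "build_null",
    "score_region",
    "score_regions",
    "compare_groups",
    "signal_pair",
]

ALPHA = 0.05  # per-region significance threshold on the raw two-tailed p


def positional_skew(x_anterior, x_posterior):
    """(ant - post) / (ant + post); vectorized; requires non-negative input.

    Raises on negative input. A both-zero pair is degenerate and raises
    here; pipeline callers route such regions through the degenerate
    path of :func:`score_region` instead.
    """
    a = np.asarray(x_anterior, dtype=np.float64)
    p = np.asarray(x_posterior, dtype=np.float64)
    if np.any(a < 0) or np.any(p < 0):
        raise ValueError("skew inputs must be non-negative")
    denom = a + p
    if np.any(denom == 0):
        raise ValueError("degenerate pair: both halves have zero signal")
    out = (a - p) / denom
    return float(out) if out.ndim == 0 else out


def accessibility_skew(x_active, x_inactive):
    """(active - inactive) / (active + inactive): skew oriented by activity."""
    return positional_skew(x_active, x_inactive)


def accessibility_skew_for_region(region: Region, x_anterior: float, x_posterior: float) -> float:
    """Orient the positional skew by the region's expected active half.

    Equals +positional_skew for anterior regions and -positional_skew
    for posterior regions; undefined (error) for D-V regions.
    """
    half = region.expected_active_half
    if half == "anterior":
        return accessibility_skew(x_anterior, x_posterior)
    if half == "posterior":
        return accessibility_skew(x_posterior, x_anterior)
    raise ValueError(f"region {region.name!r} has no A-P active half ({half})")


@dataclass(frozen=True)
class RegionSignalPair:
    """Per-region signal in each half (and the whole-embryo reference)."""

    region: Region | None
    x_anterior: float
    x_posterior: float
    x_whole: float = 0.0

    def __post_init__(self) -> None:
        for v in (self.x_anterior, self.x_posterior, self.x_whole):
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"signals must be finite and non-negative, got {v}")

    @property
    def degenerate(self) -> bool:
        return self.x_anterior == 0.0 and self.x_posterior == 0.0


@dataclass(frozen=True)
class SkewResult:
    pair: RegionSignalPair
    positional_skew: float
    accessibility_skew: float | None  # None for D-V regions
    z: float
    p: float
    significant: bool
    degenerate: bool = False


class MatchError(RuntimeError):
    """Raised when too few signal-matched random regions can be drawn."""


@dataclass
class NullModel:
    """Pooled positional skews of signal-matched random regions.

    The pooled scores are fitted by a single normal (mu, sigma); the
    D'Agostino-Pearson K^2 statistic is reported as a normality check
    (NaN when there are too few scores to compute it).
    """

    matched_regions: list[tuple[Region | Interval, list[Interval]]]
    rand_skews: np.ndarray
    mu: float
    sigma: float
    normality_stat: float
    normality_p: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("degenerate null: sigma must be > 0")


def draw_matched_regions(
    length: int,
    roi_total: float,
    reference: CoverageTrack,
    exclusion: list[Interval] | None = None,
    k: int = 10,
    tolerance: float = 0.05,
    max_tries: int = 50_000,
    rng: np.random.Generator | int | None = None,
) -> list[Interval]:
    """Draw ``k`` random regions matching a region of interest.

    Candidates are uniform over genome positions, rejected unless they
    (a) avoid the exclusion mask entirely, (b) have the ROI's length,
    and (c) have total reference signal within ``tolerance`` (relative)
    of ``roi_total``. The first ``k`` acceptable candidates under the
    seeded generator are returned.

    Raises
    ------
    MatchError
        If fewer than ``k`` matches are found within ``max_tries``
        candidate draws; the message reports the best relative deviation
        achieved.
    """
    if roi_total <= 0:
        raise ValueError("roi_total must be positive")
    if k < 1:
        raise ValueError("k must be >= 1")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    rng = np.random.default_rng(rng)
    genome = reference.genome
    chroms = [c for c, l in genome.entries if l >= length]
    if not chroms:
        raise MatchError(f"no chromosome can hold a region of length {length}")
    n_positions = np.array([genome.lengths[c] - length + 1 for c in chroms], dtype=np.float64)
    probs = n_positions / n_positions.sum()
    index = _IntervalIndex(exclusion or [])

    matches: list[Interval] = []
    best_dev = np.inf
    tries = 0
    batch = max(256, min(4096, max_tries))
    while tries < max_tries and len(matches) < k:
        m = min(batch, max_tries - tries)
        tries += m
        ci = rng.choice(len(chroms), size=m, p=probs)
        for c_idx in np.unique(ci):
            chrom = chroms[c_idx]
            n = int((ci == c_idx).sum())
            starts = rng.integers(0, genome.lengths[chrom] - length + 1, size=n)
            ends = starts + length
            ok = ~index.overlaps_batch(chrom, starts, ends)
            cs = reference.cumsum(chrom)
            totals = cs[ends] - cs[starts]
            dev = np.abs(totals - roi_total) / roi_total
            if np.any(ok):
                best_dev = min(best_dev, float(dev[ok].min()))
            accept = ok & (dev <= tolerance)
            for s in starts[accept]:
                matches.append(Interval(chrom, int(s), int(s) + length))
                if len(matches) == k:
                    break
            if len(matches) == k:
                break
    if len(matches) < k:
        raise MatchError(
            f"found {len(matches)}/{k} matched regions in {tries} tries "
            f"(best relative signal deviation {best_dev:.4g}, tolerance {tolerance:g})"
        )
    return matches


def signal_pair(
    region: Region,
    anterior: CoverageTrack,
    posterior: CoverageTrack,
    whole: CoverageTrack | None = None,
) -> RegionSignalPair:
    """Extract the half-embryo (and whole) totals for a region."""
    iv = region.interval
    return RegionSignalPair(
        region=region,
        x_anterior=anterior.interval_total(iv.chrom, iv.start, iv.end),
        x_posterior=posterior.interval_total(iv.chrom, iv.start, iv.end),
        x_whole=whole.interval_total(iv.chrom, iv.start, iv.end) if whole is not None else 0.0,
    )


def build_null(
    rois: list[Region] | list[Interval],
    anterior: CoverageTrack,
    posterior: CoverageTrack,
    reference: CoverageTrack,
    exclusion: list[Interval] | None = None,
    k: int = 10,
    tolerance: float = 0.05,
    max_tries: int = 50_000,
    rng_seed: int | np.random.Generator | None = None,
    min_scores: int = 10,
) -> NullModel:
    """Build the pooled random-region null for a set of regions of interest.

    For every ROI, ``k`` random regions matched on length and total
    reference signal are drawn; the positional skew of each matched
    region (its RandSkewScore) is computed from the same anterior and
    posterior tracks used for the ROIs. The pooled scores give the null
    mean ``mu`` and standard deviation ``sigma``.
    """
    rng = np.random.default_rng(rng_seed)
    matched: list[tuple[Region | Interval, list[Interval]]] = []
    skews: list[float] = []
    n_zero = 0
    for roi in rois:
        iv = roi.interval if isinstance(roi, Region) else roi
        roi_total = reference.interval_total(iv.chrom, iv.start, iv.end)
        if roi_total <= 0:
            n_zero += 1
            continue
        draws = draw_matched_regions(
            length=len(iv),
            roi_total=roi_total,
            reference=reference,
            exclusion=exclusion,
            k=k,
            tolerance=tolerance,
            max_tries=max_tries,
            rng=rng,
        )
        matched.append((roi, draws))
        for d in draws:
            a = anterior.interval_total(d.chrom, d.start, d.end)
            p = posterior.interval_total(d.chrom, d.start, d.end)
            if a + p > 0:
                skews.append(float((a - p) / (a + p)))
    rand = np.asarray(skews, dtype=np.float64)
    if rand.size < min_scores:
        raise MatchError(
            f"only {rand.size} random skew scores pooled (need >= {min_scores})"
        )
    mu = float(rand.mean())
    sigma = float(rand.std(ddof=1))
    # proportional tracks give bit-near-identical scores; sigma ~ 1e-17 is 0
    if sigma <= 1e-12:
        raise ValueError("degenerate null: all RandSkewScores identical (sigma = 0)")
    if rand.size >= 20:
        k2, k2_p = stats.normaltest(rand)
        k2, k2_p = float(k2), float(k2_p)
    else:
        k2 = k2_p = float("nan")
    return NullModel(
        matched_regions=matched,
        rand_skews=rand,
        mu=mu,
        sigma=sigma,
        normality_stat=k2,
        normality_p=k2_p,
    )


def score_region(pair: RegionSignalPair, null: NullModel) -> SkewResult:
    """z- and p-value of a region's positional skew under the pooled null.

    z = (skew - mu) / sigma, p = 2 * (1 - Phi(|z|)); significant at
    p < 0.05. Regions with zero signal in both halves are flagged
    degenerate: skew reported as 0, z and p unset (NaN), not significant.
    """
    if pair.degenerate:
        return SkewResult(
            pair=pair,
            positional_skew=0.0,
            accessibility_skew=None,
            z=float("nan"),
            p=float("nan"),
            significant=False,
            degenerate=True,
        )
    skew = positional_skew(pair.x_anterior, pair.x_posterior)
    acc: float | None = None
    if pair.region is not None and pair.region.axis == "AP":
        acc = accessibility_skew_for_region(pair.region, pair.x_anterior, pair.x_posterior)
    z = (skew - null.mu) / null.sigma
    p = float(2.0 * stats.norm.sf(abs(z)))
    return SkewResult(
        pair=pair,
        positional_skew=float(skew),
        accessibility_skew=acc,
        z=float(z),
        p=p,
        significant=p < ALPHA,
        degenerate=False,
    )


def score_regions(pairs: list[RegionSignalPair], null: NullModel) -> pd.DataFrame:
    """Score many regions; adds Benjamini-Hochberg q-values for reference.

    Per-region significance stays the raw p < 0.05 call; the q column is
    reported alongside but never drives the significance flag.
    """
    from statsmodels.stats.multitest import multipletests

    results = [score_region(p, null) for p in pairs]
    df = pd.DataFrame(
        {
            "name": [p.region.name if p.region is not None else "" for p in pairs],
            "chrom": [p.region.interval.chrom if p.region is not None else "" for p in pairs],
            "start": [p.region.interval.start if p.region is not None else -1 for p in pairs],
            "end": [p.region.interval.end if p.region is not None else -1 for p in pairs],
            "kind": [p.region.kind if p.region is not None else "" for p in pairs],
            "class": [p.region.expected_active_half if p.region is not None else "" for p in pairs],
            "x_anterior": [p.x_anterior for p in pairs],
            "x_posterior": [p.x_posterior for p in pairs],
            "x_whole": [p.x_whole for p in pairs],
            "positional_skew": [r.positional_skew for r in results],
            "accessibility_skew": [
                np.nan if r.accessibility_skew is None else r.accessibility_skew for r in results
            ],
            "z": [r.z for r in results],
            "p": [r.p for r in results],
            "significant": [r.significant for r in results],
            "degenerate": [r.degenerate for r in results],
        }
    )
    ok = df["p"].notna()
    df["q_bh"] = np.nan
    if ok.any():
        df.loc[ok, "q_bh"] = multipletests(df.loc[ok, "p"], method="fdr_bh")[1]
    return df


@dataclass(frozen=True)
class GroupComparison:
    """Tukey HSD table plus unadjusted pairwise Welch-free t-tests."""

    tukey: pd.DataFrame  # columns: group1, group2, diff, lwr, upr, p_adj
    ttests: pd.DataFrame  # columns: group1, group2, t, p
    anova_f: float
    anova_p: float


def compare_groups(results_by_class: dict[str, list[float]]) -> GroupComparison:
    """Compare mean positional skew across region classes.

    One-way fixed-effects ANOVA with Tukey's honestly-significant-
    difference procedure for multiplicity-adjusted pairwise contrasts
    ("diff" is mean(group2) - mean(group1)), plus plain unadjusted
    two-sample t-tests for each pair.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    if len(results_by_class) < 2:
        raise ValueError("need at least two classes")
    for cls, scores in results_by_class.items():
        if len(scores) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 observations")
    values = np.concatenate([np.asarray(v, dtype=np.float64) for v in results_by_class.values()])
    labels = np.concatenate(
        [np.repeat(cls, len(v)) for cls, v in results_by_class.items()]
    )
    f, anova_p = stats.f_oneway(*[np.asarray(v, float) for v in results_by_class.values()])
    hsd = pairwise_tukeyhsd(values, labels, alpha=ALPHA)
    tukey = pd.DataFrame(
        hsd.summary().data[1:], columns=[str(c) for c in hsd.summary().data[0]]
    ).rename(columns={"meandiff": "diff", "p-adj": "p_adj", "lower": "lwr", "upper": "upr"})[
        ["group1", "group2", "diff", "lwr", "upr", "p_adj"]
    ]
    # statsmodels rounds the summary table; recompute exact quantities
    tukey["diff"] = [
        float(np.mean(results_by_class[g2]) - np.mean(results_by_class[g1]))
        for g1, g2 in zip(tukey["group1"], tukey["group2"])
    ]
    tukey["p_adj"] = np.asarray(hsd.pvalues, dtype=np.float64)
    tukey["lwr"] = np.asarray(hsd.confint[:, 0], dtype=np.float64)
    tukey["upr"] = np.asarray(hsd.confint[:, 1], dtype=np.float64)
    rows = []
    classes = list(results_by_class)
    for i, g1 in enumerate(classes):
        for g2 in classes[i + 1 :]:
            t, p = stats.ttest_ind(results_by_class[g1], results_by_class[g2])
            rows.append({"group1": g1, "group2": g2, "t": float(t), "p": float(p)})
    return GroupComparison(
        tukey=tukey,
        ttests=pd.DataFrame(rows),
        anova_f=float(f),
        anova_p=float(anova_p),
    )
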