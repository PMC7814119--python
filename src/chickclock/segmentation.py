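"""Low-methylated region (LMR) segmentation of a methylome.

LMRs are short stretches of reduced CpG methylation that mark distal
regulatory elements; unmethylated regions (UMRs) are longer CpG-island-like
segments. Segmentation here is: running-mean smoothing over neighbouring
CpGs, maximal runs of smoothed methylation below a cutoff m, a minimum-CpG
filter, and a CpG-count split into LMR vs UMR. The cutoff can be calibrated
against a shuffled-methylome null so that the expected fraction of spurious
segments stays below a target false-discovery proportion.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .intervals import GenomicIntervalSet, merge_intervals
from .io import MethylationTrack

__all__ = [
    "SegmentationConfig",
    "smooth_methylation",
    "segment_low_methylated",
    "classify_segments",
    "calibrate_cutoff_fdr",
    "pool_interval_sets",
    "segment_lmrs",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Knobs of the LMR caller.

    smooth_k: odd number of CpGs in the centred running mean (3 smooths
    single-CpG noise without blurring region edges). m_cutoff: smoothed
    methylation below which a CpG counts as "low". min_cpgs_segment: shortest
    reportable segment. umr_cpg_threshold: segments with at least this many
    CpGs are classed UMR instead of LMR. fdr_target/null_shuffles/seed drive
    the shuffle-null cutoff calibration.
    """

    smooth_k: int = 3
    m_cutoff: float = 0.5
    min_cpgs_segment: int = 4
    umr_cpg_threshold: int = 30
    fdr_target: float = 0.05
    null_shuffles: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.m_cutoff < 1):
            raise ValueError("m_cutoff must be in (0, 1)")
        if self.smooth_k < 1 or self.smooth_k % 2 == 0:
            raise ValueError("smooth_k must be a positive odd integer")
        if self.min_cpgs_segment < 1:
            raise ValueError("min_cpgs_segment must be >= 1")
        if not (0 < self.fdr_target < 1):
            raise ValueError("fdr_target must be in (0, 1)")


def _running_mean(values: np.ndarray, k: int) -> np.ndarray:
    """Centred running mean over k nearest entries, truncated at the edges.

    NaNs are excluded from both numerator and denominator; positions whose
    whole window is NaN stay NaN.
    """
    h = k // 2
    v = np.nan_to_num(values, nan=0.0)
    w = (~np.isnan(values)).astype(float)
    csum = np.concatenate([[0.0], np.cumsum(v)])
    ccnt = np.concatenate([[0.0], np.cumsum(w)])
    n = len(values)
    idx = np.arange(n)
    lo = np.maximum(idx - h, 0)
    hi = np.minimum(idx + h + 1, n)
    cnt = ccnt[hi] - ccnt[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(cnt > 0, (csum[hi] - csum[lo]) / np.where(cnt > 0, cnt, 1), np.nan)
    return out


def smooth_methylation(track: MethylationTrack, smooth_k: int = 3) -> np.ndarray:
    """Per-CpG running-mean methylation, computed within each chromosome."""
    if smooth_k < 1 or smooth_k % 2 == 0:
        raise ValueError("smooth_k must be a positive odd integer")
    ratio = track.ratio
    out = np.full(len(ratio), np.nan)
    for _, idx in track.data.groupby("chrom", sort=False).indices.items():
        out[idx] = _running_mean(ratio[idx], smooth_k)
    return out


def _runs_below(smoothed: np.ndarray, cutoff: float) -> list[tuple[int, int]]:
    """Maximal runs (start, stop) of entries strictly below cutoff (NaN breaks)."""
    low = smoothed < cutoff  # NaN compares False
    if not low.any():
        return []
    d = np.diff(low.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if low[0]:
        starts.insert(0, 0)
    if low[-1]:
        stops.append(len(low))
    return list(zip(starts, stops))


def segment_low_methylated(
    track: MethylationTrack, smoothed: np.ndarray, config: SegmentationConfig
) -> GenomicIntervalSet:
    """Call segments as maximal runs of smoothed methylation < m_cutoff.

    Runs shorter than min_cpgs_segment are discarded. A segment spans from
    the first CpG of its run to the last (0-based half-open, so the interval
    covers the last cytosine base); n_cpgs is the run length and
    mean_methylation the mean of the *unsmoothed* ratios in the run.
    """
    ratio = track.ratio
    rows = []
    # groupby(sort=True) makes the output independent of input chromosome order
    for chrom, idx in sorted(track.data.groupby("chrom", sort=True).indices.items()):
        pos = track.data["pos"].to_numpy()[idx]
        sm = smoothed[idx]
        r = ratio[idx]
        for a, b in _runs_below(sm, config.m_cutoff):
            if b - a < config.min_cpgs_segment:
                continue
            vals = r[a:b]
            rows.append(
                (
                    chrom,
                    int(pos[a]) - 1,           # 0-based start at the first cytosine
                    int(pos[b - 1]),           # half-open end just past the last cytosine
                    "LMR",
                    b - a,
                    float(np.nanmean(vals)) if np.isfinite(vals).any() else np.nan,
                )
            )
    if not rows:
        return GenomicIntervalSet.empty()
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "segment_class", "n_cpgs", "mean_methylation"])
    return classify_segments(GenomicIntervalSet(df), config.umr_cpg_threshold)


def classify_segments(intervals: GenomicIntervalSet, umr_cpg_threshold: int = 30) -> GenomicIntervalSet:
    """Class segments with >= umr_cpg_threshold CpGs as UMR, the rest as LMR."""
    df = intervals.data.copy()
    df["segment_class"] = np.where(df["n_cpgs"] >= umr_cpg_threshold, "UMR", "LMR")
    return GenomicIntervalSet(df)


def _count_segments(track: MethylationTrack, ratios: np.ndarray, config: SegmentationConfig, cutoff: float) -> int:
    n = 0
    for _, idx in track.data.groupby("chrom", sort=False).indices.items():
        sm = _running_mean(ratios[idx], config.smooth_k)
        n += sum(1 for a, b in _runs_below(sm, cutoff) if b - a >= config.min_cpgs_segment)
    return n


def calibrate_cutoff_fdr(
    track: MethylationTrack, config: SegmentationConfig
) -> tuple[float, pd.DataFrame, bool]:
    """Choose the methylation cutoff m by shuffle-null false-discovery control.

    For each candidate m on a 0.1..0.9 grid, the false-discovery proportion is
    estimated as (mean segment count over position-preserving within-chromosome
    permutations of the ratios) / (observed segment count). Permuting ratios
    while keeping CpG positions destroys methylation clustering but preserves
    CpG spacing, so surviving segments measure genuine spatial coherence.

    Returns ``(m, fdr_table, warning)`` where m is the LARGEST candidate whose
    estimated FDR is at or below ``config.fdr_target`` — the most sensitive
    cutoff that still controls false discoveries (the estimated FDR grows with
    m, so any smaller qualifying cutoff only loses recall). If no candidate
    qualifies, or the track is degenerate (all ratios identical), the
    configured default cutoff is returned with ``warning=True``.
    """
    ratio = track.ratio
    defined = ratio[~np.isnan(ratio)]
    grid = np.round(np.arange(0.1, 0.95, 0.1), 10)
    if len(defined) < config.min_cpgs_segment or np.all(defined == defined[0]):
        table = pd.DataFrame({"m": grid, "observed": np.nan, "null_mean": np.nan, "fdr": np.nan})
        return config.m_cutoff, table, True

    observed = np.array([_count_segments(track, ratio, config, m) for m in grid], dtype=float)

    rng = np.random.default_rng(config.seed)
    null_counts = np.zeros((config.null_shuffles, len(grid)))
    chrom_groups = list(track.data.groupby("chrom", sort=False).indices.items())
    for s in range(config.null_shuffles):
        shuffled = ratio.copy()
        for _, idx in chrom_groups:
            shuffled[idx] = rng.permutation(ratio[idx])
        for gi, m in enumerate(grid):
            null_counts[s, gi] = _count_segments(track, shuffled, config, m)
    null_mean = null_counts.mean(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        fdr = np.where(observed > 0, null_mean / np.where(observed > 0, observed, 1), np.nan)
    table = pd.DataFrame({"m": grid, "observed": observed, "null_mean": null_mean, "fdr": fdr})

    ok = np.flatnonzero((~np.isnan(fdr)) & (fdr <= config.fdr_target))
    if len(ok) == 0:
        return config.m_cutoff, table, True
    return float(grid[ok[-1]]), table, False


def pool_interval_sets(sets: list[GenomicIntervalSet]) -> GenomicIntervalSet:
    """Union of interval sets, merging overlapping and book-ended intervals.

    Pooling LMR sets called per sample/tissue yields the shared feature space;
    per-segment CpG counts and means are reset (they are re-computed per
    sample later), and the class reverts to 'generic'.
    """
    frames = [s.data[["chrom", "start", "end"]] for s in sets if len(s) > 0]
    if not frames:
        return GenomicIntervalSet.empty()
    merged = merge_intervals(pd.concat(frames, ignore_index=True))
    merged["segment_class"] = "generic"
    merged["n_cpgs"] = 0
    merged["mean_methylation"] = np.nan
    return GenomicIntervalSet(merged)


def segment_lmrs(
    track: MethylationTrack, config: SegmentationConfig | None = None, auto_cutoff: bool = False
) -> tuple[GenomicIntervalSet, dict]:
    """Full single-sample LMR call: (optional) cutoff calibration, smoothing,
    segmentation, LMR/UMR classification.

    Returns the segment set plus a report dict (cutoff used, FDR table when
    calibrated, config).
    """
    config = config or SegmentationConfig()
    report: dict = {"config": config, "cutoff": config.m_cutoff, "calibrated": False}
    if auto_cutoff:
        m, table, warning = calibrate_cutoff_fdr(track, config)
        config = replace(config, m_cutoff=m)
        report.update(cutoff=m, calibrated=not warning, fdr_table=table, warning=warning)
    smoothed = smooth_methylation(track, config.smooth_k)
    return segment_low_methylated(track, smoothed, config), report
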