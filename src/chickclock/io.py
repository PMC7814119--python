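"""Per-CpG methylation call tables and operations on them.

A methylation track holds strand-resolved methylated/total read counts for
every CpG of one WGBS sample, in the column layout produced by methratio-style
callers (1-based cytosine position, ``+``/``-`` strand, CG context, counts).
Methylation ratios are always recomputed from the counts, never trusted from
the file.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicIntervalSet

__all__ = [
    "MethylationTrack",
    "MethylationParseError",
    "read_methratio",
    "write_methratio",
    "read_bedgraph_pair",
    "read_sample_sheet",
    "filter_by_coverage",
    "aggregate_strands",
    "sliding_window_methylation",
    "mean_methylation_over_intervals",
]

_COLUMNS = ["chrom", "pos", "strand", "context", "meth_count", "total_count"]


class MethylationParseError(ValueError):
    """Raised when a methylation call table violates the format contract."""


@dataclass
class MethylationTrack:
    """Sorted, deduplicated per-CpG methylation calls for one sample.

    ``data`` columns: chrom (str), pos (int, 1-based cytosine position),
    strand (+/-), context (str, CG expected), meth_count, total_count (ints,
    0 <= meth_count <= total_count).
    """

    sample_id: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.data = _validate_frame(self.data)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def ratio(self) -> np.ndarray:
        """meth_count / total_count; NaN where total_count == 0."""
        total = self.data["total_count"].to_numpy(float)
        meth = self.data["meth_count"].to_numpy(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(total > 0, meth / np.where(total > 0, total, 1), np.nan)
        return r

    def keys(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_frame(self.data[["chrom", "pos", "strand"]])


def _validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise MethylationParseError(f"missing columns: {missing}")
    df = df[_COLUMNS].copy()
    df["pos"] = df["pos"].astype(np.int64)
    df["meth_count"] = df["meth_count"].astype(np.int64)
    df["total_count"] = df["total_count"].astype(np.int64)
    if len(df):
        if (df["pos"] < 1).any():
            raise MethylationParseError("positions must be >= 1")
        bad = df["meth_count"] > df["total_count"]
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise MethylationParseError(
                f"meth_count > total_count at row {i} "
                f"({df.iloc[i]['chrom']}:{df.iloc[i]['pos']})"
            )
        if (df["meth_count"] < 0).any():
            raise MethylationParseError("negative counts")
        if not df["strand"].isin(["+", "-"]).all():
            raise MethylationParseError("strand must be '+' or '-'")
    df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort")
    df = df.drop_duplicates(subset=["chrom", "pos", "strand"], keep="first")
    return df.reset_index(drop=True)


def _looks_like_header(fields: Sequence[str]) -> bool:
    if len(fields) < 2:
        return True
    try:
        int(fields[1])
    except ValueError:
        return True
    return False


def read_methratio(path: str | Path, sample_id: str | None = None) -> MethylationTrack:
    """Read a methratio-dialect TSV into a :class:`MethylationTrack`.

    Expected columns (header optional): chrom, pos, strand, context, ratio,
    meth_count, total_count. Extra trailing columns are ignored and the ratio
    column is discarded in favour of the counts.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and _looks_like_header(fields):
                continue
            if len(fields) < 7:
                raise MethylationParseError(
                    f"{path}:{lineno}: expected >= 7 tab-separated fields, got {len(fields)}"
                )
            try:
                rows.append(
                    (
                        fields[0],
                        int(fields[1]),
                        fields[2],
                        fields[3],
                        int(fields[5]),
                        int(fields[6]),
                    )
                )
            except ValueError as exc:
                raise MethylationParseError(f"{path}:{lineno}: {exc}") from exc
    df = pd.DataFrame(rows, columns=_COLUMNS) if rows else _empty_frame()
    try:
        return MethylationTrack(sample_id or path.stem, df)
    except MethylationParseError as exc:
        raise MethylationParseError(f"{path}: {exc}") from exc


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "pos": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=str),
            "context": pd.Series(dtype=str),
            "meth_count": pd.Series(dtype=np.int64),
            "total_count": pd.Series(dtype=np.int64),
        }
    )


def write_methratio(track: MethylationTrack, path: str | Path) -> None:
    """Write a track as methratio-dialect TSV (counts round-trip exactly)."""
    df = track.data.copy()
    total = df["total_count"].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, df["meth_count"].to_numpy(float) / np.where(total > 0, total, 1), np.nan)
    out = df[["chrom", "pos", "strand", "context"]].copy()
    out["ratio"] = np.round(ratio, 6)
    out["meth_count"] = df["meth_count"]
    out["total_count"] = df["total_count"]
    out.to_csv(path, sep="\t", index=False, na_rep="nan")


def read_bedgraph_pair(
    ratio_path: str | Path,
    coverage_path: str | Path,
    sample_id: str | None = None,
) -> MethylationTrack:
    """Read a ratio bedGraph plus a matching coverage bedGraph.

    Both files are 4-column bedGraph (chrom, start, end, value) over identical
    single-base intervals; counts are reconstructed as
    ``meth = round(ratio * coverage)``. Strand is reported as '+', context CG.
    """
    names = ["chrom", "start", "end", "value"]
    r = pd.read_csv(ratio_path, sep=r"\s+", header=None, names=names, comment="t")
    c = pd.read_csv(coverage_path, sep=r"\s+", header=None, names=names, comment="t")
    if len(r) != len(c) or not (r["start"].to_numpy() == c["start"].to_numpy()).all():
        raise MethylationParseError("ratio and coverage bedGraphs do not describe the same positions")
    total = c["value"].round().astype(np.int64)
    meth = (r["value"] * c["value"]).round().astype(np.int64)
    df = pd.DataFrame(
        {
            "chrom": r["chrom"],
            "pos": r["start"].astype(np.int64) + 1,  # bedGraph is 0-based
            "strand": "+",
            "context": "CG",
            "meth_count": meth,
            "total_count": total,
        }
    )
    return MethylationTrack(sample_id or Path(ratio_path).stem, df)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a cohort sample sheet CSV.

    Required columns: sample_id, tissue, age_days, group; file_path optional.
    sample_id must be unique and age_days non-negative.
    """
    df = pd.read_csv(path)
    required = {"sample_id", "tissue", "age_days", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in sample sheet")
    if (df["age_days"] < 0).any():
        raise ValueError("age_days must be >= 0")
    return df


def filter_by_coverage(
    track: MethylationTrack, min_total: int = 3, strict: bool = False
) -> MethylationTrack:
    """Retain CpGs with total_count >= min_total (or > min_total if strict).

    The default of 3 reads is the standard minimum for a methylation ratio to
    be considered at all.
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    total = track.data["total_count"]
    mask = total > min_total if strict else total >= min_total
    return MethylationTrack(track.sample_id, track.data[mask].reset_index(drop=True))


def aggregate_strands(track: MethylationTrack) -> MethylationTrack:
    """Merge the two strands of each CpG dyad by summing read counts.

    The minus-strand cytosine of a dyad sits one base downstream of the
    plus-strand cytosine; its counts are folded onto the plus-strand position
    and the merged record is labelled '+'. Unpaired records pass through
    (minus-strand singletons are re-anchored to their dyad position).
    """
    if len(track) == 0:
        return MethylationTrack(track.sample_id, track.data.copy())
    df = track.data.copy()
    minus = df["strand"] == "-"
    if (df.loc[minus, "pos"] < 2).any():
        raise MethylationParseError("minus-strand CpG at position 1 has no dyad position")
    df.loc[minus, "pos"] = df.loc[minus, "pos"] - 1
    merged = (
        df.groupby(["chrom", "pos"], sort=True, as_index=False)
        .agg(context=("context", "first"), meth_count=("meth_count", "sum"), total_count=("total_count", "sum"))
    )
    merged["strand"] = "+"
    return MethylationTrack(track.sample_id, merged[_COLUMNS])


def sliding_window_methylation(
    track: MethylationTrack, window_bp: int = 2000, step_bp: int | None = None
) -> pd.DataFrame:
    """Mean methylation ratio in sliding genomic windows.

    Windows are 0-based half-open ``[k*step, k*step + window)``; the default
    step equals the window (non-overlapping 2-kb tiling of the genome, the
    resolution used for genome-wide methylation distributions). Windows with
    no covered CpG are omitted.

    Returns a DataFrame with chrom, start, end, n_cpgs, mean_methylation.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    step = window_bp if step_bp is None else step_bp
    if step <= 0:
        raise ValueError("step_bp must be > 0")
    out = []
    ratio = track.ratio
    for chrom, idx in track.data.groupby("chrom", sort=True).indices.items():
        pos0 = track.data["pos"].to_numpy()[idx] - 1  # 0-based
        r = ratio[idx]
        ok = ~np.isnan(r)
        pos0, r = pos0[ok], r[ok]
        if len(pos0) == 0:
            continue
        starts = np.arange(0, pos0.max() + 1, step)
        lo = np.searchsorted(pos0, starts, side="left")
        hi = np.searchsorted(pos0, starts + window_bp, side="left")
        n = hi - lo
        keep = n > 0
        csum = np.concatenate([[0.0], np.cumsum(r)])
        means = (csum[hi[keep]] - csum[lo[keep]]) / n[keep]
        out.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts[keep],
                    "end": starts[keep] + window_bp,
                    "n_cpgs": n[keep],
                    "mean_methylation": means,
                }
            )
        )
    if not out:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_cpgs", "mean_methylation"])
    return pd.concat(out, ignore_index=True)


def mean_methylation_over_intervals(
    track: MethylationTrack,
    intervals: GenomicIntervalSet,
    min_total: int = 1,
    strict: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Unweighted mean CpG methylation ratio per interval.

    Only CpGs passing the coverage rule (total_count >= min_total, or
    > min_total when strict) contribute; per-strand records each count as one
    CpG observation. Returns ``(means, counts)`` aligned with the interval
    set; an interval with no qualifying CpG gets mean NaN and count 0.
    """
    ivdf = intervals.data
    means = np.full(len(ivdf), np.nan)
    counts = np.zeros(len(ivdf), dtype=np.int64)
    if len(ivdf) == 0 or len(track) == 0:
        return means, counts
    total = track.data["total_count"]
    covmask = (total > min_total) if strict else (total >= min_total)
    sub = track.data[covmask.to_numpy()]
    with np.errstate(invalid="ignore", divide="ignore"):
        sub_ratio = sub["meth_count"].to_numpy(float) / np.where(
            sub["total_count"].to_numpy(float) > 0, sub["total_count"].to_numpy(float), np.nan
        )
    groups = sub.groupby("chrom", sort=False).indices
    for chrom, iv_idx in ivdf.groupby("chrom", sort=False).indices.items():
        if chrom not in groups:
            continue
        tr_idx = groups[chrom]
        pos0 = sub["pos"].to_numpy()[tr_idx] - 1
        r = sub_ratio[tr_idx]
        ok = ~np.isnan(r)
        pos0, r = pos0[ok], r[ok]
        if len(pos0) == 0:
            continue
        order = np.argsort(pos0, kind="mergesort")
        pos0, r = pos0[order], r[order]
        csum = np.concatenate([[0.0], np.cumsum(r)])
        starts = ivdf["start"].to_numpy()[iv_idx]
        ends = ivdf["end"].to_numpy()[iv_idx]
        lo = np.searchsorted(pos0, starts, side="left")
        hi = np.searchsorted(pos0, ends, side="left")
        n = hi - lo
        has = n > 0
        counts[iv_idx] = n
        means[iv_idx[has]] = (csum[hi[has]] - csum[lo[has]]) / n[has]
    return means, counts
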