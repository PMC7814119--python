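"""Genomic interval sets (LMR/UMR segments) with BED-backed round-tripping.

Coordinates follow the BED convention: 0-based, half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenomicIntervalSet",
    "read_intervals_bed",
    "write_intervals_bed",
    "merge_intervals",
    "intervals_from_feature_ids",
]

_IV_COLUMNS = ["chrom", "start", "end", "segment_class", "n_cpgs", "mean_methylation"]


@dataclass
class GenomicIntervalSet:
    """A sorted set of genomic intervals with optional segment annotations.

    ``data`` columns: chrom, start, end (0-based half-open), segment_class
    ({LMR, UMR, generic}), n_cpgs (int, 0 when unknown), mean_methylation
    (float in [0,1] or NaN when undefined).
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data.copy()
        if "segment_class" not in df.columns:
            df["segment_class"] = "generic"
        if "n_cpgs" not in df.columns:
            df["n_cpgs"] = 0
        if "mean_methylation" not in df.columns:
            df["mean_methylation"] = np.nan
        missing = [c for c in ("chrom", "start", "end") if c not in df.columns]
        if missing:
            raise ValueError(f"interval set missing columns: {missing}")
        df = df[_IV_COLUMNS].copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["n_cpgs"] = df["n_cpgs"].astype(np.int64)
        if len(df) and (df["start"] >= df["end"]).any():
            i = int(np.flatnonzero((df["start"] >= df["end"]).to_numpy())[0])
            raise ValueError(
                f"invalid interval (start >= end): {df.iloc[i]['chrom']}:"
                f"{df.iloc[i]['start']}-{df.iloc[i]['end']}"
            )
        self.data = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def feature_ids(self) -> list[str]:
        return [f"{c}:{s}-{e}" for c, s, e in zip(self.data["chrom"], self.data["start"], self.data["end"])]

    def total_bp(self) -> int:
        return int((self.data["end"] - self.data["start"]).sum())

    @staticmethod
    def empty() -> "GenomicIntervalSet":
        return GenomicIntervalSet(
            pd.DataFrame({"chrom": pd.Series(dtype=str), "start": pd.Series(dtype=np.int64), "end": pd.Series(dtype=np.int64)})
        )


def read_intervals_bed(path: str | Path) -> GenomicIntervalSet:
    """Read BED3/BED6(+1) intervals.

    The name field (column 4) carries segment_class, the score field
    (column 5) carries n_cpgs, an optional seventh column carries
    mean_methylation.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: BED line with < 3 fields")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            cls = f[3] if len(f) > 3 and f[3] != "." else "generic"
            n_cpgs = int(f[4]) if len(f) > 4 and f[4] != "." else 0
            mean = float(f[6]) if len(f) > 6 and f[6] not in (".", "nan") else np.nan
            rows.append((f[0], start, end, cls, n_cpgs, mean))
    df = pd.DataFrame(rows, columns=_IV_COLUMNS) if rows else None
    if df is None:
        return GenomicIntervalSet.empty()
    return GenomicIntervalSet(df)


def write_intervals_bed(intervals: GenomicIntervalSet, path: str | Path) -> None:
    """Write intervals as BED6+1 (name=segment_class, score=n_cpgs, col7=mean)."""
    df = intervals.data
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            mean = "." if pd.isna(row.mean_methylation) else f"{row.mean_methylation:.17g}"
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.segment_class}\t{row.n_cpgs}\t.\t{mean}\n"
            )


def intervals_from_feature_ids(feature_ids: list[str]) -> GenomicIntervalSet:
    """Rebuild an interval set from 'chrom:start-end' feature identifiers."""
    rows = []
    for fid in feature_ids:
        chrom, span = fid.rsplit(":", 1)
        start, end = span.split("-")
        rows.append((chrom, int(start), int(end)))
    return GenomicIntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


def merge_intervals(df: pd.DataFrame, merge_bookended: bool = True) -> pd.DataFrame:
    """Merge overlapping (and optionally book-ended) sorted intervals."""
    if len(df) == 0:
        return df.copy()
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
    out = []
    cur = None
    for row in df.itertuples(index=False):
        if cur is not None and row.chrom == cur[0] and (
            row.start < cur[2] or (merge_bookended and row.start == cur[2])
        ):
            cur[2] = max(cur[2], row.end)
        else:
            if cur is not None:
                out.append(tuple(cur))
            cur = [row.chrom, row.start, row.end]
    out.append(tuple(cur))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])
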