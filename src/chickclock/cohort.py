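"""Cohort-level methylome analyses around the clock.

Differential LMR calling between age groups, epigenetic age-acceleration
inference (predicted minus chronological age, Welch-tested against a
reference group), enrichment of clock markers in genomic features, PCA of
methylation matrices with per-component age correlation, and rank-sum tissue
contrasts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .clock import ClockModel, MethylationMatrix, predict_age
from .intervals import GenomicIntervalSet

__all__ = [
    "differential_intervals",
    "age_acceleration",
    "test_group_acceleration",
    "marker_feature_enrichment",
    "pca_with_age_correlation",
    "rank_sum_compare",
]


def differential_intervals(
    matrix_a: MethylationMatrix, matrix_b: MethylationMatrix, min_diff: float = 0.1
) -> pd.DataFrame:
    """Call features differentially methylated between two sample groups.

    Group means of raw methylation are compared; a feature is ``hyper_in_B``
    when (mean_B - mean_A) > min_diff, ``hypo_in_B`` when < -min_diff (both
    strictly), and ``unchanged`` otherwise — a difference of exactly the
    threshold is not a call. The default 0.1 ratio-difference threshold is
    the standard cut for age-group LMR comparisons.
    """
    if len(matrix_a.values) == 0 or len(matrix_b.values) == 0:
        raise ValueError("both groups must contain at least one sample")
    if list(matrix_a.feature_ids) != list(matrix_b.feature_ids):
        raise ValueError("groups must share one feature set")
    mean_a = matrix_a.values.mean(axis=0)
    mean_b = matrix_b.values.mean(axis=0)
    diff = mean_b - mean_a
    call = np.where(diff > min_diff, "hyper_in_B", np.where(diff < -min_diff, "hypo_in_B", "unchanged"))
    return pd.DataFrame(
        {"feature": matrix_a.feature_ids, "mean_A": mean_a.to_numpy(), "mean_B": mean_b.to_numpy(),
         "difference": diff.to_numpy(), "call": call}
    )


def age_acceleration(
    model: ClockModel, matrix: MethylationMatrix, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Per-sample age acceleration: predicted minus chronological age.

    Returns one row per sample with tissue, group, chronological and predicted
    age and delta; positive delta reads as faster epigenetic aging.
    """
    meta = metadata.set_index("sample_id").loc[matrix.sample_ids]
    preds = predict_age(model, matrix.values, meta["tissue"].astype(str))
    out = pd.DataFrame(
        {
            "sample_id": matrix.sample_ids,
            "tissue": meta["tissue"].to_numpy(),
            "group": meta["group"].to_numpy(),
            "age_days": meta["age_days"].to_numpy(float),
            "predicted_age": preds.to_numpy(float),
        }
    )
    out["delta"] = out["predicted_age"] - out["age_days"]
    return out


def test_group_acceleration(
    results: pd.DataFrame,
    reference_group: str,
    group_col: str = "group",
    two_sided: bool = True,
    alpha_level: float = 0.05,
) -> pd.DataFrame:
    """Welch two-sample t-test of per-group acceleration vs a reference group.

    One row per non-reference group with the group mean delta, Welch t
    statistic, p-value (two-sided by default; one-sided tests the directional
    hypothesis delta_group > delta_reference) and a significance flag at
    ``alpha_level``. Groups of fewer than two samples get an undefined p and
    are flagged as untestable.
    """
    ref = results.loc[results[group_col] == reference_group, "delta"].to_numpy(float)
    if len(ref) == 0:
        raise ValueError(f"reference group {reference_group!r} is empty")
    rows = []
    for g, sub in results.groupby(group_col, sort=True):
        if g == reference_group:
            continue
        d = sub["delta"].to_numpy(float)
        if len(d) < 2 or len(ref) < 2:
            rows.append((g, len(d), float(np.mean(d)) if len(d) else np.nan, np.nan, np.nan, False, False))
            continue
        alt = "two-sided" if two_sided else "greater"
        t, p = stats.ttest_ind(d, ref, equal_var=False, alternative=alt)
        rows.append((g, len(d), float(np.mean(d)), float(t), float(p), bool(p < alpha_level), True))
    return pd.DataFrame(
        rows, columns=["group", "n", "mean_delta", "t_statistic", "p_value", "significant", "testable"]
    )


def _marker_midpoints(markers: GenomicIntervalSet | list[tuple[str, int]]) -> list[tuple[str, int]]:
    if isinstance(markers, GenomicIntervalSet):
        df = markers.data
        return list(zip(df["chrom"], ((df["start"] + df["end"]) // 2).astype(int)))
    return [(c, int(p)) for c, p, *rest in markers]


def marker_feature_enrichment(
    markers: GenomicIntervalSet | list[tuple[str, int]],
    annotation: pd.DataFrame,
    genome_size: int,
    feature_sizes: dict[str, int] | None = None,
    mode: str = "midpoint",
) -> pd.DataFrame:
    """Enrichment of clock markers in labeled genomic features.

    enrichment(label) = (fraction of markers falling in the label's
    intervals) / (fraction of the genome covered by the label). Interval
    markers are assigned by midpoint (default) or any-overlap; CpG markers by
    position. ``annotation`` needs columns chrom, start, end, label.

    Returns a DataFrame with label, n_markers, marker_fraction,
    genome_fraction, enrichment.
    """
    pts = _marker_midpoints(markers) if mode == "midpoint" else None
    n_total = len(markers.data) if isinstance(markers, GenomicIntervalSet) else len(markers)
    if n_total == 0:
        raise ValueError("no markers supplied")
    labels = sorted(annotation["label"].unique())
    if feature_sizes is None:
        feature_sizes = {
            lab: int((annotation.loc[annotation["label"] == lab, "end"]
                      - annotation.loc[annotation["label"] == lab, "start"]).sum())
            for lab in labels
        }
    rows = []
    for lab in labels:
        sub = annotation[annotation["label"] == lab]
        n_in = 0
        if mode == "midpoint":
            for chrom, grp in sub.groupby("chrom"):
                starts = np.sort(grp["start"].to_numpy())
                ends = grp.sort_values("start")["end"].to_numpy()
                for mc, mp in pts:
                    if mc != chrom:
                        continue
                    i = np.searchsorted(starts, mp, side="right") - 1
                    if i >= 0 and mp < ends[i]:
                        n_in += 1
        else:  # any overlap of the marker interval with a label interval
            mdf = markers.data if isinstance(markers, GenomicIntervalSet) else None
            if mdf is None:
                raise ValueError("mode='overlap' requires interval markers")
            for row in mdf.itertuples(index=False):
                hit = sub[(sub["chrom"] == row.chrom) & (sub["start"] < row.end) & (sub["end"] > row.start)]
                if len(hit):
                    n_in += 1
        size = feature_sizes[lab]
        if size > genome_size:
            raise ValueError(f"feature size for {lab!r} exceeds genome size")
        marker_frac = n_in / n_total
        genome_frac = size / genome_size
        rows.append((lab, n_in, marker_frac, genome_frac,
                     marker_frac / genome_frac if genome_frac > 0 else np.nan))
    return pd.DataFrame(rows, columns=["label", "n_markers", "marker_fraction", "genome_fraction", "enrichment"])


def pca_with_age_correlation(
    matrix: MethylationMatrix, metadata: pd.DataFrame
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Column-centered PCA (via SVD) with per-component Pearson r against age.

    Returns ``(scores, variance_fractions, age_correlations)``: sample scores
    for the first min(n, p) components, the fraction of variance each
    explains, and Pearson r of each score vector with age_days (NaN for
    zero-variance components).
    """
    X = matrix.values.to_numpy(float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 features")
    if np.isnan(X).any():
        raise ValueError("matrix contains missing values")
    Xc = X - X.mean(axis=0)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = U * S
    total = (S ** 2).sum()
    varfrac = (S ** 2) / total if total > 0 else np.zeros_like(S)
    ages = metadata.set_index("sample_id").loc[matrix.sample_ids, "age_days"].to_numpy(float)
    r = np.full(scores.shape[1], np.nan)
    scale = np.abs(scores).max() if scores.size else 0.0
    for k in range(scores.shape[1]):
        s = scores[:, k]
        # null components (zero singular value up to rounding) have no correlation
        if s.std() > 1e-9 * max(scale, 1.0) and ages.std() > 0:
            sc = s - s.mean()
            ac = ages - ages.mean()
            r[k] = float(sc @ ac / np.sqrt((sc @ sc) * (ac @ ac)))
    scores_df = pd.DataFrame(
        scores, index=matrix.sample_ids, columns=[f"PC{k+1}" for k in range(scores.shape[1])]
    )
    return scores_df, varfrac, r


def rank_sum_compare(values_a, values_b, method: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) comparison.

    ``method='auto'`` uses the exact null distribution for small tie-free
    samples and the tie-corrected normal approximation otherwise;
    ``'asymptotic'`` forces the normal approximation.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
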