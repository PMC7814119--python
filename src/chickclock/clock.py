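"""Elastic-net DNA methylation clocks.

A methylation clock is a penalized linear regression of chronological age on
methylation values at selected loci. The pipeline here is: filter CpG sites
(sex chromosomes, SNP positions, per-strand coverage in every sample), build
a samples x features mean-methylation matrix (LMR means or per-CpG ratios),
subtract per-tissue per-feature training means ("tissue offset
normalization", which aligns differently matured tissues on one age axis),
and fit the elastic net

    (1/2n) * sum_i (y_i - b0 - x_i beta)^2
        + lambda * [ (1-alpha)/2 * ||beta||_2^2 + alpha * ||beta||_1 ]

by cyclic coordinate descent with an unpenalized intercept. alpha in [0,1]
mixes ridge (0) and lasso (1); the defaults of 0.9 (LMR clock) and 0.7 (CpG
clock) give sparse, interpretable marker sets. lambda is picked by k-fold
cross-validation on RMSE with ties broken toward the sparser (larger-lambda)
model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit

from .intervals import GenomicIntervalSet
from .io import MethylationTrack, mean_methylation_over_intervals

__all__ = [
    "FilterConfig",
    "MethylationMatrix",
    "ClockModel",
    "filter_clock_sites",
    "build_feature_matrix",
    "tissue_normalize",
    "fit_elastic_net",
    "elastic_net_objective",
    "default_lambda_grid",
    "select_lambda_cv",
    "train_clock",
    "predict_age",
    "cross_validate_clock",
    "serialize_model",
    "deserialize_model",
]

MODEL_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class FilterConfig:
    """Site filters applied before clock training.

    Sex-chromosome CpGs are removed (methylation there tracks sex, not age);
    CpGs at known SNP positions are removed (apparent methylation changes may
    be genotype); per-strand coverage must exceed the threshold in every
    sample (strictly greater, i.e. "> 10" for the CpG clock, "> 5" for CpGs
    inside LMRs).
    """

    sex_chromosomes: frozenset[str] = frozenset({"Z", "W", "chrZ", "chrW"})
    snp_positions: frozenset[tuple[str, int]] = frozenset()
    cpg_min_strand_cov: int = 10
    lmr_min_strand_cov: int = 5
    require_all_samples: bool = True

    def min_cov_for(self, feature_kind: str) -> int:
        return self.cpg_min_strand_cov if feature_kind == "CpG" else self.lmr_min_strand_cov


@dataclass
class MethylationMatrix:
    """Samples x features methylation values.

    ``values``: DataFrame indexed by sample_id with feature-id columns. Raw
    values are methylation ratios in [0,1]; after tissue normalization they
    are residuals around per-tissue means and ``is_normalized`` is True.
    """

    values: pd.DataFrame
    feature_kind: str = "LMR"
    is_normalized: bool = False

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ClockModel:
    """A trained methylation clock: sparse weights plus normalization state."""

    feature_kind: str
    alpha: float
    lam: float
    intercept: float
    weights: dict[str, float]
    offsets: dict[str, dict[str, float]]          # tissue -> feature -> offset
    fallback_offsets: dict[str, float]            # feature -> global training mean
    training: dict = field(default_factory=dict)

    @property
    def features(self) -> list[str]:
        return list(self.weights)


def filter_clock_sites(
    tracks: dict[str, MethylationTrack],
    config: FilterConfig,
    feature_kind: str = "CpG",
) -> pd.MultiIndex:
    """Strand-resolved CpG keys (chrom, pos, strand) surviving all filters.

    Removes sex-chromosome CpGs and CpGs at listed SNP positions, then keeps
    only keys whose per-strand total_count exceeds the threshold for
    ``feature_kind`` in every sample (when require_all_samples).
    """
    if not tracks:
        raise ValueError("no tracks supplied")
    min_cov = config.min_cov_for(feature_kind)
    kept: pd.MultiIndex | None = None
    for sample_id, track in tracks.items():
        df = track.data
        mask = ~df["chrom"].isin(config.sex_chromosomes)
        if config.snp_positions:
            snp_keys = pd.MultiIndex.from_tuples(config.snp_positions, names=["chrom", "pos"])
            here = pd.MultiIndex.from_frame(df[["chrom", "pos"]])
            mask &= ~here.isin(snp_keys)
        mask &= df["total_count"] > min_cov
        keys = pd.MultiIndex.from_frame(df.loc[mask, ["chrom", "pos", "strand"]])
        if not config.require_all_samples:
            kept = keys if kept is None else kept.union(keys)
        else:
            kept = keys if kept is None else kept.intersection(keys)
    assert kept is not None
    if len(kept) == 0:
        raise ValueError(
            "no CpG passes the coverage rule in every sample; relax the "
            "per-strand coverage threshold or set require_all_samples=False"
        )
    return kept.sortlevel([0, 1, 2])[0]


def _subset_track(track: MethylationTrack, keys: pd.MultiIndex) -> MethylationTrack:
    here = pd.MultiIndex.from_frame(track.data[["chrom", "pos", "strand"]])
    return MethylationTrack(track.sample_id, track.data[here.isin(keys)])


def build_feature_matrix(
    tracks: dict[str, MethylationTrack],
    metadata: pd.DataFrame,
    features: GenomicIntervalSet | pd.MultiIndex | None = None,
    config: FilterConfig | None = None,
    feature_kind: str | None = None,
) -> MethylationMatrix:
    """Build the raw samples x features methylation matrix.

    LMR kind (``features`` is an interval set): per-sample unweighted mean of
    filtered per-strand CpG ratios inside each interval; intervals lacking a
    qualifying CpG in any sample are dropped. CpG kind: per-site ratios at
    the filtered keys. The returned matrix has no missing entries.
    """
    config = config or FilterConfig()
    missing = [s for s in metadata["sample_id"] if s not in tracks]
    if missing:
        raise ValueError(f"samples in sheet without a track: {missing}")
    sample_ids = list(metadata["sample_id"])

    if isinstance(features, GenomicIntervalSet):
        kind = feature_kind or "LMR"
        keys = filter_clock_sites(tracks, config, feature_kind=kind)
        cols = features.feature_ids
        rows = {}
        for sid in sample_ids:
            sub = _subset_track(tracks[sid], keys)
            means, _ = mean_methylation_over_intervals(sub, features, min_total=0)
            rows[sid] = means
        values = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    else:
        kind = feature_kind or "CpG"
        keys = features if features is not None else filter_clock_sites(tracks, config, feature_kind=kind)
        cols = [f"{c}:{p}:{s}" for c, p, s in keys]
        rows = {}
        for sid in sample_ids:
            df = tracks[sid].data.set_index(["chrom", "pos", "strand"])
            sub = df.reindex(keys)
            with np.errstate(invalid="ignore", divide="ignore"):
                rows[sid] = (sub["meth_count"] / sub["total_count"]).to_numpy()
        values = pd.DataFrame.from_dict(rows, orient="index", columns=cols)

    if config.require_all_samples:
        values = values.dropna(axis=1)
    values.index.name = "sample_id"
    if values.shape[1] == 0:
        raise ValueError("no feature is covered in every sample")
    return MethylationMatrix(values=values, feature_kind=kind, is_normalized=False)


def tissue_normalize(
    matrix: MethylationMatrix, metadata: pd.DataFrame
) -> tuple[MethylationMatrix, pd.DataFrame, pd.Series]:
    """Subtract per-tissue per-feature training means.

    Returns ``(normalized matrix, offsets, fallback)`` where ``offsets`` is a
    tissue x feature DataFrame of training means and ``fallback`` the global
    per-feature mean (used at prediction time for tissues never seen in
    training). After normalization every (tissue, feature) mean on the
    training set is zero.
    """
    if matrix.is_normalized:
        raise ValueError("matrix is already normalized")
    meta = metadata.set_index("sample_id")
    tissues = meta.loc[matrix.values.index, "tissue"]
    offsets = matrix.values.groupby(tissues.to_numpy()).mean()
    offsets.index.name = "tissue"
    normalized = matrix.values - offsets.loc[tissues.to_numpy()].to_numpy()
    fallback = matrix.values.mean(axis=0)
    return (
        MethylationMatrix(values=normalized, feature_kind=matrix.feature_kind, is_normalized=True),
        offsets,
        fallback,
    )


# ---------------------------------------------------------------------------
# elastic net by cyclic coordinate descent


def _soft_threshold(z: float, t: float) -> float:
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


@njit(cache=False)
def _cd_solve(
    Xc: np.ndarray,  # (n, p), column-mean-centered, Fortran order
    yc: np.ndarray,  # (n,), mean-centered
    cj: np.ndarray,  # (p,), per-feature (1/n)||x_j||^2
    denom: np.ndarray,  # (p,), cj + lam*(1-alpha)
    thr: float,  # lam * alpha
    tol: float,
    max_iter: int,
    beta: np.ndarray,  # (p,), warm start, modified in place
) -> int:
    """Cyclic coordinate descent with active-set iteration (glmnet strategy).

    Full sweeps over all coordinates alternate with cheap sweeps restricted
    to the current active (nonzero) set until the largest coefficient update
    falls below tol. Returns the number of sweeps used.
    """
    n, p = Xc.shape
    r = yc - Xc @ beta
    sweeps = 0
    while sweeps < max_iter:
        # full sweep over every coordinate
        max_delta = 0.0
        for j in range(p):
            bj = beta[j]
            zj = cj[j] * bj
            for i in range(n):
                zj += Xc[i, j] * r[i] / n
            if zj > thr:
                bn = (zj - thr) / denom[j] if denom[j] > 0 else 0.0
            elif zj < -thr:
                bn = (zj + thr) / denom[j] if denom[j] > 0 else 0.0
            else:
                bn = 0.0
            d = bn - bj
            if d != 0.0:
                for i in range(n):
                    r[i] -= Xc[i, j] * d
                beta[j] = bn
                if abs(d) > max_delta:
                    max_delta = abs(d)
        sweeps += 1
        if max_delta <= tol:
            break
        # active-set sweeps until stable
        active = np.flatnonzero(beta)
        while sweeps < max_iter:
            max_delta_a = 0.0
            for k in range(active.shape[0]):
                j = active[k]
                bj = beta[j]
                zj = cj[j] * bj
                for i in range(n):
                    zj += Xc[i, j] * r[i] / n
                if zj > thr:
                    bn = (zj - thr) / denom[j] if denom[j] > 0 else 0.0
                elif zj < -thr:
                    bn = (zj + thr) / denom[j] if denom[j] > 0 else 0.0
                else:
                    bn = 0.0
                d = bn - bj
                if d != 0.0:
                    for i in range(n):
                        r[i] -= Xc[i, j] * d
                    beta[j] = bn
                    if abs(d) > max_delta_a:
                        max_delta_a = abs(d)
            sweeps += 1
            if max_delta_a <= tol:
                break
    return sweeps


def elastic_net_objective(
    X: np.ndarray, y: np.ndarray, beta0: float, beta: np.ndarray, alpha: float, lam: float
) -> float:
    """Value of the penalized least-squares objective being minimized."""
    r = y - beta0 - X @ beta
    return float(
        (r @ r) / (2 * len(y))
        + lam * ((1 - alpha) / 2 * (beta @ beta) + alpha * np.abs(beta).sum())
    )


def fit_elastic_net(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lam: float,
    tol: float = 1e-8,
    max_iter: int = 100_000,
    beta_init: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Minimize the elastic-net objective; returns (intercept, coefficients).

    Cyclic coordinate descent on mean-centered data with an unpenalized
    intercept. Deterministic given the inputs; ``tol`` bounds the largest
    coefficient update in the final sweep. Features are used on their natural
    scale (methylation ratios already share the [0,1] scale); standardize
    beforehand if desired.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in X or y")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0, 1]")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    n, p = X.shape
    if n < 2 or p < 1:
        raise ValueError("need at least 2 samples and 1 feature")

    xm = X.mean(axis=0)
    ym = y.mean()
    Xc = np.asfortranarray(X - xm)
    yc = y - ym
    cj = (Xc * Xc).sum(axis=0) / n
    denom = cj + lam * (1.0 - alpha)
    thr = lam * alpha

    beta = np.zeros(p) if beta_init is None else np.asarray(beta_init, dtype=float).copy()
    _cd_solve(Xc, yc, cj, denom, thr, tol, max_iter, beta)
    beta0 = ym - xm @ beta
    return float(beta0), beta


def default_lambda_grid(
    X: np.ndarray, y: np.ndarray, alpha: float, n_lambda: int = 50, ratio: float = 1e-3
) -> np.ndarray:
    """Descending geometric lambda grid from the smallest all-zero lambda."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    lam_max = np.abs(Xc.T @ yc).max() / (n * max(alpha, 1e-3))
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * ratio, n_lambda)


def _kfold_indices(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [perm[i::k] for i in range(k)]


def select_lambda_cv(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lambda_grid: np.ndarray | None = None,
    k_folds: int = 5,
    seed: int = 0,
    tol: float = 1e-6,
    one_se: bool = False,
) -> tuple[float, pd.DataFrame]:
    """Pick lambda by k-fold cross-validated RMSE.

    Returns ``(lambda*, curve)`` where curve has one row per grid value with
    the mean out-of-fold RMSE and its standard error across folds. The
    minimizer wins; exact ties go to the larger lambda (sparser model). With
    ``one_se=True`` the largest lambda whose mean RMSE stays within one
    standard error of the minimum is chosen instead (a sparser, more
    conservative model). Fold assignment is a seeded permutation.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    if k_folds < 2 or n < k_folds:
        raise ValueError("need k_folds >= 2 and n >= k_folds")
    grid = default_lambda_grid(X, y, alpha) if lambda_grid is None else np.asarray(lambda_grid, float)
    order = np.argsort(grid)[::-1]  # descending for warm starts
    grid_desc = grid[order]
    rng = np.random.default_rng(seed)
    folds = _kfold_indices(n, k_folds, rng)
    sq_err = np.zeros(len(grid_desc))
    fold_rmse = np.zeros((len(folds), len(grid_desc)))
    for fi, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        Xt, yt = X[train_idx], y[train_idx]
        beta = np.zeros(X.shape[1])
        for gi, lam in enumerate(grid_desc):
            b0, beta = fit_elastic_net(Xt, yt, alpha, lam, tol=tol, beta_init=beta)
            pred = b0 + X[test_idx] @ beta
            sq = ((pred - y[test_idx]) ** 2).sum()
            sq_err[gi] += sq
            fold_rmse[fi, gi] = np.sqrt(sq / len(test_idx))
    rmse_desc = np.sqrt(sq_err / n)
    se_desc = fold_rmse.std(axis=0, ddof=1) / np.sqrt(len(folds))
    # ties toward larger lambda: grid_desc is descending, argmin takes first
    best = int(np.argmin(rmse_desc))
    if one_se:
        within = np.flatnonzero(rmse_desc <= rmse_desc[best] + se_desc[best])
        best = int(within[0])  # largest qualifying lambda
    curve = (
        pd.DataFrame({"lam": grid_desc, "cv_rmse": rmse_desc, "cv_rmse_se": se_desc})
        .sort_values("lam")
        .reset_index(drop=True)
    )
    return float(grid_desc[best]), curve


def train_clock(
    matrix: MethylationMatrix,
    metadata: pd.DataFrame,
    alpha: float = 0.9,
    k_folds: int = 6,
    seed: int = 0,
    lambda_grid: np.ndarray | None = None,
    standardize: bool = False,
) -> ClockModel:
    """Train a clock: normalize (if needed), select lambda by CV, fit.

    Accepts a raw matrix (tissue offsets estimated here and stored on the
    model) or an already normalized one accompanied by offsets in
    ``metadata.attrs`` — the raw path is the usual one.
    """
    if matrix.is_normalized:
        raise ValueError("pass the raw matrix; train_clock estimates offsets itself")
    norm, offsets, fallback = tissue_normalize(matrix, metadata)
    meta = metadata.set_index("sample_id")
    y = meta.loc[norm.values.index, "age_days"].to_numpy(float)
    X = norm.values.to_numpy(float)
    scale = X.std(axis=0, ddof=0) if standardize else np.ones(X.shape[1])
    scale[scale == 0] = 1.0
    Xs = X / scale

    lam, curve = select_lambda_cv(Xs, y, alpha, lambda_grid, k_folds=min(k_folds, len(y)), seed=seed)
    b0, beta = fit_elastic_net(Xs, y, alpha, lam, tol=1e-8)
    beta = beta / scale  # back to the raw feature scale
    nz = np.flatnonzero(beta)
    if len(nz) == 0:
        warnings.warn("all coefficients are zero at the selected lambda; intercept-only clock")
    feats = [norm.feature_ids[j] for j in nz]
    model = ClockModel(
        feature_kind=matrix.feature_kind,
        alpha=float(alpha),
        lam=float(lam),
        intercept=float(b0),
        weights={f: float(beta[j]) for f, j in zip(feats, nz)},
        offsets={t: {f: float(offsets.loc[t, f]) for f in feats} for t in offsets.index},
        fallback_offsets={f: float(fallback[f]) for f in feats},
        training={
            "n": int(len(y)),
            "seed": int(seed),
            "k_folds": int(k_folds),
            "n_features_offered": int(X.shape[1]),
            "n_nonzero": int(len(nz)),
            "cv_rmse": float(curve.loc[np.isclose(curve["lam"], lam), "cv_rmse"].iloc[0]),
        },
    )
    return model


def predict_age(
    model: ClockModel,
    features: pd.Series | pd.DataFrame,
    tissue: str | pd.Series,
) -> float | pd.Series:
    """Predicted age in days: b0 + sum_j beta_j (x_j - offset(tissue, j)).

    ``features`` holds raw (unnormalized) feature values. A tissue absent
    from training falls back to global per-feature training means with a
    warning. Output is not clamped. Missing model features raise.
    """
    if isinstance(features, pd.DataFrame):
        tissues = tissue if isinstance(tissue, pd.Series) else pd.Series(tissue, index=features.index)
        return pd.Series(
            {sid: predict_age(model, features.loc[sid], str(tissues.loc[sid])) for sid in features.index},
            name="predicted_age",
        )
    missing = [f for f in model.features if f not in features.index or pd.isna(features[f])]
    if missing:
        raise ValueError(f"sample lacks model features: {missing[:10]}" + ("..." if len(missing) > 10 else ""))
    if tissue in model.offsets:
        off = model.offsets[tissue]
    else:
        warnings.warn(f"tissue '{tissue}' not seen in training; using global fallback offsets")
        off = model.fallback_offsets
    yhat = model.intercept
    for f, w in model.weights.items():
        yhat += w * (float(features[f]) - off[f])
    return float(yhat)


def _stratified_folds(
    metadata: pd.DataFrame, sample_ids: list[str], k: int, rng: np.random.Generator
) -> np.ndarray:
    """Fold labels per sample, stratified by (tissue, age_days)."""
    meta = metadata.set_index("sample_id").loc[sample_ids]
    fold = np.empty(len(sample_ids), dtype=int)
    next_fold = 0
    strata = meta.groupby(["tissue", "age_days"], sort=True).indices
    for key in sorted(strata):
        idx = np.array(strata[key])
        # deterministic within-stratum order (by sample id), then a seeded
        # shuffle: fold membership is invariant to the input row order
        idx = idx[np.argsort(np.asarray(sample_ids, dtype=object)[idx])]
        idx = idx[rng.permutation(len(idx))]
        for i, s in enumerate(idx):
            fold[s] = (next_fold + i) % k
        next_fold = (next_fold + len(idx)) % k
    return fold


def cross_validate_clock(
    matrix: MethylationMatrix,
    metadata: pd.DataFrame,
    alpha: float = 0.9,
    k_folds: int = 6,
    seed: int = 0,
    lambda_grid: np.ndarray | None = None,
    refit_normalization: bool = True,
    inner_folds: int = 5,
) -> tuple[pd.DataFrame, float]:
    """Out-of-fold age predictions and overall RMSE.

    Folds are stratified by (tissue, age group) and seeded. By default both
    the tissue offsets and lambda are re-estimated inside each training split
    so nothing leaks from the held-out samples; ``refit_normalization=False``
    reproduces the simpler normalize-once protocol. A test fold containing a
    tissue absent from its training split falls back to global offsets.
    """
    if matrix.is_normalized:
        raise ValueError("pass the raw matrix")
    # canonical sample order: results do not depend on input row order
    matrix = MethylationMatrix(matrix.values.sort_index(), matrix.feature_kind, False)
    sample_ids = matrix.sample_ids
    n = len(sample_ids)
    if n < k_folds:
        raise ValueError("need n >= k_folds")
    meta = metadata.set_index("sample_id")
    y = meta.loc[sample_ids, "age_days"].to_numpy(float)
    tissues = meta.loc[sample_ids, "tissue"].astype(str)
    rng = np.random.default_rng(seed)
    fold = _stratified_folds(metadata, sample_ids, k_folds, rng)

    global_norm = None
    if not refit_normalization:
        global_norm, g_off, g_fb = tissue_normalize(matrix, metadata)

    preds = np.full(n, np.nan)
    for f in range(k_folds):
        test = np.flatnonzero(fold == f)
        train = np.flatnonzero(fold != f)
        sub_ids = [sample_ids[i] for i in train]
        sub_matrix = MethylationMatrix(matrix.values.iloc[train], matrix.feature_kind, False)
        if refit_normalization:
            norm, offsets, fallback = tissue_normalize(sub_matrix, metadata)
            Xtr = norm.values.to_numpy(float)
        else:
            offsets, fallback = g_off, g_fb
            Xtr = global_norm.values.iloc[train].to_numpy(float)
        ytr = y[train]
        lam, _ = select_lambda_cv(
            Xtr, ytr, alpha, lambda_grid, k_folds=min(inner_folds, len(ytr)), seed=seed + f
        )
        b0, beta = fit_elastic_net(Xtr, ytr, alpha, lam, tol=1e-7)
        for i in test:
            t = tissues.iloc[i]
            off = offsets.loc[t].to_numpy(float) if t in offsets.index else fallback.to_numpy(float)
            x = matrix.values.iloc[i].to_numpy(float) - off
            preds[i] = b0 + x @ beta

    rmse = float(np.sqrt(np.mean((preds - y) ** 2)))
    table = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "tissue": tissues.to_numpy(),
            "age_days": y,
            "predicted_age": preds,
            "fold": fold,
        }
    )
    return table, rmse


# ---------------------------------------------------------------------------
# model (de)serialization


def serialize_model(model: ClockModel, path: str | Path) -> None:
    """Write a clock as JSON; floats are stored as decimal strings so the
    round trip is bit-exact."""
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "feature_kind": model.feature_kind,
        "alpha": repr(model.alpha),
        "lambda": repr(model.lam),
        "intercept": repr(model.intercept),
        "weights": {k: repr(v) for k, v in model.weights.items()},
        "offsets": {t: {k: repr(v) for k, v in d.items()} for t, d in model.offsets.items()},
        "fallback_offsets": {k: repr(v) for k, v in model.fallback_offsets.items()},
        "training": model.training,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def deserialize_model(path: str | Path) -> ClockModel:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"not a valid clock model file: {path}: {exc}") from exc
    if doc.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise ValueError(
            f"clock model schema version {doc.get('schema_version')!r} != {MODEL_SCHEMA_VERSION}"
        )
    return ClockModel(
        feature_kind=doc["feature_kind"],
        alpha=float(doc["alpha"]),
        lam=float(doc["lambda"]),
        intercept=float(doc["intercept"]),
        weights={k: float(v) for k, v in doc["weights"].items()},
        offsets={t: {k: float(v) for k, v in d.items()} for t, d in doc["offsets"].items()},
        fallback_offsets={k: float(v) for k, v in doc["fallback_offsets"].items()},
        training=doc.get("training", {}),
    )
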