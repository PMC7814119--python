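"""End-to-end pipeline orchestration with provenance capture.

A run is described by a YAML/dict config (stage toggles plus per-stage
parameter blocks and one master seed); stages execute in order
simulate -> segment -> matrix -> train -> crossval -> accel, each writing its
outputs plus a manifest entry (parameters, seed, output checksums).
Re-running an identical config reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from . import clock as _clock
from . import cohort as _cohort
from . import segmentation as _seg
from . import simulate as _sim
from .intervals import GenomicIntervalSet, intervals_from_feature_ids, read_intervals_bed, write_intervals_bed
from .io import MethylationTrack, aggregate_strands, filter_by_coverage, read_methratio, read_sample_sheet

__all__ = ["load_config", "validate_config", "run_pipeline", "DEFAULT_CONFIG"]

STAGES = ["simulate", "segment", "matrix", "train", "crossval", "accel"]

DEFAULT_CONFIG: dict = {
    "out_dir": "chickclock_run",
    "seed": 0,
    "stages": STAGES,
    "simulate": {
        "genome": {},            # SyntheticGenomeSpec overrides
        "design": None,           # list of cells; None -> default 4x3x3 design
        "coverage_mean": 40.0,
        "dispersion": 0.02,
        "region_noise_sd": 0.25,
    },
    "segment": {
        "min_coverage": 3,
        "cutoff": "auto",        # number or "auto" for FDR calibration
        "fdr": 0.05,
        "min_cpgs": 4,
        "smooth_k": 3,
    },
    "matrix": {
        "feature_kind": "LMR",
        "features_bed": None,     # None -> pooled segments from the segment stage
        "cpg_min_strand_cov": 10,
        "lmr_min_strand_cov": 5,
        "sex_chromosomes": ["Z", "W", "chrZ", "chrW"],
        "snp_bed": None,
    },
    "train": {"alpha": 0.9, "k_folds": 6},
    "crossval": {"alpha": 0.9, "k_folds": 6, "refit_normalization": True},
    "accel": {"reference_group": "control", "group_col": "group"},
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge(DEFAULT_CONFIG, user)


def _merge(base: dict, over: dict) -> dict:
    out = dict(base)
    for k, v in over.items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def validate_config(config: dict) -> None:
    unknown = [s for s in config.get("stages", []) if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    for key in ("features_bed", "snp_bed"):
        p = config.get("matrix", {}).get(key)
        if p is not None and not Path(p).exists():
            raise ValueError(f"matrix.{key} does not exist: {p}")
    if "simulate" not in config.get("stages", []):
        sheet = config.get("sample_sheet")
        if sheet is None or not Path(sheet).exists():
            raise ValueError("without the simulate stage a sample_sheet with file_path is required")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _snp_positions_from_bed(path: str | Path) -> frozenset[tuple[str, int]]:
    iv = read_intervals_bed(path)
    out = set()
    for row in iv.data.itertuples(index=False):
        for p in range(row.start + 1, row.end + 1):  # 1-based positions covered
            out.add((row.chrom, p))
    return frozenset(out)


def run_pipeline(config: dict, echo=None) -> dict:
    """Execute the enabled stages in order; returns the run manifest.

    Every stage appends a manifest entry with its parameters and the
    checksums of its outputs; the manifest (written to the output directory
    as ``manifest.json``) suffices to re-run any stage in isolation. A stage
    failure halts the run after recording the completed stages.
    """
    validate_config(config)
    out = Path(config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    log = echo or (lambda msg: None)
    manifest: dict = {"seed": seed, "stages": [], "config": _jsonable(config)}
    state: dict = {}

    try:
        for stage in [s for s in STAGES if s in config["stages"]]:
            log(f"[{stage}] running")
            outputs = _STAGE_FUNCS[stage](config, out, seed, state)
            manifest["stages"].append(
                {
                    "stage": stage,
                    "params": _jsonable(config.get(stage, {})),
                    "seed": seed,
                    "outputs": {str(p.relative_to(out)): _checksum(p) for p in outputs},
                }
            )
    finally:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _jsonable(obj):
    return json.loads(json.dumps(obj, default=str))


def _load_cohort(config: dict, out: Path, state: dict) -> tuple[dict[str, MethylationTrack], pd.DataFrame]:
    if "tracks" in state:
        return state["tracks"], state["sheet"]
    sheet_path = Path(config.get("sample_sheet") or out / "sim" / "samples.csv")
    sheet = read_sample_sheet(sheet_path)
    base = sheet_path.parent
    tracks = {
        row.sample_id: read_methratio(
            p if (p := Path(row.file_path)).is_absolute() else base / p, sample_id=row.sample_id
        )
        for row in sheet.itertuples(index=False)
    }
    state["tracks"], state["sheet"] = tracks, sheet
    return tracks, sheet


def _stage_simulate(config: dict, out: Path, seed: int, state: dict) -> list[Path]:
    p = config["simulate"]
    spec = _sim.default_genome_spec(seed=seed, **p.get("genome", {}))
    genome, truth = _sim.generate_genome(spec)
    design = p.get("design") or _sim.default_design()
    tracks, sheet = _sim.simulate_cohort(
        design, genome, truth, seed=seed,
        coverage_mean=p["coverage_mean"], dispersion=p["dispersion"],
        region_noise_sd=p["region_noise_sd"], out_dir=out / "sim",
    )
    state.update(tracks=tracks, sheet=sheet, genome=genome, truth=truth)
    sim_dir = out / "sim"
    return sorted(sim_dir.glob("*.tsv")) + [sim_dir / "samples.csv", sim_dir / "truth_regions.bed", sim_dir / "truth.json"]


def _stage_segment(config: dict, out: Path, seed: int, state: dict) -> list[Path]:
    p = config["segment"]
    tracks, _ = _load_cohort(config, out, state)
    cfg = _seg.SegmentationConfig(
        smooth_k=p["smooth_k"],
        m_cutoff=0.5 if p["cutoff"] == "auto" else float(p["cutoff"]),
        min_cpgs_segment=p["min_cpgs"],
        fdr_target=p["fdr"],
        seed=seed,
    )
    per_sample = []
    reports = {}
    for sid, track in tracks.items():
        prepped = aggregate_strands(filter_by_coverage(track, p["min_coverage"]))
        segs, report = _seg.segment_lmrs(prepped, cfg, auto_cutoff=p["cutoff"] == "auto")
        per_sample.append(segs)
        reports[sid] = {"cutoff": report["cutoff"], "n_segments": len(segs)}
    pooled = _seg.pool_interval_sets(per_sample)
    write_intervals_bed(pooled, out / "lmrs_pooled.bed")
    (out / "segment_report.json").write_text(json.dumps(reports, indent=1, sort_keys=True))
    state["pooled_lmrs"] = pooled
    return [out / "lmrs_pooled.bed", out / "segment_report.json"]


def _stage_matrix(config: dict, out: Path, seed: int, state: dict) -> list[Path]:
    p = config["matrix"]
    tracks, sheet = _load_cohort(config, out, state)
    snp = _snp_positions_from_bed(p["snp_bed"]) if p.get("snp_bed") else frozenset()
    fcfg = _clock.FilterConfig(
        sex_chromosomes=frozenset(p["sex_chromosomes"]),
        snp_positions=snp,
        cpg_min_strand_cov=p["cpg_min_strand_cov"],
        lmr_min_strand_cov=p["lmr_min_strand_cov"],
    )
    if p["feature_kind"] == "LMR":
        if p.get("features_bed"):
            features: GenomicIntervalSet | None = read_intervals_bed(p["features_bed"])
        else:
            features = state.get("pooled_lmrs")
            if features is None:
                features = read_intervals_bed(out / "lmrs_pooled.bed")
        matrix = _clock.build_feature_matrix(tracks, sheet, features, fcfg, feature_kind="LMR")
    else:
        matrix = _clock.build_feature_matrix(tracks, sheet, None, fcfg, feature_kind="CpG")
    matrix.values.to_csv(out / "matrix.csv")
    sheet.to_csv(out / "metadata.csv", index=False)
    state["matrix"], state["fcfg"] = matrix, fcfg
    return [out / "matrix.csv", out / "metadata.csv"]


def _require_matrix(config: dict, out: Path, state: dict) -> tuple[_clock.MethylationMatrix, pd.DataFrame]:
    if "matrix" not in state:
        values = pd.read_csv(out / "matrix.csv", index_col=0)
        state["matrix"] = _clock.MethylationMatrix(values, config["matrix"]["feature_kind"], False)
        state["sheet"] = read_sample_sheet(out / "metadata.csv")
    return state["matrix"], state["sheet"]


def _stage_train(config: dict, out: Path, seed: int, state: dict) -> list[Path]:
    p = config["train"]
    matrix, sheet = _require_matrix(config, out, state)
    model = _clock.train_clock(matrix, sheet, alpha=p["alpha"], k_folds=p["k_folds"], seed=seed)
    _clock.serialize_model(model, out / "clock.json")
    state["model"] = model
    return [out / "clock.json"]


def _stage_crossval(config: dict, out: Path, seed: int, state: dict) -> list[Path]:
    p = config["crossval"]
    matrix, sheet = _require_matrix(config, out, state)
    table, rmse = _clock.cross_validate_clock(
        matrix, sheet, alpha=p["alpha"], k_folds=p["k_folds"], seed=seed,
        refit_normalization=p["refit_normalization"],
    )
    table.to_csv(out / "crossval.csv", index=False)
    (out / "crossval_summary.json").write_text(json.dumps({"rmse_days": rmse, "k_folds": p["k_folds"]}, indent=1))
    return [out / "crossval.csv", out / "crossval_summary.json"]


def _stage_accel(config: dict, out: Path, seed: int, state: dict) -> list[Path]:
    p = config["accel"]
    matrix, sheet = _require_matrix(config, out, state)
    model = state.get("model") or _clock.deserialize_model(out / "clock.json")
    results = _cohort.age_acceleration(model, matrix, sheet)
    results.to_csv(out / "acceleration.csv", index=False)
    tests = _cohort.test_group_acceleration(results, p["reference_group"], group_col=p["group_col"])
    tests.to_csv(out / "acceleration_tests.csv", index=False)
    return [out / "acceleration.csv", out / "acceleration_tests.csv"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "segment": _stage_segment,
    "matrix": _stage_matrix,
    "train": _stage_train,
    "crossval": _stage_crossval,
    "accel": _stage_accel,
}
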