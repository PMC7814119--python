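"""Synthetic WGBS methylomes with full ground truth.

The generator emulates the statistical structure the clock pipeline assumes:
a densely methylated background genome punctuated by planted low-methylated
regions (LMRs, CpG-enriched as real regulatory elements are), a subset of
which drift with age linearly on the logit scale; per-tissue methylation
offsets confined to those regions; strand-resolved read counts drawn
beta-binomially at configurable coverage; SNP-flagged CpGs and an optional
sex chromosome; and treatment groups whose effective epigenetic age is
shifted by a fixed number of days. Every random draw flows from one master
seed, and the planted truth (region coordinates, slopes, offsets, per-sample
acceleration) is returned for recovery testing.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .intervals import GenomicIntervalSet
from .io import MethylationTrack

__all__ = [
    "SyntheticGenomeSpec",
    "SyntheticGenome",
    "SyntheticTruth",
    "generate_genome",
    "simulate_sample",
    "simulate_cohort",
    "restrict_genome",
    "default_genome_spec",
    "default_design",
    "snp_filter_positions",
]


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Layout and methylation parameters of a synthetic genome.

    CpG dyads are spaced exponentially (mean ``cpg_spacing_mean`` bp in the
    background, ``region_cpg_spacing_mean`` inside planted regions — regulatory
    LMRs are CpG-enriched). ``n_regions`` low-methylated regions of length
    drawn from ``region_length`` are placed without overlap on the autosomes;
    a fraction ``frac_age_responsive`` get an age slope of magnitude drawn
    from ``slope_range`` (logit units/day, positive with probability
    ``positive_slope_prob``; negative-slope regions start high and descend so
    trajectories stay in a realistic dynamic range). Background methylation is
    ``background_meth``; responsive regions start at ``region_meth0``.
    Per-(tissue, region) offsets are N(0, ``tissue_offset_sd``) logit units.
    ``snp_fraction`` of dyads are flagged as SNP positions.
    """

    chromosomes: tuple[tuple[str, int], ...] = (("chr1", 5_000_000), ("chrZ", 200_000))
    sex_chromosomes: frozenset[str] = frozenset({"chrZ", "chrW"})
    cpg_spacing_mean: float = 100.0
    region_cpg_spacing_mean: float = 35.0
    n_regions: int = 500
    region_length: tuple[int, int] = (300, 600)
    frac_age_responsive: float = 0.1
    background_meth: float = 0.8
    region_meth0: float = 0.1
    snp_fraction: float = 0.01
    slope_range: tuple[float, float] = (0.05, 0.15)
    positive_slope_prob: float = 0.55
    tissue_offset_sd: float = 0.5
    max_age_days: float = 35.0
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.frac_age_responsive, self.background_meth, self.region_meth0, self.snp_fraction):
            if not (0.0 <= f <= 1.0):
                raise ValueError("fractions and methylation levels must be in [0, 1]")
        if self.region_length[0] <= 0 or self.region_length[1] < self.region_length[0]:
            raise ValueError("invalid region_length range")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated genome/cohort.

    ``regions``: one row per planted region (chrom, start, end, region_id,
    age_responsive, slope [logit/day], logit_base). ``tissue_offsets`` maps a
    tissue name to a per-region offset vector (logit units), drawn lazily but
    deterministically from the master seed. ``samples`` accumulates one row
    per simulated sample (sample_id, tissue, age_days, group,
    acceleration_days, seed).
    """

    regions: pd.DataFrame
    seed: int
    tissue_offset_sd: float
    tissue_offsets: dict[str, np.ndarray] = field(default_factory=dict)
    samples: list[dict] = field(default_factory=list)

    def offsets_for(self, tissue: str) -> np.ndarray:
        if tissue not in self.tissue_offsets:
            key = zlib.crc32(tissue.encode()) & 0x7FFFFFFF
            rng = np.random.default_rng(np.random.SeedSequence([self.seed, key]))
            self.tissue_offsets[tissue] = rng.normal(0.0, self.tissue_offset_sd, len(self.regions))
        return self.tissue_offsets[tissue]

    def region_intervals(self) -> GenomicIntervalSet:
        df = self.regions[["chrom", "start", "end"]].copy()
        df["segment_class"] = "LMR"
        return GenomicIntervalSet(df)


@dataclass
class SyntheticGenome:
    """CpG dyad map of a synthetic genome plus planted-region bookkeeping.

    ``cpg_pos[chrom]`` holds 1-based plus-strand cytosine positions of each
    dyad; ``region_index[chrom]`` the planted-region row index per dyad (-1
    for background); ``snp_flag[chrom]`` marks SNP-associated dyads.
    """

    spec: SyntheticGenomeSpec
    cpg_pos: dict[str, np.ndarray]
    region_index: dict[str, np.ndarray]
    snp_flag: dict[str, np.ndarray]

    @property
    def n_cpgs(self) -> int:
        return int(sum(len(v) for v in self.cpg_pos.values()))


def _exponential_positions(rng: np.random.Generator, lo: int, hi: int, mean_gap: float) -> np.ndarray:
    """1-based dyad positions in [lo, hi) with exponential gaps (min 2 bp)."""
    if hi - lo < 2:
        return np.array([], dtype=np.int64)
    n_guess = max(8, int((hi - lo) / mean_gap * 1.5) + 8)
    gaps = np.maximum(2, np.round(rng.exponential(mean_gap, n_guess)).astype(np.int64))
    pos = lo + 1 + np.cumsum(gaps)  # 1-based
    while len(pos) and pos[-1] < hi - 1:
        extra = np.maximum(2, np.round(rng.exponential(mean_gap, n_guess)).astype(np.int64))
        pos = np.concatenate([pos, pos[-1] + np.cumsum(extra)])
    return pos[pos < hi]  # dyad (pos, pos+1) must fit


def generate_genome(spec: SyntheticGenomeSpec) -> tuple[SyntheticGenome, SyntheticTruth]:
    """Generate the CpG map, planted regions, SNP flags, and ground truth."""
    rng = np.random.default_rng(spec.seed)
    autosomes = [(n, l) for n, l in spec.chromosomes if n not in spec.sex_chromosomes]
    if spec.n_regions > 0 and not autosomes:
        raise ValueError("regions require at least one autosome")

    # apportion regions to autosomes by length, then place without overlap
    lengths = np.array([l for _, l in autosomes], dtype=float)
    counts = np.zeros(len(autosomes), dtype=int)
    if spec.n_regions:
        shares = lengths / lengths.sum()
        counts = np.floor(shares * spec.n_regions).astype(int)
        for i in np.argsort(-shares)[: spec.n_regions - counts.sum()]:
            counts[i] += 1

    region_rows = []
    rid = 0
    for (chrom, clen), k in zip(autosomes, counts):
        if k == 0:
            continue
        rl = rng.integers(spec.region_length[0], spec.region_length[1] + 1, size=k)
        free = clen - int(rl.sum()) - 2 * k  # keep a 1-bp margin per region
        if free <= 0:
            raise ValueError(f"cannot place {k} regions of given lengths on {chrom} without overlap")
        anchors = np.sort(rng.uniform(0, free, size=k))
        starts = (anchors + np.concatenate([[0], np.cumsum(rl[:-1] + 2)])).astype(np.int64) + 1
        for s, l in zip(starts, rl):
            region_rows.append((chrom, int(s), int(s + l), rid))
            rid += 1
    regions = pd.DataFrame(region_rows, columns=["chrom", "start", "end", "region_id"]) if region_rows else pd.DataFrame(
        columns=["chrom", "start", "end", "region_id"]
    )

    # age responsiveness and slopes
    n_reg = len(regions)
    n_resp = int(round(spec.frac_age_responsive * n_reg))
    responsive = np.zeros(n_reg, dtype=bool)
    if n_resp:
        responsive[rng.choice(n_reg, size=n_resp, replace=False)] = True
    mag = rng.uniform(spec.slope_range[0], spec.slope_range[1], n_reg)
    sign = np.where(rng.random(n_reg) < spec.positive_slope_prob, 1.0, -1.0)
    slope = np.where(responsive, mag * sign, 0.0)
    base = logit(spec.region_meth0)
    # descending regions start high so the trajectory ends at region_meth0
    logit_base = np.where(slope < 0, base - slope * spec.max_age_days, base)
    regions["age_responsive"] = responsive
    regions["slope"] = slope
    regions["logit_base"] = logit_base

    cpg_pos: dict[str, np.ndarray] = {}
    region_index: dict[str, np.ndarray] = {}
    snp_flag: dict[str, np.ndarray] = {}
    for chrom, clen in spec.chromosomes:
        bg = _exponential_positions(rng, 0, clen, spec.cpg_spacing_mean)
        sub = regions[regions["chrom"] == chrom]
        reg_pos_list, reg_idx_list = [], []
        for row in sub.itertuples(index=False):
            rp = _exponential_positions(rng, row.start, row.end, spec.region_cpg_spacing_mean)
            reg_pos_list.append(rp)
            reg_idx_list.append(np.full(len(rp), row.region_id, dtype=np.int64))
            bg = bg[(bg <= row.start) | (bg > row.end)]  # background stays outside regions
        pos = np.concatenate([bg] + reg_pos_list) if reg_pos_list else bg
        idx = np.concatenate([np.full(len(bg), -1, dtype=np.int64)] + reg_idx_list) if reg_idx_list else np.full(
            len(bg), -1, dtype=np.int64
        )
        order = np.argsort(pos, kind="mergesort")
        pos, idx = pos[order], idx[order]
        keep = np.concatenate([[True], np.diff(pos) >= 2])  # dyads must not collide
        pos, idx = pos[keep], idx[keep]
        cpg_pos[chrom] = pos
        region_index[chrom] = idx
        snp_flag[chrom] = rng.random(len(pos)) < spec.snp_fraction

    genome = SyntheticGenome(spec=spec, cpg_pos=cpg_pos, region_index=region_index, snp_flag=snp_flag)
    truth = SyntheticTruth(regions=regions, seed=spec.seed, tissue_offset_sd=spec.tissue_offset_sd)
    return genome, truth


def snp_filter_positions(genome: SyntheticGenome) -> frozenset[tuple[str, int]]:
    """(chrom, pos) pairs covering both strands of every SNP-flagged dyad."""
    out = set()
    for chrom, pos in genome.cpg_pos.items():
        for p in pos[genome.snp_flag[chrom]]:
            out.add((chrom, int(p)))
            out.add((chrom, int(p) + 1))
    return frozenset(out)


def restrict_genome(genome: SyntheticGenome, intervals: GenomicIntervalSet) -> SyntheticGenome:
    """Sub-genome containing only dyads inside the given intervals.

    Keeps region indices and SNP flags, so simulated truth is unchanged;
    useful when only clock-feature loci need simulating.
    """
    cpg_pos, region_index, snp_flag = {}, {}, {}
    iv = intervals.data
    for chrom, pos in genome.cpg_pos.items():
        sub = iv[iv["chrom"] == chrom]
        if len(sub) == 0:
            continue
        mask = np.zeros(len(pos), dtype=bool)
        p0 = pos - 1
        for row in sub.itertuples(index=False):
            mask |= (p0 >= row.start) & (p0 < row.end)
        if mask.any():
            cpg_pos[chrom] = pos[mask]
            region_index[chrom] = genome.region_index[chrom][mask]
            snp_flag[chrom] = genome.snp_flag[chrom][mask]
    return SyntheticGenome(spec=genome.spec, cpg_pos=cpg_pos, region_index=region_index, snp_flag=snp_flag)


def simulate_sample(
    genome: SyntheticGenome,
    truth: SyntheticTruth,
    tissue: str,
    age_days: float,
    acceleration_days: float = 0.0,
    coverage_mean: float = 40.0,
    dispersion: float = 0.02,
    region_noise_sd: float = 0.25,
    seed: int = 0,
    sample_id: str | None = None,
) -> MethylationTrack:
    """Simulate strand-resolved WGBS read counts for one sample.

    Per dyad the true methylation is
    ``mu = expit(logit_base + slope * (age + acceleration) + tissue_offset
    + region_noise)`` inside planted regions and the constant background level
    outside. Per-strand coverage is Poisson(coverage_mean / 2); methylated
    counts are beta-binomial with intraclass correlation ``dispersion``
    (plain binomial at 0). Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    spec = genome.spec
    eff_age = age_days + acceleration_days
    t_off = truth.offsets_for(tissue)
    slopes = truth.regions["slope"].to_numpy() if len(truth.regions) else np.array([])
    bases = truth.regions["logit_base"].to_numpy() if len(truth.regions) else np.array([])
    reg_noise = rng.normal(0.0, region_noise_sd, len(truth.regions)) if len(truth.regions) else np.array([])

    frames = []
    for chrom in genome.cpg_pos:
        pos = genome.cpg_pos[chrom]
        ridx = genome.region_index[chrom]
        mu = np.full(len(pos), spec.background_meth)
        in_reg = ridx >= 0
        if in_reg.any():
            rr = ridx[in_reg]
            mu[in_reg] = expit(bases[rr] + slopes[rr] * eff_age + t_off[rr] + reg_noise[rr])
        mu = np.clip(mu, 1e-6, 1 - 1e-6)

        cov = rng.poisson(coverage_mean / 2.0, size=(2, len(pos)))
        if dispersion > 0:
            theta = (1.0 - dispersion) / dispersion
            p = rng.beta(mu * theta, (1.0 - mu) * theta, size=(2, len(pos)))
        else:
            p = np.broadcast_to(mu, (2, len(pos)))
        meth = rng.binomial(cov, p)

        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": np.concatenate([pos, pos + 1]),
                    "strand": np.repeat(["+", "-"], len(pos)),
                    "context": "CG",
                    "meth_count": np.concatenate([meth[0], meth[1]]),
                    "total_count": np.concatenate([cov[0], cov[1]]),
                }
            )
        )
    sid = sample_id or f"{tissue}_{age_days:g}d_s{seed}"
    data = pd.concat(frames, ignore_index=True) if frames else None
    if data is None:
        raise ValueError("genome has no CpGs")
    return MethylationTrack(sid, data)


def default_design(
    tissues: tuple[str, ...] = ("ileum", "breast_muscle", "spleen", "jejunum"),
    ages: tuple[float, ...] = (3, 15, 34),
    n_per_cell: int = 3,
) -> list[dict]:
    """Default cohort design: 4 tissues x 3 ages x 3 replicates = 36 samples."""
    return [
        {"tissue": t, "age_days": a, "n": n_per_cell, "group": "control", "acceleration_days": 0.0}
        for t in tissues
        for a in ages
    ]


def default_genome_spec(seed: int = 0, **overrides) -> SyntheticGenomeSpec:
    """The reference genome spec used throughout tests and examples."""
    kwargs = dict(seed=seed)
    kwargs.update(overrides)
    return SyntheticGenomeSpec(**kwargs)


def simulate_cohort(
    design: list[dict],
    genome: SyntheticGenome,
    truth: SyntheticTruth,
    seed: int = 0,
    coverage_mean: float = 40.0,
    dispersion: float = 0.02,
    region_noise_sd: float = 0.25,
    out_dir=None,
) -> tuple[dict[str, MethylationTrack], pd.DataFrame]:
    """Simulate a cohort; returns (tracks by sample_id, sample sheet).

    Per-sample seeds are spawned deterministically from the master seed. When
    ``out_dir`` is given, methratio TSV tracks, the sample sheet CSV, a truth
    BED of planted regions and a truth JSON are written there.
    """
    if not design:
        raise ValueError("empty design")
    rows = []
    total = sum(int(d["n"]) for d in design)
    child_seeds = np.random.SeedSequence(seed).generate_state(total) % (2**31)
    tracks: dict[str, MethylationTrack] = {}
    i = 0
    for cell in design:
        for rep in range(int(cell["n"])):
            sid = f"{cell['tissue']}_d{cell['age_days']:g}_{cell['group']}_{rep+1}"
            s = int(child_seeds[i])
            track = simulate_sample(
                genome,
                truth,
                tissue=cell["tissue"],
                age_days=float(cell["age_days"]),
                acceleration_days=float(cell.get("acceleration_days", 0.0)),
                coverage_mean=coverage_mean,
                dispersion=dispersion,
                region_noise_sd=region_noise_sd,
                seed=s,
                sample_id=sid,
            )
            tracks[sid] = track
            row = {
                "sample_id": sid,
                "tissue": cell["tissue"],
                "age_days": float(cell["age_days"]),
                "group": cell["group"],
                "acceleration_days": float(cell.get("acceleration_days", 0.0)),
                "seed": s,
            }
            rows.append(row)
            truth.samples.append(row)
            i += 1
    sheet = pd.DataFrame(rows)

    if out_dir is not None:
        import json
        from pathlib import Path

        from .intervals import write_intervals_bed
        from .io import write_methratio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sid, track in tracks.items():
            write_methratio(track, out / f"{sid}.tsv")
        sheet2 = sheet.copy()
        # paths relative to the sheet keep the output relocatable (and runs
        # with identical configs byte-identical)
        sheet2["file_path"] = [f"{sid}.tsv" for sid in sheet2["sample_id"]]
        sheet2.to_csv(out / "samples.csv", index=False)
        write_intervals_bed(truth.region_intervals(), out / "truth_regions.bed")
        (out / "truth.json").write_text(
            json.dumps(
                {
                    "seed": seed,
                    "coverage_mean": coverage_mean,
                    "dispersion": dispersion,
                    "region_noise_sd": region_noise_sd,
                    "regions": truth.regions.to_dict(orient="list"),
                    "samples": rows,
                },
                default=str,
                indent=1,
            )
        )
    return tracks, sheet
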