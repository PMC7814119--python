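import numpy as np
import pandas as pd
import pytest

import chickclock as cc


def make_track(records, sample_id="s"):
    """records: iterable of (chrom, pos, strand, meth, total)."""
    df = pd.DataFrame(records, columns=["chrom", "pos", "strand", "meth_count", "total_count"])
    df["context"] = "CG"
    return cc.MethylationTrack(sample_id, df)


@pytest.fixture
def tiny_track():
    return make_track(
        [
            ("chr1", 100, "+", 3, 4),
            ("chr1", 101, "-", 1, 2),
            ("chr1", 200, "+", 0, 5),
            ("chr1", 300, "+", 5, 5),
            ("chr2", 50, "+", 2, 10),
        ]
    )


@pytest.fixture(scope="session")
def small_genome():
    """A compact ground-truthed genome shared by cross-module tests."""
    spec = cc.default_genome_spec(
        seed=123,
        chromosomes=(("chr1", 400_000), ("chrZ", 40_000)),
        n_regions=40,
        frac_age_responsive=0.25,
    )
    return cc.generate_genome(spec)


@pytest.fixture(scope="session")
def small_cohort(small_genome):
    genome, truth = small_genome
    design = cc.default_design(n_per_cell=2)  # 4 tissues x 3 ages x 2 = 24 samples
    tracks, sheet = cc.simulate_cohort(design, genome, truth, seed=42)
    return tracks, sheet, genome, truth


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    tracks, sheet, genome, truth = small_cohort
    fcfg = cc.FilterConfig(snp_positions=cc.snp_filter_positions(genome))
    mat = cc.build_feature_matrix(tracks, sheet, truth.region_intervals(), fcfg, feature_kind="LMR")
    return mat, sheet, genome, truth
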