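"""Simulate a ground-truthed WGBS cohort and inspect what was planted.

Generates a small synthetic genome with low-methylated regions (a quarter of
them drifting with age), simulates a 12-sample two-tissue cohort of
strand-resolved read counts, and prints the cohort layout and genome facts.
"""

import chickclock as cc

spec = cc.default_genome_spec(
    seed=1,
    chromosomes=(("chr1", 500_000), ("chrZ", 50_000)),
    n_regions=50,
    frac_age_responsive=0.25,
)
genome, truth = cc.generate_genome(spec)

design = [
    {"tissue": t, "age_days": a, "n": 2, "group": "control", "acceleration_days": 0.0}
    for t in ("ileum", "spleen")
    for a in (3, 15, 34)
]
tracks, sheet = cc.simulate_cohort(design, genome, truth, seed=1)

n_resp = int(truth.regions["age_responsive"].sum())
print(f"genome: {genome.n_cpgs} CpG dyads, {len(truth.regions)} planted LMRs "
      f"({n_resp} age-responsive)")
print(f"cohort: {len(tracks)} samples -> {sheet.groupby(['tissue','age_days']).size().to_dict()}")
one = next(iter(tracks.values()))
print(f"one track: {len(one)} strand-resolved records, "
      f"median coverage {int(one.data['total_count'].median())} reads/strand")
# The planted truth (region coordinates, slopes, tissue offsets) is what the
# segmentation and clock examples try to recover.
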