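"""Shared study conditions for the numbered analysis drivers.

One synthetic cohort mirrors the twin-study design: a discordant twin pair
(trisomic vs euploid, two technical replicates each) carrying a +3 point
global promoter hypermethylation shift and 20 planted promoter DMRs at
|delta| = 40 (17 hyper / 3 hypo), two null control twin pairs, and an
unrelated case/control pair sharing the planted effects on an independent
baseline methylome.
"""

from pathlib import Path

from twinmeth import simulate

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"

COHORT_CONFIG = simulate.SimulationConfig(
    seed=42,
    n_chromosomes=2,
    chromosome_length=5_200_000,
    n_promoters=400,
    cpgs_per_promoter_range=(20, 30),
    coverage_mean=30.0,
    global_shift=3.0,
    planted_dmrs=[{"region_class": "promoter", "delta_percent": 40.0}] * 17
    + [{"region_class": "promoter", "delta_percent": -40.0}] * 3,
)


def build_cohort():
    """Deterministically regenerate the cohort (a few seconds)."""
    annotation, layout, comparisons, truth = simulate.simulate_cohort(COHORT_CONFIG)
    return annotation, layout, comparisons, truth


def methylomes_by_group(samples, group):
    meths = simulate.methylomes_from_counts(
        {sid: c for sid, c in samples.items() if f"_{group}_" in sid}
    )
    return meths
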