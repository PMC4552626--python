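import numpy as np
import pandas as pd
import pytest

from twinmeth import simulate
from twinmeth.methcall import SampleMethylome, calls_from_counts


@pytest.fixture(scope="session")
def small_config():
    return simulate.SimulationConfig(
        seed=101,
        n_chromosomes=2,
        chromosome_length=900_000,
        n_promoters=30,
        cpgs_per_promoter_range=(15, 25),
    )


@pytest.fixture(scope="session")
def small_annotation(small_config):
    return simulate.generate_annotation(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_config, small_annotation):
    """One simulated discordant twin pair (2 replicates each) with a planted
    hyper- and hypomethylated promoter DMR."""
    cfg = simulate.SimulationConfig(
        **{
            **small_config.__dict__,
            "planted_dmrs": [
                {"region_class": "promoter", "delta_percent": 40.0},
                {"region_class": "promoter", "delta_percent": -40.0},
            ],
        }
    )
    annotation = simulate.generate_annotation(cfg)
    samples, truth = simulate.simulate_methylomes(cfg, annotation)
    methylomes = simulate.methylomes_from_counts(samples)
    return cfg, annotation, samples, truth, methylomes


def make_methylome(records, sample_id="s", min_coverage=1):
    """Hand-built methylome from (chrom, pos, strand, count_m, count_u) rows."""
    df = pd.DataFrame(records, columns=["chrom", "pos", "strand", "count_m", "count_u"])
    return calls_from_counts(df, sample_id=sample_id, min_coverage=min_coverage)
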