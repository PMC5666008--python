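import numpy as np
import pytest

from trionovo import SimConfig, simulate_trio, true_mie_table
from trionovo.pipeline import AnalysisParams, run_analysis


@pytest.fixture(scope="session")
def rich_sim():
    """A 1-Mb trio carrying every event class, reused across test modules."""
    cfg = SimConfig(
        genome_length=1_000_000,
        mu_denovo=1e-5,
        n_somatic=1,
        conversion_events=3,
        hemizygous_deletions=(("mother", 35_000), ("father", 20_000)),
        denovo_deletions=(6_000,),
        seed=11,
    )
    return simulate_trio(cfg)


@pytest.fixture(scope="session")
def rich_result(rich_sim):
    return run_analysis(rich_sim, AnalysisParams())


@pytest.fixture(scope="session")
def rich_truth(rich_sim):
    return true_mie_table(rich_sim)
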