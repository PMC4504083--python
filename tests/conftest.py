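import numpy as np
import pandas as pd
import pytest

from methleak.synthetic_cohort import CohortDesign, simulate_cohort


@pytest.fixture(scope="session")
def small_design():
    return CohortDesign(
        n_individuals=5,
        tissues=("tA", "tB", "tC"),
        n_cpgs=400,
        n_snps=120,
        fraction_cpg_disrupting=0.10,
        fraction_indirect_meqtl=0.05,
        coverage_mean_per_strand=15.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_design):
    return simulate_cohort(small_design)


@pytest.fixture(scope="session")
def small_calls(small_cohort):
    return {sid: small_cohort.stranded_calls(sid) for sid in small_cohort.evidence}


@pytest.fixture(scope="session")
def sample_map(small_cohort):
    return dict(zip(small_cohort.samples["sample_id"], small_cohort.samples["individual_id"]))
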