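import numpy as np
import pytest

from dsadyn.dtw import DEFAULT_PIPELINE_WINDOW, DtwConfig
from dsadyn.preprocess import preprocess_cohort
from dsadyn.synth import SamplingSchedule, make_cohort


@pytest.fixture(scope="session")
def pipeline_dtw() -> DtwConfig:
    return DtwConfig(window=DEFAULT_PIPELINE_WINDOW)


@pytest.fixture(scope="session")
def default_cohort():
    """The reference 88-case cohort (18/15/23/16/16 across the archetypes)."""
    return make_cohort([18, 15, 23, 16, 16], rng_seed=42)


@pytest.fixture(scope="session")
def responder47():
    """47 full-length scaled responder series from the four active archetypes."""
    sched = SamplingSchedule(p_full_followup=1.0)
    mfi, cohort = make_cohort([0, 12, 12, 12, 11], schedule=sched, rng_seed=1)
    stages = preprocess_cohort(mfi)
    truth = cohort.set_index("case_id")["true_group"]
    series = [tr.scaled for tr in stages["full_50"]]
    groups = np.array([truth[tr.case_id] for tr in stages["full_50"]])
    return series, groups
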