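import numpy as np
import pytest

from popmediate import SimulationConfig, generate_cohort
from popmediate.survey import SurveyDesign


@pytest.fixture(scope="session")
def censored_cohort():
    """Moderate cohort with Table-1-style censoring."""
    cfg = SimulationConfig(n_participants=800, n_strata=10, seed=42)
    cohort, panel, truth = generate_cohort(cfg)
    return cfg, cohort, panel, truth


@pytest.fixture(scope="session")
def complete_cohort():
    """Cohort with censoring switched off (true concentrations observed)."""
    cfg = SimulationConfig(
        n_participants=1200,
        n_strata=12,
        seed=7,
        lod_quantiles=np.zeros((15, 2)),
    )
    cohort, panel, truth = generate_cohort(cfg)
    return cfg, cohort, panel, truth


@pytest.fixture(scope="session")
def design(complete_cohort):
    _, cohort, _, _ = complete_cohort
    return SurveyDesign.from_cohort(cohort)
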