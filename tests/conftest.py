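import numpy as np
import pytest

from idpower import (
    CohortDesign,
    EffectSpec,
    ExposureSpec,
    FrailtySpec,
    Scenario,
    TransitionSet,
    WeibullParams,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def continuous_design():
    return CohortDesign(n_subjects=30_000, visit_interval_years="continuous")


@pytest.fixture
def panel_design():
    return CohortDesign(n_subjects=30_000)


@pytest.fixture
def small_null_scenario():
    """A fast, frailty-free continuous-observation scenario under the null.

    Used for calibration-style checks where the analysis model matches the
    generator exactly (no frailty, no misclassification, exact event times).
    """
    return Scenario.from_preset(
        "diabetes",
        design=CohortDesign(n_subjects=2_000, visit_interval_years="continuous"),
        exposures=ExposureSpec(prevalence_env=0.3, prevalence_gen=0.3),
        effects=EffectSpec(),
        frailty=FrailtySpec(sd=0.0),
    )


@pytest.fixture
def dementia_panel_scenario(panel_design):
    return Scenario.from_preset(
        "dementia",
        design=panel_design,
        exposures=ExposureSpec(prevalence_env=0.1, prevalence_gen=0.1),
    )
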