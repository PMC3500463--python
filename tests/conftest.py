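import numpy as np
import pandas as pd
import pytest

from figground.stimuli import StimulusParams, build_schedule
from figground.synth import (
    BehaviorModel,
    ERPTemplateSet,
    Montage,
    NoiseModel,
    TMSArtifactModel,
    simulate_subject,
)


@pytest.fixture(scope="session")
def audit_params() -> StimulusParams:
    """Scaled-down screen for Monte-Carlo stimulus audits (balance is
    resolution independent)."""
    return StimulusParams().scaled(0.25)


@pytest.fixture(scope="session")
def montage() -> Montage:
    return Montage.standard()


@pytest.fixture(scope="session")
def tiny_schedule():
    return build_schedule(n_blocks=1, trials_per_block=24, seed=11)


@pytest.fixture(scope="session")
def small_recording(tiny_schedule, montage):
    """One simulated subject (24 trials) with default calibration."""
    rec, beh = simulate_subject(
        tiny_schedule,
        ERPTemplateSet.default(),
        TMSArtifactModel(),
        NoiseModel(),
        BehaviorModel.default(),
        montage,
        seed=101,
    )
    return rec, beh
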