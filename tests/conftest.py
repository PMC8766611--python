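"""Shared fixtures: small synthetic sessions reused across test modules."""

import numpy as np
import pytest

import thermoeeg as te
from thermoeeg.config import PipelineConfig
from thermoeeg.paradigm import SessionSpec, StimulusParadigm, generate_paradigm
from thermoeeg.synth import EffectSpec, generate_eeg_session, noiseless_effects


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def five_cond_paradigm():
    """One session delivering all five conditions, 2 trials each."""
    spec = StimulusParadigm(
        sessions=(
            SessionSpec("combined", tuple(te.CONDITIONS), trials_per_condition=2),
        )
    )
    return generate_paradigm(spec, seed=11)


@pytest.fixture(scope="session")
def noisefree_session(five_cond_paradigm):
    """All five conditions, evoked transients only (no noise/alpha/artifacts)."""
    return generate_eeg_session(five_cond_paradigm, noiseless_effects(), seed=11)


@pytest.fixture(scope="session")
def default_session(five_cond_paradigm):
    """All five conditions under the default effect sizes and noise."""
    return generate_eeg_session(five_cond_paradigm, EffectSpec(), seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)
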