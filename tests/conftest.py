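import dataclasses

import numpy as np
import pytest

from mmecho.io import stitch_frames
from mmecho.synth import StudyConfig, SynthConfig, generate_lvid_trace, render_record


@pytest.fixture(scope="session")
def default_cfg():
    return SynthConfig()


@pytest.fixture(scope="session")
def clean_cfg():
    """Noise- and corruption-free config: exact round trips."""
    return SynthConfig(noise_level=0.0, corruption_rate=0.0)


@pytest.fixture(scope="session")
def clean_record(clean_cfg):
    trace = generate_lvid_trace(clean_cfg, seed=42)
    rec, gt = render_record(trace, clean_cfg, seed=42)
    return rec, gt, trace


@pytest.fixture(scope="session")
def clean_echo(clean_record):
    rec, gt, trace = clean_record
    return stitch_frames(rec), gt, trace


@pytest.fixture(scope="session")
def noisy_record(default_cfg):
    trace = generate_lvid_trace(default_cfg, seed=7)
    rec, gt = render_record(trace, default_cfg, seed=7)
    return rec, gt, trace


@pytest.fixture(scope="session")
def tiny_study_cfg(default_cfg):
    return StudyConfig(
        study_name="tiny",
        n_per_sex_per_genotype=1,
        base=dataclasses.replace(default_cfg),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
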