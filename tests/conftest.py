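import dataclasses

import numpy as np
import pytest

from rovingmmn.montage import default_montage
from rovingmmn.paradigm import ParadigmConfig
from rovingmmn.simulate import SimulationDesign
from rovingmmn.synth import SynthConfig


@pytest.fixture(scope="session")
def synth_cfg() -> SynthConfig:
    return SynthConfig()


@pytest.fixture(scope="session")
def paradigm_cfg() -> ParadigmConfig:
    return ParadigmConfig()


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_montage(montage):
    """Frontocentral six-channel montage for fast simulations."""
    return montage.subset(("F3", "Fz", "F4", "FC1", "FC2", "Cz"))


@pytest.fixture(scope="session")
def tiny_design() -> SimulationDesign:
    """Small, fast simulation design for unit tests (not the study scale)."""
    return dataclasses.replace(
        SimulationDesign(),
        n_subjects=4,
        n_blocks_per_condition=1,
        max_standards=20,
        max_deviants=20,
        paradigm=ParadigmConfig(block_len=120),
        seed=7,
    )


@pytest.fixture(scope="session")
def noise_free_design(tiny_design) -> SimulationDesign:
    return dataclasses.replace(
        tiny_design, subject_sd=0.0, noise_white_sd=0.0, noise_pink_sd=0.0
    )
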