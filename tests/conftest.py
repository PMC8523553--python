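import numpy as np
import pytest

from mvcs.synthetic import GeneratorConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_config():
    """A fast study configuration for end-to-end tests.

    Small ROIs and shortened task blocks keep a full study cheap while
    preserving the design structure (19 subjects would be the study
    scale; unit tests use fewer).
    """
    return GeneratorConfig(
        n_subjects=4,
        rois={"roiA": 16, "roiB": 12},
        rest_volumes=90,
        presses_per_block=12,
        press_interval_s=0.5,
        rest_block_s=5.0,
        seed=7,
    )


@pytest.fixture
def calibration_config():
    """Study-scale (19 subjects) configuration with compact runs,
    used for simulation-based statistical checks."""
    return GeneratorConfig(
        n_subjects=19,
        rois={"roi": 20},
        presses_per_block=12,
        press_interval_s=0.5,
        rest_block_s=5.0,
        seed=0,
    )
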