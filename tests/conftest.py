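import numpy as np
import pytest

from choroquant import CohortSimConfig, ImageSimConfig, simulate_bscan, simulate_cohort


@pytest.fixture(scope="session")
def default_scan():
    """One default-config simulated B-scan with its truth."""
    return simulate_bscan(ImageSimConfig(seed=7))


@pytest.fixture(scope="session")
def small_image_config():
    """A small, fast image configuration for geometry-focused tests."""
    return ImageSimConfig(
        height_px=160,
        width_px=192,
        choroid_mean_thickness_um=250.0,
        seed=3,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default-config simulated cohort (720 subjects, 1440 eyes)."""
    return simulate_cohort(CohortSimConfig(seed=11))
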