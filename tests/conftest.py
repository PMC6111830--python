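"""Shared fixtures: synthetic campaigns at several noise settings.

The default campaign emulates a 59-sample, six-station coastal survey over
0.83-14.33 ug/L Chl-a on the 350-1050 nm grid.  Heavier fixtures are
session-scoped so the full-resolution ISE-PLS runs happen once.
"""

import numpy as np
import pytest

from hyperchla import (SyntheticParams, generate_dataset, noise_free,
                       deterministic, savgol_smooth, trim_to_analysis_range)

CAMPAIGN_SEED = 1


def preprocess_rl(spectra, lo=400, hi=900):
    """Standard chain: smooth on the native grid, then trim."""
    return trim_to_analysis_range(savgol_smooth(spectra), lo, hi)


@pytest.fixture(scope="session")
def campaign():
    """Default noisy 59-sample campaign."""
    return generate_dataset(SyntheticParams(seed=CAMPAIGN_SEED))


@pytest.fixture(scope="session")
def campaign_noisefree():
    """Same campaign without sensor noise (composition variability kept)."""
    return generate_dataset(noise_free(SyntheticParams(seed=CAMPAIGN_SEED)))


@pytest.fixture(scope="session")
def campaign_deterministic():
    """Fully deterministic campaign: spectra are exact functions of Chl-a."""
    return generate_dataset(deterministic(SyntheticParams(seed=CAMPAIGN_SEED)))


@pytest.fixture(scope="session")
def rl_analysis(campaign):
    return preprocess_rl(campaign.spectra)


@pytest.fixture(scope="session")
def rl_noisefree(campaign_noisefree):
    return preprocess_rl(campaign_noisefree.spectra)


@pytest.fixture(scope="session")
def coarse_params():
    """Reduced 5-nm grid campaign parameters for fast pipeline tests."""
    return SyntheticParams(seed=CAMPAIGN_SEED, grid=(400.0, 900.0, 5.0))
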