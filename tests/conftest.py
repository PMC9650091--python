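import numpy as np
import pytest

from vesifret import synthetic_data as sd


@pytest.fixture(scope="session")
def biexp_decay():
    """Poisson-noise biexponential decay at 1e4 peak counts with its IRF."""
    decay, irf, truth = sd.generate_decay(
        components=((0.6, 0.5), (0.4, 2.0)), irf_fwhm_ns=0.2,
        rep_period_ns=12.5, peak_counts=1e4, seed=42,
    )
    return decay, irf, truth


@pytest.fixture(scope="session")
def small_movie():
    """Small dispersed-E movie reused by imaging tests (session-cached)."""
    movie, truth = sd.generate_movie(
        n_frames=60, field_um=(15.0, 30.0), E_spec=("normal", 0.45, 0.05),
        seed=7,
    )
    return movie, truth


def gaussian_area(amplitude: float, sigma: float) -> float:
    """Analytic area of amplitude * exp(-x^2 / (2 sigma^2))."""
    return amplitude * sigma * np.sqrt(2 * np.pi)
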