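"""Shared fixtures: small synthetic cohorts and spectra builders."""

import numpy as np
import pytest

from seraman.io import PointSpectrum, SampleSpectra
from seraman.simulate import generate_cohort, preset_null


@pytest.fixture
def axis():
    return np.arange(600.0, 1801.0, 1.0)


@pytest.fixture
def gaussian_spectrum(axis):
    """Factory: baseline + one Gaussian peak + optional noise."""

    def _make(center=1000.0, amplitude=1.0, fwhm=8.0, baseline=0.0,
              noise=0.0, seed=0, sample_id="s", point_index=0):
        rng = np.random.default_rng(seed)
        y = np.full_like(axis, float(baseline))
        y = y + amplitude * np.exp(-4 * np.log(2) * ((axis - center) / fwhm) ** 2)
        if noise:
            y = y + rng.normal(0, noise, axis.size)
        return PointSpectrum(sample_id, point_index, axis.copy(), y)

    return _make


@pytest.fixture(scope="session")
def small_cohort():
    """Two-group null cohort, 3+3 samples x 6 points, default conditions."""
    config = preset_null(seed=101, n_each=3, n_points=6)
    samples, metadata, proteins, truth = generate_cohort(config)
    return config, samples, metadata, truth


def make_sample(axis, stack, sample_id="s"):
    """SampleSpectra from a (points x channels) intensity stack."""
    points = [
        PointSpectrum(sample_id, i, axis.copy(), row.copy())
        for i, row in enumerate(stack)
    ]
    return SampleSpectra(sample_id, points, common_axis=axis)
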