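import numpy as np
import pytest

from lsdl_spectra.spectra_io import SpectraDataset, Spectrum


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    """Short descending axis for fast unit tests."""
    return np.arange(1800.0, 900.0, -8.0)  # 113 points


@pytest.fixture
def make_spectrum(small_grid):
    def _make(intensities=None, sample_id="s0", label=None, **kw):
        if intensities is None:
            intensities = np.linspace(1.0, 0.1, len(small_grid))
        return Spectrum(sample_id, small_grid, np.asarray(intensities, float),
                        label=label, **kw)

    return _make


@pytest.fixture
def labeled_dataset(small_grid, rng):
    """Tiny two-class dataset with an obvious amplitude difference."""
    spectra = []
    for i in range(6):
        base = 0.5 + 0.05 * rng.standard_normal(len(small_grid))
        bump = 1.5 * np.exp(-0.5 * ((small_grid - 1400) / 60) ** 2)
        label = "cancer" if i % 2 else "noncancer"
        y = base + (bump * (1.6 if label == "cancer" else 1.0))
        spectra.append(Spectrum(f"s{i}", small_grid, np.clip(y, 0, None), label=label))
    return SpectraDataset(spectra, name="tiny")
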