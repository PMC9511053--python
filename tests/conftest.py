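import numpy as np
import pytest

import nephroflow as nf
from nephroflow import synthdata as sd


def seeds_from_phantom(phantom, every: int = 10, jitter_um: float = 0.0, rng=None):
    """Seed clicks taken from the true centreline (optionally jittered)."""
    pts = phantom.centerline_um[::every]
    if not np.array_equal(pts[-1], phantom.centerline_um[-1]):
        pts = np.vstack([pts, phantom.centerline_um[-1]])
    if jitter_um > 0:
        rng = rng or np.random.default_rng(0)
        pts = pts + rng.normal(0, jitter_um, size=pts.shape)
    return nf.SeedAnnotation(points_px=pts / phantom.pixel_size_um - 0.5)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free straight tubule: r=10 µm, L=80 µm, snGFR=4 nl/min."""
    return sd.straight_nephron(length_um=80, radius_um=10, sngfr_nl_min=4.0,
                               noise_model=None)


@pytest.fixture(scope="session")
def clean_series(clean_phantom):
    series, truth = sd.generate_filling_series(clean_phantom)
    return series, truth


@pytest.fixture(scope="session")
def clean_path(clean_phantom, clean_series):
    series, _ = clean_series
    return nf.trace_tubule(series, seeds_from_phantom(clean_phantom))
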