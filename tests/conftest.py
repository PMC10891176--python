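"""Shared fixtures and independent oracles for the test suite."""

import math

import numpy as np
import pytest

from mottle.calibration import CalibratedImage, ROIMask


def brute_force_band_energies(patch: np.ndarray) -> np.ndarray:
    """Independent granularity oracle: explicit loop over DFT frequencies.

    Sums |DFT|^2 / N^2 over wavelength annuli lambda = 1/|f| in
    [i, i+1) px for i = 1..100, with plain Python loops and scalar
    arithmetic so it shares no binning code with the implementation.
    """
    h, w = patch.shape
    x = patch - patch.mean()
    F = np.fft.fft2(x)
    energies = [0.0] * 100
    norm = (h * w) ** 2
    for ky in range(h):
        fy = ky / h if ky <= h // 2 else (ky - h) / h
        for kx in range(w):
            fx = kx / w if kx <= w // 2 else (kx - w) / w
            f = math.hypot(fy, fx)
            if f == 0.0:
                continue
            lam = 1.0 / f
            if 1.0 <= lam < 101.0:
                energies[int(math.floor(lam)) - 1] += abs(F[ky, kx]) ** 2 / norm
    return np.array(energies)


def full_frame_image(lum: np.ndarray, px_per_mm: float = 10.0):
    """Wrap a 2-D luminance patch as a grey CalibratedImage + full mask."""
    img = CalibratedImage(np.stack([lum] * 3, axis=-1), px_per_mm)
    roi = ROIMask(np.ones(lum.shape, bool), wing="forewing")
    return img, roi


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def bruteforce_spectrum():
    return brute_force_band_energies
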