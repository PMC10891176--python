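"""HSV colour summaries of calibrated wing regions.

Calibrated reflectance triplets are converted to the standard hexcone
HSV space (hue in degrees, saturation and brightness in [0, 1]) and
summarised over a wing ROI.  HSV operates on human-visible RGB only —
no receptor-noise or cone-catch modelling is attempted.

Hue is an angle, so averaging it is subtle.  The default ``linear``
mode averages raw degree values, reproducing what a downstream
coefficient of variation on plain numeric hue columns would see; the
``circular`` mode computes the proper circular mean and resultant
length.  When hues straddle the 0/360 seam a warning is emitted,
because linear statistics are then ill-defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .calibration import CalibratedImage, ROIMask


class HueSeamWarning(UserWarning):
    """Hue values straddle the 0/360 wrap-around; linear stats are suspect."""


@dataclass
class ColourSummary:
    hue_mean: float          # degrees, [0, 360)
    sat_mean: float          # [0, 1]
    bright_mean: float       # [0, 1]
    hue_mode: str            # "linear" | "circular"
    hue_resultant: float | None = None  # circular mode only
    n_pixels: int = 0
    seam_straddle: bool = False


def _hexcone_hsv(rgb: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised hexcone RGB -> (hue deg, sat, value) on [0, 1] input."""
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    v = np.maximum(np.maximum(r, g), b)
    minc = np.minimum(np.minimum(r, g), b)
    delta = v - minc
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(v > 0, delta / v, 0.0)
        safe = np.where(delta > 0, delta, 1.0)
        h = np.where(
            delta == 0,
            0.0,
            np.where(
                v == r,
                (g - b) / safe,
                np.where(v == g, 2.0 + (b - r) / safe, 4.0 + (r - g) / safe),
            ),
        )
    h = (h * 60.0) % 360.0
    return h, s, v


def rgb_to_hsv(r, g, b):
    """Convert reflectance triplet(s) to (hue deg, saturation, value).

    Channels are clamped to [0, 1] for the conversion (specular pixels
    above 1 saturate brightness).  Achromatic pixels get hue 0 by
    convention.  Accepts scalars or broadcastable arrays.
    """
    rgb = np.stack(np.broadcast_arrays(
        np.asarray(r, float), np.asarray(g, float), np.asarray(b, float)
    ), axis=-1)
    if not np.isfinite(rgb).all():
        raise ValueError("RGB channels must be finite")
    if (rgb < 0).any():
        raise ValueError("RGB channels must be non-negative")
    rgb = np.clip(rgb, 0.0, 1.0)
    scalar = rgb.ndim == 1
    h, s, v = _hexcone_hsv(rgb)
    if scalar:
        return float(h), float(s), float(v)
    return h, s, v


def circular_mean_deg(angles_deg: np.ndarray) -> tuple[float, float]:
    """Circular mean (degrees in [0, 360)) and resultant length of angles."""
    rad = np.deg2rad(np.asarray(angles_deg, float))
    z = np.exp(1j * rad).mean()
    mean = float(np.rad2deg(np.angle(z))) % 360.0
    return mean, float(np.abs(z))


def hues_straddle_seam(hues_deg: np.ndarray, margin: float = 45.0) -> bool:
    """True when hues occupy both sides of the 0/360 wrap-around.

    Heuristic: values present both within ``margin`` below 360 and within
    ``margin`` above 0, with nothing forcing them to be one cluster.
    """
    h = np.asarray(hues_deg, float)
    near_low = (h < margin).any()
    near_high = (h > 360.0 - margin).any()
    return bool(near_low and near_high)


def summarize_colour(
    img: CalibratedImage,
    roi: ROIMask,
    hue_mode: str = "linear",
    include_achromatic_hue: bool = True,
) -> ColourSummary:
    """Mean hue, saturation and brightness over the masked wing pixels.

    Saturation and brightness are arithmetic means.  Hue is the
    arithmetic mean of degree values in ``linear`` mode (default) or the
    circular mean in ``circular`` mode; the mode used is recorded in the
    output.  Achromatic pixels (saturation 0, hue 0 by convention) are
    included in the hue mean unless ``include_achromatic_hue=False``.
    """
    if hue_mode not in ("linear", "circular"):
        raise ValueError("hue_mode must be 'linear' or 'circular'")
    mask = roi.mask
    if img.pixels.shape[:2] != mask.shape:
        raise ValueError("ROI mask shape does not match image")
    if not mask.any():
        raise ValueError("ROI mask is empty")
    pix = img.pixels[mask]
    h, s, v = rgb_to_hsv(pix[:, 0], pix[:, 1], pix[:, 2])

    hue_pool = h if include_achromatic_hue else h[s > 0]
    if hue_pool.size == 0:
        hue_pool = h  # fully achromatic ROI: fall back to the 0-convention

    straddle = hues_straddle_seam(hue_pool)
    if straddle and hue_mode == "linear":
        warnings.warn(
            "hue values straddle the 0/360 seam; the linear hue mean (and any "
            "cv built on it) is sensitive to the wrap-around — consider "
            "hue_mode='circular'",
            HueSeamWarning,
            stacklevel=2,
        )

    resultant = None
    if hue_mode == "circular":
        hue_mean, resultant = circular_mean_deg(hue_pool)
    else:
        hue_mean = float(hue_pool.mean())

    return ColourSummary(
        hue_mean=hue_mean,
        sat_mean=float(s.mean()),
        bright_mean=float(v.mean()),
        hue_mode=hue_mode,
        hue_resultant=resultant,
        n_pixels=int(mask.sum()),
        seam_straddle=straddle,
    )
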