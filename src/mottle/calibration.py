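"""Grey-standard calibration, spatial standardisation and ROI handling.

Museum specimens are photographed against a 'middle grey' card of known
reflectance (~40%).  Dividing each channel by the grey-region mean and
multiplying by the nominal reflectance converts camera counts to
approximate linear reflectance, controlling for unknown exposure and
white balance.  Values above 1 (specular highlights) are deliberately
kept: clipping would bias downstream band energies.  No gamma
linearisation is applied — channels are treated as linear camera
responses throughout, and no vision model is used.

Coordinate convention: row-major arrays, origin top-left, 0-based
indices; masks are congruent with images by shape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

logger = logging.getLogger(__name__)

#: Standard working resolution (pixels per millimetre) of the pipeline.
STANDARD_PX_PER_MM = 10.0

#: Nominal reflectance of the middle-grey photographic standard.
GREY_REFLECTANCE = 0.40

#: Minimum ROI size in true pixels (~2x2 mm at the standard resolution).
MIN_ROI_PIXELS = 400


class CalibrationError(ValueError):
    """Raised when an image cannot be calibrated (e.g. black grey region)."""


@dataclass
class RawImage:
    """An uncalibrated RGB image with known spatial scale.

    ``pixels`` is an (H, W, 3) array.  Integer dtypes are interpreted as
    8- or 16-bit camera counts; float arrays are taken as already being
    on a linear [0, 1]-ish scale.
    """

    pixels: np.ndarray
    px_per_mm: float
    min_side_px: int = 100  # relaxed synthetic floor; museum images need >=1000

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an (H, W, 3) RGB array")
        h, w = self.pixels.shape[:2]
        if min(h, w) < self.min_side_px:
            raise ValueError(
                f"image is {w}x{h} px; both sides must be >= {self.min_side_px} px"
            )
        if not (self.px_per_mm and self.px_per_mm > 0):
            raise ValueError("px_per_mm must be a positive scalar")


@dataclass
class GreyStandard:
    """Location of the grey card in an image plus its nominal reflectance.

    ``region`` is either a boolean mask congruent with the image or a
    rectangle ``(row0, row1, col0, col1)`` in half-open index convention.
    """

    region: object
    nominal_reflectance: float = GREY_REFLECTANCE

    def __post_init__(self) -> None:
        if not 0 < self.nominal_reflectance < 1:
            raise ValueError("nominal_reflectance must lie in (0, 1)")

    def mask_for(self, shape: tuple[int, int]) -> np.ndarray:
        region = self.region
        if isinstance(region, np.ndarray) and region.dtype == bool:
            if region.shape != shape:
                raise ValueError("grey mask shape does not match image")
            mask = region
        else:
            r0, r1, c0, c1 = (int(v) for v in region)
            mask = np.zeros(shape, dtype=bool)
            mask[r0:r1, c0:c1] = True
        if not mask.any():
            raise ValueError("grey-standard region is empty")
        return mask


@dataclass
class CalibratedImage:
    """Per-pixel reflectance triplets with a pixel-per-mm scale.

    Reflectance is relative to the grey standard; specular pixels may
    exceed 1 and are retained.
    """

    pixels: np.ndarray
    px_per_mm: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an (H, W, 3) reflectance array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class ROIMask:
    """Boolean wing mask congruent with its image."""

    mask: np.ndarray
    wing: str = "forewing"
    min_pixels: int = MIN_ROI_PIXELS

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.wing not in ("forewing", "hindwing"):
            raise ValueError("wing must be 'forewing' or 'hindwing'")
        n = int(self.mask.sum())
        if n < self.min_pixels:
            raise ValueError(
                f"ROI has {n} pixels; at least {self.min_pixels} required"
            )

    def area_mm2(self, px_per_mm: float) -> float:
        return float(self.mask.sum()) / px_per_mm**2


@dataclass
class RoiPatch:
    """Bounding-box crop of a masked region plus the fill statistics."""

    crop: np.ndarray
    mask: np.ndarray
    bbox: tuple[int, int, int, int]  # (row0, row1, col0, col1), half-open
    fill_value: float


def _to_unit_scale(pixels: np.ndarray) -> np.ndarray:
    """Map integer camera counts onto [0, 1]; pass floats through."""
    if pixels.dtype == np.uint8:
        return pixels.astype(float) / 255.0
    if pixels.dtype == np.uint16:
        return pixels.astype(float) / 65535.0
    if np.issubdtype(pixels.dtype, np.integer):
        return pixels.astype(float) / float(np.iinfo(pixels.dtype).max)
    return pixels.astype(float)


def normalize_to_grey(
    raw: RawImage | CalibratedImage,
    grey: GreyStandard,
    per_channel: bool = True,
) -> CalibratedImage:
    """Scale each channel so the grey region means the nominal reflectance.

    Per-channel gains (``per_channel=True``, the default) implement white
    balancing; ``per_channel=False`` applies a single luminance gain,
    preserving the raw colour balance.

    Idempotent: calibrating an already-calibrated image with the same
    grey region leaves it unchanged to within 1e-6.
    """
    pixels = _to_unit_scale(np.asarray(raw.pixels))
    mask = grey.mask_for(pixels.shape[:2])
    channel_means = pixels[mask].mean(axis=0)

    floor = 1.0 / 65535.0
    for name, mean in zip("RGB", channel_means):
        if mean < floor:
            raise CalibrationError(
                f"grey-standard mean in channel {name} is {mean:.3g} "
                f"(< {floor:.3g}); cannot derive a gain"
            )
    if per_channel:
        gains = grey.nominal_reflectance / channel_means
    else:
        gains = np.full(3, grey.nominal_reflectance / channel_means.mean())

    calibrated = pixels * gains
    prov = {
        "gains": tuple(float(g) for g in gains),
        "grey_channel_means": tuple(float(m) for m in channel_means),
        "nominal_reflectance": grey.nominal_reflectance,
        "per_channel": per_channel,
    }
    logger.debug("grey calibration gains: %s", prov["gains"])
    return CalibratedImage(calibrated, raw.px_per_mm, provenance=prov)


def rescale_to_standard_resolution(
    img: CalibratedImage,
    target_px_per_mm: float = STANDARD_PX_PER_MM,
    masks: list[ROIMask] | None = None,
) -> CalibratedImage | tuple[CalibratedImage, list[ROIMask]]:
    """Bilinearly resample an image to exactly ``target_px_per_mm``.

    Masks, if given, are resampled with nearest-neighbour interpolation
    so they remain boolean.  An image already at the target scale is
    returned unchanged.
    """
    if not (img.px_per_mm and img.px_per_mm > 0):
        raise ValueError("px_per_mm metadata missing; refusing a silent default")
    ratio = target_px_per_mm / img.px_per_mm
    if ratio == 1.0:
        return (img, masks) if masks is not None else img
    h, w = img.shape
    out_shape = (max(1, round(h * ratio)), max(1, round(w * ratio)))
    resampled = resize(
        img.pixels, out_shape + (3,), order=1, preserve_range=True,
        anti_aliasing=False,
    )
    out = CalibratedImage(resampled, target_px_per_mm, provenance=dict(img.provenance))
    out.provenance["rescaled_from_px_per_mm"] = img.px_per_mm
    if masks is None:
        return out
    out_masks = [
        ROIMask(
            resize(m.mask.astype(float), out_shape, order=0, preserve_range=True) > 0.5,
            wing=m.wing,
            min_pixels=m.min_pixels,
        )
        for m in masks
    ]
    return out, out_masks


def extract_roi(img: CalibratedImage | np.ndarray, roi: ROIMask) -> RoiPatch:
    """Crop the mask's bounding box and record the mask-interior mean.

    The interior mean luminance is used downstream as the fill value for
    outside-mask pixels before spectral analysis.  For a mask with
    disjoint components the bounding box spans all of them.
    """
    pixels = img.pixels if isinstance(img, CalibratedImage) else np.asarray(img)
    mask = roi.mask
    if pixels.shape[:2] != mask.shape:
        raise ValueError("ROI mask shape does not match image")
    if not mask.any():
        raise ValueError("ROI mask is empty")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, r1 = int(rows[0]), int(rows[-1]) + 1
    c0, c1 = int(cols[0]), int(cols[-1]) + 1
    crop = pixels[r0:r1, c0:c1]
    mask_crop = mask[r0:r1, c0:c1]
    if crop.ndim == 3:
        lum = crop.mean(axis=2)
    else:
        lum = crop
    fill = float(lum[mask_crop].mean())
    return RoiPatch(crop=crop, mask=mask_crop, bbox=(r0, r1, c0, c1), fill_value=fill)
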