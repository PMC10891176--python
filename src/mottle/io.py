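"""Disk formats: specimen manifests, images, masks, trees, factor tables.

A dataset on disk is a directory with a ``specimens.csv`` manifest
(one row per specimen x wing: specimen_id, species, wing, image_path,
mask_path, px_per_mm and the grey-standard rectangle), the image and
mask files it points to, a Newick ``tree.nwk`` and a ``factors.csv``
(species, strategy, activity, diet).  Synthetic datasets are written in
exactly this layout — 16-bit TIFF images carrying an embedded grey patch
and a per-image exposure factor, so the grey-standard calibration path
is exercised end to end — and real data can be supplied the same way
(PNG/TIFF/JPG are all readable).

Masks are 8-bit PNGs (non-zero = wing) or JSON polygon sidecars of the
form ``{"wing": "forewing", "polygon": [[x, y], ...]}``.
"""

from __future__ import annotations

import json
import zlib
from pathlib import Path
from typing import Iterator

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .calibration import (
    CalibratedImage,
    GreyStandard,
    RawImage,
    ROIMask,
    normalize_to_grey,
    rescale_to_standard_resolution,
)
from .phylo import GroupFactor, read_newick
from .synth import SyntheticDataset

GREY_RECT = (2, 14, 2, 14)  # (row0, row1, col0, col1) of the embedded grey patch
GREY_COLS = ["grey_row0", "grey_row1", "grey_col0", "grey_col1"]


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> Path:
    """Write a synthetic dataset in the on-disk manifest layout.

    Each reflectance image is multiplied by a per-image exposure factor
    (deterministic in the specimen id), given a middle-grey patch of
    reflectance 0.40 in its top-left corner, and stored as 16-bit TIFF;
    re-loading through the grey calibration recovers reflectance up to
    quantisation.  Returns the manifest path.
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    r0, r1, c0, c1 = GREY_RECT
    for img, roi, record in dataset.images:
        stem = f"{record['specimen_id']}_{record['wing']}"
        exposure_rng = np.random.default_rng(zlib.crc32(stem.encode()))
        g = 0.4 + 0.3 * exposure_rng.random()
        pixels = img.pixels.copy()
        pixels[r0:r1, c0:c1, :] = 0.40
        raw = np.clip(pixels * g, 0.0, 1.0)
        raw16 = np.round(raw * 65535.0).astype(np.uint16)
        image_path = out / "images" / f"{stem}.tiff"
        mask_path = out / "masks" / f"{stem}.png"
        iio.imwrite(image_path, raw16)
        iio.imwrite(mask_path, (roi.mask * 255).astype(np.uint8))
        rows.append(
            {
                "specimen_id": record["specimen_id"],
                "species": record["species"],
                "wing": record["wing"],
                "image_path": str(image_path.relative_to(out)),
                "mask_path": str(mask_path.relative_to(out)),
                "px_per_mm": record["px_per_mm"],
                **dict(zip(GREY_COLS, GREY_RECT)),
            }
        )
    manifest = out / "specimens.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    (out / "tree.nwk").write_text(dataset.tree.newick() + "\n")
    factors_df = pd.DataFrame(
        {"species": dataset.species}
        | {
            name: [f.mapping.get(sp) for sp in dataset.species]
            for name, f in dataset.factors.items()
        }
    )
    factors_df.to_csv(out / "factors.csv", index=False)
    dataset.generator_truth.to_csv(out / "truth.csv", index=False)
    return manifest


def read_mask(path: Path, shape: tuple[int, int], wing: str) -> ROIMask:
    """Read an ROI mask from a PNG or a JSON polygon sidecar."""
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        from skimage.draw import polygon as draw_polygon

        poly = np.asarray(payload["polygon"], float)
        rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=shape)
        mask = np.zeros(shape, dtype=bool)
        mask[rr, cc] = True
        return ROIMask(mask, wing=payload.get("wing", wing))
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return ROIMask(arr > 0, wing=wing)


def iter_manifest(
    manifest_path: str | Path,
    target_px_per_mm: float = 10.0,
    min_side_px: int = 100,
) -> Iterator[tuple[CalibratedImage, ROIMask, dict]]:
    """Load, calibrate and rescale every specimen listed in a manifest.

    Yields ``(calibrated_image, roi_mask, record)`` with the image at
    the standard resolution.  A missing or zero ``px_per_mm`` is an
    error — no silent default scale is assumed.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    table = pd.read_csv(manifest_path)
    required = {"specimen_id", "species", "wing", "image_path", "mask_path", "px_per_mm"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"manifest lacks columns: {sorted(missing)}")
    for _, row in table.iterrows():
        if not (pd.notna(row["px_per_mm"]) and row["px_per_mm"] > 0):
            raise ValueError(
                f"specimen {row['specimen_id']}: px_per_mm missing or non-positive"
            )
        arr = iio.imread(base / row["image_path"])
        if arr.ndim == 2:
            arr = np.stack([arr] * 3, axis=-1)
        raw = RawImage(arr[..., :3], float(row["px_per_mm"]), min_side_px=min_side_px)
        if all(c in table.columns for c in GREY_COLS):
            rect = tuple(int(row[c]) for c in GREY_COLS)
        else:
            rect = GREY_RECT
        calibrated = normalize_to_grey(raw, GreyStandard(rect))
        roi = read_mask(base / row["mask_path"], arr.shape[:2], str(row["wing"]))
        calibrated, (roi,) = rescale_to_standard_resolution(
            calibrated, target_px_per_mm, masks=[roi]
        )
        record = {
            "specimen_id": row["specimen_id"],
            "species": row["species"],
            "wing": row["wing"],
            "px_per_mm": target_px_per_mm,
        }
        yield calibrated, roi, record


def read_factors(path: str | Path) -> dict[str, GroupFactor]:
    """Read the species-level factor table (species, strategy, activity, diet)."""
    df = pd.read_csv(path)
    if "species" not in df.columns:
        raise ValueError("factor table needs a 'species' column")
    factors = {}
    for col in df.columns:
        if col == "species":
            continue
        mapping = {
            str(sp): str(lvl)
            for sp, lvl in zip(df["species"], df[col])
            if pd.notna(lvl)
        }
        factors[col] = GroupFactor(col, mapping)
    return factors


def read_tree(path: str | Path):
    return read_newick(Path(path).read_text())
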