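"""Synthetic wing images, trees and traits with known generative truth.

Museum imagery is replaced, for testing, by a generator whose knobs map
directly onto what the analysis measures: a Gaussian random field gives
each wing a textured pattern with a controlled dominant marking scale
(mm) and contrast amplitude, superimposed on a base HSV colour; within
a species, scale and amplitude are drawn per specimen from log-normal
distributions whose coefficient of variation is set explicitly, so the
downstream mean/cv trait table has a known target.  Ultrametric trees
come from a pure-birth process rescaled to depth 1, and Brownian-motion
traits can be simulated on them for null-distribution work.

Everything is a pure function of its seed tuple: one global seed is
expanded into per-object seeds through :func:`numpy.random.SeedSequence`
with a fixed counter scheme, so any single image can be regenerated
without replaying the whole dataset.

Marking-scale calibration.  White noise smoothed with an isotropic
Gaussian kernel of spatial s.d. sigma has power spectrum proportional
to exp(-4 pi^2 sigma^2 f^2); binned over wavelength annuli
(lambda = 1/f, band width d lambda) the energy density is proportional
to lambda^-3 exp(-4 pi^2 sigma^2 / lambda^2), which peaks at
lambda = pi * sqrt(8/3) * sigma ~= 5.13 sigma.  The kernel is therefore
sized sigma = scale / (pi sqrt(8/3)) so the granularity spectrum of the
generated texture peaks at the requested marking scale.
"""

from __future__ import annotations

import random
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.color import hsv2rgb

from .calibration import CalibratedImage, ROIMask, STANDARD_PX_PER_MM
from .phylo import GroupFactor, Phylogeny, simulate_bm_tips

#: Wavelength of the spectral peak of Gaussian-smoothed white noise,
#: in units of the kernel s.d. (see module docstring for the derivation).
GRF_PEAK_FACTOR = float(np.pi * np.sqrt(8.0 / 3.0))

#: Representable marking-scale band range of the analysis, mm.
SCALE_BAND_RANGE = (0.1, 10.0)

STRATEGY_LEVELS = ("aposematic", "camouflaged")
ACTIVITY_LEVELS = ("cathemeral", "diurnal", "nocturnal")
DIET_LEVELS = ("monophagous", "mycophagous", "oligophagous", "polyphagous")


def _species_entropy(species_id: str) -> int:
    return zlib.crc32(species_id.encode("utf-8"))


def _lognormal_sigma(cv: float) -> float:
    """Log-scale s.d. giving a log-normal the requested cv."""
    return float(np.sqrt(np.log1p(cv**2)))


@dataclass
class SpeciesGeneratorSpec:
    """Generative parameters of one synthetic species."""

    species_id: str
    group_labels: dict[str, str] = field(default_factory=dict)
    mean_marking_scale: float = 1.5   # mm, median of the per-specimen log-normal
    cv_marking_scale: float = 0.2
    mean_contrast_amp: float = 0.15   # reflectance s.d. of the texture
    cv_contrast_amp: float = 0.15
    base_hsv: tuple[float, float, float] = (40.0, 0.35, 0.45)
    hsv_sd: tuple[float, float, float] = (5.0, 0.05, 0.05)
    n_specimens: int = 30
    image_size_mm: tuple[float, float] = (30.0, 20.0)  # width, height

    def __post_init__(self) -> None:
        lo, hi = SCALE_BAND_RANGE
        if not lo <= self.mean_marking_scale <= hi:
            raise ValueError(
                f"mean_marking_scale {self.mean_marking_scale} mm outside the "
                f"representable band range [{lo}, {hi}] mm"
            )
        if self.cv_marking_scale < 0 or self.cv_contrast_amp < 0:
            raise ValueError("coefficients of variation must be >= 0")
        if not 0 <= self.mean_contrast_amp <= 0.5:
            raise ValueError("mean_contrast_amp must lie in [0, 0.5]")
        h, s, v = self.base_hsv
        if not (0 <= h < 360 and 0 <= s <= 1 and 0 < v <= 1):
            raise ValueError("base_hsv must satisfy h in [0,360), s in [0,1], v in (0,1]")
        if self.n_specimens < 2:
            raise ValueError("n_specimens must be >= 2 so a cv is defined")


def generate_wing_image(
    spec: SpeciesGeneratorSpec,
    specimen_index: int,
    seed: int,
    wing: str = "forewing",
    px_per_mm: float = STANDARD_PX_PER_MM,
) -> tuple[CalibratedImage, ROIMask]:
    """One synthetic calibrated wing image plus its elliptical ROI.

    Deterministic in ``(spec, specimen_index, seed, wing)``.  The
    luminance texture is a Gaussian random field whose correlation
    length is drawn per specimen from a log-normal with median
    ``mean_marking_scale`` and cv ``cv_marking_scale``; its amplitude
    (s.d. in reflectance units) is drawn analogously from
    ``mean_contrast_amp``.  The base colour is drawn from ``base_hsv``
    with ``hsv_sd`` noise.  The ROI is an ellipse covering >= 60% of
    the frame.
    """
    wing_code = {"forewing": 0, "hindwing": 1}[wing]
    rng = np.random.default_rng(
        np.random.SeedSequence(
            [seed % 2**31, _species_entropy(spec.species_id), specimen_index, wing_code]
        )
    )
    w_mm, h_mm = spec.image_size_mm
    W, H = round(w_mm * px_per_mm), round(h_mm * px_per_mm)

    scale = spec.mean_marking_scale * np.exp(
        _lognormal_sigma(spec.cv_marking_scale) * rng.standard_normal()
    )
    scale = float(np.clip(scale, *SCALE_BAND_RANGE))
    amp = spec.mean_contrast_amp * np.exp(
        _lognormal_sigma(spec.cv_contrast_amp) * rng.standard_normal()
    )

    h0, s0, v0 = spec.base_hsv
    hue = (h0 + spec.hsv_sd[0] * rng.standard_normal()) % 360.0
    sat = float(np.clip(s0 + spec.hsv_sd[1] * rng.standard_normal(), 0.0, 1.0))
    val = float(np.clip(v0 + spec.hsv_sd[2] * rng.standard_normal(), 0.05, 1.0))
    base_rgb = hsv2rgb(np.array([[[hue / 360.0, sat, val]]]))[0, 0]

    if spec.mean_contrast_amp > 0 and amp > 0:
        sigma_px = scale * px_per_mm / GRF_PEAK_FACTOR
        field_ = gaussian_filter(rng.standard_normal((H, W)), sigma_px, mode="wrap")
        sd = field_.std()
        texture = (amp * field_ / sd)[:, :, None] if sd > 0 else 0.0
        pixels = np.clip(base_rgb + texture, 0.0, None)
    else:
        pixels = np.broadcast_to(base_rgb, (H, W, 3)).astype(float).copy()

    yy, xx = np.ogrid[0:H, 0:W]
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    ry, rx = 0.45 * H, 0.47 * W
    ellipse = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0

    img = CalibratedImage(pixels, px_per_mm)
    img.provenance.update(
        {"synthetic": True, "species": spec.species_id, "specimen_index": specimen_index,
         "drawn_scale_mm": scale, "drawn_amp": float(amp)}
    )
    return img, ROIMask(ellipse, wing=wing)


def generate_phylogeny(n_tips: int, seed: int) -> Phylogeny:
    """Pure-birth tree rescaled so every root-to-tip path equals 1.0.

    Tips are labelled ``species_1`` .. ``species_n`` and the same seed
    always yields the identical Newick string.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    from dendropy.simulate import treesim

    rng = random.Random(int(seed) % 2**31)
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=rng,
    )
    # the process stops exactly at the n-th birth, leaving a zero-length
    # cherry; let the clock run on for a partial waiting time so every
    # terminal branch is positive (tree stays ultrametric: same increment
    # on every leaf edge)
    extra = rng.expovariate(n_tips * 1.0)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    depth = max(leaf.root_distance for leaf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / depth
    # float rescaling leaves ~1e-16 spread; pin each tip to exactly depth 1
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length += 1.0 - leaf.root_distance
    # deterministic tip labelling in leaf-iteration order
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"species_{i + 1}"
    return Phylogeny(tree)


def simulate_bm_traits(
    tree: Phylogeny, sigma2: float, seed: int
) -> dict[str, float]:
    """One Brownian-motion draw on the tree: tip -> trait value.

    Tips are jointly multivariate normal with mean 0 and covariance
    ``sigma2`` times the shared-path-length matrix.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    tree.require_ultrametric()
    labels, C = tree.vcv()
    draw = simulate_bm_tips(C, sigma2, 1, np.random.default_rng(seed))[0]
    return dict(zip(labels, draw.tolist()))


# ---------------------------------------------------------------------------
# Whole-dataset assembly

@dataclass
class SyntheticDataset:
    """Images, tree, factors and the generative truth, kept together."""

    images: list[tuple[CalibratedImage, ROIMask, dict]]
    tree: Phylogeny
    factors: dict[str, GroupFactor]
    generator_truth: pd.DataFrame

    @property
    def species(self) -> list[str]:
        return list(self.generator_truth["species"])


def generate_dataset(
    specs: list[SpeciesGeneratorSpec],
    seed: int,
    wings: tuple[str, ...] = ("forewing", "hindwing"),
) -> SyntheticDataset:
    """Generate all specimen images for a species list plus tree and factors.

    Every species appears exactly once as a tree tip; the generative
    parameters are retained verbatim in ``generator_truth``.
    """
    if len({s.species_id for s in specs}) != len(specs):
        raise ValueError("species_id values must be unique")
    images = []
    for spec in specs:
        for i in range(spec.n_specimens):
            for wing in wings:
                img, roi = generate_wing_image(spec, i, seed, wing=wing)
                record = {
                    "specimen_id": f"{spec.species_id}_{i:03d}",
                    "species": spec.species_id,
                    "wing": wing,
                    "px_per_mm": img.px_per_mm,
                }
                images.append((img, roi, record))

    tree = generate_phylogeny(len(specs), seed)
    # the tree is generated independently of the factors: place species on
    # tips in seeded random order so groups are not confounded with clades
    perm = np.random.default_rng(
        np.random.SeedSequence([seed % 2**31, 0x7EE])
    ).permutation(len(specs))
    for leaf, j in zip(tree.tree.leaf_node_iter(), perm):
        leaf.taxon.label = specs[j].species_id
    tree = Phylogeny(tree.tree)

    hypotheses = sorted({h for s in specs for h in s.group_labels})
    factors = {
        h: GroupFactor(h, {s.species_id: s.group_labels[h]
                           for s in specs if h in s.group_labels})
        for h in hypotheses
    }
    truth = pd.DataFrame(
        [
            {
                "species": s.species_id,
                "mean_marking_scale": s.mean_marking_scale,
                "cv_marking_scale": s.cv_marking_scale,
                "mean_contrast_amp": s.mean_contrast_amp,
                "cv_contrast_amp": s.cv_contrast_amp,
                "base_h": s.base_hsv[0],
                "base_s": s.base_hsv[1],
                "base_v": s.base_hsv[2],
                "n_specimens": s.n_specimens,
                **{f"group_{k}": v for k, v in s.group_labels.items()},
            }
            for s in specs
        ]
    )
    return SyntheticDataset(images, tree, factors, truth)


def default_strategy_specs(
    n_per_group: int = 20,
    n_specimens: int = 30,
    seed: int = 0,
    cv_marking_aposematic: float = 0.10,
    cv_marking_camouflaged: float = 0.35,
) -> list[SpeciesGeneratorSpec]:
    """Study-condition generators for a two-strategy comparison.

    The two groups' generators are identical except that camouflaged-like
    species get 3.5x the within-species marking-scale dispersion of
    aposematic-like species — the single designed group difference.
    Between-species spread of every generative mean (marking scale,
    contrast amplitude, base colour, wing size) is shared by both groups,
    so any other group contrast in the output is sampling noise or an
    emergent consequence of the dispersion difference.  Base hues sit in
    the warm brown band well away from the 0/360 hue seam.  Wing size
    varies between species independently of strategy (a deliberately
    null size effect).  Diel-activity is assigned so camouflaged species
    are mostly nocturnal, mirroring the strong ecological correlation
    between crypsis and night activity; diet is cycled independently.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed % 2**31, 0xD1E7]))
    specs = []
    idx = 0
    for group, cv_mark in (
        ("aposematic", cv_marking_aposematic),
        ("camouflaged", cv_marking_camouflaged),
    ):
        for j in range(n_per_group):
            idx += 1
            # between-species spread of the generative means (cv ~0.15)
            scale = 1.5 * np.exp(_lognormal_sigma(0.15) * rng.standard_normal())
            amp = 0.15 * np.exp(_lognormal_sigma(0.15) * rng.standard_normal())
            hue = float(np.clip(45.0 + 8.0 * rng.standard_normal(), 20.0, 340.0))
            sat = float(np.clip(0.45 + 0.12 * rng.standard_normal(), 0.05, 0.95))
            val = float(np.clip(0.45 + 0.08 * rng.standard_normal(), 0.15, 0.9))
            if group == "aposematic":
                activity = ACTIVITY_LEVELS[1] if j % 4 else ACTIVITY_LEVELS[0]
            else:
                activity = ACTIVITY_LEVELS[2] if j % 4 else ACTIVITY_LEVELS[0]
            width = float(np.clip(30.0 + 3.0 * rng.standard_normal(), 24.0, 36.0))
            specs.append(
                SpeciesGeneratorSpec(
                    species_id=f"species_{idx}",
                    group_labels={
                        "strategy": group,
                        "activity": activity,
                        "diet": DIET_LEVELS[j % 4],
                    },
                    mean_marking_scale=float(np.clip(scale, 0.3, 8.0)),
                    cv_marking_scale=cv_mark,
                    mean_contrast_amp=float(np.clip(amp, 0.02, 0.5)),
                    cv_contrast_amp=0.15,
                    base_hsv=(hue, sat, val),
                    hsv_sd=(5.0, 0.12 * sat, 0.10 * val),
                    n_specimens=n_specimens,
                    image_size_mm=(width, width * 2.0 / 3.0),
                )
            )
    return specs
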