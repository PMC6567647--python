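"""Synthetic micrographs with exact ground truth.

Emulates the imaging regime the picker targets: dark, low-contrast
particles — disks for top views, axis-aligned squares for side views — on a
bright noisy background, optionally with a low-frequency illumination
gradient and irregular dark ice-like blobs. Shapes are rasterized with a
1-px anti-aliased rim, additive i.i.d. Gaussian noise is applied last, and
every scene is fully reproducible from its seed.

The generator does not model physical image formation (no CTF, detector
MTF, or 3D projection); what it exercises is intensity separability under
noise, clutter and overlap, which is the regime the intensity-clustering
pipeline operates in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

from cryopick.errors import InvalidConfigError, PlacementError
from cryopick.evaluate import GroundTruthParticle
from cryopick.io import Micrograph

_MAX_ATTEMPTS = 10_000


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic scene.

    Intensities are in [0, 1]: the background sits at ``background_level``
    and particle interiors at ``background_level - particle_contrast``.
    ``min_separation`` is the extra gap demanded between shape rims during
    placement (ignored when ``allow_overlap``). The default frame size
    matches a typical counted-mode micrograph crop (1240 x 1200 px).
    """

    height: int = 1240
    width: int = 1200
    n_circles: int = 20
    radius_range: Tuple[int, int] = (10, 14)
    n_squares: int = 0
    side_range: Tuple[int, int] = (24, 32)
    background_level: float = 0.6
    particle_contrast: float = 0.3
    noise_sigma: float = 0.1
    n_ice_blobs: int = 0
    ice_contrast: float = 0.2
    min_separation: float = 4.0
    allow_overlap: bool = False
    gradient_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.height, self.width) < 64:
            raise InvalidConfigError("scene must be at least 64 x 64")
        if not 0.0 < self.background_level < 1.0:
            raise InvalidConfigError("background_level must lie in (0, 1)")
        if self.particle_contrast <= 0:
            raise InvalidConfigError("particle_contrast must be positive")
        if self.noise_sigma < 0:
            raise InvalidConfigError("noise_sigma must be >= 0")
        for name in ("radius_range", "side_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise InvalidConfigError(f"{name} must be ordered and positive")
        if self.radius_range[1] * 2 + 2 > min(self.height, self.width):
            raise InvalidConfigError("largest circle does not fit the frame")
        if self.side_range[1] + 2 > min(self.height, self.width):
            raise InvalidConfigError("largest square does not fit the frame")


@dataclass
class SceneTruth:
    """Ground truth for one scene: particle list plus rasterized masks."""

    particles: List[GroundTruthParticle]
    particle_mask: np.ndarray
    circle_mask: np.ndarray
    square_mask: np.ndarray
    ice_mask: np.ndarray = field(default=None)  # type: ignore[assignment]


def _place_shapes(spec: SceneSpec, rng: np.random.Generator
                  ) -> List[GroundTruthParticle]:
    """Rejection-sample non-overlapping shape placements."""
    wanted: List[Tuple[str, float]] = []
    for _ in range(spec.n_circles):
        wanted.append(("circle", float(rng.integers(spec.radius_range[0],
                                                    spec.radius_range[1] + 1))))
    for _ in range(spec.n_squares):
        side = float(rng.integers(spec.side_range[0], spec.side_range[1] + 1))
        wanted.append(("square", side / 2.0))
    placed: List[GroundTruthParticle] = []
    attempts = 0
    for shape, rh in wanted:
        # effective collision radius: circumradius for squares
        eff = rh * math.sqrt(2.0) if shape == "square" else rh
        margin = rh + 2.0
        while True:
            attempts += 1
            if attempts > _MAX_ATTEMPTS:
                raise PlacementError(placed=len(placed), requested=len(wanted))
            cy = rng.uniform(margin, spec.height - margin)
            cx = rng.uniform(margin, spec.width - margin)
            if spec.allow_overlap:
                break
            ok = True
            for q in placed:
                qeff = (q.radius_or_halfside * math.sqrt(2.0)
                        if q.shape == "square" else q.radius_or_halfside)
                if math.hypot(cy - q.center[0], cx - q.center[1]) \
                        < eff + qeff + spec.min_separation:
                    ok = False
                    break
            if ok:
                break
        placed.append(GroundTruthParticle(center=(cy, cx),
                                          radius_or_halfside=rh, shape=shape))
    return placed


def _shape_alpha(spec: SceneSpec, p: GroundTruthParticle) -> Tuple[np.ndarray, tuple]:
    """Anti-aliased coverage map of one shape and its slice in the frame."""
    rh = p.radius_or_halfside
    ext = int(math.ceil(rh)) + 2
    cy, cx = p.center
    top, left = int(math.floor(cy)) - ext, int(math.floor(cx)) - ext
    bottom, right = int(math.ceil(cy)) + ext + 1, int(math.ceil(cx)) + ext + 1
    top, left = max(top, 0), max(left, 0)
    bottom, right = min(bottom, spec.height), min(right, spec.width)
    yy, xx = np.mgrid[top:bottom, left:right]
    if p.shape == "circle":
        d = np.hypot(yy - cy, xx - cx)
        alpha = np.clip(rh + 0.5 - d, 0.0, 1.0)
    else:
        d = np.maximum(np.abs(yy - cy), np.abs(xx - cx))
        alpha = np.clip(rh + 0.5 - d, 0.0, 1.0)
    return alpha, (slice(top, bottom), slice(left, right))


def _ice_blob(spec: SceneSpec, rng: np.random.Generator,
              frame: Tuple[int, int]) -> Tuple[np.ndarray, tuple]:
    """An irregular smoothed-noise blob (deliberately non-circular)."""
    h, w = frame
    extent = int(rng.integers(30, 61))
    cy = int(rng.integers(extent, max(h - extent, extent + 1)))
    cx = int(rng.integers(extent, max(w - extent, extent + 1)))
    size = 2 * extent + 1
    field_ = ndimage.gaussian_filter(rng.normal(size=(size, size)), sigma=8.0)
    yy, xx = np.mgrid[-extent:extent + 1, -extent:extent + 1]
    envelope = np.clip(1.0 - np.hypot(yy, xx) / extent, 0.0, 1.0)
    field_ = field_ * envelope
    thr = np.quantile(field_, 0.92)
    blob = (field_ > thr).astype(np.float64)
    # keep only the largest connected chunk so the blob is one region
    lab, n = ndimage.label(blob)
    if n > 1:
        sizes = ndimage.sum_labels(blob, lab, index=np.arange(1, n + 1))
        blob = (lab == (1 + int(np.argmax(sizes)))).astype(np.float64)
    alpha = ndimage.gaussian_filter(blob, sigma=1.0)
    top, left = max(cy - extent, 0), max(cx - extent, 0)
    bottom, right = min(cy + extent + 1, h), min(cx + extent + 1, w)
    a_slice = alpha[top - (cy - extent):top - (cy - extent) + (bottom - top),
                    left - (cx - extent):left - (cx - extent) + (right - left)]
    return a_slice, (slice(top, bottom), slice(left, right))


def generate_scene(spec: SceneSpec) -> Tuple[Micrograph, SceneTruth]:
    """Render one scene and its exact ground truth.

    With ``noise_sigma == 0`` and no ice, particle interiors equal
    ``background_level - particle_contrast`` exactly (rim pixels are
    partially covered). The truth masks threshold shape coverage at 0.5.
    """
    rng = np.random.default_rng(spec.seed)
    particles = _place_shapes(spec, rng)

    img = np.full((spec.height, spec.width), spec.background_level)
    if spec.gradient_amplitude:
        yy, xx = np.mgrid[0:spec.height, 0:spec.width]
        img = img + spec.gradient_amplitude * np.sin(
            2.0 * math.pi * (0.7 * yy / spec.height + 0.5 * xx / spec.width))

    coverage = np.zeros_like(img)
    circle_mask = np.zeros(img.shape, dtype=bool)
    square_mask = np.zeros(img.shape, dtype=bool)
    for p in particles:
        alpha, sl = _shape_alpha(spec, p)
        coverage[sl] = np.maximum(coverage[sl], alpha)
        target = circle_mask if p.shape == "circle" else square_mask
        target[sl] |= alpha >= 0.5
    img = img - spec.particle_contrast * coverage

    ice_mask = np.zeros(img.shape, dtype=bool)
    for _ in range(spec.n_ice_blobs):
        for _try in range(50):
            alpha, sl = _ice_blob(spec, rng, img.shape)
            # keep controlled negatives: ice must not swallow a particle
            if not (coverage[sl] * (alpha >= 0.5)).any():
                break
        img[sl] = img[sl] - spec.ice_contrast * alpha
        ice_mask[sl] |= alpha >= 0.5

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    truth = SceneTruth(particles=particles,
                       particle_mask=circle_mask | square_mask,
                       circle_mask=circle_mask,
                       square_mask=square_mask,
                       ice_mask=ice_mask)
    micro = Micrograph(pixels=img, value_range=(0.0, 1.0),
                       source_id=f"synthetic-seed{spec.seed}")
    return micro, truth


# ---------------------------------------------------------------------------
# Preset suites
# ---------------------------------------------------------------------------

_PRESETS = {
    # generous contrast, sparse, no clutter: a sanity regime
    "easy": SceneSpec(height=512, width=512, n_circles=12,
                      radius_range=(12, 16), background_level=0.6,
                      particle_contrast=0.35, noise_sigma=0.05,
                      min_separation=6.0),
    # dense top-view disks, contrast/noise ratio 2.0, mild gradient
    "apoferritin_like": SceneSpec(height=512, width=512, n_circles=30,
                                  radius_range=(10, 14),
                                  background_level=0.55,
                                  particle_contrast=0.30, noise_sigma=0.15,
                                  gradient_amplitude=0.03,
                                  min_separation=4.0),
    # mixed top/side views plus ice clutter, larger particles
    "klh_like": SceneSpec(height=2048, width=2048, n_circles=12,
                          radius_range=(16, 22), n_squares=8,
                          side_range=(26, 36), background_level=0.6,
                          particle_contrast=0.30, noise_sigma=0.12,
                          n_ice_blobs=5, ice_contrast=0.22,
                          gradient_amplitude=0.04, min_separation=6.0),
    # low contrast and allowed overlaps
    "hard": SceneSpec(height=512, width=512, n_circles=25,
                      radius_range=(10, 14), background_level=0.55,
                      particle_contrast=0.18, noise_sigma=0.15,
                      n_ice_blobs=3, ice_contrast=0.15,
                      gradient_amplitude=0.05, allow_overlap=True,
                      min_separation=0.0),
}


def preset_spec(preset: str, size: Optional[int] = None,
                seed: int = 0) -> SceneSpec:
    """The SceneSpec family of a named preset, optionally resized."""
    if preset not in _PRESETS:
        raise InvalidConfigError(
            f"unknown preset {preset!r}; choose from {sorted(_PRESETS)}")
    spec = _PRESETS[preset]
    if size is not None:
        spec = replace(spec, height=size, width=size)
    return replace(spec, seed=seed)


def generate_suite(preset: str, n_images: int, seed: int,
                   size: Optional[int] = None
                   ) -> List[Tuple[Micrograph, SceneTruth]]:
    """Generate ``n_images`` reproducible scenes from a preset family.

    Per-scene seeds are spawned from ``seed`` so different images differ but
    the whole suite is a pure function of (preset, n_images, seed, size).
    """
    if n_images < 1:
        raise InvalidConfigError("n_images must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_images)
    scenes = []
    for child in children:
        child_seed = int(child.generate_state(1)[0] % (2 ** 31))
        scenes.append(generate_scene(preset_spec(preset, size=size,
                                                 seed=child_seed)))
    return scenes
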