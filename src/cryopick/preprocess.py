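"""Contrast-enhancement chain that makes particles separable by intensity.

Raw averaged micrographs have particle/background contrast of a few percent.
The chain applies, in order: percentile-based contrast stretching, mid-range
stretching, global histogram equalization, adaptive Wiener denoising,
contrast-limited adaptive histogram equalization (CLAHE), edge-preserving
guided filtering, and a grayscale morphological closing. Every step maps
[0, 1] into [0, 1] and is deterministic; each can be toggled off for
ablation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np
from scipy import ndimage
from skimage import exposure

from cryopick.errors import DegenerateInputError, InvalidConfigError
from cryopick.io import Micrograph


@dataclass(frozen=True)
class StretchLimits:
    """Lower/upper intensity limits for contrast stretching, in [0, 1]."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.low < self.high <= 1.0):
            raise InvalidConfigError(
                f"stretch limits must satisfy 0 <= low < high <= 1, "
                f"got ({self.low}, {self.high})")


@dataclass(frozen=True)
class StepToggles:
    """Per-step enable flags for the enhancement chain."""

    adjust: bool = True     # stretch limits + mid-range stretch + adjust
    equalize: bool = True
    wiener: bool = True
    clahe: bool = True
    guided: bool = True
    close: bool = True

    @classmethod
    def none(cls) -> "StepToggles":
        return cls(False, False, False, False, False, False)


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunable parameters of the enhancement chain.

    Defaults: 2%/2% stretch fractions, 5x5 Wiener window, 8x8 CLAHE tiles
    with clip limit 0.01, 5x5 guided-filter window with eps = (0.01*range)^2,
    and a 5x5 square structuring element for the closing.
    """

    low_frac: float = 0.02
    high_frac: float = 0.02
    wiener_window: int = 5
    clahe_tiles: Tuple[int, int] = (8, 8)
    clahe_clip: float = 0.01
    guided_window: int = 5
    guided_eps: float = 1e-4
    se_size: int = 5
    n_bins: int = 256
    step_toggles: StepToggles = field(default_factory=StepToggles)

    def __post_init__(self) -> None:
        for name in ("wiener_window", "guided_window", "se_size"):
            v = getattr(self, name)
            if v < 3 or v % 2 == 0:
                raise InvalidConfigError(f"{name} must be odd and >= 3, got {v}")
        for name in ("low_frac", "high_frac"):
            v = getattr(self, name)
            if not 0.0 <= v < 0.5:
                raise InvalidConfigError(f"{name} must lie in [0, 0.5), got {v}")
        if not 0.0 < self.clahe_clip <= 1.0:
            raise InvalidConfigError("clahe_clip must lie in (0, 1]")
        if self.guided_eps <= 0:
            raise InvalidConfigError("guided_eps must be positive")
        if self.n_bins < 2:
            raise InvalidConfigError("n_bins must be >= 2")


def stretch_limits(img: Micrograph, low_frac: float = 0.02,
                   high_frac: float = 0.02) -> StretchLimits:
    """Find the intensities cutting off the bottom/top pixel-mass fractions.

    ``low`` is the smallest intensity whose cumulative pixel mass reaches
    ``low_frac``; ``high`` the smallest reaching ``1 - high_frac``. A
    degenerate image (low == high) falls back to (0, 1) with a warning.
    """
    if low_frac + high_frac >= 1.0:
        raise InvalidConfigError("low_frac + high_frac must be < 1")
    v = np.sort(img.pixels, axis=None)
    n = v.size
    lo_idx = max(int(np.ceil(low_frac * n)) - 1, 0)
    hi_idx = max(int(np.ceil((1.0 - high_frac) * n)) - 1, 0)
    low, high = float(v[lo_idx]), float(v[hi_idx])
    if not low < high:
        warnings.warn("degenerate stretch limits; falling back to (0, 1)",
                      stacklevel=2)
        return StretchLimits(0.0, 1.0)
    return StretchLimits(low, high)


def midrange_stretch(img: Micrograph) -> Micrograph:
    """Divide by the maximum so the brightest pixel maps to 1."""
    high = float(img.pixels.max())
    if high <= 0:
        raise DegenerateInputError("mid-range stretch needs max intensity > 0")
    return img.with_pixels(img.pixels / high, value_range=(0.0, 1.0))


def adjust_intensity(img: Micrograph, limits: StretchLimits) -> Micrograph:
    """Linearly map [low, high] to [0, 1], clipping values outside."""
    out = (img.pixels - limits.low) / (limits.high - limits.low)
    return img.with_pixels(np.clip(out, 0.0, 1.0), value_range=(0.0, 1.0))


def equalize_histogram(img: Micrograph, n_bins: int = 256) -> Micrograph:
    """Global histogram equalization: map each pixel to its CDF value."""
    out = exposure.equalize_hist(img.pixels, nbins=n_bins)
    return img.with_pixels(out, value_range=(0.0, 1.0))


def wiener_restore(img: Micrograph, window: int = 5) -> Micrograph:
    """Locally adaptive (Wiener) denoising with reflective boundaries.

    Per pixel: ``out = mu + max(0, var - nu2) / max(var, nu2) * (x - mu)``
    with ``mu``/``var`` the local window mean/variance and the noise power
    ``nu2`` estimated as the mean of all local variances. Flat regions are
    pulled to their local mean; high-variance structure is kept.
    """
    if window < 3 or window % 2 == 0:
        raise InvalidConfigError("window must be odd and >= 3")
    x = img.pixels
    mu = ndimage.uniform_filter(x, size=window, mode="reflect")
    var = ndimage.uniform_filter(x * x, size=window, mode="reflect") - mu * mu
    var = np.maximum(var, 0.0)
    nu2 = float(var.mean())
    denom = np.maximum(var, nu2)
    with np.errstate(invalid="ignore", divide="ignore"):
        gain = np.where(denom > 0, np.maximum(var - nu2, 0.0) / denom, 0.0)
    out = mu + gain * (x - mu)
    return img.with_pixels(np.clip(out, 0.0, 1.0), value_range=(0.0, 1.0))


def clahe(img: Micrograph, tiles: Tuple[int, int] = (8, 8),
          clip: float = 0.01, n_bins: int = 256) -> Micrograph:
    """Contrast-limited adaptive histogram equalization.

    The image is divided into a ``tiles`` grid; each tile is equalized with
    its histogram clipped at ``clip`` (fraction of tile pixels per bin) and
    neighboring tile mappings are blended bilinearly.
    """
    rows, cols = tiles
    h, w = img.pixels.shape
    if rows < 1 or cols < 1 or rows > h or cols > w:
        raise InvalidConfigError(
            f"tile grid {tiles} invalid for image of shape {(h, w)}")
    if img.pixels.max() == img.pixels.min():
        return img.with_pixels(img.pixels.copy())
    kernel = (max(h // rows, 1), max(w // cols, 1))
    out = exposure.equalize_adapthist(
        np.clip(img.pixels, 0.0, 1.0), kernel_size=kernel,
        clip_limit=clip, nbins=n_bins)
    return img.with_pixels(out, value_range=(0.0, 1.0))


def guided_filter(img: Micrograph, guide: Micrograph | None = None,
                  window: int = 5, eps: float = 1e-4) -> Micrograph:
    """Edge-preserving smoothing driven by a guidance image.

    Standard local-linear-model formulation: within each window k the output
    is ``a_k * I + b_k`` with ``a_k = cov(I, p) / (var(I) + eps)`` and
    ``b_k = mean(p) - a_k * mean(I)``, then averaged over all windows
    covering each pixel. ``guide`` defaults to the image itself
    (self-guided: smooths flat regions, keeps strong edges).
    """
    if eps <= 0:
        raise InvalidConfigError("eps must be positive")
    if window < 3 or window % 2 == 0:
        raise InvalidConfigError("window must be odd and >= 3")
    p = img.pixels
    I = p if guide is None else guide.pixels
    if I.shape != p.shape:
        raise InvalidConfigError("guide and image must share a shape")

    def box(a: np.ndarray) -> np.ndarray:
        return ndimage.uniform_filter(a, size=window, mode="reflect")

    mean_I, mean_p = box(I), box(p)
    cov_Ip = box(I * p) - mean_I * mean_p
    var_I = box(I * I) - mean_I * mean_I
    a = cov_Ip / (var_I + eps)
    b = mean_p - a * mean_I
    out = box(a) * I + box(b)
    return img.with_pixels(np.clip(out, 0.0, 1.0), value_range=(0.0, 1.0))


def morph_close(img: Micrograph, se_size: int = 5) -> Micrograph:
    """Grayscale closing (dilation then erosion) with a square element.

    Fills dark gaps smaller than the element, making each particle's interior
    uniformly dark and well-connected; idempotent.
    """
    if se_size < 3 or se_size % 2 == 0:
        raise InvalidConfigError("se_size must be odd and >= 3")
    footprint = np.ones((se_size, se_size), dtype=bool)
    out = ndimage.grey_erosion(
        ndimage.grey_dilation(img.pixels, footprint=footprint),
        footprint=footprint)
    return img.with_pixels(out, value_range=(0.0, 1.0))


def preprocess(img: Micrograph, cfg: PreprocessConfig | None = None) -> Micrograph:
    """Run the full enhancement chain, honoring the per-step toggles.

    Expects intensities in [0, 1] (see :func:`cryopick.io.to_unit_range`).
    With every toggle off, the input is returned unchanged.
    """
    cfg = cfg or PreprocessConfig()
    t = cfg.step_toggles
    steps = []
    if t.adjust:
        def _adjust(im: Micrograph) -> Micrograph:
            limits = stretch_limits(im, cfg.low_frac, cfg.high_frac)
            return adjust_intensity(midrange_stretch(im), limits)
        steps.append(("intensity_adjust", _adjust))
    if t.equalize:
        steps.append(("equalize", lambda im: equalize_histogram(im, cfg.n_bins)))
    if t.wiener:
        steps.append(("wiener", lambda im: wiener_restore(im, cfg.wiener_window)))
    if t.clahe:
        steps.append(("clahe", lambda im: clahe(im, cfg.clahe_tiles,
                                                cfg.clahe_clip, cfg.n_bins)))
    if t.guided:
        steps.append(("guided", lambda im: guided_filter(
            im, None, cfg.guided_window, cfg.guided_eps)))
    if t.close:
        steps.append(("close", lambda im: morph_close(im, cfg.se_size)))
    for name, fn in steps:
        try:
            img = fn(img)
        except Exception as exc:
            raise type(exc)(f"preprocessing step '{name}': {exc}") from exc
    return img


def with_toggles(cfg: PreprocessConfig, **flags: bool) -> PreprocessConfig:
    """Return a config with some step toggles replaced."""
    return replace(cfg, step_toggles=replace(cfg.step_toggles, **flags))
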