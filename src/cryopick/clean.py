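"""Binary-mask cleaning: hole filling, size/roundness filters, shape splits.

The darkest intensity cluster is a noisy over-segmentation: particles plus
speckle, rims of ice blobs, and other debris. Cleaning fills interior holes,
opens away thin bridges, and drops components that are too small or not
round enough. For side-view (square) picking a second pass removes the
round and irregular components instead, keeping only square-like ones.

Shape conventions (frozen here and in the tests): perimeter is the
chain-length estimate with diagonal steps weighted sqrt(2) (skimage's
``perimeter``); circularity is ``4*pi*area / perimeter**2``, which can
slightly exceed 1 for small digital disks; the maximum Feret diameter is the
largest pairwise distance between boundary *pixel centers* (9*sqrt(2) for a
10x10 filled square).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage import measure

from cryopick.errors import InvalidConfigError


@dataclass(frozen=True)
class ComponentStats:
    """Shape measurements of one connected component."""

    label: int
    area: int
    perimeter: float
    circularity: float
    extent: float
    centroid: tuple  # (row, col)
    feret_max: float
    bbox: tuple  # (top, left, height, width)


@dataclass(frozen=True)
class CleaningParams:
    """Thresholds for mask cleaning and square selection.

    ``min_area`` defaults to 0.3 * pi * r_expected^2 via
    :meth:`for_expected_radius`; ``max_allowable_area`` optionally caps the
    component area in the square-keeping pass; ``circle_circularity_min`` is
    the circularity at and above which a component counts as a circle there
    (squares sit near pi/4 ~ 0.785, digital disks near 1).
    """

    min_area: int = 50
    min_circularity: float = 0.5
    square_extent_min: float = 0.87
    square_aspect_tol: float = 0.25
    max_allowable_area: Optional[int] = None
    circle_circularity_min: float = 0.9
    opening_se: int = 3

    def __post_init__(self) -> None:
        if self.min_area < 1:
            raise InvalidConfigError("min_area must be >= 1")
        if not 0.0 <= self.min_circularity <= 2.0:
            raise InvalidConfigError("min_circularity out of range")
        if not 0.0 < self.square_extent_min <= 1.0:
            raise InvalidConfigError("square_extent_min out of range")
        if self.square_aspect_tol < 0:
            raise InvalidConfigError("square_aspect_tol must be >= 0")
        if self.opening_se < 1 or self.opening_se % 2 == 0:
            raise InvalidConfigError("opening_se must be odd and >= 1")

    @classmethod
    def for_expected_radius(cls, r_expected: float, **overrides) -> "CleaningParams":
        """Scale the area filters to an expected particle radius (px)."""
        area = math.pi * r_expected ** 2
        defaults = dict(min_area=max(int(0.3 * area), 1),
                        max_allowable_area=int(4.0 * area))
        defaults.update(overrides)
        return cls(**defaults)


def _boundary_mask(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels with at least one 4-connected background neighbor."""
    cross = ndimage.generate_binary_structure(2, 1)
    interior = ndimage.binary_erosion(mask, structure=cross, border_value=0)
    return mask & ~interior


def _feret_max(component: np.ndarray) -> float:
    """Max pairwise distance between boundary pixel centers of a component."""
    pts = np.argwhere(_boundary_mask(component)).astype(np.float64)
    if len(pts) == 1:
        return 0.0
    if len(pts) > 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # collinear points; brute-force below
    return float(pdist(pts).max())


def component_stats(mask: np.ndarray,
                    connectivity: int = 8) -> List[ComponentStats]:
    """Measure every connected component of a binary mask.

    ``connectivity`` is 4 or 8 (default 8, diagonal neighbors connect).
    """
    if connectivity not in (4, 8):
        raise InvalidConfigError("connectivity must be 4 or 8")
    mask = np.asarray(mask, dtype=bool)
    labeled = measure.label(mask, connectivity=1 if connectivity == 4 else 2)
    stats: List[ComponentStats] = []
    for rp in measure.regionprops(labeled):
        perim = float(rp.perimeter)
        area = int(rp.area)
        circ = 4.0 * math.pi * area / (perim * perim) if perim > 0 else float("inf")
        top, left, bottom, right = rp.bbox
        component = labeled[top:bottom, left:right] == rp.label
        stats.append(ComponentStats(
            label=int(rp.label),
            area=area,
            perimeter=perim,
            circularity=circ,
            extent=float(rp.extent),
            centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
            feret_max=_feret_max(component),
            bbox=(top, left, bottom - top, right - left),
        ))
    return stats


def _drop_components(mask: np.ndarray, keep) -> np.ndarray:
    """Keep only components satisfying the predicate on their stats."""
    labeled = measure.label(mask, connectivity=2)
    out = np.zeros_like(mask, dtype=bool)
    for st in component_stats(mask, connectivity=8):
        if keep(st):
            out |= labeled == st.label
    return out


def clean_mask(mask: np.ndarray, params: CleaningParams) -> np.ndarray:
    """Clean a raw particle-cluster mask.

    In order: fill interior holes, binary opening with a square element,
    drop components smaller than ``min_area``, drop components with
    circularity below ``min_circularity``. Pixels of surviving components
    are left untouched.
    """
    mask = np.asarray(mask, dtype=bool)
    filled = ndimage.binary_fill_holes(mask)
    if params.opening_se > 1:
        se = np.ones((params.opening_se, params.opening_se), dtype=bool)
        opened = ndimage.binary_opening(filled, structure=se)
    else:
        opened = filled
    return _drop_components(
        opened, lambda st: st.area >= params.min_area
        and st.circularity >= params.min_circularity)


def remove_round_keep_square(mask: np.ndarray,
                             params: CleaningParams) -> np.ndarray:
    """Keep only square-like components; remove circles and irregulars.

    A component survives iff its bounding-box extent is at least
    ``square_extent_min``, its bbox aspect ratio is within
    ``square_aspect_tol`` of 1, its circularity is below
    ``circle_circularity_min`` (circles score near 1), and its area does not
    exceed ``max_allowable_area`` when that cap is set. A square rotated 45
    degrees has extent ~0.5 and is removed under the defaults — a known
    limitation of the axis-aligned criterion.
    """
    mask = np.asarray(mask, dtype=bool)

    def keep(st: ComponentStats) -> bool:
        _, _, h, w = st.bbox
        aspect_ok = w > 0 and abs(h / w - 1.0) <= params.square_aspect_tol
        area_ok = (params.max_allowable_area is None
                   or st.area <= params.max_allowable_area)
        return (st.extent >= params.square_extent_min and aspect_ok
                and st.circularity < params.circle_circularity_min and area_ok)

    return _drop_components(mask, keep)
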