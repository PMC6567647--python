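"""Shape detection on cleaned particle masks.

Top-view (circular) particles are found with a circular Hough transform fed
by the mask's own boundary pixels instead of Canny edges: every boundary
pixel votes for all centers at each candidate radius, and accumulator peaks
whose vote count reaches a fraction of the ideal circumference 2*pi*r are
accepted, with greedy non-maximum suppression. Side-view (square) particles
are first sized roughly from component area, then refined with the maximum
Feret diameter (the square's diagonal), which also exposes merged/overlapped
components as area outliers.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import asdict, dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage import measure

from cryopick.clean import CleaningParams, _boundary_mask, _feret_max, \
    clean_mask, remove_round_keep_square
from cryopick.cluster import fcm_cluster, ibc_fit_predict, kmeans_cluster, \
    select_particle_cluster
from cryopick.errors import InvalidConfigError
from cryopick.io import Micrograph
from cryopick.picks import ParticleCandidate, PickSet
from cryopick.preprocess import PreprocessConfig, preprocess


@dataclass(frozen=True)
class ClusterConfig:
    """Which clusterer builds the particle mask, and how."""

    method: str = "ibc"  # "ibc" | "kmeans" | "fcm"
    K: int = 4
    seed: int = 0
    cluster_index: int = 1
    invert: bool = False

    def __post_init__(self) -> None:
        if self.method not in ("ibc", "kmeans", "fcm"):
            raise InvalidConfigError(f"unknown cluster method {self.method!r}")


@dataclass(frozen=True)
class DetectParams:
    """Shape-detection parameters.

    ``r_min``/``r_max`` bound the circle radii voted on;
    ``vote_frac_min`` is the accepted fraction of the ideal circumference;
    ``min_separation`` (default ``r_min``) is the smallest allowed distance
    between circle centers. ``side_min``/``side_max`` bound the square side.
    """

    shape: str = "circle"  # "circle" | "square" | "both"
    r_min: int = 5
    r_max: int = 20
    vote_frac_min: float = 0.35
    min_separation: Optional[float] = None
    side_min: float = 8.0
    side_max: float = 60.0
    smooth_sigma: float = 1.0
    outlier_factor: float = 1.5

    def __post_init__(self) -> None:
        if self.shape not in ("circle", "square", "both"):
            raise InvalidConfigError(f"unknown shape mode {self.shape!r}")
        if not 0 < self.r_min <= self.r_max:
            raise InvalidConfigError("need 0 < r_min <= r_max")
        if not 0.0 < self.vote_frac_min <= 1.0:
            raise InvalidConfigError("vote_frac_min must lie in (0, 1]")
        if self.min_separation is not None and self.min_separation <= 0:
            raise InvalidConfigError("min_separation must be positive")
        if self.smooth_sigma < 0:
            raise InvalidConfigError("smooth_sigma must be >= 0")
        if self.outlier_factor <= 1:
            raise InvalidConfigError("outlier_factor must be > 1")

    @classmethod
    def for_expected_radius(cls, r_expected: float, band: float = 0.2,
                            **overrides) -> "DetectParams":
        """Radius band of +-``band`` (default 20%) around an expected radius."""
        defaults = dict(r_min=max(int(math.floor(r_expected * (1 - band))), 2),
                        r_max=int(math.ceil(r_expected * (1 + band))))
        defaults.update(overrides)
        return cls(**defaults)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the end-to-end picker needs, in one place."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    clean: CleaningParams = field(default_factory=CleaningParams)
    detect: DetectParams = field(default_factory=DetectParams)
    version: str = "1"

    def fingerprint(self) -> str:
        blob = repr(asdict(self)).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Circular Hough transform
# ---------------------------------------------------------------------------

def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Coordinates (row, col) of foreground pixels with a background 4-neighbor.

    Pixels on the image border count as boundary (outside is background).
    """
    return np.argwhere(_boundary_mask(np.asarray(mask, dtype=bool)))


def circle_offsets(r: int) -> np.ndarray:
    """Ring of integer offsets whose Euclidean length rounds to ``r``."""
    rng = np.arange(-r - 1, r + 2)
    dy, dx = np.meshgrid(rng, rng, indexing="ij")
    on = np.round(np.hypot(dy, dx)).astype(int) == r
    return np.stack([dy[on], dx[on]], axis=1)


def cht_accumulator(mask: np.ndarray, r_min: int, r_max: int) -> np.ndarray:
    """Vote accumulator of shape (n_radii, H, W).

    Each boundary pixel adds one vote to every in-bounds center cell at
    rounded distance r, for each radius r in [r_min, r_max].
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    pts = boundary_pixels(mask)
    radii = np.arange(r_min, r_max + 1)
    acc = np.zeros((len(radii), h, w), dtype=np.int32)
    if len(pts) == 0:
        return acc
    for i, r in enumerate(radii):
        off = circle_offsets(int(r))
        cy = pts[:, 0][:, None] + off[:, 0][None, :]
        cx = pts[:, 1][:, None] + off[:, 1][None, :]
        ok = (cy >= 0) & (cy < h) & (cx >= 0) & (cx < w)
        np.add.at(acc[i], (cy[ok], cx[ok]), 1)
    return acc


def _accumulator_peaks(acc: np.ndarray, r_min: int,
                       vote_frac_min: float) -> List[Tuple[float, int, int, int, int]]:
    """Cells above threshold that are 3x3 spatial maxima in their radius plane.

    Returns (vote_fraction, row, col, radius, votes) tuples.
    """
    peaks = []
    for i in range(acc.shape[0]):
        r = r_min + i
        thr = vote_frac_min * 2.0 * math.pi * r
        plane = acc[i]
        local_max = plane >= ndimage.maximum_filter(plane, size=3,
                                                    mode="constant", cval=0)
        for y, x in np.argwhere((plane >= thr) & local_max):
            votes = int(plane[y, x])
            frac = min(votes / (2.0 * math.pi * r), 1.0)
            peaks.append((frac, int(y), int(x), r, votes))
    return peaks


def _refine_center(plane: np.ndarray, y: int, x: int) -> Tuple[float, float]:
    """Sub-pixel center: vote-weighted centroid of the 3x3 neighborhood."""
    h, w = plane.shape
    ys = slice(max(y - 1, 0), min(y + 2, h))
    xs = slice(max(x - 1, 0), min(x + 2, w))
    win = plane[ys, xs].astype(np.float64)
    total = win.sum()
    if total <= 0:
        return float(y), float(x)
    gy, gx = np.mgrid[ys, xs]
    return float((win * gy).sum() / total), float((win * gx).sum() / total)


def cht_detect(mask: np.ndarray, r_min: int, r_max: int,
               vote_frac_min: float = 0.35,
               min_separation: Optional[float] = None) -> List[ParticleCandidate]:
    """Detect circles in a binary mask via the boundary-pixel Hough transform.

    Peaks with votes >= ``vote_frac_min * 2*pi*r`` are pooled over all radii
    and greedily suppressed by descending vote fraction (ties broken by
    smaller row, then col, then radius) with centers kept at least
    ``min_separation`` (default ``r_min``) apart. Centers are refined to
    sub-pixel precision by the accumulator's 3x3 centroid.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    if not 0 < r_min <= r_max:
        raise InvalidConfigError("need 0 < r_min <= r_max")
    if r_max > min(h, w) / 2:
        raise InvalidConfigError(
            f"r_max={r_max} exceeds half the smaller image dimension "
            f"({min(h, w)})")
    if min_separation is None:
        min_separation = float(r_min)
    acc = cht_accumulator(mask, r_min, r_max)
    peaks = _accumulator_peaks(acc, r_min, vote_frac_min)
    peaks.sort(key=lambda p: (-p[0], p[1], p[2], p[3]))
    kept: List[Tuple[float, int, int, int, int]] = []
    for p in peaks:
        if all(math.hypot(p[1] - q[1], p[2] - q[2]) >= min_separation
               for q in kept):
            kept.append(p)
    out = []
    for frac, y, x, r, _votes in kept:
        cy, cx = _refine_center(acc[r - r_min], y, x)
        bbox = (int(round(cy - r)), int(round(cx - r)), 2 * r + 1, 2 * r + 1)
        out.append(ParticleCandidate(center=(cy, cx), radius_or_halfside=float(r),
                                     shape="circle", score=frac, bbox=bbox))
    return out


# ---------------------------------------------------------------------------
# Square detection
# ---------------------------------------------------------------------------

def square_detect(mask: np.ndarray, side_min: float,
                  side_max: float) -> List[ParticleCandidate]:
    """Rough square picking: each component with sqrt(area) in the side band
    becomes a candidate at its centroid with halfside = sqrt(area)/2 and the
    bounding-box extent as score."""
    mask = np.asarray(mask, dtype=bool)
    out = []
    for rp in measure.regionprops(measure.label(mask, connectivity=2)):
        side = math.sqrt(rp.area)
        if not side_min <= side <= side_max:
            continue
        halfside = side / 2.0
        cy, cx = float(rp.centroid[0]), float(rp.centroid[1])
        bbox = (int(round(cy - halfside)), int(round(cx - halfside)),
                int(round(2 * halfside)), int(round(2 * halfside)))
        out.append(ParticleCandidate(center=(cy, cx),
                                     radius_or_halfside=halfside,
                                     shape="square",
                                     score=min(float(rp.extent), 1.0),
                                     bbox=bbox))
    out.sort(key=lambda p: (p.center[0], p.center[1]))
    return out


def feret_square_refine(mask: np.ndarray,
                        candidates: Sequence[ParticleCandidate],
                        smooth_sigma: float = 1.0,
                        outlier_factor: float = 1.5) -> List[ParticleCandidate]:
    """Perfect-square refinement via the maximum Feret diameter.

    Each candidate's component patch is Gaussian-smoothed and re-thresholded
    at 0.5; the refined halfside is ``feret_max / (2*sqrt(2))`` (for a square
    the Feret maximum is its diagonal). Candidates whose refined area departs
    from the cohort median by more than ``outlier_factor``x — typically
    merged, overlapping particles — are dropped. Boxes are recentered on the
    refined component centroid.
    """
    mask = np.asarray(mask, dtype=bool)
    labeled = measure.label(mask, connectivity=2)
    refined: List[Tuple[ParticleCandidate, float, Tuple[float, float]]] = []
    for cand in candidates:
        y, x = (int(round(cand.center[0])), int(round(cand.center[1])))
        y = min(max(y, 0), mask.shape[0] - 1)
        x = min(max(x, 0), mask.shape[1] - 1)
        lab = labeled[y, x]
        if lab == 0:  # centroid off-component (concave shape): nearest label
            comp_ids = np.argwhere(labeled > 0)
            if len(comp_ids) == 0:
                continue
            d = np.hypot(comp_ids[:, 0] - cand.center[0],
                         comp_ids[:, 1] - cand.center[1])
            yy, xx = comp_ids[np.argmin(d)]
            lab = labeled[yy, xx]
        comp = labeled == lab
        top, left = np.argwhere(comp).min(axis=0)
        bottom, right = np.argwhere(comp).max(axis=0) + 1
        pad = int(math.ceil(3 * smooth_sigma)) + 1
        t, l = max(top - pad, 0), max(left - pad, 0)
        b, rgt = min(bottom + pad, mask.shape[0]), min(right + pad, mask.shape[1])
        patch = comp[t:b, l:rgt].astype(np.float64)
        if smooth_sigma > 0:
            patch = ndimage.gaussian_filter(patch, sigma=smooth_sigma)
        smoothed = patch >= 0.5
        if not smoothed.any():
            continue
        feret = _feret_max(smoothed)
        if feret <= 0:
            continue
        halfside = feret / (2.0 * math.sqrt(2.0))
        cyx = ndimage.center_of_mass(smoothed)
        center = (float(cyx[0]) + t, float(cyx[1]) + l)
        refined.append((cand, halfside, center))
    if not refined:
        return []
    areas = np.array([(2 * hs) ** 2 for _, hs, _ in refined])
    med = float(np.median(areas))
    out = []
    for (cand, halfside, center), area in zip(refined, areas):
        if med > 0 and (area > outlier_factor * med or area < med / outlier_factor):
            continue
        bbox = (int(round(center[0] - halfside)),
                int(round(center[1] - halfside)),
                int(round(2 * halfside)), int(round(2 * halfside)))
        out.append(ParticleCandidate(center=center,
                                     radius_or_halfside=float(halfside),
                                     shape="square", score=cand.score,
                                     bbox=bbox))
    return out


# ---------------------------------------------------------------------------
# End-to-end picking
# ---------------------------------------------------------------------------

def compute_particle_mask(img: Micrograph, cfg: PipelineConfig) -> np.ndarray:
    """Preprocess, cluster and select the darkest-cluster mask (uncleaned)."""
    enhanced = preprocess(img, cfg.preprocess)
    cc = cfg.cluster
    if cc.method == "ibc":
        _, lmap = ibc_fit_predict(enhanced, K=cc.K)
    elif cc.method == "kmeans":
        lmap = kmeans_cluster(enhanced, K=cc.K, seed=cc.seed)
    else:
        lmap = fcm_cluster(enhanced, K=cc.K, seed=cc.seed)
    return select_particle_cluster(lmap, index=cc.cluster_index,
                                   invert=cc.invert)


def pick(img: Micrograph, cfg: PipelineConfig | None = None) -> PickSet:
    """Run the full pipeline on one micrograph and return its picks.

    Stages: preprocess -> cluster -> darkest-cluster mask -> clean ->
    circle branch (Hough) and/or square branch (round-removal, rough square
    picking, Feret refinement), both operating on the same cleaned base mask.
    With the deterministic clusterer the result is identical across reruns.
    """
    cfg = cfg or PipelineConfig()
    stage = "preprocess/cluster"
    try:
        raw_mask = compute_particle_mask(img, cfg)
        stage = "clean"
        base = clean_mask(raw_mask, cfg.clean)
        picks: List[ParticleCandidate] = []
        dp = cfg.detect
        if dp.shape in ("circle", "both"):
            stage = "cht_detect"
            picks.extend(cht_detect(base, dp.r_min, dp.r_max,
                                    dp.vote_frac_min, dp.min_separation))
        if dp.shape in ("square", "both"):
            stage = "square_detect"
            squares_mask = remove_round_keep_square(base, cfg.clean)
            rough = square_detect(squares_mask, dp.side_min, dp.side_max)
            stage = "feret_refine"
            picks.extend(feret_square_refine(squares_mask, rough,
                                             dp.smooth_sigma,
                                             dp.outlier_factor))
    except Exception as exc:
        raise type(exc)(f"pipeline stage '{stage}': {exc}") from exc
    return PickSet(picks=picks, image_id=img.source_id,
                   params_fingerprint=cfg.fingerprint())
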