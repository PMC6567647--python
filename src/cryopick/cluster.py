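"""Pixel-intensity clustering: deterministic interval clustering and baselines.

The particle mask is built by partitioning pixel intensities into K clusters
and keeping the darkest one (particles are dark on a light background after
preprocessing). The interval-based clusterer (IBC) divides [min, max] into K
equal-width intervals, so cluster identity depends only on pixel values —
no random initialization, bit-identical reruns, and one pass over the data.
K-means and fuzzy C-means baselines are provided for comparison; their raw
cluster order depends on the seed, which is exactly the instability the
deterministic method avoids, so both also offer an intensity-sorted wrapper.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from cryopick.errors import DegenerateInputError, InvalidConfigError
from cryopick.io import Micrograph


@dataclass
class IBCModel:
    """Equal-width interval model over the image intensity range.

    ``edges`` has K+1 ascending values spanning [min, max]; ``centers`` are
    interval midpoints; ``histogram`` counts pixels per interval and sums to
    the pixel count. ``op_count`` is the number of per-pixel assignment
    operations performed (one pass).
    """

    K: int
    interval_width: float
    edges: np.ndarray
    centers: np.ndarray
    histogram: np.ndarray
    op_count: int = 0


@dataclass
class LabelMap:
    """Per-pixel cluster labels in 1..K, sorted so label 1 is darkest.

    ``centers`` are ascending cluster intensities; for the baselines
    ``op_count`` counts distance evaluations and ``n_iter`` the iterations
    actually run.
    """

    labels: np.ndarray
    K: int
    method: str  # "ibc" | "kmeans" | "fcm"
    centers: np.ndarray
    op_count: int = 0
    n_iter: int = 0
    memberships: Optional[np.ndarray] = field(default=None, repr=False)


def _check_image(img: Micrograph) -> np.ndarray:
    x = img.pixels
    if float(x.max()) <= float(x.min()):
        raise DegenerateInputError("constant image cannot be clustered")
    return x


def ibc_fit_predict(img: Micrograph, K: int = 4,
                    refine: bool = False) -> Tuple[IBCModel, LabelMap]:
    """Deterministic intensity-interval clustering.

    The intensity range is split into K equal intervals of width
    ``d = (max - min) / K``; a pixel with value v gets label k iff
    v falls in the k-th half-open interval (the last interval is closed
    above so v == max gets label K). Label 1 is the darkest interval.

    With ``refine`` (off by default, keeping the default path a single
    pass), one extra pass replaces centers by cluster means and reassigns
    each pixel to the nearest center — still deterministic, still seed-free.
    """
    if K < 2:
        raise InvalidConfigError("K must be >= 2")
    x = _check_image(img)
    lo, hi = float(x.min()), float(x.max())
    d = (hi - lo) / K
    edges = lo + d * np.arange(K + 1)
    # the 1e-9 nudge keeps edge values in their half-open interval despite
    # floating-point round-off in (x - lo) / d
    idx = np.floor((x - lo) / d + 1e-9).astype(np.int64)
    np.clip(idx, 0, K - 1, out=idx)  # closes the top interval
    labels = idx + 1
    centers = (edges[:-1] + edges[1:]) / 2.0
    ops = x.size
    n_iter = 1
    if refine:
        means = np.array([x[labels == k + 1].mean()
                          if (labels == k + 1).any() else centers[k]
                          for k in range(K)])
        order = np.argsort(means, kind="stable")
        centers = means[order]
        idx = np.argmin(np.abs(x[..., None] - centers), axis=-1)
        labels = idx + 1
        ops += x.size * K
        n_iter = 2
    hist = np.bincount(idx.ravel(), minlength=K)
    model = IBCModel(K=K, interval_width=d, edges=edges, centers=centers,
                     histogram=hist, op_count=ops)
    lmap = LabelMap(labels=labels, K=K, method="ibc", centers=centers,
                    op_count=ops, n_iter=n_iter)
    return model, lmap


def _sorted_relabel(labels: np.ndarray, centers: np.ndarray,
                    K: int) -> Tuple[np.ndarray, np.ndarray]:
    """Permute labels so cluster centers ascend with the label index."""
    order = np.argsort(centers, kind="stable")
    remap = np.empty(K, dtype=np.int64)
    remap[order] = np.arange(1, K + 1)
    return remap[labels - 1], centers[order]


def _kmeanspp_init(x: np.ndarray, K: int, rng: np.random.Generator
                   ) -> np.ndarray:
    """k-means++ seeding: each next center drawn with probability ~ D^2."""
    centers = [float(rng.choice(x))]
    d2 = (x - centers[0]) ** 2
    for _ in range(K - 1):
        probs = d2 / d2.sum()
        centers.append(float(rng.choice(x, p=probs)))
        d2 = np.minimum(d2, (x - centers[-1]) ** 2)
    return np.array(centers)


def kmeans_cluster(img: Micrograph, K: int = 4, seed: int = 0,
                   max_iter: int = 100, sort_labels: bool = True) -> LabelMap:
    """Lloyd's k-means on the 1-D pixel intensities.

    Centers are seeded with D^2-weighted (k-means++) sampling of the pixel
    values, so the raw cluster order is seed-dependent; with ``sort_labels``
    (default) labels are re-indexed ascending by center intensity, which
    restores a stable particle-cluster identity.
    """
    if K < 2:
        raise InvalidConfigError("K must be >= 2")
    if max_iter < 1:
        raise InvalidConfigError("max_iter must be >= 1")
    x = _check_image(img).ravel()
    uniq = np.unique(x)
    if uniq.size < K:
        raise DegenerateInputError(
            f"only {uniq.size} distinct values for K={K}")
    rng = np.random.default_rng(seed)
    centers = _kmeanspp_init(x, K, rng)
    ops = 0
    assign = None
    for it in range(1, max_iter + 1):
        dist = np.abs(x[:, None] - centers[None, :])
        ops += x.size * K
        new_assign = np.argmin(dist, axis=1)
        if assign is not None and np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for k in range(K):
            sel = x[assign == k]
            if sel.size:
                centers[k] = sel.mean()
    labels = (assign + 1).reshape(img.pixels.shape)
    if sort_labels:
        labels, centers = _sorted_relabel(labels, centers, K)
    return LabelMap(labels=labels, K=K, method="kmeans",
                    centers=centers, op_count=ops, n_iter=it)


def kmeans_objective(img: Micrograph, lmap: LabelMap) -> float:
    """Within-cluster sum of squared intensity deviations."""
    x = img.pixels.ravel()
    centers = lmap.centers[lmap.labels.ravel() - 1]
    return float(np.sum((x - centers) ** 2))


def fcm_cluster(img: Micrograph, K: int = 4, m: float = 2.0, seed: int = 0,
                tol: float = 1e-5, max_iter: int = 200,
                sort_labels: bool = True) -> LabelMap:
    """Fuzzy C-means on the 1-D pixel intensities.

    Alternates membership and center updates until centers move less than
    ``tol``; hard labels are the argmax memberships. ``m > 1`` is the
    fuzzifier (2.0 is the common choice).
    """
    if K < 2:
        raise InvalidConfigError("K must be >= 2")
    if m <= 1:
        raise InvalidConfigError("fuzzifier m must be > 1")
    if tol <= 0:
        raise InvalidConfigError("tol must be positive")
    x = _check_image(img).ravel()
    uniq = np.unique(x)
    if uniq.size < K:
        raise DegenerateInputError(
            f"only {uniq.size} distinct values for K={K}")
    rng = np.random.default_rng(seed)
    centers = rng.choice(uniq, size=K, replace=False).astype(np.float64)
    power = 2.0 / (m - 1.0)
    ops = 0
    for it in range(1, max_iter + 1):
        dist = np.abs(x[:, None] - centers[None, :])
        ops += x.size * K
        dist = np.maximum(dist, 1e-12)
        inv = dist ** (-power)
        u = inv / inv.sum(axis=1, keepdims=True)
        um = u ** m
        new_centers = (um * x[:, None]).sum(axis=0) / um.sum(axis=0)
        shift = float(np.abs(new_centers - centers).max())
        centers = new_centers
        if shift < tol:
            break
    labels = (np.argmax(u, axis=1) + 1).reshape(img.pixels.shape)
    memberships = u.reshape(img.pixels.shape + (K,))
    if sort_labels:
        order = np.argsort(centers, kind="stable")
        labels, centers = _sorted_relabel(labels, centers, K)
        memberships = memberships[..., order]
    return LabelMap(labels=labels, K=K, method="fcm", centers=centers,
                    op_count=ops, n_iter=it, memberships=memberships)


def fcm_objective(img: Micrograph, lmap: LabelMap, m: float = 2.0) -> float:
    """FCM objective: sum of membership^m-weighted squared distances."""
    if lmap.memberships is None:
        raise InvalidConfigError("label map carries no memberships")
    x = img.pixels.ravel()
    u = lmap.memberships.reshape(-1, lmap.K)
    d2 = (x[:, None] - lmap.centers[None, :]) ** 2
    return float(np.sum((u ** m) * d2))


def select_particle_cluster(lmap: LabelMap, strategy: str = "fixed_index",
                            index: int = 1, invert: bool = False) -> np.ndarray:
    """Return the particle mask: pixels in the chosen intensity cluster.

    With intensity-sorted labels, index 1 is the darkest cluster, where the
    particles consistently land; ``strategy="darkest"`` is an alias. With
    ``invert`` (bright-particle data) the brightest cluster is used instead.
    """
    if strategy not in ("fixed_index", "darkest"):
        raise InvalidConfigError(f"unknown strategy {strategy!r}")
    if strategy == "darkest":
        index = 1
    if invert:
        index = lmap.K - index + 1
    if not 1 <= index <= lmap.K:
        raise InvalidConfigError(f"cluster index {index} outside 1..{lmap.K}")
    return lmap.labels == index
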