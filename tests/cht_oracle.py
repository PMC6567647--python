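"""Brute-force circular-Hough oracle, independent of the implementation.

Votes are *gathered* per accumulator cell from an explicit distance matrix
(the implementation scatters them from boundary pixels), and peak selection
re-derives the documented rule in plain loops.
"""

import math

import numpy as np


def brute_accumulator(mask, r_min, r_max):
    """Count, for every center cell, boundary pixels at rounded distance r.

    Independent of the implementation: boundary membership by explicit
    4-neighborhood check, votes gathered per cell from a distance matrix.
    """
    h, w = mask.shape
    pts = []
    for y in range(h):
        for x in range(w):
            if not mask[y, x]:
                continue
            for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ny, nx = y + dy, x + dx
                if not (0 <= ny < h and 0 <= nx < w) or not mask[ny, nx]:
                    pts.append((y, x))
                    break
    acc = np.zeros((r_max - r_min + 1, h, w), dtype=np.int32)
    if not pts:
        return acc
    pts = np.array(pts)
    yy, xx = np.mgrid[:h, :w]
    dist = np.hypot(yy[..., None] - pts[:, 0], xx[..., None] - pts[:, 1])
    rounded = np.round(dist).astype(int)
    for i, r in enumerate(range(r_min, r_max + 1)):
        acc[i] = (rounded == r).sum(axis=-1)
    return acc


def brute_candidates(mask, r_min, r_max, vote_frac_min, min_separation):
    """Thresholded local maxima + greedy suppression, re-derived from the
    documented rule on the brute-force accumulator."""
    acc = brute_accumulator(mask, r_min, r_max)
    peaks = []
    n_r, h, w = acc.shape
    for i in range(n_r):
        r = r_min + i
        thr = vote_frac_min * 2 * math.pi * r
        for y in range(h):
            for x in range(w):
                v = acc[i, y, x]
                if v < thr:
                    continue
                nb = acc[i, max(y - 1, 0):y + 2, max(x - 1, 0):x + 2]
                if v >= nb.max():
                    peaks.append((min(v / (2 * math.pi * r), 1.0), y, x, r))
    peaks.sort(key=lambda p: (-p[0], p[1], p[2], p[3]))
    kept = []
    for p in peaks:
        if all(math.hypot(p[1] - q[1], p[2] - q[2]) >= min_separation
               for q in kept):
            kept.append(p)
    return acc, {(y, x, r) for _f, y, x, r in kept}


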