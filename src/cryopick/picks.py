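"""Particle candidate records and pick-set containers.

Coordinates are row/col (y/x), 0-based, origin at the top-left corner of the
image, matching numpy array indexing. Bounding boxes are half-open
``[top, top+h) x [left, left+w)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, List, Sequence, Tuple


@dataclass(frozen=True)
class ParticleCandidate:
    """A single detected particle.

    ``radius_or_halfside`` is the circle radius for top views and half the
    square side for side views. ``score`` is the Hough vote fraction for
    circles and the bounding-box extent for squares, both in [0, 1].
    """

    center: Tuple[float, float]  # (row, col)
    radius_or_halfside: float
    shape: str  # "circle" | "square"
    score: float
    bbox: Tuple[int, int, int, int]  # (top, left, height, width)

    def __post_init__(self) -> None:
        if self.radius_or_halfside <= 0:
            raise ValueError("radius_or_halfside must be positive")
        if self.shape not in ("circle", "square"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")

    def to_record(self) -> dict:
        return {
            "center_y": float(self.center[0]),
            "center_x": float(self.center[1]),
            "radius_or_halfside": float(self.radius_or_halfside),
            "shape": self.shape,
            "score": float(self.score),
            "bbox": list(self.bbox),
        }

    @classmethod
    def from_record(cls, rec: dict) -> "ParticleCandidate":
        return cls(
            center=(rec["center_y"], rec["center_x"]),
            radius_or_halfside=rec["radius_or_halfside"],
            shape=rec["shape"],
            score=rec["score"],
            bbox=tuple(rec["bbox"]),
        )


@dataclass
class PickSet:
    """All particles picked from one micrograph, with provenance."""

    picks: List[ParticleCandidate] = field(default_factory=list)
    image_id: str = ""
    params_fingerprint: str = ""

    def __len__(self) -> int:
        return len(self.picks)

    def __iter__(self) -> Iterator[ParticleCandidate]:
        return iter(self.picks)

    def by_shape(self, shape: str) -> "PickSet":
        return PickSet(
            picks=[p for p in self.picks if p.shape == shape],
            image_id=self.image_id,
            params_fingerprint=self.params_fingerprint,
        )

    def to_json(self, path) -> None:
        payload = {
            "image_id": self.image_id,
            "params_fingerprint": self.params_fingerprint,
            "picks": [p.to_record() for p in self.picks],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path) -> "PickSet":
        payload = json.loads(Path(path).read_text())
        return cls(
            picks=[ParticleCandidate.from_record(r) for r in payload["picks"]],
            image_id=payload.get("image_id", ""),
            params_fingerprint=payload.get("params_fingerprint", ""),
        )


def merge_pick_sets(sets: Sequence[PickSet]) -> PickSet:
    merged = PickSet(image_id=sets[0].image_id if sets else "",
                     params_fingerprint=sets[0].params_fingerprint if sets else "")
    for s in sets:
        merged.picks.extend(s.picks)
    return merged
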