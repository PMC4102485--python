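"""Domain types: ellipses, 3-curve diagrams, region areas and quantities.

Label conventions used throughout the package:

* curves are labelled ``a``, ``b``, ``c``;
* the seven regions interior to the curves are labelled, in canonical order,
  ``a, b, c, ab, ac, bc, abc`` -- a region label names exactly the curves the
  region lies inside.

Geometry lives in abstract canvas units: the y axis increases upward and
angles are counter-clockwise radians.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping

import numpy as np

CURVE_LABELS = ("a", "b", "c")
REGION_LABELS = ("a", "b", "c", "ab", "ac", "bc", "abc")

#: per curve, the region labels whose union reconstructs the full curve
CURVE_REGIONS = {
    "a": ("a", "ab", "ac", "abc"),
    "b": ("b", "ab", "bc", "abc"),
    "c": ("c", "ac", "bc", "abc"),
}

#: pair region between two curves, keyed by frozenset of curve labels
PAIR_REGION = {
    frozenset("ab"): "ab",
    frozenset("ac"): "ac",
    frozenset("bc"): "bc",
}


@dataclass(frozen=True)
class Ellipse:
    """An ellipse: centre, semi-axes and counter-clockwise rotation.

    ``s1`` is the semi-axis along the rotated x direction.  The rotation is
    stored canonically in ``[0, pi)`` since an ellipse is invariant under a
    half-turn of its axes.
    """

    cx: float
    cy: float
    s1: float
    s2: float
    theta: float = 0.0

    def __post_init__(self) -> None:
        if not (self.s1 > 0 and self.s2 > 0):
            raise ValueError("semi-axes must be strictly positive")
        object.__setattr__(self, "theta", float(self.theta) % np.pi)

    @property
    def area(self) -> float:
        return float(np.pi * self.s1 * self.s2)

    def to_array(self) -> np.ndarray:
        return np.array([self.cx, self.cy, self.s1, self.s2, self.theta], dtype=float)

    @classmethod
    def from_array(cls, arr: Iterable[float]) -> "Ellipse":
        cx, cy, s1, s2, theta = (float(v) for v in arr)
        return cls(cx, cy, s1, s2, theta)

    def translated(self, dx: float, dy: float) -> "Ellipse":
        return Ellipse(self.cx + dx, self.cy + dy, self.s1, self.s2, self.theta)

    def scaled(self, k: float) -> "Ellipse":
        """Uniform scaling about the origin."""
        return Ellipse(self.cx * k, self.cy * k, self.s1 * k, self.s2 * k, self.theta)


@dataclass(frozen=True)
class VennDiagram3:
    """Three labelled ellipses forming a candidate 3-Venn diagram."""

    ellipses: Dict[str, Ellipse]

    def __post_init__(self) -> None:
        if tuple(sorted(self.ellipses)) != CURVE_LABELS:
            raise ValueError("diagram needs exactly the three curves a, b, c")

    def __getitem__(self, label: str) -> Ellipse:
        return self.ellipses[label]

    def to_array(self) -> np.ndarray:
        return np.stack([self.ellipses[lab].to_array() for lab in CURVE_LABELS])

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "VennDiagram3":
        return cls({lab: Ellipse.from_array(arr[i]) for i, lab in enumerate(CURVE_LABELS)})

    def translated(self, dx: float, dy: float) -> "VennDiagram3":
        return VennDiagram3({k: e.translated(dx, dy) for k, e in self.ellipses.items()})

    def scaled(self, k: float) -> "VennDiagram3":
        return VennDiagram3({k2: e.scaled(k) for k2, e in self.ellipses.items()})


@dataclass(frozen=True)
class RegionAreas:
    """The seven interior region areas of a diagram plus its topology verdict.

    ``valid`` is True iff the configuration realizes the 3-Venn topology:
    every pair of curves crosses transversally in exactly two points, every
    region is present above a positivity floor, and every region is a single
    connected zone.  ``diagnostic`` names the first failed condition.
    """

    areas: Dict[str, float]
    valid: bool
    diagnostic: str = ""

    def __post_init__(self) -> None:
        if tuple(self.areas) != REGION_LABELS:
            object.__setattr__(
                self, "areas", {lab: self.areas[lab] for lab in REGION_LABELS}
            )
        if any(v < 0 for v in self.areas.values()):
            raise ValueError("region areas must be non-negative")

    def __getitem__(self, label: str) -> float:
        return self.areas[label]

    @property
    def total(self) -> float:
        return float(sum(self.areas.values()))

    def to_array(self) -> np.ndarray:
        return np.array([self.areas[lab] for lab in REGION_LABELS], dtype=float)

    def curve_area(self, curve: str) -> float:
        """Reconstructed full area of one curve from its four regions."""
        return float(sum(self.areas[r] for r in CURVE_REGIONS[curve]))


@dataclass(frozen=True)
class Quantities7:
    """Seven strictly positive required quantities, one per interior region."""

    q: Dict[str, float]

    def __post_init__(self) -> None:
        if sorted(self.q) != sorted(REGION_LABELS):
            missing = set(REGION_LABELS) - set(self.q)
            extra = set(self.q) - set(REGION_LABELS)
            raise ValueError(
                f"quantities must be keyed by {REGION_LABELS}; "
                f"missing={sorted(missing)} unexpected={sorted(extra)}"
            )
        for lab in REGION_LABELS:
            v = float(self.q[lab])
            if not v > 0:
                raise ValueError(f"quantity {lab!r} must be > 0, got {v}")
        object.__setattr__(self, "q", {lab: float(self.q[lab]) for lab in REGION_LABELS})

    def __getitem__(self, label: str) -> float:
        return self.q[label]

    def to_array(self) -> np.ndarray:
        return np.array([self.q[lab] for lab in REGION_LABELS], dtype=float)

    @classmethod
    def from_array(cls, arr: Iterable[float]) -> "Quantities7":
        vals = list(arr)
        return cls(dict(zip(REGION_LABELS, vals)))

    @classmethod
    def from_mapping(cls, m: Mapping[str, float]) -> "Quantities7":
        return cls({k.lower(): float(v) for k, v in m.items()})

    @property
    def total(self) -> float:
        return float(sum(self.q.values()))


@dataclass(frozen=True)
class FitResult:
    """Outcome of fitting a diagram to required quantities."""

    diagram: VennDiagram3
    diag_error: float
    accurate: bool
    iterations: int
    reruns_used: int
    mode: str = "ellipses"
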