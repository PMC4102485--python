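"""Analytic areas of the regions formed by three overlapping ellipses.

The region areas are computed exactly (up to root-finding accuracy) by
decomposing overlap boundaries into elliptical arcs and integrating
(x dy - y dx)/2 along them; see :mod:`areavenn._core` for the kernels.  A
Monte-Carlo estimator is provided as an independent testing oracle.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np

from . import _core
from .diagram import CURVE_LABELS, REGION_LABELS, Ellipse, RegionAreas, VennDiagram3

__all__ = [
    "ellipse_area",
    "intersect_ellipses",
    "pair_intersection_area",
    "triple_intersection_area",
    "region_areas",
    "validate_topology",
    "monte_carlo_region_areas",
]


def ellipse_area(e: Ellipse) -> float:
    """Area enclosed by an ellipse, pi * s1 * s2."""
    return e.area


def _coincident(e1: Ellipse, e2: Ellipse) -> bool:
    if (e1.cx, e1.cy) != (e2.cx, e2.cy):
        return False
    same = (e1.s1, e1.s2, e1.theta) == (e2.s1, e2.s2, e2.theta)
    swapped = (
        e1.s1 == e2.s2
        and e1.s2 == e2.s1
        and abs(abs(e1.theta - e2.theta) - np.pi / 2) < 1e-15
    )
    circle = e1.s1 == e1.s2 == e2.s1 == e2.s2
    return same or swapped or circle


def intersect_ellipses(e1: Ellipse, e2: Ellipse) -> List[Tuple[float, float]]:
    """Transversal-or-tangent boundary intersection points of two ellipses.

    Returns 0-4 deduplicated points lying on both boundaries.  Coincident
    ellipses have no isolated intersections and raise ``ValueError``.
    """
    if _coincident(e1, e2):
        raise ValueError("coincident ellipses have no isolated intersection points")
    pts, n, _ = _core._intersect_raw(e1.to_array(), e2.to_array())
    return [(float(pts[k, 0]), float(pts[k, 1])) for k in range(n)]


def pair_intersection_area(e1: Ellipse, e2: Ellipse) -> float:
    """Area of the overlap of two ellipses (0 when disjoint, analytic otherwise)."""
    a1, a2 = e1.to_array(), e2.to_array()
    if _coincident(e1, e2):
        return min(e1.area, e2.area)
    pts, n, _ = _core._intersect_raw(a1, a2)
    return float(_core._pair_area(a1, a2, pts, n))


def triple_intersection_area(e1: Ellipse, e2: Ellipse, e3: Ellipse) -> float:
    """Area of the three-way overlap e1 & e2 & e3."""
    d = np.stack([e1.to_array(), e2.to_array(), e3.to_array()])
    p12, n12, _ = _core._intersect_raw(d[0], d[1])
    p13, n13, _ = _core._intersect_raw(d[0], d[2])
    p23, n23, _ = _core._intersect_raw(d[1], d[2])
    i12 = _core._pair_area(d[0], d[1], p12, n12)
    i13 = _core._pair_area(d[0], d[2], p13, n13)
    i23 = _core._pair_area(d[1], d[2], p23, n23)
    return float(
        _core._triple_area(d, p12, n12, p13, n13, p23, n23, i12, i13, i23)
    )


def region_areas(d: VennDiagram3) -> RegionAreas:
    """The seven interior region areas of a diagram, with its topology verdict.

    Areas follow inclusion-exclusion over the analytic pairwise and triple
    overlap areas; tiny negative round-off values are clamped to zero.
    """
    arr, valid, consistent = _core._region_areas(d.to_array())
    diagnostic = "" if valid else _diagnose(d, arr)
    if not consistent:
        diagnostic = (diagnostic + "; " if diagnostic else "") + "numerical inconsistency"
    return RegionAreas(dict(zip(REGION_LABELS, map(float, arr))), bool(valid), diagnostic)


def _diagnose(d: VennDiagram3, areas: np.ndarray) -> str:
    arrs = d.to_array()
    pairs = (("a", "b", 0, 1), ("a", "c", 0, 2), ("b", "c", 1, 2))
    for la, lb, i, j in pairs:
        pts, n, trans = _core._intersect_raw(arrs[i], arrs[j])
        if n != 2:
            return f"curves {la},{lb} intersect in {n} points (need 2)"
        if not (trans[0] and trans[1]):
            return f"curves {la},{lb} touch tangentially"
    floor = _core._VALID_FLOOR_REL * float(areas.sum())
    for lab, v in zip(REGION_LABELS, areas):
        if v <= floor:
            return f"missing region {lab}"
    return "invalid topology"


def validate_topology(d: VennDiagram3) -> Tuple[bool, str]:
    """Check that a diagram realizes the 3-Venn topology.

    Requires every pair of curves to cross transversally in exactly two
    points and all seven regions to exceed a positivity floor of 1e-12 of
    the total area.  For three convex curves with pairwise two transversal
    crossings Euler's formula gives V=6, E=12 and hence exactly 8 faces, so
    presence of all seven signatures forces each region to be one connected
    zone -- no separate connectivity search is needed.

    Returns ``(flag, diagnostic)`` where the diagnostic names the first
    failed condition (empty when valid).
    """
    ra = region_areas(d)
    return ra.valid, ra.diagnostic


def monte_carlo_region_areas(
    d: VennDiagram3, n: int = 1_000_000, seed: int = 0
) -> Tuple[RegionAreas, dict]:
    """Monte-Carlo estimate of the region areas, the testing oracle.

    Uniform rejection sampling over the bounding box of the union; each
    sample is classified by the three interior-membership predicates.
    Returns the estimated areas plus a dict of per-region binomial standard
    errors.  Deterministic for a given seed.
    """
    if n < 1:
        raise ValueError("sample count must be >= 1")
    rng = np.random.default_rng(seed)
    los, his = [], []
    for lab in CURVE_LABELS:
        e = d[lab]
        ex = np.hypot(e.s1 * np.cos(e.theta), e.s2 * np.sin(e.theta))
        ey = np.hypot(e.s1 * np.sin(e.theta), e.s2 * np.cos(e.theta))
        los.append((e.cx - ex, e.cy - ey))
        his.append((e.cx + ex, e.cy + ey))
    lo = np.min(los, axis=0)
    hi = np.max(his, axis=0)
    box = float(np.prod(hi - lo))
    xs = rng.uniform(lo[0], hi[0], n)
    ys = rng.uniform(lo[1], hi[1], n)
    inside = []
    for lab in CURVE_LABELS:
        e = d[lab]
        dx, dy = xs - e.cx, ys - e.cy
        ct, st = np.cos(e.theta), np.sin(e.theta)
        u = ct * dx + st * dy
        v = -st * dx + ct * dy
        inside.append((u / e.s1) ** 2 + (v / e.s2) ** 2 < 1.0)
    ina, inb, inc = inside
    masks = {
        "a": ina & ~inb & ~inc,
        "b": ~ina & inb & ~inc,
        "c": ~ina & ~inb & inc,
        "ab": ina & inb & ~inc,
        "ac": ina & ~inb & inc,
        "bc": ~ina & inb & inc,
        "abc": ina & inb & inc,
    }
    areas, ses = {}, {}
    for lab in REGION_LABELS:
        k = int(masks[lab].sum())
        p = k / n
        areas[lab] = box * p
        ses[lab] = box * np.sqrt(max(p * (1 - p), 1.0 / n) / n)
    return RegionAreas(areas, valid=all(v > 0 for v in areas.values())), ses
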