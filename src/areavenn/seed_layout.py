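"""Deterministic starting diagram: three circles adapted to the data.

The hill climb needs a rational initial layout.  It is built from circles
(ellipses with equal semi-axes) so that the classic two-circle construction
can be used: the two curves with the largest required totals are drawn as
circles whose separation is found by bisection on the closed-form circular
lens area, which reproduces their pairwise overlap exactly.  The third circle
is then centred on the bisector of the angle between the tangents at the
upper intersection point of the first two, at the position along that line
that best matches the required triple-overlap area.  Rotations 0, pi/3 and
2*pi/3 are assigned to curves a, b, c so that the subsequent rotation moves
explore the whole angular space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from . import _core
from .diagram import (
    CURVE_LABELS,
    CURVE_REGIONS,
    PAIR_REGION,
    Ellipse,
    Quantities7,
    VennDiagram3,
)
from .metrics import scale_quantities

__all__ = [
    "BisectionSpec",
    "curve_totals",
    "largest_two",
    "circle_lens_area",
    "two_circle_layout",
    "place_third",
    "starting_diagram",
]

#: rotation assigned to each curve of the starting diagram
START_ROTATIONS = {"a": 0.0, "b": np.pi / 3.0, "c": 2.0 * np.pi / 3.0}


@dataclass(frozen=True)
class BisectionSpec:
    """Interval and convergence control for the layout line searches."""

    lo: float
    hi: float
    tol: float = 1e-10
    max_iter: int = 200

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("need lo < hi")
        if not self.tol > 0:
            raise ValueError("need tol > 0")


def curve_totals(w: Quantities7) -> Dict[str, float]:
    """Total required area per curve: own region + two pair regions + triple."""
    return {c: sum(w[r] for r in CURVE_REGIONS[c]) for c in CURVE_LABELS}


def largest_two(w: Quantities7) -> Tuple[str, str, str]:
    """The two curves with the largest totals (ties broken a < b < c), then the third."""
    totals = curve_totals(w)
    order = sorted(CURVE_LABELS, key=lambda c: (-totals[c], c))
    first, second, third = order
    return first, second, third


def circle_lens_area(r1: float, r2: float, d: float) -> float:
    """Closed-form overlap area of two circles with radii r1, r2 at distance d.

    Strictly decreasing in d on [|r1 - r2|, r1 + r2].
    """
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        return np.pi * min(r1, r2) ** 2
    x1 = np.clip((d * d + r1 * r1 - r2 * r2) / (2.0 * d * r1), -1.0, 1.0)
    x2 = np.clip((d * d + r2 * r2 - r1 * r1) / (2.0 * d * r2), -1.0, 1.0)
    tri = 0.5 * np.sqrt(
        max(0.0, (-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2))
    )
    return r1 * r1 * np.arccos(x1) + r2 * r2 * np.arccos(x2) - tri


def two_circle_layout(
    total1: float, total2: float, overlap: float, tol: float = 1e-10
) -> Tuple[Ellipse, Ellipse]:
    """Two circles with prescribed areas whose lens area equals ``overlap``.

    Radii are sqrt(total / pi); the separation is found by bisection of the
    monotone lens-area function (the exact two-circle construction).  The
    first circle sits at the origin, the second on the positive x axis.
    """
    if not (0.0 < overlap < min(total1, total2)):
        raise ValueError("overlap must be strictly between 0 and the smaller total")
    r1 = np.sqrt(total1 / np.pi)
    r2 = np.sqrt(total2 / np.pi)
    lo = abs(r1 - r2)
    hi = r1 + r2
    span = hi - lo
    f = lambda d: circle_lens_area(r1, r2, d) - overlap
    d = brentq(
        f, lo + 1e-14 * span, hi - 1e-14 * span, xtol=tol * span, maxiter=200
    )
    return Ellipse(0.0, 0.0, r1, r1), Ellipse(float(d), 0.0, r2, r2)


def _upper_intersection(e1: Ellipse, e2: Ellipse) -> Tuple[np.ndarray, np.ndarray]:
    if e1.s1 == e1.s2 and e2.s1 == e2.s2:
        # circle-circle: closed form, robust near internal tangency where the
        # general quartic machinery can lose the near-coincident point pair
        c1 = np.array([e1.cx, e1.cy])
        c2 = np.array([e2.cx, e2.cy])
        r1, r2 = e1.s1, e2.s1
        dv = c2 - c1
        dist = float(np.linalg.norm(dv))
        if not (abs(r1 - r2) < dist < r1 + r2):
            raise ValueError("the first two curves must intersect in two points")
        x0 = (dist * dist + r1 * r1 - r2 * r2) / (2.0 * dist)
        y0 = np.sqrt(max(0.0, r1 * r1 - x0 * x0))
        ux = dv / dist
        uy = np.array([-ux[1], ux[0]])
        p = np.array([c1 + x0 * ux + y0 * uy, c1 + x0 * ux - y0 * uy])
    else:
        pts, n, _ = _core._intersect_raw(e1.to_array(), e2.to_array())
        if n < 2:
            raise ValueError("the first two curves must intersect in two points")
        p = np.array([[pts[k, 0], pts[k, 1]] for k in range(n)])
    order = np.lexsort((p[:, 0], -p[:, 1]))  # largest y first, then smallest x
    return p[order[0]], p[order[-1]]


def _bisector_direction(
    e1: Ellipse, e2: Ellipse, i1: np.ndarray, i2: np.ndarray
) -> np.ndarray:
    """Unit direction of the tangent-angle bisector at i1, pointing into the lens."""
    into = i2 - i1
    dirs = []
    for e in (e1, e2):
        radial = i1 - np.array([e.cx, e.cy])
        t = np.array([-radial[1], radial[0]])
        t /= np.linalg.norm(t)
        if t @ into < 0:
            t = -t
        dirs.append(t)
    v = dirs[0] + dirs[1]
    nv = np.linalg.norm(v)
    if nv < 1e-12:  # tangents anti-parallel; fall back to the chord direction
        v = into
        nv = np.linalg.norm(v)
    return v / nv


def place_third(
    e1: Ellipse,
    e2: Ellipse,
    w_scaled: Quantities7,
    third_total: float,
    third_required: float,
    tol: float = 1e-6,
    region_targets: Optional[np.ndarray] = None,
) -> Ellipse:
    """Position the third circle along the tangent-angle bisector.

    The centre moves on the line L through the upper intersection point of
    e1 and e2, bisecting the angle between their tangents there.  The valid
    sub-interval (u, l) of L -- positions where the circle crosses both e1
    and e2 twice and all seven regions exist -- is located by marching in
    steps of r3/50; within it, the positions minimizing the triple-overlap
    discrepancy |A(abc) - w'(abc)| are found by bounded golden-section/Brent
    refinement of the bracketed grid minima (the discrepancy is an absolute
    value, so a signed bisection does not apply).

    When the required triple overlap is attainable the discrepancy has two
    zeros -- a shallow and a deep placement of the third circle -- and the
    minimization criterion alone does not distinguish them.  If
    ``region_targets`` (the seven required region quantities in this
    arrangement's row order e1, e2, e3) is given, near-tied minima are
    disambiguated by the full starting diagram's diagError; otherwise the
    smallest-discrepancy position is returned.
    """
    r3 = np.sqrt(third_total / np.pi)
    i1, i2 = _upper_intersection(e1, e2)
    direction = _bisector_direction(e1, e2, i1, i2)

    base = np.empty((3, 5))
    base[0] = e1.to_array()
    base[1] = e2.to_array()

    def diagram_at(s: float) -> np.ndarray:
        c3 = i1 + s * direction
        base[2] = (c3[0], c3[1], r3, r3, 0.0)
        return base

    def valid_at(s: float) -> bool:
        _, valid, _ = _core._region_areas(diagram_at(s))
        return bool(valid)

    def discrepancy(s: float) -> float:
        areas, _, _ = _core._region_areas(diagram_at(s))
        return abs(areas[6] - third_required)

    # march along L to locate the valid interval (u, l).  Isolated degenerate
    # positions (the third boundary grazing a crossing of e1 and e2) can
    # split it momentarily, so the discrepancy is scanned over every valid
    # position rather than only the first contiguous stretch.
    step = r3 / 50.0
    s_max = max(
        np.linalg.norm(i1 - np.array([e.cx, e.cy])) + e.s1 for e in (e1, e2)
    ) + r3
    # the interval straddles i1: its upper endpoint u can lie above the
    # intersection point (the circle dipping into the lens from outside)
    grid = np.arange(-s_max, s_max + step, step)
    flags = np.empty(len(grid), dtype=bool)
    vals = np.empty(len(grid))
    for i, s in enumerate(grid):
        areas, valid, _ = _core._region_areas(diagram_at(s))
        flags[i] = bool(valid)
        vals[i] = abs(areas[6] - third_required) if valid else np.inf
    if not flags.any():
        warnings.warn(
            "no valid position for the third curve on the bisector; "
            "falling back to the lens midpoint",
            RuntimeWarning,
        )
        mid = 0.5 * (i1 + i2)
        return Ellipse(float(mid[0]), float(mid[1]), r3, r3)

    # |A(abc) - target| is W-shaped when the target is attainable (the triple
    # overlap rises then falls along L): bracket every local minimum on the
    # march grid, refine the best few by golden-section/Brent
    brackets = [
        i
        for i in range(len(grid))
        if np.isfinite(vals[i])
        and (i == 0 or vals[i] <= vals[i - 1])
        and (i == len(grid) - 1 or vals[i] <= vals[i + 1])
    ]
    brackets.sort(key=lambda i: vals[i])
    candidates = []  # (refined discrepancy, s)
    for i in brackets[:3]:
        lo = grid[max(0, i - 1)]
        hi = grid[min(len(grid) - 1, i + 1)]
        if lo >= hi:
            lo, hi = grid[i] - 0.5 * step, grid[i] + 0.5 * step
        res = minimize_scalar(
            discrepancy,
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": tol * 2.0 * s_max, "maxiter": 200},
        )
        s_ref = float(res.x)
        if res.fun <= vals[i] and valid_at(s_ref):
            candidates.append((float(res.fun), s_ref))
        else:
            candidates.append((float(vals[i]), float(grid[i])))
    best_disc = min(f for f, _ in candidates)
    near = [
        (f, s)
        for f, s in candidates
        if f <= best_disc + 0.01 * max(third_required, 1.0)
    ]
    if region_targets is not None and len(near) > 1:
        scored = []
        for f, s in near:
            areas, valid, _ = _core._region_areas(diagram_at(s))
            de = _core._diag_error(areas, region_targets) if valid else np.inf
            scored.append((de, f, s))
        s_opt = min(scored)[2]
    else:
        s_opt = min(near)[1]
    c3 = i1 + s_opt * direction
    return Ellipse(float(c3[0]), float(c3[1]), r3, r3)


def starting_diagram(w: Quantities7) -> VennDiagram3:
    """Assemble the deterministic three-circle starting diagram for ``w``.

    Identical (and proportional) inputs always give the identical diagram.
    """
    wp = scale_quantities(w)
    first, second, third = largest_two(wp)
    totals = curve_totals(wp)
    pair = PAIR_REGION[frozenset((first, second))]
    overlap = wp[pair] + wp["abc"]
    c1, c2 = two_circle_layout(totals[first], totals[second], overlap)
    # required region quantities in the construction's row order (e1, e2, e3),
    # used to break ties between equally good third-circle placements
    region = lambda *cs: "".join(sorted(cs))
    targets = np.array(
        [
            wp[first],
            wp[second],
            wp[third],
            wp[region(first, second)],
            wp[region(first, third)],
            wp[region(second, third)],
            wp["abc"],
        ]
    )
    c3 = place_third(c1, c2, wp, totals[third], wp["abc"], region_targets=targets)
    placed = {first: c1, second: c2, third: c3}
    return VennDiagram3(
        {
            lab: Ellipse(
                placed[lab].cx,
                placed[lab].cy,
                placed[lab].s1,
                placed[lab].s2,
                START_ROTATIONS[lab],
            )
            for lab in CURVE_LABELS
        }
    )
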