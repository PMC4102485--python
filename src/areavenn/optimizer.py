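"""Hill-climbing search over ellipse parameters with a halving cooling schedule.

Starting from the rational three-circle layout, the optimizer sweeps the
curves in the fixed order a, b, c and, for each, explores candidate centres
(eight compass offsets of ``p_gamma``), semi-axes (eight +/- ``p_alphabeta``
percentage combinations) and rotations (theta +/- ``p_theta``).  Candidate
lists are computed from the ellipse state at the start of each block and
applied greedily and cumulatively: every candidate that strictly reduces the
F6 cost while keeping a valid 3-Venn topology is accepted immediately.  At
the end of an iteration, any parameter whose property class saw no accepted
change on any ellipse is halved; the run stops as accurate as soon as the
diagram is good, or as inaccurate once all three parameters fall below 1e-6.

A run that ends inaccurate hit a local minimum.  With the rerun option the
whole search is restarted from a fresh starting diagram with all three
initial step parameters 20% larger than in the previous run (compounding),
up to 10 times; the best diagram by diagError over all runs is returned.
The search has no randomness: identical quantities give identical results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List

import numpy as np

from . import _core
from .diagram import Ellipse, FitResult, Quantities7, VennDiagram3
from .geometry import region_areas
from .metrics import GOOD_EPS, diag_error, is_good, scale_quantities
from .seed_layout import starting_diagram

logger = logging.getLogger(__name__)

__all__ = [
    "SearchParams",
    "candidate_centres",
    "candidate_semiaxes",
    "candidate_rotations",
    "hill_climb",
    "fit",
]

#: termination threshold on the cooled step parameters
PARAM_EPS = 1e-6
#: hard safety cap on iterations within one run (never reached in practice)
MAX_ITER = 200_000
#: growth factor applied to the start parameters on each rerun
RERUN_GROWTH = 1.2
#: maximum number of reruns after the first run
MAX_RERUNS = 10


@dataclass(frozen=True)
class SearchParams:
    """Initial step sizes of the three move classes.

    ``p_gamma`` is the centre offset in canvas units, ``p_alphabeta`` the
    semi-axis scaling fraction, ``p_theta`` the rotation step in radians.
    The defaults (10 units, 5%, 2*pi/3) are commensurate with diagrams in
    which the smallest required region has area 100.
    """

    p_gamma: float = 10.0
    p_alphabeta: float = 0.05
    p_theta: float = 2.0 * np.pi / 3.0

    def __post_init__(self) -> None:
        if min(self.p_gamma, self.p_alphabeta, self.p_theta) <= 0:
            raise ValueError("all search parameters must be > 0")

    def grown(self, factor: float) -> "SearchParams":
        return SearchParams(
            self.p_gamma * factor, self.p_alphabeta * factor, self.p_theta * factor
        )


def candidate_centres(e: Ellipse, p_gamma: float) -> List[Ellipse]:
    """Eight centre moves in fixed order E, W, N, S, NE, NW, SE, SW."""
    if not p_gamma > 0:
        raise ValueError("p_gamma must be > 0")
    p = p_gamma
    offs = [(p, 0), (-p, 0), (0, p), (0, -p), (p, p), (-p, p), (p, -p), (-p, -p)]
    return [Ellipse(e.cx + dx, e.cy + dy, e.s1, e.s2, e.theta) for dx, dy in offs]


def candidate_semiaxes(e: Ellipse, p_alphabeta: float) -> List[Ellipse]:
    """Eight semi-axis scalings: single axis, same-sign pair, opposite-sign pair."""
    if not 0 < p_alphabeta < 1:
        raise ValueError("p_alphabeta must be in (0, 1)")
    up, dn = 1.0 + p_alphabeta, 1.0 - p_alphabeta
    combos = [
        (up, 1.0),
        (dn, 1.0),
        (1.0, up),
        (1.0, dn),
        (up, up),
        (dn, dn),
        (up, dn),
        (dn, up),
    ]
    return [Ellipse(e.cx, e.cy, e.s1 * f1, e.s2 * f2, e.theta) for f1, f2 in combos]


def candidate_rotations(e: Ellipse, p_theta: float) -> List[Ellipse]:
    """The two rotation moves theta +/- p_theta, renormalized into [0, pi)."""
    if not p_theta > 0:
        raise ValueError("p_theta must be > 0")
    return [
        Ellipse(e.cx, e.cy, e.s1, e.s2, (e.theta + p_theta) % np.pi),
        Ellipse(e.cx, e.cy, e.s1, e.s2, (e.theta - p_theta) % np.pi),
    ]


def hill_climb(
    w: Quantities7,
    start: VennDiagram3,
    params: SearchParams | None = None,
    mode: str = "ellipses",
    _allow_invalid_start: bool = False,
) -> FitResult:
    """Run one greedy hill climb from ``start``; see the module docstring.

    In ``circles`` mode the semi-axis candidates reduce to the two uniform
    scalings and rotation moves are skipped, so the curves stay circles.
    Raises ``ValueError`` for an invalid starting diagram.
    """
    if mode not in ("ellipses", "circles"):
        raise ValueError(f"unknown mode {mode!r}")
    params = params or SearchParams()
    start_areas = region_areas(start)
    if not start_areas.valid and not _allow_invalid_start:
        raise ValueError(f"invalid starting diagram: {start_areas.diagnostic}")
    start_de = diag_error(start_areas, w)
    if start_areas.valid and start_de <= GOOD_EPS:
        return FitResult(start, start_de, True, 0, 0, mode)
    wp = scale_quantities(w)
    d_arr, iters, accurate, trace, ntr, areas = _core._hill_climb(
        start.to_array(),
        w.to_array(),
        wp.to_array(),
        params.p_gamma,
        params.p_alphabeta,
        params.p_theta,
        mode == "circles",
        PARAM_EPS,
        GOOD_EPS,
        MAX_ITER,
        1_000_000,
    )
    if logger.isEnabledFor(logging.DEBUG):
        logger.debug(
            "hill climb: %d iterations, %d accepted moves, final cost %.6g",
            iters,
            ntr,
            trace[ntr - 1] if ntr else float("nan"),
        )
    final = VennDiagram3.from_array(d_arr)
    de = float(_core._diag_error(areas, w.to_array()))
    return FitResult(final, de, bool(accurate), int(iters), 0, mode)


def cost_trace(
    w: Quantities7,
    start: VennDiagram3,
    params: SearchParams | None = None,
    mode: str = "ellipses",
) -> np.ndarray:
    """The F6 cost after every accepted move of one run (an audit log)."""
    params = params or SearchParams()
    wp = scale_quantities(w)
    _, _, _, trace, ntr, _ = _core._hill_climb(
        start.to_array(),
        w.to_array(),
        wp.to_array(),
        params.p_gamma,
        params.p_alphabeta,
        params.p_theta,
        mode == "circles",
        PARAM_EPS,
        GOOD_EPS,
        MAX_ITER,
        1_000_000,
    )
    return trace[:ntr].copy()


def fit(
    w: Quantities7,
    rerun: bool = True,
    mode: str = "ellipses",
    params: SearchParams | None = None,
) -> FitResult:
    """Fit an area-proportional 3-Venn diagram to seven positive quantities.

    Runs the hill climb from the rational starting diagram; if the result is
    not accurate and ``rerun`` is enabled, restarts with 20%-larger initial
    step parameters, up to 10 times, returning the first accurate result or
    the best diagram by diagError over all runs.
    """
    base = params or SearchParams()
    start = starting_diagram(w)
    total_iters = 0
    best: FitResult | None = None
    n_runs = 1 + (MAX_RERUNS if rerun else 0)
    for run in range(n_runs):
        run_params = base.grown(RERUN_GROWTH**run)
        result = hill_climb(w, start, run_params, mode, _allow_invalid_start=True)
        total_iters += result.iterations
        if best is None or result.diag_error < best.diag_error:
            best = result
        if result.accurate:
            best = result
            return FitResult(
                best.diagram, best.diag_error, True, total_iters, run, mode
            )
    assert best is not None
    return FitResult(
        best.diagram, best.diag_error, False, total_iters, n_runs - 1, mode
    )
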