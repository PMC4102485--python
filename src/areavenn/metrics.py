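"""Quantity scaling, diagram error measures and optimization cost functions.

The accuracy of a candidate diagram is judged on *proportions*: for each
region r, ``regionError(r) = |A(r)/sum(A) - w(r)/sum(w)|`` and the diagram
error ``diagError`` aggregates the seven region errors by their maximum.  A
diagram is *good* when its topology is valid and ``diagError <= 1e-6``.

The optimizer itself minimizes the cost ``F6 = mean_r (w'(r) - A(r))^2 / A(r)``
over quantities scaled so the smallest required region area is 100.  Dividing
by the actual area makes the cost blow up as any region collapses, which
steers the hill climb away from the classic local minimum in which the total
error is reduced by squeezing one region to nothing.  Two dimensionless
variants (F7, F8) and the venneuler-style stress are provided for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np

from . import _core
from .diagram import Quantities7, RegionAreas, REGION_LABELS, VennDiagram3
from .geometry import region_areas

#: goodness threshold on diagError
GOOD_EPS = 1e-6

__all__ = [
    "GOOD_EPS",
    "ErrorReport",
    "scale_quantities",
    "region_error",
    "diag_error",
    "error_report",
    "is_good",
    "cost_F6",
    "cost_F7",
    "cost_F8",
    "stress",
]


@dataclass(frozen=True)
class ErrorReport:
    """Per-region and diagram-level proportional errors."""

    region_errors: Dict[str, float]
    diag_error: float
    good: bool


def scale_quantities(w: Quantities7) -> Quantities7:
    """Scale quantities by 100 / min(w) so the smallest becomes exactly 100.

    Proportional inputs map to identical outputs, which is what makes the
    whole fit invariant under rescaling of the data.
    """
    arr = w.to_array()
    factor = 100.0 / arr.min()
    scaled = arr * factor
    # quantize to 12 significant digits so proportional inputs yield
    # bit-identical scaled quantities (the greedy search is sensitive to
    # last-ulp noise); the perturbation is ~1e-12 relative, far below the
    # 1e-6 goodness threshold
    return Quantities7.from_array([float(f"{v:.12g}") for v in scaled])


def _check_totals(areas: RegionAreas, w: Quantities7) -> None:
    if not areas.total > 0:
        raise ValueError("total diagram area must be positive")
    if not w.total > 0:
        raise ValueError("total quantity must be positive")


def region_error(label: str, areas: RegionAreas, w: Quantities7) -> float:
    """|A(r)/sum(A) - w(r)/sum(w)| for one region; always in [0, 1]."""
    _check_totals(areas, w)
    return abs(areas[label] / areas.total - w[label] / w.total)


def diag_error(areas: RegionAreas, w: Quantities7) -> float:
    """Maximum regionError over the seven regions; always in [0, 1]."""
    _check_totals(areas, w)
    return float(_core._diag_error(areas.to_array(), w.to_array()))


def error_report(areas: RegionAreas, w: Quantities7) -> ErrorReport:
    errs = {lab: region_error(lab, areas, w) for lab in REGION_LABELS}
    de = max(errs.values())
    return ErrorReport(errs, de, areas.valid and de <= GOOD_EPS)


def is_good(d: VennDiagram3, w: Quantities7) -> bool:
    """True iff the diagram has valid 3-Venn topology and diagError <= 1e-6."""
    areas = region_areas(d)
    return areas.valid and diag_error(areas, w) <= GOOD_EPS


def cost_F6(areas: RegionAreas, w_scaled: Quantities7) -> float:
    """mean_r (w'(r) - A(r))^2 / A(r); +inf sentinel when a region collapsed."""
    c = float(_core._cost_f6(areas.to_array(), w_scaled.to_array()))
    return np.inf if c >= _core.BIG_COST else c


def cost_F7(areas: RegionAreas, w_scaled: Quantities7) -> float:
    """Dimensionless variant: mean_r (w'(r) - A(r))^2 / A(r)^2."""
    a = areas.to_array()
    if np.any(a <= 0):
        return np.inf
    wp = w_scaled.to_array()
    return float(np.mean((wp - a) ** 2 / a**2))


def cost_F8(areas: RegionAreas, w_scaled: Quantities7) -> float:
    """Dimensionless variant: mean_r |w'(r) - A(r)| / A(r)."""
    a = areas.to_array()
    if np.any(a <= 0):
        return np.inf
    wp = w_scaled.to_array()
    return float(np.mean(np.abs(wp - a) / a))


def stress(areas: RegionAreas, w: Quantities7) -> float:
    """venneuler-style normalized loss.

    Areas are regressed on quantities through the origin
    (beta = sum(A w) / sum(w^2)) and the residual sum of squares is divided
    by the total sum of squares of the areas, so the value is in [0, 1] and
    is 0 iff areas are exactly proportional to the quantities.
    """
    a = areas.to_array()
    wv = w.to_array()
    ssa = float(a @ a)
    if ssa == 0:
        raise ValueError("stress undefined for an all-zero area vector")
    beta = float(a @ wv) / float(wv @ wv)
    return float(((a - beta * wv) ** 2).sum() / ssa)
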