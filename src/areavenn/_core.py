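"""Numba kernels for ellipse-arrangement geometry and the hill-climb inner loop.

Everything here works on plain float64 arrays so it can be jitted:

* an ellipse is a length-5 vector ``[cx, cy, s1, s2, theta]``;
* a diagram is a ``(3, 5)`` array, rows in curve order a, b, c;
* region areas are a length-7 vector in label order a, b, c, ab, ac, bc, abc.

The public, typed API lives in :mod:`areavenn.geometry` and
:mod:`areavenn.optimizer`; this module is private.

Boundary intersections are found by mapping one ellipse to the unit circle,
expressing the other as an implicit conic in that frame, and solving the
resulting quartic through companion-matrix eigenvalues (robust where the
closed-form quartic is ill-conditioned), followed by a 2x2 Newton polish on
the pair of implicit equations.  Areas of overlap regions come from exact
elliptical-arc line integrals of (x dy - y dx)/2 (Green's theorem), so the
region areas are analytic up to root-finding accuracy.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# tolerances (see docs/methods.md)
_ROOT_IMAG_TOL = 1e-8  # relative imaginary part below which a root is real
_DEDUP_TOL = 1e-9  # point merge distance in the unit-circle frame
_TRANSVERSAL_TOL = 1e-9  # sine of the crossing angle below which = tangency
_VALID_FLOOR_REL = 1e-12  # region-positivity floor, fraction of total area
_NEG_CLAMP_REL = 1e-9  # allowed negative round-off, fraction of total area

BIG_COST = 1e300  # sentinel for an invalid / collapsed diagram


@njit(cache=True)
def _conic(e):
    """Implicit conic A x^2 + B xy + C y^2 + D x + E y + F with interior < 0."""
    cx, cy, s1, s2, th = e[0], e[1], e[2], e[3], e[4]
    ct = np.cos(th)
    st = np.sin(th)
    i1 = 1.0 / (s1 * s1)
    i2 = 1.0 / (s2 * s2)
    a = ct * ct * i1 + st * st * i2
    b = 2.0 * ct * st * (i1 - i2)
    c = st * st * i1 + ct * ct * i2
    d = -2.0 * a * cx - b * cy
    ee = -b * cx - 2.0 * c * cy
    f = a * cx * cx + b * cx * cy + c * cy * cy - 1.0
    return a, b, c, d, ee, f


@njit(cache=True)
def _gval(e, x, y):
    """(u/s1)^2 + (v/s2)^2 in the ellipse frame; < 1 inside, = 1 on boundary."""
    dx = x - e[0]
    dy = y - e[1]
    ct = np.cos(e[4])
    st = np.sin(e[4])
    u = ct * dx + st * dy
    v = -st * dx + ct * dy
    return (u / e[2]) ** 2 + (v / e[3]) ** 2


@njit(cache=True)
def _param_of(e, x, y):
    """Parametric angle t of a boundary point: P(t) = c + R(theta).(s1 cos t, s2 sin t)."""
    dx = x - e[0]
    dy = y - e[1]
    ct = np.cos(e[4])
    st = np.sin(e[4])
    u = ct * dx + st * dy
    v = -st * dx + ct * dy
    return np.arctan2(v / e[3], u / e[2])


@njit(cache=True)
def _boundary_point(e, t):
    ct = np.cos(e[4])
    st = np.sin(e[4])
    qx = e[2] * np.cos(t)
    qy = e[3] * np.sin(t)
    return e[0] + ct * qx - st * qy, e[1] + st * qx + ct * qy


@njit(cache=True)
def _arc_area(e, t0, t1):
    """Exact line integral (x dy - y dx)/2 along the ccw boundary arc t0 -> t1.

    For P(t) = c + Q(t) with Q an ellipse through the origin, the integrand
    splits into the sector term s1*s2*(t1 - t0) and the chord correction
    c x (Q(t1) - Q(t0)).
    """
    if t1 <= t0:
        t1 += 2.0 * np.pi
    ct = np.cos(e[4])
    st = np.sin(e[4])
    q0x = e[2] * np.cos(t0)
    q0y = e[3] * np.sin(t0)
    q1x = e[2] * np.cos(t1)
    q1y = e[3] * np.sin(t1)
    # rotate offsets to world orientation
    w0x = ct * q0x - st * q0y
    w0y = st * q0x + ct * q0y
    w1x = ct * q1x - st * q1y
    w1y = st * q1x + ct * q1y
    sector = e[2] * e[3] * (t1 - t0)
    chord = e[0] * (w1y - w0y) - e[1] * (w1x - w0x)
    return 0.5 * (sector + chord)


@njit(cache=True)
def _real_roots(coef):
    """Real roots of a polynomial of degree <= 4 given coefficients, highest first."""
    n = coef.shape[0]
    scale = 0.0
    for i in range(n):
        a = abs(coef[i])
        if a > scale:
            scale = a
    out = np.empty(4)
    m = 0
    if scale == 0.0:
        return out[:0]
    lead = 0
    while lead < n - 1 and abs(coef[lead]) <= 1e-14 * scale:
        lead += 1
    deg = n - 1 - lead
    if deg == 0:
        return out[:0]
    if deg == 1:
        out[0] = -coef[lead + 1] / coef[lead]
        return out[:1]
    if deg == 2:
        a = coef[lead]
        b = coef[lead + 1]
        c = coef[lead + 2]
        disc = b * b - 4.0 * a * c
        # circle-circle pairs reduce to a perfect square (disc = 0 exactly in
        # real arithmetic); tolerate round-off so the double root is not lost
        dtol = 1e-10 * (b * b + abs(4.0 * a * c))
        if disc < -dtol:
            return out[:0]
        if disc < dtol:
            out[0] = -0.5 * b / a
            return out[:1]
        sq = np.sqrt(disc)
        # Citardauq form avoids cancellation
        q = -0.5 * (b + np.sign(b) * sq) if b != 0.0 else -0.5 * sq
        if q != 0.0:
            out[0] = q / a
            out[1] = c / q
        else:
            out[0] = 0.0
            out[1] = 0.0
        return out[:2]
    # degree 3 or 4: companion-matrix eigenvalues (complex dtype: the roots
    # of the quartic are complex in general)
    comp = np.zeros((deg, deg), dtype=np.complex128)
    for i in range(1, deg):
        comp[i, i - 1] = 1.0
    for i in range(deg):
        comp[i, deg - 1] = -coef[lead + deg - i] / coef[lead]
    ev = np.linalg.eigvals(comp)
    for k in range(deg):
        re = ev[k].real
        im = ev[k].imag
        if abs(im) <= _ROOT_IMAG_TOL * (1.0 + abs(re)):
            out[m] = re
            m += 1
    return out[:m]


@njit(cache=True)
def _intersect_raw(e1, e2):
    """Boundary intersection points of two ellipses.

    Returns (pts, n, transversal) where pts is (4, 2) world coordinates with
    the first n rows valid and transversal[i] flags a genuine crossing.
    """
    pts = np.empty((4, 2))
    trans = np.zeros(4, dtype=np.bool_)
    cx, cy, s1, s2, th = e1[0], e1[1], e1[2], e1[3], e1[4]
    ct = np.cos(th)
    st = np.sin(th)
    # affine map q -> world: p = c + Aq, columns scaled rotation
    a11 = ct * s1
    a12 = -st * s2
    a21 = st * s1
    a22 = ct * s2
    ca, cb, cc, cd, ce, cf = _conic(e2)
    # conic of e2 in the q-frame of e1: Q = T^T M T
    m = np.empty((3, 3))
    m[0, 0] = ca
    m[0, 1] = 0.5 * cb
    m[0, 2] = 0.5 * cd
    m[1, 0] = 0.5 * cb
    m[1, 1] = cc
    m[1, 2] = 0.5 * ce
    m[2, 0] = 0.5 * cd
    m[2, 1] = 0.5 * ce
    m[2, 2] = cf
    t = np.empty((3, 3))
    t[0, 0] = a11
    t[0, 1] = a12
    t[0, 2] = cx
    t[1, 0] = a21
    t[1, 1] = a22
    t[1, 2] = cy
    t[2, 0] = 0.0
    t[2, 1] = 0.0
    t[2, 2] = 1.0
    q = t.T @ m @ t
    A = q[0, 0]
    B = 2.0 * q[0, 1]
    C = q[1, 1]
    D = 2.0 * q[0, 2]
    E = 2.0 * q[1, 2]
    F = q[2, 2]
    nrm = max(abs(A), abs(B), abs(C), abs(D), abs(E), abs(F))
    if nrm == 0.0:
        return pts, 0, trans
    A /= nrm
    B /= nrm
    C /= nrm
    D /= nrm
    E /= nrm
    F /= nrm
    # substitute y^2 = 1 - x^2 into the conic:
    #   (1 - x^2)(Bx + E)^2 = ((A - C)x^2 + Dx + (C + F))^2
    ac = A - C
    cf2 = C + F
    coef = np.empty(5)
    coef[0] = -B * B - ac * ac
    coef[1] = -2.0 * B * E - 2.0 * ac * D
    coef[2] = B * B - E * E - D * D - 2.0 * ac * cf2
    coef[3] = 2.0 * B * E - 2.0 * D * cf2
    coef[4] = E * E - cf2 * cf2
    roots = _real_roots(coef)
    # collect candidate (x, y) on the unit circle
    cand = np.empty((8, 2))
    nc = 0
    for i in range(roots.shape[0]):
        x = roots[i]
        if abs(x) > 1.0 + 1e-8:
            continue
        if x > 1.0:
            x = 1.0
        if x < -1.0:
            x = -1.0
        denom = B * x + E
        num = ac * x * x + D * x + cf2
        if abs(denom) > 1e-10:
            y = -num / denom
            cand[nc, 0] = x
            cand[nc, 1] = y
            nc += 1
        else:
            yy = np.sqrt(max(0.0, 1.0 - x * x))
            for sgn in (1.0, -1.0):
                y = sgn * yy
                res = A * x * x + B * x * y + C * y * y + D * x + E * y + F
                if abs(res) < 1e-6:
                    cand[nc, 0] = x
                    cand[nc, 1] = y
                    nc += 1
                if yy == 0.0:
                    break
    # Newton polish on (unit circle, conic) and validity filter
    n = 0
    for i in range(nc):
        x = cand[i, 0]
        y = cand[i, 1]
        ok = True
        for _ in range(8):
            f1 = x * x + y * y - 1.0
            f2 = A * x * x + B * x * y + C * y * y + D * x + E * y + F
            if abs(f1) < 1e-14 and abs(f2) < 1e-14:
                break
            j11 = 2.0 * x
            j12 = 2.0 * y
            j21 = 2.0 * A * x + B * y + D
            j22 = B * x + 2.0 * C * y + E
            det = j11 * j22 - j12 * j21
            if abs(det) < 1e-300:
                break
            dx = (f1 * j22 - f2 * j12) / det
            dy = (j11 * f2 - j21 * f1) / det
            x -= dx
            y -= dy
        f1 = x * x + y * y - 1.0
        f2 = A * x * x + B * x * y + C * y * y + D * x + E * y + F
        if abs(f1) > 1e-7 or abs(f2) > 1e-7:
            ok = False
        if not ok:
            continue
        # dedupe in the normalized frame
        dup = False
        for k in range(n):
            qx = pts[k, 0]
            qy = pts[k, 1]
            if (qx - x) ** 2 + (qy - y) ** 2 < _DEDUP_TOL * _DEDUP_TOL:
                dup = True
                break
        if dup or n == 4:
            continue
        pts[n, 0] = x
        pts[n, 1] = y
        # transversality: angle between the two curve gradients
        g1x = 2.0 * x
        g1y = 2.0 * y
        g2x = 2.0 * A * x + B * y + D
        g2y = B * x + 2.0 * C * y + E
        n1 = np.sqrt(g1x * g1x + g1y * g1y)
        n2 = np.sqrt(g2x * g2x + g2y * g2y)
        cr = abs(g1x * g2y - g1y * g2x)
        trans[n] = n1 > 0.0 and n2 > 0.0 and cr > _TRANSVERSAL_TOL * n1 * n2
        n += 1
    # map back to world coordinates
    for k in range(n):
        qx = pts[k, 0]
        qy = pts[k, 1]
        pts[k, 0] = cx + a11 * qx + a12 * qy
        pts[k, 1] = cy + a21 * qx + a22 * qy
    return pts, n, trans


@njit(cache=True)
def _pair_area(e1, e2, pts, n):
    """Overlap area of two ellipses given their boundary intersections."""
    if n < 2:
        # disjoint or containment
        if _gval(e2, e1[0], e1[1]) < 1.0 or _gval(e1, e2[0], e2[1]) < 1.0:
            a1 = np.pi * e1[2] * e1[3]
            a2 = np.pi * e2[2] * e2[3]
            return min(a1, a2)
        return 0.0
    total = 0.0
    ts = np.empty(4)
    for which in range(2):
        if which == 0:
            es, eo = e1, e2
        else:
            es, eo = e2, e1
        for k in range(n):
            ts[k] = _param_of(es, pts[k, 0], pts[k, 1])
        tt = np.sort(ts[:n])
        for k in range(n):
            t0 = tt[k]
            t1 = tt[(k + 1) % n]
            if t1 <= t0:
                t1 += 2.0 * np.pi
            tm = 0.5 * (t0 + t1)
            px, py = _boundary_point(es, tm)
            if _gval(eo, px, py) < 1.0:
                total += _arc_area(es, t0, t1)
    return total


@njit(cache=True)
def _lens_point(e1, e2, pts, n):
    """A point interior to the overlap of e1 and e2 (overlap assumed nonempty)."""
    if n >= 2:
        return 0.5 * (pts[0, 0] + pts[1, 0]), 0.5 * (pts[0, 1] + pts[1, 1])
    # containment: centre of the smaller ellipse
    if e1[2] * e1[3] <= e2[2] * e2[3]:
        return e1[0], e1[1]
    return e2[0], e2[1]


@njit(cache=True)
def _triple_area(d, p12, n12, p13, n13, p23, n23, i12, i13, i23):
    """Area of the three-way overlap from pairwise intersection data."""
    e1 = d[0]
    e2 = d[1]
    e3 = d[2]
    total = 0.0
    nv = 0
    ts = np.empty(8)
    for which in range(3):
        m = 0
        if which == 0:
            es = e1
            for k in range(n12):
                if _gval(e3, p12[k, 0], p12[k, 1]) < 1.0:
                    ts[m] = _param_of(es, p12[k, 0], p12[k, 1])
                    m += 1
            for k in range(n13):
                if _gval(e2, p13[k, 0], p13[k, 1]) < 1.0:
                    ts[m] = _param_of(es, p13[k, 0], p13[k, 1])
                    m += 1
            oa, ob = e2, e3
        elif which == 1:
            es = e2
            for k in range(n12):
                if _gval(e3, p12[k, 0], p12[k, 1]) < 1.0:
                    ts[m] = _param_of(es, p12[k, 0], p12[k, 1])
                    m += 1
            for k in range(n23):
                if _gval(e1, p23[k, 0], p23[k, 1]) < 1.0:
                    ts[m] = _param_of(es, p23[k, 0], p23[k, 1])
                    m += 1
            oa, ob = e1, e3
        else:
            es = e3
            for k in range(n13):
                if _gval(e2, p13[k, 0], p13[k, 1]) < 1.0:
                    ts[m] = _param_of(es, p13[k, 0], p13[k, 1])
                    m += 1
            for k in range(n23):
                if _gval(e1, p23[k, 0], p23[k, 1]) < 1.0:
                    ts[m] = _param_of(es, p23[k, 0], p23[k, 1])
                    m += 1
            oa, ob = e1, e2
        nv += m
        if m == 0:
            continue
        tt = np.sort(ts[:m])
        for k in range(m):
            t0 = tt[k]
            t1 = tt[(k + 1) % m]
            if t1 <= t0:
                t1 += 2.0 * np.pi
            tm = 0.5 * (t0 + t1)
            px, py = _boundary_point(es, tm)
            if _gval(oa, px, py) < 1.0 and _gval(ob, px, py) < 1.0:
                total += _arc_area(es, t0, t1)
    if nv > 0:
        return total
    # no vertex on the triple-overlap boundary: the overlap is empty or it is
    # the smallest pairwise lens contained in the third ellipse
    imin = i12
    best = 0
    if i13 < imin:
        imin = i13
        best = 1
    if i23 < imin:
        imin = i23
        best = 2
    if imin <= 0.0:
        return 0.0
    if best == 0:
        px, py = _lens_point(e1, e2, p12, n12)
        inside = _gval(e3, px, py) < 1.0
    elif best == 1:
        px, py = _lens_point(e1, e3, p13, n13)
        inside = _gval(e2, px, py) < 1.0
    else:
        px, py = _lens_point(e2, e3, p23, n23)
        inside = _gval(e1, px, py) < 1.0
    if inside:
        return imin
    return 0.0


@njit(cache=True)
def _region_areas(d):
    """Seven region areas of a 3-curve diagram by inclusion-exclusion.

    Returns (areas, valid, consistent): ``valid`` is the full 3-Venn topology
    verdict (every pair crossing transversally in exactly 2 points and all
    seven regions above the positivity floor -- by Euler's formula on the
    arrangement this also guarantees each region is a single connected zone);
    ``consistent`` is False when round-off produced a negative area beyond
    tolerance.
    """
    areas = np.zeros(7)
    e1 = d[0]
    e2 = d[1]
    e3 = d[2]
    a1 = np.pi * e1[2] * e1[3]
    a2 = np.pi * e2[2] * e2[3]
    a3 = np.pi * e3[2] * e3[3]
    p12, n12, t12 = _intersect_raw(e1, e2)
    p13, n13, t13 = _intersect_raw(e1, e3)
    p23, n23, t23 = _intersect_raw(e2, e3)
    i12 = _pair_area(e1, e2, p12, n12)
    i13 = _pair_area(e1, e3, p13, n13)
    i23 = _pair_area(e2, e3, p23, n23)
    tri = _triple_area(d, p12, n12, p13, n13, p23, n23, i12, i13, i23)
    areas[6] = tri
    areas[3] = i12 - tri
    areas[4] = i13 - tri
    areas[5] = i23 - tri
    areas[0] = a1 - i12 - i13 + tri
    areas[1] = a2 - i12 - i23 + tri
    areas[2] = a3 - i13 - i23 + tri
    tot = a1 + a2 + a3
    consistent = True
    for i in range(7):
        if areas[i] < 0.0:
            if areas[i] > -_NEG_CLAMP_REL * tot:
                areas[i] = 0.0
            else:
                consistent = False
                areas[i] = 0.0
    union = 0.0
    for i in range(7):
        union += areas[i]
    valid = n12 == 2 and n13 == 2 and n23 == 2
    if valid:
        for k in range(2):
            if not (t12[k] and t13[k] and t23[k]):
                valid = False
    if valid:
        floor = _VALID_FLOOR_REL * union
        for i in range(7):
            if areas[i] <= floor:
                valid = False
    return areas, valid, consistent


@njit(cache=True)
def _diag_error(areas, w):
    """max_r | A(r)/sum(A) - w(r)/sum(w) |."""
    sa = 0.0
    sw = 0.0
    for i in range(7):
        sa += areas[i]
        sw += w[i]
    worst = 0.0
    for i in range(7):
        d = abs(areas[i] / sa - w[i] / sw)
        if d > worst:
            worst = d
    return worst


@njit(cache=True)
def _cost_f6(areas, wp):
    """Mean over regions of (required - actual)^2 / actual; +inf sentinel on collapse."""
    s = 0.0
    for i in range(7):
        if areas[i] <= 0.0:
            return BIG_COST
        r = wp[i] - areas[i]
        s += r * r / areas[i]
    return s / 7.0


@njit(cache=True)
def _eval_candidate(d, wp):
    areas, valid, _ = _region_areas(d)
    if not valid:
        return BIG_COST, areas
    return _cost_f6(areas, wp), areas


@njit(cache=True)
def _hill_climb(d0, w, wp, pg0, pa0, pt0, circles, eps, good_eps, max_iter, trace_cap):
    """Greedy hill climb over ellipse parameters with a halving cooling schedule.

    Candidate lists per property class are precomputed from the ellipse state
    at the start of the class block and applied cumulatively; a candidate is
    accepted iff it strictly reduces the F6 cost and keeps a valid topology.
    Returns (diagram, iterations, accurate, cost_trace, n_trace, areas).
    """
    d = d0.copy()
    areas, valid, _ = _region_areas(d)
    cost = _cost_f6(areas, wp)
    pg = pg0
    pa = pa0
    pt = pt0
    trace = np.empty(trace_cap)
    ntr = 0
    accurate = False
    it = 0
    cand_c = np.empty((8, 2))
    cand_s = np.empty((8, 2))
    while it < max_iter:
        it += 1
        ch_c = False
        ch_s = False
        ch_r = False
        for ei in range(3):
            # --- centres: E, W, N, S, NE, NW, SE, SW ---
            bx = d[ei, 0]
            by = d[ei, 1]
            cand_c[0, 0] = bx + pg
            cand_c[0, 1] = by
            cand_c[1, 0] = bx - pg
            cand_c[1, 1] = by
            cand_c[2, 0] = bx
            cand_c[2, 1] = by + pg
            cand_c[3, 0] = bx
            cand_c[3, 1] = by - pg
            cand_c[4, 0] = bx + pg
            cand_c[4, 1] = by + pg
            cand_c[5, 0] = bx - pg
            cand_c[5, 1] = by + pg
            cand_c[6, 0] = bx + pg
            cand_c[6, 1] = by - pg
            cand_c[7, 0] = bx - pg
            cand_c[7, 1] = by - pg
            for k in range(8):
                ox = d[ei, 0]
                oy = d[ei, 1]
                d[ei, 0] = cand_c[k, 0]
                d[ei, 1] = cand_c[k, 1]
                c, ar = _eval_candidate(d, wp)
                if c < cost:
                    cost = c
                    areas = ar
                    ch_c = True
                    if ntr < trace_cap:
                        trace[ntr] = c
                        ntr += 1
                else:
                    d[ei, 0] = ox
                    d[ei, 1] = oy
            # --- semi-axes ---
            b1 = d[ei, 2]
            b2 = d[ei, 3]
            if circles:
                ns = 2
                cand_s[0, 0] = b1 * (1.0 + pa)
                cand_s[0, 1] = b2 * (1.0 + pa)
                cand_s[1, 0] = b1 * (1.0 - pa)
                cand_s[1, 1] = b2 * (1.0 - pa)
            else:
                ns = 8
                cand_s[0, 0] = b1 * (1.0 + pa)
                cand_s[0, 1] = b2
                cand_s[1, 0] = b1 * (1.0 - pa)
                cand_s[1, 1] = b2
                cand_s[2, 0] = b1
                cand_s[2, 1] = b2 * (1.0 + pa)
                cand_s[3, 0] = b1
                cand_s[3, 1] = b2 * (1.0 - pa)
                cand_s[4, 0] = b1 * (1.0 + pa)
                cand_s[4, 1] = b2 * (1.0 + pa)
                cand_s[5, 0] = b1 * (1.0 - pa)
                cand_s[5, 1] = b2 * (1.0 - pa)
                cand_s[6, 0] = b1 * (1.0 + pa)
                cand_s[6, 1] = b2 * (1.0 - pa)
                cand_s[7, 0] = b1 * (1.0 - pa)
                cand_s[7, 1] = b2 * (1.0 + pa)
            for k in range(ns):
                o1 = d[ei, 2]
                o2 = d[ei, 3]
                d[ei, 2] = cand_s[k, 0]
                d[ei, 3] = cand_s[k, 1]
                c, ar = _eval_candidate(d, wp)
                if c < cost:
                    cost = c
                    areas = ar
                    ch_s = True
                    if ntr < trace_cap:
                        trace[ntr] = c
                        ntr += 1
                else:
                    d[ei, 2] = o1
                    d[ei, 3] = o2
            # --- rotations (skipped in circle mode) ---
            if not circles:
                bth = d[ei, 4]
                for k in range(2):
                    if k == 0:
                        nth = bth + pt
                    else:
                        nth = bth - pt
                    nth = nth % np.pi
                    oth = d[ei, 4]
                    d[ei, 4] = nth
                    c, ar = _eval_candidate(d, wp)
                    if c < cost:
                        cost = c
                        areas = ar
                        ch_r = True
                        if ntr < trace_cap:
                            trace[ntr] = c
                            ntr += 1
                    else:
                        d[ei, 4] = oth
        if not ch_c:
            pg *= 0.5
        if not ch_s:
            pa *= 0.5
        if not ch_r:
            pt *= 0.5
        if pg <= eps and pa <= eps and pt <= eps:
            break
        if _diag_error(areas, w) <= good_eps:
            accurate = True
            break
    return d, it, accurate, trace, ntr, areas
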