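"""Per-frame pattern detection in velocity vector fields.

Critical points (sites where u = v = 0) are located at sub-grid resolution
by intersecting the bilinear zero-level contours of u and v within each unit
cell, classified by the trace and determinant of the locally interpolated
Jacobian, and sized via winding numbers on expanding rings.  Global
behaviour is summarized by two order parameters: phi (mean normalized
velocity, near 1 for plane waves) and R (resultant phase length, near 1 for
synchrony).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .flow import circ_diff

__all__ = [
    "CriticalPoint",
    "find_critical_points",
    "jacobian_at",
    "classify_critical_point",
    "winding_number",
    "ring_path",
    "pattern_extent",
    "detect_critical_points",
    "order_parameter_phi",
    "order_parameter_R",
    "detect_global_intervals",
    "CLASS_TO_PATTERN",
]

#: classification labels -> wave pattern names.  An outward-flowing node is
#: a source (repelling, hence "unstable"); inward-flowing is a sink.
CLASS_TO_PATTERN = {
    "unstable_node": "source",
    "stable_node": "sink",
    "unstable_focus": "spiral_out",
    "stable_focus": "spiral_in",
    "saddle": "saddle",
}

MERGE_RADIUS = 0.1  # grid spaces; duplicates closer than this are merged


@dataclass
class CriticalPoint:
    """A classified zero of the velocity field at continuous coordinates."""

    x: float
    y: float
    cls: str
    trace: float
    det: float
    extent: float = 0.0
    time_step: int | None = None
    trial: int | None = None

    @property
    def ptype(self) -> str:
        return CLASS_TO_PATTERN.get(self.cls, self.cls)

    @property
    def position(self) -> tuple[float, float]:
        return (self.x, self.y)


def _bilinear_coeffs(f: np.ndarray, i: int, j: int) -> tuple[float, float, float, float]:
    """Coefficients of f(s,t) = a0 + a1*s + a2*t + a3*s*t on cell (i, j).

    s runs along columns (x), t along rows (y), both in [0, 1].
    """
    f00 = f[i, j]
    f10 = f[i, j + 1]
    f01 = f[i + 1, j]
    f11 = f[i + 1, j + 1]
    return f00, f10 - f00, f01 - f00, f00 - f10 - f01 + f11


def _cell_intersections(a, b, eps=1e-12) -> list[tuple[float, float]]:
    """Intersections of the zero curves of two bilinear patches in [0,1]^2."""
    a0, a1, a2, a3 = a
    b0, b1, b2, b3 = b
    # eliminate t: (b0 + b1 s)(a2 + a3 s) - (b2 + b3 s)(a0 + a1 s) = 0
    A = b1 * a3 - b3 * a1
    B = b0 * a3 + b1 * a2 - b2 * a1 - b3 * a0
    C = b0 * a2 - b2 * a0
    if abs(A) < eps:
        roots = [] if abs(B) < eps else [-C / B]
    else:
        disc = B * B - 4 * A * C
        if disc < 0:
            return []
        sq = np.sqrt(disc)
        roots = [(-B + sq) / (2 * A), (-B - sq) / (2 * A)]
    pts = []
    tol = 1e-9
    for s in roots:
        if not (-tol <= s <= 1 + tol):
            continue
        den_a = a2 + a3 * s
        den_b = b2 + b3 * s
        if abs(den_a) >= abs(den_b):
            if abs(den_a) < eps:
                continue
            t = -(a0 + a1 * s) / den_a
        else:
            if abs(den_b) < eps:
                continue
            t = -(b0 + b1 * s) / den_b
        if -tol <= t <= 1 + tol:
            pts.append((min(max(s, 0.0), 1.0), min(max(t, 0.0), 1.0)))
    return pts


def find_critical_points(u: np.ndarray, v: np.ndarray) -> list[tuple[float, float]]:
    """Continuous ``(x, y)`` positions where u = v = 0.

    Within each unit cell the fields are bilinearly interpolated and the
    intersections of their zero-level curves solved in closed form (a
    quadratic per cell).  Points closer than 0.1 grid spaces are merged.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("u and v must have the same shape")
    rows, cols = u.shape
    found: list[tuple[float, float]] = []
    for i in range(rows - 1):
        for j in range(cols - 1):
            cu = u[i : i + 2, j : j + 2]
            # quick reject: no sign change in either component
            if (cu > 0).all() or (cu < 0).all():
                continue
            cv = v[i : i + 2, j : j + 2]
            if (cv > 0).all() or (cv < 0).all():
                continue
            for s, t in _cell_intersections(
                _bilinear_coeffs(u, i, j), _bilinear_coeffs(v, i, j)
            ):
                found.append((j + s, i + t))
    merged: list[tuple[float, float]] = []
    for x, y in found:
        if all(np.hypot(x - mx, y - my) > MERGE_RADIUS for mx, my in merged):
            merged.append((x, y))
    return merged


def jacobian_at(
    u: np.ndarray, v: np.ndarray, pos: tuple[float, float]
) -> np.ndarray:
    """2x2 Jacobian [[du/dx, du/dy], [dv/dx, dv/dy]] at a continuous position.

    The partials are evaluated with centred differences at the four corners
    of the surrounding cell and bilinearly interpolated to ``pos``; the
    position must be far enough inside the grid for the centred stencils.
    """
    x, y = pos
    rows, cols = u.shape
    j0 = int(np.floor(x))
    i0 = int(np.floor(y))
    if j0 == cols - 1 and x == cols - 1:
        j0 -= 1
    if i0 == rows - 1 and y == rows - 1:
        i0 -= 1
    if not (1 <= j0 <= cols - 3 and 1 <= i0 <= rows - 3):
        raise ValueError(
            f"position {pos} too close to the boundary for the Jacobian stencil"
        )
    s = x - j0
    t = y - i0
    w = np.array([(1 - s) * (1 - t), s * (1 - t), (1 - s) * t, s * t])
    corners = [(i0, j0), (i0, j0 + 1), (i0 + 1, j0), (i0 + 1, j0 + 1)]
    J = np.zeros((2, 2))
    for wk, (i, j) in zip(w, corners):
        ux = (u[i, j + 1] - u[i, j - 1]) / 2
        uy = (u[i + 1, j] - u[i - 1, j]) / 2
        vx = (v[i, j + 1] - v[i, j - 1]) / 2
        vy = (v[i + 1, j] - v[i - 1, j]) / 2
        J += wk * np.array([[ux, uy], [vx, vy]])
    return J


def classify_critical_point(
    J: np.ndarray, stability_convention: str = "standard"
) -> str:
    """Classify a critical point from its Jacobian.

    Saddles have negative determinant; positive-determinant points are nodes
    when ``tau^2 >= 4*det`` and foci otherwise.  Stability labelling depends
    on the convention: ``"standard"`` marks trace < 0 as stable (attracting
    flow: sinks and spirals-in), which is consistent with outward-flowing
    fields being sources; ``"inverted"`` flips the labels (some published
    descriptions state the rule the other way around).  ``det == 0`` is
    degenerate and returned as ``"degenerate"``; a pure centre
    (trace == 0, det > 0) is reported as unstable with a ``_center`` suffix.
    """
    J = np.asarray(J, dtype=float)
    if not np.isfinite(J).all():
        raise ValueError("Jacobian must be finite")
    tau = float(np.trace(J))
    delta = float(np.linalg.det(J))
    if delta == 0:
        return "degenerate"
    if delta < 0:
        return "saddle"
    # boundary tie tau^2 == 4*det classifies as node; compare with a small
    # relative tolerance so exactly-radial fields do not flip class on
    # floating-point noise
    disc = tau * tau - 4 * delta
    scale = tau * tau + 4 * abs(delta)
    kind = "node" if disc >= -1e-9 * scale else "focus"
    if tau == 0:
        return f"unstable_{kind}_center"
    if stability_convention == "standard":
        stable = tau < 0
    elif stability_convention == "inverted":
        stable = tau > 0
    else:
        raise ValueError(f"unknown stability convention {stability_convention!r}")
    return ("stable_" if stable else "unstable_") + kind


def winding_number(
    u: np.ndarray,
    v: np.ndarray,
    path: list[tuple[int, int]],
    return_raw: bool = False,
):
    """Poincare index of the field along a closed counter-clockwise path.

    ``path`` lists ``(x, y)`` grid sites; the angle of the vector at each
    site is tracked around the loop (differences taken circularly, with the
    first site repeated at the end) and the accumulated rotation divided by
    2*pi.  Nodes and foci give +1, saddles -1, uniform fields 0.
    """
    angles = []
    for x, y in path:
        uu, vv = u[int(y), int(x)], v[int(y), int(x)]
        if uu == 0 and vv == 0:
            raise ValueError(f"zero-magnitude vector on path at site ({x}, {y})")
        angles.append(np.arctan2(vv, uu))
    angles = np.asarray(angles)
    diffs = circ_diff(np.roll(angles, -1), angles)
    raw = float(diffs.sum() / (2 * np.pi))
    index = int(np.round(raw))
    return (index, raw) if return_raw else index


def ring_path(
    center: tuple[float, float], r: int, shape: tuple[int, int]
) -> list[tuple[int, int]]:
    """Grid sites whose rounded distance to ``center`` equals ``r``, ordered
    counter-clockwise (by increasing angle in the x-y plane)."""
    cx, cy = center
    rows, cols = shape
    j_lo = max(0, int(np.floor(cx - r - 1)))
    j_hi = min(cols - 1, int(np.ceil(cx + r + 1)))
    i_lo = max(0, int(np.floor(cy - r - 1)))
    i_hi = min(rows - 1, int(np.ceil(cy + r + 1)))
    sites = []
    for i in range(i_lo, i_hi + 1):
        for j in range(j_lo, j_hi + 1):
            if int(np.round(np.hypot(j - cx, i - cy))) == r:
                sites.append((j, i))
    sites.sort(key=lambda p: np.arctan2(p[1] - cy, p[0] - cx))
    return sites


def pattern_extent(
    u: np.ndarray, v: np.ndarray, cp: CriticalPoint, max_radius: int | None = None
) -> int:
    """Largest ring radius over which all winding numbers match the class.

    Rings of radius 1, 2, ... are evaluated around the critical point; the
    extent is the largest r such that every ring up to r yields the index
    expected for the class (+1 for nodes/foci, -1 for saddles).  A ring that
    would touch the grid boundary terminates the search, as does any site
    with zero vector magnitude or an inconsistent index (e.g. a second
    critical point entering the ring).
    """
    rows, cols = u.shape
    expected = -1 if cp.cls == "saddle" else 1
    cx, cy = cp.x, cp.y
    edge_dist = min(cx, cols - 1 - cx, cy, rows - 1 - cy)
    extent = 0
    r = 1
    while True:
        if max_radius is not None and r > max_radius:
            break
        if r > edge_dist:  # ring touches the boundary
            break
        sites = ring_path((cx, cy), r, (rows, cols))
        if len(sites) < 4:
            break
        try:
            idx = winding_number(u, v, sites)
        except ValueError:
            break
        if idx != expected:
            break
        extent = r
        r += 1
    return extent


def detect_critical_points(
    u: np.ndarray,
    v: np.ndarray,
    edge_margin: float = 2.0,
    stability_convention: str = "standard",
    time_step: int | None = None,
    trial: int | None = None,
) -> list[CriticalPoint]:
    """Locate, classify and size all critical points in one velocity field.

    Points closer than ``edge_margin`` grid spaces to the boundary are
    discarded before classification (boundary derivative stencils make the
    field unreliable there); degenerate points are dropped.
    """
    rows, cols = u.shape
    out = []
    for x, y in find_critical_points(u, v):
        if min(x, cols - 1 - x, y, rows - 1 - y) < edge_margin:
            continue
        try:
            J = jacobian_at(u, v, (x, y))
        except ValueError:
            continue
        cls = classify_critical_point(J, stability_convention)
        if cls == "degenerate":
            continue
        if cls.endswith("_center"):
            cls = cls[: -len("_center")]
        cp = CriticalPoint(
            x=x,
            y=y,
            cls=cls,
            trace=float(np.trace(J)),
            det=float(np.linalg.det(J)),
            time_step=time_step,
            trial=trial,
        )
        cp.extent = pattern_extent(u, v, cp)
        out.append(cp)
    return out


def order_parameter_phi(u: np.ndarray, v: np.ndarray) -> float:
    """Mean normalized velocity ``||sum w|| / sum ||w||`` in [0, 1]."""
    norms = np.hypot(u, v)
    total = norms.sum()
    if total == 0:
        raise ValueError("order parameter undefined for an all-zero field")
    return float(np.hypot(u.sum(), v.sum()) / total)


def order_parameter_R(theta: np.ndarray) -> float:
    """Resultant vector length ``|sum exp(i*theta)| / N`` in [0, 1]."""
    theta = np.asarray(theta, dtype=float)
    if not np.isfinite(theta).all():
        raise ValueError("phases must be finite")
    return float(np.abs(np.exp(1j * theta).mean()))


def detect_global_intervals(
    values: np.ndarray,
    threshold: float,
    tdur: int = 5,
    tgap: int = 1,
) -> list[tuple[int, int]]:
    """Intervals (inclusive start/end steps) where a statistic holds.

    The statistic must exceed ``threshold`` with sub-threshold gaps of at
    most ``tgap`` consecutive steps; merged intervals shorter than ``tdur``
    steps are discarded.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    above = np.asarray(values) > threshold
    idx = np.nonzero(above)[0]
    if idx.size == 0:
        return []
    intervals = []
    start = prev = idx[0]
    for t in idx[1:]:
        if t - prev - 1 <= tgap:
            prev = t
        else:
            intervals.append((int(start), int(prev)))
            start = prev = t
    intervals.append((int(start), int(prev)))
    return [(s, e) for s, e in intervals if e - s + 1 >= tdur]
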