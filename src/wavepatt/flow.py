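"""Variational optical flow for velocity vector fields.

Estimates per-frame velocity fields ``w = (u, v)`` (grid spaces per time
step) by minimizing a robust-penalty functional combining a data-constancy
term with a smoothness term,

    E = integral[ rho(Ed^2) + alpha * rho(Es^2) ],   rho(s) = sqrt(s + beta^2),

where ``Ed = Dx*u + Dy*v + Dt`` is the linearized data-constancy error and
``Es^2 = |grad u|^2 + |grad v|^2`` the departure from smoothness.  The
Euler-Lagrange equations are solved by fixed-point iteration: the nonlinear
weights are frozen, the resulting linear elliptic system is solved exactly
(sparse direct solve), and the weights are updated until the field stops
changing.  Large ``beta`` reduces the penalty to quadratic, recovering the
classic Horn-Schunck solution (available in closed form via
:func:`solve_flow_quadratic` as an independent cross-check).

Phase inputs wrap at +/-pi, so all finite differences on phase data use
circular subtraction ``mod(a - b + pi, 2*pi) - pi``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

__all__ = [
    "VelocityFieldSeries",
    "spatial_derivatives",
    "temporal_derivative",
    "solve_flow_frame",
    "solve_flow_quadratic",
    "compute_velocity_fields",
    "flow_energy",
]

DEFAULT_ALPHA = 0.1
DEFAULT_BETA = 10.0
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 500


def circ_diff(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Circular subtraction a - b mapped into (-pi, pi]."""
    return np.mod(a - b + np.pi, 2 * np.pi) - np.pi


def _diff(a, b, is_phase):
    return circ_diff(a, b) if is_phase else a - b


def _deriv_along(frame: np.ndarray, axis: int, is_phase: bool) -> np.ndarray:
    """First derivative along one axis.

    For ordinary data, interior points (two or more nodes from the edge)
    use the five-point stencil (1/12)[-1, 8, 0, -8, 1]; points one node in
    use centred differences; edge points use one-sided differences.

    Phase data wrap at +/-pi, which invalidates the wide stencil (a 4-step
    span can exceed pi even for modest wavenumbers), so phase derivatives
    use centred differences with circular subtraction in the interior and
    circular one-sided differences at the edges.
    """
    f = np.moveaxis(frame, axis, 0)
    n = f.shape[0]
    out = np.empty_like(f, dtype=float)
    if n < 2:
        raise ValueError("need at least 2 samples along each axis")
    # one-sided at the edges
    out[0] = _diff(f[1], f[0], is_phase)
    out[-1] = _diff(f[-1], f[-2], is_phase)
    if n >= 3:
        out[1] = _diff(f[2], f[0], is_phase) / 2
        out[-2] = _diff(f[-1], f[-3], is_phase) / 2
    if n >= 5:
        if is_phase:
            out[2:-2] = _diff(f[3:-1], f[1:-3], True) / 2
        else:
            c1 = f[3:-1] - f[1:-3]  # f[i+1] - f[i-1]
            c2 = f[4:] - f[:-4]  # f[i+2] - f[i-2]
            out[2:-2] = (8 * c1 - c2) / 12
    return np.moveaxis(out, 0, axis)


def spatial_derivatives(
    frame: np.ndarray, is_phase: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(Dx, Dy)``: derivatives along columns (x) and rows (y)."""
    frame = np.asarray(frame, dtype=float)
    dx = _deriv_along(frame, axis=1, is_phase=is_phase)
    dy = _deriv_along(frame, axis=0, is_phase=is_phase)
    return dx, dy


def temporal_derivative(
    frame_t: np.ndarray, frame_t1: np.ndarray, is_phase: bool = False
) -> np.ndarray:
    """Forward difference ``frame_t1 - frame_t`` (circular for phase data)."""
    frame_t = np.asarray(frame_t, dtype=float)
    frame_t1 = np.asarray(frame_t1, dtype=float)
    if frame_t.shape != frame_t1.shape:
        raise ValueError("frames must have the same shape")
    return _diff(frame_t1, frame_t, is_phase)


def _grad_replicate(f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centred gradient with replicated (Neumann) boundary ghosts."""
    fx = np.empty_like(f)
    fy = np.empty_like(f)
    fx[:, 1:-1] = (f[:, 2:] - f[:, :-2]) / 2
    fx[:, 0] = (f[:, 1] - f[:, 0]) / 2
    fx[:, -1] = (f[:, -1] - f[:, -2]) / 2
    fy[1:-1, :] = (f[2:, :] - f[:-2, :]) / 2
    fy[0, :] = (f[1, :] - f[0, :]) / 2
    fy[-1, :] = (f[-1, :] - f[-2, :]) / 2
    return fx, fy


_STENCIL_CACHE: dict[tuple[int, int], "_Stencils"] = {}


class _Stencils:
    """Precomputed neighbour indexing and sparse structure for a grid."""

    def __init__(self, rows: int, cols: int):
        self.rows, self.cols = rows, cols
        n = rows * cols
        idx = np.arange(n).reshape(rows, cols)
        self.idx = idx
        self.neigh = {}
        for name, (di, dj) in (
            ("up", (-1, 0)),
            ("down", (1, 0)),
            ("left", (0, -1)),
            ("right", (0, 1)),
        ):
            shifted = np.full((rows, cols), -1, dtype=int)
            src = idx
            if di == -1:
                shifted[1:, :] = src[:-1, :]
            elif di == 1:
                shifted[:-1, :] = src[1:, :]
            elif dj == -1:
                shifted[:, 1:] = src[:, :-1]
            else:
                shifted[:, :-1] = src[:, 1:]
            self.neigh[name] = shifted.ravel()

        # precomputed COO structure of the full 2n x 2n system: per block
        # (u, v) the smoothness stencil entries (diag + valid neighbours)
        # plus the data-term cross-coupling diagonals
        base = np.arange(n)
        self.valid = {d: self.neigh[d] >= 0 for d in self.neigh}
        nb_rows, nb_cols = [], []
        for d in ("up", "down", "left", "right"):
            nb = self.neigh[d]
            ok = self.valid[d]
            nb_rows.append(base[ok])
            nb_cols.append(nb[ok])
        nb_rows = np.concatenate(nb_rows)
        nb_cols = np.concatenate(nb_cols)
        block_rows = np.concatenate([base, nb_rows])
        block_cols = np.concatenate([base, nb_cols])
        self._n_block = block_rows.size
        self.sys_rows = np.concatenate(
            [block_rows, block_rows + n, base, base + n]
        )
        self.sys_cols = np.concatenate(
            [block_cols, block_cols + n, base + n, base]
        )

    @classmethod
    def for_shape(cls, rows: int, cols: int) -> "_Stencils":
        key = (rows, cols)
        if key not in _STENCIL_CACHE:
            _STENCIL_CACHE[key] = cls(rows, cols)
        return _STENCIL_CACHE[key]


def _solve_linear(
    rho_d: np.ndarray,
    rho_s: np.ndarray,
    dx: np.ndarray,
    dy: np.ndarray,
    dt: np.ndarray,
    st: _Stencils,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact solve of the frozen-coefficient Euler-Lagrange system.

    The smoothness operator ``-(rho_s * lap + grad(rho_s) . grad)`` uses
    the 2D five-point Laplacian stencil with replicated (Neumann) boundary
    ghosts; a missing neighbour's gradient coefficient folds onto the
    diagonal.  The sparse structure is precomputed per grid shape; only
    the coefficient values are filled in here.
    """
    n = st.rows * st.cols
    rs = rho_s.ravel()
    gx, gy = _grad_replicate(rho_s)
    grad_coeff = {
        "right": -gx.ravel() / 2,
        "left": gx.ravel() / 2,
        "down": -gy.ravel() / 2,
        "up": gy.ravel() / 2,
    }
    diag = np.zeros(n)
    nb_data = []
    for d in ("up", "down", "left", "right"):
        ok = st.valid[d]
        diag[ok] += rs[ok]  # Laplacian: -rho_s*(u_j - u_i) per neighbour
        diag[~ok] += grad_coeff[d][~ok]  # ghost = u_i at the boundary
        nb_data.append(-rs[ok] + grad_coeff[d][ok])
    nb_data = np.concatenate(nb_data)

    rd = rho_d.ravel()
    dxf, dyf, dtf = dx.ravel(), dy.ravel(), dt.ravel()
    cross = rd * dxf * dyf
    data = np.concatenate(
        [diag + rd * dxf * dxf, nb_data, diag + rd * dyf * dyf, nb_data,
         cross, cross]
    )
    A = sp.csr_matrix((data, (st.sys_rows, st.sys_cols)), shape=(2 * n, 2 * n))
    b = np.concatenate([-rd * dxf * dtf, -rd * dyf * dtf])
    sol = spsolve(A, b)
    u = sol[:n].reshape(st.rows, st.cols)
    v = sol[n:].reshape(st.rows, st.cols)
    return u, v


def _charbonnier_weight(s: np.ndarray, beta: float) -> np.ndarray:
    """Derivative of rho(s) = sqrt(s + beta^2) with respect to s."""
    return 0.5 / np.sqrt(s + beta**2)


def flow_energy(
    frame_t: np.ndarray,
    frame_t1: np.ndarray,
    u: np.ndarray,
    v: np.ndarray,
    alpha: float,
    beta: float,
    is_phase: bool = False,
) -> float:
    """Discrete value of the penalized functional for diagnostics/tests."""
    dx0, dy0 = spatial_derivatives(frame_t, is_phase)
    dx1, dy1 = spatial_derivatives(frame_t1, is_phase)
    dx, dy = (dx0 + dx1) / 2, (dy0 + dy1) / 2
    dt = temporal_derivative(frame_t, frame_t1, is_phase)
    ed = dx * u + dy * v + dt
    ux, uy = _grad_replicate(u)
    vx, vy = _grad_replicate(v)
    es2 = ux**2 + uy**2 + vx**2 + vy**2
    rho = lambda s: np.sqrt(s + beta**2)
    return float(np.sum(rho(ed**2) + alpha * rho(es2)))


def solve_flow_frame(
    frame_t: np.ndarray,
    frame_t1: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    beta: float = DEFAULT_BETA,
    is_phase: bool = False,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    init: tuple[np.ndarray, np.ndarray] | None = None,
    track_energy: bool = False,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Velocity field between two frames by fixed-point iteration.

    Each outer iteration freezes the robust-penalty weights
    ``rho_d = rho'(Ed^2)/alpha`` and ``rho_s = rho'(Es^2)`` at the current
    field, then solves the resulting linear system exactly.  Iteration stops
    when the relative L2 update falls below ``tol``.

    Returns ``(u, v, info)`` where ``info`` holds ``n_iter``, ``residual``
    (final relative update) and ``converged``; with ``track_energy`` the
    functional value after every outer iteration is stored under
    ``"energies"`` (starting from the initial field).
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    frame_t = np.asarray(frame_t, dtype=float)
    frame_t1 = np.asarray(frame_t1, dtype=float)
    if frame_t.shape != frame_t1.shape:
        raise ValueError("frames must have the same shape")
    if not (np.isfinite(frame_t).all() and np.isfinite(frame_t1).all()):
        raise ValueError("frames must be finite")
    rows, cols = frame_t.shape
    st = _Stencils.for_shape(rows, cols)

    dx0, dy0 = spatial_derivatives(frame_t, is_phase)
    dx1, dy1 = spatial_derivatives(frame_t1, is_phase)
    dx, dy = (dx0 + dx1) / 2, (dy0 + dy1) / 2
    dt = temporal_derivative(frame_t, frame_t1, is_phase)

    if init is not None:
        u, v = np.array(init[0], dtype=float), np.array(init[1], dtype=float)
    else:
        u = np.zeros_like(frame_t)
        v = np.zeros_like(frame_t)

    def _energy(uu, vv):
        ed = dx * uu + dy * vv + dt
        ux, uy = _grad_replicate(uu)
        vx, vy = _grad_replicate(vv)
        es2 = ux**2 + uy**2 + vx**2 + vy**2
        return float(
            np.sum(np.sqrt(ed**2 + beta**2) + alpha * np.sqrt(es2 + beta**2))
        )

    cur_energy = _energy(u, v)
    energies = [cur_energy] if track_energy else None
    residual = np.inf
    prev_residual = np.inf
    relax = 1.0
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        ed = dx * u + dy * v + dt
        ux, uy = _grad_replicate(u)
        vx, vy = _grad_replicate(v)
        es2 = ux**2 + uy**2 + vx**2 + vy**2
        rho_d = _charbonnier_weight(ed**2, beta) / alpha
        rho_s = _charbonnier_weight(es2, beta)
        u_new, v_new = _solve_linear(rho_d, rho_s, dx, dy, dt, st)
        du, dv = u_new - u, v_new - v
        num = np.sqrt(np.sum(du**2 + dv**2))
        den = max(np.sqrt(np.sum(u_new**2 + v_new**2)), 1e-30)
        residual = num / den
        # backtracking under-relaxation: the raw fixed-point map can
        # oscillate for small beta, so the step is halved until the
        # functional stops increasing (damping preserves the fixed points
        # and makes the energy trajectory monotone)
        step = relax
        descended = False
        for _ in range(8):
            u_try = u + step * du
            v_try = v + step * dv
            new_energy = _energy(u_try, v_try)
            if new_energy <= cur_energy * (1 + 1e-12):
                descended = True
                break
            step *= 0.5
        if not descended:
            # no step along the fixed-point direction lowers the energy:
            # the iterate is stationary for this discretization
            break
        u, v, cur_energy = u_try, v_try, new_energy
        if step < relax:
            relax = step  # stay damped while the raw map oscillates
        elif residual < prev_residual:
            relax = min(1.0, relax * 1.2)
        elif relax > 0.25:
            relax *= 0.5
        prev_residual = residual
        if track_energy:
            energies.append(cur_energy)
        if residual < tol:
            break
    info = {
        "n_iter": n_iter,
        "residual": float(residual),
        "converged": bool(residual < tol),
    }
    if track_energy:
        info["energies"] = np.asarray(energies)
    return u, v, info


def solve_flow_quadratic(
    frame_t: np.ndarray,
    frame_t1: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    is_phase: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form quadratic-penalty (Horn-Schunck) solution.

    With a quadratic penalty the weights are constant, so the Euler-Lagrange
    system ``Dx*(Dx*u + Dy*v + Dt) - alpha*lap(u) = 0`` (and likewise for v)
    is linear and solved in a single sparse solve.  Serves as the
    independent oracle for the large-beta limit of the robust solver.
    """
    frame_t = np.asarray(frame_t, dtype=float)
    frame_t1 = np.asarray(frame_t1, dtype=float)
    rows, cols = frame_t.shape
    st = _Stencils.for_shape(rows, cols)
    dx0, dy0 = spatial_derivatives(frame_t, is_phase)
    dx1, dy1 = spatial_derivatives(frame_t1, is_phase)
    dx, dy = (dx0 + dx1) / 2, (dy0 + dy1) / 2
    dt = temporal_derivative(frame_t, frame_t1, is_phase)
    rho_d = np.full_like(frame_t, 1.0 / alpha)
    rho_s = np.ones_like(frame_t)
    return _solve_linear(rho_d, rho_s, dx, dy, dt, st)


@dataclass
class VelocityFieldSeries:
    """Velocity fields per time step and trial with solver diagnostics.

    ``u`` and ``v`` have shape ``(rows, cols, n_steps, trials)`` with one
    fewer step than input frames; field ``t`` maps frame ``t`` to ``t+1``.
    """

    u: np.ndarray
    v: np.ndarray
    alpha: float
    beta: float
    is_phase: bool
    n_iter: np.ndarray = field(default=None)  # type: ignore[assignment]
    residual: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_steps(self) -> int:
        return self.u.shape[2]

    @property
    def n_trials(self) -> int:
        return self.u.shape[3]

    def frame(self, t: int, trial: int = 0) -> tuple[np.ndarray, np.ndarray]:
        return self.u[:, :, t, trial], self.v[:, :, t, trial]


def compute_velocity_fields(
    data: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    beta: float = DEFAULT_BETA,
    is_phase: bool = False,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    warm_start: bool = True,
) -> VelocityFieldSeries:
    """Velocity fields for every consecutive frame pair in every trial.

    ``data`` has shape ``(rows, cols, time)`` or ``(rows, cols, time,
    trials)``.  Each solve is warm-started from the previous frame's field,
    which typically cuts the iteration count substantially on slowly
    evolving data.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 3:
        data = data[..., np.newaxis]
    rows, cols, n_frames, n_trials = data.shape
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    n_steps = n_frames - 1
    u = np.empty((rows, cols, n_steps, n_trials))
    v = np.empty_like(u)
    n_iter = np.empty((n_steps, n_trials), dtype=int)
    residual = np.empty((n_steps, n_trials))
    for p in range(n_trials):
        prev = None
        for t in range(n_steps):
            ut, vt, info = solve_flow_frame(
                data[:, :, t, p],
                data[:, :, t + 1, p],
                alpha=alpha,
                beta=beta,
                is_phase=is_phase,
                tol=tol,
                max_iter=max_iter,
                init=prev if warm_start else None,
            )
            u[:, :, t, p] = ut
            v[:, :, t, p] = vt
            n_iter[t, p] = info["n_iter"]
            residual[t, p] = info["residual"]
            prev = (ut, vt)
    return VelocityFieldSeries(
        u=u,
        v=v,
        alpha=alpha,
        beta=beta,
        is_phase=is_phase,
        n_iter=n_iter,
        residual=residual,
    )
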