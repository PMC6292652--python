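"""Vector-field singular value decomposition.

Velocity-field time series are stacked into a matrix with observations
(time, trials concatenated) in rows and recording sites in columns, either
as a real concatenation ``[u | v]`` or as complex numbers ``u + i*v``, and
factored as ``w = T @ Sigma @ R*``.  Each column of ``R`` is a spatial
velocity-field mode explaining a fraction ``sigma_k^2 / sum sigma_i^2`` of
the variance, with time course in the corresponding column of ``T``.  In
the complex variant temporal coefficients both scale and rotate the spatial
mode, so plane waves travelling in any direction collapse into a single
mode.

By default no mean-centering or per-site normalization is applied:
direction biases are themselves informative wave structure.  With centering
enabled the spatial modes coincide with principal-component loadings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .flow import VelocityFieldSeries

__all__ = [
    "SVDResult",
    "stack_velocity_fields",
    "decompose",
    "reconstruct",
    "mode_report",
    "plot_modes",
]


@dataclass
class SVDResult:
    variant: str  # "real" or "complex"
    temporal: np.ndarray  # (n_obs, n_modes), columns are time courses
    singular_values: np.ndarray  # (n_modes,), non-increasing
    spatial: np.ndarray  # (n_features, n_modes), orthonormal columns
    variance_fraction: np.ndarray  # (n_modes,), sums to 1
    grid_shape: tuple[int, int] | None = None
    mean: np.ndarray | None = None  # per-feature mean if centered

    @property
    def n_modes(self) -> int:
        return self.singular_values.size

    def spatial_mode_field(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        """The k-th spatial mode as 2D ``(u, v)`` grids."""
        if self.grid_shape is None:
            raise ValueError("grid shape unknown; cannot reshape mode")
        rows, cols = self.grid_shape
        col = self.spatial[:, k]
        if self.variant == "real":
            n = rows * cols
            u = col[:n].real.reshape(rows, cols)
            v = col[n:].real.reshape(rows, cols)
        else:
            u = col.real.reshape(rows, cols)
            v = col.imag.reshape(rows, cols)
        return u, v


def stack_velocity_fields(
    series: VelocityFieldSeries, variant: str = "real"
) -> np.ndarray:
    """Stack fields into (observations x features); trials concatenate along time."""
    u, v = series.u, series.v
    rows, cols, n_steps, n_trials = u.shape
    # (trial, time, site) -> (trial*time, site)
    ut = np.moveaxis(u.reshape(rows * cols, n_steps, n_trials), 0, -1)
    vt = np.moveaxis(v.reshape(rows * cols, n_steps, n_trials), 0, -1)
    ut = np.transpose(ut, (1, 0, 2)).reshape(n_trials * n_steps, rows * cols)
    vt = np.transpose(vt, (1, 0, 2)).reshape(n_trials * n_steps, rows * cols)
    if variant == "real":
        return np.hstack([ut, vt])
    if variant == "complex":
        return ut + 1j * vt
    raise ValueError(f"unknown variant {variant!r}")


def decompose(
    matrix: np.ndarray,
    variant: str = "real",
    grid_shape: tuple[int, int] | None = None,
    center: bool = False,
    normalize: bool = False,
) -> SVDResult:
    """Thin SVD of the stacked matrix with a deterministic phase convention.

    The SVD's per-mode sign/phase ambiguity is resolved by orienting each
    mode so its mean temporal coefficient is positive real (spatial modes
    then show the orientation the field actually has on average); when the
    time course averages to zero the largest-magnitude spatial component is
    made positive real instead.  Modes are ordered by decreasing singular
    value; numerically zero modes are dropped.
    """
    matrix = np.asarray(matrix)
    if not np.isfinite(matrix).all():
        raise ValueError("matrix must be finite")
    mean = None
    if center:
        mean = matrix.mean(axis=0)
        matrix = matrix - mean
    if normalize:
        sd = matrix.std(axis=0)
        sd[sd == 0] = 1.0
        matrix = matrix / sd
    T, s, Vh = np.linalg.svd(matrix, full_matrices=False)
    keep = s > s[0] * 1e-12 if s.size and s[0] > 0 else np.zeros(s.size, bool)
    T, s, Vh = T[:, keep], s[keep], Vh[keep]
    R = Vh.conj().T  # (features, modes)
    # deterministic phase convention: orient each mode so its mean temporal
    # coefficient is positive real (the spatial mode then shows the field
    # with the orientation it actually has on average, e.g. a planted
    # source stays a source); fall back to making the largest-magnitude
    # spatial component positive real when the time course averages to zero
    for k in range(s.size):
        m = T[:, k].mean()
        if np.abs(m) > 1e-9 * np.abs(T[:, k]).max():
            ref = m
        else:
            col = R[:, k]
            ref = col[int(np.argmax(np.abs(col)))]
        if np.abs(ref) > 0:
            d = np.conj(ref) / np.abs(ref)
            R[:, k] = R[:, k] * d
            T[:, k] = T[:, k] * d
    total = float(np.sum(s**2))
    var_frac = s**2 / total if total > 0 else np.zeros_like(s)
    return SVDResult(
        variant=variant,
        temporal=T,
        singular_values=s,
        spatial=R,
        variance_fraction=var_frac,
        grid_shape=grid_shape,
        mean=mean,
    )


def reconstruct(result: SVDResult, k: int | None = None) -> np.ndarray:
    """Rank-k reconstruction ``T_k Sigma_k R_k*`` (full rank if k is None)."""
    if k is None:
        k = result.n_modes
    if not (1 <= k <= result.n_modes):
        raise ValueError(f"k must be in [1, {result.n_modes}]")
    out = (
        result.temporal[:, :k]
        * result.singular_values[:k]
    ) @ result.spatial[:, :k].conj().T
    if result.mean is not None:
        out = out + result.mean
    return out


def mode_report(
    result: SVDResult,
    n_modes: int | None = None,
    Tpw: float = 0.85,
    edge_margin: float = 1.0,
) -> list[dict]:
    """Per-mode summary with automatic structure classification.

    Each spatial mode's vector field is passed through the per-frame
    detector: plane-wave-like if its order parameter phi exceeds ``Tpw``,
    otherwise any classified critical points are listed.
    """
    from .detection import detect_critical_points, order_parameter_phi

    if n_modes is None:
        n_modes = result.n_modes
    report = []
    for k in range(min(n_modes, result.n_modes)):
        u, v = result.spatial_mode_field(k)
        entry = {
            "mode": k,
            "variance_fraction": float(result.variance_fraction[k]),
            "singular_value": float(result.singular_values[k]),
        }
        try:
            phi = order_parameter_phi(u, v)
        except ValueError:
            phi = float("nan")
        entry["phi"] = phi
        if phi > Tpw:
            entry["structure"] = "plane_wave"
            entry["critical_points"] = []
        else:
            cps = detect_critical_points(u, v, edge_margin=edge_margin)
            entry["structure"] = "critical_points" if cps else "unstructured"
            entry["critical_points"] = [
                {"x": c.x, "y": c.y, "cls": c.cls, "ptype": c.ptype} for c in cps
            ]
        report.append(entry)
    return report


def plot_modes(
    result: SVDResult,
    n_modes: int = 4,
    out_path=None,
):
    """Quiver-plot the dominant spatial modes with their variance fractions.

    Returns the matplotlib figure; saves a PNG when ``out_path`` is given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = min(n_modes, result.n_modes)
    fig, axes = plt.subplots(1, max(n, 1), figsize=(3.2 * max(n, 1), 3.2))
    axes = np.atleast_1d(axes)
    for k in range(n):
        u, v = result.spatial_mode_field(k)
        rows, cols = u.shape
        yy, xx = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        ax = axes[k]
        ax.quiver(xx, yy, u, -v)  # y axis points down in grid coordinates
        ax.invert_yaxis()
        ax.set_aspect("equal")
        ax.set_title(
            f"mode {k + 1} ({100 * result.variance_fraction[k]:.1f}%)", fontsize=9
        )
        ax.set_xticks([])
        ax.set_yticks([])
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return fig
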