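"""Loading, validation and preprocessing of 4D spatiotemporal recordings.

The canonical in-memory representation is :class:`Recording`, holding a real
signal array with axes ``(row, col, time, trial)`` on a regular rectangular
lattice.  Row index increases downward, column index rightward; throughout the
package ``x`` refers to the column coordinate and ``y`` to the row coordinate.
Velocities are expressed in grid spaces per time step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Recording",
    "SamplingReport",
    "load_recording",
    "save_recording",
    "interpolate_bad_channels",
    "normalize_sites",
    "check_sampling_adequacy",
    "downsample_spatial",
    "smooth_spatial",
]

#: fraction of a channel's full range that consecutive samples should not
#: exceed for optical flow to remain well conditioned
FRAC_CHANGE_HIGH = 0.10
#: below this fraction the data may safely be down-sampled in time
FRAC_CHANGE_LOW = 0.01


@dataclass
class Recording:
    """A real-valued signal on a regular 2D lattice over time and trials.

    Parameters
    ----------
    signal : ndarray, shape (rows, cols, time, trials)
        Recorded samples.  May contain NaN only where ``channel_mask`` is
        False (prior to bad-channel interpolation).
    fs : float
        Sampling frequency in Hz.
    grid_spacing : float, optional
        Physical distance between adjacent sites; informational only.
    channel_mask : ndarray of bool, shape (rows, cols)
        True where a channel is valid.
    """

    signal: np.ndarray
    fs: float
    grid_spacing: float | None = None
    channel_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, dtype=float)
        if sig.ndim == 3:
            sig = sig[..., np.newaxis]
        if sig.ndim != 4:
            raise ValueError(
                f"signal must be 4D (row, col, time, trial); got {sig.ndim}D"
            )
        rows, cols, nt, _ = sig.shape
        if rows < 2 or cols < 2:
            raise ValueError("need at least 2 sites along each spatial axis")
        if nt < 2:
            raise ValueError("need at least 2 time samples")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.signal = sig
        if self.channel_mask is None:
            valid = np.isfinite(sig).all(axis=(2, 3))
            self.channel_mask = valid
        else:
            self.channel_mask = np.asarray(self.channel_mask, dtype=bool)
            if self.channel_mask.shape != (rows, cols):
                raise ValueError("channel_mask shape must match spatial grid")
        # samples on valid channels must be finite
        if not np.isfinite(sig[self.channel_mask]).all():
            raise ValueError("non-finite samples on channels marked valid")

    # -- convenience accessors -------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.signal.shape

    @property
    def n_rows(self) -> int:
        return self.signal.shape[0]

    @property
    def n_cols(self) -> int:
        return self.signal.shape[1]

    @property
    def n_times(self) -> int:
        return self.signal.shape[2]

    @property
    def n_trials(self) -> int:
        return self.signal.shape[3]


@dataclass
class SamplingReport:
    """Result of :func:`check_sampling_adequacy`."""

    max_frac_change: float
    warn_high: bool
    warn_low: bool


_CANONICAL = "rctp"


def _axes_from_layout(layout: str) -> list[int]:
    """Map a layout string onto canonical axis order (row, col, time, trial)."""
    layout = layout.lower()
    if sorted(layout) not in (sorted("rct"), sorted("rctp")):
        raise ValueError(
            f"layout must be a permutation of 'rct' or 'rctp'; got {layout!r}"
        )
    return [layout.index(ax) for ax in _CANONICAL if ax in layout]


def _read_array(path: Path, key: str | None) -> np.ndarray:
    suffix = path.suffix.lower()
    if suffix == ".npy":
        return np.load(path)
    if suffix == ".npz":
        with np.load(path) as npz:
            names = npz.files
            name = key if key is not None else names[0]
            return npz[name]
    if suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            if key is not None:
                return np.asarray(f[key])
            # first dataset found at root
            for name in f:
                if isinstance(f[name], h5py.Dataset):
                    return np.asarray(f[name])
            raise ValueError(f"no dataset found in {path}")
    if suffix == ".mat":
        from scipy.io import loadmat

        contents = loadmat(path)
        arrays = {
            k: v
            for k, v in contents.items()
            if not k.startswith("__") and isinstance(v, np.ndarray)
        }
        if key is not None:
            return arrays[key]
        if not arrays:
            raise ValueError(f"no numeric array found in {path}")
        return next(iter(arrays.values()))
    raise ValueError(f"unsupported container format: {path.suffix}")


def load_recording(
    path: str | Path,
    fs: float,
    layout: str = "rctp",
    key: str | None = None,
    grid_spacing: float | None = None,
) -> Recording:
    """Load a 3D/4D array container into canonical ``(row, col, time, trial)``.

    Parameters
    ----------
    path : path to an ``.npy``, ``.npz``, ``.h5``/``.hdf5`` or ``.mat`` file
        holding one numeric array.
    fs : sampling frequency in Hz.
    layout : permutation of ``'rctp'`` (or ``'rct'`` for trial-less data)
        describing the axis order in the file.
    key : dataset/variable name inside the container; first array if None.

    Channels containing non-finite samples are flagged invalid in the
    returned ``channel_mask``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = np.asarray(_read_array(path, key), dtype=float)
    axes = _axes_from_layout(layout)
    if arr.ndim != len(axes):
        raise ValueError(
            f"array is {arr.ndim}D but layout {layout!r} implies {len(axes)}D"
        )
    arr = np.transpose(arr, axes)
    if arr.ndim == 3:  # no trial axis -> single trial
        arr = arr[..., np.newaxis]
    return Recording(signal=arr, fs=fs, grid_spacing=grid_spacing)


def save_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording to ``.npz`` or ``.h5``; round-trips bit-exact."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".npz":
        np.savez(
            path,
            signal=rec.signal,
            fs=np.asarray(rec.fs),
            channel_mask=rec.channel_mask,
        )
    elif suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("signal", data=rec.signal)
            f.attrs["fs"] = rec.fs
            f.create_dataset("channel_mask", data=rec.channel_mask)
    else:
        raise ValueError(f"unsupported output format: {suffix}")
    return path


def interpolate_bad_channels(rec: Recording) -> Recording:
    """Fill invalid channels with the mean of their valid 4-neighbours.

    Applied synchronously and iteratively until every channel is filled, so
    the result does not depend on channel ordering.  Raises if an invalid
    region has no valid neighbour anywhere (cannot be filled).
    """
    mask = rec.channel_mask.copy()
    if mask.all():
        return rec
    sig = rec.signal.copy()
    sig[~mask] = np.nan
    rows, cols = mask.shape
    while not mask.all():
        filled_any = False
        new_sig = sig.copy()
        new_mask = mask.copy()
        for i, j in zip(*np.nonzero(~mask)):
            vals = []
            for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                ni, nj = i + di, j + dj
                if 0 <= ni < rows and 0 <= nj < cols and mask[ni, nj]:
                    vals.append(sig[ni, nj])
            if vals:
                new_sig[i, j] = np.mean(vals, axis=0)
                new_mask[i, j] = True
                filled_any = True
        if not filled_any:
            raise ValueError(
                "invalid channels with no valid neighbours cannot be interpolated"
            )
        sig, mask = new_sig, new_mask
    return Recording(
        signal=sig, fs=rec.fs, grid_spacing=rec.grid_spacing, channel_mask=mask
    )


def normalize_sites(
    rec: Recording,
    method: str = "zscore",
    baseline_window: tuple[int, int] | None = None,
) -> Recording:
    """Normalize each site/trial time series.

    ``zscore`` removes the sample mean and scales to unit variance;
    ``baseline_subtract`` removes the mean over ``baseline_window`` (a
    half-open ``(start, stop)`` index range on the time axis); ``none``
    returns the input unchanged.
    """
    if method == "none":
        return rec
    sig = rec.signal
    if method == "zscore":
        mean = sig.mean(axis=2, keepdims=True)
        std = sig.std(axis=2, keepdims=True)
        zero = std == 0
        if zero.any():
            r, c, _, p = np.argwhere(zero)[0]
            raise ValueError(
                f"zero-variance site (row={r}, col={c}, trial={p}) under zscore"
            )
        out = (sig - mean) / std
    elif method == "baseline_subtract":
        if baseline_window is None:
            raise ValueError("baseline_subtract requires baseline_window")
        start, stop = baseline_window
        if not (0 <= start < stop <= sig.shape[2]):
            raise ValueError("baseline_window outside the time axis")
        base = sig[:, :, start:stop, :].mean(axis=2, keepdims=True)
        out = sig - base
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return Recording(
        signal=out,
        fs=rec.fs,
        grid_spacing=rec.grid_spacing,
        channel_mask=rec.channel_mask,
    )


def check_sampling_adequacy(rec: Recording) -> SamplingReport:
    """Report the largest frame-to-frame change relative to each site's range.

    Optical flow assumes small changes between consecutive frames; a site
    stepping by more than 10% of its full range between frames triggers
    ``warn_high``.  A maximum step far below that (under 1% of range)
    indicates the data may be temporally down-sampled (``warn_low``).
    """
    sig = rec.signal
    rng = sig.max(axis=2) - sig.min(axis=2)  # (rows, cols, trials)
    step = np.abs(np.diff(sig, axis=2)).max(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(rng > 0, step / np.where(rng > 0, rng, 1.0), 0.0)
    max_frac = float(frac.max())
    return SamplingReport(
        max_frac_change=max_frac,
        warn_high=max_frac > FRAC_CHANGE_HIGH,
        warn_low=max_frac < FRAC_CHANGE_LOW,
    )


def downsample_spatial(rec: Recording, factor: int) -> Recording:
    """Reduce spatial resolution by block-averaging ``factor``×``factor`` cells.

    Rows/columns beyond the last full block are truncated (with a warning).
    The sampling frequency is unchanged.
    """
    if factor < 1:
        raise ValueError("factor must be a positive integer")
    if factor == 1:
        return rec
    rows, cols = rec.n_rows, rec.n_cols
    if factor > rows or factor > cols:
        raise ValueError("factor larger than a spatial dimension")
    new_r, new_c = rows // factor, cols // factor
    if rows % factor or cols % factor:
        warnings.warn(
            f"spatial dimensions ({rows}, {cols}) not divisible by {factor}; "
            "truncating trailing rows/columns",
            stacklevel=2,
        )
    sig = rec.signal[: new_r * factor, : new_c * factor]
    sig = sig.reshape(new_r, factor, new_c, factor, rec.n_times, rec.n_trials)
    out = sig.mean(axis=(1, 3))
    return Recording(signal=out, fs=rec.fs, grid_spacing=rec.grid_spacing)


def smooth_spatial(rec: Recording, sigma: float) -> Recording:
    """Optional Gaussian spatial blur applied frame-by-frame (sigma in grid units)."""
    if sigma <= 0:
        return rec
    from scipy.ndimage import gaussian_filter

    out = gaussian_filter(
        rec.signal, sigma=(sigma, sigma, 0, 0), mode="nearest"
    )
    return Recording(
        signal=out,
        fs=rec.fs,
        grid_spacing=rec.grid_spacing,
        channel_mask=rec.channel_mask,
    )
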