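"""Temporal linking of detections and transition statistics.

Per-frame critical points are chained into persistent pattern instances by
greedy nearest-neighbour matching gated on displacement and time gap, then
filtered by duration and spatial extent.  Evolution dynamics are quantified
by counting observed transitions between pattern types and comparing to the
count expected if patterns began and ended at random times,

    n_exp(pA -> pB) = nA * nB * window / t_trial,

with significance assessed by Bonferroni-corrected paired t-tests across
trials.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .detection import CriticalPoint

__all__ = [
    "PatternInstance",
    "TransitionStats",
    "link_patterns",
    "count_transitions",
    "expected_transitions",
    "transition_significance",
]

GLOBAL_TYPES = ("plane_wave", "synchrony")


@dataclass
class PatternInstance:
    """A persistent spatiotemporal pattern.

    ``trajectory`` lists ``(t, x, y)`` for complex patterns and is empty for
    global (plane-wave / synchrony) intervals.  Positions during bridged
    gaps are linearly interpolated for reporting.
    """

    ptype: str
    trial: int
    t_start: int
    t_end: int
    trajectory: list[tuple[int, float, float]] = field(default_factory=list)
    mean_extent: float = 0.0

    @property
    def duration(self) -> int:
        return self.t_end - self.t_start + 1


@dataclass
class TransitionStats:
    pairs: list[tuple[str, str]]
    observed: np.ndarray  # (n_pairs, n_trials)
    expected: np.ndarray  # (n_pairs, n_trials)
    frac_change: np.ndarray  # (n_pairs,)
    p_values: np.ndarray  # Bonferroni-corrected, NaN where not applicable
    significant: np.ndarray  # at corrected 0.05


class _Chain:
    __slots__ = ("ptype", "points", "last_t")

    def __init__(self, ptype: str, t: int, cp: CriticalPoint):
        self.ptype = ptype
        self.points = [(t, cp)]
        self.last_t = t

    @property
    def last_pos(self) -> tuple[float, float]:
        return self.points[-1][1].position


def _ptype_of(cp: CriticalPoint, combine_nodes_foci: bool, combine_spirals: bool) -> str:
    p = cp.ptype
    if combine_nodes_foci:
        if p in ("source", "spiral_out"):
            return "expanding"
        if p in ("sink", "spiral_in"):
            return "contracting"
    elif combine_spirals and p in ("spiral_in", "spiral_out"):
        return "spiral"
    return p


def _finalize(chain: _Chain, trial: int, tdur: int, min_extent: float) -> PatternInstance | None:
    t_start = chain.points[0][0]
    t_end = chain.points[-1][0]
    if t_end - t_start + 1 < tdur:
        return None
    mean_extent = float(np.mean([cp.extent for _, cp in chain.points]))
    if mean_extent < min_extent:
        return None
    # interpolate positions across bridged gaps for reporting
    ts = np.array([t for t, _ in chain.points])
    xs = np.array([cp.x for _, cp in chain.points])
    ys = np.array([cp.y for _, cp in chain.points])
    full_t = np.arange(t_start, t_end + 1)
    traj = [
        (int(t), float(np.interp(t, ts, xs)), float(np.interp(t, ts, ys)))
        for t in full_t
    ]
    return PatternInstance(
        ptype=chain.ptype,
        trial=trial,
        t_start=int(t_start),
        t_end=int(t_end),
        trajectory=traj,
        mean_extent=mean_extent,
    )


def link_patterns(
    frames: list[list[CriticalPoint]],
    Ldisp: float = 0.5,
    tgap: int = 1,
    tdur: int = 5,
    Lradius: float = 2.0,
    trial: int = 0,
    combine_nodes_foci: bool = False,
    combine_spirals: bool = False,
) -> list[PatternInstance]:
    """Chain same-type critical points across frames into pattern instances.

    Successive members of a chain must be separated by at most ``tgap + 1``
    time steps and at most ``Ldisp`` grid spaces.  Matching is greedy per
    frame by smallest displacement (ties by earlier detection order), which
    is deterministic and adequate given the tight default gate.  Chains
    shorter than ``tdur`` steps or with mean winding-number extent below
    ``Lradius`` are discarded.
    """
    active: list[_Chain] = []
    done: list[_Chain] = []
    for t, cps in enumerate(frames):
        still_active = []
        for ch in active:
            if t - ch.last_t > tgap + 1:
                done.append(ch)
            else:
                still_active.append(ch)
        active = still_active

        candidates = []
        for ci, ch in enumerate(active):
            lx, ly = ch.last_pos
            for di, cp in enumerate(cps):
                if _ptype_of(cp, combine_nodes_foci, combine_spirals) != ch.ptype:
                    continue
                d = np.hypot(cp.x - lx, cp.y - ly)
                if d <= Ldisp:
                    candidates.append((d, di, ci))
        candidates.sort()
        used_det: set[int] = set()
        used_chain: set[int] = set()
        for d, di, ci in candidates:
            if di in used_det or ci in used_chain:
                continue
            active[ci].points.append((t, cps[di]))
            active[ci].last_t = t
            used_det.add(di)
            used_chain.add(ci)
        for di, cp in enumerate(cps):
            if di not in used_det:
                active.append(
                    _Chain(_ptype_of(cp, combine_nodes_foci, combine_spirals), t, cp)
                )
    done.extend(active)
    out = []
    for ch in done:
        inst = _finalize(ch, trial, tdur, Lradius)
        if inst is not None:
            out.append(inst)
    out.sort(key=lambda p: (p.t_start, p.ptype))
    return out


def count_transitions(
    patterns: list[PatternInstance],
    window: float,
    fs: float = 1.0,
    include_self: bool = False,
) -> dict[tuple[str, str], int]:
    """Observed transition counts per ordered type pair within one trial.

    A transition pA -> pB is counted whenever an instance of pB starts
    within ``window`` seconds (strictly after) an instance of pA ends.
    Same-type transitions are excluded by default (a bridged gap is the same
    pattern, not a transition).
    """
    window_steps = window * fs
    counts: dict[tuple[str, str], int] = defaultdict(int)
    for pa in patterns:
        for pb in patterns:
            if pb is pa:
                continue
            if not include_self and pa.ptype == pb.ptype:
                continue
            lag = pb.t_start - pa.t_end
            if 0 < lag <= window_steps:
                counts[(pa.ptype, pb.ptype)] += 1
    return dict(counts)


def expected_transitions(
    nA: int, nB: int, window: float, ttrial: float
) -> float:
    """Expected transition count under the random-times null."""
    if ttrial <= 0:
        raise ValueError("ttrial must be positive")
    return nA * nB * window / ttrial


def transition_significance(
    observed: dict[tuple[str, str], np.ndarray],
    expected: dict[tuple[str, str], np.ndarray],
    alpha: float = 0.05,
) -> TransitionStats:
    """Paired t-tests of observed vs expected counts across trials.

    Requires at least two trials.  P-values are Bonferroni-corrected over
    the number of pairs tested; pairs that are identically zero in both
    observed and expected counts are reported as not applicable (NaN).
    ``frac_change`` is the mean over trials of obs/exp - 1 (trials with zero
    expectation excluded).
    """
    pairs = sorted(set(observed) | set(expected))
    if not pairs:
        return TransitionStats(
            pairs=[],
            observed=np.empty((0, 0)),
            expected=np.empty((0, 0)),
            frac_change=np.empty(0),
            p_values=np.empty(0),
            significant=np.empty(0, dtype=bool),
        )
    n_trials = len(next(iter((observed or expected).values())))
    if n_trials < 2:
        raise ValueError("transition significance requires at least 2 trials")
    obs = np.zeros((len(pairs), n_trials))
    exp = np.zeros((len(pairs), n_trials))
    for k, pair in enumerate(pairs):
        if pair in observed:
            obs[k] = observed[pair]
        if pair in expected:
            exp[k] = expected[pair]
    raw_p = np.full(len(pairs), np.nan)
    frac = np.full(len(pairs), np.nan)
    for k in range(len(pairs)):
        nz = exp[k] > 0
        if nz.any():
            frac[k] = float(np.mean(obs[k, nz] / exp[k, nz]) - 1)
        diffs = obs[k] - exp[k]
        if np.allclose(obs[k], 0) and np.allclose(exp[k], 0):
            continue  # not applicable
        if np.allclose(diffs, diffs[0]):
            # degenerate paired test (zero variance of differences)
            raw_p[k] = 0.0 if abs(diffs[0]) > 0 else 1.0
            continue
        raw_p[k] = stats.ttest_rel(obs[k], exp[k]).pvalue
    n_tests = int(np.sum(~np.isnan(raw_p)))
    corrected = np.minimum(raw_p * max(n_tests, 1), 1.0)
    significant = np.where(np.isnan(corrected), False, corrected < alpha)
    return TransitionStats(
        pairs=pairs,
        observed=obs,
        expected=exp,
        frac_change=frac,
        p_values=corrected,
        significant=significant.astype(bool),
    )
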