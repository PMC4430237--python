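"""Regime classification: single-center dynamics and network coordination patterns.

An isolated center can be silent (activity decays to zero), bursting
(sustained relaxation oscillation), or tonic (constant non-zero activity),
depending on its leak reversal potential E_L.  The two boundaries in E_L are
located by bisection on simulation-based classification.

Network coordination patterns are classified from the converged LF-RF phase
difference: synchronized (dphi near 0 or 1, "hopping"), symmetric alternation
(dphi near 0.5), or coupled alternation (anything else, the asymmetric
branches born from the pitchfork).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model_core import CenterParams
from .simulate import SolverOptions, Trajectory, detect_bursts, integrate_center

__all__ = [
    "CenterRegime",
    "PatternLabel",
    "classify_center",
    "find_regime_boundary",
    "classify_pattern",
    "TOL_SYNC",
    "TOL_ALT",
]

# Phase-classification tolerances.  The sweep data cluster tightly at 0, 0.5
# and 1; the generous synchronization tolerance absorbs near-synchronous
# overlapping-burst states that occur at the edge of the hysteresis region.
TOL_SYNC = 0.05
TOL_ALT = 0.01

# Single-center classification: simulate 60 s after a 20 s transient.
TRANSIENT_MS = 20_000.0
WINDOW_MS = 60_000.0
TONIC_MIN_ACTIVITY = 0.01
OSC_RANGE = 0.05       # minimum activity range of a sustained oscillation
MIN_OSC_CYCLES = 3


@dataclass(frozen=True)
class CenterRegime:
    """Label plus diagnostics for one isolated center."""

    label: str                 # silent | bursting | tonic | undefined
    n_bursts: int
    activity_min: float
    activity_max: float

    @property
    def activity_range(self) -> float:
        return self.activity_max - self.activity_min


@dataclass(frozen=True)
class PatternLabel:
    """Coordination pattern of the two flexor centers."""

    label: str                 # synchronized | symmetric_alternation | coupled_alternation | undefined
    dphi: float


def classify_center(E_L: float, p: CenterParams = CenterParams(),
                    solver: SolverOptions = SolverOptions(),
                    transient: float = TRANSIENT_MS,
                    window: float = WINDOW_MS) -> CenterRegime:
    """Classify an isolated center (all synaptic weights zero) at a given E_L.

    Bursting means a sustained oscillation: at least MIN_OSC_CYCLES cycles
    with activity range above OSC_RANGE in the post-transient window.  Near
    the tonic boundary the oscillation shrinks and its troughs stay above
    zero activity, so the oscillation range — not a return to full silence —
    is the bursting criterion.  Tonic means persistent, essentially constant
    activity; silent means activity has decayed to zero.
    """
    traj = integrate_center(E_L, p=p, duration=transient + window, solver=solver)
    w = traj.t >= transient
    a = traj.activity[0][w]
    a_min, a_max = float(a.min()), float(a.max())
    bursts = detect_bursts(
        Trajectory(traj.t[w], traj.V[:, w], traj.h[:, w], traj.activity[:, w]), 1)

    if a_max - a_min > OSC_RANGE:
        # count oscillation cycles as upward mean-crossings
        mid = 0.5 * (a_min + a_max)
        n_cycles = int(np.sum((a[:-1] < mid) & (a[1:] >= mid)))
        if n_cycles >= MIN_OSC_CYCLES:
            return CenterRegime("bursting", max(n_cycles, len(bursts)), a_min, a_max)
        return CenterRegime("undefined", len(bursts), a_min, a_max)
    if a_max < TONIC_MIN_ACTIVITY:
        return CenterRegime("silent", 0, a_min, a_max)
    if a_min > TONIC_MIN_ACTIVITY:
        return CenterRegime("tonic", 0, a_min, a_max)
    return CenterRegime("undefined", len(bursts), a_min, a_max)


_BOUNDARY_KINDS = {
    "silent_to_bursting": ("silent", "bursting"),
    "bursting_to_tonic": ("bursting", "tonic"),
}


def find_regime_boundary(kind: str, bracket: tuple[float, float],
                         tol: float = 0.1,
                         p: CenterParams = CenterParams(),
                         solver: SolverOptions = SolverOptions()) -> float:
    """Bisect the E_L value separating two single-center regimes.

    The bracket endpoints must classify to the two regimes named by `kind`
    (in increasing-E_L order); returns the bracket midpoint once its width is
    below `tol` (mV).
    """
    if kind not in _BOUNDARY_KINDS:
        raise ValueError(f"unknown boundary kind {kind!r}")
    lo_label, hi_label = _BOUNDARY_KINDS[kind]
    lo, hi = bracket
    if not lo < hi:
        raise ValueError("bracket must be increasing")
    got_lo = classify_center(lo, p, solver).label
    got_hi = classify_center(hi, p, solver).label
    if (got_lo, got_hi) != (lo_label, hi_label):
        raise ValueError(
            f"bracket does not straddle {kind}: endpoints classify as "
            f"({got_lo}, {got_hi}), expected ({lo_label}, {hi_label})")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if classify_center(mid, p, solver).label == lo_label:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def classify_pattern(dphi: float, tol_sync: float = TOL_SYNC,
                     tol_alt: float = TOL_ALT) -> PatternLabel:
    """Label a converged LF-RF phase difference.

    Pure function of dphi and the tolerances; NaN maps to "undefined".
    """
    if math.isnan(dphi):
        return PatternLabel("undefined", dphi)
    if min(dphi % 1.0, 1.0 - dphi % 1.0) < tol_sync:
        return PatternLabel("synchronized", dphi)
    if abs(dphi - 0.5) < tol_alt:
        return PatternLabel("symmetric_alternation", dphi)
    return PatternLabel("coupled_alternation", dphi)
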