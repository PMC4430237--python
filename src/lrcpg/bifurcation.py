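"""Bifurcation sweeps over the excitation parameter with warm-started continuation.

The excitation parameter alpha is stepped across its range; at each step the
steady state is computed and its final state seeds the next step, as in
parameter continuation.  Forward and backward sweeps together expose
hysteresis: alpha intervals where the two directions settle on different
coordination patterns are direct evidence of bistability.

Because the perfectly synchronized state (V_LF = V_RF, h_LF = h_RF) spans an
invariant manifold of the exactly symmetric vector field, a warm start taken
from a symmetric state would track that manifold forever even where it is
unstable.  Every warm start is therefore given a tiny symmetry-breaking kick
(+PERTURB_MV on V_LF, 1e-3 mV by default) so that unstable symmetric states
can escape while genuinely stable ones simply re-converge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .model_core import CenterParams, NetworkConfig, NetworkState
from .regimes import PatternLabel, classify_pattern
from .simulate import (
    ConvergenceOptions,
    CycleMetrics,
    SolverOptions,
    SteadyState,
    alt_seed,
    steady_state_metrics,
)

__all__ = [
    "SweepResult",
    "HysteresisRegion",
    "ThresholdResult",
    "sweep",
    "hysteresis_regions",
    "locate_threshold",
    "phase_vs_frequency",
    "phase_duration_curve",
    "PERTURB_MV",
]

PERTURB_MV = 1e-3


def _perturbed(state: NetworkState, eps: float = PERTURB_MV) -> NetworkState:
    s = NetworkState(state.V.copy(), state.h.copy())
    s.V[0] += eps
    return s


@dataclass
class SweepResult:
    """Per-alpha steady-state metrics for one sweep direction."""

    direction: str                     # "forward" | "backward"
    alphas: np.ndarray                 # in sweep order
    metrics: list                      # CycleMetrics | None per point
    labels: list                       # PatternLabel per point
    converged: np.ndarray              # bool per point
    oscillatory: np.ndarray            # bool per point
    final_states: list                 # NetworkState per point

    def dphi(self) -> np.ndarray:
        return np.array([m.dphi_LF_RF if m is not None else np.nan for m in self.metrics])

    def frequency(self) -> np.ndarray:
        return np.array([m.frequency if m is not None else np.nan for m in self.metrics])

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for i, a in enumerate(self.alphas):
            m = self.metrics[i]
            rows.append({
                "alpha": a,
                "direction": self.direction,
                "converged": bool(self.converged[i]),
                "oscillatory": bool(self.oscillatory[i]),
                "label": self.labels[i].label,
                "dphi_LF_RF": m.dphi_LF_RF if m else np.nan,
                "dphi_F_E": m.dphi_F_E if m else np.nan,
                "frequency_Hz": m.frequency if m else np.nan,
                "period_ms": m.period if m else np.nan,
                "amplitude_F": m.amplitude_F if m else np.nan,
                "dur_flexor_ms": m.dur_flexor if m else np.nan,
                "dur_extensor_ms": m.dur_extensor if m else np.nan,
                "duty_cycle_flexor": m.duty_cycle_flexor if m else np.nan,
            })
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class HysteresisRegion:
    """alpha interval on which forward and backward sweeps disagree."""

    alpha_lo: float
    alpha_hi: float
    label_forward: str
    label_backward: str


def sweep(direction: str, alpha_range: tuple[float, float] = (0.0, 1.2),
          n_points: int = 1000,
          p: CenterParams = CenterParams(),
          cfg: NetworkConfig = NetworkConfig(),
          seed_state: Optional[NetworkState] = None,
          conv: ConvergenceOptions = ConvergenceOptions(),
          solver: SolverOptions = SolverOptions(),
          perturb: float = PERTURB_MV) -> SweepResult:
    """Warm-started sweep of alpha in the given direction.

    The first point starts from `seed_state` (alternating-branch preset by
    default); every later point starts from the previous point's final state
    plus the symmetry-breaking kick.  Non-oscillatory points are recorded and
    the sweep continues from their (fixed-point) final state.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    alphas = np.linspace(*alpha_range, n_points)
    if direction == "backward":
        alphas = alphas[::-1]
    state = seed_state if seed_state is not None else alt_seed()

    metrics, labels, final_states = [], [], []
    convd = np.zeros(len(alphas), dtype=bool)
    osc = np.zeros(len(alphas), dtype=bool)
    for i, a in enumerate(alphas):
        r = steady_state_metrics(_perturbed(state, perturb), float(a), p, cfg, conv, solver)
        metrics.append(r.metrics)
        labels.append(classify_pattern(r.metrics.dphi_LF_RF) if r.metrics is not None
                      else PatternLabel("undefined", np.nan))
        convd[i] = r.converged
        osc[i] = r.oscillatory
        final_states.append(r.final_state)
        # A fixed point carries no branch identity (and is typically exactly
        # symmetric); chain it and the continuation silently symmetrizes.
        # Re-seed from the branch preset after non-oscillatory points instead.
        state = r.final_state if r.oscillatory else (
            seed_state if seed_state is not None else alt_seed())
    return SweepResult(direction, alphas, metrics, labels, convd, osc, final_states)


def hysteresis_regions(fwd: SweepResult, bwd: SweepResult) -> list[HysteresisRegion]:
    """alpha intervals where forward and backward pattern labels differ.

    Both sweeps must share the same alpha grid.  Points that did not converge
    (in either sweep) are ignored.  Contiguous disagreeing points are merged
    into regions.
    """
    a_f = fwd.alphas
    a_b = bwd.alphas[::-1]
    if len(a_f) != len(a_b) or not np.allclose(a_f, a_b):
        raise ValueError("sweeps must share the same alpha grid")
    lab_f = [l.label for l in fwd.labels]
    lab_b = [l.label for l in bwd.labels][::-1]
    ok = fwd.converged & bwd.converged[::-1]
    differ = np.array([ok[i] and lab_f[i] != lab_b[i] for i in range(len(a_f))])

    regions = []
    i = 0
    while i < len(differ):
        if differ[i]:
            j = i
            while j + 1 < len(differ) and differ[j + 1]:
                j += 1
            regions.append(HysteresisRegion(float(a_f[i]), float(a_f[j]),
                                            lab_f[i], lab_b[i]))
            i = j + 1
        else:
            i += 1
    return regions


@dataclass
class ThresholdResult:
    """Localized transition: alpha_star with the steady states on both sides."""

    alpha_star: float
    alpha_before: float
    alpha_after: float
    state_before: SteadyState
    state_after: SteadyState


def locate_threshold(predicate: Callable[[SteadyState], bool],
                     bracket: tuple[float, float],
                     direction: str = "forward",
                     p: CenterParams = CenterParams(),
                     cfg: NetworkConfig = NetworkConfig(),
                     seed_state: Optional[NetworkState] = None,
                     tol_alpha: float = 0.005,
                     conv: ConvergenceOptions = ConvergenceOptions(),
                     solver: SolverOptions = SolverOptions(),
                     perturb: float = PERTURB_MV) -> ThresholdResult:
    """Bisect the alpha at which `predicate` of the steady state flips.

    Direction-consistent: every trial point is warm-started from a state
    converged on the sweep's "from" side (the low-alpha side for forward,
    the high-alpha side for backward), so hysteretic thresholds are measured
    on the branch the stated sweep direction would actually follow.
    """
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    a_from, a_to = bracket
    if direction == "forward" and not a_from < a_to:
        raise ValueError("forward bracket must be increasing")
    if direction == "backward":
        if a_from < a_to:
            a_from, a_to = a_to, a_from

    seed = seed_state if seed_state is not None else alt_seed()

    def _carry(r):
        # same rule as sweep(): a fixed point has no branch identity
        return r.final_state if r.oscillatory else seed

    r_from = steady_state_metrics(_perturbed(seed, perturb), a_from, p, cfg, conv, solver)
    p_from = predicate(r_from)
    state_from = _carry(r_from)
    r_to = steady_state_metrics(_perturbed(state_from, perturb), a_to, p, cfg, conv, solver)
    p_to = predicate(r_to)
    if p_from == p_to:
        raise ValueError(
            f"predicate does not differ across bracket: {p_from} at both "
            f"alpha={a_from} and alpha={a_to}")

    r_before, r_after = r_from, r_to
    while abs(a_to - a_from) > tol_alpha:
        mid = 0.5 * (a_from + a_to)
        r_mid = steady_state_metrics(_perturbed(state_from, perturb), mid, p, cfg, conv, solver)
        if predicate(r_mid) == p_from:
            a_from = mid
            state_from = _carry(r_mid)
            r_before = r_mid
        else:
            a_to = mid
            r_after = r_mid
    return ThresholdResult(0.5 * (a_from + a_to), a_from, a_to, r_before, r_after)


def phase_vs_frequency(result: SweepResult):
    """Re-index converged oscillatory sweep points by measured frequency.

    Returns a DataFrame with columns (alpha, frequency_Hz, dphi, label); no
    interpolation is performed.
    """
    import pandas as pd

    rows = []
    for i, a in enumerate(result.alphas):
        m = result.metrics[i]
        if m is None or not result.converged[i]:
            continue
        rows.append({"alpha": a, "frequency_Hz": m.frequency,
                     "dphi": m.dphi_LF_RF, "label": result.labels[i].label})
    return pd.DataFrame(rows)


def phase_duration_curve(result: SweepResult):
    """Flexor/extensor phase durations vs cycle period (seconds) per sweep point."""
    import pandas as pd

    rows = []
    for i, a in enumerate(result.alphas):
        m = result.metrics[i]
        if m is None or not result.converged[i]:
            continue
        rows.append({"alpha": a, "period_s": m.period / 1000.0,
                     "dur_flexor_s": m.dur_flexor / 1000.0,
                     "dur_extensor_s": m.dur_extensor / 1000.0})
    return pd.DataFrame(rows)
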