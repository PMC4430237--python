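"""Fast-slow geometry: nullclines, knees (folds), and nullcline bands.

With tau_h two to three orders of magnitude slower than the membrane time
constant, a center is a relaxation oscillator whose trajectory hugs the
stable branches of the V-nullcline and jumps at its folds ("knees").  The
V-nullcline under a fixed synaptic drive is obtained by exact algebraic
inversion of the voltage equation for h:

    h(V) = -[g_L (V-E_L) + exc g_SynE (V-E_SynE) + inh g_SynI (V-E_SynI)]
           / [g_NaP m_inf(V) (V-E_Na)],

where exc/inh are summed (weight x presynaptic activity) drives.  The
h-nullcline is simply h_inf(V).  Bands of V-nullclines over a drive range
(e.g. the input received from the contralateral flexor between burst onset
and offset) support the release-on-escape vs release-on-shutdown arguments:
excitatory drive lowers the left knee, inhibitory drive raises it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import CenterParams, NetworkConfig, gating_functions

__all__ = [
    "DriveSpec",
    "NullclineCurve",
    "v_nullcline",
    "h_nullcline",
    "nullcline_band",
    "knee_count_boundary",
]

H_PHYSICAL_MAX = 1.2   # h values beyond this are reported but flagged non-physical
KNEE_REFINE_TOL = 1e-4  # mV


@dataclass(frozen=True)
class DriveSpec:
    """Synaptic drive onto one center: summed weight x activity, plus its E_L."""

    excitatory_drive: float
    inhibitory_drive: float
    E_L: float

    def __post_init__(self) -> None:
        if self.excitatory_drive < 0 or self.inhibitory_drive < 0:
            raise ValueError("drives must be non-negative")


@dataclass
class NullclineCurve:
    """h(V) along a V grid, with fold points (knees) of the curve.

    knees lists (V, h) pairs of interior local extrema of h(V); this model
    class has 0 or 2 of them (the cubic-like shape).  physical flags whether
    each h value lies within [0, H_PHYSICAL_MAX].
    """

    V: np.ndarray
    h: np.ndarray
    knees: list
    physical: np.ndarray

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"V": self.V, "h": self.h, "physical": self.physical})


def _h_on_v_nullcline(V: np.ndarray, drive: DriveSpec, p: CenterParams,
                      cfg: NetworkConfig) -> np.ndarray:
    m_inf, _, _ = gating_functions(V, p)
    num = (p.g_L * (V - drive.E_L)
           + drive.excitatory_drive * cfg.g_SynE * (V - cfg.E_SynE)
           + drive.inhibitory_drive * cfg.g_SynI * (V - cfg.E_SynI))
    den = p.g_NaP * m_inf * (V - p.E_Na)
    return -num / den


def _refine_knee(Va: float, Vb: float, drive: DriveSpec, p: CenterParams,
                 cfg: NetworkConfig) -> tuple[float, float]:
    """Bisect a sign change of dh/dV to KNEE_REFINE_TOL, via central differences."""
    eps = 1e-6

    def slope(v):
        hs = _h_on_v_nullcline(np.array([v - eps, v + eps]), drive, p, cfg)
        return hs[1] - hs[0]

    sa = slope(Va)
    while Vb - Va > KNEE_REFINE_TOL:
        mid = 0.5 * (Va + Vb)
        sm = slope(mid)
        if (sa > 0) == (sm > 0):
            Va, sa = mid, sm
        else:
            Vb = mid
    Vk = 0.5 * (Va + Vb)
    hk = float(_h_on_v_nullcline(np.array([Vk]), drive, p, cfg)[0])
    return Vk, hk


def v_nullcline(drive: DriveSpec, p: CenterParams = CenterParams(),
                cfg: NetworkConfig = NetworkConfig(),
                V_grid: np.ndarray | None = None) -> NullclineCurve:
    """V-nullcline h(V) under a fixed synaptic drive, with knee detection.

    Exact algebraic inversion (no root-finding); the grid must exclude E_Na,
    where the persistent-sodium driving force vanishes.  Knees are grid sign
    changes of dh/dV refined by bisection.
    """
    if V_grid is None:
        V_grid = np.arange(-75.0, -10.0, 0.01)
    V_grid = np.asarray(V_grid, dtype=float)
    if np.any(np.isclose(V_grid, p.E_Na, atol=1e-9)):
        raise ValueError("V grid must exclude E_Na (division by zero)")
    h = _h_on_v_nullcline(V_grid, drive, p, cfg)
    dh = np.diff(h)
    sign_change = np.where(np.sign(dh[:-1]) * np.sign(dh[1:]) < 0)[0]
    knees = [_refine_knee(V_grid[i], V_grid[i + 2], drive, p, cfg) for i in sign_change]
    physical = (h >= 0.0) & (h <= H_PHYSICAL_MAX)
    return NullclineCurve(V_grid, h, knees, physical)


def h_nullcline(p: CenterParams = CenterParams(),
                V_grid: np.ndarray | None = None) -> NullclineCurve:
    """h-nullcline: the steady-state inactivation h_inf(V), monotone decreasing."""
    if V_grid is None:
        V_grid = np.arange(-75.0, -10.0, 0.01)
    V_grid = np.asarray(V_grid, dtype=float)
    _, h_inf, _ = gating_functions(V_grid, p)
    return NullclineCurve(V_grid, h_inf, [], np.ones_like(V_grid, dtype=bool))


def nullcline_band(drive_lo: DriveSpec, drive_hi: DriveSpec,
                   p: CenterParams = CenterParams(),
                   cfg: NetworkConfig = NetworkConfig(),
                   V_grid: np.ndarray | None = None):
    """Pair of V-nullclines spanning a drive range, with their knees.

    Both drives must share E_L.  Returns (lower_curve, upper_curve) in the
    order given; their knee lists support release-on-escape vs
    release-on-shutdown comparisons via relative knee heights.
    """
    if drive_lo.E_L != drive_hi.E_L:
        raise ValueError("band edges must share E_L")
    lo = v_nullcline(drive_lo, p, cfg, V_grid)
    hi = v_nullcline(drive_hi, p, cfg, V_grid)
    return lo, hi


def knee_count_boundary(bracket: tuple[float, float] = (-60.0, -45.0),
                        tol: float = 1e-3,
                        p: CenterParams = CenterParams(),
                        cfg: NetworkConfig = NetworkConfig()) -> float:
    """E_L at which the drive-free V-nullcline loses its two knees (cubic shape).

    Bisection on the knee count of the uncoupled nullcline; this is the
    geometric counterpart of the bursting-to-tonic transition.
    """
    def n_knees(EL):
        return len(v_nullcline(DriveSpec(0.0, 0.0, EL), p, cfg).knees)

    lo, hi = bracket
    if n_knees(lo) < 2 or n_knees(hi) != 0:
        raise ValueError("bracket must go from 2 knees to 0 knees")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if n_knees(mid) >= 2:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
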