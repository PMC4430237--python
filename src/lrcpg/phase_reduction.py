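"""Weak-coupling phase model of left-right flexor coordination.

For weak commissural coupling, each side reduces to a phase oscillator and
the phase difference phi between left and right flexors obeys

    dphi/dt = G(phi),      G(phi) = A sin(phi) - B sin(2 phi),

the first two terms of the Fourier expansion of an odd, 2*pi-periodic
coupling function.  phi = 0 (synchronization / hopping) and phi = pi
(alternation) are always fixed points; phi = 0 is stable iff A < 2B and
phi = pi is stable iff A > -2B, so for -2B < A < 2B (possible only with
B > 0) both coexist — the bistability seen in the single-knockout sweeps.
Interior fixed points at arccos(A/2B) separate the two basins.

The effective coupling A aggregates the commissural pathways: excitatory
flexor-flexor coupling (V3) pushes toward synchronization (enters with minus
sign), while V0_D inhibition and the crossed extensor-to-flexor V0_V
excitation (effectively inhibitory between flexors) push toward alternation:

    A(alpha) = -V3_0 + V0V_0 + V0D_0 + alpha * (-k3 + k0V + k0D),

each pathway strength growing affinely with the excitation parameter alpha.
A potential P(phi) = -int G dphi = A cos(phi) - (B/2) cos(2 phi) renders
stable states as valleys.

B is not constrained by the pathway weights; only A/(2B) matters for the
topology, and B defaults to 1.  The default pathway parameters are the
illustrative values used for the published scenario diagrams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "PhaseReductionParams",
    "FixedPoint",
    "effective_coupling_A",
    "coupling_G",
    "potential_P",
    "fixed_points",
    "reduced_bifurcation_diagram",
]


@dataclass(frozen=True)
class PhaseReductionParams:
    """Basal strengths and alpha-slopes of the three commissural pathways.

    Defaults are the illustrative scenario values: V3_0=4, k3=2, V0V_0=0,
    k0V=3, V0D_0=11, k0D=0, B=1.  With them the intact A(alpha) = 7 + alpha
    stays above 2B for every alpha >= 0, so only alternation is stable.
    """

    V3_0: float = 4.0
    k3: float = 2.0
    V0V_0: float = 0.0
    k0V: float = 3.0
    V0D_0: float = 11.0
    k0D: float = 0.0
    B: float = 1.0

    def __post_init__(self) -> None:
        for name in ("V3_0", "k3", "V0V_0", "k0V", "V0D_0", "k0D"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class FixedPoint:
    phi: float          # radians in [0, 2*pi)
    stability: str      # "stable" | "unstable" | "degenerate"


_KNOCKOUTS = {
    "intact": (),
    "dV0V": ("V0V",),
    "dV0D": ("V0D",),
    "dV0": ("V0V", "V0D"),
}


def _apply_knockout(params: PhaseReductionParams, knockout: str) -> PhaseReductionParams:
    if knockout not in _KNOCKOUTS:
        raise ValueError(f"unknown knockout {knockout!r}; choose from {sorted(_KNOCKOUTS)}")
    kw = {}
    for path in _KNOCKOUTS[knockout]:
        if path == "V0V":
            kw.update(V0V_0=0.0, k0V=0.0)
        if path == "V0D":
            kw.update(V0D_0=0.0, k0D=0.0)
    return replace(params, **kw)


def effective_coupling_A(alpha: float,
                         params: PhaseReductionParams = PhaseReductionParams(),
                         knockout: str = "intact") -> float:
    """Effective flexor-flexor coupling A(alpha); affine in alpha.

    A knockout zeroes both the basal strength and the slope of the deleted
    pathway, so with both V0 types removed A = -V3_0 - alpha*k3 < 0 always.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    q = _apply_knockout(params, knockout)
    return (-q.V3_0 + q.V0V_0 + q.V0D_0) + alpha * (-q.k3 + q.k0V + q.k0D)


def coupling_G(phi, A: float, B: float):
    """Phase-difference velocity G(phi) = A sin(phi) - B sin(2 phi); odd, 2*pi-periodic."""
    phi = np.asarray(phi, dtype=float)
    return A * np.sin(phi) - B * np.sin(2.0 * phi)


def potential_P(phi, A: float, B: float):
    """Potential P(phi) = A cos(phi) - (B/2) cos(2 phi), with -dP/dphi = G."""
    phi = np.asarray(phi, dtype=float)
    return A * np.cos(phi) - 0.5 * B * np.cos(2.0 * phi)


def _stability(dG: float, tol: float = 1e-12) -> str:
    if dG < -tol:
        return "stable"
    if dG > tol:
        return "unstable"
    return "degenerate"


def fixed_points(A: float, B: float) -> list[FixedPoint]:
    """All fixed points of dphi/dt = G(phi) on [0, 2*pi), with stability.

    phi = 0 and phi = pi always; interior roots phi* = arccos(A/2B) and
    2*pi - phi* exist when B != 0 and |A/(2B)| <= 1, with stability opposite
    to the adjacent 0/pi points.  dG/dphi = A cos(phi) - 2B cos(2 phi).
    """
    pts = [FixedPoint(0.0, _stability(A - 2.0 * B)),
           FixedPoint(math.pi, _stability(-A - 2.0 * B))]
    if B != 0.0 and abs(A / (2.0 * B)) <= 1.0:
        phi_star = math.acos(A / (2.0 * B))
        dG = A * math.cos(phi_star) - 2.0 * B * math.cos(2.0 * phi_star)
        if phi_star not in (0.0, math.pi):
            pts.append(FixedPoint(phi_star, _stability(dG)))
            pts.append(FixedPoint(2.0 * math.pi - phi_star, _stability(dG)))
    return sorted(pts, key=lambda fp: fp.phi)


def reduced_bifurcation_diagram(params: PhaseReductionParams = PhaseReductionParams(),
                                knockout: str = "intact",
                                alpha_grid: np.ndarray | None = None):
    """Fixed-point branches of the reduced model over an alpha grid.

    Returns a DataFrame with columns (alpha, A, phi, dphi, stability), where
    dphi = phi / 2*pi is the normalized phase difference matching the
    full-model diagrams.
    """
    import pandas as pd

    if alpha_grid is None:
        alpha_grid = np.linspace(0.0, 8.0, 401)
    rows = []
    for a in np.asarray(alpha_grid, dtype=float):
        A = effective_coupling_A(a, params, knockout)
        for fp in fixed_points(A, params.B):
            rows.append({"alpha": a, "A": A, "phi": fp.phi,
                         "dphi": fp.phi / (2.0 * math.pi), "stability": fp.stability})
    return pd.DataFrame(rows)
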