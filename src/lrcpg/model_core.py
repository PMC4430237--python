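"""Equations and parameter containers for the four-center locomotor CPG model.

The network consists of four activity-based (non-spiking) centers — left/right
flexor (LF, RF) and left/right extensor (LE, RE) — each a two-variable
conditional burster driven by the persistent sodium current I_NaP.  Per center,

    C dV/dt = -I_NaP - I_L - I_SynE - I_SynI,
    tau_h(V) dh/dt = h_inf(V) - h,

with I_NaP = g_NaP * m_inf(V) * h * (V - E_Na) and I_L = g_L * (V - E_L).
Population output is the piecewise-linear activity f(V) in [0, 1].

Left and right sides are coupled by three commissural pathways: excitatory V3
(flexor <-> flexor), inhibitory V0_D (flexor <-> flexor), and excitatory V0_V
(extensor -> contralateral flexor).  On each side the flexor inhibits the
extensor (weight b1) and the extensor inhibits the flexor (weight b2).

A single excitation parameter alpha (mimicking NMDA concentration) raises the
leak reversal potentials of all centers and scales the excitatory commissural
weights:

    E_LF = E_LF0 * (1 - beta_E * alpha),    a_3 = a_30 * (1 + beta_a * alpha),
    E_LE = E_LE0 * (1 - beta_E * alpha),    a_V = a_V0 * (1 + beta_a * alpha).

Units are fixed as pF / nS / mV / ms (currents in pA) throughout; no
conversion factors appear anywhere.

Center index convention: 1 = LF, 2 = LE, 3 = RF, 4 = RE (0-based internally).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from importlib import resources
from typing import NamedTuple

import numpy as np

__all__ = [
    "CenterParams",
    "NetworkConfig",
    "NetworkState",
    "Excitation",
    "default_center_params",
    "default_network_config",
    "output_activity",
    "gating_functions",
    "excitation_map",
    "single_center_rhs",
    "network_rhs",
    "save_params",
    "load_params",
]


@dataclass(frozen=True)
class CenterParams:
    """Intrinsic constants of one rhythm-generating center.

    Defaults reproduce the published parameter set for the I_NaP burster:
    capacitance and conductances in pF/nS, voltages in mV, times in ms.
    """

    C: float = 20.0            # membrane capacitance (pF)
    g_NaP: float = 5.0         # max persistent-Na conductance (nS)
    g_L: float = 2.8           # leak conductance (nS)
    E_Na: float = 50.0         # Na reversal potential (mV)
    V_mNaP: float = -40.0      # I_NaP activation half-voltage (mV)
    k_mNaP: float = -6.0       # activation slope (mV, negative)
    V_hNaP: float = -55.0      # inactivation half-voltage (mV)
    k_hNaP: float = 10.0       # inactivation slope (mV, positive)
    V_tauNaP: float = -40.0    # center of the tau_h(V) curve (mV)
    k_tauNaP: float = -12.0    # width of the tau_h(V) curve (mV)
    tau_hNaP_max: float = 4000.0  # max inactivation time constant (ms)
    V_min: float = -50.0       # output-function threshold (mV)
    V_max: float = 0.0         # output-function saturation (mV)

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.g_NaP < 0:
            raise ValueError("g_NaP must be non-negative")
        if self.g_L <= 0:
            raise ValueError("g_L must be positive")
        if self.tau_hNaP_max <= 0:
            raise ValueError("tau_hNaP_max must be positive")
        if not self.V_min < self.V_max:
            raise ValueError("V_min must be below V_max")
        if not self.k_mNaP < 0:
            raise ValueError("k_mNaP must be negative (activation increases with V)")
        if not self.k_hNaP > 0:
            raise ValueError("k_hNaP must be positive (inactivation decreases with V)")


@dataclass(frozen=True)
class NetworkConfig:
    """Coupling weights, synaptic constants, and alpha-scaling coefficients.

    Pathway knockouts are expressed as boolean flags that zero the
    corresponding weight, leaving the published default weights intact —
    mirroring genetic elimination of a commissural interneuron class.
    """

    E_LF0: float = -63.0     # basal flexor leak reversal (mV), silent side of the bursting band
    E_LE0: float = -50.0     # basal extensor leak reversal (mV), tonic when uncoupled
    beta_E: float = 0.1      # fractional rise of E_L per unit alpha
    g_SynE: float = 0.1      # max excitatory synaptic conductance (nS)
    g_SynI: float = 0.6      # max inhibitory synaptic conductance (nS)
    E_SynE: float = -10.0    # excitatory synaptic reversal (mV)
    E_SynI: float = -75.0    # inhibitory synaptic reversal (mV)
    a_30: float = 0.5        # basal V3 weight (flexor <-> flexor excitation)
    a_V0: float = 0.5        # basal V0_V weight (extensor -> contralateral flexor)
    a_D: float = 0.35        # V0_D weight (flexor <-> flexor inhibition), alpha-independent
    b_1: float = 10.0        # ipsilateral flexor -> extensor inhibition
    b_2: float = 0.1         # ipsilateral extensor -> flexor inhibition
    beta_a: float = 3.0      # fractional rise of excitatory weights per unit alpha
    include_V0D: bool = True
    include_V0V: bool = True
    include_V3: bool = True

    def __post_init__(self) -> None:
        for name in ("a_30", "a_V0", "a_D", "b_1", "b_2", "g_SynE", "g_SynI"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.E_SynI < self.E_SynE:
            raise ValueError("E_SynI must be below E_SynE")


@dataclass
class NetworkState:
    """Instantaneous state of the four-center network.

    V and h are length-4 arrays ordered (LF, LE, RF, RE).  h stays inside
    [0, 1] under the dynamics whenever it starts there.
    """

    V: np.ndarray
    h: np.ndarray

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float).copy()
        self.h = np.asarray(self.h, dtype=float).copy()
        if self.V.shape != (4,) or self.h.shape != (4,):
            raise ValueError("NetworkState requires length-4 V and h")

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.V, self.h])

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "NetworkState":
        y = np.asarray(y, dtype=float)
        return cls(V=y[:4], h=y[4:])

    def mirrored(self) -> "NetworkState":
        """Swap left and right sides (LF<->RF, LE<->RE)."""
        idx = np.array([2, 3, 0, 1])
        return NetworkState(V=self.V[idx], h=self.h[idx])


def default_center_params() -> CenterParams:
    return CenterParams()


def default_network_config(**overrides) -> NetworkConfig:
    return NetworkConfig(**overrides)


def output_activity(V, p: CenterParams = CenterParams()):
    """Piecewise-linear population output f(V) in [0, 1].

    0 below V_min, 1 above V_max, linear in between.  Vectorized over V.
    """
    V = np.asarray(V, dtype=float)
    f = (V - p.V_min) / (p.V_max - p.V_min)
    return np.clip(f, 0.0, 1.0)


class GatingValues(NamedTuple):
    m_inf: np.ndarray
    h_inf: np.ndarray
    tau_h: np.ndarray


def gating_functions(V, p: CenterParams = CenterParams()) -> GatingValues:
    """Steady-state I_NaP activation/inactivation and inactivation time constant.

    m_inf increases with V (k_mNaP < 0), h_inf decreases (k_hNaP > 0);
    tau_h peaks at tau_hNaP_max at V = V_tauNaP.
    """
    V = np.asarray(V, dtype=float)
    m_inf = 1.0 / (1.0 + np.exp((V - p.V_mNaP) / p.k_mNaP))
    h_inf = 1.0 / (1.0 + np.exp((V - p.V_hNaP) / p.k_hNaP))
    tau_h = p.tau_hNaP_max / np.cosh((V - p.V_tauNaP) / p.k_tauNaP)
    return GatingValues(m_inf, h_inf, tau_h)


class Excitation(NamedTuple):
    """alpha-resolved drive levels and commissural weights (knockouts applied)."""

    E_LF: float
    E_LE: float
    a_3: float
    a_V: float
    a_D: float


def excitation_map(alpha: float, cfg: NetworkConfig = NetworkConfig()) -> Excitation:
    """Resolve the excitation parameter alpha into leak reversals and weights.

    E_L values rise linearly with alpha (they are negative, so the factor
    (1 - beta_E*alpha) moves them toward zero); the excitatory commissural
    weights a_3 and a_V grow as (1 + beta_a*alpha).  Knockout flags zero the
    corresponding weight after scaling.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    E_LF = cfg.E_LF0 * (1.0 - cfg.beta_E * alpha)
    E_LE = cfg.E_LE0 * (1.0 - cfg.beta_E * alpha)
    a_3 = cfg.a_30 * (1.0 + cfg.beta_a * alpha) if cfg.include_V3 else 0.0
    a_V = cfg.a_V0 * (1.0 + cfg.beta_a * alpha) if cfg.include_V0V else 0.0
    a_D = cfg.a_D if cfg.include_V0D else 0.0
    return Excitation(E_LF, E_LE, a_3, a_V, a_D)


def single_center_rhs(
    V: float,
    h: float,
    E_L: float,
    p: CenterParams = CenterParams(),
    exc_drive: float = 0.0,
    inh_drive: float = 0.0,
    g_SynE: float = 0.1,
    g_SynI: float = 0.6,
    E_SynE: float = -10.0,
    E_SynI: float = -75.0,
):
    """Right-hand side of one center with fixed synaptic drive.

    exc_drive / inh_drive are summed (weight x presynaptic activity) terms, so
    the synaptic currents are drive * g_Syn * (V - E_Syn).  Used for the
    uncoupled model, nullcline verification, and fast-slow geometry.
    Returns (dV/dt, dh/dt) in mV/ms and 1/ms.
    """
    m_inf, h_inf, tau_h = gating_functions(V, p)
    I_NaP = p.g_NaP * m_inf * h * (V - p.E_Na)
    I_L = p.g_L * (V - E_L)
    I_SynE = exc_drive * g_SynE * (V - E_SynE)
    I_SynI = inh_drive * g_SynI * (V - E_SynI)
    dV = -(I_NaP + I_L + I_SynE + I_SynI) / p.C
    dh = (h_inf - h) / tau_h
    return dV, dh


def synaptic_drives(f: np.ndarray, exc: Excitation, cfg: NetworkConfig):
    """Summed excitatory and inhibitory drives (weight x activity) per center.

    f is the length-4 activity vector (LF, LE, RF, RE).  Flexors receive V3
    excitation from the contralateral flexor and V0_V excitation from the
    contralateral extensor; they are inhibited by the contralateral flexor
    (V0_D) and the ipsilateral extensor (b2).  Extensors receive only
    ipsilateral flexor inhibition (b1) and no excitatory synaptic input.
    """
    fLF, fLE, fRF, fRE = f
    exc_drive = np.array(
        [
            exc.a_3 * fRF + exc.a_V * fRE,   # -> LF
            0.0,                             # -> LE
            exc.a_3 * fLF + exc.a_V * fLE,   # -> RF
            0.0,                             # -> RE
        ]
    )
    inh_drive = np.array(
        [
            exc.a_D * fRF + cfg.b_2 * fLE,   # -> LF
            cfg.b_1 * fLF,                   # -> LE
            exc.a_D * fLF + cfg.b_2 * fRE,   # -> RF
            cfg.b_1 * fRF,                   # -> RE
        ]
    )
    return exc_drive, inh_drive


def network_rhs(
    state: NetworkState,
    alpha: float,
    p: CenterParams = CenterParams(),
    cfg: NetworkConfig = NetworkConfig(),
):
    """Vector field of the four-center network at excitation alpha.

    Returns (dV/dt, dh/dt) as length-4 arrays.  Equivariant under the
    left<->right index swap; reduces to four uncoupled single-center systems
    when all activities are zero.
    """
    exc = excitation_map(alpha, cfg)
    V, h = state.V, state.h
    m_inf, h_inf, tau_h = gating_functions(V, p)
    f = output_activity(V, p)
    exc_drive, inh_drive = synaptic_drives(f, exc, cfg)

    E_L = np.array([exc.E_LF, exc.E_LE, exc.E_LF, exc.E_LE])
    I_NaP = p.g_NaP * m_inf * h * (V - p.E_Na)
    I_L = p.g_L * (V - E_L)
    I_SynE = exc_drive * cfg.g_SynE * (V - cfg.E_SynE)
    I_SynI = inh_drive * cfg.g_SynI * (V - cfg.E_SynI)
    dV = -(I_NaP + I_L + I_SynE + I_SynI) / p.C
    dh = (h_inf - h) / tau_h
    return dV, dh


# ---------------------------------------------------------------------------
# Parameter serialization
# ---------------------------------------------------------------------------

def save_params(path, p: CenterParams, cfg: NetworkConfig) -> None:
    """Write center and network parameters to a JSON file."""
    with open(path, "w") as fh:
        json.dump({"center": asdict(p), "network": asdict(cfg)}, fh, indent=2)


def load_params(path) -> tuple[CenterParams, NetworkConfig]:
    """Read parameters written by :func:`save_params` (unknown keys rejected)."""
    with open(path) as fh:
        blob = json.load(fh)
    unknown = set(blob) - {"center", "network"}
    if unknown:
        raise ValueError(f"unknown top-level keys: {sorted(unknown)}")
    return CenterParams(**blob.get("center", {})), NetworkConfig(**blob.get("network", {}))


def bundled_default_params() -> tuple[CenterParams, NetworkConfig]:
    """Load the bundled default parameter file (identical to the dataclass defaults)."""
    text = resources.files("lrcpg.data").joinpath("default_params.json").read_text()
    blob = json.loads(text)
    return CenterParams(**blob["center"]), NetworkConfig(**blob["network"])
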