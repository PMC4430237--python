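"""Numerical integration, burst-event extraction, and per-cycle metrics.

The network is a relaxation-oscillator system: V moves on a millisecond
timescale while h follows tau_h up to 4 s, and the piecewise-linear output
f(V) has kinks at V_min/V_max.  The workhorse integrator is a compiled
fixed-step RK4 at dt = 0.1 ms (non-stiff at these scales; the kinks rule out
high-order adaptive error control being meaningful anyway).  SciPy's adaptive
RK45 with max_step <= 1 ms is available as an independent cross-check via
``SolverOptions(method="rk45")``.

Burst onsets/offsets are threshold crossings of f(V) with hysteresis
(theta_on > theta_off) and sub-sample linear interpolation of crossing times.
Cycle metrics follow the standard fictive-locomotion conventions: the period
is the interval between successive left-flexor (LF) burst onsets, phase
differences are onset lags divided by the period, and the extensor phase
duration is the period minus the flexor burst duration (extensors are
tonically driven and shaped by flexor inhibition, so complementarity defines
them unambiguously even when both extensors are co-active).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .model_core import (
    CenterParams,
    NetworkConfig,
    NetworkState,
    excitation_map,
    network_rhs,
    output_activity,
)

__all__ = [
    "SolverOptions",
    "ConvergenceOptions",
    "Trajectory",
    "BurstEvent",
    "CycleMetrics",
    "SteadyState",
    "cold_start",
    "sync_seed",
    "alt_seed",
    "integrate",
    "integrate_center",
    "detect_bursts",
    "cycle_metrics",
    "steady_state_metrics",
]

# Default burst-detection thresholds: small hysteresis debounces threshold
# chatter near f ~ 0 without affecting onset times of full-size bursts.
THETA_ON = 0.05
THETA_OFF = 0.02
MIN_GAP_MS = 50.0


@dataclass(frozen=True)
class SolverOptions:
    """Integrator settings.

    method "rk4": compiled fixed-step RK4 (default).  method "rk45": SciPy
    adaptive RK45 with max_step capped at 1 ms.  record_dt is the output
    sampling interval; noise_amp (pA) enables additive current noise via
    Euler-Maruyama with a mandatory seed.
    """

    method: str = "rk4"
    dt: float = 0.1              # fixed step (ms)
    record_dt: float = 1.0       # output grid (ms)
    rtol: float = 1e-8           # rk45 only
    atol: float = 1e-10          # rk45 only
    max_step: float = 1.0        # rk45 only (ms)
    noise_amp: float = 0.0       # additive current noise amplitude (pA)
    noise_seed: Optional[int] = None


@dataclass(frozen=True)
class ConvergenceOptions:
    """Steady-state convergence settings for warm-started sweeps."""

    tol: float = 1e-3          # circular tolerance on successive dphi values
    n_consec: int = 3          # number of consecutive small differences required
    discard_cycles: int = 5    # transient cycles dropped before testing
    t_cap: float = 300_000.0   # per-point model-time cap (ms)
    chunk: float = 30_000.0    # integration chunk (ms)
    settle_window: float = 10_000.0  # window for the fixed-point (silence) test (ms)


@dataclass
class Trajectory:
    """Time series of the four centers: t (ms), V and h (4 x N), activity f(V)."""

    t: np.ndarray
    V: np.ndarray
    h: np.ndarray
    activity: np.ndarray

    def final_state(self) -> NetworkState:
        return NetworkState(V=self.V[:, -1], h=self.h[:, -1])

    def to_dataframe(self):
        import pandas as pd

        cols = {"t": self.t}
        for i in range(4):
            cols[f"V{i + 1}"] = self.V[i]
        for i in range(4):
            cols[f"h{i + 1}"] = self.h[i]
        for i in range(4):
            cols[f"f{i + 1}"] = self.activity[i]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass(frozen=True)
class BurstEvent:
    """One burst of a center: onset/offset times (ms) and peak activity."""

    center_id: int   # 1=LF, 2=LE, 3=RF, 4=RE
    t_onset: float
    t_offset: float
    peak_activity: float

    def __post_init__(self) -> None:
        if not self.t_onset < self.t_offset:
            raise ValueError("burst onset must precede offset")

    @property
    def duration(self) -> float:
        return self.t_offset - self.t_onset


@dataclass(frozen=True)
class CycleMetrics:
    """Per-cycle locomotor metrics measured from LF burst onsets.

    dphi values are onset lags divided by the period, wrapped to [0, 1);
    NaN marks a cycle in which the contralateral/extensor onset was missing.
    """

    period: float          # ms
    frequency: float       # Hz (= 1000 / period)
    amplitude_F: float     # peak LF activity in the cycle
    dphi_LF_RF: float
    dphi_F_E: float
    dur_flexor: float      # ms, LF burst duration
    dur_extensor: float    # ms, period - dur_flexor
    duty_cycle_flexor: float


# ---------------------------------------------------------------------------
# Initial-condition presets
# ---------------------------------------------------------------------------

def cold_start() -> NetworkState:
    """Deterministic near-symmetric start; +1 mV on LF breaks exact symmetry."""
    return NetworkState(V=np.array([-59.0, -60.0, -60.0, -60.0]), h=np.full(4, 0.6))


def sync_seed() -> NetworkState:
    """Both flexors poised to fire together (probes the synchronized branch)."""
    return NetworkState(V=np.array([-40.0, -60.0, -40.0, -60.0]),
                        h=np.array([0.7, 0.6, 0.7, 0.6]))


def alt_seed() -> NetworkState:
    """Flexors in opposite phases (probes the alternating branch)."""
    return NetworkState(V=np.array([-40.0, -60.0, -65.0, -60.0]),
                        h=np.array([0.7, 0.6, 0.4, 0.6]))


# ---------------------------------------------------------------------------
# Compiled integrator core
# ---------------------------------------------------------------------------
# Parameter vector layout for the jitted kernels (alpha and knockouts already
# resolved): [C, gNaP, gL, ENa, VmNaP, kmNaP, VhNaP, khNaP, VtauNaP, ktauNaP,
# tau_max, Vmin, Vmax, gSynE, gSynI, ESynE, ESynI, a3, aV, aD, b1, b2,
# EL1, EL2, EL3, EL4]

def _pack(alpha: float, p: CenterParams, cfg: NetworkConfig,
          E_L_override: Optional[float] = None) -> np.ndarray:
    exc = excitation_map(alpha, cfg)
    if E_L_override is None:
        E_L = (exc.E_LF, exc.E_LE, exc.E_LF, exc.E_LE)
    else:
        E_L = (E_L_override,) * 4
    return np.array(
        [p.C, p.g_NaP, p.g_L, p.E_Na, p.V_mNaP, p.k_mNaP, p.V_hNaP, p.k_hNaP,
         p.V_tauNaP, p.k_tauNaP, p.tau_hNaP_max, p.V_min, p.V_max,
         cfg.g_SynE, cfg.g_SynI, cfg.E_SynE, cfg.E_SynI,
         exc.a_3, exc.a_V, exc.a_D, cfg.b_1, cfg.b_2,
         E_L[0], E_L[1], E_L[2], E_L[3]],
        dtype=np.float64,
    )


@njit(cache=True)
def _rhs(y, pv, dy):
    C = pv[0]
    gNaP = pv[1]
    gL = pv[2]
    ENa = pv[3]
    Vm = pv[4]
    km = pv[5]
    Vh = pv[6]
    kh = pv[7]
    Vtau = pv[8]
    ktau = pv[9]
    tau_max = pv[10]
    Vmin = pv[11]
    Vmax = pv[12]
    gSynE = pv[13]
    gSynI = pv[14]
    ESynE = pv[15]
    ESynI = pv[16]
    a3 = pv[17]
    aV = pv[18]
    aD = pv[19]
    b1 = pv[20]
    b2 = pv[21]

    f = np.empty(4)
    for i in range(4):
        v = y[i]
        if v < Vmin:
            f[i] = 0.0
        elif v >= Vmax:
            f[i] = 1.0
        else:
            f[i] = (v - Vmin) / (Vmax - Vmin)

    # summed weight x activity drives; extensors get no excitatory input
    excd0 = a3 * f[2] + aV * f[3]
    excd2 = a3 * f[0] + aV * f[1]
    inhd0 = aD * f[2] + b2 * f[1]
    inhd1 = b1 * f[0]
    inhd2 = aD * f[0] + b2 * f[3]
    inhd3 = b1 * f[2]
    excd = (excd0, 0.0, excd2, 0.0)
    inhd = (inhd0, inhd1, inhd2, inhd3)

    for i in range(4):
        v = y[i]
        hh = y[4 + i]
        m_inf = 1.0 / (1.0 + math.exp((v - Vm) / km))
        h_inf = 1.0 / (1.0 + math.exp((v - Vh) / kh))
        tau = tau_max / math.cosh((v - Vtau) / ktau)
        I_NaP = gNaP * m_inf * hh * (v - ENa)
        I_L = gL * (v - pv[22 + i])
        I_SynE = excd[i] * gSynE * (v - ESynE)
        I_SynI = inhd[i] * gSynI * (v - ESynI)
        dy[i] = -(I_NaP + I_L + I_SynE + I_SynI) / C
        dy[4 + i] = (h_inf - hh) / tau


@njit(cache=True)
def _rk4(y0, pv, dt, n_steps, rec_every):
    n_rec = n_steps // rec_every + 1
    out = np.empty((n_rec, 8))
    t_out = np.empty(n_rec)
    y = y0.copy()
    k1 = np.empty(8)
    k2 = np.empty(8)
    k3 = np.empty(8)
    k4 = np.empty(8)
    tmp = np.empty(8)
    out[0] = y
    t_out[0] = 0.0
    j = 1
    for step in range(1, n_steps + 1):
        _rhs(y, pv, k1)
        for i in range(8):
            tmp[i] = y[i] + 0.5 * dt * k1[i]
        _rhs(tmp, pv, k2)
        for i in range(8):
            tmp[i] = y[i] + 0.5 * dt * k2[i]
        _rhs(tmp, pv, k3)
        for i in range(8):
            tmp[i] = y[i] + dt * k3[i]
        _rhs(tmp, pv, k4)
        for i in range(8):
            y[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
        if step % rec_every == 0 and j < n_rec:
            out[j] = y
            t_out[j] = step * dt
            j += 1
    return t_out[:j], out[:j], y


@njit(cache=True)
def _euler_maruyama(y0, pv, dt, n_steps, rec_every, sigma, seed):
    """Additive white current noise on V (pA); fixed-step stochastic scheme."""
    np.random.seed(seed)
    n_rec = n_steps // rec_every + 1
    out = np.empty((n_rec, 8))
    t_out = np.empty(n_rec)
    y = y0.copy()
    dy = np.empty(8)
    C = pv[0]
    sq = sigma * math.sqrt(dt) / C
    out[0] = y
    t_out[0] = 0.0
    j = 1
    for step in range(1, n_steps + 1):
        _rhs(y, pv, dy)
        for i in range(8):
            y[i] += dt * dy[i]
        for i in range(4):
            y[i] += sq * np.random.normal()
        if step % rec_every == 0 and j < n_rec:
            out[j] = y
            t_out[j] = step * dt
            j += 1
    return t_out[:j], out[:j], y


def _integrate_packed(y0: np.ndarray, pv: np.ndarray, duration: float,
                      solver: SolverOptions) -> Trajectory:
    if duration <= 0:
        raise ValueError("duration must be positive")
    if solver.method == "rk4":
        rec_every = max(1, int(round(solver.record_dt / solver.dt)))
        n_steps = int(round(duration / solver.dt))
        if solver.noise_amp > 0.0:
            if solver.noise_seed is None:
                raise ValueError("noise requires an explicit noise_seed")
            t, Y, _ = _euler_maruyama(y0, pv, solver.dt, n_steps, rec_every,
                                      solver.noise_amp, solver.noise_seed)
        else:
            t, Y, _ = _rk4(y0, pv, solver.dt, n_steps, rec_every)
        V = Y[:, :4].T.copy()
        h = Y[:, 4:].T.copy()
    elif solver.method == "rk45":
        from scipy.integrate import solve_ivp

        if solver.noise_amp > 0.0:
            raise ValueError("noise is only supported with the fixed-step scheme")

        def fun(_t, y):
            dy = np.empty(8)
            _rhs(y, pv, dy)
            return dy

        t_eval = np.arange(0.0, duration + 0.5 * solver.record_dt, solver.record_dt)
        sol = solve_ivp(fun, (0.0, duration), y0, method="RK45", t_eval=t_eval,
                        rtol=solver.rtol, atol=solver.atol, max_step=solver.max_step)
        if not sol.success:
            raise RuntimeError(f"integration failed at t={sol.t[-1]:.1f} ms: {sol.message}")
        t = sol.t
        V = sol.y[:4]
        h = sol.y[4:]
    else:
        raise ValueError(f"unknown solver method {solver.method!r}")

    Vmin, Vmax = pv[11], pv[12]
    activity = np.clip((V - Vmin) / (Vmax - Vmin), 0.0, 1.0)
    return Trajectory(t=t, V=V, h=h, activity=activity)


def integrate(initial: NetworkState, alpha: float,
              p: CenterParams = CenterParams(),
              cfg: NetworkConfig = NetworkConfig(),
              duration: float = 60_000.0,
              solver: SolverOptions = SolverOptions()) -> Trajectory:
    """Integrate the four-center network for `duration` ms."""
    pv = _pack(alpha, p, cfg)
    return _integrate_packed(initial.as_vector(), pv, duration, solver)


def integrate_center(E_L: float, p: CenterParams = CenterParams(),
                     initial: tuple[float, float] = (-60.0, 0.6),
                     duration: float = 60_000.0,
                     solver: SolverOptions = SolverOptions()) -> Trajectory:
    """Integrate a single uncoupled center at an explicit leak reversal E_L.

    All synaptic weights are zero, so the four network slots evolve as
    identical independent copies; read any one of them.
    """
    cfg = NetworkConfig(a_30=0.0, a_V0=0.0, a_D=0.0, b_1=0.0, b_2=0.0)
    pv = _pack(0.0, p, cfg, E_L_override=E_L)
    V0, h0 = initial
    y0 = np.array([V0] * 4 + [h0] * 4, dtype=float)
    return _integrate_packed(y0, pv, duration, solver)


# ---------------------------------------------------------------------------
# Burst detection
# ---------------------------------------------------------------------------

def _cross_time(t0, t1, a0, a1, level):
    """Linear interpolation of the time at which activity crosses `level`."""
    if a1 == a0:
        return t0
    return t0 + (level - a0) / (a1 - a0) * (t1 - t0)


def detect_bursts(traj: Trajectory, center_id: int,
                  theta_on: float = THETA_ON, theta_off: float = THETA_OFF,
                  min_gap: float = MIN_GAP_MS) -> list[BurstEvent]:
    """Extract burst events from f(V) of one center.

    Onset = upward crossing of theta_on; offset = subsequent downward crossing
    of theta_off.  Events separated by silent gaps shorter than min_gap are
    merged; a burst already in progress at t=0 and a trailing burst without an
    offset are dropped as incomplete.
    """
    if not 0.0 < theta_off < theta_on < 1.0:
        raise ValueError("require 0 < theta_off < theta_on < 1")
    a = traj.activity[center_id - 1]
    t = traj.t
    events: list[BurstEvent] = []
    in_burst = a[0] >= theta_on
    skip_first = in_burst  # partial burst at the start of the record
    t_on = t[0]
    on_idx = 0
    for i in range(1, len(a)):
        if not in_burst and a[i - 1] < theta_on <= a[i]:
            in_burst = True
            t_on = _cross_time(t[i - 1], t[i], a[i - 1], a[i], theta_on)
            on_idx = i
        elif in_burst and a[i - 1] >= theta_off > a[i]:
            in_burst = False
            t_off = _cross_time(t[i - 1], t[i], a[i - 1], a[i], theta_off)
            if skip_first:
                skip_first = False
                continue
            peak = float(np.max(a[max(on_idx - 1, 0):i + 1]))
            if events and t_on - events[-1].t_offset < min_gap:
                prev = events.pop()
                events.append(BurstEvent(center_id, prev.t_onset, t_off,
                                         max(prev.peak_activity, peak)))
            else:
                events.append(BurstEvent(center_id, t_on, t_off, peak))
    return events


# ---------------------------------------------------------------------------
# Cycle metrics
# ---------------------------------------------------------------------------

def _first_onset_in(events: Sequence[BurstEvent], t0: float, t1: float):
    for ev in events:
        if t0 <= ev.t_onset < t1:
            return ev.t_onset
    return None


def cycle_metrics(bursts_LF: Sequence[BurstEvent],
                  bursts_RF: Sequence[BurstEvent],
                  bursts_LE: Sequence[BurstEvent] = ()) -> list[CycleMetrics]:
    """Per-cycle metrics from burst event lists.

    Each cycle spans successive LF onsets.  dphi_LF_RF is the lag of the first
    RF onset in the cycle divided by the period (wrapped to [0,1)); dphi_F_E
    likewise with LE onsets.  Cycles missing the contralateral (or extensor)
    onset get NaN for that phase.
    """
    if len(bursts_LF) < 2:
        raise ValueError("need at least two LF bursts to form a cycle")
    out = []
    for ev, ev_next in zip(bursts_LF[:-1], bursts_LF[1:]):
        period = ev_next.t_onset - ev.t_onset
        t_rf = _first_onset_in(bursts_RF, ev.t_onset, ev_next.t_onset)
        dphi = ((t_rf - ev.t_onset) / period) % 1.0 if t_rf is not None else math.nan
        t_le = _first_onset_in(bursts_LE, ev.t_onset, ev_next.t_onset)
        dphi_fe = ((t_le - ev.t_onset) / period) % 1.0 if t_le is not None else math.nan
        dur_f = ev.duration
        out.append(CycleMetrics(
            period=period,
            frequency=1000.0 / period,
            amplitude_F=ev.peak_activity,
            dphi_LF_RF=dphi,
            dphi_F_E=dphi_fe,
            dur_flexor=dur_f,
            dur_extensor=period - dur_f,
            duty_cycle_flexor=dur_f / period,
        ))
    return out


def circular_diff(a: float, b: float) -> float:
    """Distance between two phases in [0,1) on the circle."""
    d = abs(a - b) % 1.0
    return min(d, 1.0 - d)


# ---------------------------------------------------------------------------
# Steady-state convergence
# ---------------------------------------------------------------------------

@dataclass
class SteadyState:
    """Outcome of steady_state_metrics.

    oscillatory=False marks relaxation to a fixed point (a distinct outcome
    from non-convergence, which leaves converged=False with metrics from the
    last observed cycle).
    """

    metrics: Optional[CycleMetrics]
    converged: bool
    oscillatory: bool
    final_state: NetworkState
    n_cycles: int
    dphi_history: np.ndarray
    t_total: float


def steady_state_metrics(initial: NetworkState, alpha: float,
                         p: CenterParams = CenterParams(),
                         cfg: NetworkConfig = NetworkConfig(),
                         conv: ConvergenceOptions = ConvergenceOptions(),
                         solver: SolverOptions = SolverOptions()) -> SteadyState:
    """Integrate in chunks until the LF-RF phase difference settles.

    Convergence requires `n_consec` successive circular differences of
    dphi_LF_RF below `tol` after discarding the first `discard_cycles` cycles.
    Returns the last cycle's metrics together with the final state for
    warm-starting continuation sweeps.
    """
    pv = _pack(alpha, p, cfg)
    y = initial.as_vector()
    t_parts: list[np.ndarray] = []
    y_parts: list[np.ndarray] = []
    t_offset = 0.0
    n_steps_chunk = int(round(conv.chunk / solver.dt))
    rec_every = max(1, int(round(solver.record_dt / solver.dt)))

    while True:
        t, Y, y = _rk4(y, pv, solver.dt, n_steps_chunk, rec_every)
        t_parts.append(t[1:] + t_offset)
        y_parts.append(Y[1:])
        t_offset += t[-1]

        t_all = np.concatenate(t_parts)
        Y_all = np.concatenate(y_parts)
        Vmin, Vmax = pv[11], pv[12]
        act = np.clip((Y_all[:, :4].T - Vmin) / (Vmax - Vmin), 0.0, 1.0)
        traj = Trajectory(t=t_all, V=Y_all[:, :4].T, h=Y_all[:, 4:].T, activity=act)

        lf = detect_bursts(traj, 1)
        if len(lf) < 2:
            # possibly a fixed point: test whether activity has settled
            w = t_all >= t_all[-1] - conv.settle_window
            settled = np.all(np.ptp(act[:, w], axis=1) < 1e-4)
            if settled and t_offset >= 2 * conv.chunk:
                return SteadyState(None, True, False, NetworkState(Y_all[-1, :4], Y_all[-1, 4:]),
                                   0, np.empty(0), t_offset)
            if t_offset >= conv.t_cap:
                return SteadyState(None, False, len(lf) > 0,
                                   NetworkState(Y_all[-1, :4], Y_all[-1, 4:]), len(lf),
                                   np.empty(0), t_offset)
            continue

        rf = detect_bursts(traj, 3)
        le = detect_bursts(traj, 2)
        cycles = cycle_metrics(lf, rf, le)
        dphi = np.array([c.dphi_LF_RF for c in cycles])
        usable = dphi[conv.discard_cycles:]
        if len(usable) >= conv.n_consec + 1 and not np.any(np.isnan(usable[-(conv.n_consec + 1):])):
            tail = usable[-(conv.n_consec + 1):]
            diffs = [circular_diff(tail[i + 1], tail[i]) for i in range(conv.n_consec)]
            if max(diffs) < conv.tol:
                return SteadyState(cycles[-1], True, True,
                                   NetworkState(Y_all[-1, :4], Y_all[-1, 4:]),
                                   len(cycles), dphi, t_offset)
        if t_offset >= conv.t_cap:
            return SteadyState(cycles[-1] if cycles else None, False, True,
                               NetworkState(Y_all[-1, :4], Y_all[-1, 4:]),
                               len(cycles), dphi, t_offset)
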