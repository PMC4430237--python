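# Methods

## Model

Each rhythm-generating center is an activity-based, non-spiking population
model with two state variables: the mean membrane potential `V` (mV) and the
slow inactivation gate `h` of the persistent sodium current. Per center,

```
C dV/dt = -I_NaP - I_L - I_SynE - I_SynI
tau_h(V) dh/dt = h_inf(V) - h

I_NaP = g_NaP * m_inf(V) * h * (V - E_Na)
I_L   = g_L * (V - E_L)
m_inf(V) = 1 / (1 + exp((V - V_mNaP)/k_mNaP)),   k_mNaP < 0
h_inf(V) = 1 / (1 + exp((V - V_hNaP)/k_hNaP)),   k_hNaP > 0
tau_h(V) = tau_max / cosh((V - V_tauNaP)/k_tauNaP)
```

Population output is the piecewise-linear `f(V)`: 0 below `V_min = -50` mV,
1 above `V_max = 0` mV, linear between. The kinks are kept exact (no
smoothing). Units are pF/nS/mV/ms throughout, so currents are in pA with no
conversion factors.

The network has four centers — left/right flexor (LF, RF) and left/right
extensor (LE, RE) — with:

* V3: mutual flexor–flexor excitation, weight `a_3`;
* V0_D: mutual flexor–flexor inhibition, weight `a_D`;
* V0_V: crossed extensor→flexor excitation, weight `a_V`;
* ipsilateral flexor→extensor inhibition `b_1` and extensor→flexor
  inhibition `b_2`.

Extensor centers receive no excitatory synaptic input. A single excitation
parameter `alpha` (0–1.2 by default), standing in for the NMDA concentration
used to control fictive-locomotion frequency in isolated-cord preparations,
raises all leak reversals, `E_L = E_L0 (1 - beta_E alpha)`, and scales the
excitatory commissural weights, `a_3 = a_30 (1 + beta_a alpha)` and likewise
`a_V`. Knockouts of a commissural class are flags that zero the corresponding
weight after scaling; the default parameter values are never edited. The
default parameter set (bundled as `data/default_params.json`) is: C = 20 pF,
g_NaP = 5 nS, g_L = 2.8 nS, E_Na = 50 mV, V_mNaP = −40, k_mNaP = −6,
V_hNaP = −55, k_hNaP = 10, V_tauNaP = −40, k_tauNaP = −12, tau_max = 4000 ms,
E_LF0 = −63, E_LE0 = −50, g_SynE = 0.1 nS, g_SynI = 0.6 nS, E_SynE = −10,
E_SynI = −75, a_30 = a_V0 = 0.5, a_D = 0.35, b_1 = 10, b_2 = 0.1,
beta_E = 0.1, beta_a = 3.

With these intrinsic parameters an isolated center is silent for
E_L below ≈ −62.2 mV, a burster up to ≈ −54.1 mV, and tonically active above.
The flexor basal leak reversal sits just below the bursting band (flexors are
conditional bursters recruited by excitation) and the extensor basal value
above it (extensors are tonic unless inhibited) — the flexor-dominated,
asymmetric half-center architecture.

## Numerics

The vector field is non-stiff at these scales but has kinks from `f(V)`, and
warm-started sweeps need on the order of 1e6 right-hand-side evaluations per
sweep point. The default integrator is therefore a compiled (numba)
fixed-step RK4 at `dt = 0.1 ms` with output sampled at 1 ms; SciPy's adaptive
RK45 (max step 1 ms, rtol 1e-8) is available through
`SolverOptions(method="rk45")` and serves as an independent cross-check in
the tests. Halving the fixed step changes converged phase differences by
less than 1e-3 (tested). Threshold crossings for burst detection are
interpolated linearly between output samples, so onset times are resolved
well below the output grid.

Burst detection uses an onset threshold `theta_on = 0.05` on `f(V)` with a
release threshold `theta_off = 0.02` and a 50 ms merge gap; the hysteresis
debounces chatter near threshold without affecting full-size bursts. Cycle
period is the interval between successive LF burst onsets; phase differences
are onset lags divided by the period, wrapped to [0, 1). The extensor phase
duration is defined as period minus flexor burst duration: extensors are
tonically driven and shaped by flexor inhibition, so complementarity defines
the extensor phase unambiguously even when both extensors are co-active at
low excitation.

Steady states are declared when, after discarding the first 5 cycles, the
circular difference of successive LF–RF phase values stays below 1e-3 for 3
consecutive cycles (2e-4 over 4 cycles during threshold bisection, which
needs phase resolution finer than the pinning tolerance); the per-point model
time cap is 300 s. Relaxation to a fixed point (activity range < 1e-4 over
10 s) is reported as a distinct non-oscillatory outcome.

## Sweeps, symmetry, and seeding

Bifurcation structure is read off warm-started parameter sweeps: `alpha` is
stepped across [0, 1.2] (1000 steps by default; the analyses shipped here use
100 plus bisection refinement for speed) and each step starts from the
previous step's final state. Two details matter:

* **Symmetry kick.** The perfectly synchronized state (`V_LF = V_RF`,
  `h_LF = h_RF`) spans an invariant manifold of the exactly left–right
  equivariant vector field. A warm start taken from a symmetric state
  therefore tracks synchronization forever — even where it is unstable —
  because no numerical asymmetry is ever introduced (the integrator is
  equivariant to the last bit). Every warm start consequently receives a
  +1e-3 mV kick on `V_LF`: unstable symmetric states escape, stable ones
  re-converge. This deliberately replaces bit-exact warm starting.
* **Re-seeding after silence.** A fixed point carries no branch identity
  (and is typically exactly symmetric), so after a non-oscillatory point the
  next point is re-seeded from the sweep's branch preset rather than from
  the fixed point.

Branch presets: `cold` (near-rest with +1 mV on LF), `alt-seed` (flexors in
opposite phases), `sync-seed` (flexors poised to fire together). Branch
identity at low excitation (phase difference below vs above 0.5) is chosen by
the preset.

Thresholds in `alpha` are localized by direction-consistent bisection: each
trial is warm-started from a state converged on the sweep's "from" side, so
hysteretic transitions are measured on the branch the stated direction
follows. Hysteresis regions are intervals where forward and backward sweeps
disagree in pattern label; coordination labels use `tol_sync = 0.05` (phase
distance from 0/1; generous enough to absorb near-synchronous
overlapping-burst states at the edge of the bistable interval) and
`tol_alt = 0.01` (distance from 0.5).

Single-center regimes are classified from 60 s of model time after a 20 s
transient. "Bursting" is a sustained oscillation: at least 3 cycles with an
activity range above 0.05. Near the tonic boundary the oscillation shrinks
smoothly and its troughs stay above zero activity, so requiring a return to
full silence would misplace the boundary; the oscillation-range criterion
reproduces the geometric picture (the boundary where the V-nullcline loses
its knees lies ~0.5 mV above the dynamical oscillation death, the expected
fold–Hopf offset at this finite timescale separation).

## Fast–slow geometry

V-nullclines under fixed synaptic drive are computed by exact algebraic
inversion for `h(V)`; drives are summed (weight × presynaptic activity)
scalars, matching how the input bands are parameterized in the analysis
(maximal/minimal presynaptic activity). Knees are sign changes of `dh/dV`
on a 0.01 mV grid refined by bisection to 1e-4 mV — a closed-form derivative
exists, but grid-plus-refinement is robust to the `f(V)` kink. `h` values
outside [0, 1.2] are reported but flagged non-physical. Excitatory drive
lowers the left knee's `h`-coordinate and inhibitory drive raises it, which
is the geometric content of the two synchronizing mechanisms: release-on-
escape (the lagging flexor sits above the excited knee and jumps with the
leader → synchronization) versus release-on-shutdown (it activates only when
the leader's inhibition ends → alternation).

## Phase reduction

For weak coupling the left–right phase difference obeys
`dphi/dt = G(phi) = A sin(phi) - B sin(2 phi)`, the first two harmonics of an
odd 2π-periodic coupling function. `phi = 0` (hopping) is stable iff
`A < 2B`, `phi = pi` (alternation) iff `A > -2B`; both are stable for
`-2B < A < 2B`, which requires `B > 0` — the second harmonic is what makes
bistability possible. Interior fixed points `arccos(A/2B)` are the basin
separatrices. The effective coupling aggregates the pathways,
`A(alpha) = -V3_0 + V0V_0 + V0D_0 + alpha (-k3 + k0V + k0D)`, each strength
affine in `alpha`; knockouts zero both the basal value and the slope of the
deleted pathway. Default illustrative values V3_0=4, k3=2, V0V_0=0, k0V=3,
V0D_0=11, k0D=0 give the four scenario topologies (intact: alternation always
stable; both V0 deleted: hopping always stable; single knockouts: pitchfork
transitions in opposite directions). `B` is not determined by the pathway
weights — only `A/2B` matters for topology — and defaults to 1; quantitative
`alpha` values of the reduced model's bifurcations are therefore illustrative,
and only branch topology is asserted.

## Known limitations and parameter-set caveat

The default parameter set is implemented exactly as published. Two printed
constants could not be reconciled with results computed from that same set:

* the printed silent→bursting boundary is −62.7 mV, while the printed
  parameters yield −62.22 mV (confirmed independently by the algebraic
  knee-crossing geometry and by both integrators);
* several published transition positions in `alpha` (the intact pitchfork
  near 0.55, the V0_D-deleted switch near 0.8, the V0_V-deleted loss of
  alternation near 0.9) correspond in this implementation to the same
  transitions at systematically lower excitation — the flexor duty cycle
  reaches 0.5 earlier in `alpha`, compressing the coupled-alternation
  window toward the oscillation onset, and the V0_V-deleted anti-phase
  branch remains stable up to `alpha = 1.2` when followed by continuation
  (its loss is then measured as a basin boundary from alternating-seed
  starts).

All qualitative structure — the three single-center regimes, intact
alternation at every excitation level, hopping when both V0 classes are
removed, frequency-dependent pattern switching in opposite directions for
the two single knockouts, bistability with hysteresis between them, monotone
frequency rise and amplitude fall, and the much stronger dependence of the
extensor phase duration on cycle period — is reproduced. No parameter was
adjusted away from the published values to improve quantitative agreement.

Other limitations: no spiking dynamics, motoneurons, or afferent circuitry;
the alternative V0_V routing through ipsilateral inhibitory relays is not
modeled (only the crossed extensor→flexor excitation); the additive
current-noise option (Euler–Maruyama, seed required) exists to reproduce
intermittent pattern switching qualitatively and is not validated against
recordings; and no Lyapunov/Floquet machinery is provided — stability is
operational, i.e. what converged simulations from perturbed starts do.
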