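# lrcpg — left–right coordination in locomotor CPG circuits

`lrcpg` implements a simplified four-center model of the mammalian spinal
locomotor network and the dynamical-systems machinery used to analyze how
genetically identified commissural interneuron (CIN) classes shape left–right
limb coordination. It is aimed at computational neuroscientists studying
central pattern generators (CPGs), gait transitions, and the
frequency-dependent roles of the V0_D, V0_V and V3 commissural pathways.

## The model

Each of four rhythm-generating centers — left/right flexor (LF, RF) and
left/right extensor (LE, RE) — is an activity-based, non-spiking population
model driven by the persistent sodium current I_NaP:

```
C V̇ᵢ = −ḡ_NaP m∞(Vᵢ) hᵢ (Vᵢ − E_Na) − ḡ_L (Vᵢ − E_L,i) − I_SynE,i − I_SynI,i
τ_h(Vᵢ) ḣᵢ = h∞(Vᵢ) − hᵢ
```

with population output f(V) piecewise-linear between V_min = −50 mV and
V_max = 0 mV. Flexors are conditional bursters; extensors, if uncoupled, are
tonically active. The sides are coupled by mutual flexor–flexor excitation
(V3), mutual flexor–flexor inhibition (V0_D), and crossed extensor→flexor
excitation (V0_V); on each side the flexor inhibits its extensor (b₁) and
vice versa (b₂). A single excitation parameter α ∈ [0, 1.2] — a stand-in for
the NMDA concentration that sets fictive-locomotion frequency in isolated
spinal cords — raises every leak reversal, E_L = E_L0(1 − β_E α), and scales
the excitatory commissural weights, a₃ = a₃₀(1 + β_a α), a_V = a_V0(1 + β_a α).
Genetic CIN ablations are represented by flags that zero the corresponding
pathway weight.

The package provides:

* `model_core` — equations, parameter containers, JSON serialization;
* `simulate` — compiled RK4 / SciPy RK45 integration, burst detection,
  per-cycle metrics (frequency, flexor amplitude, LF–RF and flexor–extensor
  phase differences, phase durations), steady-state convergence;
* `regimes` — silent/bursting/tonic classification of an isolated center and
  synchronized/alternation labeling of network patterns;
* `bifurcation` — warm-started forward/backward sweeps over α, hysteresis
  (bistability) detection, direction-consistent threshold bisection, and the
  phase-vs-frequency transform;
* `phase_plane` — V- and h-nullclines, knee (fold) detection, nullcline
  bands for fast–slow (release-on-escape vs release-on-shutdown) arguments;
* `phase_reduction` — the weak-coupling phase model
  φ̇ = A sin φ − B sin 2φ with A(α) assembled from pathway strengths, its
  fixed points, stability, potential landscape and scenario diagrams;
* `cli` — scenario presets (`intact`, `dV0V`, `dV0D`, `dV0`), result
  bundles, and the `lrcpg` command-line tool.

See `docs/methods.md` for the numerical choices and their rationale.

## Worked example

```python
from lrcpg import alt_seed, classify_pattern, preset_scenario, steady_state_metrics

sc = preset_scenario("intact")
r = steady_state_metrics(alt_seed(), alpha=0.8, p=sc.center, cfg=sc.network)
m = r.metrics
print(f"converged: {r.converged} after {r.n_cycles} cycles")
print(f"frequency: {m.frequency:.3f} Hz   period: {m.period/1000:.2f} s")
print(f"LF-RF phase difference: {m.dphi_LF_RF:.3f}  -> {classify_pattern(m.dphi_LF_RF).label}")
print(f"flexor amplitude: {m.amplitude_F:.3f}   flexor duty cycle: {m.duty_cycle_flexor:.3f}")
```

prints

```
converged: True after 10 cycles
frequency: 0.426 Hz   period: 2.34 s
LF-RF phase difference: 0.500  -> symmetric_alternation
flexor amplitude: 0.548   flexor duty cycle: 0.534
```

i.e. at α = 0.8 the intact network walks: the two flexor centers burst in
perfect anti-phase (Δφ = 0.5) at 0.43 Hz, each flexor burst filling about
half the cycle. Repeating the same call with `preset_scenario("dV0")` (both
V0 CIN classes removed) yields Δφ = 1.000 → `synchronized`: the hopping gait
observed in V0-ablated mice. Sweeps expose how these patterns change with
excitation:

```
lrcpg sweep --scenario dV0V --direction forward --n-points 200 --out sweep.csv
lrcpg hysteresis --scenario dV0V --n-points 200 --out regions.csv
lrcpg phase-reduction --scenario dV0D --alpha-max 8 --out branches.csv
```

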