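# Methods

This note documents the models implemented in `nmdashunt`, the parameter
choices that matter, the numerical procedures, and the limits of what the
package's synthetic experiments can show.

## 1. Steady-state single-compartment model (`nmdashunt.nmda`)

A dendritic membrane patch is one electrical node with a leak conductance
`g_L → E_L = −70 mV`, an optional shunting conductance `g_I → E_I` (default
−70 mV, i.e. a pure shunt), and `N_syn` glutamate-bound NMDA channels of
unitary conductance `g_unit` (default 50 pS, a typical single-channel value;
only the product `N_syn·g_unit` matters, so thresholds are reported both as
counts and as nS). The NMDA conductance is

```
g_NMDA(V, t) = N_syn · g_unit · p(t) · B(V)
```

with the normalized biexponential gating `p(t)` (τ_rise = 2.1 ms,
τ_decay = 18.8 ms; peak exactly 1 at t* = ln(τs/τf)·τsτf/(τs−τf) ≈ 5.18 ms)
and the exponential Mg²⁺-block factor
`B(V) = 1/(1 + ([Mg]/η)·e^(−γV))`, `[Mg] = 1 mM`, `η = 3.57 mM`.

**Capacitive currents are ignored** (quasi-static assumption): the NMDA
conductance dwells near its peak long enough for the membrane to equilibrate.
The membrane potential is then the root of the Kirchhoff current balance;
when several roots exist, the one **closest to the resting potential** is
taken. The N-shaped NMDA I–V relation makes the system bistable over a window
of `N_syn`; as `N_syn` crosses the upper edge of that window the nearest-rest
root jumps discontinuously onto the depolarized branch — the NMDA spike.

**Block steepness γ.** The default is γ = 0.10 /mV (e-fold per 10 mV). This
is a deliberate choice, not the classic γ = 0.062 /mV: a short calculation
shows that multiple current-balance roots require
`γ·(1 − B(V)) > 1/(V − E_L) + 1/(E_NMDA − V)` for some V, and with
E_L = −70 mV, E_NMDA = 0 mV the right-hand side has a floor of ≈ 0.057 /mV
(at V ≈ −35 mV). With γ = 0.062 the inequality is unreachable at any Mg²⁺
concentration — the steady-state circuit would have a *unique* equilibrium at
every excitation level, hence no all-or-none spike at all. γ = 0.10 lies
within the range of steeper Mg-unblock characterizations used in
basal-dendrite NMDA-spike modeling and yields a robustly regenerative
geometry whose plateau saturates (the equilibrium rises by <3% of the
depolarization between threshold and 1.5× threshold). Because threshold and
spike height follow from an exact co-scaling argument (both saddle-node
conditions are linear in `N_syn` and in total leak), two key results are
*independent of γ*: threshold ∝ total leak conductance, and spike height at
the initiation site invariant under pure shunts.

**Root finding.** The residual is scanned on a 0.1 mV grid over
[min(E_L, E_I) − 20, E_NMDA + 20] mV (all physical roots lie inside), sign
changes are refined by Brent's method to 10⁻⁶ mV. The spike threshold is
found by an exhaustive integer scan of `N_syn`; a count is classified as
spiking when its only equilibrium lies above the separatrix (the unstable
middle root remembered from the bistable window, or — if the window is
narrower than one grid step — when the nearest-rest root jumps by more than
¼ of (E_NMDA − rest)). Optional bisection refines the threshold to a
requested fractional resolution (0.01 is used for percentage effects).

## 2. Two-compartment and chain model (`nmdashunt.chain`)

The canonical circuit is a dendritic node (NMDA + `g_dL` + `g_dI`) coupled by
an axial conductance `g_a` to a somatic node (`g_sL` + `g_sI`); all
inhibitory reversals default to rest. Everything except the NMDA conductance
is ohmic, so the network seen from the NMDA node collapses to a Thevenin
equivalent and the single-compartment solver applies unchanged; the other
node voltages follow from the passive divider relations. Two exact
consequences organize the phenomenology:

* input conductance at the dendrite
  `g_TotalL = g_dL + g_dI + g_a(g_sL + g_sI)/(g_a + g_sL + g_sI)` — the
  spike threshold is proportional to it;
* attenuation `A = (g_a + g_sL + g_sI)/g_a` — with reversals at rest,
  somatic depolarization equals dendritic depolarization divided by `A` at
  every solution point, so somatic inhibition is exactly divisive at the
  soma.

The chain generalization to N nodes (reduction sweeping in from both ends,
back-substitution outward from the NMDA node) is package plumbing that lets
on-path placements be probed in the steady-state framework; the two-node
configuration is the validated core. The worked example set
(`g_dL=1, g_dI=3, g_a=4, g_sL=6, g_sI=3`) reproduces the printed circuit
quantities exactly and is used by `scripts/acceptance.py`; sweeps may instead
use configurations satisfying the "attenuation ≥ 5" design constraint — both
are exposed in config.

**Effect summaries.** Percentage changes are computed on depolarization
relative to rest (V − rest), matching the experimental definition; each
inhibited configuration is compared against the no-inhibition control.
Threshold changes are ratios of threshold counts (refined to 0.01);
"height" is the somatic depolarization on the spike plateau, evaluated at 3×
the configuration's own threshold (the plateau is flat there, and
divisiveness makes the ratio independent of the evaluation point — a tested
invariant). With a non-rest inhibitory reversal, each model's own resting
state is the baseline, mirroring slice measurements taken on top of the
IPSP.

## 3. Cable model (`nmdashunt.cable`)

A ball-and-stick surrogate: soma modeled as an iso-potential cylinder
(20 µm, length = diameter) plus one unbranched dendrite (default 200 µm,
tapering 1.5 → 0.8 µm, ≤ 10 µm compartments, 2 µm default). The placement
protocols use a 300 µm dendrite so inhibition can sit 80 µm distal to
excitation at 125 µm. Passive parameters: R_m 10 kΩ·cm² (dendrite) /
20 kΩ·cm² (soma), C_m 2 / 1 µF/cm², R_a 100 Ω·cm (the source table prints
"100 Ωm", read as a typographic unit slip — 100 Ω·m would be 100× the usual
cortical value). Hodgkin–Huxley Na⁺/K⁺ channels with standard squid-derived
rate functions at low densities: Na 25 (soma) / 3 (dendrite) pS/µm² — the
dendritic value is a flagged reading of a source figure printed in volume
units (0.003 pS/µm³) — and K 3 / 0.03 pS/µm². The qualitative results do not
depend on these channels (a tested property); they are included for realism
of the somatic response.

**Somatic tree load.** A reconstructed pyramidal cell presents the basal
dendrite with the conductance and capacitance of the entire remaining tree.
The surrogate adds this as a lumped somatic load, `g_load = 15 nS` and
`c_load = 300 pF`, sized to the ~60 MΩ somatic input resistance reported for
these cells and a ~20 ms time constant. Without it the soma would follow the
dendrite almost one-to-one and the location dichotomy (which lives in the
dendrite-to-soma impedance mismatch) would disappear.

**Synapses.** Biexponential conductances normalized to unit peak: AMPA
(0.05/0.5 ms, E = 0 mV), NMDA (2.1/18.8 ms, E = 0 mV, multiplied by the same
Mg-block factor as in the steady-state model, evaluated at the previous
step's voltage), GABA_A (E = −70 mV) with the two printed kinetic pairs
("short": 0.5/100 ms, "long": 0.5/2 ms — the labels look inverted in the
source table and are preserved as printed; "short" i.e. the 100 ms-decay
pair is the default, emulating sustained iontophoresis-like inhibition).
Excitatory synapses sit 0.5 µm apart around 125 µm from the soma, 6 nS peak
AMPA each, single 0.1 ms-pulse activation; GABA onset leads excitation by
10 ms. Poisson-train stimulation (50 Hz default) is available and requires
an explicit seeded generator.

**NMDA:AMPA peak ratio.** The source's value is behind a figure placeholder.
The default 1.0 was fixed once from a pilot on the surrogate: it places the
control spike threshold mid-range of a 0–36 synapse axis (as in the
reference input–output curves), whereas 2.0 pushed the threshold to ~2
synapses, too coarse to quantify. It is a config parameter.

**Inhibition strengths.** Somatic sweeps use the published 30–150 nS range
(90 nS default). Dendritic placements default to 2–8 nS rather than the
published 10–40 nS: the surrogate's thin unbranched dendrite has a local
input conductance of only a few nS (no spines, branches, or sister
dendrites), so the published values extinguish spiking over any practical
stimulus range. The guiding principle — mirror the source, which chose
conductances producing input-resistance changes comparable to experiment —
is applied to the surrogate's own impedances.

**Integration.** Backward Euler (Crank–Nicolson optional) on the tridiagonal
compartment system, dt = 0.025 ms (enforced ceiling); synaptic conductance
time courses evaluated analytically on the time grid; HH gates advanced by
exponential integrators. The somatic row of the solved linear system is
checked each step (current conservation to solver round-off); NaN or
out-of-range voltages abort with a diagnostic. Halving dt changes peak
somatic depolarization by <0.5% (tested). Peaks are measured relative to the
pre-stimulus baseline (the step before the earliest synaptic onset).

## 4. I/O-curve analysis (`nmdashunt.io_curves`)

Mirrors the slice protocol. The raw threshold (breakpoint) is the stimulus
level with the maximum first difference of the responses; ties break toward
the lower stimulus. Levels below the breakpoint get a least-squares line
through the origin; levels at and above it get the three-parameter logistic
`v_max/(1 + exp(−(s − s_half)/k))` by multi-start (5 starts seeded from data
quantiles — deterministic) bounded least squares. The fitted threshold is
`s_half` (exactly the steepest-slope point for this zero-baseline
parameterization — the source's printed formula is unavailable, and no
baseline offset is assumed) and the height is `v_max`.

Two bounds stabilize jump-shaped curves: `s_half` is confined to [last
subthreshold level, max level] (the threshold provably lies there), and `k`
is capped at 2× the level spacing — the spike transition is at most a couple
of levels wide, and an unbounded width lets the fit chase the slow
post-spike creep of cable-model curves with an inflated asymptote. With
fewer than 3 suprathreshold points, `k` is pinned to half the level spacing
and the fit flagged. A curve with no interior jump standing out (max first
difference at the first interval, or below 2× the median) is flagged
degenerate — the spike-free signature of linear or concave saturating
curves, e.g. with NMDA blocked. Effects are
`100·(x_test/x_control − 1)` for threshold, height and subthreshold slope.

## 5. Synthetic data (`nmdashunt.synth`)

The generator emulates somatic i/o curves from slice experiments: a linear
subthreshold rise through the origin, a jump onto the logistic branch at the
threshold `s_half`, saturation at `v_max`, and i.i.d. Gaussian noise on the
peak responses (the experimental noise model is unspecified; Gaussian on
peaks is the simplest defensible choice). Defaults: sub_slope 0.5 mV/unit,
v_max 20 mV, s_half 8, k 1, 12 uniform levels to 16, noise 0.3 mV — the
threshold sits mid-grid and the sigmoid width is comparable to the level
spacing, so the suprathreshold jump (not the sigmoid's own rise) marks the
threshold, as in recorded NMDA-spike curves. Paired (control, inhibited)
curves apply multiplicative threshold/height shifts, divide the subthreshold
slope by the threshold factor (a shunt stretches the subthreshold limb), and
share a grid extended to twice the larger threshold. Seeds are mandatory;
identical seeds give identical curves.

What the generator does *not* emulate: trial-to-trial threshold jitter,
correlated noise, IPSP baseline drift, uncaging-spot variability, and
cell-to-cell morphology differences. Passing recovery tests therefore show
that the fitting pipeline is unbiased under the stated noise model, not that
it would match any particular slice dataset.

## 6. Problem sizes and test design

The test-suite experiments are sized for laptop-scale runs: cable i/o curves
use a 0–36 synapse grid in steps of 4 with 70 ms simulations at dt = 0.025 ms
(~150 compartments); solver-vs-brute-force checks use 200 random circuit
instances against 0.001 mV dense grid scans; fitter-recovery checks use 50
seeds per effect point across six effect points spanning the
threshold-dominant and gain-dominant regions. `scripts/acceptance.py`
recomputes the worked two-compartment quantities directly; it involves no
simulation and is deterministic (the seed argument is accepted for interface
uniformity).

## 7. Known limitations

* The exact experimental percentages (e.g. 284±78% threshold increase,
  31±7% height suppression) depend on unpublished cell-specific morphology
  and are not reproduction targets; the package reproduces the *topology* of
  the effect plane and the exact circuit algebra.
* The steady-state models ignore capacitance; timing-dependent phenomena
  (e.g. the modest spike-height increase under fast-decaying dendritic
  inhibition) appear only in the cable model.
* The cable surrogate is unbranched, spineless and axonless; axon/myelin
  parameter rows of the source table are out of scope, as are calcium
  dynamics and the firing-rate pooling extension.
* The receptor model is a normalized conductance time course × Mg block, not
  a kinetic state machine; no stochastic gating, no temperature dependence.
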