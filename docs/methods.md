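# Model and methods

`vtanic` simulates a minimal ventral tegmental area (VTA) microcircuit: one
conductance-based dopamine (DA) neuron inhibited by a population of
fast-spiking GABA interneurons, with beta2-containing nicotinic ACh receptor
(nAChR) pools on either cell type. The circuit is driven by three extrinsic
inputs — a merged Poisson glutamatergic afferent, a common pulsatile
cholinergic afferent, and a slow systemic nicotine concentration profile —
and its output is quantified by DA-neuron firing rate, percent spikes within
bursts (%SWB, 80/160 ms interval criterion) and mean burst length.

## Receptor kinetics

Each nAChR pool is a mean-field two-variable system: activated fraction `a`
and desensitized fraction `d`; only activated, sensitized receptors conduct,
`g = g_max * a * (1 - d)`, with reversal at 0 mV (non-selective cation
current, no voltage dependence). Activation tracks the effective agonist
concentration `c_ACh + w * c_nic` (nicotine potency `w = 3`) through a Hill
function with exponent 1.05 and relaxes with tau_act = 5 ms.
Desensitization is driven by nicotine alone (Hill exponent 0.5) and relaxes
with a nicotine-dependent time constant
`tau_des = 500 ms + 6e5 ms / (1 + (c_nic / K_tau)^3)`,
i.e. ~600 s at rest falling toward a 500 ms floor at saturating nicotine.
Because `d` depends only on nicotine, endogenous ACh pulses activate
transiently without desensitizing, while sustained nicotine activates weakly
but desensitizes deeply — the temporal asymmetry that underlies every
condition-specific effect in the circuit.

The half-concentrations are **calibration constants**, configured per pool
(DA-pool vs GABA-pool namespaces):

| pool | EC50 (uM) | IC50 (uM) | K_tau (uM) |
|------|-----------|-----------|------------|
| DA   | 120       | 0.4       | 0.25       |
| GABA | 150       | 0.05      | 0.10       |

Two considerations fix these scales. First, the maximal conductances of the
knockout / re-expression conditions are prescribed (5–10 mS/cm² on the DA
neuron, 1.5–4 mS/cm² on GABA neurons) and are comparable to the spike
conductances, so activation fractions must remain O(10^-3..10^-2) for the
currents to act as modulations rather than clamps. Second, the fast-spiking
interneuron's input gain (~20 Hz per uA/cm²) is more than an order of
magnitude steeper than the DA pacemaker's (~0.6 Hz per uA/cm²); with a
single shared sensitivity, any nicotine level strong enough to excite the DA
neuron directly silences it through the GABA pathway. Giving the GABA pool
faster, deeper desensitization (low IC50 and K_tau) makes its
nicotine-driven rate surge transient, so that in the double re-expression
case the direct DA excitation outlasts and outweighs the GABA-mediated
inhibition, as required by the effect matrix.

## DA neuron

Single compartment, C_m = 1 uF/cm², twelve currents (all written
`I = g x (E - V)`, depolarizing positive): L-type Ca, SK (Ca-activated K),
slow K, delayed-rectifier K, transient Na, persistent (subthreshold) Na,
leak, h-current, NMDA, AMPA, GABA-A and nAChR. Gating variables follow
`dX/dt = (X_inf(V) - X)/tau_X` with sigmoid steady states; the Na
inactivation time constant is bell-shaped around its half-inactivation.

The pacemaker mechanism is spike-gated Ca entry with SK feedback: the
L-type activation midpoint sits at -25 mV, so Ca flows essentially only
during spikes; each spike adds ~0.14 uM Ca (k_Ca = 0.011 uM cm²/uA/ms),
which decays with tau_Ca = 200 ms; SK (half-activation 0.25 uM, Hill 4,
g_SK = 2 mS/cm²) then imposes ~200–300 ms of hyperpolarization. This
arrangement was chosen over a subthreshold Ca oscillator after calibration:
sustained subthreshold Ca influx creates a stable hyperpolarized fixed point
(rest lock) whenever the SK loop is strong enough to pace below 5 Hz. The
delayed rectifier is positioned to be active at plateau voltages (half
-30 mV, tau 3 ms), which keeps the spike limit cycle alive under tonic
depolarization instead of collapsing into depolarization block; the
isolated cell then has a monotone f–I curve and fires 1–5 Hz at rest
(CV < 0.01) with transiently fast firing when SK is relieved.

A modest h-current (g_h = 0.1 mS/cm², half -80 mV, tau 150 ms) activates
during deep hyperpolarization — in practice, during synchronized GABA
volleys — and speeds the post-inhibitory rebound, helping convert
disinhibition gaps into short-ISI doublets.

NMDA input carries the glutamatergic drive (g_NMDA = 4 mS/cm²) through a
slow near-tonic gate (tau 250 ms, per-spike saturating increment 0.018 at
50 Hz drive) and the standard sigmoidal Mg block
`B(V) = 1/(1 + ([Mg]/3.57 mM) exp(-0.062 V))`, [Mg] = 1 mM; B(-80) < 0.1,
so the current is regenerative near threshold and negligible in the
afterhyperpolarization. AMPA (voltage-independent) defaults to zero
conductance — the excitatory afferents act through NMDA receptors in this
model — and is available as a config override. GABA-A input (g_GABA =
2.5 mS/cm², E = -70 mV) pools the per-neuron gates of the whole GABA
population (mean of per-neuron gates, so total inhibition is independent of
population size); the gate is fast (tau 6 ms, increment 1.0), which makes
synchronized volleys pulsatile while asynchronous firing yields a small
tonic level.

## GABA neurons

Fast-spiking interneurons with Wang–Buzsaki Na/K kinetics, leak conductance
heterogeneous across the population (uniform on [0.025, 0.075] mS/cm², the
prescribed 0.05 + 0.05(rnd - 0.5) rule) and a small constant bias current
(0.15 uA/cm²) that makes each cell tonically active at ~12–20 Hz. The
population default is 60 neurons (the afferent-convergence range discussed
for subcortical inputs is 20–60); a larger population smooths the pooled
inhibition without changing its mean, because of the 1/N gate pooling.

## Inputs

* **Glutamatergic**: one merged homogeneous Poisson train at 50 Hz (the
  aggregate of many asynchronous afferents). In the wild-type condition
  under nicotine the rate switches to 60 Hz while the nicotine concentration
  exceeds 5% of its peak (representing nicotinic facilitation of afferents
  outside the simulated circuit).
* **Cholinergic**: interspike intervals drawn from a two-mode
  instantaneous-frequency mixture — N(30 Hz, 7 Hz) with weight 0.7 and
  N(3.3 Hz, 7 Hz) with weight 0.3, rejected below 0.5 Hz — giving runs of
  ~33 ms intervals broken by ~300 ms pauses. Every GABA neuron and the DA
  pool receive this common train; each spike contributes an
  instantaneous-rise exponential concentration pulse (5 uM / 3 ms decay at
  the DA pool, 10 uM / 4 ms at the GABA pool). Short pulses matter: with
  decay constants toward 10 ms, single cholinergic pulses trigger multiple
  spikes per GABA neuron at the prescribed conductances, the population
  rate inflates, and the added tonic inhibition reverses the sign of the
  GABA-re-expression rate effect; between 3 and 5 ms the behavior is stable.
* **Nicotine**: concentration follows the positive two-exponential bump
  `A (e^{-t/tau_decay} - e^{-t/tau_rise})`, normalized so the peak equals
  the configured amplitude (0.5 uM), with rise 0.5 min and decay 3 min;
  the peak occurs 64.5 s after onset (analytic).

## Numerics

Fixed-step integration, default dt = 0.025 ms. Voltages use explicit Euler;
every first-order relaxation (gating variables, synaptic gates, receptor
fractions, intracellular Ca) uses exponential-Euler, exact for
piecewise-constant inputs and immune to the 5 ms vs 600 s stiffness gap in
the receptor pool. Afferent spikes are binned to the grid; voltage-dependent
steady states and decay factors are tabulated on a 0.05 mV grid and
linearly interpolated inside a compiled (numba) inner loop. Spikes are
upward crossings of -20 mV with a 2 ms lockout. Halving dt changes isolated
spike times by well under 1 ms over 10 s. All randomness flows through four
named streams (glutamate, ACh, GABA heterogeneity, initial conditions)
derived from one master seed, so every run is bit-reproducible from its
config. Degenerate inputs are defined by limits (zero agonist gives zero
activation); concentrations must be non-negative; a numeric blow-up aborts
with the failure time.

The first 10 s of every run are discarded from all metrics (settling). The
nicotine experiment compares a 90 s pre-onset baseline with the 60–240 s
post-onset window — the sustained-activation phase, past the initial
concentration-rise transient during which the not-yet-desensitized GABA
surge dominates all conditions.

## What the generator does and does not emulate

The synthetic afferents reproduce the stationary statistics the circuit
model needs: aggregate Poisson excitation, bursty common cholinergic drive,
slow nicotine pharmacokinetics. They do not emulate behaviorally structured
afferent activity (reward-locked glutamatergic bursts), spatial agonist
diffusion, cholinergic-neuron network dynamics, or nicotine metabolism
beyond the two-exponential profile. Passing tests therefore show that the
*circuit mechanisms* — balance, synchrony-driven disinhibition bursting,
pulsatile-vs-sustained receptor activation — behave as described under
stationary drive; they do not validate the model against task-evoked in
vivo dynamics.

## Calibration contracts and a known limitation

The intrinsic kinetic constants are not uniquely identified by the
available description; they were calibrated once, in-repo, against the
testable contracts: isolated pacemaking at 1–5 Hz with CV < 0.1; balanced
knockout firing within +-30% of the isolated rate with near-zero %SWB;
GABA-re-expression under ACh raising both rate and %SWB; double
re-expression matching wild-type statistics with doublet-dominated bursts
of mean length ~2.7 spikes; and the directional nicotine effect matrix.

Three sub-contracts could not be met jointly with the others; the
corresponding acceptance tests assert them faithfully and fail.

* **Balanced-knockout ISI CV.** The synaptic conductances needed to support
  volley-driven disinhibition bursting leave the balanced state with CV
  ~0.35–0.45, above the < 0.3 regularity target. The trade-off is
  structural: reducing synaptic fluctuations (weaker gates, slower NMDA,
  larger populations) restores CV < 0.3 but collapses the re-expression
  effect sizes and burst statistics, and vice versa. The knockout %SWB
  (~1–2%) and the ±30% rate balance do hold.
* **Nicotine-phase %SWB in the double re-expression and wild-type cases.**
  The firing-rate responses are correct and significant (rate up in both,
  wild-type exceeding double re-expression), but %SWB stays flat rather
  than rising. A nicotine-phase %SWB increase would require a *sustained*
  elevation of tonic GABA inhibition (which preferentially cancels single
  spikes); every desensitization setting slow and deep enough to sustain
  that inhibition also flips the net rate effect negative, because the
  interneurons' input gain is far steeper than the DA pacemaker's. With
  the chosen fast-desensitizing GABA pool the rate matrix is reproduced and
  the bursting effect is sacrificed; the reverse choice is also available
  via the per-pool receptor config, but not both at once.

## Other deliberate choices

* Desensitization depends on nicotine only, exactly as the printed
  equations specify; ACh-driven desensitization is absent by construction.
* The tau_des expression is read as additive base + saturating term
  (500 + 6e5/(1 + (c/K_tau)^3) ms), the reading consistent with a ~600 s
  resting constant and a 500 ms floor.
* ACh concentration at the two pools derives from the same spike train with
  pool-specific amplitudes (and decay constants), not from independent
  trains.
* E_GABA = -70 mV keeps GABA input hyperpolarizing over the subthreshold
  range; cm = 1 uF/cm² for both cell types.
* The per-cell scatter of experimental cohorts is emulated across random
  seeds, not across heterogeneous DA neurons (the model has one DA neuron).
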