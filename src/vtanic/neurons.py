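"""Conductance-based single-compartment VTA neuron models.

Two cell types are modelled:

* **DA neuron** -- a slow pacemaker whose interspike rhythm is set by an
  L-type Ca / SK (Ca-activated K) oscillation, with transient Na and
  delayed-rectifier K spike currents, a subthreshold (persistent) Na
  current, a slow subthreshold K current, an h-current and leak.  Synaptic
  input arrives through NMDA (with voltage-dependent Mg block), AMPA and
  GABA-A gates plus a nicotinic receptor pool.
* **GABA neuron** -- a fast-spiking interneuron (transient Na +
  delayed-rectifier K + leak, Wang-Buzsaki kinetics) made tonically active
  by a small bias current; leak conductance is heterogeneous across the
  population, dispersing baseline rates.

All gating variables follow dX/dt = (X_inf(V) - X)/tau_X.  The functions
here are plain numpy and are evaluated both directly (tests, derivative
inspection) and on a voltage grid to build the lookup tables used by the
compiled integrator, so there is a single source of truth for the kinetics.

The intrinsic-current kinetic constants are calibration choices: they are
tuned so the isolated DA cell pacemakes at 1-5 Hz with low ISI variability,
fires NMDA-dependent bursts, and the GABA population covers a 5-25 Hz
baseline range (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

__all__ = [
    "GatingSpec",
    "DANeuronParams",
    "GABANeuronParams",
    "NeuronState",
    "gating_step",
    "da_derivatives",
    "gaba_derivatives",
    "make_gaba_population",
    "mg_block",
]

SPIKE_THRESHOLD_MV = -20.0   # upward crossing marks a spike
SPIKE_LOCKOUT_MS = 2.0       # refractory lockout for detection


def _sigm(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class GatingSpec:
    """Generic first-order gate: steady state and time constant vs voltage."""

    steady_state: Callable[[float], float]
    tau: Callable[[float], float]


def gating_step(x: float, v: float, spec: GatingSpec, dt: float) -> float:
    """Exact exponential relaxation of a gate over ``dt`` at frozen voltage."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    x_inf = spec.steady_state(v)
    tau = spec.tau(v)
    return x_inf + (x - x_inf) * np.exp(-dt / tau)


# ---------------------------------------------------------------------------
# DA neuron
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DANeuronParams:
    """DA neuron parameters (conductances mS/cm^2, potentials mV, times ms).

    The Ca/SK pair produces the slow pacemaker oscillation; ``k_ca`` converts
    Ca current (uA/cm^2) into Ca influx (uM/ms) and ``tau_ca`` is the removal
    time constant.  ``g_nmda`` and ``g_gaba`` carry the balanced synaptic
    drive; ``g_ampa`` defaults to 0 (the excitatory afferents act through
    NMDA receptors; AMPA is available as an override).
    """

    cm: float = 1.0
    # L-type Ca (activates in the spike voltage range; spike-gated Ca entry)
    g_ca: float = 0.06
    e_ca: float = 100.0
    mca_half: float = -25.0
    mca_slope: float = 3.5
    # SK (Ca-activated K): sets the slow pacemaker rhythm
    g_sk: float = 2.0
    k_sk: float = 0.25         # half-activation [Ca], uM
    sk_hill: float = 4.0
    # Ca dynamics
    k_ca: float = 0.011        # uM per (uA/cm^2 * ms)
    tau_ca: float = 200.0
    # slow K (minor adaptation; activates near spike voltages)
    g_ks: float = 0.01
    uks_half: float = -30.0
    uks_slope: float = 10.0
    uks_tau: float = 250.0
    # delayed rectifier (active at plateau voltages -> no depolarization block)
    g_dr: float = 6.0
    ndr_half: float = -30.0
    ndr_slope: float = 8.0
    ndr_tau: float = 3.0
    # transient Na
    g_na: float = 35.0
    e_na: float = 55.0
    mna_half: float = -32.0
    mna_slope: float = 5.0
    hna_half: float = -45.0
    hna_slope: float = 6.0
    hna_tau_base: float = 0.4
    hna_tau_amp: float = 6.0
    # subthreshold (persistent) Na
    g_sna: float = 0.008
    msna_half: float = -50.0
    msna_slope: float = 5.0
    # leak
    g_leak: float = 0.03
    e_leak: float = -52.0
    # h-current (post-inhibitory rebound after synchronized GABA volleys)
    g_h: float = 0.1
    qh_half: float = -80.0
    qh_slope: float = 7.0
    qh_tau: float = 150.0
    e_h: float = -30.0
    # K reversal
    e_k: float = -90.0
    # synaptic
    g_nmda: float = 4.0
    g_ampa: float = 0.0
    e_glu: float = 0.0
    g_gaba: float = 2.5
    e_gaba: float = -70.0
    mg: float = 1.0            # external Mg, mM
    mg_k: float = 3.57         # Mg block concentration scale, mM
    mg_gamma: float = 0.062    # Mg block voltage sensitivity, 1/mV
    i_const: float = 0.0       # constant injected current, uA/cm^2

    # -- gating functions (vectorized over v) --
    def mca_inf(self, v):
        return _sigm((v - self.mca_half) / self.mca_slope)

    def mna_inf(self, v):
        return _sigm((v - self.mna_half) / self.mna_slope)

    def hna_inf(self, v):
        return _sigm(-(v - self.hna_half) / self.hna_slope)

    def hna_tau(self, v):
        h = self.hna_inf(v)
        return self.hna_tau_base + self.hna_tau_amp * 4.0 * h * (1.0 - h)

    def ndr_inf(self, v):
        return _sigm((v - self.ndr_half) / self.ndr_slope)

    def msna_inf(self, v):
        return _sigm((v - self.msna_half) / self.msna_slope)

    def qh_inf(self, v):
        return _sigm(-(v - self.qh_half) / self.qh_slope)

    def uks_inf(self, v):
        return _sigm((v - self.uks_half) / self.uks_slope)

    def sk_act(self, ca):
        cn = np.asarray(ca, float) ** self.sk_hill
        return cn / (cn + self.k_sk ** self.sk_hill)


def mg_block(v, p: DANeuronParams):
    """Voltage-dependent Mg unblock factor of the NMDA conductance in (0, 1)."""
    return 1.0 / (1.0 + (p.mg / p.mg_k) * np.exp(-p.mg_gamma * np.asarray(v, float)))


@dataclass
class NeuronState:
    """Membrane voltage, gating fractions, and (DA only) intracellular Ca."""

    v: float
    gates: dict
    ca: float = 0.0


def da_resting_state(p: DANeuronParams, v0: float = -60.0, ca0: float = 0.1) -> NeuronState:
    """A state with every gate at its steady state for ``v0``."""
    return NeuronState(
        v=v0,
        gates={
            "h": float(p.hna_inf(v0)),
            "n": float(p.ndr_inf(v0)),
            "q": float(p.qh_inf(v0)),
            "u": float(p.uks_inf(v0)),
        },
        ca=ca0,
    )


def da_currents(s: NeuronState, syn: dict, p: DANeuronParams) -> dict:
    """All 12 membrane currents (uA/cm^2, positive = depolarizing).

    ``syn`` supplies the synaptic gate activations ``s_nmda``, ``s_ampa``,
    ``s_gaba`` (fractions) and the nicotinic current ``i_nachr`` (uA/cm^2).
    """
    v, ca = s.v, s.ca
    h, n = s.gates["h"], s.gates["n"]
    q, u = s.gates["q"], s.gates["u"]
    return {
        "ca": p.g_ca * p.mca_inf(v) * (p.e_ca - v),
        "kca": p.g_sk * p.sk_act(ca) * (p.e_k - v),
        "k": p.g_ks * u * (p.e_k - v),
        "dr": p.g_dr * n ** 3 * (p.e_k - v),
        "na": p.g_na * p.mna_inf(v) ** 3 * h * (p.e_na - v),
        "sna": p.g_sna * p.msna_inf(v) * (p.e_na - v),
        "leak": p.g_leak * (p.e_leak - v),
        "h": p.g_h * q * (p.e_h - v),
        "nmda": p.g_nmda * syn.get("s_nmda", 0.0) * mg_block(v, p) * (p.e_glu - v),
        "ampa": p.g_ampa * syn.get("s_ampa", 0.0) * (p.e_glu - v),
        "gaba": p.g_gaba * syn.get("s_gaba", 0.0) * (p.e_gaba - v),
        "nachr": syn.get("i_nachr", 0.0),
    }


def da_derivatives(s: NeuronState, syn: dict, p: DANeuronParams) -> dict:
    """Time derivatives of the DA neuron state (v in mV/ms, ca in uM/ms,
    gates as (inf - x)/tau)."""
    if not np.isfinite(s.v) or not np.isfinite(s.ca):
        raise ValueError("non-finite neuron state")
    cur = da_currents(s, syn, p)
    i_total = sum(cur.values()) + p.i_const
    v = s.v
    return {
        "v": i_total / p.cm,
        "ca": p.k_ca * cur["ca"] - s.ca / p.tau_ca,
        "h": (p.hna_inf(v) - s.gates["h"]) / p.hna_tau(v),
        "n": (p.ndr_inf(v) - s.gates["n"]) / p.ndr_tau,
        "q": (p.qh_inf(v) - s.gates["q"]) / p.qh_tau,
        "u": (p.uks_inf(v) - s.gates["u"]) / p.uks_tau,
    }


# ---------------------------------------------------------------------------
# GABA neuron (Wang-Buzsaki fast-spiking interneuron)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GABANeuronParams:
    """Fast-spiking GABA interneuron.

    ``g_leak`` is heterogeneous across the population (uniform on
    [0.025, 0.075] mS/cm^2, i.e. 0.05 + 0.05*(rnd - 0.5)); together with the
    small bias current ``i_bias`` it sets the tonic baseline rate.
    """

    cm: float = 1.0
    g_na: float = 35.0
    e_na: float = 55.0
    g_k: float = 9.0
    e_k: float = -90.0
    g_leak: float = 0.05
    e_leak: float = -65.0
    i_bias: float = 0.15     # uA/cm^2, tonic drive
    phi: float = 5.0         # gating temperature factor

    # Wang-Buzsaki rate functions (1/ms); v in mV
    @staticmethod
    def _alpha_m(v):
        x = -(v + 35.0) / 10.0
        return 0.1 * (v + 35.0) / (1.0 - np.exp(np.minimum(x, 50.0)))

    @staticmethod
    def _beta_m(v):
        return 4.0 * np.exp(-(v + 60.0) / 18.0)

    @staticmethod
    def _alpha_h(v):
        return 0.07 * np.exp(-(v + 58.0) / 20.0)

    @staticmethod
    def _beta_h(v):
        return 1.0 / (1.0 + np.exp(-(v + 28.0) / 10.0))

    @staticmethod
    def _alpha_n(v):
        x = -(v + 34.0) / 10.0
        return 0.01 * (v + 34.0) / (1.0 - np.exp(np.minimum(x, 50.0)))

    @staticmethod
    def _beta_n(v):
        return 0.125 * np.exp(-(v + 44.0) / 80.0)

    def m_inf(self, v):
        v = np.asarray(v, float)
        a, b = self._alpha_m(v), self._beta_m(v)
        return a / (a + b)

    def h_inf(self, v):
        v = np.asarray(v, float)
        a, b = self._alpha_h(v), self._beta_h(v)
        return a / (a + b)

    def h_tau(self, v):
        v = np.asarray(v, float)
        return 1.0 / (self.phi * (self._alpha_h(v) + self._beta_h(v)))

    def n_inf(self, v):
        v = np.asarray(v, float)
        a, b = self._alpha_n(v), self._beta_n(v)
        return a / (a + b)

    def n_tau(self, v):
        v = np.asarray(v, float)
        return 1.0 / (self.phi * (self._alpha_n(v) + self._beta_n(v)))


def gaba_resting_state(p: GABANeuronParams, v0: float = -64.0) -> NeuronState:
    return NeuronState(v=v0, gates={"h": float(p.h_inf(v0)), "n": float(p.n_inf(v0))})


def gaba_currents(s: NeuronState, i_nachr: float, p: GABANeuronParams) -> dict:
    v = s.v
    h, n = s.gates["h"], s.gates["n"]
    return {
        "na": p.g_na * p.m_inf(v) ** 3 * h * (p.e_na - v),
        "k": p.g_k * n ** 4 * (p.e_k - v),
        "leak": p.g_leak * (p.e_leak - v),
        "bias": p.i_bias,
        "nachr": i_nachr,
    }


def gaba_derivatives(s: NeuronState, i_nachr: float, p: GABANeuronParams) -> dict:
    """Time derivatives of the GABA neuron state."""
    if not np.isfinite(s.v):
        raise ValueError("non-finite neuron state")
    cur = gaba_currents(s, i_nachr, p)
    v = s.v
    return {
        "v": sum(cur.values()) / p.cm,
        "h": (p.h_inf(v) - s.gates["h"]) / p.h_tau(v),
        "n": (p.n_inf(v) - s.gates["n"]) / p.n_tau(v),
    }


def make_gaba_population(n: int, rng_seed, base: GABANeuronParams | None = None):
    """``n`` GABA neuron parameter sets with i.i.d. uniform leak conductances.

    g_leak = 0.05 + 0.05*(U - 0.5) mS/cm^2 with U uniform on [0, 1];
    reproducible given the seed.
    """
    if n < 1:
        raise ValueError(f"population size must be >= 1, got {n}")
    if base is None:
        base = GABANeuronParams()
    rng = np.random.default_rng(rng_seed)
    gl = 0.05 + 0.05 * (rng.random(n) - 0.5)
    return [replace(base, g_leak=float(g)) for g in gl]
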