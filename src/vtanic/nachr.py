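"""Four-state nicotinic acetylcholine receptor (nAChR) kinetics.

The receptor pool is described by two mean-field fractions: the activated
fraction ``a`` and the desensitized fraction ``d``.  The four underlying
states (deactivated/sensitized, activated/sensitized, activated/desensitized,
deactivated/desensitized) enter the conductance only through the product
``a * (1 - d)``: receptors conduct when they are both activated and
sensitized.

Activation tracks the combined agonist concentration (ACh plus nicotine
weighted by its potency ``w``) through a Hill function with a fast time
constant (5 ms), while desensitization is driven by nicotine alone, with a
Hill steady state and a nicotine-dependent time constant that drops from
~600 s at zero nicotine toward a 500 ms floor at saturating concentrations.
Endogenous ACh pulses therefore activate the pool transiently without
desensitizing it, whereas sustained nicotine activates weakly but
desensitizes slowly and profoundly -- the temporal asymmetry at the heart of
the circuit model.

Integration uses an exponential-Euler update, which is exact for
piecewise-constant agonist concentrations and robust to the five-orders-of-
magnitude gap between the activation and desensitization time scales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

__all__ = [
    "NAChRParams",
    "NAChRState",
    "activation_steady_state",
    "desensitization_steady_state",
    "desensitization_tau",
    "step_receptor",
    "conductance",
    "receptor_current",
]


@dataclass(frozen=True)
class NAChRParams:
    """Parameters of one nAChR pool (e.g. the pool on the DA neuron).

    Concentrations in uM, conductances in mS/cm^2, times in ms.

    ``ec50``, ``ic50`` and ``k_tau`` are calibration constants of the
    beta2-containing receptor lineage this model follows; they are deliberate
    configuration choices (see docs/methods.md) rather than universally
    agreed constants.
    """

    g_max: float = 0.0        # maximal conductance, mS/cm^2
    e_rev: float = 0.0        # reversal potential, mV (non-selective cation)
    ec50: float = 100.0       # half-activation agonist concentration, uM
    ic50: float = 0.2         # half-desensitization nicotine concentration, uM
    k_tau: float = 0.25       # half-saturation of the desensitization tau, uM
    w: float = 3.0            # potency of nicotine relative to ACh
    n_act: float = 1.05       # activation Hill exponent
    n_des: float = 0.5        # desensitization Hill exponent
    tau_act: float = 5.0      # activation time constant, ms
    tau_des_base: float = 500.0    # desensitization tau floor, ms
    tau_des_amp: float = 6.0e5     # desensitization tau span, ms

    def __post_init__(self) -> None:
        for f in fields(self):
            val = getattr(self, f.name)
            if f.name in ("g_max", "w"):
                if val < 0:
                    raise ValueError(f"{f.name} must be >= 0, got {val}")
            elif f.name == "e_rev":
                continue
            elif val <= 0:
                raise ValueError(f"{f.name} must be > 0, got {val}")


@dataclass
class NAChRState:
    """Activated and desensitized fractions of a receptor pool."""

    a: float = 0.0
    d: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.a <= 1.0 and 0.0 <= self.d <= 1.0):
            raise ValueError(f"fractions must lie in [0, 1], got a={self.a}, d={self.d}")


def _check_conc(c: float, name: str) -> None:
    if c < 0:
        raise ValueError(f"{name} must be non-negative, got {c}")


def activation_steady_state(c_ach: float, c_nic: float, p: NAChRParams) -> float:
    """Steady-state activated fraction for given ACh and nicotine levels.

    Hill function of the effective agonist concentration ``c_ach + w*c_nic``
    with exponent ``n_act``; the zero-agonist limit is 0.
    """
    _check_conc(c_ach, "c_ach")
    _check_conc(c_nic, "c_nic")
    c_eff = c_ach + p.w * c_nic
    if c_eff == 0.0:
        return 0.0
    return 1.0 / (1.0 + (p.ec50 / c_eff) ** p.n_act)


def desensitization_steady_state(c_nic: float, p: NAChRParams) -> float:
    """Steady-state desensitized fraction; depends on nicotine only."""
    _check_conc(c_nic, "c_nic")
    if c_nic == 0.0:
        return 0.0
    return 1.0 / (1.0 + (p.ic50 / c_nic) ** p.n_des)


def desensitization_tau(c_nic: float, p: NAChRParams) -> float:
    """Nicotine-dependent desensitization time constant, ms.

    Decreases from ``tau_des_base + tau_des_amp`` at zero nicotine toward the
    ``tau_des_base`` floor at saturating nicotine (cubic Hill saturation with
    half point ``k_tau``).
    """
    _check_conc(c_nic, "c_nic")
    return p.tau_des_base + p.tau_des_amp / (1.0 + (c_nic / p.k_tau) ** 3)


def step_receptor(
    s: NAChRState, c_ach: float, c_nic: float, dt: float, p: NAChRParams
) -> NAChRState:
    """Advance the receptor pool by ``dt`` ms under constant concentrations.

    Exponential-Euler update: exact first-order relaxation of ``a`` toward its
    steady state with ``tau_act``, and of ``d`` toward its steady state with
    the nicotine-dependent desensitization tau.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if dt > p.tau_act / 2:
        raise ValueError(
            f"dt={dt} ms too large for activation time constant {p.tau_act} ms "
            f"(require dt <= tau_act/2)"
        )
    a_inf = activation_steady_state(c_ach, c_nic, p)
    d_inf = desensitization_steady_state(c_nic, p)
    tau_d = desensitization_tau(c_nic, p)
    a = a_inf + (s.a - a_inf) * math.exp(-dt / p.tau_act)
    d = d_inf + (s.d - d_inf) * math.exp(-dt / tau_d)
    return NAChRState(a=a, d=d)


def conductance(s: NAChRState, p: NAChRParams) -> float:
    """Pool conductance ``g_max * a * (1 - d)``, mS/cm^2."""
    return p.g_max * s.a * (1.0 - s.d)


def receptor_current(s: NAChRState, v: float, p: NAChRParams) -> float:
    """Membrane current ``g * (E_rev - v)``, uA/cm^2 (positive = depolarizing)."""
    return conductance(s, p) * (p.e_rev - v)
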