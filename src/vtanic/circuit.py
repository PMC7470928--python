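"""VTA microcircuit assembly and simulation.

One DA neuron receives merged Poisson glutamatergic input (NMDA, optionally
AMPA), pooled GABA-A input from a population of tonically active GABA
neurons, and a nicotinic receptor current.  Every GABA neuron and the DA
neuron carry a (possibly zero-conductance) beta2-nAChR pool driven by a
common pulsatile ACh afferent train and/or a slow nicotine concentration
profile.  The knockout / re-expression conditions differ only in the two
maximal receptor conductances.

Integration is fixed-step (default dt = 0.025 ms): exponential-Euler for
gates, gating variables and receptor pools, explicit Euler for voltages;
afferent spikes are binned to the grid.  All randomness derives from one
master seed through independent named streams, so a config reproduces its
run bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import _kernel
from .inputs import (
    AChPulseParams,
    AChTrainParams,
    NicotineProtocol,
    SpikeTrain,
    generate_bimodal_ach_train,
    generate_poisson_train,
)
from .metrics import pattern_metrics
from .nachr import NAChRParams
from .neurons import DANeuronParams, GABANeuronParams, make_gaba_population

__all__ = [
    "CONDITIONS",
    "CircuitConfig",
    "SynapticGate",
    "GateParams",
    "SimulationResult",
    "condition_conductances",
    "gate_step",
    "run_simulation",
    "run_nicotine_experiment",
]

# maximal nAChR conductances (DA pool, GABA pool) per condition, mS/cm^2
CONDITIONS = {
    "KO": (0.0, 0.0),
    "REEXP_DA": (5.0, 0.0),
    "REEXP_GABA": (0.0, 4.0),
    "REEXP_BOTH": (10.0, 1.5),
    "WT": (10.0, 1.5),
}

# named RNG stream order under the master seed
_STREAMS = ("glu", "ach", "gaba_heterogeneity", "initial_conditions")


def condition_conductances(condition: str) -> tuple[float, float]:
    """(g_ach_da, g_ach_gaba) in mS/cm^2 for a named condition."""
    try:
        return CONDITIONS[condition]
    except KeyError:
        raise ValueError(
            f"unknown condition {condition!r}; expected one of {sorted(CONDITIONS)}"
        ) from None


@dataclass
class SynapticGate:
    """First-order synaptic activation: per-spike saturating increment,
    exponential decay."""

    s: float = 0.0
    increment: float = 1.0
    decay_tau: float = 10.0


def gate_step(g: SynapticGate, presyn_spikes_in_dt: int, dt: float) -> SynapticGate:
    """Advance a gate by ``dt`` ms: decay, then one saturating increment
    ``s += increment * (1 - s)`` per presynaptic spike."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    s = g.s * math.exp(-dt / g.decay_tau)
    for _ in range(presyn_spikes_in_dt):
        s += g.increment * (1.0 - s)
    return SynapticGate(s=s, increment=g.increment, decay_tau=g.decay_tau)


@dataclass(frozen=True)
class GateParams:
    """Kinetics of the three synaptic gate types on the DA neuron.

    NMDA is slow (near-tonic under 50 Hz Poisson drive); the GABA gate is
    fast so that synchronous GABA volleys produce pulsatile inhibition while
    asynchronous firing produces a nearly constant level.
    """

    nmda_tau: float = 250.0
    nmda_inc: float = 0.018
    ampa_tau: float = 5.0
    ampa_inc: float = 0.5
    gaba_tau: float = 6.0
    gaba_inc: float = 1.0


@dataclass
class CircuitConfig:
    """Complete, reproducible description of one simulation run."""

    condition: str = "KO"
    master_seed: int = 0
    duration: float = 200_000.0   # ms
    dt: float = 0.025             # ms
    n_gaba: int = 60
    transient_ms: float = 10_000.0  # discarded from metrics
    glu_rate_baseline: float = 50.0   # Hz, merged Poisson afferent
    glu_rate_nicotine: float = 60.0   # Hz, WT only, while nicotine is elevated
    ach_input: AChTrainParams | None = field(default_factory=AChTrainParams)
    ach_pulse_da: AChPulseParams = field(default_factory=lambda: AChPulseParams(5.0, 3.0))
    ach_pulse_gaba: AChPulseParams = field(default_factory=lambda: AChPulseParams(10.0, 4.0))
    nicotine: NicotineProtocol | None = None
    # Receptor pools are configured independently (DA-pool vs GABA-pool):
    # their effective agonist sensitivities are separate calibration choices.
    nachr_da: NAChRParams = field(default_factory=lambda: NAChRParams(ec50=120.0, ic50=0.4))
    nachr_gaba: NAChRParams = field(
        default_factory=lambda: NAChRParams(ec50=150.0, ic50=0.05, k_tau=0.1)
    )
    da: DANeuronParams = field(default_factory=DANeuronParams)
    gaba: GABANeuronParams = field(default_factory=GABANeuronParams)
    gates: GateParams = field(default_factory=GateParams)
    g_ach_da: float | None = None    # override of the condition preset
    g_ach_gaba: float | None = None
    record_traces: bool = False
    trace_stride_ms: float = 1.0

    def conductances(self) -> tuple[float, float]:
        g_da, g_gb = condition_conductances(self.condition)
        if self.g_ach_da is not None:
            g_da = self.g_ach_da
        if self.g_ach_gaba is not None:
            g_gb = self.g_ach_gaba
        return g_da, g_gb

    def stream_seed(self, name: str):
        """Child seed for one named RNG stream."""
        idx = _STREAMS.index(name)
        return np.random.SeedSequence(self.master_seed).spawn(len(_STREAMS))[idx]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["__format__"] = "vtanic.CircuitConfig.v1"
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CircuitConfig":
        d = dict(d)
        d.pop("__format__", None)
        for key, typ in [
            ("ach_input", AChTrainParams),
            ("ach_pulse_da", AChPulseParams),
            ("ach_pulse_gaba", AChPulseParams),
            ("nicotine", NicotineProtocol),
            ("nachr_da", NAChRParams),
            ("nachr_gaba", NAChRParams),
            ("da", DANeuronParams),
            ("gaba", GABANeuronParams),
            ("gates", GateParams),
        ]:
            if d.get(key) is not None and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class SimulationResult:
    """Spike trains, optional traces, and metadata of one run."""

    da_spikes: SpikeTrain
    gaba_spikes: list
    config: CircuitConfig
    mean_nachr_current_da: float   # uA/cm^2, time-average after transient
    mean_s_gaba: float             # pooled GABA gate average after transient
    traces: dict | None = None
    nicotine_window: tuple | None = None  # (t_on, t_off) of elevated nicotine, ms

    def da_metrics(self, t_start: float | None = None, t_stop: float | None = None):
        """Pattern metrics of the DA train on [t_start, t_stop) (defaults:
        after the settling transient, to the end of the run)."""
        t0 = self.config.transient_ms if t_start is None else t_start
        t1 = self.config.duration if t_stop is None else t_stop
        t = self.da_spikes.times
        sel = t[(t >= t0) & (t < t1)]
        return pattern_metrics(sel, duration_ms=t1 - t0)

    def gaba_rates(self, t_start: float | None = None) -> np.ndarray:
        t0 = self.config.transient_ms if t_start is None else t_start
        dur = self.config.duration - t0
        return np.array(
            [1000.0 * np.sum(tr.times >= t0) / dur for tr in self.gaba_spikes]
        )

    def save(self, out_dir) -> None:
        """Write spike tables, metrics, config echo and optional traces."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"time_ms": self.da_spikes.times}).to_csv(
            out / "da_spikes.csv", index=False
        )
        rows = [
            (i, t)
            for i, tr in enumerate(self.gaba_spikes)
            for t in tr.times
        ]
        pd.DataFrame(rows, columns=["train_id", "time_ms"]).to_csv(
            out / "gaba_spikes.csv", index=False
        )
        m = self.da_metrics()
        meta = {
            "config_hash": self.config.config_hash(),
            "master_seed": self.config.master_seed,
            "condition": self.config.condition,
            "da_rate_hz": m.rate,
            "da_pct_swb": m.pct_swb,
            "da_mean_burst_len": None if math.isnan(m.mean_burst_len) else m.mean_burst_len,
            "da_isi_cv": None if math.isnan(m.isi_cv) else m.isi_cv,
            "n_bursts": m.n_bursts,
            "mean_nachr_current_da": self.mean_nachr_current_da,
        }
        (out / "metrics.json").write_text(json.dumps(meta, indent=2))
        (out / "config.json").write_text(
            json.dumps(self.config.to_dict(), indent=2, default=float)
        )
        if self.traces is not None:
            tr = self.traces
            pd.DataFrame(
                {
                    "time_ms": tr["t"],
                    "c_ach_da_uM": tr["c_ach_da"],
                    "c_nic_uM": tr["c_nic"],
                }
            ).to_csv(out / "concentrations.csv", index=False)
            np.savez_compressed(out / "traces.npz", **tr)


def _bin_counts(train: SpikeTrain | None, dt: float, n_steps: int) -> np.ndarray:
    counts = np.zeros(n_steps, dtype=np.uint8)
    if train is not None and len(train):
        idx = np.minimum((train.times / dt).astype(np.int64), n_steps - 1)
        np.add.at(counts, idx, 1)
    return counts


def _nicotine_elevated_window(p: NicotineProtocol, duration: float) -> tuple:
    """Interval (ms) where the nicotine concentration exceeds 5% of its peak."""
    from .inputs import nicotine_concentration

    t = np.arange(p.onset, duration, 100.0)
    if t.size == 0:
        return (duration, duration)
    c = nicotine_concentration(p, t)
    above = c > 0.05 * p.amplitude
    if not above.any():
        return (duration, duration)
    return (float(t[above][0]), float(t[above][-1]) + 100.0)


def _make_glu_train(cfg: CircuitConfig, seed) -> SpikeTrain:
    """Merged Poisson glutamatergic train; in the WT condition under nicotine
    the rate switches to ``glu_rate_nicotine`` while nicotine is elevated."""
    rng = np.random.default_rng(seed)
    if cfg.condition != "WT" or cfg.nicotine is None:
        return generate_poisson_train(cfg.glu_rate_baseline, cfg.duration, rng)
    t_on, t_off = _nicotine_elevated_window(cfg.nicotine, cfg.duration)
    times = []
    for lo, hi, rate in [
        (0.0, t_on, cfg.glu_rate_baseline),
        (t_on, t_off, cfg.glu_rate_nicotine),
        (t_off, cfg.duration, cfg.glu_rate_baseline),
    ]:
        if hi > lo and rate > 0:
            seg = generate_poisson_train(rate, hi - lo, rng)
            times.append(seg.times + lo)
    allt = np.concatenate(times) if times else np.empty(0)
    return SpikeTrain(allt, cfg.duration)


_log = logging.getLogger("vtanic.circuit")


def run_simulation(cfg: CircuitConfig) -> SimulationResult:
    """Integrate the coupled circuit for ``cfg.duration`` ms."""
    if cfg.dt <= 0:
        raise ValueError("dt must be > 0")
    dt = cfg.dt
    n_steps = int(round(cfg.duration / dt))
    seeds = {s: cfg.stream_seed(s) for s in _STREAMS}
    t_wall = time.time()
    _log.info(
        "run start: condition=%s hash=%s master_seed=%d duration=%.0f ms",
        cfg.condition, cfg.config_hash(), cfg.master_seed, cfg.duration,
    )

    glu_train = _make_glu_train(cfg, seeds["glu"])
    if cfg.ach_input is not None:
        ach_train = generate_bimodal_ach_train(cfg.ach_input, cfg.duration, seeds["ach"])
    else:
        ach_train = SpikeTrain(np.empty(0), cfg.duration)

    glu_counts = _bin_counts(glu_train, dt, n_steps)
    ach_counts = _bin_counts(ach_train, dt, n_steps)
    ach_fac_da = math.exp(-dt / cfg.ach_pulse_da.decay_tau)
    ach_fac_gb = math.exp(-dt / cfg.ach_pulse_gaba.decay_tau)

    g_da, g_gb = cfg.conductances()
    rp_da = _kernel.pack_receptor_params(cfg.nachr_da, g_da, dt)
    rp_gb = _kernel.pack_receptor_params(cfg.nachr_gaba, g_gb, dt)

    pop = make_gaba_population(cfg.n_gaba, seeds["gaba_heterogeneity"], cfg.gaba)
    gl_arr = np.array([p.g_leak for p in pop])

    da_tab = _kernel.build_da_tables(cfg.da, dt)
    gaba_tab = _kernel.build_gaba_tables(cfg.gaba, dt)
    dp = _kernel.pack_da_params(cfg.da)
    gp = _kernel.pack_gaba_params(cfg.gaba)
    gt = np.array(
        [
            math.exp(-dt / cfg.gates.nmda_tau), cfg.gates.nmda_inc,
            math.exp(-dt / cfg.gates.ampa_tau), cfg.gates.ampa_inc,
            math.exp(-dt / cfg.gates.gaba_tau), cfg.gates.gaba_inc,
        ]
    )

    # nicotine recursion constants
    nic = cfg.nicotine
    nic_window = None
    if nic is not None and nic.amplitude > 0:
        nic_on = int(round(nic.onset / dt))
        nic_off = n_steps
        fr = math.exp(-dt / (nic.tau_rise * 60000.0))
        fd = math.exp(-dt / (nic.tau_decay * 60000.0))
        from .inputs import _peak_time_min

        s_pk = _peak_time_min(nic)
        norm = math.exp(-s_pk / nic.tau_decay) - math.exp(-s_pk / nic.tau_rise)
        amp_norm = nic.amplitude / norm
        nic_window = _nicotine_elevated_window(nic, cfg.duration)
    else:
        nic_on, nic_off, fr, fd, amp_norm = n_steps + 1, n_steps + 1, 1.0, 1.0, 0.0

    rng_init = np.random.default_rng(seeds["initial_conditions"])
    v0 = -55.0 + 10.0 * (rng_init.random() - 0.5)
    ca0 = 0.1
    vg0 = -70.0 + 20.0 * rng_init.random(cfg.n_gaba)
    hg0 = np.asarray(cfg.gaba.h_inf(vg0))
    ng0 = np.asarray(cfg.gaba.n_inf(vg0))

    stride = int(round(cfg.trace_stride_ms / dt)) if cfg.record_traces else 0
    discard_steps = int(round(cfg.transient_ms / dt))
    dur_s = cfg.duration / 1000.0
    da_cap = int(dur_s * 100) + 64
    gaba_cap = int(cfg.n_gaba * dur_s * 250) + 64

    out = _kernel.run_circuit(
        n_steps, dt, stride, discard_steps,
        da_tab, gaba_tab, dp, gp, gl_arr, gt, rp_da, rp_gb,
        glu_counts, ach_counts,
        cfg.ach_pulse_da.amplitude, cfg.ach_pulse_gaba.amplitude,
        ach_fac_da, ach_fac_gb,
        nic_on, nic_off, amp_norm, fr, fd,
        v0, ca0,
        float(cfg.da.hna_inf(v0)), float(cfg.da.ndr_inf(v0)),
        float(cfg.da.qh_inf(v0)), float(cfg.da.uks_inf(v0)),
        vg0, hg0, ng0,
        da_cap, gaba_cap,
    )
    (status, t_fail, da_t, _n_da, g_t, g_id, _n_g, mean_iach, mean_sg, tr) = out
    if status != 0:
        raise FloatingPointError(
            f"numeric blow-up at t = {t_fail:.3f} ms (condition {cfg.condition}, "
            f"seed {cfg.master_seed}); reduce dt or check parameters"
        )

    da_spikes = SpikeTrain(da_t, cfg.duration)
    gaba_spikes = [
        SpikeTrain(g_t[g_id == j], cfg.duration) for j in range(cfg.n_gaba)
    ]
    _log.info(
        "run done: condition=%s hash=%s wall=%.1f s, %d DA spikes",
        cfg.condition, cfg.config_hash(), time.time() - t_wall, da_t.size,
    )
    traces = None
    if cfg.record_traces:
        names = [
            "t", "v_da", "ca", "s_nmda", "s_gaba", "c_ach_da", "c_nic",
            "a_da", "d_da", "a_gaba", "d_gaba", "v_gaba0",
        ]
        traces = {nm: tr[i] for i, nm in enumerate(names)}
    return SimulationResult(
        da_spikes=da_spikes,
        gaba_spikes=gaba_spikes,
        config=cfg,
        mean_nachr_current_da=mean_iach,
        mean_s_gaba=mean_sg,
        traces=traces,
        nicotine_window=nic_window,
    )


def run_nicotine_experiment(cfg: CircuitConfig) -> SimulationResult:
    """Baseline-then-nicotine protocol with pre/post analysis windows.

    Requires ``cfg.nicotine`` with onset at least 100 s into the run (so a
    settled baseline window exists).  The result carries ``pre_window`` and
    ``post_window`` attributes (ms intervals) for metric comparison: the
    pre window is the last 90 s before onset; the post window covers the
    sustained-activation phase (60-240 s after onset), past the initial
    pharmacokinetic transient of the concentration rise.
    """
    if cfg.nicotine is None:
        raise ValueError("cfg.nicotine must be set for a nicotine experiment")
    if cfg.nicotine.onset < 100_000.0:
        raise ValueError("nicotine onset must allow a >= 100 s baseline")
    res = run_simulation(cfg)
    onset = cfg.nicotine.onset
    pre = (max(cfg.transient_ms, onset - 90_000.0), onset)
    post = (onset + 60_000.0, min(onset + 240_000.0, cfg.duration))
    res.pre_window = pre
    res.post_window = post
    return res
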