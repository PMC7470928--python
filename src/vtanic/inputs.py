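"""Extrinsic drive to the VTA microcircuit.

Three input streams are generated here:

* a merged Poisson glutamatergic afferent spike train (the aggregate of
  ~20-60 asynchronous excitatory afferents, represented at their net rate);
* a cholinergic afferent spike train whose interspike intervals are drawn
  from a bimodal instantaneous-frequency distribution (fast mode 30 Hz,
  slow mode 3.3 Hz), producing bursty pulsatile ACh release;
* a slow nicotine concentration profile -- a difference of two exponentials
  normalized so that its peak equals the configured amplitude.

Spike trains are converted to agonist concentration traces by summing
instantaneous-rise, exponentially decaying pulses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SpikeTrain",
    "AChTrainParams",
    "AChPulseParams",
    "NicotineProtocol",
    "generate_poisson_train",
    "generate_bimodal_ach_train",
    "concentration_from_train",
    "nicotine_concentration",
    "nicotine_peak_time",
    "save_trains",
    "load_trains",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted event times (ms) of one afferent or simulated neuron."""

    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.size:
            if np.any(np.diff(t) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if t[0] < 0 or t[-1] > self.duration:
                raise ValueError("spike times must lie within [0, duration]")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def rate(self) -> float:
        """Mean firing rate in Hz."""
        return 1000.0 * len(self) / self.duration if self.duration > 0 else 0.0


@dataclass(frozen=True)
class AChTrainParams:
    """Bimodal-ISI cholinergic train: mixture of two instantaneous-frequency
    modes (Hz).  The fast mode dominates (weight 0.7), giving runs of ~33 ms
    intervals broken by ~300 ms pauses from the slow mode."""

    f_fast: float = 30.0
    f_slow: float = 3.3
    sd: float = 7.0
    weight_fast: float = 0.7
    weight_slow: float = 0.3
    f_min: float = 0.5  # rejection floor for sampled frequencies, Hz

    def __post_init__(self) -> None:
        if abs(self.weight_fast + self.weight_slow - 1.0) > 1e-9:
            raise ValueError("mode weights must sum to 1")
        if not (0 < self.f_min < self.f_slow < self.f_fast):
            raise ValueError("require 0 < f_min < f_slow < f_fast")
        if self.sd <= 0:
            raise ValueError("sd must be > 0")


@dataclass(frozen=True)
class AChPulseParams:
    """Per-spike ACh concentration pulse: instantaneous rise to ``amplitude``
    (uM), exponential decay with ``decay_tau`` (ms).  Pulses superpose."""

    amplitude: float = 5.0
    decay_tau: float = 10.0

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.decay_tau <= 0:
            raise ValueError("amplitude and decay_tau must be > 0")


@dataclass(frozen=True)
class NicotineProtocol:
    """Systemic nicotine exposure: double-exponential concentration bump.

    ``amplitude`` is the peak concentration (uM); rise and decay time
    constants are in minutes (0.5 / 3 by default); ``onset`` in ms.
    """

    amplitude: float = 0.5
    tau_rise: float = 0.5
    tau_decay: float = 3.0
    onset: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.tau_rise < self.tau_decay):
            raise ValueError("require 0 < tau_rise < tau_decay")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


def generate_poisson_train(rate: float, duration: float, rng_seed) -> SpikeTrain:
    """Homogeneous Poisson spike train at ``rate`` Hz over ``duration`` ms."""
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    if duration <= 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    if rate == 0:
        return SpikeTrain(np.empty(0), duration)
    rng = np.random.default_rng(rng_seed)
    mean_isi = 1000.0 / rate
    # draw in blocks until past the end
    times = []
    t = 0.0
    n_block = max(16, int(1.5 * duration / mean_isi) + 16)
    while t < duration:
        isis = rng.exponential(mean_isi, size=n_block)
        cum = t + np.cumsum(isis)
        times.append(cum[cum < duration])
        t = cum[-1]
    out = np.concatenate(times) if times else np.empty(0)
    return SpikeTrain(out, duration)


def generate_bimodal_ach_train(
    p: AChTrainParams, duration: float, rng_seed
) -> SpikeTrain:
    """Cholinergic afferent train with bimodal instantaneous frequency.

    Each interval: pick the fast mode with probability ``weight_fast``,
    sample f ~ Normal(mode, sd) rejected below ``f_min``, take ISI = 1000/f.
    """
    if duration <= 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    rng = np.random.default_rng(rng_seed)
    times = []
    t = 0.0
    while True:
        mode = p.f_fast if rng.random() < p.weight_fast else p.f_slow
        f = rng.normal(mode, p.sd)
        while f < p.f_min:
            f = rng.normal(mode, p.sd)
        t += 1000.0 / f
        if t >= duration:
            break
        times.append(t)
    return SpikeTrain(np.asarray(times), duration)


def concentration_from_train(
    train: SpikeTrain, p: AChPulseParams, t_grid: np.ndarray
) -> np.ndarray:
    """Agonist concentration trace (uM) on ``t_grid`` (ms) from a spike train.

    Each spike contributes ``amplitude * exp(-(t - t_spike)/decay_tau)`` for
    t >= t_spike; contributions sum.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    c = np.zeros_like(t_grid)
    for ts in train.times:
        m = t_grid >= ts
        c[m] += p.amplitude * np.exp(-(t_grid[m] - ts) / p.decay_tau)
    return c


def nicotine_concentration(p: NicotineProtocol, t) -> np.ndarray:
    """Nicotine concentration (uM) at time(s) ``t`` (ms).

    Zero before onset; afterwards a positive two-exponential bump
    ``A * (exp(-s/tau_decay) - exp(-s/tau_rise)) / N`` with ``s`` the time
    since onset (min) and ``N`` normalizing the peak to ``A``, so that
    "amplitude" means peak concentration.
    """
    t = np.asarray(t, dtype=float)
    s = (t - p.onset) / 60000.0  # minutes since onset
    raw = np.where(s > 0, np.exp(-s / p.tau_decay) - np.exp(-s / p.tau_rise), 0.0)
    s_peak = _peak_time_min(p)
    norm = np.exp(-s_peak / p.tau_decay) - np.exp(-s_peak / p.tau_rise)
    out = p.amplitude * raw / norm
    return out if out.ndim else float(out)


def _peak_time_min(p: NicotineProtocol) -> float:
    tr, td = p.tau_rise, p.tau_decay
    return tr * td / (td - tr) * np.log(td / tr)


def nicotine_peak_time(p: NicotineProtocol) -> float:
    """Time of the concentration peak, ms after onset (analytic)."""
    return p.onset + 60000.0 * _peak_time_min(p)


def save_trains(trains, path) -> None:
    """Write spike trains as two-column delimited text (train_id, time_ms)."""
    import pandas as pd

    rows = [(i, t) for i, tr in enumerate(trains) for t in tr.times]
    pd.DataFrame(rows, columns=["train_id", "time_ms"]).to_csv(path, index=False)


def load_trains(path, duration: float | None = None) -> list[SpikeTrain]:
    """Read spike trains from a two-column (train_id, time_ms) text table."""
    import pandas as pd

    df = pd.read_csv(path)
    if duration is None:
        duration = float(df["time_ms"].max()) if len(df) else 0.0
    out = []
    for _, grp in df.groupby("train_id", sort=True):
        out.append(SpikeTrain(np.sort(grp["time_ms"].to_numpy(float)), duration))
    return out
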