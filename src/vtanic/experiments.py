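"""Reproduction harness: named condition presets and multi-seed batch runs.

Two preset families cover the full condition x input-regime design:

* ``fig5`` -- the four knockout / re-expression conditions under endogenous
  pulsatile ACh input (spontaneous-activity comparison);
* ``fig6`` -- all five conditions (including the wild-type-like case with
  its glutamatergic rate increase) under the slow nicotine concentration
  bump, with pre/post analysis windows.

Each preset runs ``n_seeds`` independent simulations with per-run master
seeds derived from one experiment seed, removes the settling transient,
and aggregates firing rate, %SWB and mean burst length as mean +/- SEM.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .circuit import (
    CircuitConfig,
    SimulationResult,
    run_nicotine_experiment,
    run_simulation,
)
from .inputs import NicotineProtocol
from .metrics import pattern_metrics

__all__ = [
    "ExperimentSpec",
    "ACH_CONDITIONS",
    "NICOTINE_CONDITIONS",
    "preset_config",
    "derive_seeds",
    "run_preset",
    "compare_windows",
]

log = logging.getLogger("vtanic.experiments")

ACH_CONDITIONS = ("KO", "REEXP_DA", "REEXP_GABA", "REEXP_BOTH")
NICOTINE_CONDITIONS = ("KO", "REEXP_DA", "REEXP_GABA", "REEXP_BOTH", "WT")

# per-run durations (ms): spontaneous regime and baseline+nicotine regime
ACH_DURATION = 200_000.0
NICOTINE_ONSET = 100_000.0
NICOTINE_DURATION = 340_000.0


@dataclass
class ExperimentSpec:
    """One batch experiment: preset name, seed count, per-run duration."""

    preset: str = "fig5"
    n_seeds: int = 10
    master_seed: int = 0
    duration: float | None = None   # override per-run duration, ms
    save_raw: bool = False
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")
        if self.preset not in ("fig5", "fig6"):
            raise ValueError(f"unknown preset {self.preset!r} (expected fig5 or fig6)")


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-run master seeds below 2^31."""
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint32)
    return [int(s) % (2**31) for s in state]


def preset_config(condition: str, regime: str, master_seed: int,
                  duration: float | None = None) -> CircuitConfig:
    """Standard CircuitConfig for one (condition, regime) cell."""
    if regime == "ach":
        return CircuitConfig(
            condition=condition,
            master_seed=master_seed,
            duration=duration or ACH_DURATION,
        )
    if regime == "nicotine":
        return CircuitConfig(
            condition=condition,
            master_seed=master_seed,
            duration=duration or NICOTINE_DURATION,
            nicotine=NicotineProtocol(onset=NICOTINE_ONSET),
        )
    raise ValueError(f"unknown regime {regime!r}")


def compare_windows(result: SimulationResult, pre_window, post_window) -> dict:
    """Signed (post - pre) differences of rate, %SWB and burst length.

    Windows are (start_ms, stop_ms), non-overlapping, each >= 60 s.
    """
    for w in (pre_window, post_window):
        if w[1] - w[0] < 60_000.0:
            raise ValueError("windows must each span >= 60 s")
        if w[0] < 0 or w[1] > result.config.duration:
            raise ValueError("window outside the simulated interval")
    if not (pre_window[1] <= post_window[0] or post_window[1] <= pre_window[0]):
        raise ValueError("windows must not overlap")
    t = result.da_spikes.times
    out = {}
    for name, (a, b) in [("pre", pre_window), ("post", post_window)]:
        sel = t[(t >= a) & (t < b)]
        out[name] = pattern_metrics(sel, duration_ms=b - a)
    mpre, mpost = out["pre"], out["post"]
    return {
        "d_rate": mpost.rate - mpre.rate,
        "d_pct_swb": mpost.pct_swb - mpre.pct_swb,
        "d_mean_burst_len": (
            mpost.mean_burst_len - mpre.mean_burst_len
            if not (math.isnan(mpost.mean_burst_len) or math.isnan(mpre.mean_burst_len))
            else float("nan")
        ),
        "pre": mpre,
        "post": mpost,
    }


def _sem(x) -> float:
    x = np.asarray(x, float)
    x = x[~np.isnan(x)]
    if x.size <= 1:
        return float("nan")
    return float(np.std(x, ddof=1) / np.sqrt(x.size))


def run_preset(spec: ExperimentSpec) -> pd.DataFrame:
    """Run one preset; returns the summary table (one row per condition).

    For ``fig5`` metrics are computed on the post-transient interval of each
    run; for ``fig6`` the pre/post nicotine windows are compared and both
    absolute values and differences are tabulated.  Raw spike tables are
    written per seed when ``spec.save_raw`` and ``spec.out_dir`` are set.
    """
    seeds = derive_seeds(spec.master_seed, spec.n_seeds)
    rows = []
    conditions = ACH_CONDITIONS if spec.preset == "fig5" else NICOTINE_CONDITIONS
    regime = "ach" if spec.preset == "fig5" else "nicotine"
    for cond in conditions:
        per_seed = []
        for i, seed in enumerate(seeds):
            cfg = preset_config(cond, regime, seed, spec.duration)
            log.info("preset %s: %s seed %d/%d (master %d)",
                     spec.preset, cond, i + 1, len(seeds), seed)
            try:
                if regime == "ach":
                    res = run_simulation(cfg)
                    m = res.da_metrics()
                    rec = {
                        "seed": seed,
                        "rate": m.rate,
                        "pct_swb": m.pct_swb,
                        "mean_burst_len": m.mean_burst_len,
                        "isi_cv": m.isi_cv,
                    }
                else:
                    res = run_nicotine_experiment(cfg)
                    cmpd = compare_windows(res, res.pre_window, res.post_window)
                    rec = {
                        "seed": seed,
                        "rate_pre": cmpd["pre"].rate,
                        "rate_post": cmpd["post"].rate,
                        "pct_swb_pre": cmpd["pre"].pct_swb,
                        "pct_swb_post": cmpd["post"].pct_swb,
                        "d_rate": cmpd["d_rate"],
                        "d_pct_swb": cmpd["d_pct_swb"],
                    }
            except FloatingPointError as exc:
                log.error("run failed (%s seed %d): %s", cond, seed, exc)
                rec = {"seed": seed, "failed": True}
                per_seed.append(rec)
                continue
            per_seed.append(rec)
            if spec.save_raw and spec.out_dir:
                res.save(Path(spec.out_dir) / f"{cond}_seed{seed}")
        ok = [r for r in per_seed if not r.get("failed")]
        row = {
            "condition": cond,
            "regime": regime,
            "n_seeds": len(ok),
            "n_failed": len(per_seed) - len(ok),
        }
        if ok:
            keys = [k for k in ok[0] if k != "seed"]
            for k in keys:
                vals = np.asarray([r[k] for r in ok], float)
                finite = vals[~np.isnan(vals)]
                row[f"{k}_mean"] = float(finite.mean()) if finite.size else float("nan")
                row[f"{k}_sem"] = _sem(vals)
        rows.append(row)
    table = pd.DataFrame(rows)
    if spec.out_dir:
        out = Path(spec.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / f"{spec.preset}_summary.csv", index=False)
        meta = {
            "preset": spec.preset,
            "master_seed": spec.master_seed,
            "seeds": seeds,
            "config_hash": preset_config(
                conditions[0], regime, 0, spec.duration
            ).config_hash(),
        }
        (out / f"{spec.preset}_meta.json").write_text(json.dumps(meta, indent=2))
    return table
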