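"""Shared fixtures: multi-seed batches of the condition matrix.

The expensive simulations are run once per session and shared by the
acceptance tests; each fixture returns plain per-seed records (metrics,
burst sizes, population rates) rather than full results to keep memory flat.
"""

from __future__ import annotations

import numpy as np
import pytest

from vtanic import CircuitConfig, run_nicotine_experiment, run_simulation
from vtanic.circuit import replace
from vtanic.experiments import NICOTINE_ONSET, compare_windows, derive_seeds, preset_config
from vtanic.metrics import detect_bursts, pattern_metrics, synchrony_index

N_SEEDS = 10
ACH_RUN_MS = 200_000.0
MASTER = 20_260
ACH_CONDS = ("KO", "REEXP_DA", "REEXP_GABA", "REEXP_BOTH")
NIC_CONDS = ("KO", "REEXP_DA", "REEXP_GABA", "REEXP_BOTH", "WT")


@pytest.fixture(scope="session")
def seeds():
    return derive_seeds(MASTER, N_SEEDS)


@pytest.fixture(scope="session")
def ach_runs(seeds):
    """Per-condition, per-seed records of the spontaneous (ACh) regime."""
    out = {}
    for cond in ACH_CONDS:
        rows = []
        for seed in seeds:
            cfg = preset_config(cond, "ach", seed, duration=ACH_RUN_MS)
            res = run_simulation(cfg)
            t = res.da_spikes.times
            t = t[t >= cfg.transient_ms]
            part = detect_bursts(t)
            rows.append(
                {
                    "seed": seed,
                    "metrics": res.da_metrics(),
                    "burst_sizes": [len(b) for b in part.bursts],
                    "gaba_rate": float(res.gaba_rates().mean()),
                }
            )
        out[cond] = rows
    return out


@pytest.fixture(scope="session")
def nic_runs(seeds):
    """Per-condition, per-seed pre/post-nicotine comparisons."""
    out = {}
    for cond in NIC_CONDS:
        rows = []
        for seed in seeds:
            cfg = preset_config(cond, "nicotine", seed)
            res = run_nicotine_experiment(cfg)
            cw = compare_windows(res, res.pre_window, res.post_window)
            rec = {
                "seed": seed,
                "d_rate": cw["d_rate"],
                "d_pct_swb": cw["d_pct_swb"],
                "pre": cw["pre"],
                "post": cw["post"],
            }
            # GABA rate and synchrony pre/post for the mechanism criterion
            if cond == "REEXP_GABA" and len(rows) < 3:
                pre_w, post_w = res.pre_window, res.post_window
                def _win(tr, w):
                    return tr.times[(tr.times >= w[0]) & (tr.times < w[1])]
                g_pre = [_win(tr, pre_w) for tr in res.gaba_spikes]
                g_post = [_win(tr, post_w) for tr in res.gaba_spikes]
                rec["gaba_rate_pre"] = float(
                    np.mean([1000.0 * g.size / (pre_w[1] - pre_w[0]) for g in g_pre])
                )
                rec["gaba_rate_post"] = float(
                    np.mean([1000.0 * g.size / (post_w[1] - post_w[0]) for g in g_post])
                )
                rec["sync_pre"] = synchrony_index(g_pre, bin_ms=10.0, rng_seed=0)
                rec["sync_post"] = synchrony_index(g_post, bin_ms=10.0, rng_seed=0)
            rows.append(rec)
        out[cond] = rows
    return out


@pytest.fixture(scope="session")
def sync_runs(seeds):
    """GABA-population synchrony under common ACh vs the knockout baseline."""
    out = {"KO": [], "REEXP_GABA": []}
    for cond in out:
        for seed in seeds[:3]:
            cfg = preset_config(cond, "ach", seed, duration=100_000.0)
            res = run_simulation(cfg)
            trains = [
                tr.times[tr.times >= cfg.transient_ms] for tr in res.gaba_spikes
            ]
            out[cond].append(
                {
                    "seed": seed,
                    "sync": synchrony_index(trains, bin_ms=10.0, rng_seed=0),
                    "gaba_rate": float(res.gaba_rates().mean()),
                    "metrics": res.da_metrics(),
                }
            )
    return out


@pytest.fixture(scope="session")
def isolated_da():
    """Isolated DA neuron (no synaptic drive), 60 s."""
    cfg = CircuitConfig(condition="KO", master_seed=1, duration=60_000.0,
                        ach_input=None)
    cfg.da = replace(cfg.da, g_nmda=0.0, g_gaba=0.0)
    return run_simulation(cfg)
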