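"""Circuit assembly: condition presets, gates, determinism, balance, and
the pulsatile-vs-constant-input asymmetry."""

import json
import math

import numpy as np
import pytest

from vtanic import (
    CircuitConfig,
    SynapticGate,
    condition_conductances,
    gate_step,
    run_nicotine_experiment,
    run_simulation,
)
from vtanic.circuit import _make_glu_train, _nicotine_elevated_window, replace
from vtanic.inputs import NicotineProtocol


class TestConditionPresets:
    @pytest.mark.parametrize("cond,expected", [
        ("KO", (0.0, 0.0)),
        ("REEXP_DA", (5.0, 0.0)),
        ("REEXP_GABA", (0.0, 4.0)),
        ("REEXP_BOTH", (10.0, 1.5)),
        ("WT", (10.0, 1.5)),
    ])
    def test_table_values(self, cond, expected):
        assert condition_conductances(cond) == expected

    def test_double_reexpression_rebalancing_factors(self):
        # vs the single re-expression cases: GABA-pool conductance reduced
        # by a factor of ~2.6, DA-pool conductance doubled
        g_da_single, _ = condition_conductances("REEXP_DA")
        _, g_gb_single = condition_conductances("REEXP_GABA")
        g_da_both, g_gb_both = condition_conductances("REEXP_BOTH")
        assert g_da_both == pytest.approx(2.0 * g_da_single)
        assert g_gb_single / g_gb_both == pytest.approx(2.6, abs=0.1)

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            condition_conductances("WILDTYPE")


class TestSynapticGate:
    def test_pure_decay(self):
        g = SynapticGate(s=0.5, increment=0.2, decay_tau=10.0)
        out = gate_step(g, 0, 10.0)
        assert out.s == pytest.approx(0.5 / math.e, rel=1e-12)

    def test_saturating_increments(self):
        g = SynapticGate(s=0.0, increment=0.5, decay_tau=1e9)
        for _ in range(50):
            g = gate_step(g, 1, 1e-6)
        assert g.s < 1.0
        assert g.s == pytest.approx(1.0, abs=1e-6)

    def test_synchronous_volley_vs_spread_input(self):
        # n spikes in one step give a larger instantaneous peak than the same
        # n spikes spread over time, but bounded by saturation
        n, tau = 8, 10.0
        sync = gate_step(SynapticGate(0.0, 0.2, tau), n, 1e-9).s
        g = SynapticGate(0.0, 0.2, tau)
        for _ in range(n):
            g = gate_step(g, 1, 15.0)
        assert sync > g.s
        assert sync <= 1.0
        assert sync == pytest.approx(1.0 - (1.0 - 0.2) ** n, rel=1e-9)

    def test_shot_noise_mean(self):
        # steady Poisson drive at rate r: mean s ~= r * tau * inc / 1000
        rng = np.random.default_rng(0)
        rate, tau, inc, dt = 20.0, 20.0, 0.02, 0.5
        g = SynapticGate(0.0, inc, tau)
        vals = []
        for i in range(200_000):
            k = rng.poisson(rate * dt / 1000.0)
            g = gate_step(g, k, dt)
            if i > 2000:
                vals.append(g.s)
        expected = rate * tau * inc / 1000.0
        assert np.mean(vals) == pytest.approx(expected, rel=0.1)

    def test_rejects_nonpositive_dt(self):
        with pytest.raises(ValueError):
            gate_step(SynapticGate(), 0, 0.0)


class TestDeterminism:
    def test_identical_config_identical_trains(self):
        cfg = CircuitConfig(condition="REEXP_GABA", master_seed=5, duration=20_000.0)
        a = run_simulation(cfg)
        b = run_simulation(cfg)
        np.testing.assert_array_equal(a.da_spikes.times, b.da_spikes.times)
        for ta, tb in zip(a.gaba_spikes, b.gaba_spikes):
            np.testing.assert_array_equal(ta.times, tb.times)

    def test_seed_changes_output(self):
        a = run_simulation(CircuitConfig(condition="KO", master_seed=1, duration=20_000.0))
        b = run_simulation(CircuitConfig(condition="KO", master_seed=2, duration=20_000.0))
        assert a.da_spikes.times.size != b.da_spikes.times.size or not np.array_equal(
            a.da_spikes.times, b.da_spikes.times
        )

    def test_ko_insensitive_to_ach_input(self):
        # with both receptor conductances at zero, the cholinergic drive is
        # fully decoupled: spike trains match the ACh-off run exactly
        on = CircuitConfig(condition="KO", master_seed=3, duration=30_000.0)
        off = CircuitConfig(condition="KO", master_seed=3, duration=30_000.0,
                            ach_input=None)
        ra, rb = run_simulation(on), run_simulation(off)
        np.testing.assert_array_equal(ra.da_spikes.times, rb.da_spikes.times)

    def test_config_roundtrip_and_hash(self):
        cfg = CircuitConfig(condition="WT", master_seed=11,
                            nicotine=NicotineProtocol(onset=100_000.0))
        d = json.loads(json.dumps(cfg.to_dict(), default=float))
        cfg2 = CircuitConfig.from_dict(d)
        assert cfg2.config_hash() == cfg.config_hash()
        assert cfg2.conductances() == cfg.conductances()
        cfg3 = CircuitConfig(condition="WT", master_seed=12)
        assert cfg3.config_hash() != cfg.config_hash()


class TestBalanceAndAsymmetry:
    def test_ko_rate_near_isolated_pacemaker(self, isolated_da, ach_runs):
        r_iso = isolated_da.da_metrics().rate
        r_ko = np.mean([r["metrics"].rate for r in ach_runs["KO"]])
        assert abs(r_ko - r_iso) <= 0.3 * r_iso

    def test_constant_current_fails_to_burst(self):
        """A constant current matching the mean nicotinic drive raises the
        firing rate but barely moves %SWB, while the same drive delivered as
        synchronized GABA volleys (receptor re-expression on GABA neurons)
        raises %SWB much more -- the voltage-independence asymmetry."""
        d_swb_const, d_swb_rg, d_rate_const = [], [], []
        for seed in (101, 102):
            ko = run_simulation(
                CircuitConfig(condition="KO", master_seed=seed, duration=100_000.0)
            )
            rb = run_simulation(
                CircuitConfig(condition="REEXP_BOTH", master_seed=seed,
                              duration=100_000.0)
            )
            i_mean = rb.mean_nachr_current_da
            assert i_mean > 0.0
            cfg_const = CircuitConfig(condition="KO", master_seed=seed,
                                      duration=100_000.0)
            cfg_const.da = replace(cfg_const.da, i_const=i_mean)
            const = run_simulation(cfg_const)
            rg = run_simulation(
                CircuitConfig(condition="REEXP_GABA", master_seed=seed,
                              duration=100_000.0)
            )
            m_ko, m_c = ko.da_metrics(), const.da_metrics()
            d_rate_const.append(m_c.rate - m_ko.rate)
            d_swb_const.append(m_c.pct_swb - m_ko.pct_swb)
            d_swb_rg.append(rg.da_metrics().pct_swb - m_ko.pct_swb)
        assert np.mean(d_rate_const) > 0.0
        assert np.mean(d_swb_const) < 5.0
        assert np.mean(d_swb_rg) > np.mean(d_swb_const)


class TestNicotineMachinery:
    def test_elevated_window_brackets_peak(self):
        p = NicotineProtocol(onset=100_000.0)
        t0, t1 = _nicotine_elevated_window(p, 1_000_000.0)
        peak = 100_000.0 + 64_503.0
        assert t0 < peak < t1
        assert t1 - t0 > 200_000.0

    def test_wt_glu_rate_switch(self):
        cfg = CircuitConfig(condition="WT", master_seed=7, duration=400_000.0,
                            nicotine=NicotineProtocol(onset=100_000.0))
        tr = _make_glu_train(cfg, cfg.stream_seed("glu"))
        t0, t1 = _nicotine_elevated_window(cfg.nicotine, cfg.duration)
        t = tr.times
        r_base = 1000.0 * np.sum(t < t0) / t0
        r_nic = 1000.0 * np.sum((t >= t0) & (t < t1)) / (t1 - t0)
        assert r_base == pytest.approx(50.0, rel=0.05)
        assert r_nic == pytest.approx(60.0, rel=0.05)

    def test_requires_nicotine_and_baseline(self):
        with pytest.raises(ValueError):
            run_nicotine_experiment(CircuitConfig(condition="KO"))
        with pytest.raises(ValueError):
            run_nicotine_experiment(
                CircuitConfig(condition="KO",
                              nicotine=NicotineProtocol(onset=5_000.0))
            )


class TestRobustness:
    def test_numeric_blowup_reported_with_time(self):
        cfg = CircuitConfig(condition="KO", master_seed=1, duration=5_000.0,
                            dt=0.5, ach_input=None)
        cfg.da = replace(cfg.da, g_na=500.0, g_dr=0.5)
        with pytest.raises(FloatingPointError, match="t ="):
            run_simulation(cfg)

    def test_save_writes_artifacts(self, tmp_path):
        cfg = CircuitConfig(condition="KO", master_seed=1, duration=15_000.0,
                            record_traces=True)
        res = run_simulation(cfg)
        res.save(tmp_path)
        for name in ("da_spikes.csv", "gaba_spikes.csv", "metrics.json",
                     "config.json", "concentrations.csv"):
            assert (tmp_path / name).exists(), name
        meta = json.loads((tmp_path / "metrics.json").read_text())
        assert meta["config_hash"] == cfg.config_hash()
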