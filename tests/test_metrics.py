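"""Burst-partition, %SWB, windowed metrics and synchrony index.

The burst detector is validated exhaustively against an independent
formulation of the interval criterion: classify each ISI as short (< 80 ms),
middle (80-160 ms) or long (> 160 ms); within every maximal run of
non-long ISIs, a burst spans from the first short ISI to the end of the
run (middle ISIs can extend but never open a burst).
"""

import itertools

import numpy as np
import pytest

from vtanic import (
    SpikeTrain,
    detect_bursts,
    generate_poisson_train,
    isi_cv,
    mean_burst_length,
    pattern_metrics,
    percent_swb,
    synchrony_index,
    windowed_metrics,
)


def oracle_partition(times, onset=80.0, term=160.0):
    """Independent run-based reading of the two-threshold criterion."""
    isis = np.diff(times)
    n = len(times)
    bursts = []
    i = 0
    while i < len(isis):
        if isis[i] > term:
            i += 1
            continue
        j = i
        while j < len(isis) and isis[j] <= term:
            j += 1
        run = list(range(i, j))  # maximal run of non-long ISIs
        shorts = [k for k in run if isis[k] < onset]
        if shorts:
            first = shorts[0]
            bursts.append(tuple(range(first, j + 1)))  # spike indices
        i = j
    in_burst = {k for b in bursts for k in b}
    singles = tuple(k for k in range(n) if k not in in_burst)
    return tuple(bursts), singles


class TestBurstDetection:
    def test_all_long_isis_no_bursts(self):
        part = detect_bursts(np.array([0.0, 200.0, 400.0, 600.0]))
        assert part.n_bursts == 0
        assert percent_swb(part) == 0.0

    def test_worked_six_spike_example(self):
        # bursts {0,50,100} and {1000,1060}: 5 of 6 spikes in bursts
        part = detect_bursts(np.array([0.0, 50.0, 100.0, 300.0, 1000.0, 1060.0]))
        assert part.bursts == ((0, 1, 2), (4, 5))
        assert percent_swb(part) == pytest.approx(83.33, abs=0.01)

    def test_minimal_doublet(self):
        part = detect_bursts(np.array([0.0, 50.0]))
        assert part.bursts == ((0, 1),)
        assert percent_swb(part) == 100.0

    def test_boundary_ties(self):
        # ISI exactly 80 does not open a burst
        assert detect_bursts(np.array([0.0, 80.0, 160.0])).n_bursts == 0
        # ISI exactly 160 continues an open burst
        part = detect_bursts(np.array([0.0, 50.0, 210.0]))
        assert part.bursts == ((0, 1, 2),)

    def test_middle_isi_cannot_open_but_extends(self):
        # [120, 40]: burst opens at the 40 ms pair only
        part = detect_bursts(np.array([0.0, 120.0, 160.0]))
        assert part.bursts == ((1, 2),)
        # back-to-back: a middle ISI merges flanking short pairs
        part = detect_bursts(np.array([0.0, 40.0, 160.0, 200.0]))
        assert part.bursts == ((0, 1, 2, 3),)

    def test_exhaustive_against_independent_oracle(self):
        grid = (40.0, 120.0, 200.0)
        for n_isi in range(1, 6):
            for isis in itertools.product(grid, repeat=n_isi):
                t = np.concatenate([[0.0], np.cumsum(isis)])
                part = detect_bursts(t)
                ob, osing = oracle_partition(t)
                assert part.bursts == ob, f"isis={isis}"
                assert part.singles == osing, f"isis={isis}"

    @pytest.mark.parametrize("shift", [0.0, 1234.5, 1e6])
    def test_shift_and_silence_invariance(self, shift):
        base = np.array([0.0, 50.0, 100.0, 300.0, 1000.0, 1060.0])
        ref = detect_bursts(base)
        assert detect_bursts(base + shift).bursts == ref.bursts
        padded = np.concatenate([base, [base[-1] + 5000.0]])
        assert detect_bursts(padded).bursts == ref.bursts

    def test_partition_consistency(self):
        t = np.sort(generate_poisson_train(8.0, 60_000.0, 11).times)
        part = detect_bursts(t)
        assert percent_swb(part) * part.n / 100.0 == pytest.approx(
            sum(len(b) for b in part.bursts)
        )
        covered = set(part.singles) | {i for b in part.bursts for i in b}
        assert covered == set(range(part.n))
        assert all(len(b) >= 2 for b in part.bursts)

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            detect_bursts(np.array([10.0, 5.0]))


class TestSummaries:
    def test_mean_burst_length(self):
        part = detect_bursts(np.array([0.0, 50.0, 100.0, 1000.0, 1060.0]))
        assert [len(b) for b in part.bursts] == [3, 2]
        assert mean_burst_length(part) == 2.5

    def test_mean_burst_length_undefined_without_bursts(self):
        part = detect_bursts(np.array([0.0, 500.0]))
        with pytest.raises(ValueError):
            mean_burst_length(part)

    def test_pattern_metrics_rate(self):
        tr = SpikeTrain(np.arange(0.0, 10_000.0, 250.0), 10_000.0)
        m = pattern_metrics(tr)
        assert m.rate == pytest.approx(4.0)
        assert m.isi_cv == pytest.approx(0.0, abs=1e-12)

    def test_isi_cv_poisson_near_one(self):
        t = generate_poisson_train(10.0, 120_000.0, 3).times
        assert isi_cv(t) == pytest.approx(1.0, abs=0.12)


class TestWindowedMetrics:
    def test_tracks_stationary_rate(self):
        tr = generate_poisson_train(10.0, 120_000.0, 4)
        wm = windowed_metrics(tr, window_ms=20_000.0, step_ms=20_000.0)
        assert wm.rate_hz.mean() == pytest.approx(10.0, rel=0.1)
        assert wm.rate_hz.std() < 2.5

    def test_tracks_step_change(self):
        a = generate_poisson_train(4.0, 60_000.0, 5).times
        b = generate_poisson_train(12.0, 60_000.0, 6).times + 60_000.0
        t = np.concatenate([a, b])
        wm = windowed_metrics(t, window_ms=20_000.0, step_ms=10_000.0,
                              duration_ms=120_000.0)
        early = wm[wm.time_ms < 50_000.0].rate_hz.mean()
        late = wm[wm.time_ms > 75_000.0].rate_hz.mean()
        assert early == pytest.approx(4.0, rel=0.3)
        assert late == pytest.approx(12.0, rel=0.3)

    def test_empty_window_zero(self):
        wm = windowed_metrics(np.array([100.0]), window_ms=1000.0,
                              step_ms=1000.0, duration_ms=5000.0)
        assert (wm.rate_hz[wm.n_spikes == 0] == 0.0).all()
        assert (wm.pct_swb[wm.n_spikes == 0] == 0.0).all()

    def test_window_too_small_rejected(self):
        with pytest.raises(ValueError):
            windowed_metrics(np.array([1.0]), window_ms=500.0)


class TestSynchronyIndex:
    def test_identical_copies_near_one(self):
        t = generate_poisson_train(10.0, 60_000.0, 7).times
        idx = synchrony_index([t.copy() for _ in range(10)], bin_ms=10.0, rng_seed=0)
        assert idx > 0.8

    def test_independent_trains_near_zero(self):
        trains = [generate_poisson_train(10.0, 60_000.0, s).times for s in range(10)]
        idx = synchrony_index(trains, bin_ms=10.0, rng_seed=0)
        assert idx < 0.1

    def test_common_pulse_drive_exceeds_independent(self):
        rng = np.random.default_rng(0)
        pulses = np.sort(rng.uniform(0, 60_000.0, 120))
        driven, indep = [], []
        for s in range(8):
            base = generate_poisson_train(5.0, 60_000.0, 100 + s).times
            jit = pulses + rng.normal(0.0, 1.0, pulses.size)
            driven.append(np.sort(np.concatenate([base, jit])))
            indep.append(generate_poisson_train(7.0, 60_000.0, 200 + s).times)
        assert (synchrony_index(driven, bin_ms=10.0, rng_seed=1)
                > synchrony_index(indep, bin_ms=10.0, rng_seed=1) + 0.1)

    def test_requires_two_trains(self):
        with pytest.raises(ValueError):
            synchrony_index([np.array([1.0, 2.0])])
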