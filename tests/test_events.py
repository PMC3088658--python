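"""Event identification, precision statistics, exponential fits, jitter estimators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tempocode as tc
from tempocode import events as ev
from tempocode import synthetic as syn
from tempocode import timing_models as tm


def _doublet_raster(rng, n_trials=60, sd1=0.3, sd2=0.5, extra=None, lead_fast=0):
    """Trials spiking at 100+-sd1 and 102.6+-sd2 ms, nothing else."""
    trials = []
    for i in range(n_trials):
        t = [100.0 + sd1 * rng.standard_normal(), 102.6 + sd2 * rng.standard_normal()]
        if extra is not None and (i % 10) < extra * 10:  # interspersed contamination
            t.append(101.3 + 0.1 * rng.standard_normal())
        if i < lead_fast:
            t += list(rng.uniform(10.0, 90.0, size=6))
        trials.append(syn.SpikeTrain(np.sort(t), 200.0))
    return syn.TrialRaster(trials)


class TestIdentifyEvents:
    def test_single_clean_event(self, rng):
        events = ev.identify_events(_doublet_raster(rng))
        assert len(events) == 1
        assert abs(events[0].mean_isi_ms - 2.6) < 0.3

    def test_contaminated_event_rejected(self, rng):
        events = ev.identify_events(_doublet_raster(rng, extra=0.3))
        assert events == []

    def test_adaptation_trials_excluded(self, rng):
        raster = _doublet_raster(rng, n_trials=60, lead_fast=5)
        events = ev.identify_events(raster)
        assert len(events) == 1
        assert events[0].n_trials <= 55

    def test_too_few_trials_rejected(self, rng):
        with pytest.raises(ValueError):
            ev.identify_events(_doublet_raster(rng, n_trials=10))


class TestEventPrecision:
    def test_independent_spikes_isi_sd(self, rng):
        t1 = 100.0 + 0.6 * rng.standard_normal(200_000)
        t2 = 106.5 + 0.5 * rng.standard_normal(200_000)
        e = ev.DoubletEvent(t_first=t1, t_second=t2)
        _, isi_sd, r = ev.event_precision(e)
        assert abs(isi_sd - ev.independent_isi_sd(0.6, 0.5)) < 0.01
        assert abs(ev.independent_isi_sd(0.6, 0.5) - 0.8) < 0.02
        assert abs(r) < 0.02

    def test_perfect_correlation(self):
        t1 = np.array([99.5, 100.0, 100.5, 101.0])
        e = ev.DoubletEvent(t_first=t1, t_second=t1 + 2.6)
        jit, isi_sd, r = ev.event_precision(e)
        assert isi_sd == 0.0 and abs(r - 1.0) < 1e-12 and jit > 0

    def test_correlation_recovery(self, rng):
        # pairs with known R = 0.8 and SDs 0.3 / 0.5
        t1 = 0.3 * rng.standard_normal(50_000)
        z = rng.standard_normal(50_000)
        t2 = 2.6 + 0.8 * (0.5 / 0.3) * t1 + 0.5 * np.sqrt(1 - 0.64) * z
        e = ev.DoubletEvent(t_first=t1, t_second=t2)
        _, _, r = ev.event_precision(e)
        assert 0.75 <= r <= 0.85

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_variance_identity(self, seed):
        rng = np.random.default_rng(seed)
        t1 = rng.normal(0, 1.0, 50)
        t2 = 3.0 + 0.5 * t1 + rng.normal(0, 0.5, 50)
        var_isi = np.var(t2 - t1, ddof=1)
        ident = np.var(t1, ddof=1) + np.var(t2, ddof=1) - 2 * np.cov(t1, t2, ddof=1)[0, 1]
        assert abs(var_isi - ident) < 1e-9 * max(1.0, var_isi)


class TestExponentialFits:
    def test_reference_jitter_model_evaluation(self):
        assert abs(tm.jitter_vs_isi(2.0) - 0.44) < 0.005
        # plateau: the fitted form tends to x3 as ISI grows
        assert abs(tm.jitter_vs_isi(1e6) - 1.1) < 1e-9

    def test_jitter_parameter_recovery(self, rng):
        grid = np.array([2, 3, 4, 5, 6, 8, 10, 12, 15, 20, 25, 30, 40, 50, 65.0])
        y = tm.jitter_vs_isi(grid) + rng.normal(0, 0.02, grid.size)
        fit = ev.fit_jitter_vs_isi(grid, y)
        assert fit.order == 3
        assert 1.0 <= fit.params[2] <= 1.2

    def test_correlation_parameter_recovery(self, rng):
        grid = np.array([2, 3, 4, 5, 7, 10, 15, 20, 30, 40.0])
        y = tm.correlation_vs_isi(grid) + rng.normal(0, 0.01, grid.size)
        fit = ev.fit_correlation_vs_isi(grid, y)
        assert 2.0 <= fit.params[0] <= 2.6

    def test_too_few_points_refused(self):
        with pytest.raises(ValueError):
            ev.fit_jitter_vs_isi([2.0, 3.0, 4.0], [0.5, 0.6, 0.7])

    def test_prediction_ci_positive(self, rng):
        grid = np.linspace(2, 60, 12)
        y = tm.jitter_vs_isi(grid) + rng.normal(0, 0.05, grid.size)
        fit = ev.fit_jitter_vs_isi(grid, y)
        ci = fit.prediction_ci95(grid)
        assert np.all(ci >= 0) and np.all(np.isfinite(ci))


class TestRasterJitter:
    def test_known_latency_sd_recovered(self, rng):
        events = [
            ev.SingleSpikeEvent(latencies=100.0 * (k + 1) + 1.3 * rng.standard_normal(85))
            for k in range(50)
        ]
        assert abs(ev.raster_jitter(events) - 1.3) < 0.1

    def test_zero_noise_gives_zero(self):
        events = [ev.SingleSpikeEvent(latencies=np.full(30, 55.0))]
        assert ev.raster_jitter(events) == 0.0

    def test_translation_invariance(self, rng):
        lat = 80.0 + 1.1 * rng.standard_normal(40)
        a = ev.raster_jitter([ev.SingleSpikeEvent(latencies=lat)])
        b = ev.raster_jitter([ev.SingleSpikeEvent(latencies=lat + 7.0)])
        assert abs(a - b) < 1e-12

    def test_detection_from_raster(self, rng):
        centers = 60.0 + 50.0 * np.arange(20)
        trials = []
        for _ in range(40):
            trials.append(
                syn.SpikeTrain(np.sort(centers + 1.0 * rng.standard_normal(20)), 1100.0)
            )
        raster = syn.TrialRaster(trials)
        assert abs(ev.raster_jitter(raster) - 1.0) < 0.2


class TestDejittering:
    def _segments(self, rng, n=400, shift_sd=2.1, snr=3.0):
        kern = tc.generate_stimulus(200.0, seed=31).samples
        t = np.arange(kern.size) / 10.0
        shifts = rng.normal(0.0, shift_sd, n)
        segs = np.stack([np.interp(t + s, t, kern) for s in shifts])
        noise = rng.standard_normal(segs.shape) * 0.0
        if snr is not None:
            nz = tc.generate_stimulus(200.0 * n, seed=33).samples.reshape(n, kern.size)
            noise = nz * np.sqrt(np.mean(kern**2) / (snr * np.mean(nz**2)))
        return segs + noise, shifts

    def test_known_shift_sd_recovered(self, rng):
        segs, shifts = self._segments(rng)
        est, jitter, converged = ev.dejitter_latencies(segs, 10_000.0)
        assert converged
        assert 1.9 <= jitter <= 2.3
        # recovered shifts track the generating shifts
        assert np.corrcoef(est, shifts - shifts.mean())[0, 1] > 0.95

    def test_zero_shifts_give_zero(self, rng):
        segs, _ = self._segments(rng, shift_sd=0.0, snr=None)
        _, jitter, _ = ev.dejitter_latencies(segs, 10_000.0)
        assert jitter < 0.05

    def test_dejitter_exceeds_raster_with_invariance_noise(self, rng):
        # response-invariance variability adds on top of biophysical jitter
        segs, _ = self._segments(rng, shift_sd=2.1)
        _, dj, _ = ev.dejitter_latencies(segs, 10_000.0)
        raster_est = ev.raster_jitter(
            [ev.SingleSpikeEvent(latencies=1.3 * rng.standard_normal(85)) for _ in range(50)]
        )
        assert dj > raster_est
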