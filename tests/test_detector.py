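"""Spindle detector: filters, envelopes, thresholds, events, rejection."""

import numpy as np
import pytest
from scipy import signal as sps

from spindlesep.bands import SigmaBand
from spindlesep.detector import (ChannelThresholds, broadband_reject,
                                 channel_thresholds, design_detection_filter,
                                 detect_events, detect_spindles,
                                 reject_artifacts, sigma_envelope,
                                 spindle_metrics)
from spindlesep.eeg_io import SpindleEvent
from spindlesep.ged import filter_zero_phase

FS = 400.0


class TestDetectionFilter:
    def test_gain_profile(self):
        k = design_detection_filter(13.5, FS)
        w, h = sps.freqz(k, worN=[12.35, 13.5, 14.65], fs=FS)
        mag = np.abs(h)
        assert mag[1] >= 0.99
        assert mag[0] <= 0.05 and mag[2] <= 0.05

    def test_zero_phase_keeps_pulse_centered(self):
        k = design_detection_filter(13.5, FS, order=1000)
        x = np.zeros(8000)
        t = np.arange(2000) / FS
        burst = np.hanning(2000) * np.sin(2 * np.pi * 13.5 * t)
        x[3000:5000] = burst
        y = filter_zero_phase(x, k)
        com_x = (np.arange(len(x)) * x**2).sum() / (x**2).sum()
        com_y = (np.arange(len(y)) * y**2).sum() / (y**2).sum()
        assert abs(com_x - com_y) <= 1.0

    def test_distinct_centers_same_length(self):
        k1 = design_detection_filter(10.9, FS)
        k2 = design_detection_filter(13.5, FS)
        assert len(k1) == len(k2)
        assert not np.allclose(k1, k2)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            design_detection_filter(0.8, FS)
        with pytest.raises(ValueError):
            design_detection_filter(199.0, FS)


class TestEnvelope:
    def test_sinusoid_envelope_is_amplitude(self):
        t = np.arange(int(30 * FS)) / FS
        x = 3.0 * np.sin(2 * np.pi * 12.0 * t)
        env = sigma_envelope(x, FS)
        inner = env[int(2 * FS) : -int(2 * FS)]
        np.testing.assert_allclose(inner, 3.0, rtol=0.02)

    def test_hann_burst_envelope_recovered(self):
        t = np.arange(int(10 * FS)) / FS
        hann = np.zeros(len(t))
        i0, n = int(4 * FS), int(1.5 * FS)
        hann[i0 : i0 + n] = np.hanning(n)
        x = hann * np.sin(2 * np.pi * 13.0 * t)
        env = sigma_envelope(x, FS)
        r = np.corrcoef(env[i0 : i0 + n], hann[i0 : i0 + n])[0, 1]
        assert r >= 0.98

    def test_zero_signal(self):
        assert np.all(sigma_envelope(np.zeros(4000), FS) == 0)


class TestThresholds:
    def test_stated_arithmetic(self):
        thr = channel_thresholds(np.array([1.0, 1.0, 1.0, 3.0]))
        assert thr.mean == pytest.approx(1.5)
        assert thr.sd == pytest.approx(1.0)  # sample SD
        assert thr.upper == pytest.approx(4.5)
        assert thr.lower == pytest.approx(2.5)

    def test_constant_envelope_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            channel_thresholds(np.full(100, 2.0))

    def test_scaling_linearity(self, rng):
        env = np.abs(rng.standard_normal(1000)) + 0.1
        t1 = channel_thresholds(env)
        t2 = channel_thresholds(2.0 * env)
        assert t2.upper == pytest.approx(2 * t1.upper)
        assert t2.lower == pytest.approx(2 * t1.lower)


def burst_envelope(dur_s, amp, fs=FS, total_s=20.0, at_s=8.0, base=0.5):
    env = np.full(int(total_s * fs), base)
    n = int(dur_s * fs)
    i0 = int(at_s * fs)
    env[i0 : i0 + n] += amp * np.hanning(n)
    return env


class TestDetectEvents:
    thr = ChannelThresholds("Cz", "fast", mean=0.5, sd=0.25)  # up 1.25, lo .75

    def test_planted_burst_delimited_by_lower_crossings(self):
        env = burst_envelope(1.0, 5.0)
        events = detect_events(env, self.thr, FS)
        assert len(events) == 1
        onset, dur, peak, mean = events[0]
        # true lower-threshold crossings of the planted Hann envelope
        n = int(1.0 * FS)
        hann = 0.5 + 5.0 * np.hanning(n)
        above = np.flatnonzero(hann >= self.thr.lower)
        t_lo = 8.0 + above[0] / FS
        t_hi = 8.0 + above[-1] / FS
        assert abs(onset - t_lo) <= 0.15
        assert abs(onset + dur - t_hi) <= 0.15
        assert peak == pytest.approx(5.5, rel=0.01)

    def test_short_burst_rejected(self):
        env = burst_envelope(0.3, 5.0)
        assert detect_events(env, self.thr, FS) == []

    def test_subthreshold_envelope_yields_nothing(self):
        env = burst_envelope(1.0, 0.5)  # peaks at 1.0 < upper 1.25
        assert detect_events(env, self.thr, FS) == []

    def test_overlong_event_rejected(self):
        env = burst_envelope(4.0, 5.0, total_s=30.0)
        assert detect_events(env, self.thr, FS) == []

    def test_undelimitable_event_at_edge_discarded(self):
        env = np.full(int(5 * FS), 5.0)  # above upper from sample 0
        assert detect_events(env, self.thr, FS) == []

    def test_merged_upper_excursions_one_event(self):
        # two upper crossings inside one lower-threshold excursion
        env = np.full(int(10 * FS), 0.5)
        n = int(0.8 * FS)
        i0 = int(4 * FS)
        env[i0 : i0 + n] = 2.0
        env[i0 + n : i0 + n + 40] = 1.0   # dips below upper, stays above lower
        env[i0 + n + 40 : i0 + 2 * n + 40] = 2.0
        events = detect_events(env, self.thr, FS)
        assert len(events) == 1


class TestRejection:
    def band(self):
        return SigmaBand("S", "fast", 13.5)

    def test_clean_spindle_retained_click_rejected(self, rng):
        t = np.arange(int(1.0 * FS)) / FS
        clean = 10.0 * np.hanning(len(t)) * np.sin(2 * np.pi * 13.5 * t)
        assert not broadband_reject(clean, FS, self.band())
        click = clean + 40.0 * rng.standard_normal(len(t))
        assert broadband_reject(click, FS, self.band())

    def test_outlier_amplitude_rule(self):
        def ev(onset, mean_amp):
            return SpindleEvent("S", 1, "N2", "fast", "Cz", onset, 1.0,
                                mean_amp, mean_amp)

        t = np.arange(int(120 * FS)) / FS
        sig = np.sin(2 * np.pi * 13.5 * t)[None, :]
        events = [ev(float(k), 1.0 + 0.001 * k) for k in range(100)]
        events.append(ev(110.0, 50.0))  # gross outlier
        kept = reject_artifacts(events, sig, {"Cz": 0}, FS, self.band())
        assert len(kept) == 100
        assert all(e.mean_amp < 40 for e in kept)

    def test_single_event_outlier_rule_vacuous(self):
        t = np.arange(int(5 * FS)) / FS
        sig = np.sin(2 * np.pi * 13.5 * t)[None, :]
        only = [SpindleEvent("S", 1, "N2", "fast", "Cz", 1.0, 1.0, 9.9, 9.9)]
        kept = reject_artifacts(only, sig, {"Cz": 0}, FS, self.band())
        assert kept == only


class TestMetrics:
    def test_density_and_missing_amplitude(self):
        evs = [SpindleEvent("S", 1, "N2", "fast", "Cz", float(i), 0.5, 2.0)
               for i in range(30)]
        m = spindle_metrics(evs, 10.0, ["Cz", "Fz"])
        assert m["Cz"]["density"] == pytest.approx(3.0)
        assert m["Cz"]["amplitude"] == pytest.approx(2.0)
        assert m["Fz"]["density"] == 0.0
        assert np.isnan(m["Fz"]["amplitude"])
        with pytest.raises(ValueError):
            spindle_metrics(evs, 0.0, ["Cz"])


class TestEndToEnd:
    def test_planted_events_recovered_on_channel(self, montage16):
        from spindlesep.laplacian import apply_csd, build_csd_transform
        from spindlesep.synth import SynthParams, simulate_subject

        params = SynthParams(n_channels=16, minutes_n2=6.0, minutes_n3=0.0,
                             slow_density=0.0, fast_density=4.0, seed=31)
        rec, hyp, gt = simulate_subject(params, montage16)
        lap = apply_csd(rec, build_csd_transform(montage16))
        band = SigmaBand("S", "fast", gt.fast_freq)
        spe = int(30 * lap.fs)
        slices = [slice(i * spe, (i + 1) * spe)
                  for i in hyp.epochs_of("N2")]
        events = detect_spindles(lap.data, lap.fs, lap.labels, band,
                                 slices, {"N2": slices}, subject="S",
                                 order=1000)
        region = gt.events[0].channel_region
        got = [e for e in events if e.channel == region]
        truth = [e for e in gt.events if e.duration >= 0.5]
        hits = 0
        for ev in truth:
            if any(abs(g.onset - ev.onset) <= 0.5 for g in got):
                hits += 1
        assert hits / len(truth) >= 0.8
        # durations always within bounds, no overlap within channel
        for e in events:
            assert 0.4 - 1e-9 <= e.duration <= 3.0 + 1e-9
        got.sort(key=lambda e: e.onset)
        for a, b in zip(got, got[1:]):
            assert a.onset + a.duration <= b.onset + 1e-9
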