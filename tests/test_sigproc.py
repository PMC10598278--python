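"""Filtering, event detection and frequency profiling."""

import numpy as np
import pytest

from isletchip.profiles import IsletProfile
from isletchip.protocol import ProtocolSegment, ProtocolTimeline
from isletchip.sigproc import (
    EventTrain,
    acquisition_filter,
    detect_events,
    estimate_noise_sigma,
    frequency_profile,
    segment_stats,
    sp_band_filter,
)
from isletchip.simulate import Recording, render_waveform, simulate_recording

from _helpers import match_events


def make_recording(x, fs=1000.0, occupied=None, timeline=None):
    x = np.atleast_2d(np.asarray(x, dtype=np.float32))
    if occupied is None:
        occupied = [True] * x.shape[0]
    return Recording(x, fs, list(range(1, x.shape[0] + 1)), np.asarray(occupied), timeline)


def fft_amplitude(y, fs, freq):
    n = len(y)
    spec = np.abs(np.fft.rfft(y * np.hanning(n))) * 2 / (0.5 * n)
    freqs = np.fft.rfftfreq(n, 1 / fs)
    return spec[np.argmin(np.abs(freqs - freq))]


class TestAcquisitionFilter:
    def test_dc_removed(self):
        rec = make_recording(np.full(60_000, 123.0))
        out = acquisition_filter(rec)
        mid = out.samples[0, 20_000:40_000]
        assert np.abs(mid).max() < 0.01

    def test_in_band_tone_preserved(self):
        fs = 1000.0
        t = np.arange(int(60 * fs)) / fs
        rec = make_recording(np.sin(2 * np.pi * 1.0 * t))
        out = acquisition_filter(rec)
        assert np.abs(out.samples[0, 20_000:40_000]).max() == pytest.approx(1.0, rel=0.05)

    def test_near_corner_tone_preserved_and_infrasound_rejected(self):
        # at 1 kHz the upper corner clamps to 450 Hz: a 400 Hz tone must
        # survive within 10% while a 0.01 Hz component is strongly attenuated
        fs = 1000.0
        t = np.arange(int(60 * fs)) / fs
        x = np.sin(2 * np.pi * 400 * t) + np.sin(2 * np.pi * 0.01 * t)
        out = acquisition_filter(make_recording(x, fs))
        y = out.samples[0]
        assert fft_amplitude(y, fs, 400.0) == pytest.approx(1.0, rel=0.10)
        assert np.abs(y[20_000:40_000]).max() < 1.2  # 0.01 Hz contribution gone

    def test_output_length_equals_input(self):
        rec = make_recording(np.random.default_rng(0).standard_normal(10_000))
        assert acquisition_filter(rec).n_samples == rec.n_samples

    def test_rate_too_low_rejected(self):
        rec = make_recording(np.zeros(100), fs=0.2)
        with pytest.raises(ValueError, match="too low"):
            acquisition_filter(rec)


class TestSpBandFilter:
    def test_sp_waveform_energy_preserved(self):
        fs = 1000.0
        _, snip = render_waveform(0.0, 50.0, 1.0, fs)
        x = np.zeros(int(60 * fs), dtype=np.float32)
        x[20_000 : 20_000 + len(snip)] = snip
        out = sp_band_filter(make_recording(x, fs), decimate_to_hz=None)
        energy_ratio = (out.samples[0] ** 2).sum() / (x**2).sum()
        assert energy_ratio >= 0.90

    def test_white_noise_rms_reduced(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(60_000).astype(np.float32) * 5
        out = sp_band_filter(make_recording(x))
        assert out.samples.std() < x.std()

    def test_zero_in_zero_out(self):
        out = sp_band_filter(make_recording(np.zeros(30_000)))
        assert np.abs(out.samples).max() == 0

    def test_decimation_changes_rate_but_not_band_content(self):
        fs = 1000.0
        t = np.arange(int(120 * fs)) / fs
        x = 10 * np.sin(2 * np.pi * 0.5 * t)
        out = sp_band_filter(make_recording(x, fs))
        assert out.sampling_rate_hz == 50.0
        mid = out.samples[0, out.n_samples // 4 : out.n_samples // 2]
        assert np.abs(mid).max() == pytest.approx(10.0, rel=0.05)

    def test_corner_above_nyquist_rejected(self):
        rec = make_recording(np.zeros(1000), fs=4.0)
        with pytest.raises(ValueError, match="Nyquist"):
            sp_band_filter(rec, corner_hz=3.0, decimate_to_hz=None)


class TestNoiseEstimate:
    def test_recovers_white_noise_sp_band_sigma(self):
        # white noise of RMS 5 µV at 1 kHz carries 5*sqrt(2.9/500) µV in the
        # 0.1-3 Hz band; the high-band estimate must predict that level and
        # agree with the SP-band filter's actual output
        rng = np.random.default_rng(2)
        x = rng.standard_normal((3, 120_000)).astype(np.float32) * 5
        sigma = estimate_noise_sigma(make_recording(x))
        expected = 5 * np.sqrt(2.9 / 500)
        np.testing.assert_allclose(sigma, expected, rtol=0.10)
        measured = sp_band_filter(make_recording(x)).samples.std(axis=-1)
        np.testing.assert_allclose(sigma, measured, rtol=0.20)

    def test_insensitive_to_slow_potentials(self):
        # adding large SP waveforms must not inflate the noise estimate
        fs = 1000.0
        rng = np.random.default_rng(3)
        x = rng.standard_normal(int(120 * fs)).astype(np.float32) * 5
        clean_sigma = estimate_noise_sigma(make_recording(x.copy(), fs))[0]
        _, snip = render_waveform(0.0, 50.0, 1.0, fs)
        for start in range(0, len(x) - len(snip), int(1.3 * fs)):
            x[start : start + len(snip)] += snip
        loaded_sigma = estimate_noise_sigma(make_recording(x, fs))[0]
        assert loaded_sigma == pytest.approx(clean_sigma, rel=0.1)


class TestDetector:
    def test_all_zero_trace_has_no_events(self):
        rec = make_recording(np.zeros(30_000))
        out = detect_events(sp_band_filter(rec), noise_sigma_uV=1.0)
        assert out.total_events() == 0

    def test_empty_recording_gives_empty_train(self):
        rec = make_recording(np.zeros((1, 0)))
        out = detect_events(rec, noise_sigma_uV=1.0)
        assert out.total_events() == 0

    def test_ten_isolated_waveforms_detected_exactly(self):
        fs = 1000.0
        rng = np.random.default_rng(7)
        x = rng.standard_normal(int(120 * fs)).astype(np.float32) * 5  # SNR 10
        truth = 10.0 + 10.0 * np.arange(10)
        for ev in truth:
            first, snip = render_waveform(ev, 50.0, 1.0, fs)
            x[first : first + len(snip)] += snip
        rec = make_recording(x, fs)
        out = detect_events(sp_band_filter(rec), noise_sigma_uV=estimate_noise_sigma(rec))
        tp, fp, fn = match_events(truth, out.events[1], tol_s=1.0)
        assert (tp, fp, fn) == (10, 0, 0)

    def test_fixed_threshold_mode(self):
        fs = 1000.0
        x = np.zeros(int(30 * fs), dtype=np.float32)
        first, snip = render_waveform(10.0, 50.0, 1.0, fs)
        x[first : first + len(snip)] += snip
        out = detect_events(
            sp_band_filter(make_recording(x, fs)), threshold_mode="fixed_uV", threshold_uV=20.0
        )
        assert len(out.events[1]) == 1
        with pytest.raises(ValueError, match="threshold_uV"):
            detect_events(sp_band_filter(make_recording(x, fs)), threshold_mode="fixed_uV")

    def test_refractory_spacing_enforced(self):
        fs = 1000.0
        rng = np.random.default_rng(5)
        x = rng.standard_normal(int(300 * fs)).astype(np.float32) * 5
        t = 5.0
        while t < 290:
            first, snip = render_waveform(t, 50.0, 1.0, fs)
            x[first : first + len(snip)] += snip
            t += 1.15
        rec = make_recording(x, fs)
        out = detect_events(sp_band_filter(rec), noise_sigma_uV=estimate_noise_sigma(rec))
        assert np.diff(out.events[1]).min() >= 1.0 - 1e-9

    def test_detection_deterministic(self):
        fs = 1000.0
        prof = IsletProfile(archetype="t", baseline_rate_hz=0.0, rate_map={"G15": 0.3})
        tl = ProtocolTimeline((ProtocolSegment("G15", 0, 120, 15.0),))
        rec, _ = simulate_recording(prof, tl, 4, 0.5, fs, seed=11)
        outs = []
        for _ in range(2):
            out = detect_events(sp_band_filter(rec), noise_sigma_uV=estimate_noise_sigma(rec))
            outs.append(out)
        for e in outs[0].events:
            np.testing.assert_array_equal(outs[0].events[e], outs[1].events[e])


def make_train(events_by_el, duration=120.0, occupied=None):
    ids = sorted(events_by_el)
    if occupied is None:
        occupied = [True] * len(ids)
    return EventTrain(
        events={e: np.asarray(v, dtype=float) for e, v in events_by_el.items()},
        duration_s=duration, electrode_ids=ids, occupied=np.asarray(occupied),
    )


class TestFrequencyProfile:
    def test_uniform_events_give_count_over_duration(self):
        train = make_train({1: np.linspace(1, 59, 30)}, duration=60.0, occupied=[True])
        prof = frequency_profile(train, window_s=60.0)
        assert prof.per_electrode_hz[0, 0] == pytest.approx(0.5)

    def test_empty_train_gives_zero_profile(self):
        train = make_train({1: [], 2: []}, duration=180.0)
        prof = frequency_profile(train, window_s=60.0)
        assert prof.n_windows == 3
        assert np.all(prof.per_electrode_hz == 0)
        assert np.all(prof.aggregate_mean_hz == 0)

    def test_two_electrode_aggregate_mean_and_sem(self):
        # electrodes at 0.2 and 0.4 Hz: aggregate mean 0.3 Hz, SEM (sample
        # sd over sqrt(2)) = 0.1 Hz in every window
        ev1 = np.arange(0.5, 120, 5.0)   # 0.2 Hz
        ev2 = np.arange(0.5, 120, 2.5)   # 0.4 Hz
        prof = frequency_profile(make_train({1: ev1, 2: ev2}), window_s=60.0)
        np.testing.assert_allclose(prof.aggregate_mean_hz, 0.3)
        np.testing.assert_allclose(prof.aggregate_sem_hz, 0.1)

    def test_profile_additive_over_disjoint_event_sets(self):
        rng = np.random.default_rng(6)
        a = np.sort(rng.uniform(0, 300, 40))
        b = np.sort(rng.uniform(0, 300, 25))
        both = np.sort(np.r_[a, b])
        pa = frequency_profile(make_train({1: a}, 300.0, [True]), 60.0)
        pb = frequency_profile(make_train({1: b}, 300.0, [True]), 60.0)
        pab = frequency_profile(make_train({1: both}, 300.0, [True]), 60.0)
        np.testing.assert_allclose(
            pab.per_electrode_hz, pa.per_electrode_hz + pb.per_electrode_hz
        )

    def test_empty_electrode_subset_rejected(self):
        train = make_train({1: [1.0]}, 60.0, [True])
        with pytest.raises(ValueError, match="empty"):
            frequency_profile(train, electrodes=[])

    def test_unoccupied_excluded_from_aggregate_but_reported(self):
        ev = np.arange(0.5, 60, 2.0)
        train = make_train({1: ev, 2: []}, 60.0, occupied=[True, False])
        prof = frequency_profile(train, 60.0)
        assert prof.electrodes_used == [1]
        assert prof.per_electrode_hz.shape == (1, 2)
        assert prof.aggregate_mean_hz[0] == pytest.approx(0.5)


class TestSegmentStats:
    def timeline(self):
        return ProtocolTimeline((
            ProtocolSegment("A", 0, 300, 1.0),
            ProtocolSegment("B", 300, 600, 15.0),
            ProtocolSegment("C", 600, 660, 11.0),  # too short after discard
        ))

    def test_constant_rate_recovered_in_every_segment(self):
        ev = np.arange(0.25, 660, 2.5)  # 0.4 Hz throughout
        prof = frequency_profile(make_train({1: ev, 2: ev + 0.1}, 660.0), 60.0)
        stats = segment_stats(prof, self.timeline(), discard_initial_s=60.0)
        assert [s.label for s in stats] == ["A", "B"]  # C flagged and excluded
        for s in stats:
            assert s.mean_hz == pytest.approx(0.4, abs=0.02)

    def test_step_rate_across_boundary(self):
        ev = np.arange(300.25, 600, 2.5)  # silent then 0.4 Hz in B
        prof = frequency_profile(make_train({1: ev, 2: ev + 0.1}, 660.0), 60.0)
        stats = {s.label: s for s in segment_stats(prof, self.timeline())}
        assert stats["A"].mean_hz == 0.0
        assert stats["B"].mean_hz == pytest.approx(0.4, abs=0.02)

    def test_single_window_segment_mean_equals_window_value(self):
        tl = ProtocolTimeline((ProtocolSegment("A", 0, 120, 1.0),))
        ev = np.arange(60.5, 120, 2.0)  # 0.5 Hz only in the second window
        prof = frequency_profile(make_train({1: ev, 2: ev + 0.1}, 120.0), 60.0)
        stats = segment_stats(prof, tl)
        assert len(stats) == 1 and stats[0].n_windows == 1
        assert stats[0].mean_hz == pytest.approx(0.5)

    def test_discard_removes_transient_window(self):
        tl = ProtocolTimeline((ProtocolSegment("A", 0, 180, 1.0),))
        ev = np.arange(0.5, 60, 1.0)  # burst only in the first (discarded) window
        prof = frequency_profile(make_train({1: ev, 2: ev + 0.1}, 180.0), 60.0)
        stats = segment_stats(prof, tl, discard_initial_s=60.0)
        assert stats[0].mean_hz == 0.0
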