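"""Pulse curation chain: segmentation, preprocessing, beats, landmarks."""

import numpy as np
import pytest

from icpflow.errors import (
    DegenerateSignalError,
    InsufficientBeatsError,
    LandmarkFailureError,
    TooShortError,
)
from icpflow.pulses import (
    MeanPulse,
    average_pulse,
    BeatSet,
    detect_landmarks,
    extract_beats,
    preprocess_signal,
    pulse_parameters,
    segment_windows,
)
from icpflow.simulate import (
    PatientSimConfig,
    PulseMorphParams,
    RawRecording,
    simulate_pulse_template,
    simulate_recording,
)

FS = 250.0


def make_recording(duration_s, icp_value=None):
    n = int(duration_s * FS)
    channels = {"cranial_expansion": np.sin(2 * np.pi * 1.2 * np.arange(n) / FS)}
    if icp_value is not None:
        channels["icp_mmHg"] = np.full(n, float(icp_value))
    return RawRecording("p1", FS, channels)


class TestSegmentation:
    def test_sixty_seconds_gives_six_windows(self):
        windows = segment_windows(make_recording(60.0))
        assert len(windows) == 6
        assert all(len(w.samples) == 2500 for w in windows)

    def test_trailing_partial_window_dropped(self):
        assert len(segment_windows(make_recording(95.0))) == 9

    def test_reference_icp_is_window_mean(self):
        windows = segment_windows(make_recording(30.0, icp_value=12.0))
        assert all(w.reference_icp_mmHg == pytest.approx(12.0) for w in windows)

    def test_too_short_recording(self):
        with pytest.raises(TooShortError):
            segment_windows(make_recording(5.0))


class TestPreprocess:
    def test_linear_trend_removed(self, clean_recording):
        x = clean_recording.channels["cranial_expansion"][: int(30 * FS)]
        t = np.arange(len(x)) / FS
        out = preprocess_signal(x + 5.0 * t, FS)
        assert abs(np.mean(out)) < 0.05
        slope = np.polyfit(t, out, 1)[0]
        assert abs(slope) < 0.05

    def test_inverted_signal_restored(self, clean_recording):
        x = clean_recording.channels["cranial_expansion"][: int(30 * FS)]
        out_pos = preprocess_signal(x, FS)
        out_neg = preprocess_signal(-x, FS)
        # polarity fixed: both orientations give an upright pulse train
        assert np.corrcoef(out_pos, out_neg)[0, 1] > 0.95

    def test_upstroke_is_fast_limb_after_preprocess(self, clean_recording):
        from icpflow.pulses import _upstroke_is_slow

        x = clean_recording.channels["cranial_expansion"][: int(30 * FS)]
        assert not _upstroke_is_slow(preprocess_signal(x, FS), FS, 1.0)

    def test_empty_input_raises(self):
        with pytest.raises(DegenerateSignalError):
            preprocess_signal(np.array([]), FS)


class TestBeats:
    def test_beat_count_at_60_bpm(self, clean_recording):
        x = clean_recording.channels["cranial_expansion"][: int(10 * FS)]
        beats = extract_beats(preprocess_signal(x, FS), FS, 1.0)
        assert len(beats.onset_indices) == pytest.approx(10, abs=1)

    def test_injected_spikes_rejected(self, clean_recording):
        x = clean_recording.channels["cranial_expansion"][: int(10 * FS)].copy()
        amp = 6.0 * np.ptp(x)
        for start_s in (2.3, 6.1):  # two artifacts inside distinct beats
            i = int(start_s * FS)
            x[i : i + int(0.2 * FS)] += amp
        beats = extract_beats(preprocess_signal(x, FS), FS, 1.0)
        assert beats.n_rejected >= 1
        assert len(beats.beats) >= 7

    def test_onset_spacing_respects_refractory(self, clean_recording):
        x = clean_recording.channels["cranial_expansion"][: int(10 * FS)]
        beats = extract_beats(preprocess_signal(x, FS), FS, 1.0)
        assert np.all(np.diff(beats.onset_indices) >= 0.5 * FS / 1.0)

    def test_too_few_beats_raises(self):
        with pytest.raises(InsufficientBeatsError):
            extract_beats(np.zeros(2500), FS, 1.0)


class TestAveraging:
    def test_identical_beats_average_to_any_single_beat(self):
        beat = simulate_pulse_template(PulseMorphParams(), 230)
        beats = BeatSet(onset_indices=np.arange(5) * 230, beats=[beat.copy() for _ in range(5)])
        pulse = average_pulse(beats)
        single = np.interp(np.linspace(0, 1, 100), np.linspace(0, 1, 230), beat)
        single -= single[0]
        assert np.allclose(pulse.values, single, atol=1e-12)
        assert len(pulse.values) == 100

    def test_needs_three_beats(self):
        beats = BeatSet(onset_indices=np.array([0, 10]), beats=[np.ones(10)] * 2)
        with pytest.raises(InsufficientBeatsError):
            average_pulse(beats)

    def test_noise_averages_down_as_sqrt_n(self, rng):
        template = simulate_pulse_template(PulseMorphParams(), 100)
        template = template - template[0]
        n_beats, sigma = 25, 0.05
        resid_sds = []
        for _ in range(40):  # Monte-Carlo over noise draws
            noisy = [template + rng.normal(0, sigma, 100) for _ in range(n_beats)]
            noisy = [b - b[0] for b in noisy]
            beats = BeatSet(onset_indices=np.arange(n_beats) * 100, beats=noisy)
            pulse = average_pulse(beats)
            resid_sds.append(np.std(pulse.values - template))
        expected = sigma / np.sqrt(n_beats)
        assert np.mean(resid_sds) == pytest.approx(expected, rel=0.45)


def mean_pulse_from_template(morph, n=100):
    v = simulate_pulse_template(morph, n)
    return MeanPulse(values=v - v[0], n_beats_averaged=5, amplitude=float(np.ptp(v)))


class TestLandmarks:
    def test_three_bump_amplitude_ratio_recovered(self):
        morph = PulseMorphParams(
            a1=1.0, a2=1.2, a3=0.8, tau1=0.15, tau2=0.42, tau3=0.70,
            width1=0.05, width2=0.05, width3=0.05,
        )
        lm = detect_landmarks(mean_pulse_from_template(morph))
        assert lm.a_p2 / lm.a_p1 == pytest.approx(1.2, abs=0.05)
        assert lm.t_p1 < lm.t_p2

    def test_merged_peaks_resolved_via_shoulder(self):
        # overlapping bumps: single maximum with a shoulder on the rising limb
        morph = PulseMorphParams(
            a1=0.8, a2=1.1, a3=0.0, tau1=0.22, tau2=0.38,
            width1=0.08, width2=0.09,
        )
        lm = detect_landmarks(mean_pulse_from_template(morph))
        assert lm.t_p1 < lm.t_p2

    def test_monotone_ramp_fails(self):
        pulse = MeanPulse(values=np.linspace(0, 1, 100), n_beats_averaged=5, amplitude=1.0)
        with pytest.raises(LandmarkFailureError):
            detect_landmarks(pulse)


class TestPulseParams:
    def test_ttp_is_fraction_of_global_max(self):
        v = np.zeros(100)
        v[30] = 1.0
        pulse = MeanPulse(values=v, n_beats_averaged=5, amplitude=1.0)
        morph = PulseMorphParams()
        lm = detect_landmarks(mean_pulse_from_template(morph))
        params = pulse_parameters(pulse, lm)
        assert params.ttp == pytest.approx(30 / 99)

    def test_symmetric_triangle_auc_half(self):
        v = np.concatenate([np.linspace(0, 1, 50), np.linspace(1, 0, 50)])
        v = np.interp(np.linspace(0, 99, 100), np.arange(100), v)
        pulse = MeanPulse(values=v, n_beats_averaged=5, amplitude=1.0)
        lm = detect_landmarks(mean_pulse_from_template(PulseMorphParams()))
        params = pulse_parameters(pulse, lm)
        assert params.auc == pytest.approx(0.5, abs=0.02)

    def test_icc_class_boundaries(self):
        morphs = {
            1: PulseMorphParams().with_p2p1(0.7),
            3: PulseMorphParams().with_p2p1(1.45),
        }
        for expected, morph in morphs.items():
            pulse = mean_pulse_from_template(morph)
            params = pulse_parameters(pulse, detect_landmarks(pulse))
            assert params.icc_class == expected

    def test_amplitude_scale_invariance(self):
        morph = PulseMorphParams(
            a1=1.0, a2=1.2, a3=0.8, tau1=0.15, tau2=0.42, tau3=0.70,
            width1=0.05, width2=0.05, width3=0.05,
        )
        p1 = mean_pulse_from_template(morph)
        scaled = MeanPulse(values=3.0 * p1.values, n_beats_averaged=5,
                           amplitude=3.0 * p1.amplitude)
        a = pulse_parameters(p1, detect_landmarks(p1))
        b = pulse_parameters(scaled, detect_landmarks(scaled))
        assert a.p2p1_ratio == pytest.approx(b.p2p1_ratio, rel=1e-9)
        assert a.ttp == b.ttp
        assert a.auc == pytest.approx(b.auc, rel=1e-9)


class TestRecoveryAcrossSimulatedWindows:
    def test_p2p1_recovery_over_sweep(self):
        """Extracted P2/P1 tracks the generator over a 0.6-1.6 sweep."""
        from scipy import stats

        from icpflow.pipeline import process_recording

        gens, exts = [], []
        for i, p in enumerate(np.linspace(0.6, 1.6, 11)):
            cfg = PatientSimConfig(
                patient_id=f"S{i}", duration_s=30.0, artifact_rate_per_min=0.0,
                morph_drift_sd=0.0, noise_sd=0.02,
            )
            rec = simulate_recording(cfg, PulseMorphParams().with_p2p1(p), seed=100 + i)
            feats, _, _ = process_recording(rec)
            for _, row in feats.iterrows():
                w = int(row["window_id"].split("_")[1])
                gens.append(rec.truth.loc[w, "p2p1_true"])
                exts.append(row["p2p1"])
        gens, exts = np.array(gens), np.array(exts)
        assert len(gens) >= 20
        assert stats.spearmanr(gens, exts).statistic >= 0.9
        assert np.mean(np.abs(gens - exts)) <= 0.05

    def test_window_accounting_conserved(self):
        from icpflow.pipeline import process_recording

        cfg = PatientSimConfig(patient_id="A", duration_s=60.0,
                               artifact_rate_per_min=2.0)
        rec = simulate_recording(cfg, seed=77)
        _, qc, acct = process_recording(rec)
        assert acct.conserved()
        assert acct.n_windows == 6 == len(qc)
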