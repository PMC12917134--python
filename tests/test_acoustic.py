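"""Acoustic features: VAD, pause/rate features, descriptor subset,
descriptor selection, SNR."""

import numpy as np
import pandas as pd
import pytest

from speechcog import acoustic as A
from speechcog.acoustic import (ACOUSTIC_FEATURES, EGEMAPS_SUBSET,
                                VoiceSegments, Waveform, count_phonemes,
                                detect_voice_segments, egemaps_subset,
                                estimate_snr, pause_features, rate_features,
                                select_descriptors)
from speechcog.cohort import WaveformPlan, synthesize_waveform

SR = 16000


def _tone(duration, f0=150.0, amp=0.3, sr=SR):
    t = np.arange(int(duration * sr)) / sr
    return amp * np.sin(2 * np.pi * f0 * t)


def _noise(duration, amp=1e-3, sr=SR, seed=0):
    rng = np.random.default_rng(seed)
    return amp * rng.standard_normal(int(duration * sr))


# ---------------------------------------------------------------------------
# VAD
# ---------------------------------------------------------------------------

class TestVad:
    def test_pure_silence_yields_no_segments(self):
        w = Waveform(_noise(3.0), SR)
        assert detect_voice_segments(w).intervals == []

    def test_continuous_tone_is_one_full_segment(self):
        w = Waveform(_tone(3.0) + _noise(3.0), SR)
        seg = detect_voice_segments(w)
        assert len(seg.intervals) == 1
        s, e = seg.intervals[0]
        assert s == pytest.approx(0.0, abs=0.05)
        assert e == pytest.approx(3.0, abs=0.05)

    def test_burst_boundaries_within_two_frames(self):
        plan = WaveformPlan([(1.0, 2.5), (3.5, 5.0)], 6.0, f0=150.0)
        w = synthesize_waveform(plan, sample_rate=SR)
        seg = detect_voice_segments(w)
        assert len(seg.intervals) == 2
        tol = 2 * 0.03  # two 30 ms frames
        for (gs, ge), (ps, pe) in zip(seg.intervals, plan.voiced_intervals):
            assert gs == pytest.approx(ps, abs=tol)
            assert ge == pytest.approx(pe, abs=tol)

    def test_unsupported_sample_rate_rejected(self):
        w = Waveform(np.zeros(100), 30)
        with pytest.raises(ValueError):
            detect_voice_segments(w)


# ---------------------------------------------------------------------------
# Pause features
# ---------------------------------------------------------------------------

class TestPauseFeatures:
    def test_hand_computed_example(self):
        seg = VoiceSegments([(1.0, 3.0), (5.0, 8.0)], 10.0)
        fv = pause_features(seg)
        assert fv["fraction_of_pause"] == pytest.approx(2 / 7)
        assert fv["mean_duration"] == 2.0
        assert fv["std_duration"] == 0.0

    def test_single_segment_has_zero_pause(self):
        fv = pause_features(VoiceSegments([(0.5, 4.0)], 5.0))
        assert fv["fraction_of_pause"] == 0.0

    def test_population_std_of_two_pauses(self):
        # pauses 1 s and 3 s
        seg = VoiceSegments([(0.0, 1.0), (2.0, 3.0), (6.0, 7.0)], 8.0)
        fv = pause_features(seg)
        assert fv["mean_duration"] == 2.0
        assert fv["std_duration"] == 1.0

    def test_no_voiced_segments_flagged_invalid(self):
        fv = pause_features(VoiceSegments([], 5.0))
        assert not fv.is_valid("fraction_of_pause")


# ---------------------------------------------------------------------------
# Phonemes and rates
# ---------------------------------------------------------------------------

class TestRates:
    def test_lexicon_lookup(self):
        assert count_phonemes("cat").count == 3

    def test_doubling_text_doubles_count(self):
        text = "the boy took the cookie"
        single = count_phonemes(text).count
        assert count_phonemes(text + " " + text).count == 2 * single

    def test_fallback_fraction_reported(self):
        pc = count_phonemes("cat zzyzzx")
        assert pc.fallback_fraction == 0.5

    def test_rates_direct_ratios(self):
        fv = rate_features(120, 60.0, 40.0)
        assert fv["speech_rate"] == 2.0
        assert fv["articulation_rate"] == 3.0

    def test_equal_lengths_equal_rates(self):
        fv = rate_features(100, 50.0, 50.0)
        assert fv["speech_rate"] == fv["articulation_rate"]

    def test_zero_voiced_invalidates_articulation(self):
        fv = rate_features(100, 50.0, 0.0)
        assert not fv.is_valid("articulation_rate")


# ---------------------------------------------------------------------------
# eGeMAPS subset
# ---------------------------------------------------------------------------

class TestEgemaps:
    def test_silence_gives_floor_loudness_and_no_voiced_segments(self):
        w = Waveform(_noise(2.0), SR)
        fv = egemaps_subset(w)
        assert fv["VoicedSegmentsPerSec"] == 0.0
        assert fv["loudness_sma3_percentile50.0"] < 0.01

    def test_voiced_segments_per_second_from_plan(self):
        # 4 bursts in 2 s
        iv = [(0.1, 0.3), (0.6, 0.8), (1.1, 1.3), (1.6, 1.8)]
        plan = WaveformPlan(iv, 2.0, f0=160.0)
        w = synthesize_waveform(plan, sample_rate=SR)
        seg = detect_voice_segments(w, min_gap_s=0.05)
        fv = egemaps_subset(w, segments=seg)
        assert fv["VoicedSegmentsPerSec"] == pytest.approx(2.0)

    def test_amplitude_doubling_raises_level_six_db(self):
        x = _tone(2.0) + _noise(2.0)
        lo = egemaps_subset(Waveform(x, SR))["equivalentSoundLevel_dBp"]
        hi = egemaps_subset(Waveform(2 * x, SR))["equivalentSoundLevel_dBp"]
        assert hi - lo == pytest.approx(20 * np.log10(2), abs=0.01)

    def test_too_short_input_flagged_invalid(self):
        fv = egemaps_subset(Waveform(_tone(0.5), SR))
        assert not any(fv.valid.values())

    def test_all_descriptor_names_present(self):
        plan = WaveformPlan([(0.2, 1.8), (2.4, 3.6)], 4.0, f0=140.0)
        w = synthesize_waveform(plan, sample_rate=SR)
        fv = egemaps_subset(w)
        assert fv.names == list(EGEMAPS_SUBSET)


# ---------------------------------------------------------------------------
# Descriptor selection
# ---------------------------------------------------------------------------

class TestDescriptorSelection:
    def _data(self, seed=0, n=200):
        rng = np.random.default_rng(seed)
        target = rng.normal(0, 1, n)
        f1 = target + rng.normal(0, 0.5, n)
        f3 = rng.normal(0, 1, n)
        cands = pd.DataFrame({"f1": f1, "f2": f1.copy(), "f3": f3})
        targets = pd.DataFrame({"language": target})
        return cands, targets

    def test_duplicate_column_dropped_by_greedy_pass(self):
        cands, targets = self._data()
        sel = select_descriptors(cands, targets, top_k=2)
        assert sel.kept == ["f1"]
        sel = select_descriptors(cands, targets, top_k=3)
        assert sel.kept == ["f1", "f3"]

    def test_everything_kept_below_cap(self):
        rng = np.random.default_rng(1)
        cands = pd.DataFrame(rng.normal(0, 1, (300, 4)),
                             columns=list("abcd"))
        targets = pd.DataFrame({"y": rng.normal(0, 1, 300)})
        sel = select_descriptors(cands, targets, top_k=10)
        assert sorted(sel.kept) == list("abcd")

    def test_target_copy_ranks_first(self):
        cands, targets = self._data()
        cands["exact"] = targets["language"]
        sel = select_descriptors(cands, targets, top_k=4)
        assert sel.ranked[0] == "exact"

    def test_constant_column_excluded_with_warning(self):
        cands, targets = self._data()
        cands["const"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            sel = select_descriptors(cands, targets)
        assert "const" not in sel.ranked

    def test_input_order_invariance(self):
        cands, targets = self._data(seed=5)
        a = select_descriptors(cands, targets, top_k=3)
        b = select_descriptors(cands[["f3", "f1", "f2"]], targets, top_k=3)
        assert set(a.kept) == set(b.kept)


# ---------------------------------------------------------------------------
# SNR
# ---------------------------------------------------------------------------

class TestSnr:
    def _wave_and_seg(self, sig_amp, noise_amp):
        sig = sig_amp * np.sin(2 * np.pi * 150 * np.arange(SR) / SR)
        noise = noise_amp * np.sin(2 * np.pi * 150 * np.arange(SR) / SR)
        x = np.concatenate([noise, sig])
        return Waveform(x, SR), VoiceSegments([(1.0, 2.0)], 2.0)

    def test_hundredfold_power_is_twenty_db(self):
        w, seg = self._wave_and_seg(1.0, 0.1)
        assert estimate_snr(w, seg) == pytest.approx(20.0, abs=0.01)

    def test_equal_powers_zero_db(self):
        w, seg = self._wave_and_seg(0.2, 0.2)
        assert estimate_snr(w, seg) == pytest.approx(0.0, abs=0.01)

    def test_global_scaling_invariance(self):
        w, seg = self._wave_and_seg(0.5, 0.05)
        scaled = Waveform(w.samples * 0.3, SR)
        assert estimate_snr(w, seg) == pytest.approx(
            estimate_snr(scaled, seg), abs=1e-9)

    def test_all_voiced_raises(self):
        w = Waveform(_tone(1.0), SR)
        with pytest.raises(ValueError):
            estimate_snr(w, VoiceSegments([(0.0, 1.0)], 1.0))


# ---------------------------------------------------------------------------
# Orchestrator
# ---------------------------------------------------------------------------

class TestExtractAll:
    def test_full_vector_names_and_determinism(self):
        plan = WaveformPlan([(0.3, 2.0), (2.8, 4.5)], 5.0, f0=130.0)
        w = synthesize_waveform(plan, sample_rate=SR)
        text = "the boy took the cookie from the jar"
        a = A.extract_all_acoustic(w, text)
        b = A.extract_all_acoustic(w, text)
        assert a.names == list(ACOUSTIC_FEATURES)
        assert len(a.names) == 27
        assert a.values == b.values
        assert a["audio_length"] == pytest.approx(len(w.samples) / SR)
        # articulation rate >= speech rate when pauses exist
        assert a["articulation_rate"] >= a["speech_rate"]
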