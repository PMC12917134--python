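"""Waveform-derived acoustic features.

Two groups, mirroring the analysis feature table:

* hand-crafted pause/rate features driven by an energy-based voice activity
  detector (VAD): audio length, fraction of pause, mean/std pause duration,
  speech rate and articulation rate (phonemes per second of audio / of
  voiced time);
* a 21-descriptor subset of the extended Geneva minimalistic acoustic
  parameter set (eGeMAPS), each computed as a documented approximation of
  the published descriptor (frame-RMS loudness, FFT spectral flux, mel
  cepstra, autocorrelation F0, LPC formants).  The contract is the named
  vector, not bit-compatibility with any external extractor.

All framing uses 25 ms analysis windows with a 10 ms hop unless stated
otherwise; the VAD uses 30 ms frames, 10 ms hop, an adaptive energy
threshold (noise floor + 10 dB) and a 3-frame hangover.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.io import wavfile
from scipy.linalg import solve_toeplitz
from scipy.signal import find_peaks

from ._wordlists import PHONEME_COUNTS
from .features import FeatureVector

__all__ = [
    "Waveform", "VoiceSegments", "DescriptorSelection", "PhonemeCount",
    "EGEMAPS_SUBSET", "ACOUSTIC_FEATURES",
    "read_wav", "write_wav",
    "detect_voice_segments", "pause_features", "count_phonemes",
    "rate_features", "egemaps_subset", "select_descriptors", "estimate_snr",
    "extract_all_acoustic",
]


@dataclass
class Waveform:
    """Mono PCM audio as float samples in [-1, 1]."""

    samples: np.ndarray
    sample_rate: int
    participant_id: str = ""
    task: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.samples.ndim != 1:
            raise ValueError("waveform must be mono (1-D samples)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass
class VoiceSegments:
    """Sorted, non-overlapping voiced intervals [start_s, end_s)."""

    intervals: list[tuple[float, float]] = field(default_factory=list)
    total_duration_s: float = 0.0

    def __post_init__(self):
        prev_end = 0.0
        for s, e in self.intervals:
            if s < prev_end - 1e-9 or e <= s:
                raise ValueError("voiced intervals must be sorted and "
                                 "non-overlapping with positive length")
            prev_end = e
        if self.intervals and self.intervals[-1][1] > self.total_duration_s + 1e-6:
            raise ValueError("voiced interval extends past total duration")

    @property
    def voiced_duration_s(self) -> float:
        return sum(e - s for s, e in self.intervals)

    def pauses(self) -> list[float]:
        """Durations of gaps between consecutive voiced intervals
        (leading/trailing silence excluded)."""
        return [s2 - e1 for (_, e1), (s2, _)
                in zip(self.intervals, self.intervals[1:])]


def read_wav(path) -> Waveform:
    """Read a 16-bit PCM mono WAV file; other encodings are rejected."""
    sr, data = wavfile.read(path)
    if data.dtype != np.int16:
        raise ValueError(f"expected 16-bit PCM WAV, got dtype {data.dtype}")
    if data.ndim != 1:
        raise ValueError("expected mono WAV")
    return Waveform(data.astype(float) / 32768.0, sr)


def write_wav(path, w: Waveform) -> None:
    clipped = np.clip(w.samples, -1.0, 1.0)
    wavfile.write(path, w.sample_rate, (clipped * 32767).astype(np.int16))


# ---------------------------------------------------------------------------
# Framing helpers
# ---------------------------------------------------------------------------

def _frame(x: np.ndarray, frame_len: int, hop: int) -> np.ndarray:
    """(n_frames, frame_len) view; trailing partial frame dropped."""
    if len(x) < frame_len:
        return np.empty((0, frame_len))
    n = 1 + (len(x) - frame_len) // hop
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n)[:, None]
    return x[idx]


def _frame_rms_db(frames: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    rms = np.sqrt(np.mean(frames ** 2, axis=1))
    return 20.0 * np.log10(np.maximum(rms, floor))


# ---------------------------------------------------------------------------
# Voice activity detection
# ---------------------------------------------------------------------------

def detect_voice_segments(w: Waveform, frame_ms: float = 30.0,
                          hop_ms: float = 10.0,
                          energy_threshold_db: float = 10.0,
                          hangover_frames: int = 3,
                          min_gap_s: float = 0.15,
                          silence_floor_db: float = -50.0) -> VoiceSegments:
    """Energy-based VAD with adaptive threshold and hangover smoothing.

    A frame is voiced when its RMS level exceeds the estimated noise floor
    (5th percentile of frame levels) by ``energy_threshold_db``.  Homogeneous
    signals (dynamic range < threshold) are decided globally against
    ``silence_floor_db`` dBFS.  Voiced runs are extended by
    ``hangover_frames`` frames, and segments separated by gaps shorter than
    ``min_gap_s`` are merged.
    """
    frame_len = int(round(frame_ms * 1e-3 * w.sample_rate))
    hop = int(round(hop_ms * 1e-3 * w.sample_rate))
    if frame_len < 2 or hop < 1:
        raise ValueError(f"sample rate {w.sample_rate} too low for "
                         f"{frame_ms} ms frames")
    frames = _frame(w.samples, frame_len, hop)
    dur = w.duration_s
    if frames.shape[0] == 0:
        return VoiceSegments([], dur)
    levels = _frame_rms_db(frames)
    p05, p50, p95 = np.percentile(levels, [5, 50, 95])
    if p95 - p05 < energy_threshold_db:
        # homogeneous: all speech or all silence
        if p50 > silence_floor_db:
            return VoiceSegments([(0.0, dur)], dur)
        return VoiceSegments([], dur)
    voiced = levels > p05 + energy_threshold_db
    # hangover: keep frames voiced for a few frames after a voiced run
    out = voiced.copy()
    run = 0
    for i, v in enumerate(voiced):
        if v:
            run = hangover_frames
        elif run > 0:
            out[i] = True
            run -= 1
    voiced = out
    # frames -> intervals
    intervals: list[tuple[float, float]] = []
    start = None
    for i, v in enumerate(voiced):
        t0 = i * hop / w.sample_rate
        if v and start is None:
            start = t0
        elif not v and start is not None:
            intervals.append((start, t0 + (frame_len - hop) / w.sample_rate))
            start = None
    if start is not None:
        intervals.append((start, dur))
    # merge short gaps
    merged: list[tuple[float, float]] = []
    for s, e in intervals:
        if merged and s - merged[-1][1] < min_gap_s:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    merged = [(s, min(e, dur)) for s, e in merged]
    return VoiceSegments(merged, dur)


def pause_features(seg: VoiceSegments) -> FeatureVector:
    """Pause statistics over the lead/trail-trimmed span.

    Pauses are the gaps between consecutive voiced segments within
    [first voiced start, last voiced end]; the fraction-of-pause denominator
    is that trimmed span.  With zero voiced segments all three features are
    flagged invalid; with a single pause the (population) std is 0.
    """
    fv = FeatureVector()
    if not seg.intervals:
        for name in ("fraction_of_pause", "mean_duration", "std_duration"):
            fv.set_invalid(name)
        return fv
    span = seg.intervals[-1][1] - seg.intervals[0][0]
    pauses = seg.pauses()
    total_pause = sum(pauses)
    fv.set("fraction_of_pause", total_pause / span if span > 0 else 0.0)
    if pauses:
        fv.set("mean_duration", float(np.mean(pauses)))
        fv.set("std_duration", float(np.std(pauses)))
    else:
        fv.set("mean_duration", 0.0)
        fv.set("std_duration", 0.0)
    return fv


# ---------------------------------------------------------------------------
# Phoneme counting and rates
# ---------------------------------------------------------------------------

class PhonemeCount(NamedTuple):
    count: int
    fallback_fraction: float


def _fallback_phonemes(word: str) -> int:
    """Letter-based phoneme estimate for out-of-lexicon words: number of
    vowel groups plus number of consonant letters after collapsing doubled
    letters (floor 1)."""
    w = re.sub(r"(.)\1+", r"\1", word.lower())
    vowels = len(re.findall(r"[aeiouy]+", w))
    consonants = sum(1 for c in w if c.isalpha() and c not in "aeiouy")
    return max(vowels + consonants, 1)


def count_phonemes(text: str,
                   g2p_lexicon: dict[str, int] | None = None) -> PhonemeCount:
    """Total phoneme count of a transcript via the grapheme-to-phoneme
    lexicon, with the documented letter-based fallback; reports the fraction
    of words that needed the fallback."""
    lex = PHONEME_COUNTS if g2p_lexicon is None else g2p_lexicon
    words = re.findall(r"[A-Za-z]+(?:'[A-Za-z]+)?", text)
    total = 0
    fallbacks = 0
    for w in words:
        lw = w.lower()
        if lw in lex:
            total += lex[lw]
        else:
            total += _fallback_phonemes(lw)
            fallbacks += 1
    frac = fallbacks / len(words) if words else 0.0
    return PhonemeCount(total, frac)


def rate_features(phonemes: int, audio_length_s: float,
                  voiced_length_s: float) -> FeatureVector:
    """speech_rate = phonemes / audio length;
    articulation_rate = phonemes / voiced length (invalid at zero voiced)."""
    if audio_length_s <= 0:
        raise ValueError("audio_length_s must be positive")
    fv = FeatureVector()
    fv.set("speech_rate", phonemes / audio_length_s)
    if voiced_length_s > 0:
        fv.set("articulation_rate", phonemes / voiced_length_s)
    else:
        fv.set_invalid("articulation_rate")
    return fv


# ---------------------------------------------------------------------------
# eGeMAPS-style descriptor subset
# ---------------------------------------------------------------------------

EGEMAPS_SUBSET: tuple[str, ...] = (
    "F0semitoneFrom27.5Hz_sma3nz_meanRisingSlope",
    "loudness_sma3_percentile20.0",
    "loudness_sma3_percentile50.0",
    "loudness_sma3_percentile80.0",
    "loudness_sma3_meanRisingSlope",
    "spectralFlux_sma3_amean",
    "spectralFlux_sma3_stddevNorm",
    "mfcc1_sma3_stddevNorm",
    "mfcc3_sma3_amean",
    "mfcc3_sma3_stddevNorm",
    "F1bandwidth_sma3nz_stddevNorm",
    "F1amplitudeLogRelF0_sma3nz_amean",
    "alphaRatioV_sma3nz_stddevNorm",
    "spectralFluxV_sma3nz_stddevNorm",
    "mfcc1V_sma3nz_stddevNorm",
    "alphaRatioUV_sma3nz_amean",
    "spectralFluxUV_sma3nz_amean",
    "loudnessPeaksPerSec",
    "VoicedSegmentsPerSec",
    "MeanUnvoicedSegmentLength",
    "equivalentSoundLevel_dBp",
)


def _stddev_norm(x: np.ndarray) -> float:
    """Coefficient of variation: std / |mean| (eGeMAPS 'stddevNorm')."""
    m = np.mean(x)
    return float(np.std(x) / max(abs(m), 1e-12))


def _mean_rising_slope(contour: np.ndarray, dt: float) -> float:
    """Mean slope over maximal strictly-rising runs of a contour."""
    slopes = []
    i = 0
    n = len(contour)
    while i < n - 1:
        if contour[i + 1] > contour[i]:
            j = i
            while j < n - 1 and contour[j + 1] > contour[j]:
                j += 1
            slopes.append((contour[j] - contour[i]) / ((j - i) * dt))
            i = j
        else:
            i += 1
    return float(np.mean(slopes)) if slopes else 0.0


def _mel_filterbank(n_filters: int, n_fft: int, sr: int) -> np.ndarray:
    def hz_to_mel(f):
        return 2595.0 * np.log10(1.0 + f / 700.0)

    def mel_to_hz(m):
        return 700.0 * (10.0 ** (m / 2595.0) - 1.0)

    mels = np.linspace(hz_to_mel(20.0), hz_to_mel(sr / 2), n_filters + 2)
    hz = mel_to_hz(mels)
    bins = np.floor((n_fft + 1) * hz / sr).astype(int)
    fb = np.zeros((n_filters, n_fft // 2 + 1))
    for m in range(1, n_filters + 1):
        lo, ctr, hi = bins[m - 1], bins[m], bins[m + 1]
        for k in range(lo, ctr):
            if ctr > lo:
                fb[m - 1, k] = (k - lo) / (ctr - lo)
        for k in range(ctr, hi):
            if hi > ctr:
                fb[m - 1, k] = (hi - k) / (hi - ctr)
    return fb


def _mfcc(spec: np.ndarray, sr: int, n_fft: int, n_coef: int = 4) -> np.ndarray:
    """MFCCs 0..n_coef-1 per frame from a magnitude spectrogram."""
    from scipy.fft import dct
    fb = _mel_filterbank(26, n_fft, sr)
    energies = np.log(np.maximum(spec ** 2 @ fb.T, 1e-12))
    return dct(energies, type=2, norm="ortho", axis=1)[:, :n_coef]


def _autocorr_f0(frame: np.ndarray, sr: int, fmin: float = 60.0,
                 fmax: float = 400.0) -> float:
    """Autocorrelation pitch estimate; 0 when unvoiced/aperiodic."""
    x = frame - np.mean(frame)
    if np.max(np.abs(x)) < 1e-8:
        return 0.0
    ac = np.correlate(x, x, mode="full")[len(x) - 1:]
    ac = ac / ac[0]
    lo = int(sr / fmax)
    hi = min(int(sr / fmin), len(ac) - 1)
    if hi <= lo:
        return 0.0
    lag = lo + int(np.argmax(ac[lo:hi]))
    if ac[lag] < 0.3:
        return 0.0
    return sr / lag


def _lpc_f1(frame: np.ndarray, sr: int, order: int = 12):
    """First formant frequency and bandwidth via LPC (autocorrelation
    method); returns (nan, nan) when no root falls in the F1 range."""
    x = (frame - np.mean(frame)) * np.hamming(len(frame))
    if np.max(np.abs(x)) < 1e-8:
        return np.nan, np.nan
    r = np.correlate(x, x, mode="full")[len(x) - 1:len(x) + order]
    if r[0] <= 0:
        return np.nan, np.nan
    try:
        a = solve_toeplitz((r[:-1], r[:-1]), r[1:])
    except np.linalg.LinAlgError:
        return np.nan, np.nan
    roots = np.roots(np.concatenate(([1.0], -a)))
    roots = roots[np.imag(roots) > 0]
    freqs = np.angle(roots) * sr / (2 * np.pi)
    bws = -sr / np.pi * np.log(np.maximum(np.abs(roots), 1e-12))
    sel = (freqs > 90) & (freqs < 1500) & (bws < 700)
    if not np.any(sel):
        return np.nan, np.nan
    i = np.argmin(freqs[sel])
    return float(freqs[sel][i]), float(bws[sel][i])


def egemaps_subset(w: Waveform, segments: VoiceSegments | None = None,
                   frame_ms: float = 25.0, hop_ms: float = 10.0,
                   ) -> FeatureVector:
    """The 21 contracted eGeMAPS-style descriptors.

    Requires at least 1 s of audio (all descriptors flagged invalid
    otherwise).  Voiced/unvoiced frame assignment follows ``segments``
    (computed by :func:`detect_voice_segments` when not supplied).
    """
    fv = FeatureVector()
    if w.duration_s < 1.0:
        for name in EGEMAPS_SUBSET:
            fv.set_invalid(name)
        return fv
    if segments is None:
        segments = detect_voice_segments(w)
    sr = w.sample_rate
    frame_len = int(round(frame_ms * 1e-3 * sr))
    hop = int(round(hop_ms * 1e-3 * sr))
    frames = _frame(w.samples, frame_len, hop)
    n_frames = frames.shape[0]
    dt = hop / sr
    times = np.arange(n_frames) * dt + frame_len / sr / 2

    voiced_mask = np.zeros(n_frames, dtype=bool)
    for s, e in segments.intervals:
        voiced_mask |= (times >= s) & (times < e)

    # loudness proxy: frame RMS
    loud = np.sqrt(np.mean(frames ** 2, axis=1))
    fv.set("loudness_sma3_percentile20.0", float(np.percentile(loud, 20)))
    fv.set("loudness_sma3_percentile50.0", float(np.percentile(loud, 50)))
    fv.set("loudness_sma3_percentile80.0", float(np.percentile(loud, 80)))
    smooth = np.convolve(loud, np.ones(3) / 3, mode="same")
    fv.set("loudness_sma3_meanRisingSlope", _mean_rising_slope(smooth, dt))

    # spectra
    n_fft = 1 << (frame_len - 1).bit_length()
    spec = np.abs(np.fft.rfft(frames * np.hanning(frame_len), n=n_fft, axis=1))
    freqs = np.fft.rfftfreq(n_fft, 1 / sr)

    flux = np.concatenate(([0.0],
                           np.sqrt(np.mean(np.diff(spec, axis=0) ** 2, axis=1))))
    fv.set("spectralFlux_sma3_amean", float(np.mean(flux)))
    fv.set("spectralFlux_sma3_stddevNorm", _stddev_norm(flux))

    mfcc = _mfcc(spec, sr, n_fft)
    fv.set("mfcc1_sma3_stddevNorm", _stddev_norm(mfcc[:, 1]))
    fv.set("mfcc3_sma3_amean", float(np.mean(mfcc[:, 3])))
    fv.set("mfcc3_sma3_stddevNorm", _stddev_norm(mfcc[:, 3]))

    # alpha ratio: energy 50-1000 Hz over 1-5 kHz, in dB, per frame
    low_band = (freqs >= 50) & (freqs < 1000)
    high_band = (freqs >= 1000) & (freqs < 5000)
    e_low = np.sum(spec[:, low_band] ** 2, axis=1)
    e_high = np.sum(spec[:, high_band] ** 2, axis=1)
    alpha = 10 * np.log10(np.maximum(e_low, 1e-12) /
                          np.maximum(e_high, 1e-12))

    n_voiced = int(np.sum(voiced_mask))
    n_unvoiced = n_frames - n_voiced
    if n_voiced >= 2:
        fv.set("alphaRatioV_sma3nz_stddevNorm",
               _stddev_norm(alpha[voiced_mask]))
        fv.set("spectralFluxV_sma3nz_stddevNorm",
               _stddev_norm(flux[voiced_mask]))
        fv.set("mfcc1V_sma3nz_stddevNorm",
               _stddev_norm(mfcc[voiced_mask, 1]))
    else:
        for name in ("alphaRatioV_sma3nz_stddevNorm",
                     "spectralFluxV_sma3nz_stddevNorm",
                     "mfcc1V_sma3nz_stddevNorm"):
            fv.set_invalid(name)
    if n_unvoiced >= 1:
        fv.set("alphaRatioUV_sma3nz_amean",
               float(np.mean(alpha[~voiced_mask])))
        fv.set("spectralFluxUV_sma3nz_amean",
               float(np.mean(flux[~voiced_mask])))
    else:
        fv.set_invalid("alphaRatioUV_sma3nz_amean")
        fv.set_invalid("spectralFluxUV_sma3nz_amean")

    # F0 contour on voiced frames (semitones from 27.5 Hz)
    f0_st = []
    f1_bw = []
    f1_rel = []
    for i in np.flatnonzero(voiced_mask):
        f0 = _autocorr_f0(frames[i], sr)
        if f0 > 0:
            f0_st.append(12.0 * np.log2(f0 / 27.5))
            # relative F1 amplitude (dB of spectral magnitude at F1 vs F0)
            freq_res = sr / n_fft
            k0 = int(round(f0 / freq_res))
            f1, bw = _lpc_f1(frames[i], sr)
            if np.isfinite(f1):
                f1_bw.append(bw)
                k1 = int(round(f1 / freq_res))
                if 0 < k0 < spec.shape[1] and 0 < k1 < spec.shape[1]:
                    f1_rel.append(20 * np.log10(
                        max(spec[i, k1], 1e-12) / max(spec[i, k0], 1e-12)))
    if len(f0_st) >= 2:
        fv.set("F0semitoneFrom27.5Hz_sma3nz_meanRisingSlope",
               _mean_rising_slope(np.asarray(f0_st), dt))
    else:
        fv.set_invalid("F0semitoneFrom27.5Hz_sma3nz_meanRisingSlope")
    if len(f1_bw) >= 2:
        fv.set("F1bandwidth_sma3nz_stddevNorm",
               _stddev_norm(np.asarray(f1_bw)))
    else:
        fv.set_invalid("F1bandwidth_sma3nz_stddevNorm")
    if f1_rel:
        fv.set("F1amplitudeLogRelF0_sma3nz_amean", float(np.mean(f1_rel)))
    else:
        fv.set_invalid("F1amplitudeLogRelF0_sma3nz_amean")

    # loudness peaks per second
    if np.ptp(loud) > 0:
        peaks, _ = find_peaks(smooth, prominence=0.25 * np.std(loud))
        fv.set("loudnessPeaksPerSec", len(peaks) / w.duration_s)
    else:
        fv.set("loudnessPeaksPerSec", 0.0)

    fv.set("VoicedSegmentsPerSec", len(segments.intervals) / w.duration_s)
    pauses = segments.pauses()
    fv.set("MeanUnvoicedSegmentLength",
           float(np.mean(pauses)) if pauses else 0.0)
    fv.set("equivalentSoundLevel_dBp",
           10 * np.log10(max(np.mean(w.samples ** 2), 1e-12)))
    return fv.reorder(list(EGEMAPS_SUBSET))


# ---------------------------------------------------------------------------
# Descriptor selection (effect-size ranking + redundancy removal)
# ---------------------------------------------------------------------------

@dataclass
class DescriptorSelection:
    ranked: list[str]
    kept: list[str]
    scores: dict[str, float]
    corr: "object"          # pandas.DataFrame of candidate correlations
    top_k: int
    corr_cap: float


def select_descriptors(candidates, targets, top_k: int = 30,
                       corr_cap: float = 0.85) -> DescriptorSelection:
    """Rank candidate descriptors by their maximum absolute Pearson
    correlation to any composite score (development set only), keep the
    ``top_k``, then greedily drop the lower-ranked member of any pair with
    absolute inter-candidate correlation above ``corr_cap``.

    ``candidates``: DataFrame (participants x descriptors);
    ``targets``: DataFrame (participants x composite scores) on the same
    index.  Constant candidate columns are excluded with a warning.  Ties in
    the ranking score are broken by the candidate column order.
    """
    import pandas as pd
    candidates = pd.DataFrame(candidates)
    targets = pd.DataFrame(targets)
    if len(candidates) != len(targets):
        raise ValueError("candidates and targets must cover the same "
                         "participants")
    usable = []
    for col in candidates.columns:
        if candidates[col].nunique() <= 1:
            warnings.warn(f"descriptor {col!r} is constant; excluded "
                          "(correlation undefined)")
        else:
            usable.append(col)
    scores = {}
    for col in usable:
        scores[col] = float(max(abs(candidates[col].corr(targets[t]))
                                for t in targets.columns))
    order = {c: i for i, c in enumerate(candidates.columns)}
    ranked = sorted(usable, key=lambda c: (-scores[c], order[c]))
    short = ranked[:top_k]
    corr = candidates[usable].corr()
    kept: list[str] = []
    for c in short:
        if all(abs(corr.loc[c, k]) <= corr_cap for k in kept):
            kept.append(c)
    return DescriptorSelection(ranked, kept, scores, corr, top_k, corr_cap)


def estimate_snr(w: Waveform, seg: VoiceSegments) -> float:
    """Signal-to-noise ratio: 10 log10(mean voiced power / mean pause power).

    Raises ``ValueError`` when either voiced or pause samples are absent.
    """
    mask = np.zeros(len(w.samples), dtype=bool)
    for s, e in seg.intervals:
        mask[int(s * w.sample_rate):int(e * w.sample_rate)] = True
    if not mask.any():
        raise ValueError("no voiced samples: SNR undefined")
    if mask.all():
        raise ValueError("no pause samples: SNR undefined")
    p_sig = np.mean(w.samples[mask] ** 2)
    p_noise = np.mean(w.samples[~mask] ** 2)
    return float(10 * np.log10(max(p_sig, 1e-20) / max(p_noise, 1e-20)))


# ---------------------------------------------------------------------------
# Orchestrator
# ---------------------------------------------------------------------------

ACOUSTIC_FEATURES: tuple[str, ...] = (
    "audio_length", "fraction_of_pause", "mean_duration", "std_duration",
    "speech_rate", "articulation_rate") + EGEMAPS_SUBSET


def extract_all_acoustic(w: Waveform, transcript_text: str,
                         vad_kwargs: dict | None = None) -> FeatureVector:
    """Fixed-order acoustic feature vector (6 hand-crafted + 21 descriptor
    subset); validity flags propagate from sub-extractors."""
    seg = detect_voice_segments(w, **(vad_kwargs or {}))
    fv = FeatureVector()
    fv.set("audio_length", w.duration_s)
    fv.update(pause_features(seg))
    ph = count_phonemes(transcript_text)
    fv.update(rate_features(ph.count, w.duration_s, seg.voiced_duration_s))
    fv.update(egemaps_subset(w, segments=seg))
    return fv.reorder(list(ACOUSTIC_FEATURES))
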