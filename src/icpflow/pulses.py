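"""Pulse curation chain and morphological parameter extraction.

One 10-s window of cranial-expansion signal is turned into an onset-aligned
mean pulse and its morphological parameters through the stages: detrending
band-pass filter, polarity verification, beat (onset) detection with a
refractory period, artifact rejection (duration, amplitude and template
agreement), linear length normalization, point-wise averaging, and finally
landmark detection (P1/P2/P3) with the derived P2/P1, TTP and AUC parameters.

Windows that cannot yield at least three clean beats, or whose mean pulse has
no identifiable P1/P2 landmarks, raise :class:`WindowExcluded` subclasses so
the caller can keep exact accounting of every exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import (
    DegenerateSignalError,
    InsufficientBeatsError,
    LandmarkFailureError,
    TooShortError,
)
from .simulate import RawRecording

PULSE_LENGTH = 100  # resample points per mean pulse
BANDPASS_HZ = (0.3, 20.0)
MIN_BEATS = 3
BEAT_CORR_THRESHOLD = 0.7
AMPLITUDE_MAD_FACTOR = 3.0
P1_REGION_END = 0.45  # fractional time bound for the P1 candidate
P2_REGION_END = 0.70
MIN_CANDIDATE_FRAC = 0.10  # candidates below this fraction of max are noise


@dataclass
class Window:
    """One nominal 10-s analysis window of the cranial-expansion channel."""

    window_id: str
    patient_id: str
    start_s: float
    fs_hz: float
    samples: np.ndarray
    reference_icp_mmHg: float | None = None


@dataclass
class BeatSet:
    onset_indices: np.ndarray  # strictly increasing, refractory-spaced
    beats: list[np.ndarray]  # accepted per-beat sample slices
    n_rejected: int = 0


@dataclass
class MeanPulse:
    """Onset-aligned, length-normalized average beat (length PULSE_LENGTH)."""

    values: np.ndarray
    n_beats_averaged: int
    amplitude: float  # max minus onset value, in sensor units

    def __post_init__(self) -> None:
        if len(self.values) != PULSE_LENGTH:
            raise ValueError(f"mean pulse must have {PULSE_LENGTH} points")
        if self.n_beats_averaged < MIN_BEATS:
            raise InsufficientBeatsError("mean pulse needs >= 3 beats")


@dataclass
class PulseLandmarks:
    t_p1: float
    t_p2: float
    a_p1: float
    a_p2: float
    t_p3: float | None = None
    a_p3: float | None = None
    p3_present: bool = False

    def __post_init__(self) -> None:
        if not self.t_p1 < self.t_p2:
            raise ValueError("t_p1 must precede t_p2")
        if self.a_p1 <= 0:
            raise ValueError("a_p1 must be positive")


@dataclass
class PulseParams:
    p2p1_ratio: float
    ttp: float
    auc: float
    icc_class: int


def segment_windows(rec: RawRecording, window_s: float = 10.0) -> list[Window]:
    """Cut a recording into non-overlapping consecutive windows; the trailing
    partial window is dropped. ``reference_icp`` is the arithmetic mean of the
    ICP channel inside the window when that channel exists."""
    win_len = int(round(window_s * rec.fs_hz))
    n_windows = rec.n_samples // win_len
    if n_windows == 0:
        raise TooShortError(
            f"recording of {rec.duration_s:.1f} s is shorter than one "
            f"{window_s:.0f}-s window"
        )
    signal = rec.channels["cranial_expansion"]
    icp = rec.channels.get("icp_mmHg")
    windows = []
    for w in range(n_windows):
        sl = slice(w * win_len, (w + 1) * win_len)
        windows.append(
            Window(
                window_id=f"{rec.patient_id}_{w:04d}",
                patient_id=rec.patient_id,
                start_s=w * window_s,
                fs_hz=rec.fs_hz,
                samples=signal[sl].copy(),
                reference_icp_mmHg=float(np.mean(icp[sl])) if icp is not None else None,
            )
        )
    return windows


def _detect_onsets(samples: np.ndarray, fs_hz: float, f0_hz: float) -> np.ndarray:
    """Onsets = the local minima preceding each systolic upstroke, found as
    prominent troughs with a refractory period of 0.5/f0 seconds.

    Troughs are detected directly (rather than as minima between systolic
    peaks) so that large intra-beat artifact spikes, which distort the peak
    sequence, leave the beat boundaries intact."""
    distance = max(int(0.5 * fs_hz / f0_hz), 1)
    sigma = 1.4826 * float(np.median(np.abs(samples - np.median(samples))))
    prominence = 0.5 * sigma if sigma > 0 else None
    troughs, _ = sps.find_peaks(-samples, distance=distance, prominence=prominence)
    return troughs.astype(int)


def preprocess_signal(samples: np.ndarray, fs_hz: float) -> np.ndarray:
    """Detrend (zero-phase 2nd-order Butterworth band-pass 0.3–20 Hz) and fix
    polarity.

    The systolic upstroke is the fast limb of the pulse: if the median
    onset-to-maximum time exceeds the median maximum-to-next-onset time over
    the detected beats, the sensor polarity is inverted and the signal is
    negated.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise DegenerateSignalError("empty signal")
    if not np.all(np.isfinite(samples)):
        raise DegenerateSignalError("signal contains non-finite values")
    samples = _suppress_spikes(samples, fs_hz)
    sos = sps.butter(2, BANDPASS_HZ, btype="bandpass", fs=fs_hz, output="sos")
    filtered = sps.sosfiltfilt(sos, samples)

    f0 = _estimate_f0(filtered, fs_hz)
    if f0 is not None and _upstroke_is_slow(filtered, fs_hz, f0):
        filtered = -filtered
    return filtered


def _suppress_spikes(samples: np.ndarray, fs_hz: float, n_mads: float = 6.0) -> np.ndarray:
    """Bridge extreme excursions (movement-artifact spikes) by linear
    interpolation before filtering.

    Done on the raw signal because the band-pass high-pass stage rings for
    around a second after a large spike, which would contaminate the beats
    neighbouring the artifact. Excursions beyond ``n_mads`` robust SDs from
    the median, dilated by 0.1 s, are replaced."""
    med = float(np.median(samples))
    sigma = 1.4826 * float(np.median(np.abs(samples - med)))
    if sigma == 0:
        return samples
    bad = np.abs(samples - med) > n_mads * sigma
    if not bad.any():
        return samples
    pad = max(int(0.1 * fs_hz), 1)
    bad = np.convolve(bad.astype(float), np.ones(2 * pad + 1), mode="same") > 0
    if bad.all():
        return samples
    out = samples.copy()
    idx = np.arange(len(samples))
    out[bad] = np.interp(idx[bad], idx[~bad], samples[~bad])
    return out


def _estimate_f0(samples: np.ndarray, fs_hz: float) -> float | None:
    from .quality import estimate_psd, fundamental_frequency

    try:
        return fundamental_frequency(estimate_psd(samples, fs_hz))
    except Exception:
        return None


def _upstroke_is_slow(samples: np.ndarray, fs_hz: float, f0_hz: float) -> bool:
    onsets = _detect_onsets(samples, fs_hz, f0_hz)
    if len(onsets) < 4:
        return False
    up, down = [], []
    for o, nxt in zip(onsets[:-1], onsets[1:]):
        p = o + int(np.argmax(samples[o:nxt]))
        if p == o or p == nxt:
            continue
        up.append(p - o)
        down.append(nxt - p)
    if not up:
        return False
    return float(np.median(up)) > float(np.median(down))


def extract_beats(samples: np.ndarray, fs_hz: float, f0_hz: float) -> BeatSet:
    """Identify beats and reject artifacts.

    A beat (onset-to-onset slice) is rejected when its duration falls outside
    [0.5/f0, 1.8/f0] s, its peak-to-peak amplitude deviates from the window
    median by more than 3 MAD, or it correlates with the running beat
    template below 0.7.
    """
    samples = np.asarray(samples, dtype=float)
    onsets = _detect_onsets(samples, fs_hz, f0_hz)
    if len(onsets) < MIN_BEATS + 1:
        raise InsufficientBeatsError(
            f"only {max(len(onsets) - 1, 0)} beats detected (need >= {MIN_BEATS})"
        )

    raw_beats = [samples[a:b] for a, b in zip(onsets[:-1], onsets[1:])]
    durations = np.diff(onsets) / fs_hz
    dur_ok = (durations >= 0.5 / f0_hz) & (durations <= 1.8 / f0_hz)

    ptps = np.array([np.ptp(b) for b in raw_beats])
    med = float(np.median(ptps[dur_ok])) if dur_ok.any() else float(np.median(ptps))
    mad = float(np.median(np.abs(ptps - med)))
    tol = AMPLITUDE_MAD_FACTOR * mad + 0.05 * med  # floor avoids zero-MAD overrejection
    amp_ok = np.abs(ptps - med) <= tol

    stage1 = dur_ok & amp_ok
    resampled = np.stack([_resample_beat(b, PULSE_LENGTH) for b in raw_beats])
    if stage1.any():
        template = resampled[stage1].mean(axis=0)
    else:
        template = resampled.mean(axis=0)
    corr_ok = np.array([_safe_corr(r, template) >= BEAT_CORR_THRESHOLD for r in resampled])

    keep = stage1 & corr_ok
    accepted = [raw_beats[i] for i in np.flatnonzero(keep)]
    n_rejected = int(len(raw_beats) - len(accepted))
    if len(accepted) < MIN_BEATS:
        raise InsufficientBeatsError(
            f"only {len(accepted)} beats survived artifact rejection"
        )
    return BeatSet(onset_indices=onsets, beats=accepted, n_rejected=n_rejected)


def _resample_beat(beat: np.ndarray, length: int) -> np.ndarray:
    x_old = np.linspace(0.0, 1.0, len(beat))
    x_new = np.linspace(0.0, 1.0, length)
    out = np.interp(x_new, x_old, beat)
    return out - out[0]


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def average_pulse(beats: BeatSet, length: int = PULSE_LENGTH) -> MeanPulse:
    """Linearly resample each beat to ``length`` points from its onset,
    subtract the onset baseline, and take the point-wise mean."""
    if len(beats.beats) < MIN_BEATS:
        raise InsufficientBeatsError(f"need >= {MIN_BEATS} beats to average")
    resampled = np.stack([_resample_beat(b, length) for b in beats.beats])
    values = resampled.mean(axis=0)
    return MeanPulse(
        values=values,
        n_beats_averaged=len(beats.beats),
        amplitude=float(np.max(values) - values[0]),
    )


def _shoulder_candidates(smooth: np.ndarray) -> np.ndarray:
    """Inflection-shoulder candidates: local minima of the second derivative
    (a merged sub-peak flattens the curve without producing a maximum).

    A curvature-prominence floor rejects numerical ripple, e.g. on an exactly
    linear segment where the second derivative is zero up to rounding."""
    d2 = sps.savgol_filter(smooth, 11, 3, deriv=2)
    floor = 1e-6 * max(float(np.ptp(smooth)), 1e-30)
    cands, _ = sps.find_peaks(-d2, prominence=floor)
    return cands


def detect_landmarks(pulse: MeanPulse) -> PulseLandmarks:
    """Locate the P1/P2 (and optional P3) sub-peaks of the mean pulse.

    The pulse is Savitzky–Golay smoothed (window 11, order 3); candidates are
    its local maxima, augmented with second-derivative shoulder candidates
    when fewer than two maxima exist or a region has no candidate. P1 is the
    earliest candidate at fractional time <= 0.45, P2 the next candidate at
    <= 0.7, P3 (optional) the first after P2. Sub-noise candidates (below 10%
    of the pulse maximum) are discarded; coincident candidates resolve to the
    larger amplitude.
    """
    v = np.asarray(pulse.values, dtype=float)
    n = len(v)
    smooth = sps.savgol_filter(v, 11, 3)
    baseline = smooth[0]
    peaks, _ = sps.find_peaks(smooth)
    candidates = set(int(p) for p in peaks)
    if len(candidates) < 2:
        candidates.update(int(c) for c in _shoulder_candidates(smooth))

    max_amp = float(np.max(smooth) - baseline)
    if max_amp <= 0:
        raise LandmarkFailureError("pulse has no positive excursion")

    def usable(cands: set[int]) -> list[int]:
        out = [c for c in sorted(cands)
               if (smooth[c] - baseline) >= MIN_CANDIDATE_FRAC * max_amp]
        return out

    cand = usable(candidates)
    t = lambda i: i / (n - 1)  # noqa: E731
    amp = lambda i: float(smooth[i] - baseline)  # noqa: E731

    p1_cands = [c for c in cand if t(c) <= P1_REGION_END]
    if not p1_cands:
        candidates.update(int(c) for c in _shoulder_candidates(smooth))
        cand = usable(candidates)
        p1_cands = [c for c in cand if t(c) <= P1_REGION_END]
    if not p1_cands:
        raise LandmarkFailureError("no P1 candidate at fractional time <= 0.45")
    p1 = p1_cands[0]

    p2_cands = [c for c in cand if t(p1) < t(c) <= P2_REGION_END]
    if not p2_cands:
        candidates.update(int(c) for c in _shoulder_candidates(smooth))
        cand = usable(candidates)
        p2_cands = [c for c in cand if t(p1) < t(c) <= P2_REGION_END]
    if not p2_cands:
        raise LandmarkFailureError("no P2 candidate between P1 and fractional time 0.7")
    p2 = p2_cands[0]

    p3_cands = [c for c in cand if t(c) > t(p2)]
    p3 = p3_cands[0] if p3_cands else None
    return PulseLandmarks(
        t_p1=t(p1), t_p2=t(p2), a_p1=amp(p1), a_p2=amp(p2),
        t_p3=t(p3) if p3 is not None else None,
        a_p3=amp(p3) if p3 is not None else None,
        p3_present=p3 is not None,
    )


def pulse_parameters(pulse: MeanPulse, lm: PulseLandmarks) -> PulseParams:
    """P2/P1 ratio, normalized time-to-peak, normalized AUC, and the ordinal
    compliance class (1: P2/P1 < 1.0; 2: 1.0–1.2; 3: > 1.2 — a documented
    stand-in for the clinical intracranial-compliance scale)."""
    if lm.a_p1 <= 0:
        raise ZeroDivisionError("a_p1 must be positive")
    v = np.asarray(pulse.values, dtype=float)
    ttp = float(np.argmax(v)) / (len(v) - 1)
    peak = float(np.max(v))
    auc = float(np.trapezoid(v / peak, dx=1.0 / (len(v) - 1))) if peak > 0 else 0.0
    p2p1 = lm.a_p2 / lm.a_p1
    if p2p1 < 1.0:
        icc_class = 1
    elif p2p1 <= 1.2:
        icc_class = 2
    else:
        icc_class = 3
    return PulseParams(p2p1_ratio=float(p2p1), ttp=ttp, auc=auc, icc_class=icc_class)
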