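"""Window-level orchestration: recording -> per-window feature table.

Each 10-s window passes through the quality gate (spectral SNR, then mean
pulse morphology), the pulse curation chain, landmark extraction and the
feature bank. Every window ends in exactly one of four states — accepted,
rejected by quality, insufficient beats, or landmark failure — and the
accounting is returned alongside the feature table so no window is silently
dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegenerateSignalError,
    InsufficientBeatsError,
    LandmarkFailureError,
    NoFundamentalError,
)
from .features import build_feature_vector, pulse_column_names
from .pulses import (
    MeanPulse,
    Window,
    average_pulse,
    detect_landmarks,
    extract_beats,
    preprocess_signal,
    pulse_parameters,
    segment_windows,
)
from .quality import (
    MORPHOLOGY_THRESHOLD,
    SNR_THRESHOLD,
    QualityReport,
    compute_snr,
    estimate_psd,
    fundamental_frequency,
    morphology_score,
)
from .simulate import RawRecording

STATUS_ACCEPTED = "accepted"
STATUS_QUALITY = "rejected_quality"
STATUS_BEATS = "insufficient_beats"
STATUS_LANDMARK = "landmark_failure"


@dataclass
class WindowResult:
    window: Window
    status: str
    qc: QualityReport | None = None
    mean_pulse: MeanPulse | None = None
    features: dict[str, float] | None = None


@dataclass
class Accounting:
    """Conservation ledger: windows in == sum of the four outcomes."""

    n_windows: int = 0
    counts: dict[str, int] = field(
        default_factory=lambda: {
            STATUS_ACCEPTED: 0, STATUS_QUALITY: 0, STATUS_BEATS: 0, STATUS_LANDMARK: 0
        }
    )

    def add(self, status: str) -> None:
        self.n_windows += 1
        self.counts[status] += 1

    def conserved(self) -> bool:
        return self.n_windows == sum(self.counts.values())


def process_window(
    window: Window,
    snr_threshold: float = SNR_THRESHOLD,
    morphology_threshold: float = MORPHOLOGY_THRESHOLD,
) -> WindowResult:
    """Run one window through quality gating, pulse curation and the feature
    bank. Exclusions are captured in the result status, never raised."""
    reject = lambda status, qc=None: WindowResult(window, status, qc=qc)  # noqa: E731
    x = np.asarray(window.samples, dtype=float)
    degenerate_qc = QualityReport(
        snr=0.0, f0_hz=np.nan, snr_pass=False,
        morphology_score=0.0, morphology_pass=False, degenerate=True,
    )
    if x.size == 0 or not np.all(np.isfinite(x)) or np.ptp(x) == 0:
        return reject(STATUS_QUALITY, degenerate_qc)
    try:
        spec = estimate_psd(x, window.fs_hz)
        f0 = fundamental_frequency(spec)
        snr = compute_snr(spec, f0)
    except (DegenerateSignalError, NoFundamentalError, ValueError):
        return reject(STATUS_QUALITY, degenerate_qc)
    if snr <= snr_threshold:
        qc = QualityReport(snr=snr, f0_hz=f0, snr_pass=False,
                           morphology_score=0.0, morphology_pass=False)
        return reject(STATUS_QUALITY, qc)

    try:
        clean = preprocess_signal(x, window.fs_hz)
        beats = extract_beats(clean, window.fs_hz, f0)
        pulse = average_pulse(beats)
    except InsufficientBeatsError:
        qc = QualityReport(snr=snr, f0_hz=f0, snr_pass=True,
                           morphology_score=0.0, morphology_pass=False)
        return reject(STATUS_BEATS, qc)

    score = morphology_score(pulse.values)
    morph_pass = score >= morphology_threshold and pulse.values[0] < np.max(pulse.values)
    qc = QualityReport(snr=snr, f0_hz=f0, snr_pass=True,
                       morphology_score=score, morphology_pass=morph_pass)
    if not morph_pass:
        return reject(STATUS_QUALITY, qc)

    try:
        lm = detect_landmarks(pulse)
    except LandmarkFailureError:
        return WindowResult(window, STATUS_LANDMARK, qc=qc, mean_pulse=pulse)
    params = pulse_parameters(pulse, lm)
    feats = build_feature_vector(pulse, params, qc, beats, spectrum=spec, fs_hz=window.fs_hz)
    feats["n_beats"] = float(pulse.n_beats_averaged)
    return WindowResult(window, STATUS_ACCEPTED, qc=qc, mean_pulse=pulse, features=feats)


def process_recording(
    rec: RawRecording,
    window_s: float = 10.0,
    snr_threshold: float = SNR_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame, Accounting]:
    """Process every window of one recording.

    Returns ``(features, qc_table, accounting)`` where ``features`` has one
    row per *accepted* window (named features, the 100-point mean pulse, the
    window-mean reference ICP when present) and ``qc_table`` has one row per
    window with its quality report and final status.
    """
    acct = Accounting()
    feat_rows, qc_rows = [], []
    for window in segment_windows(rec, window_s):
        res = process_window(window, snr_threshold=snr_threshold)
        acct.add(res.status)
        qc = res.qc
        qc_rows.append(
            {
                "window_id": window.window_id,
                "patient_id": window.patient_id,
                "snr": qc.snr if qc else np.nan,
                "f0_hz": qc.f0_hz if qc else np.nan,
                "morphology_score": qc.morphology_score if qc else np.nan,
                "accepted": res.status == STATUS_ACCEPTED,
                "status": res.status,
            }
        )
        if res.status != STATUS_ACCEPTED:
            continue
        row: dict[str, object] = {
            "window_id": window.window_id,
            "patient_id": window.patient_id,
        }
        row.update(res.features)
        for name, val in zip(pulse_column_names(), res.mean_pulse.values):
            row[name] = float(val)
        row["reference_icp_mmHg"] = (
            window.reference_icp_mmHg if window.reference_icp_mmHg is not None else np.nan
        )
        feat_rows.append(row)
    features = pd.DataFrame(feat_rows)
    qc_table = pd.DataFrame(qc_rows)
    assert acct.conserved(), "window accounting violated"
    return features, qc_table, acct


def process_cohort(
    recordings: list[RawRecording], window_s: float = 10.0, snr_threshold: float = SNR_THRESHOLD
) -> tuple[pd.DataFrame, pd.DataFrame, Accounting]:
    """Concatenate per-recording results over a cohort."""
    total = Accounting()
    feats, qcs = [], []
    for rec in recordings:
        f, q, a = process_recording(rec, window_s, snr_threshold)
        feats.append(f)
        qcs.append(q)
        total.n_windows += a.n_windows
        for k, v in a.counts.items():
            total.counts[k] += v
    features = pd.concat([f for f in feats if len(f)], ignore_index=True) if feats else pd.DataFrame()
    qc_table = pd.concat(qcs, ignore_index=True) if qcs else pd.DataFrame()
    return features, qc_table, total


def split_feature_table(
    features: pd.DataFrame,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Split a cohort feature table into (X, y, groups) for the estimator."""
    meta = ["window_id", "patient_id", "reference_icp_mmHg"]
    X = features.drop(columns=[c for c in meta if c in features.columns])
    y = features["reference_icp_mmHg"].to_numpy(dtype=float)
    groups = features["patient_id"].to_numpy(dtype=object)
    return X, y, groups
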