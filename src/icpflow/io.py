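"""Delimited-text recording I/O, manifests and resampling."""

from __future__ import annotations

import json
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import FormatError
from .simulate import DEFAULT_FS_HZ, RawRecording

TIME_COLUMN = "time_s"
IRREGULARITY_TOLERANCE = 0.01  # relative deviation of a time step
MAX_IRREGULAR_FRACTION = 0.01


def write_recording(rec: RawRecording, path: str | Path) -> Path:
    """One UTF-8 CSV per recording: a ``time_s`` column plus one column per
    channel, '.' decimal separator, fixed 6-decimal formatting so identical
    recordings serialize byte-for-byte identically."""
    path = Path(path)
    df = pd.DataFrame({TIME_COLUMN: rec.time_s()})
    for name, values in rec.channels.items():
        df[name] = values
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def read_timeseries(
    path: str | Path,
    patient_id: str | None = None,
    expected_fs_hz: float | None = None,
) -> RawRecording:
    """Read and validate a delimited-text recording.

    Checks: the time column exists, time is strictly increasing, at most 1%
    of the time steps deviate from the median step by more than 1%, and the
    inferred rate matches the manifest rate when given. Violations raise
    :class:`FormatError` naming the first offending line (1-based, counting
    the header)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file not found")
    df = pd.read_csv(path)
    if TIME_COLUMN not in df.columns:
        raise FormatError(f"{path}: missing required column '{TIME_COLUMN}'")
    channels = [c for c in df.columns if c != TIME_COLUMN]
    if not channels:
        raise FormatError(f"{path}: no channel columns beyond '{TIME_COLUMN}'")
    t = df[TIME_COLUMN].to_numpy(dtype=float)
    dt = np.diff(t)
    nonpos = np.flatnonzero(dt <= 0)
    if nonpos.size:
        raise FormatError(
            f"{path}: non-monotone time at line {int(nonpos[0]) + 3}"
        )
    med = float(np.median(dt))
    irregular = np.abs(dt - med) > IRREGULARITY_TOLERANCE * med
    if irregular.mean() > MAX_IRREGULAR_FRACTION:
        first = int(np.flatnonzero(irregular)[0]) + 3
        raise FormatError(
            f"{path}: >{MAX_IRREGULAR_FRACTION:.0%} irregular sampling "
            f"(first at line {first})"
        )
    fs = 1.0 / med
    if expected_fs_hz is not None and abs(fs - expected_fs_hz) / expected_fs_hz > 0.01:
        raise FormatError(
            f"{path}: inferred rate {fs:.1f} Hz does not match manifest "
            f"rate {expected_fs_hz:.1f} Hz"
        )
    return RawRecording(
        patient_id=patient_id or path.stem,
        fs_hz=fs,
        channels={c: df[c].to_numpy(dtype=float) for c in channels},
    )


def resample_recording(rec: RawRecording, target_fs_hz: float = DEFAULT_FS_HZ) -> RawRecording:
    """Polyphase-filter resampling of every channel to a common rate."""
    if abs(rec.fs_hz - target_fs_hz) < 1e-9:
        return rec
    frac = Fraction(target_fs_hz / rec.fs_hz).limit_denominator(1000)
    channels = {
        name: sps.resample_poly(values, frac.numerator, frac.denominator)
        for name, values in rec.channels.items()
    }
    return RawRecording(rec.patient_id, target_fs_hz, channels, truth=rec.truth)


def read_manifest(manifest_path: str | Path) -> dict:
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FormatError(f"{manifest_path}: manifest not found")
    return json.loads(manifest_path.read_text())


def load_cohort(manifest_path: str | Path, resample_to: float | None = DEFAULT_FS_HZ) -> list[RawRecording]:
    """Load every patient recording listed in a manifest, validating the
    sampling rate and resampling to the configured common rate."""
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    root = manifest_path.parent
    recordings = []
    for pid, entry in sorted(manifest["patients"].items()):
        rec = read_timeseries(root / entry["file"], patient_id=pid,
                              expected_fs_hz=entry.get("fs_hz"))
        truth_file = entry.get("truth_file")
        if truth_file and (root / truth_file).exists():
            rec.truth = pd.read_csv(root / truth_file)
        if resample_to is not None:
            rec = resample_recording(rec, resample_to)
        recordings.append(rec)
    return recordings
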