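"""Transcranial-Doppler closed-form baseline.

Noninvasive cerebral perfusion pressure from the diastolic-to-mean
middle-cerebral-artery velocity ratio,

    nCPP = ABP * FVd / FVm + 14 mmHg,

where the 14 mmHg term is a pre-established calibration (zeroing) constant,
and the derived noninvasive ICP estimate

    eICP_TCD = ABP - nCPP,

which may be negative and is deliberately never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CALIBRATION_MMHG = 14.0


@dataclass(frozen=True)
class TcdWindowInputs:
    """Window-mean arterial pressure (mmHg) and MCA velocities (cm/s)."""

    abp_mmHg: float
    fvd_cm_s: float
    fvm_cm_s: float
    calibration_mmHg: float = CALIBRATION_MMHG

    def __post_init__(self) -> None:
        if self.fvm_cm_s <= 0:
            raise ZeroDivisionError("fvm_cm_s must be > 0")
        if self.fvd_cm_s < 0:
            raise ValueError("fvd_cm_s must be >= 0")
        if self.abp_mmHg <= 0:
            raise ValueError("abp_mmHg must be > 0")


def estimate_ncpp(inp: TcdWindowInputs) -> float:
    """nCPP = ABP * FVd/FVm + calibration, no clamping."""
    return inp.abp_mmHg * inp.fvd_cm_s / inp.fvm_cm_s + inp.calibration_mmHg


def estimate_eicp_tcd(inp: TcdWindowInputs) -> float:
    """eICP_TCD = ABP - nCPP (identity: eICP_TCD + nCPP = ABP exactly)."""
    return inp.abp_mmHg - estimate_ncpp(inp)


def baseline_table(
    abp: np.ndarray, fvd: np.ndarray, fvm: np.ndarray, ids=None
) -> pd.DataFrame:
    """Vectorized per-window baseline predictions."""
    abp = np.asarray(abp, dtype=float)
    fvd = np.asarray(fvd, dtype=float)
    fvm = np.asarray(fvm, dtype=float)
    if np.any(fvm <= 0):
        raise ZeroDivisionError("fvm must be > 0 for every window")
    ncpp = abp * fvd / fvm + CALIBRATION_MMHG
    return pd.DataFrame(
        {
            "id": ids if ids is not None else np.arange(len(abp)),
            "abp_mmHg": abp,
            "fvd_cm_s": fvd,
            "fvm_cm_s": fvm,
            "ncpp_mmHg": ncpp,
            "eicp_tcd_mmHg": abp - ncpp,
        }
    )
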