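"""Synthetic cohort simulator for pulsatile cranial-expansion recordings.

The cranial-expansion pulse is modelled as a triphasic beat — three Gaussian
bumps standing in for the percussion (P1), tidal (P2) and dicrotic (P3)
sub-peaks of the intracranial-pressure pulse. Beats are concatenated with a
stochastic per-beat period (heart-rate jitter), amplitude-modulated at the
respiratory frequency, and corrupted with baseline wander, additive noise and
sparse movement-artifact spikes.

Ground-truth ICP follows a known linear law in the realized pulse morphology,

    ICP = beta0 + beta1 * (P2/P1) + beta2 * TTP + u_patient + eps,

with a patient random intercept ``u_patient`` and window noise ``eps``. The
law is a simulator construct: its direction (higher P2/P1 => higher ICP)
mirrors the clinical association between an elevated P2/P1 ratio and reduced
intracranial compliance, and its parameters are calibrated so that the
cohort's marginal ICP distribution resembles a neurocritical-care population
(~5% of 10-s windows at or above 20 mmHg; sub-20 mean near 9.8 mmHg).

Coupled channels (window-mean ICP, ABP and transcranial-Doppler FVd/FVm) are
piecewise-constant per 10-s window; only their window means are consumed
downstream.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidMorphologyError, TooShortError

DEFAULT_FS_HZ = 250.0
WINDOW_S = 10.0


@dataclass(frozen=True)
class PulseMorphParams:
    """Triphasic pulse shape: three Gaussian bumps on the unit period.

    ``tau*`` are fractional peak times in (0, 1), strictly increasing;
    ``a*`` are peak amplitudes (arbitrary sensor units, a1 > 0);
    ``width*`` are bump standard deviations as fractions of the period.
    """

    tau1: float = 0.16
    tau2: float = 0.40
    tau3: float = 0.64
    a1: float = 1.0
    a2: float = 0.90
    a3: float = 0.55
    width1: float = 0.065
    width2: float = 0.085
    width3: float = 0.080

    def __post_init__(self) -> None:
        if not (0.0 < self.tau1 < self.tau2 < self.tau3 < 1.0):
            raise InvalidMorphologyError(
                f"peak times must satisfy 0 < tau1 < tau2 < tau3 < 1, "
                f"got ({self.tau1}, {self.tau2}, {self.tau3})"
            )
        if self.a1 <= 0 or self.a2 < 0 or self.a3 < 0:
            raise InvalidMorphologyError("a1 must be > 0 and a2, a3 >= 0")
        for w in (self.width1, self.width2, self.width3):
            if not (0.0 < w < 0.5):
                raise InvalidMorphologyError(f"widths must lie in (0, 0.5), got {w}")

    def with_p2p1(self, p2p1: float) -> "PulseMorphParams":
        """Return a copy whose nominal P2/P1 amplitude ratio is ``p2p1``."""
        return dataclasses.replace(self, a2=float(p2p1) * self.a1)


@dataclass(frozen=True)
class IcpLawParams:
    """Parameters of the synthetic morphology -> ICP ground-truth law (mmHg)."""

    beta0: float = -2.5
    beta1: float = 12.0
    beta2: float = 4.0
    eps_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.eps_sd < 0:
            raise ValueError("eps_sd must be >= 0")
        if self.beta1 <= 0:
            raise ValueError("beta1 must be > 0 (elevated P2/P1 raises ICP)")


@dataclass
class PatientSimConfig:
    """Per-patient simulation settings.

    Rates and SDs are in natural units: heart rate in bpm, respiratory
    frequency in Hz, durations in seconds, artifact rate per minute. The
    morphology drifts between consecutive 10-s windows as an AR(1) process on
    the P2/P1 ratio so that ICP varies within a recording.
    """

    patient_id: str = "sim"
    hr_mean_bpm: float = 75.0
    hr_sd_bpm: float = 2.0
    resp_freq_hz: float = 0.25
    resp_mod_frac: float = 0.10
    drift_sd: float = 0.05
    noise_sd: float = 0.03
    artifact_rate_per_min: float = 0.5
    duration_s: float = 600.0
    morph_drift_ar1_coef: float = 0.85
    morph_drift_sd: float = 0.06
    patient_offset_mmHg: float = 0.0

    def __post_init__(self) -> None:
        if self.duration_s < 10.0:
            raise TooShortError("duration_s must be >= 10 s")
        if not (40.0 <= self.hr_mean_bpm <= 180.0):
            raise ValueError("hr_mean_bpm must lie in [40, 180]")
        for name in ("hr_sd_bpm", "drift_sd", "noise_sd", "morph_drift_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class RawRecording:
    """Multichannel uniformly-sampled recording for one patient."""

    patient_id: str
    fs_hz: float
    channels: dict[str, np.ndarray]
    truth: pd.DataFrame | None = None  # per-window generator ground truth

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be > 0")
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError(f"channels have unequal lengths: {lengths}")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs_hz


def simulate_pulse_template(morph: PulseMorphParams, n_points: int) -> np.ndarray:
    """Evaluate the triphasic beat template on a uniform grid over [0, 1).

    Deterministic in its inputs: the sum of three Gaussian bumps at the
    configured fractional times. Raises ``InvalidMorphologyError`` via the
    dataclass validator for a non-increasing tau sequence.
    """
    if n_points <= 0:
        raise ValueError("n_points must be positive")
    t = np.arange(n_points) / n_points
    out = np.zeros(n_points)
    for a, tau, w in (
        (morph.a1, morph.tau1, morph.width1),
        (morph.a2, morph.tau2, morph.width2),
        (morph.a3, morph.tau3, morph.width3),
    ):
        out += a * np.exp(-0.5 * ((t - tau) / w) ** 2)
    return out


def template_landmarks(morph: PulseMorphParams, n_fine: int = 4000) -> tuple[float, float]:
    """Realized (p2p1, ttp) of a template, by fine-grid local-maxima search.

    The realized P2/P1 ratio differs slightly from the nominal a2/a1 when the
    bumps overlap; this brute-force evaluation is the generator's ground truth
    for downstream parameter-recovery checks. TTP is the fractional time of
    the global maximum.
    """
    y = simulate_pulse_template(morph, n_fine)
    interior = (y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:])
    peaks = np.flatnonzero(interior) + 1
    ttp = float(np.argmax(y)) / n_fine
    if len(peaks) >= 2:
        p2p1 = float(y[peaks[1]] / y[peaks[0]])
    else:
        p2p1 = float(morph.a2 / morph.a1)  # merged bumps: nominal ratio
    return p2p1, ttp


def ground_truth_icp(
    p2p1: float,
    ttp: float,
    law: IcpLawParams,
    u_patient: float = 0.0,
    rng: np.random.Generator | None = None,
) -> float:
    """Window-mean ICP (mmHg) from realized morphology via the linear law."""
    if p2p1 <= 0:
        raise ValueError(f"p2p1 must be > 0, got {p2p1}")
    if not (0.0 <= ttp <= 1.0):
        raise ValueError(f"ttp must lie in [0, 1], got {ttp}")
    eps = 0.0
    if law.eps_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        eps = float(rng.normal(0.0, law.eps_sd))
    return law.beta0 + law.beta1 * p2p1 + law.beta2 * ttp + u_patient + eps


def _artifact_bump(n: int) -> np.ndarray:
    """Raised-cosine spike shape of n samples."""
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / max(n - 1, 1)))


def simulate_recording(
    cfg: PatientSimConfig,
    morph_init: PulseMorphParams | None = None,
    law: IcpLawParams | None = None,
    seed: int | np.random.SeedSequence | None = None,
    fs_hz: float = DEFAULT_FS_HZ,
) -> RawRecording:
    """Simulate one patient's multichannel recording.

    The cranial-expansion channel is a concatenation of beat templates whose
    P2/P1 ratio follows an AR(1) drift across 10-s windows; the ICP, ABP and
    Doppler-velocity channels are piecewise-constant per window. The realized
    per-window morphology and coupled-channel values are attached as
    ``RawRecording.truth``.
    """
    morph = morph_init if morph_init is not None else PulseMorphParams()
    law = law if law is not None else IcpLawParams()
    rng = np.random.default_rng(seed)

    n_samples = int(round(cfg.duration_s * fs_hz))
    win_len = int(round(WINDOW_S * fs_hz))
    n_windows = max(n_samples // win_len, 1)

    # AR(1) drift of the P2/P1 ratio across windows (stationary, zero mean)
    phi, sd = cfg.morph_drift_ar1_coef, cfg.morph_drift_sd
    drift = np.zeros(n_windows)
    if sd > 0 and n_windows > 1:
        innov = rng.normal(0.0, sd * np.sqrt(max(1.0 - phi**2, 0.0)), n_windows)
        drift[0] = rng.normal(0.0, sd)
        for w in range(1, n_windows):
            drift[w] = phi * drift[w - 1] + innov[w]

    base_p2p1 = morph.a2 / morph.a1
    window_morphs: list[PulseMorphParams] = []
    truth_rows = []
    for w in range(n_windows):
        p2p1_nom = float(np.clip(base_p2p1 + drift[w], 0.30, 2.20))
        m = morph.with_p2p1(p2p1_nom)
        window_morphs.append(m)
        p2p1_true, ttp_true = template_landmarks(m)
        icp = ground_truth_icp(p2p1_true, ttp_true, law, cfg.patient_offset_mmHg, rng)
        icp = max(icp, 0.0)
        abp = float(np.clip(rng.normal(90.0, 10.0), 50.0, None))
        fvm = float(np.clip(rng.normal(60.0, 8.0), 20.0, None))
        ratio = float(np.clip(0.55 - 0.01 * (icp - 10.0), 0.20, 0.90))
        truth_rows.append(
            {
                "window": w,
                "p2p1_true": p2p1_true,
                "ttp_true": ttp_true,
                "icp_mmHg": icp,
                "abp_mmHg": abp,
                "fvm_cm_s": fvm,
                "fvd_cm_s": fvm * ratio,
            }
        )
    truth = pd.DataFrame(truth_rows)

    # Beat-by-beat synthesis; each beat uses the morphology of the window
    # containing its onset.
    signal = np.zeros(n_samples)
    pos = 0
    while pos < n_samples:
        hr = max(rng.normal(cfg.hr_mean_bpm, cfg.hr_sd_bpm), 30.0)
        period_s = 60.0 / hr
        n_beat = max(int(round(period_s * fs_hz)), 4)
        w = min(pos // win_len, n_windows - 1)
        beat = simulate_pulse_template(window_morphs[w], n_beat)
        end = min(pos + n_beat, n_samples)
        signal[pos:end] = beat[: end - pos]
        pos += n_beat

    t = np.arange(n_samples) / fs_hz
    if cfg.resp_mod_frac > 0:
        signal = signal * (1.0 + cfg.resp_mod_frac * np.sin(2.0 * np.pi * cfg.resp_freq_hz * t))
    if cfg.drift_sd > 0:
        signal = signal + np.cumsum(rng.normal(0.0, cfg.drift_sd / np.sqrt(fs_hz), n_samples))
    if cfg.noise_sd > 0:
        signal = signal + rng.normal(0.0, cfg.noise_sd, n_samples)

    beat_amp = float(np.max(simulate_pulse_template(morph, 256)))
    n_artifacts = rng.poisson(cfg.artifact_rate_per_min * cfg.duration_s / 60.0)
    for _ in range(n_artifacts):
        start = int(rng.uniform(0, n_samples))
        dur = int(rng.uniform(0.1, 0.5) * fs_hz)
        amp = rng.uniform(3.0, 10.0) * beat_amp * rng.choice([-1.0, 1.0])
        end = min(start + dur, n_samples)
        signal[start:end] += amp * _artifact_bump(end - start)

    expand = lambda col: np.repeat(truth[col].to_numpy(), win_len)[:n_samples]  # noqa: E731

    def piecewise(col: str) -> np.ndarray:
        vals = expand(col)
        if len(vals) < n_samples:  # trailing partial window: hold last value
            vals = np.concatenate([vals, np.full(n_samples - len(vals), vals[-1])])
        return vals

    channels = {
        "cranial_expansion": signal,
        "icp_mmHg": piecewise("icp_mmHg"),
        "abp_mmHg": piecewise("abp_mmHg"),
        "fvd_cm_s": piecewise("fvd_cm_s"),
        "fvm_cm_s": piecewise("fvm_cm_s"),
    }
    return RawRecording(cfg.patient_id, fs_hz, channels, truth=truth)


@dataclass
class CohortConfig:
    """Cohort-level distributions from which per-patient settings are drawn.

    Defaults are calibrated so that, over a default cohort, roughly 5% of 10-s
    windows carry ICP >= 20 mmHg and the sub-20 mean ICP is near 9.8 mmHg.
    """

    duration_s: float = 600.0
    law: IcpLawParams = field(default_factory=IcpLawParams)
    p2p1_mean: float = 1.0
    p2p1_sd: float = 0.50
    p2p1_range: tuple[float, float] = (0.35, 2.10)
    u_patient_sd: float = 1.5
    hr_range_bpm: tuple[float, float] = (55.0, 95.0)
    tau_jitter: float = 0.02
    fs_hz: float = DEFAULT_FS_HZ
    noise_sd: float = 0.03
    artifact_rate_per_min: float = 0.5


def draw_patient(
    cohort: CohortConfig, patient_id: str, rng: np.random.Generator
) -> tuple[PatientSimConfig, PulseMorphParams]:
    """Draw one patient's simulation config and baseline morphology."""
    p2p1 = float(np.clip(rng.normal(cohort.p2p1_mean, cohort.p2p1_sd), *cohort.p2p1_range))
    j = cohort.tau_jitter
    morph = PulseMorphParams(
        tau1=0.16 + rng.uniform(-j, j),
        tau2=0.40 + rng.uniform(-j, j),
        tau3=0.64 + rng.uniform(-j, j),
    ).with_p2p1(p2p1)
    cfg = PatientSimConfig(
        patient_id=patient_id,
        hr_mean_bpm=float(rng.uniform(*cohort.hr_range_bpm)),
        duration_s=cohort.duration_s,
        noise_sd=cohort.noise_sd,
        artifact_rate_per_min=cohort.artifact_rate_per_min,
        patient_offset_mmHg=float(rng.normal(0.0, cohort.u_patient_sd)),
    )
    return cfg, morph


def simulate_cohort_recordings(
    n_patients: int, cohort: CohortConfig | None = None, seed: int | None = None
) -> list[RawRecording]:
    """Simulate a cohort in memory; per-patient streams are spawned from the
    master seed so the cohort is reproducible and patients are independent."""
    if n_patients < 2:
        raise ValueError("n_patients must be >= 2")
    cohort = cohort if cohort is not None else CohortConfig()
    master = np.random.SeedSequence(seed)
    draw_ss, *patient_ss = master.spawn(n_patients + 1)
    draw_rng = np.random.default_rng(draw_ss)
    recordings = []
    for i in range(n_patients):
        cfg, morph = draw_patient(cohort, f"P{i + 1:03d}", draw_rng)
        recordings.append(
            simulate_recording(cfg, morph, cohort.law, seed=patient_ss[i], fs_hz=cohort.fs_hz)
        )
    return recordings


def simulate_cohort(
    n_patients: int,
    out_dir: str | Path,
    cohort: CohortConfig | None = None,
    seed: int | None = None,
) -> Path:
    """Simulate a cohort and write one delimited-text file per patient plus a
    JSON manifest; returns the manifest path."""
    from .io import write_recording  # local import to avoid a cycle

    cohort = cohort if cohort is not None else CohortConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    recordings = simulate_cohort_recordings(n_patients, cohort, seed)
    patients = {}
    for rec in recordings:
        fname = f"{rec.patient_id}.csv"
        write_recording(rec, out_dir / fname)
        truth_name = f"{rec.patient_id}_truth.csv"
        rec.truth.to_csv(out_dir / truth_name, index=False, float_format="%.6f")
        patients[rec.patient_id] = {
            "file": fname,
            "truth_file": truth_name,
            "fs_hz": rec.fs_hz,
        }
    manifest = {
        "seed": seed,
        "fs_hz": cohort.fs_hz,
        "law": dataclasses.asdict(cohort.law),
        "patients": patients,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path
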