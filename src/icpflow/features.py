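"""Per-window feature bank, Isomap pulse embedding, and feature selection.

The feature bank reconstructs every named category used for ICP estimation
from pulse morphology: landmark features (P2/P1, P3/P1, TTP, AUC, widths and
slopes), spectral features (relative harmonic powers, spectral centroid,
SNR), beat statistics (moments of the mean pulse, beat-to-beat variability,
heart rate) and a 25-component Isomap embedding of the raw mean-pulse shape.
Candidate features are then ranked by the absolute Spearman correlation with
the invasive-ICP target and greedily filtered for redundancy down to 15.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.manifold import Isomap

from .errors import NotAcceptedError
from .pulses import BeatSet, MeanPulse, PulseParams
from .quality import SNR_RANGE_HZ, HARMONIC_HALFWIDTH_HZ, QualityReport, SpectrumEstimate, _band_integral

N_EMBEDDING_COMPONENTS = 25
N_SELECTED_FEATURES = 15
REDUNDANCY_THRESHOLD = 0.9
MIN_TARGET_RHO = 0.05
PULSE_COLUMN_PREFIX = "pulse_"


def pulse_column_names(length: int = 100) -> list[str]:
    return [f"{PULSE_COLUMN_PREFIX}{i:02d}" for i in range(length)]


def build_feature_vector(
    pulse: MeanPulse,
    params: PulseParams,
    qc: QualityReport,
    beats: BeatSet,
    spectrum: SpectrumEstimate | None = None,
    fs_hz: float = 250.0,
) -> dict[str, float]:
    """Deterministic named-feature mapping for one accepted window.

    Raises :class:`NotAcceptedError` for windows the quality gate rejected.
    Scale-invariant features (ratios, normalized times, relative powers) are
    unchanged under amplitude scaling of the signal; ``amplitude`` and the
    raw moments scale with it.
    """
    if not qc.accepted:
        raise NotAcceptedError("feature extraction requires an accepted window")
    v = np.asarray(pulse.values, dtype=float)
    n = len(v)
    grad = np.gradient(v, 1.0 / (n - 1))
    imax = int(np.argmax(v))
    peak = float(v[imax])

    a_p3 = 0.0
    from .pulses import detect_landmarks

    lm = detect_landmarks(pulse)
    if lm.p3_present and lm.a_p3 is not None:
        a_p3 = lm.a_p3

    feats: dict[str, float] = {
        "p2p1": params.p2p1_ratio,
        "p3p1": a_p3 / lm.a_p1,
        "p3p2": a_p3 / lm.a_p2 if lm.a_p2 > 0 else 0.0,
        "t_p1": lm.t_p1,
        "t_p2": lm.t_p2,
        "ttp": params.ttp,
        "auc": params.auc,
        "amplitude": pulse.amplitude,
        "width50": float(np.sum(v >= 0.5 * peak)) / (n - 1) if peak > 0 else 0.0,
        "max_upstroke_slope": float(np.max(grad)),
        "mean_decay_slope": float(np.mean(grad[imax:])) if imax < n - 1 else 0.0,
        "icc_class": float(params.icc_class),
    }

    # Spectral set: relative harmonic powers over the 0.1-25 Hz range
    denom = _band_integral(spectrum, *SNR_RANGE_HZ) if spectrum is not None else 0.0
    for k in range(1, 6):
        if spectrum is not None and denom > 0 and np.isfinite(qc.f0_hz):
            num = _band_integral(
                spectrum,
                max(k * qc.f0_hz - HARMONIC_HALFWIDTH_HZ, SNR_RANGE_HZ[0]),
                k * qc.f0_hz + HARMONIC_HALFWIDTH_HZ,
            )
            feats[f"h{k}"] = num / denom
        else:
            feats[f"h{k}"] = 0.0
    if spectrum is not None and denom > 0:
        mask = (spectrum.freqs_hz >= SNR_RANGE_HZ[0]) & (spectrum.freqs_hz <= SNR_RANGE_HZ[1])
        psd, f = spectrum.psd[mask], spectrum.freqs_hz[mask]
        feats["spectral_centroid"] = float(np.sum(f * psd) / np.sum(psd))
    else:
        feats["spectral_centroid"] = 0.0
    feats["snr"] = qc.snr

    # Statistical set
    periods = np.diff(beats.onset_indices) / fs_hz
    amps = np.array([float(np.ptp(b)) for b in beats.beats])
    feats.update(
        {
            "pulse_mean": float(np.mean(v)),
            "pulse_sd": float(np.std(v, ddof=1)),
            "pulse_skew": float(stats.skew(v)),
            "pulse_kurtosis": float(stats.kurtosis(v)),
            "bb_period_sd": float(np.std(periods, ddof=1)) if len(periods) > 1 else 0.0,
            "bb_amplitude_sd": float(np.std(amps, ddof=1)) if len(amps) > 1 else 0.0,
            "heart_rate_bpm": 60.0 / float(np.mean(periods)) if len(periods) else 0.0,
        }
    )
    bad = [k for k, val in feats.items() if not np.isfinite(val)]
    if bad:
        raise ValueError(f"non-finite features: {bad}")
    return feats


NAMED_FEATURES = [
    "p2p1", "p3p1", "p3p2", "t_p1", "t_p2", "ttp", "auc", "amplitude",
    "width50", "max_upstroke_slope", "mean_decay_slope", "icc_class",
    "h1", "h2", "h3", "h4", "h5", "spectral_centroid", "snr",
    "pulse_mean", "pulse_sd", "pulse_skew", "pulse_kurtosis",
    "bb_period_sd", "bb_amplitude_sd", "heart_rate_bpm",
]


class PulseIsomap(BaseEstimator, TransformerMixin):
    """Isomap embedding of amplitude-normalized mean pulses.

    Geodesic distances over a k-nearest-neighbour graph, reduced to
    ``n_components`` coordinates; out-of-sample pulses are mapped through the
    fitted kernel so held-out windows never influence the manifold.
    """

    def __init__(
        self,
        n_components: int = N_EMBEDDING_COMPONENTS,
        n_neighbors: int = 10,
        auto_connect: bool = False,
    ):
        self.n_components = n_components
        self.n_neighbors = n_neighbors
        self.auto_connect = auto_connect

    @staticmethod
    def _normalize(pulses: np.ndarray) -> np.ndarray:
        pulses = np.asarray(pulses, dtype=float)
        scale = np.max(np.abs(pulses), axis=1, keepdims=True)
        scale[scale == 0] = 1.0
        return pulses / scale

    def fit(self, X: np.ndarray, y=None) -> "PulseIsomap":
        X = self._normalize(X)
        if len(X) < max(50, self.n_components + 1):
            raise ValueError(
                f"need >= {max(50, self.n_components + 1)} training pulses, got {len(X)}"
            )
        import warnings

        n_neighbors = self.n_neighbors
        while True:
            self.isomap_ = Isomap(n_neighbors=n_neighbors, n_components=self.n_components)
            with warnings.catch_warnings():
                warnings.simplefilter("error", UserWarning)
                try:
                    self.embedding_ = self.isomap_.fit_transform(X)
                    break
                except UserWarning as exc:  # disconnected neighbour graph
                    if self.auto_connect and 2 * n_neighbors < len(X):
                        n_neighbors *= 2
                        continue
                    raise ValueError(
                        "neighbour graph is disconnected; increase n_neighbors"
                    ) from exc
        self.n_neighbors_used_ = n_neighbors
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = self._normalize(np.atleast_2d(X))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"pulse length {X.shape[1]} != fitted length {self.n_features_in_}"
            )
        return self.isomap_.transform(X)

    def feature_names(self) -> list[str]:
        return [f"iso_{i + 1}" for i in range(self.n_components)]


def fit_embedding(train_pulses: np.ndarray, n_neighbors: int = 10) -> PulseIsomap:
    """Fit the 25-component Isomap on a stack of mean-pulse vectors."""
    return PulseIsomap(n_neighbors=n_neighbors).fit(np.asarray(train_pulses))


def apply_embedding(model: PulseIsomap, pulses: np.ndarray) -> np.ndarray:
    return model.transform(pulses)


@dataclass
class SelectionResult:
    selected_names: list[str]
    rho_with_target: dict[str, float]
    redundancy_threshold: float


class SpearmanRedundancySelector(BaseEstimator, TransformerMixin):
    """Rank features by |Spearman rho| with the target, then greedily keep
    the top ``k`` while excluding any candidate whose |Spearman rho| with an
    already-selected feature reaches the redundancy threshold. Candidates
    with |rho| below ``min_target_rho`` (little to no relation with the
    target) are dropped outright."""

    def __init__(
        self,
        k: int = N_SELECTED_FEATURES,
        redundancy_threshold: float = REDUNDANCY_THRESHOLD,
        min_target_rho: float = MIN_TARGET_RHO,
    ):
        self.k = k
        self.redundancy_threshold = redundancy_threshold
        self.min_target_rho = min_target_rho

    def fit(self, X: pd.DataFrame, y: np.ndarray) -> "SpearmanRedundancySelector":
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X))
            X.columns = [str(c) for c in X.columns]
        y = np.asarray(y, dtype=float)
        if X.shape[1] < 2:
            raise ValueError("need >= 2 candidate features")
        if np.std(y) == 0:
            raise ValueError("degenerate target: zero variance")

        rhos: dict[str, float] = {}
        for name in X.columns:
            col = X[name].to_numpy(dtype=float)
            if np.std(col) == 0:
                rhos[name] = 0.0
                continue
            rho = stats.spearmanr(col, y).statistic
            rhos[name] = 0.0 if not np.isfinite(rho) else float(rho)

        ranked = sorted(rhos, key=lambda nm: abs(rhos[nm]), reverse=True)
        selected: list[str] = []
        for name in ranked:
            if len(selected) >= self.k:
                break
            if abs(rhos[name]) < self.min_target_rho:
                continue
            col = X[name].to_numpy(dtype=float)
            redundant = False
            for kept in selected:
                r = stats.spearmanr(col, X[kept].to_numpy(dtype=float)).statistic
                if np.isfinite(r) and abs(r) >= self.redundancy_threshold:
                    redundant = True
                    break
            if not redundant:
                selected.append(name)
        self.selected_names_ = selected
        self.rho_with_target_ = rhos
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X))
            X.columns = [str(c) for c in X.columns]
        return X[self.selected_names_]

    def result(self) -> SelectionResult:
        return SelectionResult(
            selected_names=list(self.selected_names_),
            rho_with_target={n: self.rho_with_target_[n] for n in self.selected_names_},
            redundancy_threshold=self.redundancy_threshold,
        )


def select_features(
    features: pd.DataFrame,
    target: np.ndarray,
    k: int = N_SELECTED_FEATURES,
    redundancy_threshold: float = REDUNDANCY_THRESHOLD,
) -> SelectionResult:
    """Functional wrapper over :class:`SpearmanRedundancySelector`."""
    sel = SpearmanRedundancySelector(k=k, redundancy_threshold=redundancy_threshold)
    sel.fit(features, target)
    return sel.result()
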