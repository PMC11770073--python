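# Methods

## Scope and shape

`icpflow` estimates window-mean intracranial pressure (ICP) noninvasively
from the morphology of cranial-expansion pulse waveforms. The learning core
is organised as scikit-learn estimators — `IcpEnsembleRegressor`
(fit/predict), `PulseIsomap` and `SpearmanRedundancySelector`
(fit/transform) — so the pieces compose with standard model-selection
tooling; the module-level functions (`train_ensemble`, `select_features`,
`fit_embedding`, ...) are thin wrappers over these classes. A click CLI
(`icpflow`) drives the batch pipeline over delimited-text recordings.

## The synthetic cohort

No public dataset of cranial-extensometer recordings with concurrent
invasive ICP exists, so the test substrate is a simulator whose ground truth
is known by construction.

**Pulse model.** One beat is the sum of three Gaussian bumps on the unit
period — the simplest form in which the P1/P2/P3 amplitudes (a₁..a₃),
times (τ₁ < τ₂ < τ₃) and widths are independently controllable. Defaults:
τ = (0.16, 0.40, 0.64), a = (1.0, 0.9, 0.55), widths ≈ 0.07–0.09 of the
period. The *realized* P2/P1 ratio and TTP of a template are measured by a
fine-grid local-maxima search (`template_landmarks`), because overlapping
bumps shift the attained maxima away from the nominal amplitudes; all
ground-truth bookkeeping uses the realized values.

**Recording assembly.** Beats are concatenated with per-beat periods drawn
from a Gaussian heart-rate process (default 75 ± 2 bpm; cohort draws span
55–95 bpm), amplitude-modulated at the respiratory frequency (0.25 Hz,
±10%), with random-walk baseline wander, additive Gaussian noise
(SD 0.03 of the unit pulse amplitude), and Poisson-arriving movement
artifacts (0.5/min) shaped as raised-cosine spikes of 3–10× the beat
amplitude lasting 0.1–0.5 s. Sampling rate defaults to 250 Hz.

**Ground-truth ICP law.** Per 10-s window,

    ICP = β₀ + β₁·(P2/P1) + β₂·TTP + u_patient + ε,

with defaults β₀ = −2.5, β₁ = 12 mmHg per unit ratio, β₂ = 4 mmHg per unit
fractional TTP, ε ~ N(0, 2 mmHg), and a patient random intercept
u ~ N(0, 1.5 mmHg). The P2/P1 ratio drifts across windows as a stationary
AR(1) (coefficient 0.85, SD 0.06) around a patient baseline drawn from
N(1.0, 0.5) clipped to [0.35, 2.1]. Two deliberate choices:

- *Most cohort ICP variance is carried by morphology, not by the patient
  intercept.* The intercept is not identifiable from waveform shape for a
  held-out patient, so it acts as an irreducible error floor; keeping its SD
  at 1.5 mmHg makes parameter recovery a meaningful test while still
  modelling between-patient offsets.
- *Calibration to a neurocritical-care population.* The defaults are set so
  that, over a default cohort, the sub-20 mmHg windows average ≈ 9.8 mmHg
  and roughly 4–7% of windows are ≥ 20 mmHg — the class imbalance that the
  inverse-frequency weighting exists to address. ICP is floored at 0 mmHg.

**Coupled channels.** The ICP, ABP and Doppler-velocity channels are
piecewise-constant per window (the pipeline consumes only window means).
ABP ~ N(90, 10) mmHg; FVm ~ N(60, 8) cm/s; and the diastolic/mean velocity
ratio falls linearly with ICP, FVd/FVm = clip(0.55 − 0.01·(ICP − 10),
0.2, 0.9) — an arbitrary but monotone coupling, sufficient to exercise the
TCD baseline's direction of response.

**What the simulator does not emulate.** There is no biomechanical skull
model; the waveform phenomenology (Gaussian bumps, additive artifacts) is a
stand-in, and the morphology → ICP law is linear by construction. Passing
tests therefore demonstrate that the pipeline recovers a known law from
realistically corrupted signals — not clinical accuracy on real patients.

## Signal quality

The SNR is computed on a Welch PSD (Hann window, 4-s segments, 50% overlap
— chosen for ≤ 0.25 Hz resolution on 10-s windows; the estimate satisfies
the discrete Parseval identity within leakage tolerance). "Fundamental plus
first three harmonics" is implemented as bands k·f₀ ± 0.3 Hz for k = 1..4
(`n_bands` is switchable); the half-width absorbs heart-rate variability
within a window and keeps bands disjoint for f₀ ≥ 0.6 Hz, and overlapping
bands are merged before integration so no energy is double-counted. Power
spectra (not amplitude) are integrated; the SNR gate is 0.35.

The second quality stage replaces a proprietary pulse classifier (trained
on manually labelled pulses that are not available) with a transparent
rule: Pearson correlation ≥ 0.8 between the window's mean pulse and a
canonical triphasic template, plus the requirement that the pulse rises
from its onset. The canonical template is itself produced by passing a
clean default-morphology pulse train through the same band-pass/average
chain, so the comparison is not biased by filter-induced shape changes.

## Pulse curation numerics

- Band-pass: zero-phase 2nd-order Butterworth, 0.3–20 Hz.
- Polarity: the systolic upstroke must be the fast limb; if the median
  onset→peak time exceeds the median peak→next-onset time, the signal is
  negated.
- Beat rejection: duration outside [0.5/f₀, 1.8/f₀]; peak-to-peak amplitude
  outside median ± 3·MAD (with a 5%-of-median floor so that identical clean
  beats, whose MAD is 0, are not rejected); correlation with the running
  mean-beat template < 0.7. Windows keep exact accounting of rejections;
  fewer than 3 surviving beats excludes the window.
- Landmarks: Savitzky–Golay smoothing (window 11, order 3); candidates are
  local maxima, augmented by local minima of the second derivative
  (shoulders) when a region lacks a maximum; P1 = earliest candidate at
  fractional time ≤ 0.45, P2 = next at ≤ 0.7, P3 optional afterwards.
  Candidates below 10% of the pulse maximum are treated as noise. The
  region boundaries are configurable constants chosen from standard
  ICP-pulse phenomenology.
- TTP is normalized by pulse duration (heart-rate invariant); AUC is the
  trapezoidal area of the max-normalized pulse over the unit interval; the
  ordinal compliance class is the P2/P1 binning (< 1.0, 1.0–1.2, > 1.2) — a
  documented stand-in for the clinical compliance scale.

## Features and selection

The feature bank has ~26 named features across the landmark, spectral and
beat-statistics groups plus 25 Isomap coordinates of the amplitude-
normalized mean pulse (neighbour count 10, automatically doubled inside
ensemble training if the neighbour graph disconnects). It is deliberately
smaller than an exhaustive industrial bank; the pipeline's contracts do not
depend on its cardinality. Selection ranks candidates by |Spearman ρ| with
invasive ICP, drops candidates with |ρ| < 0.05, and greedily excludes any
candidate whose |ρ| with an already-selected feature is ≥ 0.9, stopping at
15. The embedding and the selection are fitted inside each training split
only — held-out patients can never influence either (leakage is tested).

## Ensemble

"10-fold cross-validation" with "80%/20% allocation" is implemented as ten
seeded patient-level shuffle splits at 80/20 (a strict group-10-fold mode
is available behind a flag), which honours both statements at once; window
counts per fold vary because allocation is by patient. `regularization`
maps to the L2 leaf-value penalty of histogram gradient boosting. Class
weights are w_c = N/(2·N_c), which keeps the unweighted mean of the sample
weights at exactly 1 (unchanged effective sample size). The grid search
(trees × depth) scores by mean held-out MAE over the same split plan — a
slightly optimistic but simple choice. Predictions are the median of the
ten fold models; for the even fold count this is the mean of the two
central order statistics.

## Evaluation conventions

Differences are estimate − reference (eICP − ICP) throughout, so
per-patient difference columns are sign-consistent with overestimation
being positive. Bland–Altman uses the sample (n−1) SD and 1.96 for the 95%
limits. Window-level pooling is the primary analysis; per-patient summaries
are provided separately. NPV/PPV treat ≥ threshold (default 20 mmHg) as
positive for both reference and estimate, and report NaN (flagged, not
raised) when a denominator is empty.

## Problem sizes

The reference experiment — also run by `scripts/acceptance.py` — simulates
50 patients × 10 min (3000 windows, 250 Hz), holds out every fifth patient,
and trains the full 4000-tree ensemble on the rest; it completes in a few
minutes on one CPU. Unit and property tests use 8–12-patient cohorts at
5 min per patient with reduced tree counts, which exercise identical code
paths at a fraction of the cost.

## Known limitations

- The simulator's waveform phenomenology is synthetic; no claim about
  clinical accuracy on real patients follows from these tests.
- The morphology gate uses a single canonical template; strongly abnormal
  but physiological morphologies score lower correlations and are more
  often rejected.
- The patient random intercept is irreducible for held-out patients; the
  achievable MAE floor grows with its SD.
- Landmark detection assumes a roughly triphasic pulse; exotic waveforms
  (e.g., single dominant P3) fall back to shoulder candidates or are
  excluded as landmark failures, which is accounted but not recovered.
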