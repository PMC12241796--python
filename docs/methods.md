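# Methods

`sepnoise` quantifies "sensorimotor neural noise" from stimulus-locked
EEG epochs, operationalised as trial-by-trial variability in the
magnitude and timing of responses to a discrete somatosensory stimulus.
This note documents the model behind each stage, the tunable parameters
and their defaults, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the underlying analysis
description left the design open.

## Data model

The unit of analysis is an `EpochSet`: a single-channel time × trials
matrix of voltages (µV), sampled at `fs` Hz (default 500), spanning
`t_start_ms` to `t_end_ms` around stimulus onset (default −200 to
+500 ms). Samples sit at `t = t_start_ms + k·(1000/fs)` with both
endpoints included when the span is an exact multiple of the sample
period — 351 samples for the default epoch. Epochs must straddle onset.

## Pre-processing stages

**Artifact rejection.** A trial is dropped when any sample exceeds
±100 µV, or when any consecutive-sample voltage step exceeds 50 µV/ms
(evaluated as |Δv|/Δt with Δt = 1000/fs ms; the evaluation grid is a
design choice since only the µV/ms rate is standard). Rejection is fully
automatic and reported per criterion; a trial violating both criteria is
counted once, under amplitude, so the report partitions the input.
Manual vetoes enter through an explicit exclusion list rather than
interactive inspection, for reproducibility.

**Baseline correction.** Each trial's mean over [−200, 0) ms is
subtracted from the whole trial. The window is half-open so the
stimulus-onset sample counts as post-stimulus (the endpoint convention
is not standardised; this one keeps onset out of the baseline). The
operation is idempotent and preserves within-trial differences.

**Quality gate.** Participants with fewer than `min_trials` surviving
trials (default 50, configurable) fail with an error naming them. The
default approximates the smallest per-participant trial count such
recordings typically retain (~53 of 75 delivered pulses).

## Variability metrics

**SD curves.** At each time point, the sample SD (n−1) across trials.
Z-scored SD curves first standardise every trial over the full epoch
(mean 0, SD 1; sample SD); this removes per-trial scale so that groups
differing only in noise magnitude produce nearly coincident curves —
the control used to ask whether the *shape* of the post-stimulus
variability rise differs, separately from its baseline level. Constant
trials cannot be standardised and are dropped with a report.

**Coefficient of variation.** CV(t) = SD(t)/|mean(t)| across trials.
The sign/zero handling of the across-trial mean is not standardised; we
use the absolute mean and flag points with |mean| < 1e−9 µV as undefined
(NaN), excluding them from medians. CV is summarised as the median of
defined points within four 100 ms windows: −200..−101, −100..−1, 0..99
and 100..200 ms. The fourth window is kept one sample longer than the
others, exactly as conventionally printed, rather than regularised.
Median aggregation is retained deliberately: near-zero means make
pointwise CV heavy-tailed, and the median tames the residual
instability. Pre-stimulus CV on baseline-corrected data is large by
construction (the across-trial mean is near zero), so the informative
quantity is its substantial drop after stimulus onset.

## Aperiodic (1/f) slope

The PSD is estimated with Welch's averaged, modified periodogram
method: each stimulus-locked trial is one full-epoch segment,
mean-detrended and Hamming-windowed; modified periodograms (one-sided
density scaling, µV²/Hz) are averaged across trials and restricted to
1–45 Hz. With 351-sample epochs the grid resolution is ≈1.43 Hz.
Segment length and overlap are unspecified in the underlying analysis
description; one-segment-per-trial is the natural reading of a PSD
computed "for all trials" and is documented here as the package's
choice. Known estimator property: the constant-detrend notch leaks
through the Hamming kernel into the lowest grid bin (~1.43 Hz), biasing
it ≈13% low for white noise independent of trial count; all higher bins
are unbiased.

The aperiodic noise estimate is the OLS slope of log10 PSD on frequency
in **linear Hz** (a semilog fit, matching the convention of regressing
"log PSD with respect to frequency"; a log–log variant is available via
`log_freq=True` but is not the default). Flatter (less negative) slopes
indicate relatively more high-frequency power, interpreted as more
asynchronous neural activity. The base-10 logarithm rescales slope and
intercept jointly; the choice is recorded in output metadata. Band
power summaries (default 25–45 Hz) are unweighted means over grid
points in the closed band.

## Inter-trial phase coherence

Instantaneous phase comes from complex Morlet wavelet convolution
(default 5 cycles, truncated at ±3 Gaussian SDs, 1 Hz grid within each
band). ITPC at a (frequency, time) point is |N⁻¹ Σ exp(iφ)| across
trials, in [0, 1]; band curves average over the band's frequency grid.
Raw ITPC is reported without chance-level correction — the trial count
is carried alongside, and for N uniform phases the expected resultant
is ≈ √π/(2√N) (≈0.11 at N = 75).

Edge handling: samples within one wavelet half-length of an epoch edge
are flagged unreliable. Two consequences on 700 ms epochs at 5 cycles:

* theta-band (4–7 Hz) wavelets do not fit the epoch at all; the
  low-level API raises a domain error and band-level helpers skip the
  band with a warning. The pre/post analysis therefore uses alpha
  (8–12), beta (13–30) and low gamma (31–45 Hz). Theta ITPC requires
  longer epochs or fewer cycles (both configurable).
* the default pre-stimulus window [−50, 0) lies wholly inside the alpha
  edge region; window means use the reliable subset when any exists and
  otherwise fall back to the full window with a warning. Wavelet
  smoothing leaks post-stimulus alignment into the pre window, biasing
  the pre mean upward — so a post > pre contrast computed this way is
  conservative.

The pre window is half-open [−50, 0) and the post window closed
[0, 100] ms, keeping the onset sample post-stimulus.

## Group statistics

**Hedges' G.** G = J·(mean₁ − mean₂)/s_pooled with the n−1-weighted
pooled SD and small-sample correction J = 1 − 3/(4·df − 1); the exact
gamma-ratio correction is available behind a flag and differs by
< 1e−3 at df ≥ 18. Group 1 is the control group, so negative G means
the patient-like group is larger. Pointwise effect curves mark
|G| > 0.5 (a moderate effect) with no cluster criterion and no
multiple-comparison correction — an exploratory display convention, not
confirmatory inference, and documented as such in outputs.

**Mixed ANOVA.** The classical balanced split-plot decomposition:
between-subject SS splits into Group and subjects-within-group error;
within-subject SS into the within factor, the interaction, and the
within × subjects error; F ratios use the standard expected mean
squares. Balance is required (no imputation) and no sphericity
correction is applied. A zero error mean square yields NaN F/p,
reported as degenerate rather than fabricated.

**Regression.** OLS with intercept of each derived outcome on the
clinical predictors (age, sex coded F=0/M=1, IQ, premonitory-urge
score, and tic-severity motor/vocal/impairment subscores). Alongside
the full model, per-predictor univariate r, R², F and p are emitted,
since small-cohort findings are conventionally reported in that form;
both readings are reproducible from the output. Constant and collinear
columns fail with the offending columns named.

**Derived outcomes** (one row per participant): P2 peak amplitude from
the trial-averaged SEP; alpha- and low-gamma-band ITPC change across
onset (post [0, 100] ms mean vs pre [−50, 0) mean); mean CV change
across onset (post [0, 200] vs pre [−200, 0)); mean SD over the entire
epoch; mean PSD over 25–45 Hz. Because "post subtracted from pre"
admits either sign convention, both `*_post_minus_pre` and
`*_pre_minus_post` columns are emitted; neither is silently canonical.

## SEP component measurement

Components are measured in five a-priori windows centred on
grand-average peak times: N1 (18 ± 10 ms), P1 (40 ± 20), N2 (66 ± 20),
P2 (98 ± 20) and P3 (272 ± 50 ms), negative polarity for N components.
(The P1 component is known under several latency-based aliases; the
window centre fixed here is 40 ms.) Peaks are extrema on the raw sample
grid — no interpolation or smoothing, as 2 ms resolution matches the
reporting precision of such tables — with ties broken to the earliest
sample and windows closed on the grid. On a waveform monotone within a
window the reported peak sits on the window boundary. Amplitudes are
baseline-to-peak on baseline-corrected data. Per-trial peak times give
each participant's mean latency and latency SD (n−1) per component.

## Synthetic data generator

No public recordings accompany the analysis this package implements, so
validation uses a generative model with the minimal structure that makes
every stage's expected behaviour testable:

* **Evoked template** — a sum of Gaussian components (amplitude ×
  exp(−(t−latency)²/2·width²)). Defaults: N1 −2.5 µV @ 18 ms (width
  4 ms), P1 +3 @ 40 (8), N2 −3.5 @ 66 (10), P2 +5 @ 98 (12), P3 +3.5 @
  272 (30). Amplitudes and widths are free parameters chosen for
  realistic single-trial signal-to-noise at a centro-parietal electrode;
  they are not published values.
* **Trial jitter** — per trial and component, latency jitter (SDs 1.6,
  2.0, 2.9, 3.3, 6.5 ms, matched to observed across-trial timing SDs)
  and amplitude jitter (0.5–1 µV). Jitter is a shared per-trial shift
  per component, not per-sample warping.
* **Background noise** — spectral synthesis with amplitude ∝ f^(−χ/2),
  independent uniform phases, rescaled to an exact per-trial SD.
  Synthesis runs on a 4×-length stretch and the epoch is excerpted:
  epochs cut from a recording are excerpts of a continuous process, and
  direct epoch-length circular synthesis would concentrate a steep
  spectrum's low-frequency power in epoch-periodic components that
  baseline correction cannot remove, unlike the in-window drift real
  data show. Defaults: control-like σ = 4 µV, χ = 2.0; patient-like
  σ = 6 µV (1.5×), χ = 1.5 (flatter).
* **Phase reset** — an ongoing 10 Hz, 2 µV oscillation with random
  per-trial phase; from `reset_time_ms` onward a `post_alignment`
  fraction of trials lock to a common phase (control-like 0.85 from
  5 ms; patient-like 0.7 from 25 ms — weaker and delayed by 20 ms).
* **Between-participant heterogeneity** — a lognormal multiplier
  (log-SD 0.3) on each participant's noise scale, keeping group SD
  curves positive and right-skewed as in real EEG.
* **Clinical table** — synthetic covariates within realistic adult
  ranges (age 19–54, IQ 80–128, urge score 16–80, tic-severity total
  14–81), balanced sex.

The default design is 19 participants per group × 75 trials at 500 Hz,
−200..+500 ms. All outputs are pure functions of (configuration, seed).

What the generator does **not** emulate: volume conduction and
multichannel covariance, ocular/muscle/tic artifacts, inter-stimulus
timing structure (epochs are independent), oscillatory bands beyond the
single alpha carrier, and any coupling between clinical scores and
neural parameters. Passing recovery tests therefore demonstrates that
the pipeline measures what the model puts in — elevated noise scale,
flattened spectral exponent, delayed phase alignment — not that real
recordings satisfy the model.

## Validation problem sizes

The recovery suite runs the full default design (19 + 19 × 75 trials,
fixed seed), chosen to mirror the study-scale conditions while keeping
the whole test suite fast (≈20 s). Worked-example effect sizes are
recomputed from published group summaries (n = 19 per group) and agree
with the printed values within the rounding of their inputs (±0.02).

## Known limitations

* Single-channel pipeline by design; no topographies, no ICA.
* Pointwise |G| > 0.5 marking is exploratory; no correction for
  multiplicity across time points or frequencies.
* The mixed ANOVA assumes balance and applies no sphericity correction
  (with two within levels, sphericity is trivially satisfied for the
  coherence analysis, but not for the four CV windows).
* CV is numerically fragile wherever the evoked mean crosses zero;
  medians within windows mitigate but do not remove this.
* The 1/f slope from a semilog fit over 1–45 Hz is not comparable in
  units to log–log spectral exponents; use the `log_freq` flag for
  cross-study comparison.
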