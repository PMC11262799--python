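# Methods

`neuroshare` decides, for multichannel intracranial EEG responses to two
stimulus domains (speech and music), whether each channel's response is
**shared**, **preferred**, or **selective** — across spectral band power,
stimulus encoding (temporal response functions), and seed-based spectral
coherence — and validates every stage on synthetic cohorts with known
ground truth.  This note documents the models, the statistical machinery,
the numerical choices, and the limits of what the synthetic validation can
show.

## The response taxonomy

For each channel (or seed connection) two *simple effects* are tested —
speech vs baseline and music vs baseline — plus one *difference effect*
(speech vs music).  Writing S, M, D for the three significances:

| S | M | D | label |
|---|---|---|-------|
| ✓ | ✓ | ✓ | preferred, toward the larger response |
| ✓ | ✓ | ✗ | shared |
| ✓/✗ (xor) | | ✓ | selective for the significant domain |
| ✓/✗ (xor) | | ✗ | shared |
| ✗ | ✗ | — | none (difference not assessed) |

A selective-pattern channel whose difference favors the *non*-significant
domain is flagged `inconsistent`; it is surfaced in the tables and counted
with shared in summaries.  For band power the taxonomy is computed
separately for activations (condition > baseline) and deactivations; a
simple effect counts only if its sign matches the direction under study.
Coherence is one-sided (no deactivation analog), so connections have no
direction split.

## Preprocessing

* **Bipolar re-referencing**: adjacent same-shaft contacts are differenced
  into virtual channels (common-mode signals cancel exactly); shafts with a
  single contact contribute nothing.
* **High-frequency amplitude (HFa)**: the 80–120 Hz range is split into
  four 10-Hz sub-bands; each is band-passed (4th-order Butterworth,
  forward–backward so the group delay is zero), its analytic amplitude is
  taken, normalized by its own temporal mean, and the four normalized
  traces are averaged.  The output has temporal mean ≈ 1 per channel.
* **Artifact rejection** uses a robust centre + spread rule: a statistic is
  an outlier if it exceeds `median + 2·IQR` across channels (epochs).
  Channels are tested on broadband *and* HFa variance, per condition, and
  a channel rejected anywhere is dropped everywhere (the tests require a
  common channel set).  Epochs (5-s, non-overlapping, trailing remainder
  dropped) are flagged on the maximum absolute amplitude summed across
  *retained* channels only, per condition independently.  "Maximum
  amplitude" is read as absolute: bipolar sEEG is sign-symmetric.

## Spectral analysis

Welch band power per epoch × channel × band: the six canonical bands are
delta 1–4, theta 5–8, alpha 8–12, beta 18–30, low-gamma 30–50, and HFa
80–120 Hz (closed intervals; the shared 8-Hz edge belongs to both theta
and alpha, and the 4–5 / 12–18 Hz gaps are left open on purpose).  Each
5-s epoch is zero-padded with 3.5 s on both sides purely as spectral
interpolation — a finer frequency grid for the narrow low bands; nothing
is removed afterwards.  Welch settings: Hann window, 2.5-s segments, 50%
overlap (0.4 Hz native resolution, adequate for the 1–4 Hz band).  PSDs
are computed in float32; band values are the mean PSD over in-band bins.

Statistical testing operates on **log10 band power**: power is
approximately log-normal, so the log is the scale on which a t statistic
is meaningful, and the generator defines its effect sizes there.

## The tmax permutation engine

Multichannel family-wise error control uses the max-statistic method: the
condition labels of the pooled epochs are permuted (1000 times by
default), the Welch two-sample t is recomputed per channel, and the
maximum |t| over channels enters the null distribution.  Every channel's
observed |t| is then compared against that common null, so the correction
automatically sharpens as channels are added.  p-values carry the +1
smoothing, `p = (1 + #{tmax ≥ |t|}) / (n_perm + 1)`, and are two-tailed;
the response direction is read from the sign of the mean difference.

Two implementation details matter:

* **Exactness at small n.**  When the number of distinct label splits
  `C(n, k)` does not exceed `n_perm + 1`, all splits are enumerated and
  the p-values are exact (the acceptance suite verifies equality with a
  brute-force oracle on 4+4-epoch problems).
* **Swap invariance.**  The permutation null is built on a canonical
  (lexicographically sorted) arrangement of the pooled epochs using the
  smaller group size, so exchanging the two inputs changes only the sign
  of t, never the p-value — the taxonomy therefore swaps speech↔music
  labels exactly when the inputs are exchanged.

An unpaired test is used because run lengths differ between conditions
(≈115 speech vs ≈116 music epochs vs fewer baseline epochs); labels are
swapped between pooled epochs, which is the exchangeability the 5-s epoch
grid provides.  Benjamini–Hochberg FDR (via statsmodels) is reserved for
the TRF and coherence p-value families.

## Temporal response functions

Stimulus features at 100 Hz: the **envelope** (32-band gammatone
filterbank, ERB-spaced centres 80–8000 Hz via `scipy.signal.gammatone`;
per-band analytic amplitude, summed, anti-alias filtered, downsampled,
z-scored) and **peakRate** (half-wave-rectified first difference of the
raw envelope; strict local maxima become events carrying the derivative
value; z-scored over the full series, zeros included).  peakRate is
computed on the *raw* envelope so rectification is meaningful.

Neural targets at 100 Hz: **LF** (1–9 Hz band-passed broadband) and
**HFa amplitude** (as above, anti-aliased and downsampled).  The TRF is a
forward ridge regression on a lagged design matrix, lags −150…1000 ms in
10-ms steps (116 lags, the 100-Hz sample interval), identity penalty,
unpenalized intercept, zero-padded edges.  λ is chosen by contiguous
5-fold cross-validation on designated auditory channels over the training
span, grid 10⁰…10⁸ by default; near-ties (validation-r differences below
1e-6) resolve toward the smallest λ.  The 80/20 train/holdout split is
contiguous (final 20% held out) so temporal autocorrelation cannot leak
across the boundary.

**Scoring.**  Per channel, Pearson r between predicted and observed
holdout, Fisher z = atanh(r), and a parametric two-sided p from the
t-transform of r.  Because both series are band-limited, the nominal
holdout length wildly overstates the degrees of freedom; the p uses the
Bartlett effective sample size `n_eff = n / (1 + 2 Σ_k ρ_x(k) ρ_y(k))`
(truncated at n/4 lags, clipped to [4, n]).  For white series this
reduces to the nominal n.  Without the correction, channels with no
injected response score "significant" at 30–50% and the smoother envelope
feature is spuriously favored.

**Model comparison.**  Four models (envelope/peakRate × LF/HFa) are
compared on the per-patient percentage of channels significantly encoding
speech and/or music (union, q < 0.01).  The winner is the model capturing
the largest mean percentage; every other model is compared to it with
Wilcoxon signed-rank tests across patients, BH-corrected.  A result is
*decisive* only when all pairwise q < 0.05 — the winner itself does not
require decisiveness, because the two LF models are genuinely close: a
linear LF readout makes envelope and peakRate features nearly collinear,
and percentages of significant channels often tie between them.  The
**seed channel** per patient is the channel with the largest mean
(r_speech, r_music) among channels significant in at least one domain
(q < 0.01); ties break to the lower index; patients without any such
channel are excluded from connectivity.

## Connectivity

Magnitude-squared coherence between a seed and every other channel:
Hann-windowed per-epoch cross-spectra are averaged over epochs,
`C(f) = |⟨S_xy⟩|² / (⟨S_xx⟩⟨S_yy⟩)`, then averaged over in-band
frequencies.  Channels immediately neighboring the seed on the same shaft
(radius 1 bipolar channel) are excluded as a volume-conduction guard.  On
independent signals the estimator is biased upward by ≈ 1/n_epochs, which
is exactly why significance uses **epoch-shuffle surrogates**: permuting
the epoch order of the seed alone (identity excluded, 1000 iterations)
preserves every channel's spectrum while destroying cross-channel
alignment at lags ≥ 1 epoch, so the null carries the estimator bias.
Per-channel empirical p with +1 smoothing, BH q across channels,
significant at q < 0.01.  Note the BH floor: with m channels and n_surr
surrogates the smallest attainable q is ≈ m/(rank · (n_surr + 1)), so a
*lone* coupled channel among ~13 cannot reach q < 0.01 at 1000 surrogates
— detectable couplings come in groups, as they do in real data.

The speech−music **difference effect** is tested by permuting condition
labels across pooled epochs and recomputing both coherences (two-tailed,
1000 permutations, BH-corrected), with the same canonical-pooling
construction as the tmax engine so it is exactly swap-symmetric.

## Aggregation

**Cross-frequency selectivity**: starting from the channels selective to
one domain in one band (activation and deactivation pooled), each further
band in ascending-frequency wrap-around order deducts every channel with
*any* significant response to the other domain there (shared, preferred,
other-selective, or inconsistent, either direction).  The percentage
trace is non-increasing by construction.

**Population prevalence**: preferred-labeled channels are excluded first;
per-direction labels are collapsed per channel (significant in either
direction counts; selectivity must agree across directions, otherwise
shared).  A region × band cell is reported when ≥ 2 patients have ≥ 2
significant channels there; a patient is selective only if *all* their
significant channels in the region are selective for the same domain —
any mixture or shared channel makes the patient's profile shared.

## The synthetic cohort generator

Per channel and run, the signal is
`1/f background + narrowband oscillations + TRF response + artifacts`
at 500 Hz:

* **Background**: 1/f^χ Gaussian noise (χ = 1 by default, spectrum
  flattened below 0.5 Hz), base std 10 µV, with per-channel lognormal
  gain (σ = 0.25) — electrodes sit at different depths, and the spread is
  what makes the IQR-based artifact rule meaningful.  Normalization uses
  the *expected* (analytic) std, preserving natural variance fluctuations.
* **Oscillations** are narrowband-filtered Gaussian noise (raised-cosine
  band edges), not sinusoids, so coherence and power statistics behave
  like field data and surrogate nulls are non-degenerate.
* **Effect sizes** are defined on per-epoch log band power (mean shift /
  pooled SD).  A one-off internal calibration (60 background epochs,
  fixed internal seed, cached) measures per band the mean Welch band
  power, the SD of log band power, and the band power of a unit-variance
  oscillation; the requested d is then converted to an oscillation power
  by solving `ln(1 + P/µ) = d · σ_pooled(P)` by fixed point, where
  σ_pooled accounts for the *shrinkage* of the relative log fluctuation
  when power is added.  Activations put the oscillation in the responsive
  run(s); deactivations put it in the baseline run; the weaker domain of
  a preferred pair gets d/2.
* **Stimuli** are amplitude-modulated noise whose reference envelope is a
  quasi-periodic train of Hann events: mean rates 4.5 Hz (speech-like)
  and 2 Hz (music-like), interval jitter 0.15 of the mean interval, event
  amplitudes uniform(0.5, 1), event half-widths uniform(0.25, 0.6) of the
  mean interval.  The rates are conventional speech/music modulation
  values, not measured ones.  Variable event durations matter: they
  decorrelate envelope weight from onset-edge sharpness (as syllable and
  note durations do), which is what gives the envelope and peakRate
  features distinguishable LF signatures at all — with fixed-width events
  the two models are nearly collinear (measured envelope-model capture
  ≈ 0.97 vs ≈ 0.85 of the peakRate ceiling).
* **TRF channels** add `kernel ⊛ feature`, scaled so the 1–9 Hz variance
  of the response over the 1–9 Hz background variance equals the
  requested SNR; the analytic holdout ceiling is `sqrt(snr/(1+snr))`.
* **Couplings**: within a band, a coupled channel shares a component
  `κ·z + sqrt(1−κ²)·w` with the seed's oscillation z, both at an
  oscillation-to-background PSD ratio γ; expected magnitude-squared
  coherence is `κ²·(γ/(1+γ))²`.
* **Artifacts** last: artifact channels get variance ×50; artifact epochs
  get a 0.5-s Hann burst of ×30 channel-std amplitude on *all* channels
  simultaneously (movement-like — the summed-amplitude epoch statistic is
  designed for exactly this), so bursts do not masquerade as bad channels.

Determinism: one root `SeedSequence` per cohort; same seed ⇒ bit-identical
cohorts and byte-identical pipeline tables.

### What the generator does not emulate

No acoustic realism (phonemes, instruments — only envelope statistics);
no volume conduction or montage forward model (recordings are generated
at the virtual-channel level; bipolar re-referencing applies to real
contact recordings); no line noise (a 50 Hz notch exists for real EDF
input); no cross-run temporal continuity (conditions are independent
sessions); no non-stationarity, eye/muscle artifacts, or epileptic
activity.  Passing recovery tests therefore show the *statistical
machinery* is correct and calibrated under the stated signal model — not
that the pipeline is robust to every pathology of clinical recordings.

## Problem sizes used by the test suite and results script

Chosen as desk-scale study conditions: false-positive calibration uses
200 one-patient null cohorts (12 channels, 80-s runs, one tmax family per
band → 1200 trials at α = 0.01); taxonomy recovery uses 6 patients × 80
channels × 6 bands at d = 1.5 with 103 epochs per condition; TRF kernel
recovery uses a 240-s run at 0 dB SNR; model comparison uses ten cohorts
of 6 patients × 12 channels (100-s runs) with peakRate→LF responses whose
encoding strengths span holdout r ≈ 0.1–0.7, mirroring the weak-to-strong
range seen in cortex; coherence checks use 100 epochs; the end-to-end
demonstration cohort has 2 patients × 16–24 channels with 120–150-s runs.

## Known limitations

* The Bartlett-corrected parametric p for holdout correlations is a
  large-sample approximation; calibration on strongly autocorrelated
  targets is approximate (the suite checks it empirically).
* The effect-size calibration is a delta-method approximation; injected
  d is recovered within ±20% at d ≥ 1.5, not exactly.
* The BH floor on surrogate q-values (above) makes isolated couplings
  undetectable at q < 0.01 with 1000 surrogates and few channels.
* Region labels are opaque strings; no atlas mapping or electrode
  localization is performed.
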