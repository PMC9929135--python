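# Methods

This note documents the models, numerical choices, and deliberate design
decisions behind `polysom`, and what the synthetic-data validation does
and does not establish about real recordings.

## Data model and conventions

Time is seconds from recording start everywhere inside the package;
Zeitgeber time (ZT0 = lights-on, ZT12 = lights-off of the entrained
12:12 cycle) appears only at reporting boundaries. Epochs are 10 s,
0-based, half-open; a partial trailing epoch is dropped on load, never
padded. Vigilance labels are WAKE / NREM / REM / ARTIFACT; ARTIFACT
epochs are excluded from percentage denominators and spectra, and they
*break* episodes rather than bridging them — the conservative choice for
fragmentation metrics, since bridging would merge runs and hide short
bouts.

Signals live in EDF (read via `mne`; written by a minimal in-package
writer, 16-bit records, because no installed library writes EDF) or in a
documented CSV dialect (`#fs=`, `#start_zt_s=` headers, one `eeg,emg`
microvolt pair per row), defined because the commercial acquisition
formats are proprietary.

## Spectral analysis

Per-epoch spectra are a single Hann-tapered FFT per 10-s epoch (no Welch
sub-windows): 10 s gives 0.1 Hz native resolution, aggregated by mean
onto a 0.5 Hz grid, centers 0.5–fmax Hz. fmax defaults to 50 Hz; the
wide-band valence analysis uses 64 Hz. Band membership is *inclusive on
bin centers*: a band `[lo, hi]` selects the centers inside the closed
interval, so delta "0.75–4 Hz" selects centers 1.0–4.0 (the grid has no
0.75 center). Band summaries are means over selected bins — power
*density*, keeping bands of unequal width comparable. Bands: delta
0.75–4, low theta 3.5–7.5, high theta 8–11.5, theta 6–9 (used for
scoring and wake time courses), gamma 30–50 Hz.

Normalization is state-dependent and per-animal: each epoch's bin is
expressed as % of that animal's baseline-day mean spectrum *for the same
vigilance state*. Self-normalizing a baseline day therefore returns
state-wise day means of exactly 100% per bin — a fixture-free invariant
the tests exploit. Zero baseline bins propagate as missing, never as
infinities.

The wake valence marker is `theta_ratio` = mean density in low theta /
mean density in high theta, computed on wake spectra from the
deprivation window; it is scale-invariant by construction, so gain
differences between animals cancel.

## Vigilance scoring

The classifier is an explicit, auditable cascade per epoch (the
commercial auto-scorers it replaces are black boxes, so accuracy against
the generator's ground truth is the stated contract): (1) EMG RMS at or
above the wake threshold → WAKE; (2) else delta/total density ratio at
or above the NREM threshold → NREM; (3) else theta/delta at or above the
REM threshold with EMG at or below the atonia ceiling → REM; (4) else
NREM with an ambiguity flag (count logged). Features: delta, theta
(6–9 Hz) and total (0.75–50 Hz) mean densities from the spectral module,
EMG band-passed 5–30 Hz (4th-order Butterworth, zero-phase) before the
per-epoch RMS, and a robust EEG amplitude (1.4826·MAD).

Post-smoothing is deliberately minimal: an isolated single epoch flanked
by two identical states takes the flanking state, and REM directly after
WAKE becomes NREM (rodent REM is entered from NREM). Anything stronger
would erase the genuinely short bouts the fragmentation analysis exists
to count.

Per-animal calibration derives the wake threshold and the delta-fraction
threshold from exact 1-D two-class k-means splits (of log EMG RMS and
log delta/total; the log makes them scale-equivariant: doubling all EMG
doubles the threshold), and the REM EMG ceiling as half the muscle-quiet
class mean. A split is trusted only if the class-mean gap exceeds 3.5
pooled within-class SDs — splitting a unimodal Gaussian yields ≈2.7
whatever its scale, so values near that are treated as "no second mode"
and fixed defaults are used with a warning.

## Sleep architecture

Episodes are maximal runs of one state; transitions are counted between
adjacent non-ARTIFACT epochs; on artifact-free hypnograms total
transitions equal episodes − 1, and both are validated against
brute-force run enumeration on a thousand random hypnograms. Episode
histograms use power-of-two minute edges (0.5, 1, 2, 4, 8, 16, 32) with
an open top class and a named "<8 min" short-episode aggregate. Hourly
state percentages are on the ZT-aligned hour grid and sum to 100 over
non-ARTIFACT epochs; fully-artifactual hours are missing, not zero.
State-minute totals count integer epochs internally and convert to
minutes once, so conservation is exact at epoch resolution.

Sleep latency after a stimulus is the time to the first *two consecutive*
NREM epochs — the 20-s criterion realized on the 10-s grid, the key
interpretive decision in this module (a single 10-s epoch cannot satisfy
a 20-s criterion). The onset epoch must start within the 1-h scoring
window; its consolidating second epoch may extend past it. An absent
onset yields a censored (+inf) latency while the window's sleep
percentages are still reported. Latency is NREM-only; total sleep
(NREM+REM) of the window is reported alongside.

## Sleep-deprivation accounting

Lost sleep = baseline-window NREM minutes − test-window NREM minutes;
the normalized SD response = recovery NREM / lost, with the recovery
window running from SD end to ZT24 of the same day (multi-day recovery
is out of scope). Non-positive lost sleep makes the normalization
meaningless and raises rather than returning a signed ratio. The hourly
response is cumulative recovery through each hour over lost, so the
total equals the last hourly element — an internal consistency check.

Cumulative recovery expresses the accumulated (test − baseline) NREM
difference as % of the 24 h day per hour since SD end; the recovery rate
is the ordinary least-squares slope of that series (% h⁻¹) — the fit had
to be chosen because "rate" alone does not define one, and a slope on
the cumulative curve is the simplest estimator that uses every hour.

The homeostat fit (`fit_homeostat`) is state-driven: S is simulated from
the hypnogram (S += (1−S)·Δt/τ_rise in wake/REM, S −= S·Δt/τ_decay in
NREM) and (τ_rise, τ_decay, gain, S₀, scale) are found by bounded least
squares matching scale·(1+gain·S)² to per-epoch NREM SWA. A naive
exponential fit to the hourly SWA curve was rejected: wake interruptions
during recovery mix τ_rise into the apparent decay and bias the constant
by ~20–25% at realistic recovery-sleep fractions, whereas the
state-driven fit is unbiased because it models those interruptions.
Gain, S₀ and scale trade off partially (only τ_decay is sharply
identified by a single SD day); the fit is run on the concatenated
baseline + test days for extra dynamics.

Spearman correlations (marker vs rebound) use average ranks; the
two-sided p-value is an exact permutation enumeration for n ≤ 9 and the
t approximation above that. Group inferential machinery (ANOVA, post-hoc
corrections) is deliberately out of scope; functions return tidy
per-animal tables.

## Circadian and masking analysis

The chi-squared periodogram follows Sokolove–Bushell: fold the 1-min
trace at each trial period P (20–28 h, 1-min steps) into K complete
cycles (trailing remainder dropped — the simplest unbiased choice),
Qp = K·N′·Σ(column mean − grand mean)² / Σ(x − grand mean)² with
N′ = K·P, referred to χ²(P−1). Qp is affine-invariant. The stored
significance line is the per-period χ² quantile at α (default 0.001,
used for plotting and null calibration); the *peak* is declared only
where Qp clears the Bonferroni-corrected line α/n_periods, because with
~480 trial periods an uncorrected line fires somewhere on most pure-noise
traces. Rhythm amplitude is reported under both readings of
"peak-to-nadir extracted from the periodogram peak": the Qp excess above
the line (scale-invariant) and the folded-waveform peak-to-nadir (count
units); neither is privileged.

Activity onsets are threshold crossings (per-cycle median by default)
requiring ≥30 above-threshold minutes in the next 60, ≥80% of the
immediately following 10 min active (rejects isolated pre-onset count
spikes), and a preceding 240-min stretch ≥90% below threshold. All knobs
are parameters since the commercial detector is proprietary. Phase angle
of entrainment is the mean (onset ZT − 12 h), positive after lights-off;
onset variability is the residual SD around the onset-vs-cycle
regression (the slope absorbs free-running drift); phase shifts are the
gap between pre- and post-pulse regression lines extrapolated to the
pulse day, negative = delay, with the first 2 post-pulse cycles excluded
as re-entrainment transients. Onsets in DD are detected against a
sliding grid at the current period estimate.

Masking: pulse analyses difference state percentages in the pulse window
against the same clock window of the baseline day; ultradian 1 h:1 h
days are summed per segment type with exact 24-h conservation; sustained
masking compares LD light-phase NREM with the DD subjective day (first
half of each free-running cycle from the periodogram fit), per cycle.

## The synthetic generator

The generator's defaults are the study conditions every test and the
acceptance script run under. It emulates an adult laboratory mouse:

* **Chain**: semi-Markov over {WAKE, NREM, REM} with exponential-like
  (geometric in epochs) bout lengths — chosen over an epoch-wise Markov
  chain so bout-duration histograms are directly controllable. Mean
  bouts: wake 300 s (light) / 900 s (dark), NREM 480/300 s, REM 100 s;
  REM entered only from NREM (p = 0.35), REM→WAKE 0.6; wake bout length
  additionally modulated ±30% sinusoidally, peaking mid-dark. This
  yields ≈51% wake, 45% NREM, 4% REM, minutes-scale bouts — typical
  laboratory-mouse figures.
* **Homeostat**: τ_rise 8 h, τ_decay 2 h, S₀ 0.5, gain 0.8; NREM delta
  *amplitude* scales as 1+gain·S (so power as its square). The classic
  two-process form; parameters are config, not claims.
* **Signals**: shared 1/f Gaussian background (RMS 10 µV) plus per-state
  band-limited sinusoids (NREM delta 45 µV at 2 Hz; wake low/high theta
  18 µV at 6 and 9.5 Hz; REM theta 35 µV at 7 Hz), frequency jittered
  within the component bandwidth, faded over 0.5 s at epoch boundaries;
  EMG is Gaussian at state RMS 25/8/3 µV with a smoothed envelope.
* **Parametric spectrograms**: for cohort-scale experiments the per-epoch
  spectra are drawn directly as the template's expected density times
  Gamma(5, 1/5) multiplicative noise — exactly the distribution of a
  0.5 Hz bin averaged from five χ²(2) periodogram bins — instead of
  synthesizing and FFT-ing hundreds of days of raw signal. The scoring
  validation uses the full signal path.
* **Deprivation**: sleep epochs inside the window resample to WAKE with
  probability 1−leak (leak 0.05, residual sleep under enforced wake);
  after the window the NREM propensity is multiplied by the rebound gain
  (none 1.4, appetitive 1.2, aversive 1.8 — aversive > appetitive, the
  observed direction), and aversive deprivation halves REM entries
  during recovery. Valence also shifts the wake theta composition during
  the window (×1.6 on high theta for appetitive, on low theta for
  aversive); the two effects are kept independent so "marker predicts
  rebound" is falsifiable by switching one off.
* **Activity**: Poisson counts around a half-period active square
  profile, onset 0.25 h after lights-off, onset jitter SD 10 min, free
  running at 23.8 h in DD; a light pulse applies a configured −0.8 h
  shift to subsequent cycles. Masking resamples epochs whose lighting
  contradicts the entrained phase (wake→NREM at 0.6 per epoch under a
  light pulse, sleep→WAKE at 0.6 under a dark pulse; magnitudes are
  calibration knobs, no quantitative reference exists).
* Identical seed + config → bit-identical outputs.

What passing these tests shows: the pipeline's estimators recover the
quantities the generator encodes, at realistic sizes and noise. What it
does not show: robustness to real-world artifacts the generator omits —
electrode drift and movement artifacts, state-transition spectra,
non-stationary 1/f slopes, cage-specific activity waveforms, scorer
disagreement. The scoring contract in particular (≈99% agreement at
default noise) reflects well-separated synthetic state signatures;
performance on real signals depends on per-animal calibration quality.

## Problem sizes

The validation suite runs one full 24 h signal-synthesis day for the
scoring contract (8,640 epochs at 128 Hz), 6-h recordings along the
noise ladder, 50 two-day SD simulations (20 of them fitted) for the
homeostat, 100 + 100 marker cohorts, 60 ten-day actigraphy traces for
period recovery plus 200 eight-day null traces, and 10-vs-10 cohorts for
the genotype contrast — sizes chosen to keep Monte-Carlo error well
inside the asserted tolerances.

## Known limitations

* The scoring cascade has no artifact detector beyond what callers mask
  explicitly; ARTIFACT labels must come from input.
* `fit_homeostat` identifies τ_decay sharply only when the series
  contains a deprivation-scale pressure excursion; on undisturbed
  baseline days the gain/scale/S₀ trade-off widens.
* The chain is memoryless within states; real bout-length distributions
  have heavier tails, which would mostly affect the histogram tails.
* Exact Spearman permutation p-values stop at n = 9 (9! evaluations);
  beyond that the t approximation is standard but approximate.
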