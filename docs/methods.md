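# Methods

This note documents the models, numerical choices and validation logic
behind `dlam`, in the spirit of the methods documentation of simulation and
statistics packages: what each stage computes, which knobs matter, what the
synthetic generator does and does not emulate, and where genuinely open
design choices were fixed.

## Experimental structure assumed

Stimuli are dichoptic phase-reversing gratings shown in condition blocks
separated by gray interblock intervals. Four canonical conditions:
*monocular* (contralateral eye only), *concordant* (both eyes, same
orientation and phase), *phase offset* (same orientation, 180° spatial
phase difference) and *orthogonal* (90° orientation difference, the classic
rivalry stimulus). Laminar sessions default to 100 s blocks with 30 s
gray intervals, five blocks per condition, one reversal per second (500
trials per condition); imaging sessions use 10 s blocks with 10 s gray.
All interblock gray time is the baseline for every z-score and for ΔF/F.
Reversal rate is a parameter because block protocols are sometimes quoted
in cycles rather than reversals; the default of 1 reversal/s is the value
that makes five 100 s blocks yield 500 trials.

## LFP conditioning

Order: per-channel mean (DC) subtraction → anti-aliased decimation to
1 kHz → 3rd-order 1–300 Hz Butterworth bandpass → local linear detrend →
3rd-order 58–62 Hz Butterworth notch.

- **Zero phase.** All IIR filters run forward–backward (`sosfiltfilt`).
  Evoked-component latencies are measured downstream, so group delay must
  stay below a sample; the zero-phase choice doubles the nominal stopband
  attenuation, which the filter contracts account for.
- **Decimation.** Each stage (ratios factored so none exceeds 13) applies
  an order-8 Butterworth at 0.4× its target rate before striding. A
  Chebyshev anti-alias design was rejected: its passband ripple compounds
  across stages and the doubled (zero-phase) ripple exceeded the 1%
  passband-preservation contract at 10 Hz.
- **Local detrend.** Least-squares lines on 0.5 s windows sliding by
  0.1 s, combined by triangular-weight overlap averaging into a smooth
  trend that is subtracted; the trace is reflect-padded by one window so
  edges see full overlap. This reproduces the behaviour of the usual
  sliding-window detrenders without binding to any toolbox's internals.
- Every step stamps itself into a provenance list and refuses to run
  twice; re-running a recorded chain is bit-identical.

## VEP components

Trials are extracted per reversal event, baselined by the mean of their
first 10 ms, averaged, and smoothed with a Gaussian of 10 ms full width at
half maximum (truncated at ±3σ and renormalized so constants pass
unchanged; "width" figures for smoothing kernels are interpreted as FWHM
throughout). The negativity is the minimum in a configurable early window
(default 25–100 ms); the positivity is the maximum after the measured
negativity inside a late window (default 60–250 ms); magnitude is
positivity − negativity. The search windows are configuration, not claims:
the defaults bracket the early activity peak (40–80 ms) and the late
positivity (100–200 ms) with margin. Averaging precedes smoothing; for a
linear smoother the order only matters at trial edges.

## CSD and laminar alignment

The map is the negative central second spatial difference (1/h², sinks
negative) of the trial-averaged LFP after 20 ms-FWHM temporal smoothing
and 5-point Hamming spatial smoothing (weights 0.08, 0.54, 1.00, 0.54,
0.08, normalized to unit sum). The composite spatial stencil is 7 channels
wide, so the output covers interior channels only — three dropped per
probe end, no extrapolation. A depth-linear potential maps to exactly
zero; a quadratic maps to a constant.

**Sink selection.** Per channel, the baseline window (default 0–20 ms
post-reversal) gives a mean and SD; a sink (source) crossing is the CSD
falling below mean − k·SD (rising above mean + k·SD), k = 2 by default,
inside the search window (default 20–120 ms). Two robustness terms are
part of the rule:

- crossings must also exceed 10% of the map's peak magnitude
  (`rel_floor`), so a noise-free map does not flag quantization ripple as
  "2 SD below a zero-variance baseline";
- crossing times closer than one temporal-smoothing width (20 ms,
  `tie_window_ms`) are treated as simultaneous — latency differences
  below the smoothing scale are not resolvable, and at 1 ms resolution
  the raw earliest-crossing rule picks the sink's neighbour roughly a
  third of the time under realistic noise. Within the earliest group the
  deepest (most negative) trough wins, exact ties going to the deeper
  channel. The candidate must lie below some channel with a source
  crossing.

Depths are then signed relative to the sink channel (positive =
superficial) and layers labelled by the fixed table L2/3 (+300, +60],
L4 (+60, −80], L5 (−80, −260], L6 (−260, −460] µm — each layer includes
its deep boundary and excludes its superficial one, so the shared
endpoints partition cleanly; anything outside ±(300/−460) is "out".
Units are labelled with the same table.

## MUAe

Common-median referencing (per-channel median, then per-timepoint
cross-channel median), a second-order 60 Hz IIR notch whose −10 dB
bandwidth is 10 Hz (for the standard biquad this corresponds to a −3 dB
bandwidth of 30 Hz, Q = 2), 3rd-order 500–5000 Hz Butterworth bandpass,
rectification, 3rd-order 250 Hz low-pass, then stride decimation to 1 kHz
(the low-pass already anti-aliases). A zero-phase low-pass of a rectified
signal can undershoot slightly below zero; the envelope is clipped at zero
to keep it a magnitude. Z-scoring uses the mean/SD of all concatenated
interblock samples per channel; 1.96 is the significance threshold for a
visual response. Condition responses are trial-aligned averages grouped by
layer, differenced against the monocular condition, and summarized as
means over the early (40–80 ms) and late (100–200 ms) windows.

## Single units

Trough-to-peak latency is (argmax after the global trough − trough
index)/fs, trough ties breaking earliest. FS < 0.4 ms < RS; exactly 0.4 ms
goes to RS with a logged warning. PSTHs use 1 ms bins, rate =
counts/(n_trials · bin), which reduces to the familiar ×2 rule at 500
trials. Early/late windows are half-open, [40, 80) and [100, 200) ms, so
a shared boundary bin is never counted twice. Per-unit z-scores bin the
whole recording at 1 ms, smooth with the same 10 ms Gaussian used for
display, and reference the interblock mean/SD; units with no interblock
spikes have an undefined baseline and are flagged excluded rather than
scored — the alternative (imputing a tiny SD) would manufacture huge
z-values for the quietest cells.

## Calcium

F_true = F_roi − 0.7·F_neuropil; ΔF/F = (F − F̄_gray)/F̄_gray with the gray
mean over all interblock frames of the session (per-block baselining is a
config option; session-wide is the default). Sessions under 100 ROIs are
excluded. Condition responses average all in-block frames over all blocks
of a condition — blocks are equal length by design, so this weights them
equally — then average over ROIs and animals.

## Repeated-measures inference

One-way RM-ANOVA on a subjects × conditions matrix via the standard
within-subject decomposition, F = MS_cond/MS_error on (k−1), (k−1)(n−1)
df. Greenhouse–Geisser ε̂ = tr(S̃)²/((k−1)·ΣS̃²) with S̃ the double-centered
sample covariance of the condition columns, clipped to [1/(k−1), 1]; both
df are scaled by ε̂ before the p value. Missing cells are refused, not
imputed. Pairwise contrasts are paired t tests with the Šídák family-wise
adjustment 1 − (1 − p)^m; a contrast with zero within-pair variance is
flagged degenerate. Only this family is implemented; two-way designs and
Tukey/Dunnett post-hocs are out of scope.

## The synthetic generator

The generator's role is to encode the qualitative effect structure of the
experiment with exact ground truth, not to be biophysical.

- **LFP.** A CSD profile is prescribed (Gaussian sink, σ = 1.2 channels,
  balanced Gaussian source 4 channels above) and integrated twice along
  depth by solving the discrete Poisson equation with grounded probe ends
  — the exact inverse of the analysis stencil, so noise-free inverse
  consistency is testable to machine precision. The forward model is
  normalized so the sink-channel deflection equals the configured evoked
  amplitude (150 µV default). The evoked time course is a difference of
  Gaussians peaking ≈ 64 ms (its negative lobe produces the later VEP
  positivity) plus a 100–200 ms plateau; per-condition early/late gains
  default to monocular 1.0/0.15, concordant 1.5/0.15, phase offset
  0.5/0.15, orthogonal 1.25/0.9 — concordant early up, phase offset early
  down, orthogonal late up.
- **Noise.** 1/f-amplitude Gaussian background (50 µV RMS), spatially
  smoothed along the probe (Gaussian σ = 4 channels) with a 10%
  spatially-independent component — volume-conducted background is
  coherent across 20 µm sites, and a spatially-white model would be
  pathological under a second spatial derivative — plus a common 60 Hz
  sinusoid (20 µV). Samples are quantized to the acquisition step
  (0.195 µV/count) so disk round trips are bit exact.
- **Spikes.** Inhomogeneous Poisson, rate = base·(1 + g_E·k_E(t) +
  g_L·k_L(t)) with k_E a raised cosine on 40–80 ms and k_L a Tukey plateau
  on 100–200 ms, sampled by inverse-CDF within each reversal period;
  homogeneous base rate during gray. Templates are biphasic with
  grid-exact trough-to-peak separations (RS 0.5–0.8 ms, FS 0.2–0.3 ms);
  a helper inserts scaled templates into a noisy 25 kHz trace for
  envelope tests.
- **Calcium.** Spike counts at ~14.9 Hz frames convolved with an
  exponential kernel (τ = 0.6 s, GCaMP6f-like), a shared neuropil trace
  (slow background + 30% of the mean population signal) mixed in with
  α = 0.7, and Poisson-like shot noise. Session presets encode the two
  observed cell-class patterns: excitatory-like (orthogonal > monocular)
  and SOM-like (orthogonal < monocular).
- One seed fans out to independent child streams (schedule, lfp, spikes,
  calcium), so identical seeds give bit-identical data per modality.

Not emulated: eye movements and behavioural state, display crosstalk,
electrode drift, spike-sorting and segmentation errors, biophysical volume
conduction, and realistic cross-unit correlations. Passing recovery tests
therefore demonstrates that the analysis inverts its own generative
assumptions at realistic signal-to-noise — not that those assumptions
exhaust real data.

## Validation studies and sizes

`dlam.studies` fixes the problem sizes used by the test battery and the
acceptance script, chosen to validate each property at desk scale:

- sink recovery: 20 sessions, 64 channels, one 100-trial monocular block
  at 1 kHz, default noise;
- effect recovery: 50 replicates of 24 units × 4 conditions × 250 trials
  (sign pattern, GG-ANOVA and Šídák contrasts at α = 0.05);
- null false-positive rate: 500 replicates of 30 units × 30 trials with
  all gains equal — 30 subjects keeps the GG-corrected test near nominal
  (the correction is conservative at small n);
- MUAe monotonicity: inserted in-window rates 5/10/20 Hz on a 4-channel
  25 kHz trace; calcium orderings: 20 replicates per preset, 50 ROIs,
  4 blocks per condition.

## Known limitations

- `compute_csd` needs ≥ 7 channels for a non-empty interior map (the
  validated minimum is 5, which yields an empty map).
- The MUAe stage requires wide-band 25 kHz input; sessions simulated at
  1 kHz for LFP-only work skip it (logged).
- Non-integer decimation ratios are refused rather than resampled.
- The RM-ANOVA refuses unbalanced designs; use a mixed model elsewhere if
  subjects miss conditions.
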