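# Methods

## The model

A single receptor carrying one donor and one acceptor dye is assumed to
occupy, at every camera frame t (interval Δt = 0.1 s), one of K discrete
conformational states. The hidden state sequence is a first-order Markov
chain with row-stochastic per-frame transition matrix A and initial
distribution π. Conditional on state k, the observed apparent FRET
efficiency E_app(t) = I_A/(I_A + I_D) is Gaussian with state mean μ_k and a
single variance σ² **shared by all states** — the states differ in dye
separation, not in noise. One model (A, π, μ, σ²) is fit per experimental
condition, jointly to all screened trajectories of that condition; each
trajectory is an independent chain started from π.

Fitting is Baum–Welch (EM) with sufficient statistics pooled across
trajectories; all recursions are per-frame normalized so underflow is
impossible at any trajectory length. σ² is re-estimated as the single
posterior-weighted residual variance pooled over all states and frames.
Viterbi decoding (log space, ties broken toward the lower state index at
every backtracking step) idealizes each trajectory; frame-weighted Viterbi
labels give the state populations. States are always reported with means
strictly descending, so state 0 is the highest-FRET (inactive, "R") state.

### Numerical choices

- Convergence: relative log-likelihood change < 1e-6, max 1000 iterations.
- Variance floor 1e-6 FRET²; hitting it is flagged in the fit result.
- Initialization is deterministic: means evenly spaced between the 2.5th
  and 97.5th percentile of the pooled E_app (the median for K = 1), σ² =
  pooled variance / K, A with 0.95 diagonals, π uniform. Spacing means over
  the observed *range* rather than over quantiles matters when occupancies
  are strongly skewed (e.g. 0.75/0.20/0.05): quantile-placed means pile
  onto the dominant peak and EM stalls in a collapsed optimum in which two
  states share one mean. No random restarts are needed on any fixture; the
  `seed` arguments exist for interface stability and derived per-dataset
  seeding.
- Trajectories of unequal length are batched by padding with unit emission
  likelihoods, which provably leaves every normalizer and the total
  log-likelihood unchanged.

## State-count selection

For each candidate K (default 2..5) and condition, the pooled E_app sample
is fit with a K-component Gaussian mixture (free per-component variances,
initialized from the HMM's means and stationary occupancies, scikit-learn
backend) and scored by BIC = p·ln(n) − 2·ln(L̂) with p = 3K − 1 (K means, K
variances, K − 1 free weights) and n the pooled frame count. n deliberately
ignores temporal autocorrelation, matching frame-level histogram practice.
Because one state count must describe a receptor under every condition, the
BIC is summed across conditions and the argmin taken (ties to smaller K —
parsimony). Per-condition BICs are reported as well. For the selected K the
spread of sorted GMM means across conditions ("peak consistency") is
computed; a spread above 0.05 FRET units raises a flag, since comparable
conditions must agree on where the states sit.

## Trace processing and screening

Corrections follow the standard order: donor' = donor − bg_D, acceptor' =
acceptor − bg_A − α·donor', with α the donor bleed-through fraction.
Nothing is floored; negative excursions carry real noise information.
E_app is computed on pre-bleach frames only and is **not clamped** to
[0, 1]; frames whose summed intensity falls below 1e-9 are dropped and
counted. Frames are 0-indexed; `bleach_frame` is the first post-bleach
frame.

Photobleach detection replaces the by-eye screen applied to real data with
a transparent change-point scan. Per channel (acceptor, and donor+acceptor
total) the noise scale σ is estimated robustly from median absolute first
differences; candidate splits are scored by the Welch-type standardized
mean difference |m₁ − m₂| / (σ·√(1/n₁ + 1/n₂)) and accepted at score ≥ 5
(`StepDetectConfig.z_threshold`), with exhaustive evaluation inside a
depth-limited binary segmentation. Standardizing by the
*noise* scale rather than the raw segment standard deviation is essential:
on multi-state traces the raw SD is dominated by conformational switching
and a genuine acceptor bleach in a low-FRET-rich condition would otherwise
be undetectable at any sensible threshold. A downward step is *bleach-like*
only if its post-step segment sits at the channel's lowest inter-event
level (tolerance max(0.05 × span, 3σ/√n_post)): a bleach lands at
background, a conformational transition lands at another positive FRET
level. The photobleach is the **last** bleach-like event (terminal signal
loss); events are classified simultaneous vs acceptor-only by whether the
donor itself drops there (after acceptor-only bleaching the donor rises to
the full total intensity because energy transfer stops). A total-intensity
event falling inside an acceptor event's post-segment supersedes it as one
simultaneous event — the acceptor scan often cannot resolve a short final
low-FRET dwell from the full loss that follows it.

The screen accepts a trace iff: exactly one bleach event; pre-bleach
donor/acceptor Pearson correlation ≤ −0.2; pre-bleach length ≥ 20 frames.
Every failed rule is reported (`no_bleach_step`, `multi_step`, `too_short`,
`no_dynamics`, `poor_anticorrelation`). On the default presets acceptance
is 0.91–0.95, bleach classes are recovered essentially perfectly, and the
bleach frame is localized with median error 0.

Known screen limitation: a two-acceptor molecule whose first bleach lands
at an intermediate *positive* level is locally indistinguishable from a
conformational transition (both are anti-correlated and total-conserving);
only loss events that reach background are counted.

## The synthetic-data generator

The generator is the model's generative twin plus a detection chain. Per
frame the emitted FRET is e_t = μ_state + jitter, with jitter ~ N(0,
0.075) representing intra-state donor–acceptor distance/orientation
fluctuations; e_t is deliberately left unbounded so the emission is exactly
Gaussian in E-space (the analysis never clamps E_app either). Ideal
intensities split a constant total T = 1000 as donor = T(1 − e_t),
acceptor = T·e_t — the jitter is what anti-correlates the channels within
a single dwell, as in real traces — and each channel adds independent
N(0, 30) read noise plus optional background; the recorded acceptor adds
α × donor bleed-through (default α = 0, as for dye pairs with clean
spectral separation; set it explicitly to emulate contaminated channels).
The effective E_app standard deviation is ≈ 0.08 across the preset FRET
range.

Bleaching: per-frame hazards (defaults 0.002 acceptor-only, 0.001
simultaneous) draw a geometric bleach time, truncated so every trace
bleaches at least 30 frames (3 s) before the window ends — the screen only
retains molecules whose bleach step was observed, so longer-lived
molecules would simply have been recorded longer; the post-bleach tail is
what determines the background level for detection. After acceptor-only
bleaching the donor recovers to T; after simultaneous bleaching both
channels drop to background. Donor-bleach-first molecules are not
simulated (no FRET signal; screened out in practice).

Dwell times are geometric at the frame level; "seconds-scale" dynamics are
encoded by per-state escape probabilities ≤ ~0.07 per 0.1 s frame.
Transition matrices are built by a detailed-balance birth–death
construction: states are ordered by FRET, only adjacent states exchange
(A[i,i+1] = s·min(1, π_{i+1}/π_i) etc. for symmetric exchange rates s),
which fixes the stationary distribution exactly and yields the sequential
connectivity the TDP analysis should recover.

Preset stationary fractions (state order R, R', [R*'], R*):

| preset | fractions | encodes |
|---|---|---|
| apo-CXCR4 | 0.75/0.20/0.05 | inactive-dominant 3-state landscape |
| CXCL12-CXCR4 | 0.47/0.20/0.33 | R* up 28 points vs apo |
| apo-ACKR3 | 0.25 × 4 | near-uniform 4-state landscape |
| CXCL12-ACKR3 | 0.14/0.12/0.32/0.42 | R*+R*' up 24 points vs apo |
| VUF16840-ACKR3 | 0.55/0.25/0.12/0.08 | inverse agonist, R-shifted |
| Y257L-ACKR3 | 0.60/0.16/0.12/0.12 | mutant, R-dominant, damped dynamics |

State means: CXCR4 0.85/0.59/0.19; ACKR3 0.85/0.66/0.39/0.11. Ligand
presets share their receptor's means (only populations shift), so
cross-condition peak consistency holds by construction. Absolute apo
fractions are modeling choices; the ligand presets pin the *differences*
to the headline printed shifts.

What the generator does **not** emulate: shot-noise scaling with intensity,
triplet blinking, spectral crosstalk beyond the single bleed-through term,
gamma/quantum-yield asymmetries, slow drift, or multi-molecule aggregates.
Passing recovery tests therefore demonstrates correctness of the analysis
chain under its own model assumptions — not robustness to every pathology
of real recordings.

## Landscape summaries

- **Populations**: fraction of Viterbi-labeled frames per state.
- **Composite histograms**: per-state Gaussian KDEs (bandwidth 0.04, fixed
  512-point grid on [−0.2, 1.2]) scaled by occupancy so the state curves
  sum to the unit-integral envelope.
- **TDP**: every consecutive label change contributes one event at
  (dwell-mean E_app before, dwell-mean E_app after); events pool across
  molecules into a 2-D Gaussian KDE (σ = 0.03, 128² grid on [−0.2, 1.2]²,
  total probability 1). Using dwell-averaged *raw* E_app rather than
  fitted means keeps distinct underlying FRET levels distinguishable even
  if a model state were to lump them — which is exactly what makes the
  mixed-labeling counterexample (four levels, two cross-peak pairs)
  testable. Peaks are 3×3-neighborhood local maxima above 10% of the
  global maximum.
- **Dwells**: first and last dwell of every path are censored (their true
  extent is unobserved); exponential rate = 1/mean. Note that *complete*
  dwells inside a finite recording window are mildly length-biased (long
  dwells are more likely to touch a window edge); the bias is ~E[dwell]/T
  and negligible for windows ≥ 20 dwell lengths.
- **Comparisons**: per-state and grouped population differences in
  percentage points (f_b − f_a)·100; per-state deltas sum to zero by
  construction.

## Problem sizes

Recovery runs use 150 traces × 300 frames per condition (≈ 28,000
accepted pre-bleach frames), which puts estimator noise comfortably inside
the stated tolerances: state means recover to ±0.01, the shared σ to
±0.005, and the injected 28-point R* shift to ±2–3 points across seeds.
Unit and property tests use smaller sizes chosen so each statistical
assertion still sits ≥3 standard errors from its threshold.

## Design choices on genuinely open points

- Whether π is shared or per-trajectory is not observable from single fits;
  π is shared, matching the "one model per condition" philosophy.
- BIC could be computed per condition or per receptor; both are reported,
  selection uses the sum across conditions.
- The TDP recipe (axis quantity, normalization) varies across the
  literature; the dwell-averaged raw-E_app dialect with global
  normalization over all transitions is documented above and exposed via
  configuration (smoothing σ, peak threshold).
- E_app is always computed on corrected intensities and always fit on the
  corrected scale.
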