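# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, and what the synthetic-data tests do and do not
establish about real film data.

## Color features

All stages operate on a 12-channel feature vector from four color spaces:
RGB, CIELAB, HSV, YCbCr. Conventions:

* Input RGB is gamma-encoded sRGB in [0, 1]. HSV and YCbCr are computed on
  the gamma-encoded values (the usual imaging practice); Lab linearizes
  first.
* Lab uses the IEC 61966-2-1 sRGB→XYZ matrix with the D65 reference white
  defined as the image of (1, 1, 1) under that matrix, so the neutral axis
  maps to a = b = 0 exactly and white to L = 100 exactly.
* YCbCr is the BT.601 analog form, Y = 0.299R + 0.587G + 0.114B,
  Cb = (B−Y)/1.772 + 0.5, Cr = (R−Y)/1.402 + 0.5, scaled so every channel
  lies in [0, 1] with neutral at 0.5.
* Hue is stored as a fraction of the hue circle in [0, 1), not degrees, so
  that one slope threshold (see below) is meaningful across channels. The
  hue of an achromatic pixel is defined as 0.
* Feature extraction from an image averages RGB over the foreground mask
  *before* conversion. Averaging in RGB sidesteps hue wraparound and makes
  the extracted vector the feature vector of the mean color. This is a
  choice: averaging per color space would weight pixels differently in the
  nonlinear channels.

Segmentation is out of scope — masks are inputs (the original data
acquisition used interactive graph-cut tooling; nothing in the analysis
depends on how the mask was drawn).

## Response-time (stabilization) detection

Per channel: numerical gradient over frames (central differences inside,
one-sided at the ends — `numpy.gradient`, the same scheme as MATLAB's
`gradient`), absolute value, centered moving average (window 10 frames,
shrinking at the edges), then threshold 0.001 channel units/frame with a
50-frame consecutive-run requirement. Defaults follow the study procedure;
the moving-average window is not stated there, and 10 frames was chosen to
suppress frame-level noise without blurring events at the 50-frame scale.

One definitional point matters. "First run of 50 quiet frames" is not a
usable completion criterion on its own: a film whose transition starts
late is quiet *before* the transition too, and the first quiet run would
be at frame 1. A steady state, by definition, persists — so the detector
reports the first frame from which the smoothed |slope| stays below the
threshold **through the end of the recording**, requiring at least
`consecutive_frames` qualifying frames so a short quiet tail cannot count.
This rule gives frame 1 on a constant series, never fires on a steady
ramp, detects the post-transition plateau of a late sigmoid, and is
monotone in both parameters: raising the threshold can only move detection
earlier; lengthening the run requirement can only move it later (or to
"not stabilized").

The reported response time is the hue channel's stabilization time — hue
shows the cleanest sigmoidal transition — with an option to require hue,
saturation and the Lab `a` channel jointly (the latest of the three is then
reported). Frames are numbered from 1; with the default 1 frame/s, frame f
corresponds to t = f − 1 seconds.

## Synthetic data

No public raw data exist, so generators reproduce the study conditions:

* **Kinetics**: each channel follows a logistic
  v(t) = v₀ + (v∞ − v₀)/(1 + e^(−r(t−t₀))) + ε, ε ~ N(0, σ²), sampled at
  1 frame/s for 600 s and clipped to the channel's physical range. Plateau
  colors encode the observed endpoints — yellow at pH 6 (visually almost
  unchanged from the dry film), green at pH 7, blue at pH 8–10 with hue
  rising toward pH 10 — and transition midpoints encode the observed
  ordering (fastest at pH 6, slowest at pH 7, fastest alkaline response at
  pH 8). Default frame noise is σ = 5·10⁻⁴ channel units: a masked mean
  over a few thousand pixels with per-pixel noise ~0.01 has a standard
  error of a few 10⁻⁴. This scale also respects a hard constraint of the
  detection rule: the expected moving-averaged |gradient| of pure frame
  noise is σ·√(1/π)·√2 ≈ 0.8σ, so frame noise at the 0.001-threshold scale
  would keep the smoothed slope above threshold forever, for any window.
* **Formulation dataset**: the full factorial design (PEG 6/8/10 % w/v ×
  BTB 0.01/0.03/0.05 % w/v × pH 6–10 × 4 replicates = 180 records), with
  y = surface(x₁, x₂) + pH offset + N(0, σ²), floored at 1 s. The default
  surface is the published fitness function; pH offsets (−60, +60, −20, 0,
  +20 s for pH 6–10) encode the same ordering as the kinetics midpoints;
  replicate noise σ = 111.5 s is calibrated so the within-cell variance
  (pH-offset spread 1600 s² plus noise) reproduces the study's within mean
  square of ≈14,043 s².
* **Film images**: a flat-color rectangle (75 % of each side) on a dark
  background with i.i.d. Gaussian pixel noise clipped to [0, 1] — enough
  structure to exercise masked extraction, nothing more.

What passing tests on these data do **not** show: the logistic form is
phenomenological, not a diffusion model of dye chemistry; illumination
drift, shadows, specular highlights and mask errors of real video are
absent; and the pH offsets enter additively, whereas real formulation × pH
kinetics need not be additive.

## Feature selection

PCA is run on the feature **correlation** matrix — the Kaiser criterion's
eigenvalue-1 reference only makes sense for standardized features, and the
12 channels live on mixed scales. Components with eigenvalue > 1 are
retained (strict inequality, evaluated with a 10⁻⁹ guard so an
exactly-unit spectrum retains nothing). Loading columns are unit-norm with
the largest-magnitude element made positive; a constant column is an error
naming the column.

ReliefF is the Kononenko multiclass variant: for each sampled instance,
k = 10 nearest hits and, per other class, k nearest misses by Manhattan
distance on range-normalized features; miss contributions are weighted by
P(class)/(1 − P(own class)). All rows are sampled by default. The diff of
a zero-range feature is defined as 0, so constant features get weight
exactly 0. pH is treated as 5 discrete classes rather than a numeric
target — the regression variant (RReliefF) is a different algorithm. Ties
in neighbor selection break on row index for reproducibility.

## Multigene GP

Function set {+, −, ×, ln, square} with ephemeral random constants in
[−10, 10]: the two nonlinearities are exactly those appearing in the
published surface, so that model class is expressible. Gene count ≤ 20 and
tree depth ≤ 10; a 20-gene cap only makes sense in a multigene
architecture, which is why models are weighted gene sums with the weights
fit by ordinary least squares at every evaluation (rank-deficient systems
fall back to a small ridge, logged). Fitness is training RMSE; selection
is size-10 tournament, with probability 0.1 replaced by a Pareto
tournament on (RMSE, total node count) to control bloat. Crossover
(p = 0.84) is half high-level (exchanging random gene subsets, truncated
to the gene cap) and half subtree crossover; mutation (p = 0.14) replaces
a random subtree; the remainder is reproduction; the top 10 % are copied
unchanged. Offspring violating the depth cap are retried up to 10 times,
then the parent gene is kept. A gene whose log argument is non-positive on
any training point gets infinite fitness rather than a silently patched
"protected log"; at prediction time the domain error propagates, naming
the offending gene. The best-ever individual (ties broken toward lower
complexity) is returned. All 180 records are used for training — no
validation split is part of the procedure — so `train_rmse` is a fit
statistic, not a generalization estimate.

## Metaheuristics

PO, POA and SBOA follow their original published update rules (parrot
foraging/staying/communicating/fear behaviors chosen uniformly at random;
pelican prey-approach then surface-winging with greedy acceptance;
secretary-bird three-stage hunting then escape, greedy). Where the sources
leave run settings open, defaults are population 30 and 100 iterations.
Out-of-bounds candidates are clamped to the box by default (`reflect` is
available); PO moves unconditionally and tracks the best-ever solution,
POA and SBOA accept only improvements. Candidates whose objective is NaN
are rejected. Each run records a best-so-far convergence curve, which is
non-increasing by construction, and is fully reproducible from its seed.

The deterministic cross-check, `grid_refine_minimize`, evaluates a full
lattice (2000 points per axis by default) and then refines the best point
by bounded 1-D minimization along each coordinate with a bracket of one
lattice spacing, halving until the point moves less than the tolerance.
Refinement accepts only strict improvements, so a minimizer on the domain
boundary (as the PEG coordinate here is) is returned exactly.

The published fitness expression is typeset flat; the grouping implemented
is −152·ln(x₁ + x₂ + ln x₂ + x₂²), with natural logs throughout. This
reading reproduces the published optimum values to ~2·10⁻⁶ at the
published minimizers, whereas reading the tail terms outside the
logarithm misses them by ~25.8 — a purely numerical disambiguation.

## ANOVA

Balanced two-way layout with interaction, computed from the textbook
sums-of-squares decomposition; F statistics refer MS_effect/MS_within to
the F distribution (p-values and critical values via its regularized
incomplete-beta representation in scipy, accurate well past the 10⁻⁶
contract). Unbalanced designs are rejected — the study design is balanced
(9 cells × 20) — and an all-constant response reports SS = 0 with NaN F
statistics rather than a spurious 0/0. Display rounding is 2 decimals;
full precision is kept internally. The replicates within a formulation
cell pool all five pH levels, so the pH effect deliberately sits in the
within-cell variance, as in the study design.

## Problem sizes used in the test suite

Unit tests run reduced GP budgets (population 40, 8 generations) — the
planted-linear recovery needs only a {x₁, x₂} basis plus least squares.
The end-to-end checks use the full study configuration: GP at population
100 × 50 generations across 10 seeds, metaheuristics at population 30 ×
100 iterations across 10 seeds, type-I-error calibration over 2000
simulated null datasets (3×3 cells × 3 replicates), and the 2000×2000
deterministic grid. The full suite completes in well under five minutes on
one CPU.

## Known limitations

* The stabilization rule is threshold-based; no changepoint or model-fit
  estimator is provided, by design.
* GP is stochastic: it recovers representable laws reliably, but there is
  no guarantee of rediscovering the published expression symbol-for-symbol
  from noisy data — that expression is therefore carried explicitly as the
  reference objective.
* The metaheuristic implementations follow the published update equations,
  but those papers leave minor details (e.g. boundary handling) open;
  clamping was chosen and is configurable.
* ReliefF distances use Manhattan on range-normalized features; other diff
  functions would reweight features with heavy-tailed distributions.
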