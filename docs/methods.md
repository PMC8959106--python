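# Methods

## Gait representation and the Fourier codec

A gait cycle is one stride of one joint, sampled uniformly on the
half-open grid u_i = i/L₀, i = 0..L₀−1 (so the 100% sample, which would
duplicate the 0% one, is never stored). The default L₀ = 101 follows the
standard time-normalization of clinical gait analysis (percent of cycle,
0–100). Cycles of other lengths are resampled by periodic linear
interpolation by default — robust for short, noisy recordings — with
FFT-based band-limited resampling available for clean band-limited
signals (`method="fourier"`).

The codec stores the amplitude–phase cosine series

θ(u) = a₀ + Σ_{h=1..n} a_h cos(2πhu − φ_h),   n = 3 by default.

Harmonics are integer multiples of the gait-cycle fundamental; because
the cycle period is fixed by the time normalization, the per-harmonic
free parameters are amplitude and phase, not frequency. Three harmonics
retain the gross shape of sagittal hip/knee/ankle waveforms (the knee's
swing-phase peak needs the second harmonic) while keeping the regression
targets few. Extraction uses the FFT of the resampled cycle: on a
uniform grid the DFT coefficients coincide with the least-squares
projection onto the truncated basis, so a₀ is the sample mean,
a_h = 2|X_h|/L₀ and φ_h = −arg X_h. Features are kept in a canonical
form (a_h ≥ 0, φ_h ∈ (−π, π]); canonicalization is a pure reparameterization
and never changes the waveform. Cycle segmentation (gait-event
detection) is out of scope: inputs are pre-segmented single cycles,
flexion positive, degrees.

## Anthropometry

Body parameters are a fixed 28-slot vector: 23 classical measurements
(leg length, knee diameter, malleolus width, …, waist circumference, in
cm) plus five configurable slots defaulting to height (cm), weight (kg),
age (years), sex (0/1) and walking speed (m/s). Before regression the
slots are z-scored with cohort means and population (1/N) standard
deviations; slots constant across a training cohort carry no information
and are flagged and excluded from the model input rather than treated as
an error, because small cohorts routinely tie on coarse measurements.

## Gaussian process regression

The anthropometry-to-feature map is learned with exact GP regression,
written from scratch (kernel, Cholesky-based evidence with analytic
gradients, bounded multi-start L-BFGS-B in log-hyperparameter space,
exact posterior). The kernel is squared-exponential with Gaussian
observation noise; both an isotropic and a per-dimension (ARD)
lengthscale variant are implemented. The pipeline default is isotropic:
with cohorts of ten to twenty subjects and 27–28 informative input
dimensions, one lengthscale per dimension is badly over-parameterized
(more hyperparameters than training points) and fits no better, so ARD
is left as an option for larger cohorts.

Numerical choices: targets are centred by their training mean (so the
posterior reverts to the cohort-average feature far from the data, which
is exactly the desired fallback — an out-of-range subject receives the
population-average gait); a jitter starting at 1e−10 and escalating
tenfold to at most 1e−4 is added before factorization; hyperparameter
bounds span three decades either side of the data scales (target SD for
σ_f and σ_n, median pairwise input distance for ℓ); five optimizer
starts by default, the first data-driven and the rest drawn log-uniform
within the bounds from the configured seed; numerically constant targets
short-circuit to a degenerate model predicting the constant. Predictive
variance is the latent (noise-free) variance, clamped at zero.

## The generation pipeline

Each joint contributes 2n+1 = 7 regression targets: a₀ and the Cartesian
harmonic components c_h = a_h cos φ_h, s_h = a_h sin φ_h. Phases are
never regressed directly — the 2π wrap would put an artificial
discontinuity into a smooth anthropometry-to-feature map, and averaging
phases across the wrap is meaningless; the Cartesian pair is smooth and
converts back exactly (a_h = √(c_h²+s_h²), φ_h = atan2(s_h, c_h)). One
independent GP per joint-target gives 42 models; left and right sides
are modeled independently (no symmetry constraint), matching the
convention of reporting them separately. Training data can be
partitioned into walking-speed sets, each with its own normalizer and
bank; the default is a single set, since any binning is cohort-specific.
Per-model seeds derive deterministically from the pipeline seed, so
training is bit-reproducible. Models serialize to JSON with exact float
round-trip; reloading reproduces predictions bit-identically.

`export_trajectory` resamples a generated cycle to a controller grid
(e.g. 1000 Hz over a configurable cycle duration) by periodic linear
interpolation; closed-loop control itself is out of scope.

## Evaluation

Leave-one-subject-out: for each held-out subject the full pipeline
(normalizer + 42 GPs) is retrained on the remainder and the subject's
six cycles are predicted from body parameters alone. Metrics are the
mean absolute error (degrees) and Pearson correlation between predicted
and actual cycles, both computed on the common L₀-grid; a subject's
trials are scored individually and averaged before the across-subject
mean and sample SD (n−1) are taken — the sample-SD convention is the one
that exactly reproduces the published clinical summary tables, so it is
used throughout. The comparison baseline predicts every held-out subject
with the training-mean feature vector, i.e. the population-average gait:
beating it is the operational meaning of "individualized".

## Synthetic cohorts

No public paired anthropometry/gait database exists at this scale, so
the pipeline's test bed is a generator with known ground truth. Body
parameters are drawn uniformly from plausible adult ranges (height
153–174 cm and weight 51–90 kg span a typical small rehabilitation
cohort; sex is Bernoulli(½)). True coefficients are a canonical-walk
template (hip ≈ ±25° dominated by the fundamental, knee ≈ 0–60° with a
strong second harmonic, ankle ≈ ±15°; left/right differ slightly) plus
an effect map, linear in the centred slots by default (e.g. knee a₁
+0.5°/cm of thigh length, hip a₁ +6°/(m/s) of walking speed, a small
negative age effect), with a quadratic option to exercise the GP's
nonlinearity. Observed cycles are the reconstructed waveforms plus
i.i.d. Gaussian noise, default SD 0.5° per sample — the order of joint
encoder noise. Cycles are synthesized directly on the L₀-grid so that
noise-free extraction recovers the truth exactly.

The template constants are synthetic, shaped like normal sagittal gait;
they are not measured data. What the generator does not emulate:
intra-subject stride-to-stride variability structure (noise is white),
pathological asymmetries, kinematic constraints between joints, and
ground-contact dynamics. Passing the recovery tests therefore shows the
pipeline can learn a smooth anthropometry-to-gait map in the presence of
measurement noise — not that real hemiplegic gait is this predictable.

Default cohort size is 20 subjects: large enough for the GP to beat the
population-mean baseline on every joint, small enough that the full
leave-one-out run (20 retrainings × 42 GPs) completes in well under a
minute. With six or fewer subjects the posterior reverts toward the
cohort mean and the individualized prediction approaches (but should
never substantially exceed) the baseline error; the ankle's margin over
the baseline is the slimmest at any size because the default effect map
gives ankle coefficients the weakest anthropometry dependence relative
to the noise.

Synthetic clinical sessions draw per-session baselines (SpO₂ 97–99%, HR
75–105 bpm) and before/after changes from session-specific normal
distributions calibrated to the published nine-patient trial (SpO₂
−2.33/−0.78%, HR +10.78/+5.67 bpm; SDs recomputed from the per-subject
values). The published tables constrain only the marginals, but a paired
design implies within-subject correlation of responses across days; a
between-session correlation of 0.6 (a shared subject-level
responsiveness) is assumed, which reproduces a paired-difference SD near
the one observed in the real table. Values are kept continuous (real
monitors round to integers; rounding would discretize the test
statistics without changing any conclusion at these SDs).

## Clinical statistics

Variations are signed (after − before): a "decrease of 2.33%" is a mean
variation of −2.33. Summaries use the sample SD, validated by exact
agreement with three of the four published SDs; the fourth (general-
session SpO₂, printed 1.1414) is inconsistent with its own per-subject
values, which recompute to √2 ≈ 1.4142 (a plausible digit transposition)
— the tool reports the recomputed value and flags the discrepancy rather
than replicating it. The between-condition comparison is a two-sided
paired t-test on per-subject (general − individualized) changes, with an
exact Wilcoxon signed-rank alternative (zeros dropped, average ranks for
ties, null distribution by exact sign-flip enumeration via dynamic
programming for n ≤ 25, tie-corrected normal approximation beyond).
The source study does not name its test; on the packaged tables both
tests reject at α = 0.05 for both measures, so the headline conclusion
is test-robust. No causal or physiological model is implied — the module
computes descriptive and paired statistics only.

## Known limitations

- Three harmonics cannot represent sharp transients (e.g. heel-strike
  spikes); raise `n_harmonics` if the data warrant it.
- Isotropic lengthscales treat all z-scored body parameters as equally
  relevant a priori; relevance determination needs more subjects than
  the cohorts targeted here.
- The leave-one-out protocol retrains the entire bank per fold; cost
  grows quadratically-ish with cohort size and linearly with folds.
- Fixed hyperparameter bounds can clip the optimum for targets whose
  scale is dominated by a single outlier subject.
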