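# Methods

## The model

Each brain region *i* of an N-region network is a Stuart–Landau oscillator —
the normal form of a supercritical Hopf bifurcation — written in real
coordinates z_i = x_i + i·y_i and coupled diffusively through a structural
connectome C:

    dx_i/dt = (a_i − x_i² − y_i²)·x_i − ω_i·y_i + G·Σ_j C_ij·(x_j − x_i) + β·η_i(t)
    dy_i/dt = (a_i − x_i² − y_i²)·y_i + ω_i·x_i + G·Σ_j C_ij·(y_j − y_i) + β·η_i(t)

For a_i < 0 the node fluctuates noisily around a stable fixed point; for
a_i > 0 it oscillates on a limit cycle of radius √a_i at angular frequency
ω_i.  The x component stands in for the regional BOLD signal.  The
per-region bifurcation parameters a = {a_i} and the global coupling G are
the quantities the package infers from data.

### Numerical integration

Euler–Maruyama with step dt = 0.1 s by default; the x output is sampled
every TR after a discarded burn-in (default 60 s).  Noise is drawn
independently for the x and y equations of every region (the independence
is an assumption; the model statement does not resolve it).  Integration
aborts with a named-step error if any |z| exceeds 1e6; because the explicit
Euler map is unstable for |a| ≳ 10 at dt = 0.1 s, both fitters clamp their
parameter search to [−6, 6].

**Noise convention.**  The model's noise level is conventionally quoted as
"SD 0.02" without an integration scheme.  This package interprets that
number as the standard deviation of the additive noise received by one
Euler step at the reference resolution dt = 0.1 s, i.e. a diffusion
coefficient β = 0.02/√0.1 ≈ 0.0632 s^(−1/2) (`DEFAULT_NOISE_SD`); the
integrator itself scales noise by β√dt, so refining dt remains meaningful.
The alternative reading (β = 0.02 as the diffusion coefficient) produces a
nearly deterministic, fully phase-locked system in which the FCD
distribution degenerates and the gradient-descent fit cannot operate on the
documented timescale of tens of iterations; the per-step reading reproduces
that documented behaviour, which is why it is the default.  Users with a
different convention can pass any β explicitly.

## Features guiding the fit

* **fALFF** — fraction of the amplitude spectrum (square root of the
  single-taper periodogram of the demeaned signal) lying in the
  low-frequency band, default 0.01–0.1 Hz, relative to a total band of
  (0, Nyquist].  Dimensionless, scale-invariant, in [0, 1].
* **ALFF** — mean in-band amplitude (signal units; scales with the signal).
* **Power ratio p** — same ratio as fALFF computed on squared amplitudes.
  The distinction between the amplitude-sum (fALFF) and power-sum (p)
  ratios is this package's documented interpretation; the upstream
  empirical features came from external preprocessing that does not print
  formulas.

The adaptive fitter guides its gradient with fALFF because, across
simulations with known parameters, fALFF of the variance-normalized signal
tracks the bifurcation parameter better than ALFF or p at the node, mean
and range levels (the `feature_parameter_study` reproduces this ordering).
The fALFF–a relation is sigmoidal: it saturates for |a| beyond roughly 1,
which bounds how much information any feature-guided method can extract
about strongly sub- or supercritical regions.

## Functional connectivity dynamics (FCD)

Phases are the analytic-signal (Hilbert) phases of the 0.01–0.1 Hz
band-passed, demeaned signal.  The phase-interaction matrix at time t is
P_ij(t) = cos(φ_i(t) − φ_j(t)) — the standard choice in the FCD literature,
adopted here because the construction is inherited from prior work without
a printed formula.  Sliding windows of 30 TRs with a 1-TR stride average
P(t) elementwise; windows that do not fit are dropped, never padded.  The
M×M FCD matrix holds cosine similarities between the vectorized
(upper-triangle, diagonal excluded — the constant diagonal would only
inflate similarity) window means, and the distribution of its
upper-triangle values is the dynamical fingerprint.  Distributions are
compared with the two-sample Kolmogorov–Smirnov (KS) statistic.  The "mean
FCD" used by the fitter's gradient correction is the mean of that value
multiset.

## The fitting pipeline

1. **Global coupling scan.**  With a ≡ 0 (criticality), G is scanned over
   0–2 in steps of 0.1; each grid point simulates with a fixed derived seed
   and the KS distance to the empirical FCD distribution is recorded; the
   argmin wins (earliest on ties).  On data generated at criticality the
   KS-vs-G curve is U-shaped and recovers the generating G to within about
   one grid step.  On strongly heterogeneous data the critical model family
   cannot mimic the empirical FCD for any G and the scan becomes
   uninformative; the intended workflow therefore averages per-subject
   optima into one group-level G (`group_coupling`) and fixes it for the
   per-region fits, and the synthetic-validation harness defaults to the
   fixed group value.
2. **Homogeneous initialization scan.**  At the fixed G, a homogeneous a0
   is scanned (default −0.05…0.05, step 0.01; a wider −0.075…0.05 step
   0.005 grid is accepted via configuration) and the KS argmin seeds the
   heterogeneous fit.
3. **Adaptive gradient descent.**  Per iteration t: simulate with the
   current â_t (one stochastic realization by default;
   `realizations_per_iter` averages several), mean-scale both empirical and
   simulated fALFF (x/mean(x); mean scaling preserves the between-region
   ratios the heterogeneous parameters encode, whereas z-scoring and
   min-max are outlier-sensitive), and update

       â_{t+1} = â_t + η·(f_emp − f_sim_t + mean FCD_emp − mean FCD_sim_t)

   The scalar FCD-mean correction exploits the positive correlation between
   mean FCD and mean a: a too-static simulation pushes the whole vector up,
   a too-synchronized one pushes it down.  Diagnostics recorded per
   iteration: KS_t, conv_t = max|f_emp − f_sim_t|, corr_t = corr(â_t, f_emp)
   (defined as 0 when â_t is constant, as at the first iteration).
4. **Loss-based iteration selection.**  Because of the sigmoidal
   feature–parameter relation, conv_t plateaus noisily and threshold
   stopping is fragile.  Instead every iteration is scored by the
   approximate loss

       L_t = z(KS_t) + z(conv_t) + z(−corr_t)

   (z = standardization across iterations) and the argmin iteration is the
   fit.  The correlation term is entered negated so that higher corr_t
   lowers the loss; written with +corr_t the term would penalize exactly
   the qualitative agreement it is meant to reward, contradicting its
   motivation, so the negated form is used and flagged here.  On synthetic
   data, where a* is known, the actual loss z(mean|a*−â_t|) + z(1−corr(a*,â_t))
   is the benchmark; a 1-iteration trajectory gets loss [0], and an exactly
   constant component raises an error rather than dividing by zero.
5. **Traditional baseline.**  â ≡ 0 start, gradient on the raw power ratio
   p with a fixed global learning rate, stopping when max|p_emp − p_sim| < r.
   Neither r nor the rate is documented upstream; the defaults (rate 2,
   r = 0.05) were chosen once so the baseline iterates stably (the p–a
   slope is shallow, so rates below ~10 are fixed-point stable) and are
   deliberately not tuned further.

### Learning rate

The individualized prescription — η equal to half the regional SD of the
subject's fALFF — is exposed as `learning_rate_mode="half_sd_falff"`.  With
mean-scaled fALFF that SD is of order 0.05–0.1, giving steps of ~0.005 per
iteration: an order of magnitude too slow to traverse the bifurcation
range [−4, 4] within the tens-to-hundreds of iterations over which the
loss selection demonstrably operates.  The default is therefore a fixed
η = 0.5 on the mean-scaled features, which restores the documented
convergence timescale (interior loss minima around iterations 30–250);
the individualized mode remains available for data whose feature spread
matches its assumptions.

## Synthetic ground truth

`synth` owns the study conditions:

* **Connectomes** — Watts–Strogatz graphs, N = 90, 35% density (ring-lattice
  degree = nearest even integer to density·(N−1)), rewiring probability
  0.35 by default (0, 0.35, 0.5 and 1 are all exercised), independent
  exponential edge weights (rewired edges get fresh draws); Barabási–Albert
  graphs with m = round(density·(N−1)/2) provide a scale-free alternative
  (realized density below target; reported, not forced).
* **Weight scale** — the generator normalizes to mean node strength 0.6
  rather than maximum 0.3.  Only the product of G and node strength enters
  the dynamics, and exponential-weight graphs max-normalized to 0.3 carry
  3–4× the strength of the heavy-tailed empirical tractography matrices
  the 0.3 convention comes from, which would park G ≈ 1 deep in the
  phase-locked regime.  Strength 0.6 places the critical (a = 0) system's
  synchronization transition at G ≈ 1.2, inside the standard scan range,
  mirroring the empirical situation.  `normalize_max(0.3)` remains the
  pipeline step for real SC matrices.
* **Ground truth** — per subject, x1 ~ U(−4, 0) and x2 ~ U(0, 4) are drawn,
  then a*_i ~ U(x1, x2) (the printed ranges are garbled upstream; this is
  the adopted reading, and both stages are configurable).  ω_i ~ 2π·U(0.01,
  0.1) rad/s; G* = 1 (the value used in the synthetic experiments; the
  empirical application used 1.5); noise per the default convention.
* **Series** — T = 200 TRs at TR = 2 s by default: the scale of the
  empirical recordings and small enough for desk-scale ensembles.

The recovery harness gives the fitter the generating ω and the group-level
G, so its errors measure the inference of a, not frequency estimation.

### What the generator does *not* emulate

Hemodynamics (no balloon model — x is the signal), measurement noise,
head-motion artifacts, preprocessing residue, inter-subject connectome
variability beyond graph randomness, and parcellation effects.  Passing
recovery here shows the inference machinery is correct and characterizes
its intrinsic limits; it does not certify accuracy on empirical BOLD.

## Known limitations (measured, not hidden)

* **Feature information ceiling.**  corr(a*, fALFF_emp) is the effective
  ceiling on corr(a*, â).  Subjects whose a* spans both signs reach
  ceilings of 0.85–0.95; subjects drawn with x2 ≈ 0 (all-subcritical, a
  ~12% event under the two-stage sampler) have ceilings near 0.1–0.4
  because the saturated feature carries almost no information.  Ensemble
  mean correlations therefore settle around 0.55–0.75 at T = 200, with the
  fitter operating essentially at the ceiling.
* **KS floor.**  Re-simulating at the true a* against the "empirical"
  realization yields mean KS ≈ 0.13 at T = 200 (window count M = 171):
  the finite-sample KS of concentrated FCD distributions does not reach
  0.1 even for an oracle; fitted values land around 0.15–0.3 depending on
  how many strongly synchronized subjects the sampler draws.
* **Loss-argmin jitter.**  With one stochastic realization per iteration
  both losses have broad, noisy minima; the *iterations* selected by the
  approximate and actual losses can differ by tens even when the selected
  *parameter vectors* are nearly equivalent.  The agreement claim holds at
  the level of loss landscapes, not argmin indices, at these run lengths.
* Sign recovery for |a*| > 0.5 and the direction of every
  adaptive-vs-traditional aggregate are robust across ensembles.

## Group statistics

Welch's unequal-variance t-test per region (the variant is this package's
choice), Benjamini–Hochberg step-up FDR, Cohen's d with the classical
pooled-SD estimator, and the significance rule p_FDR < 0.05 together with
|d| > 0.25.  Confusion-matrix metrics return NaN for a zero denominator
without poisoning the other metrics.  The SVM wrapper (stratified 5-fold
CV, z-scoring fit on training folds, minority oversampling by
with-replacement duplication, RBF grid C ∈ {1,10,100,1000},
γ ∈ {1e-4…1e-1}) is a thin convenience over scikit-learn, not a
contribution.

## Numerical and reproducibility choices

* All randomness flows from integer seeds through `numpy` SeedSequences;
  per-iteration and per-grid-point simulator seeds are derived
  deterministically and recorded in the trajectory, so any fit replays
  bit-identically.
* Butterworth order-4 zero-phase (forward–backward) band-pass; filtering
  to (0, Nyquist) is a pass-through apart from demeaning.  An optional
  `trim_s` argument drops filter edges; the default keeps the full series
  so empirical and simulated FCD window counts always agree.
* Proportional thresholding keeps ceil(fraction · N(N−1)/2) upper-triangle
  entries, ties broken by (weight desc, row asc, column asc), then mirrors,
  preserving symmetry.
* Cosine similarities are clipped to [−1, 1] against rounding; the FCD
  matrix is symmetrized and its diagonal pinned to exactly 1.
* Ensemble sizes in the shipped tests and the acceptance script (10–20
  subjects, 200 TRs, 300 iterations) are desk-scale choices that keep a
  full validation run in minutes; the harness accepts larger values.
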