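# hopffit

Adaptive parameter fitting for Hopf (Stuart–Landau) whole-brain models of
resting-state BOLD dynamics.

## What problem this solves

Whole-brain computational models place one oscillator per brain region on a
structural connectome and let global dynamics emerge from local dynamics
plus anatomy.  In the Hopf model each region *i* obeys the normal form of a
supercritical Hopf bifurcation,

    dz_i/dt = (a_i + iω_i − |z_i|²)·z_i + G·Σ_j C_ij·(z_j − z_i) + β·η_i(t),

so a single per-region number a_i says whether the region sits in a noisy
fixed-point regime (a_i < 0), at criticality (a_i ≈ 0), or on a limit cycle
(a_i > 0).  Fitted to a subject's BOLD recording, the vector {a_i} and the
global coupling G are compact, interpretable descriptions of regional
dynamics — usable for group comparisons and as classification features in
clinical research.

Fitting those parameters reliably is the hard part.  This package
implements and validates an adaptive pipeline:

1. **Initialization** — scan G (0–2, step 0.1) at criticality and a
   homogeneous a₀ (−0.05–0.05, step 0.01), each by minimizing the
   Kolmogorov–Smirnov (KS) distance between empirical and simulated
   functional-connectivity-dynamics (FCD) distributions;
2. **Adaptive gradient descent** on the per-region parameters, guided by
   the mismatch of mean-scaled fALFF (fractional amplitude of low-frequency
   fluctuations) with a scalar correction from the mismatch of FCD means:
   Δa_t = η·(f_emp − f_sim_t + mean FCD_emp − mean FCD_sim_t);
3. **Loss-based iteration selection** — every iteration is scored by an
   approximate loss, z(KS_t) + z(conv_t) + z(−corr_t), and the arg-min
   iteration is the fit, avoiding fragile convergence thresholds;
4. **Validation by parameter recovery** — synthetic subjects with known
   ground-truth parameters on Watts–Strogatz / Barabási–Albert connectomes
   quantify recovery accuracy and the improvement over the traditional
   threshold-stopping baseline.

It is aimed at computational-neuroscience researchers who want a tested,
reproducible implementation of the method plus the synthetic machinery to
probe when it can and cannot work.  See `docs/methods.md` for the model,
the conventions, and the method's measured limits.

## Worked example

Fit one synthetic subject end to end:

```python
import numpy as np
from hopffit import FitConfig
from hopffit.synth import NetworkSpec, make_ground_truth, synthesize_subject
from hopffit.fitting import scan_homogeneous_a, adaptive_fit

truth = make_ground_truth(NetworkSpec(n=90), seed=1)      # a*, C, omega, G*
emp, template = synthesize_subject(truth)                 # 200 TRs at TR=2s

cfg = FitConfig(seed=1)
a0 = scan_homogeneous_a(emp, truth.network, truth.G_star, sim=template, cfg=cfg)
traj = adaptive_fit(emp, truth.network, truth.G_star, a0.opt, cfg, template)

print(f"selected iteration {traj.selected_iter}, KS {traj.ks_selected:.3f}")
print(f"corr(a*, a_hat) = {np.corrcoef(truth.a_star, traj.a_selected)[0,1]:.3f}")
```

prints:

```
selected iteration 114, KS 0.093
corr(a*, a_hat) = 0.925
```

The selected iteration sits well inside the 300-iteration budget (the loss
found an interior optimum), the FCD distributions match to KS ≈ 0.09, and
the recovered parameter pattern correlates 0.93 with the generating truth.
Subjects whose ground truth never crosses criticality carry less spectral
information and recover with lower correlation — `docs/methods.md`
quantifies this ceiling.

The same pipeline runs from the shell on delimited-text inputs:

```sh
hopffit netgen --model ws --n 90 --seed 1 --out sc.tsv
hopffit simulate --sc sc.tsv --a 0.0 --g 1.0 --seed 2 --out bold.tsv
hopffit fit --ts bold.tsv --sc sc.tsv --tr 2.0 --g auto --out fitdir/
```

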