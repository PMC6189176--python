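# substage

**Subtype and Stage Inference for cross-sectional biomarker cohorts.**

Neurodegenerative diseases are heterogeneous in two ways at once: different
patient subgroups follow different progression patterns (*phenotypic*
heterogeneity), and a cross-sectional cohort samples every subgroup at every
point along its course (*temporal* heterogeneity). Clustering methods model
the first and ignore the second; disease-progression models do the
opposite. `substage` implements the model known in the field as **SuStaIn**
(Subtype and Stage Inference), which disentangles both from purely
cross-sectional data: it simultaneously discovers disease *subtypes* — each
defined by the order in which biomarkers reach z-score milestones — and
*stages* every subject along their subtype's course. It is aimed at
researchers working with control-referenced scalar biomarkers (regional
brain volumes, CSF or cognitive measures) who want data-driven patient
stratification with honest uncertainty.

## The model

Each biomarker `i` is expressed as a z-score relative to controls and
carries thresholds `z ∈ {1, 2, 3}` plus a cap `z_max,i`. The `N = Σ_i R_i`
threshold crossings are *events*; a subtype is an ordering `S` of all N
events. On a model-time axis `t ∈ [0, 1]` the event at position `k`
completes at `t = (k+1)/(N+1)`, and biomarker means follow the
piecewise-linear trajectory `g_i(t)` through those milestones. With
Gaussian noise `σ_i` and a uniform prior over the latent time, one subtype
explains the data as

    P(X | S) = Π_j  Σ_{k=0}^{N}  ∫_stage_k  Π_i N(x_ij ; g_i(t), σ_i) dt ,

and a cohort is a mixture over `C` subtypes, `P(X | M) = Σ_c f_c P(X | S_c)`.
Fitting is greedy E-M over event positions with 25 random restarts, grown
hierarchically in `C` by cluster splitting; uncertainty in each subtype's
ordering comes from MCMC over admissible sequences; the number of subtypes
is selected by the cross-validation information criterion
`CVIC = −2 × out-of-sample log-likelihood` with a 6-unit parsimony rule;
subjects are then assigned a subtype, a stage, and a strength of
assignment, integrating over the MCMC samples. See `docs/methods.md` for
the full account.

## Worked example

Simulate a two-subtype cohort with known ground truth, fit the hierarchy,
sample the posterior and subtype/stage every subject:

```python
import numpy as np
import substage as ss

cfg = ss.canonical_two_subtype_config(n_subjects=500, seed=42)
data, truth, truth_model = ss.simulate_cohort(cfg)

fits = ss.fit_hierarchical(data, cfg.event_set, truth_model.noise,
                           c_max=2, n_restarts=25, seed=1)
model = fits[-1].model
print("log-likelihood per C:", [round(f.log_likelihood, 1) for f in fits])
print("fractions:", np.round(model.fractions, 3))

samples = ss.mcmc_sample(data, model, n_samples=100_000, seed=3)
pos = ss.positional_distribution(samples)
assignments = ss.assign_subjects(data, samples, cfg.event_set,
                                 truth_model.noise)
report = ss.recovery_report(truth, truth_model, model, positional=pos,
                            assignments=assignments, min_t=0.2)
for k in ("assignment_accuracy", "fraction_error", "stage_spearman"):
    print(k, round(report[k], 3))
```

This prints

```
log-likelihood per C: [-5006.7, -4382.8]
fractions: [0.509 0.491]
assignment_accuracy 0.962
fraction_error 0.009
stage_spearman 0.951
```

— the two-subtype model improves the fit by ~620 log-likelihood units over
a single progression pattern, recovers the 50/50 subtype fractions to
within 0.01, assigns 96% of progressed subjects (true `t > 0.2`) to the
correct subtype, and its stages track the true disease times with Spearman
ρ ≈ 0.95. `truth` carries each simulated subject's generating subtype,
disease time and stage, which is what `recovery_report` scores against.

A command-line pipeline wraps the same steps for CSV cohorts
(`substage simulate | fit | crossval | assign | plot`); run
`substage --help` for the flags. Raw-volume inputs are control-referenced
(covariate regression, z-scoring, sign flip) before event selection;
already-z-scored tables skip that with `--zscored`.

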