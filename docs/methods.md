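# Methods

## Model and assumptions

The analysis treats free phenylalanine as a single well-mixed pool fed by
two pathways and drained by one consumption flux:

* **v₁** — plastidial arogenate pathway, produces unlabelled phenylalanine
  when the tracer is ¹⁵N-tyrosine (tyrosine is not an amino donor for the
  plastidial aminotransferase);
* **v₂** — cytosolic phenylpyruvate pathway, uses tyrosine as amino donor
  and is the only entry route of the ¹⁵N label;
* **v_c** — consumption into phenylalanine-derived volatiles, assumed
  constant over the window and measured by cumulative emission.

Balances: dC/dt = v₁ + v₂ − v_c and d(fC)/dt = v₂·f_Tyr − v_c·f, with C the
pool (nmol·gFW⁻¹), f its ¹⁵N fraction and f_Tyr the tyrosine ¹⁵N fraction.
Assumptions inherited from the experimental design: tyrosine labelling is at
pseudo-steady state (>0.8 within 2 h), so f_Tyr enters as the arithmetic
mean of its post-feeding observations; C(t) and f(t) are affine over 0–6 h;
compartment-resolved pools are not identifiable from these data and are not
modelled. Labelled material leaves the pool in proportion to the current
enrichment f (well-mixed consumption).

Because the two trends are affine, the labelled-pool rate is the exact
product rule d(fC)/dt = f·(dC/dt) + C·(df/dt) — no finite differences.  A
config switch (`enrichment_balance="enrichment_only"`) replaces it by
C·(df/dt) for sensitivity analysis, i.e. drops dilution of enrichment by
pool growth from the balance; the full product rule is the default and is
what the conservation identity v₁+v₂−v_c = dC/dt is checked against.

## Trend estimation

Intercepts are measured t = 0 values and are held fixed, leaving the
one-parameter least-squares slope b = Σtᵢ(yᵢ−y₀)/Σtᵢ².  Residual variance
uses n−1 degrees of freedom (one parameter estimated); slope variance is
SSR/(n−1)/Σtᵢ².  Fitting is per biological replicate by default, with a
pooled mode (all replicate points in one fit per genotype, intercept = mean
of the replicate t₀ values, replicate values tied at the same harvest time
averaged) provided because the published design is compatible with either
reading; neither is asserted as "the" original
procedure.  Cumulative emission is fit through zero; a decreasing cumulative
series warns by default (noise can produce small decreases) and raises in
strict mode.

## Flux inversion and summaries

v₂(t) = [d(fC)/dt + v_c·f(t)]/f_Tyr and v₁(t) = dC/dt − v₂(t) + v_c are
evaluated every 0.1 h (6 min) over [0, 6] h (61 points; configurable).
Endpoint summaries (t₀, t₆), v₂/v₁ ratios and percent changes are read off
the grid endpoints of the same trajectories, not refit.  Negative flux
estimates are reported with a warning and never clipped — clipping would
silently violate the conservation identity.  Division by f_Tyr ≤ 0 is a
hard error.

## Error propagation

First-order (delta-method) propagation over independent inputs:
Var(y) = Σ(∂f/∂xᵢ)²·Var(xᵢ).  Random inputs are the two slopes and v_c;
f_Tyr's variance (sample variance of its mean) is included by default and
can be toggled off, since which inputs the original analysis propagated is
not documented.  Intercepts are constants and contribute nothing.  No
covariance terms: the slopes come from disjoint series.  The analytic
variances are validated against a seeded Monte-Carlo resampler (normal
draws at the point estimates; fractions outside (0, 1] rejected and
redrawn), which agrees within 5% at CV 2% inputs and 10⁵ draws.  The
genotype-mean flux carries SE = √(Σᵢ Varᵢ)/n over replicates — this is the
standard error the package reports and the one its coverage checks use.

## Genotype comparison

Absolute fluxes at matched times: Welch (unequal-variance) two-tailed
t-tests on per-replicate estimates, Bonferroni-corrected over the family of
comparisons performed (default m = 4 per genotype pair: v₁ and v₂ at t₀ and
t₆).  Welch is the safer default for the unbalanced n = 3 vs n = 6 design;
a pooled-variance path exists via the pooled fitting mode (z-style statistic
on delta-method variances).  Trend of v₂: genotypes are unpaired, so a
literally paired test of slopes is not well defined; the default compares
per-replicate v₂ slopes (OLS over the grid) as independent samples, and an
explicit `paired_times` mode pairs genotype-mean v₂ values at matched grid
times — each result records which mode produced it.  Perturbed lines that
do not have their own usable emission series get v_c = control v_c × mean
fractional emission (configured per genotype); its variance scales by the
squared fraction.

## Synthetic data generator

The generator defines the study conditions; its defaults are fixed once:

| parameter | default | meaning |
|---|---|---|
| sampling times | 0 (intercepts), 2, 4, 6 h | harvest design |
| pool_t0 / pool_slope | 100 / 5 nmol·gFW⁻¹(·h⁻¹) | linear pool rise |
| frac_t0 / frac_slope | 0 / 0.009 h⁻¹ | linear labelling rise |
| f_tyr plateau | 0.85 | ">80% within 2 h" pseudo-steady state |
| v_c | 10 nmol·gFW⁻¹·h⁻¹ | constant consumption |
| cv_pool, cv_emission | 0.05 | multiplicative noise on concentrations |
| sd_fraction | 0.01 | additive noise on fractions, clipped to [0,1] |
| replicates | 3 control / 6 perturbed | unbalanced design |

Noise magnitudes are package defaults chosen as realistic for LC-MS pool
and enrichment measurements; the source study reports no noise model.  The
default control parameters give v₂/v₁ ≈ 0.18 at t₆ and the default
perturbation (v1_scale 0.68, v2_slope_scale 1.7, vc_fraction 0.7) gives v₁
32% lower at t₀, ≈38% lower at t₆ and a t₆ ratio ≈0.45 — the qualitative
pattern of an export-impaired line.

**exact_linear mode** emits exactly affine observables, so the estimator's
assumptions hold identically and zero-noise recovery is exact (the central
oracle).  **mechanistic mode** prescribes affine v₁(t), v₂(t) and integrates
the balances with fixed-step RK4 (step 0.005 h), checked against the
closed-form solution f(t) = (v₂f_Tyr/v_c)(1−e^{−(v_c/C₀)t}) for constant
fluxes with balanced pool; it probes robustness when linearity only
approximately holds.  Intercept rows are emitted noise-free: the estimator
treats t = 0 values as known constants, and exact_linear's role is to make
that assumption literally true.  What the generator does **not** emulate:
compartmentation, feedback inhibition kinetics, label recycling into
tyrosine, heteroscedasticity structure of real LC-MS beyond a constant CV,
and replicate-to-replicate biological parameter variation.  Passing tests
therefore demonstrate correctness of the estimator under its own
assumptions and mild violations, not unbiasedness on arbitrary real data.

**Genotype-pair construction.**  To keep the perturbed genotype inside the
exact-linear family (so the oracle stays exact), perturbations act in
parameter space: v_c is scaled by the emission fraction, df/dt by the trend
factor, and dC/dt is solved so that v₁(0) is scaled exactly.  Pointwise
scaling of v₁(t) at every t would generally make dC/dt time-varying, which
the affine family cannot represent; the difference only matters when the
labelling trend is nonzero, and vanishes for flat-v₂ scenarios.

## Numerical choices and edge cases

* Grid: 61 points at 0.1 h; summaries use endpoints; `at()` matches grid
  times to 1e-9 h.
* Degenerate designs (all times zero, <2 points) and empty series are
  errors; duplicate (genotype, replicate, variable, time) rows are rejected,
  never averaged; `frac_*` values above 1 are rejected, never rescaled.
* Zero-variance groups in t-tests: identical means → t = 0, p = 1;
  separated means → p = 0 (the limit of vanishing jitter).
* Monte-Carlo determinism: one `numpy` Generator per call, seeded.
* Calibration/coverage simulations in tests run at grid step 0.5 h: the
  endpoint fluxes are identical for any grid containing 0 and 6 h because
  trajectories are affine in time.

## Known limitations

* The reported ±2 s.e. interval for a genotype-mean flux covers the truth
  in ~90% of repeats under the default conditions, not 95%: slope variances
  come from 3-point fits (2 df) and the multiplicative pool noise is mildly
  heteroscedastic while the fit assumes constant variance.
* With n = 3 control replicates the v₂-trend test has limited power for
  trend contrasts below ~2×.
* Negative flux estimates can occur under noise and are reported as such.
* The pooled fitting mode treats pooled points as one series; it does not
  model between-replicate variance components (no mixed models).
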