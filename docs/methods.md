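# Methods

This note documents the statistical models, the synthetic-data generator, the
numerical choices, and the known limitations of `psen1traj`.

## The cross-sectional trajectory model

Each outcome (MMSE, CDR-SB, ICV-adjusted bilateral hippocampal volume,
composite PiB SUVR, CSF analytes) is modelled on participant-visit rows as a
linear mixed-effects model over EYO (expected years to symptom onset):

```
y_ij = Xb + u_family + e,   u ~ N(0, s2_f),  e ~ N(0, s2_e)
```

Fixed effects: intercept; age at visit; sex (F reference); APOE e4 carrier
status (non-carrier reference); years of education for the cognitive/clinical
outcomes only; the EYO basis; group indicators (NC reference; CY reference for
carrier-only designs; pre-200 reference for the codon grouping); and the
interaction of each group indicator with each EYO basis column. The single
random intercept is on family membership — siblings share expected onset age,
genetics, and environment.

**EYO basis.** Either linear, or a restricted cubic spline with knots at the
0.10/0.50/0.90 empirical quantiles of the pooled EYO of the rows entering that
outcome's model (configurable to carrier-only placement). With three knots the
spline contributes the linear column plus exactly one nonlinear column, so
"linear EYO x group" and "cubic EYO x group" each name a single coefficient.
The basis uses the truncated-power natural-spline construction normalized by
(t_k - t_1)^2, so all columns share the scale of EYO; nonlinear columns are
identically zero at or below the first knot and the fitted function is exactly
linear beyond the boundary knots.

**Estimation and inference.** Maximum likelihood (not REML) throughout, so the
likelihood-ratio test between the linear and spline fixed-effect structures is
valid and reported estimates come from the same fit that was compared. The
spline form is retained when the LRT p-value is below 0.05 (configurable); the
added degrees of freedom are the nonlinear column plus its group interactions.
Wald tests on coefficients use the asymptotic normal reference rather than a
Satterthwaite/Kenward-Roger degree-of-freedom correction — a deliberate
simplification, adequate at the cohort sizes simulated here, and the reason
very small p-values are reported on the order they are. The TM-vs-CY contrast
is available both as a linear contrast of the NC-reference coefficients and by
refitting with CY as the reference level; the two agree to numerical
precision and a test enforces it. Benjamini-Hochberg step-up adjustment is
applied to the CSF analytes' p-values (the package authors its own vectorized
step-up; a unit test cross-checks it against `statsmodels.multipletests` and
an enumeration oracle).

Age at visit and EYO are both included by default (both are listed model
covariates); they are correlated but not collinear because expected onset age
varies across families. A warning fires if their correlation exceeds 0.97 and
a config switch drops either.

## Divergence-point estimation

The question "when do TM and CY trajectories separate?" is answered on the
posterior of the same mixed model. Priors are weakly informative:
normal(0, (10 x sd_y)^2) on every fixed effect and half-normal(5 x sd_y) on
both SD components (configurable). Because the model is linear-Gaussian, the
coefficient vector integrates out of the likelihood in closed form; the
sampler therefore alternates

1. univariate slice-sampling updates of log sigma_family and log sigma_resid
   on the marginal posterior (coefficients integrated out), and
2. an exact multivariate-normal draw of the coefficients given the variances,

using the family-block structure of the marginal covariance (Sherman-Morrison
per family) so each marginal-likelihood evaluation is O(n p + F p^2). This is
a valid MCMC scheme with near-independent draws — effective sample sizes are
close to the number of kept iterations — and it is exactly reproducible from a
seed. Four chains are run by default; split-chain R-hat and bulk ESS (ArviZ)
are attached to every draw set, and sampling raises (carrying the diagnostics)
if R-hat exceeds 1.1. A posterior-agreement test requires posterior means
within 0.1 SE of the ML estimates on a moderate cohort.

The TM-CY difference curve is evaluated per draw on an EYO grid (default -25
to +10 by 0.1 y, clipped to the observed EYO support; extrapolated divergences
are refused). All covariate terms cancel in the difference, so no reference
covariate values are needed. The divergence point is the earliest grid EYO at
which the equal-tailed credible interval (default level 0.99; HPD not
implemented) excludes zero **and keeps excluding it at every later grid
point**. The persistence rule resolves what "first point of exclusion" should
mean when tails of the spline wiggle: a transient excursion that returns to
overlap zero does not count as divergence onset.

**Detection lag — an intrinsic limitation.** A calibrated credible-exclusion
estimator cannot flag a divergence until the true gap exceeds roughly
z x SE(difference curve), z ~ 2.6 at level 0.99. When the gap grows slowly
(e.g. 0.1 residual-SD per year), the estimate lags the true onset by
(2.6 x SE)/rate years — about 2.4 y at 400 carriers in the validation
experiments (median estimate -7.6 for a true onset at -10.0). The flip side is
honest null calibration: with identical group curves, a divergence is reported
in well under 5% of replicates at level 0.99. Reported divergence EYOs should
therefore be read as "separation is detectable from here", an upper bound
(later EYO) on the true separation onset. Raising the credible level never
moves the estimate earlier (tested), and estimates are stable to grid
refinement below 0.1 y.

The sensitivity variant (hippocampal-volume divergence controlling for
concurrent amyloid and p-tau181) is the same pipeline with extra fixed
effects, exposed via `extra_covariates`.

## Mediation

Sequential standardized regressions at the baseline visit, complete cases
only: outcome ~ group + covariates (direct effect), mediator ~ group +
covariates (path a), outcome ~ group + mediator + covariates (path b and the
residual direct effect). Outcome, mediator, and continuous covariates are
z-scored on the analysis sample (fixed scalings reused across bootstrap
resamples), so effects are in outcome-SD units; the group contrast stays a
0/1 indicator. For nested OLS fits the decomposition
direct = residual + a x b is an algebraic identity, which the tests assert to
1e-10. The indirect effect's interval is a percentile bootstrap resampling
whole families within group strata (families never span the two carrier
groups by construction, so strata stay intact and within-family correlation
is preserved). Default 5000 resamples; fewer than 100 is refused. "Full
mediation" is declared when the direct effect is significant, the residual
direct effect is not, and the indirect interval excludes zero. No causal
identification is claimed — this is the standard statistical mediation
decomposition, sensitive to unmeasured confounding like any other.

## Longitudinal slopes

Per-subject annualized rates of change are OLS slopes of the outcome on years
since the subject's own first visit (not EYO — "annualized" means per year of
follow-up). Subjects without two distinct usable time points are excluded and
logged. Group comparison is a two-sample t-test on the extracted slopes among
subjects whose baseline EYO is at or past a supplied threshold (by design an
explicit input — typically the cross-sectional divergence estimate — never a
hard-coded constant). Welch's unequal-variance test is the default since
nothing pins down the variance assumption; the pooled-variance Student test is
a flag away. BLUP-based slope extraction is not implemented; per-subject OLS
matches the "extracted slopes" framing and is exactly testable.

## The synthetic cohort generator

The generator emulates a DIAN-like observational ADAD cohort:

* **Structure.** Default 202 NC / 65 CY / 135 TM subjects. Carriers are
  chunked into families by a configurable carriers-per-family distribution;
  each family carries a single variant codon (drawn from the packaged TM or
  CY topology intervals, so re-classifying the codons reproduces the groups);
  non-carrier siblings attach to random carrier families. Baseline EYO is
  uniform over (-25, +10); expected onset age is truncated-normal (47, 7);
  visit counts and ~1.4-year intervals give a mean follow-up near 3.2 years
  among returnees, with EYO and age advancing in lockstep.
* **Mean curves.** Non-carriers follow a gentle linear EYO trend. Carriers add
  a hinged cubic disease term (flat before an onset EYO, accelerating after),
  which reproduces the sigmoidal look of real trajectory data with fully
  interpretable truth. TM carriers additionally separate from CY by a linear
  hinge that is exactly zero before the configured divergence EYO — making
  the true divergence point well-defined — and grows at a constant rate after
  it. Covariate effects (education on MMSE, head size on raw volumes) are
  small and configurable.
* **Noise.** Independent family, subject, and residual Gaussian components
  per outcome, at scales matching the outcome units (e.g. MMSE residual SD
  1.5 points, hippocampal 230 mm^3). Raw measurement columns add left/right
  hemisphere asymmetry around the bilateral mean and regional scatter around
  the composite SUVR, so the preprocessing stage has real work to undo.
* **Determinism.** One seed; three split RNG streams (structure, covariates,
  noise) so changing the visit design does not perturb covariate draws. Same
  config and seed give byte-identical output files.

What the generator does **not** emulate: floor/ceiling effects (MMSE is not
clipped at 30, CDR-SB can dip slightly below 0 — clipping would bias the
mean-recovery tests the generator exists to support), missingness mechanisms,
scanner or assay batch effects, practice effects, dropout related to decline,
and the upstream calculation of expected onset age (EYO is generated
directly; in real data the expected onset comes from mutation- or
parental-onset information upstream of this package). Passing tests therefore
demonstrate the *estimators* behave as designed under the stated model, not
that real ADAD data meet those assumptions.

## Validation experiment design

The recovery and calibration experiments (`psen1traj.validation`) generate
data from *within the fitted model family*: a linear-in-EYO base trajectory,
family intercepts, independent residuals, and (where present) the linear-hinge
TM-CY gap. This makes every fitted coefficient's true value well-defined
(closed form in `linear_recovery_truth_betas`), makes "calibration" refer to a
correctly specified model, and sets sigma_subject = 0 so the family-intercept
model is exact. Problem sizes: 400 carriers in 100 families for fixed-effect
recovery (100 replicates; >= 95% of estimates within 3 SE); 400 carriers for
divergence recovery (100 replicates at 1000 draws each); 200 carriers, 200
replicates for null calibration; n = 500 with 500 bootstrap draws for
mediation recovery (50 replicates); 60 subjects per group, 200 replicates for
slope-test power. `scripts/acceptance.py` re-runs the same designs at reduced
replicate counts and reports the measured quantities.

Under gross mean-model misspecification (a strongly curved carrier trajectory
fitted with the 3-knot spline), residual and family variances absorb the
misfit and the credible bands become anti-conservative; the calibration
statements above do not extend to that regime. This is a property of any
parametric trajectory model and is why the model-selection step (linear vs
spline) exists.

## Numerical choices

* MixedLM fits use statsmodels' default optimizer with a Powell fallback;
  convergence failures are flagged on the result, never silent. A constant
  outcome degenerates cleanly (exact intercept, zero variances, flagged).
* Knot placement refuses fewer than 10 distinct EYO values or tied quantiles,
  advising the linear form.
* Equal-tailed credible intervals by empirical quantiles; >= 1000 posterior
  draws are required before a divergence is reported.
* All report files are written twice: rounded for reading, full-precision
  (`%.17g`) machine-readable twins alongside. Archives contain no timestamps
  or absolute paths, so a rerun from the same seed is byte-identical.
* Codon-200 boundary: "before codon 200" means codon < 200; codon 200 itself
  is post-200 (configurable). Variants are assigned by a single affected
  codon; insertions/deletions spanning a domain boundary are not specially
  handled and parse to their first numbered codon.
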