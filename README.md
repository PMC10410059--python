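# psen1traj

Trajectory heterogeneity in autosomal-dominant Alzheimer's disease (ADAD) by
*PSEN1* variant protein-domain group.

Pathogenic *PSEN1* variants cause ADAD with near-complete penetrance, yet
carriers differ widely in when and how fast they decline. One candidate
explanation is *where* in presenilin-1 the variant falls: transmembrane (TM)
helices participate directly in γ-secretase's intramembrane cleavage of APP,
while cytoplasmic (CY) portions are involved in substrate recruitment and
processivity. `psen1traj` implements, as a reusable and fully tested pipeline,
the statistical machinery needed to ask whether TM and CY carriers follow
different clinical, cognitive, and biomarker trajectories across **EYO**
(expected years to symptom onset: visit age minus the family's expected age at
onset, negative = pre-symptomatic):

* **Variant classification** — map a variant's codon to TM/CY via a packaged
  presenilin-1 topology table (UniProt P49768 provenance), plus the historical
  pre/post-codon-200 alternative grouping.
* **Preprocessing** — EYO computation, bilateral volume averaging with
  residual-method intracranial-volume adjustment, 7-region bilateral composite
  PiB-PET SUVR, reference-level covariate coding, complete-case flags.
* **Spline mixed models** — for outcome $y_{ij}$ of subject $i$ in family $f$:

  $y_{ij} = X_{ij}\beta + u_f + \varepsilon_{ij}, \qquad
  u_f \sim N(0, \sigma_f^2),\ \varepsilon \sim N(0, \sigma_e^2)$

  where $X$ contains age, sex, APOE ε4, education (cognitive outcomes only),
  a restricted cubic spline of EYO with knots at the 0.10/0.50/0.90 quantiles
  (3 knots ⇒ a linear and one nonlinear column), group, and group × EYO-basis
  interactions. Fits are maximum likelihood; the spline terms are retained or
  dropped per outcome by likelihood-ratio test.
* **Divergence points** — the fixed effects get weakly-informative priors and
  are sampled exactly by a collapsed Gibbs sampler (coefficients integrate out
  in closed form; the two variance components move by slice sampling on the
  marginal posterior). The TM−CY difference curve is evaluated per draw on an
  EYO grid, and the divergence point is the earliest grid EYO whose 99%
  equal-tailed credible interval excludes zero *persistently* (at every later
  grid point).
* **Mediation** — product-of-coefficients test of whether hippocampal-volume
  differences account for cognitive differences, with a family-cluster
  percentile bootstrap for the indirect effect.
* **Longitudinal slopes** — per-subject annualized OLS slopes, compared
  TM vs CY by Welch's t-test among subjects past a divergence threshold.
* **Synthetic cohorts** — a generator with family clustering, longitudinal
  follow-up, and group mean curves with a *known* divergence point, so every
  stage is testable with ground truth (the real study data are restricted).

## Worked example

```python
import psen1traj as pt

cohort, truth = pt.simulate_cohort(pt.SimConfig(seed=1))   # 202 NC / 65 CY / 135 TM
table = pt.assemble(cohort)

fit_lin = pt.fit_lmem(table, pt.ModelSpec("mmse", eyo_form="linear"))
fit_rcs = pt.fit_lmem(table, pt.ModelSpec("mmse", eyo_form="rcs"))
sel = pt.lrt_select(fit_lin, fit_rcs)
# LRT: chi2(3) = 1235.9, p = 1.17e-267 -> rcs        (the spline is kept)

post = pt.sample_posterior(table, pt.ModelSpec("hv"), n_draws=4000, seed=1)
res = pt.divergence_point(pt.difference_curves(post), level=0.99)
# HV divergence EYO: -7.7   (generating truth: -10.9)

med = pt.mediate(table, outcome="mmse", mediator="hv", n_boot=2000, seed=1)
# direct -0.129; mediator 0.886; residual 0.129; indirect -0.258 CI (-0.454, -0.085)

slopes = pt.subject_slopes(table, "mmse")
cmp = pt.compare_slopes(slopes, threshold_eyo=-3.8)
# t(17) = -0.85, p = 0.407; TM -2.95/yr vs CY -2.45/yr (n=36/13)
```

Reading the numbers: the likelihood-ratio test overwhelmingly favours the
nonlinear EYO spline for MMSE (trajectories accelerate near onset). The
hippocampal-volume divergence point is estimated at EYO −7.7 against a
generating truth of −10.9 — credible-exclusion divergence estimates lag the
true separation onset until the gap clears the posterior uncertainty (see
`docs/methods.md`). The mediation decomposition satisfies
direct = residual + indirect exactly (−0.129 = 0.129 − 0.258). At this demo
cohort's size (65 CY carriers), the post-divergence slope contrast is not
significant — a realistic reminder that these designs are power-hungry.

The same chain is available from the shell:

```bash
psen1traj simulate --seed 1 --out-prefix run/sim
psen1traj prepare  --in run/sim_cohort.csv --out run/prepared.csv
psen1traj fit      --in run/prepared.csv --outcomes mmse,cdr_sb,hv,pib --out run/models.csv
psen1traj diverge  --in run/prepared.csv --outcome hv --seed 1 --out-prefix run/hv
psen1traj mediate  --in run/prepared.csv --seed 1 --out run/mediation.csv
psen1traj slopes   --in run/prepared.csv --outcome mmse --threshold run/hv_divergence.csv --out-prefix run/long
psen1traj report   --in run/prepared.csv --stage models=run/models.csv --seed 1 --out-dir run/archive
```

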