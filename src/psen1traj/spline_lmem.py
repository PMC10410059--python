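"""Linear mixed-effects trajectory models over EYO.

EYO enters either linearly or as a restricted cubic spline with knots at the
0.10 / 0.50 / 0.90 empirical quantiles (so three knots contribute two columns:
the linear term and one nonlinear term). Models include group (NC reference)
and group-by-EYO-basis interactions, demographic covariates, and a family
random intercept; estimation is by maximum likelihood so that likelihood-ratio
comparisons of fixed-effect structures (linear vs cubic EYO) are valid and the
reported estimates come from the same fit. Inference on fixed effects uses the
asymptotic normal reference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DegenerateKnotsError, InputError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "CLINICAL_OUTCOMES",
    "CSF_OUTCOMES",
    "SplineSpec",
    "ModelSpec",
    "FitResult",
    "knots_from_quantiles",
    "rcs_basis",
    "build_design",
    "fit_lmem",
    "lrt_select",
    "wald_contrast",
    "group_difference_contrast",
    "bh_adjust",
    "fit_report",
]

#: Outcomes whose models include years of education as a covariate.
CLINICAL_OUTCOMES = frozenset({"mmse", "cdr_sb"})

#: Outcomes whose p-values receive Benjamini-Hochberg adjustment in reports.
CSF_OUTCOMES = frozenset({"ptau181", "ab4240"})


# --------------------------------------------------------------------------
# spline basis
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SplineSpec:
    """Restricted-cubic-spline specification for the EYO axis."""

    knot_probs: tuple[float, ...] = (0.10, 0.50, 0.90)
    knots: tuple[float, ...] | None = None

    def __post_init__(self):
        p = np.asarray(self.knot_probs, dtype=float)
        if p.ndim != 1 or len(p) < 3 or (p <= 0).any() or (p >= 1).any() or \
                not (np.diff(p) > 0).all():
            raise ConfigError(
                "knot_probs must be >=3 strictly increasing values in (0,1)"
            )
        if self.knots is not None and not (np.diff(self.knots) > 0).all():
            raise ConfigError("resolved knots must be strictly increasing")

    def resolve(self, eyo_values) -> "SplineSpec":
        if self.knots is not None:
            return self
        return replace(
            self, knots=tuple(knots_from_quantiles(eyo_values, self.knot_probs))
        )


def knots_from_quantiles(values, probs=(0.10, 0.50, 0.90)) -> np.ndarray:
    """Empirical quantiles (linear order-statistic interpolation) as knots."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(np.unique(x)) < 10:
        raise DegenerateKnotsError(
            "need >= 10 distinct EYO values to place spline knots"
        )
    knots = np.quantile(x, np.asarray(probs, dtype=float))
    if not (np.diff(knots) > 0).all():
        raise DegenerateKnotsError(
            f"knot quantiles collapsed to {knots}; use the linear EYO form"
        )
    return knots


def rcs_basis(x, knots) -> np.ndarray:
    """Restricted (natural) cubic spline basis: k knots -> k-1 columns.

    Column 1 is x itself; nonlinear columns use the truncated-power
    construction constrained to be linear beyond the boundary knots, scaled by
    (t_k - t_1)^2 so all columns share the scale of x. Nonlinear columns vanish
    for x at or below the first knot.
    """
    t = np.asarray(knots, dtype=float)
    if t.ndim != 1 or len(t) < 3:
        raise ConfigError("rcs_basis needs >= 3 knots")
    if not (np.diff(t) > 0).all():
        raise ConfigError("knots must be strictly increasing")
    x = np.asarray(x, dtype=float)
    k = len(t)
    norm = (t[-1] - t[0]) ** 2

    def tp3(u):
        return np.where(u > 0.0, u ** 3, 0.0)

    cols = [x]
    for j in range(k - 2):
        col = (
            tp3(x - t[j])
            - tp3(x - t[k - 2]) * (t[k - 1] - t[j]) / (t[k - 1] - t[k - 2])
            + tp3(x - t[k - 1]) * (t[k - 2] - t[j]) / (t[k - 1] - t[k - 2])
        ) / norm
        cols.append(col)
    return np.column_stack(cols)


# --------------------------------------------------------------------------
# model specification and design
# --------------------------------------------------------------------------

_DEFAULT_COVARIATES = ("visit_age", "sex", "apoe4")


@dataclass(frozen=True)
class ModelSpec:
    """One outcome model: covariate set, EYO form, grouping variable."""

    outcome: str
    covariates: tuple[str, ...] | None = None  # None -> defaults for outcome
    eyo_form: str = "rcs"  # "rcs" | "linear"
    group_var: str = "tmcy"  # "tmcy" | "codon200"
    extra_covariates: tuple[str, ...] = ()
    reference: str | None = None  # None -> first present level (NC when there)

    def __post_init__(self):
        if self.eyo_form not in ("rcs", "linear"):
            raise ConfigError(f"unknown eyo_form {self.eyo_form!r}")
        if self.group_var not in ("tmcy", "codon200"):
            raise ConfigError(f"unknown group_var {self.group_var!r}")
        if self.covariates is not None:
            has_edu = "education" in self.covariates
            clinical = self.outcome in CLINICAL_OUTCOMES
            if has_edu != clinical:
                raise ConfigError(
                    "education is included exactly for clinical/cognitive "
                    f"outcomes; outcome={self.outcome!r}, covariates="
                    f"{self.covariates}"
                )

    @property
    def resolved_covariates(self) -> tuple[str, ...]:
        if self.covariates is not None:
            return self.covariates
        cov = _DEFAULT_COVARIATES
        if self.outcome in CLINICAL_OUTCOMES:
            cov = cov + ("education",)
        return cov


_COVARIATE_COLUMNS = {
    "visit_age": "visit_age",
    "sex": "sex_M",
    "apoe4": "apoe4_carrier",
    "education": "education",
}


@dataclass(frozen=True)
class DesignInfo:
    """Everything needed to rebuild linear predictors on new EYO grids."""

    columns: tuple[str, ...]
    knots: tuple[float, ...] | None
    eyo_form: str
    group_levels: tuple[str, ...]   # non-reference levels with indicator columns
    reference: str
    eyo_support: tuple[float, float]
    outcome: str


def _eyo_basis(eyo, eyo_form, knots):
    if eyo_form == "linear":
        return np.asarray(eyo, dtype=float)[:, None], ("eyo1",)
    basis = rcs_basis(eyo, knots)
    names = tuple(f"eyo{j + 1}" for j in range(basis.shape[1]))
    return basis, names


def build_design(
    table: pd.DataFrame,
    model: ModelSpec,
    spline: SplineSpec | None = None,
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray, DesignInfo]:
    """Complete-case outcome vector, named design matrix, family labels, info.

    Group coding: indicator columns for each non-reference level (reference NC
    when present, else CY for TM-vs-CY carrier models; pre200 for the codon
    grouping), plus interactions of each indicator with every EYO basis column.
    Knots are placed on the pooled EYO of the rows entering this model.
    """
    if model.group_var == "tmcy":
        group_col, levels_order = "group", ["NC", "CY", "TM"]
    else:
        group_col, levels_order = "codon_group", ["pre200", "post200"]
        table = table[table[group_col].isin(levels_order)]

    cov_cols = [_COVARIATE_COLUMNS[c] for c in model.resolved_covariates]
    cov_cols += list(model.extra_covariates)
    need = [model.outcome, "eyo", "family_id", group_col] + cov_cols
    missing = [c for c in need if c not in table.columns]
    if missing:
        raise ValidationError(f"table lacks columns {missing}")
    data = table.dropna(subset=need).copy()

    present = [g for g in levels_order if (data[group_col] == g).any()]
    requested = [g for g in levels_order if g in set(pd.unique(table[group_col].dropna()))]
    empty = sorted(set(requested) - set(present))
    if empty:
        raise InputError(
            f"group(s) {empty} have no complete-case rows for outcome "
            f"{model.outcome!r}; the design would be singular"
        )
    if len(present) < 2:
        raise InputError(
            f"need >= 2 groups with data, found {present} for {model.outcome!r}"
        )
    if model.reference is not None:
        if model.reference not in present:
            raise InputError(
                f"requested reference level {model.reference!r} has no data; "
                f"present: {present}"
            )
        reference = model.reference
    else:
        reference = present[0]

    eyo = data["eyo"].to_numpy(dtype=float)
    knots = None
    if model.eyo_form == "rcs":
        spline = (spline or SplineSpec()).resolve(eyo)
        knots = spline.knots
    basis, basis_names = _eyo_basis(eyo, model.eyo_form, knots)

    X = {"intercept": np.ones(len(data))}
    for c in cov_cols:
        X[c] = data[c].to_numpy(dtype=float)
    for j, nm in enumerate(basis_names):
        X[nm] = basis[:, j]
    nonref = [g for g in present if g != reference]
    for g in nonref:
        ind = (data[group_col] == g).to_numpy(dtype=float)
        X[g] = ind
        for j, nm in enumerate(basis_names):
            X[f"{g}:{nm}"] = ind * basis[:, j]

    Xdf = pd.DataFrame(X, index=data.index)
    y = data[model.outcome].to_numpy(dtype=float)
    fam = data["family_id"].to_numpy()

    if np.linalg.matrix_rank(Xdf.to_numpy()) < Xdf.shape[1]:
        raise InputError(
            "singular design matrix; check for collinear covariates or "
            "degenerate group/EYO structure"
        )
    if "visit_age" in cov_cols:
        r = np.corrcoef(Xdf["visit_age"], eyo)[0, 1]
        if abs(r) > 0.97:
            warnings.warn(
                f"visit_age and EYO are nearly collinear (r={r:.3f}); consider "
                "dropping one of them"
            )

    info = DesignInfo(
        columns=tuple(Xdf.columns),
        knots=tuple(knots) if knots is not None else None,
        eyo_form=model.eyo_form,
        group_levels=tuple(nonref),
        reference=reference,
        eyo_support=(float(eyo.min()), float(eyo.max())),
        outcome=model.outcome,
    )
    return y, Xdf, fam, info


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FitResult:
    """ML estimates of a family-random-intercept LMEM."""

    beta: pd.Series
    se: pd.Series
    vcov: pd.DataFrame
    var_family: float
    var_resid: float
    loglik: float
    n_obs: int
    n_families: int
    converged: bool
    design_info: DesignInfo


def fit_lmem(
    table: pd.DataFrame,
    model: ModelSpec,
    spline: SplineSpec | None = None,
) -> FitResult:
    """Fit by maximum likelihood with a family random intercept.

    Non-convergence is flagged on the result, never silent; a singular design
    or an empty group raises before fitting.
    """
    from statsmodels.regression.mixed_linear_model import MixedLM
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    y, Xdf, fam, info = build_design(table, model, spline)
    p = Xdf.shape[1]
    if len(y) < 10 * p:
        raise InputError(
            f"{len(y)} complete cases for {p} fixed effects; need >= {10 * p}"
        )

    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        mod = MixedLM(y, Xdf.to_numpy(), groups=fam)
        try:
            res = mod.fit(reml=False)
        except np.linalg.LinAlgError:
            res = mod.fit(reml=False, method="powell")
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
    if not getattr(res, "converged", True):
        converged = False
    if not converged:
        logger.warning("LMEM for %s flagged non-converged", model.outcome)

    names = list(Xdf.columns)
    beta = pd.Series(res.fe_params, index=names, dtype=float)
    vcov = pd.DataFrame(
        np.asarray(res.cov_params())[:p, :p], index=names, columns=names
    )
    se = pd.Series(np.sqrt(np.diag(vcov)), index=names)
    return FitResult(
        beta=beta,
        se=se,
        vcov=vcov,
        var_family=float(np.asarray(res.cov_re)[0, 0]),
        var_resid=float(res.scale),
        loglik=float(res.llf),
        n_obs=int(len(y)),
        n_families=int(pd.unique(fam).size),
        converged=converged,
        design_info=info,
    )


@dataclass(frozen=True)
class LrtResult:
    statistic: float
    df: int
    pvalue: float
    chosen: str  # "rcs" | "linear"


def lrt_select(fit_linear: FitResult, fit_rcs: FitResult, alpha: float = 0.05) -> LrtResult:
    """Likelihood-ratio choice between linear and spline EYO structures.

    The nonlinear spline columns and their group interactions are the added
    degrees of freedom; the spline form is retained iff p < alpha.
    """
    if fit_linear.n_obs != fit_rcs.n_obs:
        raise InputError(
            f"model fits use different rows ({fit_linear.n_obs} vs {fit_rcs.n_obs})"
        )
    df = len(fit_rcs.beta) - len(fit_linear.beta)
    if df < 0:
        raise InputError("fit_rcs has fewer parameters than fit_linear")
    stat = max(2.0 * (fit_rcs.loglik - fit_linear.loglik), 0.0)
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    return LrtResult(statistic=stat, df=df, pvalue=p,
                     chosen="rcs" if p < alpha else "linear")


@dataclass(frozen=True)
class ContrastResult:
    term: str
    estimate: float
    se: float
    z: float
    pvalue: float


def wald_contrast(fit: FitResult, term: str) -> ContrastResult:
    """Wald test of a single coefficient against zero (normal reference)."""
    if term not in fit.beta.index:
        raise InputError(
            f"unknown term {term!r}; available: {list(fit.beta.index)}"
        )
    b = float(fit.beta[term])
    se = float(fit.se[term])
    z = b / se
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return ContrastResult(term=term, estimate=b, se=se, z=z, pvalue=p)


def group_difference_contrast(
    fit: FitResult, term_suffix: str, groups: tuple[str, str] = ("TM", "CY")
) -> ContrastResult:
    """Linear contrast between two group coefficients sharing a basis term.

    For an NC-reference fit, the TM-vs-CY effect on e.g. the linear EYO term is
    beta['TM:eyo1'] - beta['CY:eyo1']; term_suffix '' contrasts the group main
    effects. Equivalent to refitting with the second group as reference.
    """
    a, b = groups
    name_a = f"{a}:{term_suffix}" if term_suffix else a
    name_b = f"{b}:{term_suffix}" if term_suffix else b
    c = pd.Series(0.0, index=fit.beta.index)
    for nm, w in ((name_a, 1.0), (name_b, -1.0)):
        if nm in c.index:
            c[nm] = w
        elif nm.startswith(fit.design_info.reference):
            pass  # reference level contributes zero
        else:
            raise InputError(f"unknown term {nm!r} in contrast")
    est = float(c @ fit.beta)
    se = float(np.sqrt(c @ fit.vcov.to_numpy() @ c))
    z = est / se
    return ContrastResult(
        term=f"{a}-{b}:{term_suffix or 'group'}", estimate=est, se=se, z=z,
        pvalue=2.0 * float(stats.norm.sf(abs(z))),
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise InputError("pvalues must be a 1-D vector")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise InputError("p-values must lie in [0, 1]")
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


# --------------------------------------------------------------------------
# batch reporting (Table-2-shaped)
# --------------------------------------------------------------------------

def fit_report(
    table: pd.DataFrame,
    outcomes: Sequence[str],
    spline: SplineSpec | None = None,
    group_var: str = "tmcy",
    alpha: float = 0.05,
    extra_covariates: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Fit each outcome with linear and spline EYO forms, keep the LRT winner,
    and report B / SE / p for every group-by-EYO interaction and pairwise
    group comparison; CSF outcomes receive a BH-adjusted column.
    """
    extra_covariates = extra_covariates or {}
    rows = []
    for out in outcomes:
        extra = tuple(extra_covariates.get(out, ()))
        spec_lin = ModelSpec(out, eyo_form="linear", group_var=group_var,
                             extra_covariates=extra)
        spec_rcs = ModelSpec(out, eyo_form="rcs", group_var=group_var,
                             extra_covariates=extra)
        fit_lin = fit_lmem(table, spec_lin, spline)
        fit_rcs = fit_lmem(table, spec_rcs, spline)
        sel = lrt_select(fit_lin, fit_rcs, alpha=alpha)
        fit = fit_rcs if sel.chosen == "rcs" else fit_lin
        info = fit.design_info
        basis_terms = (
            ("eyo1", "linear EYO x group"),
        )
        if sel.chosen == "rcs":
            basis_terms += tuple(
                (f"eyo{j}", "cubic EYO x group")
                for j in range(2, len(info.knots))
            )
        levels = list(info.group_levels)
        ref = info.reference
        for term, label in basis_terms:
            row = {
                "outcome": out, "term": label, "eyo_form": sel.chosen,
                "lrt_stat": sel.statistic, "lrt_p": sel.pvalue,
                "n_obs": fit.n_obs, "converged": fit.converged,
            }
            for g in levels:
                c = wald_contrast(fit, f"{g}:{term}")
                row[f"{g}_vs_{ref}_B"] = c.estimate
                row[f"{g}_vs_{ref}_SE"] = c.se
                row[f"{g}_vs_{ref}_p"] = c.pvalue
            if len(levels) == 2:
                a, b = levels[1], levels[0]
                c = group_difference_contrast(fit, term, (a, b))
                row[f"{a}_vs_{b}_B"] = c.estimate
                row[f"{a}_vs_{b}_SE"] = c.se
                row[f"{a}_vs_{b}_p"] = c.pvalue
            rows.append(row)
    report = pd.DataFrame(rows)
    # BH over the CSF analyses' p-value columns, within each contrast
    csf_mask = report["outcome"].isin(CSF_OUTCOMES)
    if csf_mask.any():
        for col in [c for c in report.columns if c.endswith("_p")]:
            vals = report.loc[csf_mask, col].dropna()
            if len(vals):
                report.loc[vals.index, col.replace("_p", "_p_bh")] = bh_adjust(
                    vals.to_numpy()
                )
    return report
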