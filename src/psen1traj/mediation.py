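"""Mediation of group differences in cognition by hippocampal volume.

Sequential standardized regressions (product-of-coefficients framework) at the
baseline visit:

* direct:          outcome ~ group + covariates
* mediator model:  mediator ~ group + covariates            (path a)
* outcome model:   outcome ~ group + mediator + covariates  (path b and the
                   residual direct effect)

Outcome, mediator and continuous covariates are z-scored on the analysis
sample, so coefficients are in outcome-SD units per unit predictor; the group
contrast stays a 0/1 indicator. For ordinary least squares on a common sample
the identity ``direct = residual_direct + a * b`` holds exactly. Uncertainty in
the indirect effect a*b comes from a percentile bootstrap that resamples whole
families within group strata (families never span the two carrier groups, so
this respects both the clustering and the group sizes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

__all__ = ["MediationResult", "mediate"]

_DEFAULT_COVARIATES = ("visit_age", "sex_M", "apoe4_carrier", "education")
_BINARY = {"sex_M", "apoe4_carrier"}


def _ols(y: np.ndarray, X: np.ndarray):
    """Coefficients, their SEs and two-sided t-test p-values."""
    n, p = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - rank
    if dof <= 0:
        return beta, np.full(p, np.nan), np.full(p, np.nan)
    s2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.maximum(s2 * np.diag(XtX_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    pvals = np.where(se > 0, pvals, 0.0)
    return beta, se, pvals


@dataclass(frozen=True)
class MediationResult:
    direct_effect: float
    direct_p: float
    mediator_effect: float
    mediator_p: float
    residual_direct: float
    residual_p: float
    path_a: float
    indirect_effect: float
    indirect_ci: tuple[float, float]
    ci_level: float
    n_subjects: int
    n_boot: int
    seed: int
    outcome: str
    mediator: str
    groups: tuple[str, str]

    @property
    def full_mediation(self) -> bool:
        """Direct effect significant, residual direct not, indirect CI excludes 0."""
        lo, hi = self.indirect_ci
        return (
            self.direct_p < 0.05
            and self.residual_p >= 0.05
            and (lo > 0.0 or hi < 0.0)
        )


def mediate(
    table: pd.DataFrame,
    outcome: str = "mmse",
    mediator: str = "hv",
    groups: tuple[str, str] = ("TM", "CY"),
    covariates: tuple[str, ...] = _DEFAULT_COVARIATES,
    n_boot: int = 5000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> MediationResult:
    """Estimate the indirect (mediated) effect of group on the outcome.

    Uses each subject's baseline (first) visit, complete cases only. The group
    indicator is 1 for ``groups[0]`` and 0 for ``groups[1]``.
    """
    if n_boot < 100:
        raise InputError(f"n_boot must be >= 100, got {n_boot}")
    need = [outcome, mediator, "subject_id", "family_id", "visit", "group",
            *covariates]
    missing = [c for c in need if c not in table.columns]
    if missing:
        raise InputError(f"table lacks columns {missing}")

    df = table[table["group"].astype(str).isin(groups)].copy()
    df = df.sort_values(["subject_id", "visit"]).groupby("subject_id").head(1)
    df = df.dropna(subset=[outcome, mediator, *covariates])
    n = len(df)
    if n < 10:
        raise InputError(f"only {n} complete baseline cases; need >= 10")
    if float(np.std(df[mediator])) == 0.0:
        raise InputError("mediator is constant; mediation is undefined")

    g = (df["group"].astype(str) == groups[0]).to_numpy(dtype=float)
    # fixed full-sample standardization so bootstrap resamples stay comparable
    def z(col):
        v = df[col].to_numpy(dtype=float)
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else v - v.mean()

    y = z(outcome)
    m = z(mediator)
    C = [np.ones(n), g]
    for c in covariates:
        C.append(df[c].to_numpy(dtype=float) if c in _BINARY else z(c))
    X_direct = np.column_stack(C)
    X_full = np.column_stack(C[:2] + [m] + C[2:])

    b1, _, p1 = _ols(y, X_direct)           # y ~ g + C
    b2, _, p2 = _ols(y, X_full)             # y ~ g + m + C
    b3, _, p3 = _ols(m, X_direct)           # m ~ g + C
    direct, direct_p = float(b1[1]), float(p1[1])
    residual, residual_p = float(b2[1]), float(p2[1])
    b_path, b_p = float(b2[2]), float(p2[2])
    a_path = float(b3[1])
    indirect = a_path * b_path

    # family-cluster percentile bootstrap within group strata
    fam = df["family_id"].to_numpy()
    strata = []
    for grp in groups:
        fams = pd.unique(fam[df["group"].astype(str) == grp])
        strata.append(fams)
    fam_rows = {f: np.flatnonzero(fam == f) for f in pd.unique(fam)}
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x6d6564]))
    boots = np.empty(n_boot)
    for bi in range(n_boot):
        idx_parts = []
        for fams in strata:
            pick = rng.choice(fams, size=len(fams), replace=True)
            idx_parts.extend(fam_rows[f] for f in pick)
        idx = np.concatenate(idx_parts)
        yb, mb, gb = y[idx], m[idx], X_direct[idx]
        bb3 = np.linalg.lstsq(gb, mb, rcond=None)[0]
        Xf = X_full[idx]
        bb2 = np.linalg.lstsq(Xf, yb, rcond=None)[0]
        boots[bi] = bb3[1] * bb2[2]
    alpha = (1.0 - ci_level) / 2.0
    ci = (float(np.quantile(boots, alpha)), float(np.quantile(boots, 1 - alpha)))

    return MediationResult(
        direct_effect=direct, direct_p=direct_p,
        mediator_effect=b_path, mediator_p=b_p,
        residual_direct=residual, residual_p=residual_p,
        path_a=a_path, indirect_effect=indirect, indirect_ci=ci,
        ci_level=ci_level, n_subjects=n, n_boot=n_boot, seed=seed,
        outcome=outcome, mediator=mediator, groups=groups,
    )
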