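"""Bayesian estimation of the EYO at which TM and CY trajectories diverge.

The same fixed-effect design as the ML mixed model is given weakly-informative
priors (normal(0, (prior_scale * sd_y)^2) on each coefficient, half-normal on
the family and residual SDs) and sampled exactly:

* the fixed effects integrate out in closed form given the two variance
  components (the model is linear-Gaussian), so the sampler alternates
  univariate slice-sampling updates of (log sigma_family, log sigma_resid) on
  the marginal posterior with exact Gaussian draws of the coefficient vector;
* the family-block structure of the marginal covariance V = sigma_e^2 I +
  sigma_f^2 Z Z' makes every marginal-likelihood evaluation O(n p + F p^2) via
  the Sherman-Morrison identity on each family block.

Posterior group-difference curves on an EYO grid then give the divergence
point: the earliest grid EYO at which the equal-tailed credible interval
excludes zero *and keeps excluding it at every later grid point* (the
persistence rule resolves transient crossings). Multiple chains are run and
split-chain R-hat / effective sample size are attached to every draw set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError, SamplingError
from .spline_lmem import DesignInfo, ModelSpec, SplineSpec, build_design, rcs_basis

__all__ = [
    "PosteriorDraws",
    "DiffCurves",
    "DivergenceResult",
    "sample_posterior",
    "difference_curves",
    "divergence_point",
    "default_grid",
]


# --------------------------------------------------------------------------
# marginal likelihood machinery
# --------------------------------------------------------------------------

class _MarginalLMM:
    """Sufficient statistics for V = s2e*I + s2f*ZZ' with family blocks."""

    def __init__(self, X: np.ndarray, y: np.ndarray, fam_codes: np.ndarray):
        self.n, self.p = X.shape
        self.F = int(fam_codes.max()) + 1
        self.m = np.bincount(fam_codes, minlength=self.F).astype(float)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.S = np.zeros((self.F, self.p))
        np.add.at(self.S, fam_codes, X)
        self.t = np.bincount(fam_codes, weights=y, minlength=self.F)

    def suff(self, s2f: float, s2e: float):
        c = s2f / (s2e + self.m * s2f)
        A = (self.XtX - self.S.T @ (c[:, None] * self.S)) / s2e
        b = (self.Xty - self.S.T @ (c * self.t)) / s2e
        q = (self.yty - float((c * self.t) @ self.t)) / s2e
        logdetV = float(
            np.sum((self.m - 1.0) * np.log(s2e) + np.log(s2e + self.m * s2f))
        )
        return A, b, q, logdetV


def _log_marginal_posterior(stats_, lsf, lse, prior_prec, half_scales):
    """log p(log sf, log se | y) with beta integrated out (up to a constant)."""
    s2f, s2e = np.exp(2.0 * lsf), np.exp(2.0 * lse)
    A, b, q, logdetV = stats_.suff(s2f, s2e)
    M = A + np.diag(prior_prec)
    try:
        L = np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        return -np.inf, None, None
    w = np.linalg.solve(L, b)
    logdetM = 2.0 * float(np.sum(np.log(np.diag(L))))
    ll = -0.5 * (logdetV + logdetM + q - float(w @ w))
    # half-normal priors on the SDs, with the log-scale Jacobian
    sf, se = np.sqrt(s2f), np.sqrt(s2e)
    cf, ce = half_scales
    lp = -0.5 * (sf / cf) ** 2 + lsf - 0.5 * (se / ce) ** 2 + lse
    return ll + lp, L, w


def _slice_update(logpost, x0, lp0, rng, w=1.0, max_steps=50):
    """Univariate slice sampling (stepping-out then shrinkage)."""
    logy = lp0 + np.log(rng.random())
    lo = x0 - w * rng.random()
    hi = lo + w
    steps = max_steps
    while steps > 0 and logpost(lo) > logy:
        lo -= w
        steps -= 1
    steps = max_steps
    while steps > 0 and logpost(hi) > logy:
        hi += w
        steps -= 1
    while True:
        x1 = lo + (hi - lo) * rng.random()
        lp1 = logpost(x1)
        if lp1 > logy:
            return x1, lp1
        if x1 < x0:
            lo = x1
        else:
            hi = x1


# --------------------------------------------------------------------------
# public API
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PosteriorDraws:
    """Fixed-effect posterior draws with convergence diagnostics attached."""

    draws: np.ndarray               # (n_draws, p)
    param_names: tuple[str, ...]
    sd_family: np.ndarray           # (n_draws,)
    sd_resid: np.ndarray
    ess: pd.Series
    rhat: pd.Series
    seed: int
    n_chains: int
    design_info: DesignInfo

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]


def _diagnostics(chains: np.ndarray, names) -> tuple[pd.Series, pd.Series]:
    """Split-chain R-hat and bulk ESS via ArviZ; chains is (C, T, p)."""
    import arviz as az

    ds = az.from_dict(posterior={"beta": chains})
    ess = az.ess(ds)["beta"].to_numpy()
    rhat = az.rhat(ds)["beta"].to_numpy()
    return (
        pd.Series(np.atleast_1d(ess), index=names, dtype=float),
        pd.Series(np.atleast_1d(rhat), index=names, dtype=float),
    )


def sample_posterior(
    table: pd.DataFrame,
    model: ModelSpec,
    spline: SplineSpec | None = None,
    n_draws: int = 4000,
    seed: int = 0,
    n_chains: int = 4,
    warmup: int | None = None,
    prior_scale: float = 10.0,
    sd_prior_scale: float = 5.0,
    rhat_max: float = 1.1,
    prior_only: bool = False,
) -> PosteriorDraws:
    """Sample the fixed-effect posterior of the family-intercept LMEM.

    Reproducible given ``seed``; raises SamplingError (carrying the
    diagnostics) if split-chain R-hat exceeds ``rhat_max``. With
    ``prior_only=True`` the data likelihood is dropped and draws come from the
    stated priors (a prior-predictive check of the prior specification).
    """
    y, Xdf, fam, info = build_design(table, model, spline)
    X = Xdf.to_numpy()
    names = tuple(Xdf.columns)
    p = X.shape[1]
    sd_y = float(np.std(y))
    if sd_y == 0.0:
        raise InputError("outcome is constant; posterior sampling is pointless")
    prior_sd = prior_scale * sd_y
    prior_prec = np.full(p, 1.0 / prior_sd ** 2)
    half_scales = (sd_prior_scale * sd_y, sd_prior_scale * sd_y)

    ss = np.random.SeedSequence([int(seed), 0x9e3779b9])
    chain_seeds = ss.spawn(n_chains)
    per_chain = int(np.ceil(n_draws / n_chains))
    if warmup is None:
        warmup = max(150, per_chain // 2)

    total = per_chain * n_chains

    if prior_only:
        rng = np.random.default_rng(chain_seeds[0])
        beta = rng.normal(0.0, prior_sd, size=(total, p))
        sdf = np.abs(rng.normal(0.0, half_scales[0], total))
        sde = np.abs(rng.normal(0.0, half_scales[1], total))
        chains = beta.reshape(n_chains, per_chain, p)
        ess, rhat = _diagnostics(chains, names)
        return PosteriorDraws(beta, names, sdf, sde, ess, rhat, seed,
                              n_chains, info)

    fam_codes = pd.factorize(fam)[0]
    stats_ = _MarginalLMM(X, y, fam_codes)

    all_beta = np.empty((n_chains, per_chain, p))
    all_sf = np.empty((n_chains, per_chain))
    all_se = np.empty((n_chains, per_chain))
    for ci in range(n_chains):
        rng = np.random.default_rng(chain_seeds[ci])
        lse = float(np.log(sd_y * (0.5 + 0.5 * rng.random())))
        lsf = float(np.log(sd_y * (0.2 + 0.4 * rng.random())))
        lp, L, w = _log_marginal_posterior(
            stats_, lsf, lse, prior_prec, half_scales
        )
        for it in range(warmup + per_chain):
            lsf, lp = _slice_update(
                lambda v: _log_marginal_posterior(
                    stats_, v, lse, prior_prec, half_scales)[0],
                lsf, lp, rng,
            )
            lse, lp = _slice_update(
                lambda v: _log_marginal_posterior(
                    stats_, lsf, v, prior_prec, half_scales)[0],
                lse, lp, rng,
            )
            if it >= warmup:
                _, L, w = _log_marginal_posterior(
                    stats_, lsf, lse, prior_prec, half_scales
                )
                mean = np.linalg.solve(L.T, w)
                z = rng.standard_normal(p)
                beta = mean + np.linalg.solve(L.T, z)
                k = it - warmup
                all_beta[ci, k] = beta
                all_sf[ci, k] = np.exp(lsf)
                all_se[ci, k] = np.exp(lse)

    ess, rhat = _diagnostics(all_beta, names)
    if float(rhat.max()) > rhat_max:
        raise SamplingError(
            f"posterior sampling failed to converge (max R-hat = "
            f"{rhat.max():.3f} > {rhat_max})",
            diagnostics={"rhat": rhat, "ess": ess},
        )
    return PosteriorDraws(
        draws=all_beta.reshape(-1, p),
        param_names=names,
        sd_family=all_sf.reshape(-1),
        sd_resid=all_se.reshape(-1),
        ess=ess,
        rhat=rhat,
        seed=seed,
        n_chains=n_chains,
        design_info=info,
    )


@dataclass(frozen=True)
class DiffCurves:
    """Posterior draws of the TM - CY expected-outcome difference on a grid."""

    eyo_grid: np.ndarray
    diff_draws: np.ndarray  # (n_draws, n_grid)
    groups: tuple[str, str]
    outcome: str


def default_grid(step: float = 0.1,
                 span: tuple[float, float] = (-25.0, 10.0)) -> np.ndarray:
    lo, hi = span
    return np.round(np.arange(lo, hi + step / 2, step), 10)


def difference_curves(
    draws: PosteriorDraws,
    grid: Sequence[float] | None = None,
    groups: tuple[str, str] = ("TM", "CY"),
) -> DiffCurves:
    """Per-draw difference of linear predictors between two groups.

    All covariate terms cancel; only group main effects and group-by-EYO
    interactions survive, so no covariate reference values are needed (the
    result is provably invariant to them). The grid is clipped to the observed
    EYO support; an entirely out-of-support grid is an error (no extrapolated
    divergence).
    """
    info = draws.design_info
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or not (np.diff(grid) > 0).all():
        raise InputError("grid must be strictly increasing")
    lo, hi = info.eyo_support
    inside = (grid >= lo) & (grid <= hi)
    if not inside.any():
        raise InputError(
            f"grid {grid.min()}..{grid.max()} lies outside the observed EYO "
            f"support {lo:.2f}..{hi:.2f}"
        )
    grid = grid[inside]

    basis, basis_names = _basis_on_grid(info, grid)
    names = list(draws.param_names)
    a, b = groups

    def coef(nm):
        if nm in names:
            return draws.draws[:, names.index(nm)]
        if nm.split(":")[0] == info.reference:
            return np.zeros(draws.n_draws)
        raise InputError(f"group term {nm!r} absent from the sampled model")

    diff = (coef(a) - coef(b))[:, None] * np.ones((1, len(grid)))
    for j, bn in enumerate(basis_names):
        diff = diff + (coef(f"{a}:{bn}") - coef(f"{b}:{bn}"))[:, None] * basis[:, j]
    return DiffCurves(eyo_grid=grid, diff_draws=diff, groups=groups,
                      outcome=info.outcome)


def _basis_on_grid(info: DesignInfo, grid: np.ndarray):
    if info.eyo_form == "linear":
        return grid[:, None], ("eyo1",)
    basis = rcs_basis(grid, np.asarray(info.knots))
    return basis, tuple(f"eyo{j + 1}" for j in range(basis.shape[1]))


@dataclass(frozen=True)
class DivergenceResult:
    """First EYO with persistent credible exclusion of zero (or None)."""

    divergence_eyo: float | None
    credible_level: float
    eyo_grid: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    median: np.ndarray
    outcome: str
    groups: tuple[str, str]
    n_draws: int


def divergence_point(curves: DiffCurves, level: float = 0.99) -> DivergenceResult:
    """Equal-tailed credible bands per grid point; the divergence EYO is the
    earliest grid point whose band excludes zero at this and every later grid
    point (persistence rule). None when no such point exists."""
    if not 0.0 < level < 1.0:
        raise InputError(f"credible level must be in (0,1), got {level}")
    n_draws = curves.diff_draws.shape[0]
    if n_draws < 1000:
        raise InputError(
            f"need >= 1000 posterior draws for a reported divergence, got {n_draws}"
        )
    alpha = (1.0 - level) / 2.0
    lower = np.quantile(curves.diff_draws, alpha, axis=0)
    upper = np.quantile(curves.diff_draws, 1.0 - alpha, axis=0)
    median = np.quantile(curves.diff_draws, 0.5, axis=0)
    excludes = (lower > 0.0) | (upper < 0.0)
    div = None
    if excludes.size and excludes[-1]:
        not_excl = np.where(~excludes)[0]
        first = 0 if len(not_excl) == 0 else int(not_excl[-1]) + 1
        div = float(curves.eyo_grid[first])
    return DivergenceResult(
        divergence_eyo=div,
        credible_level=level,
        eyo_grid=curves.eyo_grid,
        lower=lower,
        upper=upper,
        median=median,
        outcome=curves.outcome,
        groups=curves.groups,
        n_draws=n_draws,
    )
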