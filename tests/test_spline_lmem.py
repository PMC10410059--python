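"""Spline basis, mixed-model fitting, model selection, contrasts, and FDR."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import erfc

import psen1traj as pt
from psen1traj.errors import ConfigError, DegenerateKnotsError, InputError
from psen1traj.spline_lmem import wald_contrast
from psen1traj.validation import linear_recovery_config, linear_recovery_truth_betas


def quantile_oracle(x, p):
    """Independent order-statistic interpolation (the stated quantile rule)."""
    xs = np.sort(np.asarray(x, dtype=float))
    h = (len(xs) - 1) * p
    lo = int(np.floor(h))
    hi = min(lo + 1, len(xs) - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def rcs_oracle(x, knots):
    """Independent re-implementation of the restricted truncated-power basis."""
    t = list(map(float, knots))
    k = len(t)
    norm = (t[-1] - t[0]) ** 2
    out = [float(x)]
    for j in range(k - 2):
        def plus3(u):
            return u ** 3 if u > 0 else 0.0
        val = plus3(x - t[j])
        val -= plus3(x - t[k - 2]) * (t[k - 1] - t[j]) / (t[k - 1] - t[k - 2])
        val += plus3(x - t[k - 1]) * (t[k - 2] - t[j]) / (t[k - 1] - t[k - 2])
        out.append(val / norm)
    return out


class TestKnots:
    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateKnotsError):
            pt.knots_from_quantiles(np.full(100, 3.0))

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(DegenerateKnotsError):
            pt.knots_from_quantiles([1, 2, 3, 4, 5] * 10)

    def test_symmetric_sample_middle_knot_is_median(self):
        x = np.concatenate([-np.arange(1, 50), [0], np.arange(1, 50)])
        knots = pt.knots_from_quantiles(x)
        assert knots[1] == pytest.approx(np.median(x))

    def test_matches_order_statistic_oracle(self, rng):
        x = rng.normal(0, 10, 237)
        knots = pt.knots_from_quantiles(x, (0.1, 0.5, 0.9))
        for k, p in zip(knots, (0.1, 0.5, 0.9)):
            assert k == pytest.approx(quantile_oracle(x, p), abs=1e-12)


class TestRcsBasis:
    KNOTS = (-20.9, -6.2, 3.2)

    def test_matches_truncated_power_oracle_at_reference_points(self):
        for x in (-20.0, -5.0, 0.0, 5.0):
            got = pt.rcs_basis([x], self.KNOTS)[0]
            np.testing.assert_allclose(got, rcs_oracle(x, self.KNOTS), atol=1e-12)

    def test_nonlinear_columns_vanish_at_or_below_first_knot(self, rng):
        x = self.KNOTS[0] - rng.uniform(0, 30, 100)
        basis = pt.rcs_basis(x, self.KNOTS)
        assert np.all(basis[:, 1:] == 0.0)

    def test_linear_beyond_boundary_knots(self):
        # second finite differences vanish in both tails
        for base in (self.KNOTS[-1] + 1.0, self.KNOTS[-1] + 10.0):
            b = pt.rcs_basis([base, base + 1, base + 2], self.KNOTS)
            second_diff = b[2] - 2 * b[1] + b[0]
            np.testing.assert_allclose(second_diff, 0.0, atol=1e-9)

    def test_rejects_bad_knots(self):
        with pytest.raises(ConfigError):
            pt.rcs_basis([0.0], (-5.0, 5.0))
        with pytest.raises(ConfigError):
            pt.rcs_basis([0.0], (3.0, 1.0, 5.0))

    @given(
        shift=st.floats(-10, 10),
        scale=st.floats(0.5, 3.0),
        x=st.floats(-40, 40),
    )
    @settings(max_examples=100, deadline=None)
    def test_oracle_agreement_under_knot_transformations(self, shift, scale, x):
        knots = tuple(k * scale + shift for k in self.KNOTS)
        got = pt.rcs_basis([x], knots)[0]
        np.testing.assert_allclose(got, rcs_oracle(x, knots), atol=1e-8)


@pytest.fixture(scope="module")
def recovery_fit():
    """Degenerate limit: no family variance, one subject per family, one visit
    per subject - the marginal covariance is proportional to the identity, so
    the mixed-model estimates must coincide with ordinary least squares."""
    import dataclasses

    cfg = dataclasses.replace(
        linear_recovery_config(101, sigma_family=0.0, carriers_per_family=1),
        n_visits_dist=(1.0,),
    )
    df, _ = pt.simulate_cohort(cfg)
    prep = pt.assemble(df)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = pt.fit_lmem(prep, pt.ModelSpec("mmse", eyo_form="linear"))
    return cfg, prep, fit


class TestFitLmem:
    def test_zero_family_variance_matches_ols_closed_form(self, recovery_fit):
        _, prep, fit = recovery_fit
        y, X, _, _ = pt.build_design(prep, pt.ModelSpec("mmse", eyo_form="linear"))
        # oracle: normal equations
        A = X.to_numpy()
        ols = np.linalg.solve(A.T @ A, A.T @ y)
        np.testing.assert_allclose(fit.beta.to_numpy(), ols, atol=1e-6)

    def test_constant_outcome_degenerates_cleanly(self, recovery_fit):
        _, prep, _ = recovery_fit
        flat = prep.copy()
        flat["mmse"] = 12.5
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = pt.fit_lmem(flat, pt.ModelSpec("mmse", eyo_form="linear"))
        assert fit.beta["intercept"] == pytest.approx(12.5, abs=1e-9)
        assert fit.beta.drop("intercept").abs().max() < 1e-9
        assert fit.var_family == pytest.approx(0.0, abs=1e-9)
        assert fit.var_resid == pytest.approx(0.0, abs=1e-9)

    def test_row_permutation_invariance(self, recovery_fit, rng):
        _, prep, fit = recovery_fit
        shuffled = prep.sample(frac=1.0, random_state=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit2 = pt.fit_lmem(shuffled, pt.ModelSpec("mmse", eyo_form="linear"))
        np.testing.assert_allclose(
            fit.beta.to_numpy(), fit2.beta.to_numpy(), atol=1e-9
        )

    def test_parameter_recovery_within_3se(self):
        cfg = linear_recovery_config(2024, n_per_group=500)
        df, _ = pt.simulate_cohort(cfg)
        prep = pt.assemble(df)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = pt.fit_lmem(prep, pt.ModelSpec("mmse", eyo_form="linear"))
        truth = linear_recovery_truth_betas(cfg)
        for name, value in truth.items():
            assert abs(fit.beta[name] - value) <= 3 * fit.se[name], name

    def test_family_variance_recovery(self):
        cfg = linear_recovery_config(7, n_per_group=500, carriers_per_family=2,
                                     sigma_family=1.0)
        df, _ = pt.simulate_cohort(cfg)
        prep = pt.assemble(df)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = pt.fit_lmem(prep, pt.ModelSpec("mmse", eyo_form="linear"))
        assert fit.var_family == pytest.approx(1.0, rel=0.35)
        assert fit.var_resid == pytest.approx(1.5 ** 2, rel=0.15)

    def test_empty_group_is_informative_error(self, prepared):
        carriers_only = prepared[prepared["group"].astype(str) != "NC"]
        spec = pt.ModelSpec("mmse", reference="NC")
        with pytest.raises(InputError, match="NC"):
            pt.fit_lmem(carriers_only, spec)

    def test_se_equals_sqrt_vcov_diagonal(self, mmse_fit_rcs):
        np.testing.assert_allclose(
            mmse_fit_rcs.se.to_numpy(),
            np.sqrt(np.diag(mmse_fit_rcs.vcov.to_numpy())),
            rtol=1e-12,
        )


class TestLrt:
    def test_identical_fits_give_zero_statistic_unit_p(self, mmse_fit_rcs):
        sel = pt.lrt_select(mmse_fit_rcs, mmse_fit_rcs)
        assert sel.statistic == 0.0 and sel.pvalue == 1.0
        assert sel.chosen == "linear"

    def test_statistic_and_p_match_chi_square_oracle(self, recovery_fit):
        _, prep, fit_lin = recovery_fit
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit_rcs = pt.fit_lmem(prep, pt.ModelSpec("mmse", eyo_form="rcs"))
        sel = pt.lrt_select(fit_lin, fit_rcs)
        assert sel.statistic == pytest.approx(
            2 * (fit_rcs.loglik - fit_lin.loglik), abs=1e-9
        )
        # two carrier groups, one nonlinear column -> 2 added parameters;
        # chi-square(2) survival function has the closed form exp(-x/2)
        assert sel.df == 2
        assert sel.pvalue == pytest.approx(np.exp(-sel.statistic / 2), rel=1e-10)

    def test_strong_cubic_group_effect_selects_spline(self, prepared):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit_lin = pt.fit_lmem(prepared, pt.ModelSpec("mmse", eyo_form="linear"))
            fit_rcs = pt.fit_lmem(prepared, pt.ModelSpec("mmse", eyo_form="rcs"))
        assert pt.lrt_select(fit_lin, fit_rcs).chosen == "rcs"

    def test_invariance_to_affine_covariate_rescaling(self, recovery_fit):
        _, prep, fit_lin = recovery_fit
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit_rcs = pt.fit_lmem(prep, pt.ModelSpec("mmse", eyo_form="rcs"))
            scaled = prep.copy()
            scaled["education"] = 10.0 * scaled["education"] + 3.0
            f1 = pt.fit_lmem(scaled, pt.ModelSpec("mmse", eyo_form="linear"))
            f2 = pt.fit_lmem(scaled, pt.ModelSpec("mmse", eyo_form="rcs"))
        base = pt.lrt_select(fit_lin, fit_rcs).statistic
        assert pt.lrt_select(f1, f2).statistic == pytest.approx(base, abs=1e-4)

    def test_mismatched_rows_rejected(self, recovery_fit, mmse_fit_rcs):
        with pytest.raises(InputError):
            pt.lrt_select(recovery_fit[2], mmse_fit_rcs)


class TestWald:
    @staticmethod
    def _fake_fit(beta, se):
        names = list(beta)
        return pt.FitResult(
            beta=pd.Series(beta), se=pd.Series(se),
            vcov=pd.DataFrame(np.diag(np.array(list(se.values())) ** 2),
                              index=names, columns=names),
            var_family=0.0, var_resid=1.0, loglik=0.0, n_obs=100,
            n_families=50, converged=True, design_info=None,
        )

    def test_zero_estimate_gives_unit_p(self):
        fit = self._fake_fit({"x": 0.0}, {"x": 1.0})
        assert wald_contrast(fit, "x").pvalue == 1.0

    def test_z_1p96_gives_p_near_05(self):
        fit = self._fake_fit({"x": 1.96}, {"x": 1.0})
        assert wald_contrast(fit, "x").pvalue == pytest.approx(0.05, abs=1e-3)

    @given(z=st.floats(-8, 8))
    @settings(max_examples=100, deadline=None)
    def test_p_matches_gaussian_tail_oracle(self, z):
        fit = self._fake_fit({"x": z}, {"x": 1.0})
        oracle = erfc(abs(z) / np.sqrt(2.0))  # 2*(1 - Phi(|z|))
        assert wald_contrast(fit, "x").pvalue == pytest.approx(oracle, rel=1e-9)

    def test_unknown_term_lists_available(self, mmse_fit_rcs):
        with pytest.raises(InputError, match="intercept"):
            wald_contrast(mmse_fit_rcs, "nonesuch")

    def test_tm_vs_cy_contrast_agrees_with_cy_reference_refit(self, prepared):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit_nc = pt.fit_lmem(prepared, pt.ModelSpec("mmse"))
            fit_cy = pt.fit_lmem(prepared, pt.ModelSpec("mmse", reference="CY"))
        for suffix in ("", "eyo1", "eyo2"):
            via_contrast = pt.group_difference_contrast(fit_nc, suffix)
            term = f"TM:{suffix}" if suffix else "TM"
            via_refit = wald_contrast(fit_cy, term)
            assert via_contrast.estimate == pytest.approx(
                via_refit.estimate, abs=1e-6
            )
            assert via_contrast.se == pytest.approx(via_refit.se, rel=1e-3)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert pt.bh_adjust([0.037])[0] == 0.037

    def test_all_equal_ps_stay_equal(self):
        out = pt.bh_adjust([0.2] * 5)
        np.testing.assert_array_equal(out, 0.2)

    @staticmethod
    def brute_force(p):
        """Oracle: direct min-over-tail of the step-up definition."""
        n = len(p)
        order = sorted(range(n), key=lambda i: p[i])
        adj = [None] * n
        for rank_pos, i in enumerate(order):
            candidates = [
                p[j] * n / (pos + 1)
                for pos, j in enumerate(order)
                if pos >= rank_pos
            ]
            adj[i] = min(1.0, min(candidates))
        return adj

    @given(
        p=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=8)
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force_enumeration_exactly(self, p):
        got = pt.bh_adjust(p)
        assert list(got) == self.brute_force(p)

    def test_cross_check_against_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.uniform(0, 1, rng.integers(2, 30))
            ours = pt.bh_adjust(p)
            theirs = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(ours, theirs, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            pt.bh_adjust([0.2, 1.4])
        with pytest.raises(InputError):
            pt.bh_adjust([-0.1])

    def test_monotone_and_bounded(self, rng):
        p = rng.uniform(0, 1, 50)
        adj = pt.bh_adjust(p)
        assert np.all(adj <= 1.0) and np.all(adj >= 0.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


def test_education_inclusion_rule_enforced():
    with pytest.raises(ConfigError):
        pt.ModelSpec("hv", covariates=("visit_age", "education"))
    with pytest.raises(ConfigError):
        pt.ModelSpec("mmse", covariates=("visit_age",))
    assert "education" in pt.ModelSpec("mmse").resolved_covariates
    assert "education" not in pt.ModelSpec("hv").resolved_covariates


def test_fit_report_shape_and_bh_column(prepared):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = pt.fit_report(prepared, ["mmse", "ptau181"])
    assert set(report["outcome"]) == {"mmse", "ptau181"}
    assert {"TM_vs_NC_B", "CY_vs_NC_B", "TM_vs_CY_B"} <= set(report.columns)
    csf = report[report["outcome"] == "ptau181"]
    assert csf["TM_vs_NC_p_bh"].notna().all()
    non_csf = report[report["outcome"] == "mmse"]
    assert non_csf["TM_vs_NC_p_bh"].isna().all()
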