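"""Pre-specified simulation designs for validating the pipeline.

These configurations are the study conditions under which the estimators'
statistical properties (parameter recovery, divergence-point recovery, null
calibration, mediation recovery, slope-test power) are measured. They generate
data from within the fitted model family - a linear-in-EYO base trajectory,
family random intercepts, independent Gaussian residuals - so that "truth" is
well-defined for every fitted coefficient and calibration statements refer to
a correctly specified model. The TM-CY separation, where present, is a linear
hinge: zero before the divergence EYO, growing at a constant rate after it.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .synthetic_cohort import OUTCOMES, CurveParams, SimConfig

__all__ = [
    "linear_recovery_config",
    "linear_recovery_truth_betas",
    "divergence_recovery_config",
    "divergence_null_config",
    "mediation_chain_table",
    "slope_cohort_table",
]

_EYO_MIN = -25.0


def _flat_curves(outcome: str, curve: CurveParams) -> dict[str, CurveParams]:
    curves = {
        k: dataclasses.replace(v, carrier_amp=0.0, tm_gap_rate=0.0)
        for k, v in SimConfig().curve_params.items()
    }
    curves[outcome] = curve
    return curves


def _sigmas(outcome, family, resid):
    return (
        {k: (family if k == outcome else 0.0) for k in OUTCOMES},
        {k: 0.0 for k in OUTCOMES},
        {k: (resid if k == outcome else 1.0) for k in OUTCOMES},
    )


def linear_recovery_config(
    seed: int,
    n_per_group: int = 200,
    carriers_per_family: int = 4,
    gap_rate: float = -0.10,
    sigma_family: float = 0.7,
    sigma_resid: float = 1.5,
) -> SimConfig:
    """Carrier-only cohort whose MMSE truth lies exactly in the span of the
    linear-EYO model: base slope plus a TM separation that is affine over the
    whole EYO range (hinged at the range minimum), so every fitted fixed
    effect has a closed-form true value (`linear_recovery_truth_betas`)."""
    curve = CurveParams(level=29.0, nc_slope=-0.10, onset_eyo=_EYO_MIN,
                        carrier_amp=0.0, width=10.0, tm_gap_rate=gap_rate)
    sf, ss, sr = _sigmas("mmse", sigma_family, sigma_resid)
    return SimConfig(
        n_per_group={"NC": 0, "CY": n_per_group, "TM": n_per_group},
        family_size_dist=tuple(
            [0.0] * (carriers_per_family - 1) + [1.0]
        ),
        curve_params=_flat_curves("mmse", curve),
        sigma_family=sf, sigma_subject=ss, sigma_resid=sr,
        covariate_effects={"mmse": {"education": 0.06}},
        true_divergence_eyo={"mmse": _EYO_MIN,
                             **{k: None for k in OUTCOMES if k != "mmse"}},
        seed=seed,
    )


def linear_recovery_truth_betas(config: SimConfig) -> dict[str, float]:
    """True fixed effects of the linear-EYO MMSE model for a CY-reference,
    carrier-only fit of a `linear_recovery_config` cohort."""
    cp = config.curve_params["mmse"]
    div = config.true_divergence_eyo["mmse"]
    rate = cp.tm_gap_rate
    edu = config.covariate_effects.get("mmse", {}).get("education", 0.0)
    # TM - CY difference = rate * (e - div) is affine: main effect -rate*div
    return {
        "intercept": cp.level,
        "visit_age": 0.0,
        "sex_M": 0.0,
        "apoe4_carrier": 0.0,
        "education": edu,
        "eyo1": cp.nc_slope,
        "TM": -rate * div,
        "TM:eyo1": rate,
    }


def divergence_recovery_config(
    seed: int,
    n_per_group: int = 200,
    divergence_eyo: float = -10.0,
    gap_at_eyo0: float = 1.0,
    sigma_family: float = 0.3,
    sigma_resid: float = 1.0,
) -> SimConfig:
    """Carrier cohort with a known TM-CY divergence: linear base trajectory,
    and a linear-hinge gap that reaches ``gap_at_eyo0`` residual-SDs at EYO 0.
    """
    rate = -gap_at_eyo0 * sigma_resid / abs(divergence_eyo)
    curve = CurveParams(level=29.0, nc_slope=-0.10, onset_eyo=_EYO_MIN,
                        carrier_amp=0.0, width=10.0, tm_gap_rate=rate)
    sf, ss, sr = _sigmas("mmse", sigma_family, sigma_resid)
    return SimConfig(
        n_per_group={"NC": 0, "CY": n_per_group, "TM": n_per_group},
        curve_params=_flat_curves("mmse", curve),
        sigma_family=sf, sigma_subject=ss, sigma_resid=sr,
        covariate_effects={},
        true_divergence_eyo={"mmse": divergence_eyo,
                             **{k: None for k in OUTCOMES if k != "mmse"}},
        seed=seed,
    )


def divergence_null_config(
    seed: int,
    n_per_group: int = 100,
    sigma_family: float = 0.3,
    sigma_resid: float = 1.0,
) -> SimConfig:
    """Identical TM and CY mean curves: any reported divergence is a false
    positive (used to check calibration of the credible-exclusion rule)."""
    curve = CurveParams(level=29.0, nc_slope=-0.10, onset_eyo=_EYO_MIN,
                        carrier_amp=0.0, width=10.0, tm_gap_rate=0.0)
    sf, ss, sr = _sigmas("mmse", sigma_family, sigma_resid)
    return SimConfig(
        n_per_group={"NC": 0, "CY": n_per_group, "TM": n_per_group},
        curve_params=_flat_curves("mmse", curve),
        sigma_family=sf, sigma_subject=ss, sigma_resid=sr,
        covariate_effects={},
        true_divergence_eyo={k: None for k in OUTCOMES},
        seed=seed,
    )


def mediation_chain_table(
    seed: int,
    n_per_group: int = 250,
    a_path: float = 1.0,
    b_path: float = 0.8,
    direct: float = 0.0,
    mediator_noise_sd: float = 1.0,
    outcome_noise_sd: float = 1.0,
) -> pd.DataFrame:
    """Cross-sectional group -> mediator -> outcome chain with known paths.

    With ``direct = 0`` the group effect on the outcome is fully mediated.
    Standard covariate columns are generated with no effect so the mediation
    module's default covariate set can be used unchanged.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x636861]))
    n = 2 * n_per_group
    group = np.repeat(["TM", "CY"], n_per_group)
    g = (group == "TM").astype(float)
    mediator = a_path * g + rng.normal(0.0, mediator_noise_sd, n)
    outcome = (
        b_path * mediator + direct * g + rng.normal(0.0, outcome_noise_sd, n)
    )
    return pd.DataFrame({
        "subject_id": [f"S{i + 1:04d}" for i in range(n)],
        "family_id": [f"F{i // 2 + 1:04d}" for i in range(n)],  # sibling pairs
        "visit": 1,
        "group": group,
        "visit_age": rng.normal(40.0, 8.0, n),
        "sex_M": rng.integers(0, 2, n).astype(float),
        "apoe4_carrier": rng.integers(0, 2, n).astype(float),
        "education": rng.normal(15.0, 2.8, n),
        "hv": mediator,
        "mmse": outcome,
    })


def slope_cohort_table(
    seed: int,
    n_per_group: int = 60,
    slope_gap_sd: float = 1.0,
    slope_sd: float = 0.5,
    visit_noise_sd: float = 0.1,
    n_visits: int = 4,
    visit_interval: float = 1.2,
    baseline_eyo_range: tuple[float, float] = (-10.0, 0.0),
) -> pd.DataFrame:
    """Longitudinal carriers whose true annualized slopes differ between TM
    and CY by ``slope_gap_sd`` between-subject slope SDs (TM declines faster).
    Small visit-level noise keeps extracted OLS slopes close to the truth."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x736c70]))
    rows = []
    for gi, grp in enumerate(("CY", "TM")):
        mu = -1.0 - (slope_gap_sd * slope_sd if grp == "TM" else 0.0)
        slopes = rng.normal(mu, slope_sd, n_per_group)
        base_eyo = rng.uniform(*baseline_eyo_range, n_per_group)
        base_age = rng.uniform(35.0, 50.0, n_per_group)
        intercepts = rng.normal(25.0, 2.0, n_per_group)
        for i in range(n_per_group):
            sid = f"S{gi * n_per_group + i + 1:04d}"
            for v in range(n_visits):
                t = v * visit_interval
                rows.append({
                    "subject_id": sid,
                    "family_id": sid.replace("S", "F"),
                    "group": grp,
                    "visit": v + 1,
                    "visit_age": base_age[i] + t,
                    "eyo": base_eyo[i] + t,
                    "mmse": intercepts[i] + slopes[i] * t
                    + rng.normal(0.0, visit_noise_sd),
                })
    return pd.DataFrame(rows)
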