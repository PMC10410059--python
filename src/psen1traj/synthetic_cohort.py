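"""Simulate ADAD-like observational cohorts with known ground truth.

The generator emulates the statistical structure the downstream mixed models
assume: three groups of sibling participants (non-carriers NC, cytoplasmic CY
and transmembrane TM PSEN1 variant carriers) clustered in families, observed
longitudinally across expected years to symptom onset (EYO = age minus the
family's expected age at onset). Each outcome follows a group-specific mean
curve over EYO plus family, subject and residual Gaussian noise.

Mean-curve family
-----------------
Non-carriers follow ``level + nc_slope * eyo`` (mild normal ageing). Carriers
add a hinged natural-cubic disease term that is flat before ``onset_eyo`` and
accelerates after it::

    carrier(e) = level + nc_slope * e + carrier_amp * ((e - onset)/width)^3_+

TM carriers additionally separate from CY carriers by a linear hinge that is
exactly zero before the configured divergence EYO::

    tm(e) = carrier(e) + tm_gap_rate * (e - divergence_eyo)_+

so TM and CY mean curves are identical below the divergence point *by
construction*, which makes the true divergence EYO a well-defined quantity for
recovery tests of the divergence estimator.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError

__all__ = [
    "OUTCOMES",
    "PIB_REGIONS",
    "CurveParams",
    "SimConfig",
    "GroundTruth",
    "simulate_cohort",
    "truth_difference_curve",
    "write_cohort",
    "write_truth",
    "read_truth",
]

#: Outcomes carried by the simulator. ``hv`` is the bilateral hippocampal
#: volume in mm^3 (before left/right split and ICV coupling), ``pib`` the
#: cortical composite PiB SUVR, CSF analytes in pg/mL or ratio units.
OUTCOMES = ("mmse", "cdr_sb", "hv", "pib", "ptau181", "ab4240")

#: Regions entering the cortical composite SUVR (each with lh/rh columns).
PIB_REGIONS = (
    "lat_orbitofrontal",
    "med_orbitofrontal",
    "rostral_middle_frontal",
    "superior_frontal",
    "superior_temporal",
    "middle_temporal",
    "precuneus",
)


@dataclass(frozen=True)
class CurveParams:
    """Mean-trajectory parameters for one outcome.

    level / nc_slope define the non-carrier line; onset_eyo, carrier_amp and
    width define the carriers' hinged-cubic disease term; tm_gap_rate is the
    post-divergence linear separation of TM from CY (outcome units per year).
    """

    level: float
    nc_slope: float = 0.0
    onset_eyo: float = -15.0
    carrier_amp: float = 0.0
    width: float = 10.0
    tm_gap_rate: float = 0.0


def _default_curves() -> dict[str, CurveParams]:
    return {
        "mmse": CurveParams(29.0, -0.03, -12.0, -3.0, 10.0, -0.30),
        "cdr_sb": CurveParams(0.2, 0.0, -8.0, 2.5, 10.0, 0.25),
        "hv": CurveParams(3600.0, -6.0, -15.0, -150.0, 10.0, -25.0),
        "pib": CurveParams(1.05, 0.0, -18.0, 0.25, 10.0, 0.005),
        "ptau181": CurveParams(25.0, 0.1, -20.0, 8.0, 10.0, 3.0),
        "ab4240": CurveParams(0.090, 0.0, -22.0, -0.004, 10.0, 0.0),
    }


def _default_divergence() -> dict[str, float | None]:
    # Defaults for demonstration cohorts; recovery experiments set their own.
    return {
        "mmse": -3.8,
        "cdr_sb": -1.1,
        "hv": -10.9,
        "pib": -8.4,
        "ptau181": 3.1,
        "ab4240": None,
    }


def _default_sigma(kind: str) -> dict[str, float]:
    table = {
        "family": {"mmse": 0.7, "cdr_sb": 0.2, "hv": 120.0, "pib": 0.08,
                   "ptau181": 5.0, "ab4240": 0.004},
        "subject": {"mmse": 1.0, "cdr_sb": 0.5, "hv": 180.0, "pib": 0.12,
                    "ptau181": 8.0, "ab4240": 0.006},
        "resid": {"mmse": 1.5, "cdr_sb": 0.6, "hv": 230.0, "pib": 0.15,
                  "ptau181": 12.0, "ab4240": 0.010},
    }
    return dict(table[kind])


def _default_covariate_effects() -> dict[str, dict[str, float]]:
    # Units: outcome units per covariate unit; sex/apoe4 are 0/1 indicators
    # (male, epsilon4 carrier); icv couples raw volumes to head size.
    return {
        "mmse": {"education": 0.06},
        "hv": {"icv": 0.0012},
    }


@dataclass(frozen=True)
class SimConfig:
    """Full description of a simulated cohort; the defaults emulate the DIAN-like
    study structure (group sizes 202/65/135, EYO span -25..+10, ~3 years of
    longitudinal follow-up among returnees)."""

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"NC": 202, "CY": 65, "TM": 135}
    )
    #: probabilities of 1, 2, ... carriers per family
    family_size_dist: Sequence[float] = (0.70, 0.20, 0.07, 0.03)
    eyo_range: tuple[float, float] = (-25.0, 10.0)
    #: probabilities of 1, 2, ... visits per subject
    n_visits_dist: Sequence[float] = (0.45, 0.20, 0.13, 0.10, 0.07, 0.05)
    visit_interval_years: tuple[float, float] = (1.4, 0.35)  # mean, SD
    curve_params: Mapping[str, CurveParams] = field(default_factory=_default_curves)
    sigma_family: Mapping[str, float] = field(
        default_factory=lambda: _default_sigma("family")
    )
    sigma_subject: Mapping[str, float] = field(
        default_factory=lambda: _default_sigma("subject")
    )
    sigma_resid: Mapping[str, float] = field(
        default_factory=lambda: _default_sigma("resid")
    )
    covariate_effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_covariate_effects
    )
    true_divergence_eyo: Mapping[str, float | None] = field(
        default_factory=_default_divergence
    )
    # demographics (Bernoulli/truncated-normal parameters)
    p_female: float = 0.58
    p_apoe4: float = 0.30
    education_mean_sd: tuple[float, float] = (15.0, 2.8)
    education_bounds: tuple[float, float] = (6.0, 22.0)
    aao_mean_sd: tuple[float, float] = (47.0, 7.0)
    aao_bounds: tuple[float, float] = (30.0, 60.0)
    # measurement plumbing for raw columns
    icv_mean_sd: tuple[float, float] = (1.45e6, 1.4e5)
    lr_asym_sd: float = 40.0       # left/right hippocampus split around the mean
    suvr_region_sd: float = 0.04   # regional scatter around the composite
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.eyo_range
        if not lo < hi:
            raise ConfigError(f"eyo_range min must be < max, got {self.eyo_range}")
        for g, n in self.n_per_group.items():
            if n < 0:
                raise ConfigError(f"negative count for group {g}")
        if self.n_per_group.get("CY", 0) + self.n_per_group.get("TM", 0) <= 0:
            raise ConfigError("at least one carrier group must be non-empty")
        if self.visit_interval_years[0] <= 0:
            raise ConfigError("visit interval mean must be positive")
        for name, sig in (("sigma_family", self.sigma_family),
                          ("sigma_subject", self.sigma_subject),
                          ("sigma_resid", self.sigma_resid)):
            for k, v in sig.items():
                if v < 0:
                    raise ConfigError(f"{name}[{k!r}] must be >= 0")
        for dist_name, dist in (("family_size_dist", self.family_size_dist),
                                ("n_visits_dist", self.n_visits_dist)):
            p = np.asarray(dist, dtype=float)
            if (p < 0).any() or not np.isclose(p.sum(), 1.0):
                raise ConfigError(f"{dist_name} must be a probability vector")
        for out, d in self.true_divergence_eyo.items():
            rate = self.curve_params[out].tm_gap_rate if out in self.curve_params else 0.0
            if d is None and rate != 0.0:
                raise ConfigError(
                    f"{out}: tm_gap_rate != 0 requires a divergence EYO"
                )


def _hinge_cubic(e: np.ndarray, onset: float, width: float) -> np.ndarray:
    u = np.maximum(np.asarray(e, dtype=float) - onset, 0.0) / width
    return u ** 3


def _mean_curve(cp: CurveParams, group: str, eyo, divergence: float | None):
    e = np.asarray(eyo, dtype=float)
    base = cp.level + cp.nc_slope * e
    if group == "NC":
        return base
    val = base + cp.carrier_amp * _hinge_cubic(e, cp.onset_eyo, cp.width)
    if group == "TM" and divergence is not None and cp.tm_gap_rate != 0.0:
        val = val + cp.tm_gap_rate * np.maximum(e - divergence, 0.0)
    return val


@dataclass(frozen=True)
class GroundTruth:
    """Generating mean curves and true divergence points for recovery tests."""

    curve_params: Mapping[str, CurveParams]
    divergence_eyo: Mapping[str, float | None]
    covariate_effects: Mapping[str, Mapping[str, float]]

    def mean_curve(self, group: str, outcome: str, eyo) -> np.ndarray:
        """Evaluate the noiseless group mean trajectory at the given EYOs."""
        if outcome not in self.curve_params:
            raise ConfigError(f"unknown outcome {outcome!r}")
        return _mean_curve(
            self.curve_params[outcome], group, eyo, self.divergence_eyo.get(outcome)
        )


def truth_difference_curve(truth: GroundTruth, outcome: str, eyo_grid) -> np.ndarray:
    """True TM - CY mean difference on an EYO grid (zero below the divergence)."""
    grid = np.asarray(eyo_grid, dtype=float)
    return truth.mean_curve("TM", outcome, grid) - truth.mean_curve(
        "CY", outcome, grid
    )


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Draw by resampling out-of-bound values; exact for our mild truncations."""
    x = rng.normal(mean, sd, size)
    bad = (x < lo) | (x > hi)
    while bad.any():
        x[bad] = rng.normal(mean, sd, bad.sum())
        bad = (x < lo) | (x > hi)
    return x


def _draw_counts(rng, probs, n):
    return rng.choice(np.arange(1, len(probs) + 1), size=n, p=np.asarray(probs))


def simulate_cohort(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one cohort table (one row per participant-visit) plus its truth.

    Families are built around carriers: each family carries a single PSEN1
    variant (hence a single TM-or-CY identity), carriers are chunked into
    families by the family-size distribution, and non-carrier siblings are
    attached to existing carrier families at random. The family random
    intercept is shared by all members regardless of carrier status.

    Three RNG streams (structure, covariates, noise) are split from the seed so
    that, e.g., changing the visit distribution does not perturb covariate
    draws.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_struct, rng_cov, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )

    n_nc = int(config.n_per_group.get("NC", 0))
    n_cy = int(config.n_per_group.get("CY", 0))
    n_tm = int(config.n_per_group.get("TM", 0))

    # --- structure stream: families, variant codons, visit schedules -------
    families: list[dict] = []  # {"variant_group", "codon", "members": [...]}
    from .variant_domains import default_domain_table

    table = default_domain_table()
    tm_codons = np.concatenate(
        [np.arange(s, e + 1) for s, e, lab in table.intervals if lab == "TM"]
    )
    cy_codons = np.concatenate(
        [np.arange(s, e + 1) for s, e, lab in table.intervals if lab == "CY"]
    )

    def _chunk_carriers(n_car, group, codon_pool):
        remaining = n_car
        while remaining > 0:
            size = int(_draw_counts(rng_struct, config.family_size_dist, 1)[0])
            size = min(size, remaining)
            codon = int(rng_struct.choice(codon_pool))
            families.append(
                {"variant_group": group, "codon": codon, "carriers": size, "nc": 0}
            )
            remaining -= size

    _chunk_carriers(n_cy, "CY", cy_codons)
    _chunk_carriers(n_tm, "TM", tm_codons)
    if not families:  # NC-only cohorts are rejected by SimConfig validation
        raise ConfigError("no carrier families generated")
    # attach NC siblings to random carrier families
    nc_fam = rng_struct.integers(0, len(families), size=n_nc)
    for j in nc_fam:
        families[j]["nc"] += 1

    subj_rows = []
    sid = 0
    for fid, fam in enumerate(families):
        for _ in range(fam["carriers"]):
            subj_rows.append((sid, fid, fam["variant_group"], fam["codon"]))
            sid += 1
        for _ in range(fam["nc"]):
            subj_rows.append((sid, fid, "NC", None))
            sid += 1
    n_subj = len(subj_rows)

    n_visits = _draw_counts(rng_struct, config.n_visits_dist, n_subj)
    mu_iv, sd_iv = config.visit_interval_years
    intervals = [
        _truncated_normal(rng_struct, mu_iv, sd_iv, 0.25, mu_iv + 6 * sd_iv + 1,
                          int(k - 1))
        for k in n_visits
    ]

    # --- covariate stream ---------------------------------------------------
    lo_e, hi_e = config.eyo_range
    baseline_eyo = rng_cov.uniform(lo_e, hi_e, n_subj)
    aao = _truncated_normal(rng_cov, *config.aao_mean_sd, *config.aao_bounds, n_subj)
    sex_f = rng_cov.random(n_subj) < config.p_female
    apoe4 = rng_cov.random(n_subj) < config.p_apoe4
    edu = _truncated_normal(
        rng_cov, *config.education_mean_sd, *config.education_bounds, n_subj
    )
    icv = rng_cov.normal(*config.icv_mean_sd, n_subj)

    # --- noise stream: random effects and residuals -------------------------
    fam_eff = {
        out: rng_noise.normal(0.0, config.sigma_family.get(out, 0.0), len(families))
        for out in OUTCOMES
    }
    subj_eff = {
        out: rng_noise.normal(0.0, config.sigma_subject.get(out, 0.0), n_subj)
        for out in OUTCOMES
    }

    truth = GroundTruth(
        curve_params=dict(config.curve_params),
        divergence_eyo=dict(config.true_divergence_eyo),
        covariate_effects={k: dict(v) for k, v in config.covariate_effects.items()},
    )

    records = []
    for i, (sid_i, fid_i, group_i, codon_i) in enumerate(subj_rows):
        offsets = np.concatenate([[0.0], np.cumsum(intervals[i])])
        for v, off in enumerate(offsets, start=1):
            eyo_v = baseline_eyo[i] + off
            age_v = aao[i] + eyo_v
            rec = {
                "subject_id": f"S{sid_i + 1:04d}",
                "family_id": f"F{fid_i + 1:03d}",
                "group": group_i,
                "codon": codon_i,
                "visit": v,
                "visit_age": age_v,
                "sex": "F" if sex_f[i] else "M",
                "apoe4": "carrier" if apoe4[i] else "non-carrier",
                "education": edu[i],
                "expected_aao": aao[i],
                "icv": icv[i],
            }
            for out in OUTCOMES:
                cp = config.curve_params[out]
                val = float(
                    _mean_curve(cp, group_i, eyo_v,
                                config.true_divergence_eyo.get(out))
                )
                eff = config.covariate_effects.get(out, {})
                val += eff.get("education", 0.0) * edu[i]
                val += eff.get("age", 0.0) * age_v
                val += eff.get("sex", 0.0) * (0.0 if sex_f[i] else 1.0)
                val += eff.get("apoe4", 0.0) * (1.0 if apoe4[i] else 0.0)
                if out == "hv":
                    val += eff.get("icv", 0.0) * (icv[i] - config.icv_mean_sd[0])
                val += fam_eff[out][fid_i] + subj_eff[out][i]
                val += rng_noise.normal(0.0, config.sigma_resid.get(out, 0.0))
                rec[f"__{out}"] = val
            records.append(rec)

    df = pd.DataFrame.from_records(records)

    # raw measurement columns: hippocampus split L/R, regional SUVRs
    hv = df.pop("__hv").to_numpy()
    asym = rng_noise.normal(0.0, config.lr_asym_sd, len(df))
    df["hv_left"] = hv + asym
    df["hv_right"] = hv - asym
    pib = df.pop("__pib").to_numpy()
    for region in PIB_REGIONS:
        for hemi in ("lh", "rh"):
            df[f"pib_suvr_{region}_{hemi}"] = pib + rng_noise.normal(
                0.0, config.suvr_region_sd, len(df)
            )
    df["mmse"] = df.pop("__mmse")
    df["cdr_sb"] = df.pop("__cdr_sb")
    df["csf_ptau181"] = df.pop("__ptau181")
    df["csf_ab42_ab40"] = df.pop("__ab4240")

    # stable column order
    lead = ["subject_id", "family_id", "group", "codon", "visit", "visit_age",
            "sex", "apoe4", "education", "expected_aao", "icv",
            "hv_left", "hv_right"]
    suvr_cols = [f"pib_suvr_{r}_{h}" for r in PIB_REGIONS for h in ("lh", "rh")]
    df = df[lead + suvr_cols + ["mmse", "cdr_sb", "csf_ptau181", "csf_ab42_ab40"]]
    return df, truth


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    """Comma-separated, header row, UTF-8, 'NA' for missing; fixed float text."""
    df.to_csv(path, index=False, na_rep="NA", float_format="%.10g")


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    doc = {
        "curve_params": {
            k: dataclasses.asdict(v) for k, v in truth.curve_params.items()
        },
        "divergence_eyo": dict(truth.divergence_eyo),
        "covariate_effects": {k: dict(v) for k, v in truth.covariate_effects.items()},
    }
    with open(path, "wt", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_truth(path: str | Path) -> GroundTruth:
    with open(path, "rt", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return GroundTruth(
        curve_params={k: CurveParams(**v) for k, v in doc["curve_params"].items()},
        divergence_eyo=doc["divergence_eyo"],
        covariate_effects=doc.get("covariate_effects", {}),
    )
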