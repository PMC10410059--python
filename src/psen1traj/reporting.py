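"""Demographics tables, formatted reports, and reproducible run archives.

Demographics follow the conventional baseline table: mean (SD) for continuous
characteristics and % for categorical ones, with pairwise between-group tests
(t-tests for continuous, chi-square on contingency counts for categorical;
no continuity correction by default, no multiplicity adjustment — each pair is
tested on its own). Every human-readable report written here is rounded at a
documented precision and accompanied by a full-precision machine-readable
twin. Archives contain no timestamps, so a rerun from the same seed is
byte-identical.
"""

from __future__ import annotations

import json
import logging
import shutil
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "DemographicsReport",
    "demographics",
    "write_report",
    "run_report",
]

_CONTINUOUS = (
    ("education", "Education, years"),
    ("visit_age", "Age at visit, years"),
    ("expected_aao", "AAO, years"),
    ("eyo", "EYO, years"),
)
_CATEGORICAL = (
    ("sex", "F", "Female, %"),
    ("apoe4", "carrier", "APOE e4 carrier, %"),
)


@dataclass(frozen=True)
class DemographicsReport:
    summary: pd.DataFrame  # characteristic x group: mean (SD) or %
    tests: pd.DataFrame    # pairwise statistics, p-values, significance flags


def demographics(
    table: pd.DataFrame,
    groups: tuple[str, ...] = ("NC", "CY", "TM"),
    equal_var: bool = False,
    yates: bool = False,
    alpha: float = 0.05,
) -> DemographicsReport:
    """Baseline (first-visit) characteristics by group with pairwise tests."""
    base = (
        table.sort_values(["subject_id", "visit"])
        .groupby("subject_id", observed=True)
        .head(1)
    )
    present = [g for g in groups if (base["group"].astype(str) == g).any()]
    small = [
        g for g in present
        if (base["group"].astype(str) == g).sum() < 2
    ]
    if small:
        warnings.warn(
            f"group(s) {small} have < 2 subjects; between-group tests suppressed"
        )

    sub = {g: base[base["group"].astype(str) == g] for g in present}
    summary_rows = {}
    for col, label in _CONTINUOUS:
        if col not in base.columns:
            continue
        summary_rows[label] = {
            g: f"{sub[g][col].mean():.1f} ({sub[g][col].std(ddof=1):.1f})"
            for g in present
        }
    for col, pos, label in _CATEGORICAL:
        if col not in base.columns:
            continue
        summary_rows[label] = {
            g: f"{100.0 * (sub[g][col] == pos).mean():.1f}" for g in present
        }
    summary = pd.DataFrame(summary_rows).T[present]

    pairs = [(a, b) for i, a in enumerate(present) for b in present[i + 1:]]
    test_rows = []
    for col, label in _CONTINUOUS:
        if col not in base.columns:
            continue
        for a, b in pairs:
            if a in small or b in small:
                continue
            x = sub[a][col].dropna()
            y = sub[b][col].dropna()
            res = stats.ttest_ind(x, y, equal_var=equal_var)
            test_rows.append({
                "characteristic": label, "pair": f"{a} vs {b}", "test": "t",
                "statistic": float(res.statistic), "p": float(res.pvalue),
                "significant": bool(res.pvalue < alpha),
            })
    for col, pos, label in _CATEGORICAL:
        if col not in base.columns:
            continue
        for a, b in pairs:
            if a in small or b in small:
                continue
            counts = np.array([
                [(sub[g][col] == pos).sum(), (sub[g][col] != pos).sum()]
                for g in (a, b)
            ])
            if (counts.sum(axis=0) == 0).any():
                continue
            chi2, p, _, _ = stats.chi2_contingency(counts, correction=yates)
            test_rows.append({
                "characteristic": label, "pair": f"{a} vs {b}",
                "test": "chi-square", "statistic": float(chi2), "p": float(p),
                "significant": bool(p < alpha),
            })
    tests = pd.DataFrame(
        test_rows,
        columns=["characteristic", "pair", "test", "statistic", "p",
                 "significant"],
    )
    return DemographicsReport(summary=summary, tests=tests)


def write_report(df: pd.DataFrame, path: str | Path, precision: int = 4) -> None:
    """Rounded human-readable CSV plus a '.full.csv' full-precision twin."""
    path = Path(path)
    rounded = df.copy()
    for c in rounded.columns:
        if pd.api.types.is_float_dtype(rounded[c]):
            rounded[c] = rounded[c].round(precision)
    rounded.to_csv(path, index=False, na_rep="NA")
    twin = path.with_suffix(".full.csv")
    df.to_csv(twin, index=False, na_rep="NA", float_format="%.17g")


def run_report(
    out_dir: str | Path,
    stage_outputs: dict[str, str | Path],
    config: dict,
    seed: int,
) -> dict:
    """Assemble a reproducibility archive: stage reports + config + seed +
    software version, with a manifest noting any missing stage."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "psen1traj",
        "version": __version__,
        "seed": int(seed),
        "stages": {},
    }
    for stage in sorted(stage_outputs):
        src = Path(stage_outputs[stage])
        if not src.exists():
            logger.warning("stage %s output missing: %s", stage, src)
            manifest["stages"][stage] = {"file": None, "status": "missing"}
            continue
        dest = out_dir / src.name
        if src.resolve() != dest.resolve():
            shutil.copyfile(src, dest)
        manifest["stages"][stage] = {"file": src.name, "status": "present"}
    with open(out_dir / "config.yaml", "wt", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    with open(out_dir / "manifest.json", "wt", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def plot_divergence(result, path: str | Path) -> None:
    """Convenience credible-band plot of the TM-CY difference curve."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(result.eyo_grid, result.lower, result.upper, alpha=0.3,
                    label=f"{result.credible_level:.0%} credible band")
    ax.plot(result.eyo_grid, result.median, lw=1.5, label="posterior median")
    ax.axhline(0.0, color="k", lw=0.8)
    if result.divergence_eyo is not None:
        ax.axvline(result.divergence_eyo, color="k", ls=":",
                   label=f"divergence EYO = {result.divergence_eyo:.1f}")
    ax.set_xlabel("EYO (years)")
    ax.set_ylabel(f"{result.groups[0]} - {result.groups[1]} difference")
    ax.set_title(result.outcome)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
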