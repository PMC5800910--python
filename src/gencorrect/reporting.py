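"""Baseline characteristics table, cumulative incidence and pipeline orchestration.

The baseline table contrasts subjects with and without incident digestive
cancer: normally distributed continuous variables as mean +/- SD compared by
Student's t-test; the right-skewed serum biomarkers as median (IQR) compared
by the Mann-Whitney U test; categorical variables as n (%) compared by the
Pearson chi-squared test without continuity correction.  The skewed set is
fixed by variable list (the biomarkers), not by a normality test, so the
report is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import BIOMARKER_COLUMNS, Cohort, write_cohort
from .correction import CorrectedLevels, correct_levels
from .concordance import run_c_suite
from .panel import CorrectionPanel, load_snp_panel
from .risk import run_model_suite
from .simulate import SimulationConfig, simulate_cohort

__all__ = [
    "baseline_table",
    "cumulative_incidence",
    "incidence_rate_per_1000",
    "percent_change",
    "chi_squared_test",
    "run_pipeline",
]

_CONTINUOUS = (("age", "Age (years)"), ("bmi", "BMI (kg/m2)"))
_CATEGORICAL = (
    ("sex", "Gender", ("male", "female")),
    ("smoking", "Smoking status", ("ever", "never")),
    ("drinking", "Drinking status", ("ever", "never")),
    ("physical_activity", "Physical activity", ("yes", "no")),
    ("family_history", "Family history of cancer", ("yes", "no")),
)


def chi_squared_test(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared on a contingency table, no continuity correction."""
    chi2, p, _, _ = stats.chi2_contingency(np.asarray(table), correction=False)
    return float(chi2), float(p)


def _fmt_mean_sd(x: pd.Series) -> str:
    return f"{x.mean():.2f} ± {x.std():.2f}"


def _fmt_median_iqr(x: pd.Series) -> str:
    q1, med, q3 = x.quantile([0.25, 0.5, 0.75])
    return f"{med:.2f} ({q1:.2f}-{q3:.2f})"


def baseline_table(
    cohort: Cohort, corrected: CorrectedLevels | None = None
) -> pd.DataFrame:
    """Case vs non-case baseline table with per-variable significance tests.

    One row per characteristic (plus one row per level for categorical
    variables); columns: summaries for both groups, the test used and its
    two-sided p-value.  Per-variable denominators are printed so partially
    missing variables are explicit.
    """
    ph = cohort.phenotypes
    cases = ph[ph["event"] == 1]
    ctrls = ph[ph["event"] == 0]
    if len(cases) == 0 or len(ctrls) == 0:
        raise ValueError("baseline table needs >= 1 case and >= 1 non-case")
    rows = []

    for col, label in _CONTINUOUS:
        a, b = cases[col].dropna(), ctrls[col].dropna()
        _, p = stats.ttest_ind(a, b, equal_var=True)
        rows.append(
            {
                "characteristic": label,
                "level": "",
                "cases": _fmt_mean_sd(a),
                "non_cases": _fmt_mean_sd(b),
                "n_cases": len(a),
                "n_non_cases": len(b),
                "test": "t-test",
                "p_value": float(p),
            }
        )

    for col, label, levels in _CATEGORICAL:
        counts = np.array(
            [[int((g[col] == lv).sum()) for g in (cases, ctrls)] for lv in levels]
        )
        _, p = chi_squared_test(counts.T)
        rows.append(
            {
                "characteristic": label,
                "level": "",
                "cases": "",
                "non_cases": "",
                "n_cases": int(counts[:, 0].sum()),
                "n_non_cases": int(counts[:, 1].sum()),
                "test": "chi-squared",
                "p_value": float(p),
            }
        )
        for lv, (nc, nn) in zip(levels, counts):
            rows.append(
                {
                    "characteristic": label,
                    "level": lv,
                    "cases": f"{nc} ({100 * nc / counts[:, 0].sum():.1f}%)",
                    "non_cases": f"{nn} ({100 * nn / counts[:, 1].sum():.1f}%)",
                    "n_cases": int(nc),
                    "n_non_cases": int(nn),
                    "test": "",
                    "p_value": np.nan,
                }
            )

    marker_series = {
        f"{m} (raw)": ph[col] for m, col in BIOMARKER_COLUMNS.items()
    }
    if corrected is not None:
        for m in corrected.biomarkers:
            marker_series[f"{m} (genetic corrected)"] = corrected.corrected(m)
    for label, series in marker_series.items():
        a = series.loc[cases.index].dropna()
        b = series.loc[ctrls.index].dropna()
        _, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append(
            {
                "characteristic": label,
                "level": "",
                "cases": _fmt_median_iqr(a),
                "non_cases": _fmt_median_iqr(b),
                "n_cases": len(a),
                "n_non_cases": len(b),
                "test": "Mann-Whitney U",
                "p_value": float(p),
            }
        )
    return pd.DataFrame(rows)


def incidence_rate_per_1000(n_events: int, n_total: int) -> float:
    """Cumulative incidence per 1,000 subjects, reported at 2 dp."""
    if n_total <= 0:
        raise ValueError("cohort is empty")
    return round(1000.0 * n_events / n_total, 2)


def cumulative_incidence(cohort: Cohort) -> float:
    """Cumulative incidence of digestive cancer per 1,000, at 2 dp."""
    return incidence_rate_per_1000(cohort.n_events, cohort.n_subjects)


def percent_change(mean_raw: float, mean_corrected: float) -> float:
    """Percent reduction of the mean level by correction:
    ``100 * (raw - corrected) / raw`` (negative if correction raises it)."""
    if mean_raw == 0:
        raise ValueError("raw mean is zero")
    return 100.0 * (mean_raw - mean_corrected) / mean_raw


def run_pipeline(
    config: SimulationConfig | None = None,
    out_dir: str | Path = "gencorrect-report",
    panels: Sequence[CorrectionPanel] | None = None,
    cohort: Cohort | None = None,
    write_cohort_files: bool = False,
) -> dict:
    """simulate/load -> correct -> baseline -> risk ORs -> discrimination.

    Writes the three report tables (baseline, OR grid, C grid) as TSV, a
    correction summary, and a provenance log; byte-identical across runs at
    a fixed seed.  Returns the in-memory bundle.
    """
    config = config or SimulationConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panels = list(panels) if panels is not None else load_snp_panel()

    stage = "simulate"
    try:
        if cohort is None:
            cohort = simulate_cohort(config, panels)
        stage = "correct"
        corrected = correct_levels(cohort, panels)
        stage = "baseline"
        table1 = baseline_table(cohort, corrected)
        stage = "risk"
        table3 = run_model_suite(cohort, corrected)
        stage = "discrimination"
        table4 = run_c_suite(cohort, corrected)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    summary = corrected.summary().reset_index()
    table1.to_csv(out / "baseline_table.tsv", sep="\t", index=False)
    table3.to_csv(out / "odds_ratios.tsv", sep="\t", index=False)
    table4.to_csv(out / "concordance.tsv", sep="\t", index=False)
    summary.to_csv(out / "correction_summary.tsv", sep="\t", index=False)
    if write_cohort_files:
        write_cohort(cohort, out / "phenotypes.tsv", out / "genotypes.tsv")

    provenance = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": {
            "n_subjects": config.n_subjects,
            "target_incidence": config.target_incidence,
            "followup_years": config.followup_years,
            "log_sd": dict(config.log_sd),
            "baseline_level": dict(config.baseline_level),
            "disease_effect": dict(config.disease_effect),
        },
        "n_subjects": cohort.n_subjects,
        "n_events": cohort.n_events,
        "cumulative_incidence_per_1000": cumulative_incidence(cohort),
        "stages": ["simulate", "correct", "baseline", "risk", "discrimination"],
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))
    return {
        "cohort": cohort,
        "corrected": corrected,
        "baseline_table": table1,
        "odds_ratios": table3,
        "concordance": table4,
        "summary": summary,
        "provenance": provenance,
    }
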