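"""Logistic risk models: odds ratios for raw vs corrected biomarker exposures.

Unconditional logistic regression of incident digestive cancer on each
exposure, under three nested covariate models:

* Model 1 - crude;
* Model 2 - age + sex;
* Model 3 - age + sex + BMI + smoking + drinking + physical activity +
  family history of cancer.

Exposures are standardized to mean-zero unit-SD *log* levels, so every
odds ratio is per 1 SD of log biomarker level; the serum markers are
strongly right-skewed and a per-unit OR would be dominated by outliers.
The three-marker combination score is, by default, the re-standardized
equal-weight sum of the three per-marker z-scores, with a "joint" mode
(in-sample logistic linear predictor on the three z-scores) as an
alternative weighting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import BIOMARKER_COLUMNS, Cohort
from .correction import CorrectedLevels

__all__ = [
    "RiskModelResult",
    "standardize_exposure",
    "fit_logistic",
    "combination_score",
    "model_covariates",
    "run_model_suite",
    "MODEL_IDS",
]

MODEL_IDS = (1, 2, 3)
_Z95 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class RiskModelResult:
    """One cell of the OR grid: exposure x covariate model."""

    exposure: str
    model_id: int
    odds_ratio: float
    ci95: tuple[float, float]
    p_value: float
    n_events: int
    n_total: int
    beta: float
    se: float
    loglik: float

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo <= self.odds_ratio <= hi):
            raise ValueError("CI must contain the odds ratio")


def standardize_exposure(levels) -> np.ndarray:
    """z-score the natural-log levels: mean 0, SD 1 (population SD)."""
    x = np.asarray(levels, dtype=float)
    if (x <= 0).any():
        raise ValueError("levels must be positive")
    logx = np.log(x)
    sd = logx.std()
    if sd == 0:
        raise ValueError("levels have zero variance")
    return (logx - logx.mean()) / sd


def fit_logistic(
    outcome,
    exposure,
    covariates: pd.DataFrame | None = None,
    *,
    exposure_label: str = "exposure",
    model_id: int = 1,
) -> RiskModelResult:
    """Maximum-likelihood logistic fit; OR and Wald 95% CI for the exposure.

    ``covariates`` (optional) enter linearly alongside the exposure.  Raises
    on degenerate outcomes (all 0 or all 1) and on separation.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure, dtype=float)
    if y.min() == y.max():
        raise ValueError("outcome has no variation (need >= 1 event and >= 1 non-event)")
    cols = {"exposure": x}
    if covariates is not None:
        for c in covariates.columns:
            cols[c] = covariates[c].to_numpy(dtype=float)
    # a binary predictor with an empty predictor-by-outcome cell has a
    # divergent MLE (quasi-complete separation): reject it by name
    for name, v in cols.items():
        lv = np.unique(v)
        if lv.size == 2:
            for val in lv:
                if y[v == val].min() == y[v == val].max():
                    raise ValueError(
                        f"quasi-complete separation on {name!r} "
                        f"(no outcome variation at {name} = {val})"
                    )
    X = sm.add_constant(pd.DataFrame(cols))
    try:
        fit = sm.Logit(y, X).fit(disp=0, method="newton", tol=1e-10, maxiter=100)
    except np.linalg.LinAlgError as err:
        raise ValueError(f"logistic fit failed (collinear covariates?): {err}") from err
    except Exception as err:  # statsmodels PerfectSeparationError
        if "Separation" in type(err).__name__ or "separation" in str(err).lower():
            raise ValueError(f"perfect separation on {exposure_label!r}") from err
        raise
    beta = float(fit.params["exposure"])
    se = float(fit.bse["exposure"])
    return RiskModelResult(
        exposure=exposure_label,
        model_id=model_id,
        odds_ratio=float(np.exp(beta)),
        ci95=(float(np.exp(beta - _Z95 * se)), float(np.exp(beta + _Z95 * se))),
        p_value=float(fit.pvalues["exposure"]),
        n_events=int(y.sum()),
        n_total=int(y.size),
        beta=beta,
        se=se,
        loglik=float(fit.llf),
    )


def combination_score(
    afp,
    ca199,
    cea,
    mode: str = "sum",
    outcome=None,
) -> np.ndarray:
    """Three-marker combination score on the standardized log scale.

    ``"sum"`` (default): equal-weight sum of the three per-marker z-scores,
    re-standardized to unit SD.  ``"joint"``: in-sample logistic linear
    predictor on the three z-scores (requires ``outcome``), standardized.
    """
    zs = np.column_stack(
        [standardize_exposure(afp), standardize_exposure(ca199), standardize_exposure(cea)]
    )
    if mode == "sum":
        s = zs.sum(axis=1)
    elif mode == "joint":
        if outcome is None:
            raise ValueError("joint mode requires the outcome vector")
        y = np.asarray(outcome, dtype=float)
        fit = sm.Logit(y, sm.add_constant(zs)).fit(disp=0)
        s = zs @ fit.params[1:]
    else:
        raise ValueError(f"unknown combination mode {mode!r}")
    sd = s.std()
    if sd == 0:
        raise ValueError("combination score has zero variance")
    return (s - s.mean()) / sd


def model_covariates(cohort: Cohort, model_id: int) -> pd.DataFrame | None:
    """Covariate design for one of the three nested models (None for crude)."""
    ph = cohort.phenotypes
    if model_id == 1:
        return None
    cov = pd.DataFrame(index=ph.index)
    cov["age"] = ph["age"].astype(float)
    cov["male"] = (ph["sex"] == "male").astype(float)
    if model_id == 2:
        return cov
    if model_id == 3:
        cov["bmi"] = ph["bmi"].astype(float)
        cov["smoking"] = (ph["smoking"] == "ever").astype(float)
        cov["drinking"] = (ph["drinking"] == "ever").astype(float)
        cov["physical_activity"] = (ph["physical_activity"] == "yes").astype(float)
        cov["family_history"] = (ph["family_history"] == "yes").astype(float)
        return cov
    raise ValueError(f"unknown model id {model_id}")


def exposure_grid(
    cohort: Cohort,
    corrected: CorrectedLevels,
    combination_mode: str = "sum",
) -> dict[tuple[str, str], np.ndarray]:
    """Standardized exposures keyed ``(marker-or-combination, raw|corrected)``."""
    y = cohort.phenotypes["event"].to_numpy()
    grid: dict[tuple[str, str], np.ndarray] = {}
    for m in corrected.biomarkers:
        grid[(m, "raw")] = standardize_exposure(corrected.raw(m))
        grid[(m, "corrected")] = standardize_exposure(corrected.corrected(m))
    for kind in ("raw", "corrected"):
        levels = [
            corrected.raw(m) if kind == "raw" else corrected.corrected(m)
            for m in ("AFP", "CA19-9", "CEA")
        ]
        grid[("combination", kind)] = combination_score(
            *levels, mode=combination_mode, outcome=y
        )
    return grid


def run_model_suite(
    cohort: Cohort,
    corrected: CorrectedLevels,
    models: Sequence[int] = MODEL_IDS,
    combination_mode: str = "sum",
) -> pd.DataFrame:
    """Fit the full OR grid: 4 exposures x raw/corrected x covariate models.

    Returns a tidy DataFrame with one row per cell (8 exposures x
    ``len(models)``), including OR, Wald 95% CI, p-value and log-likelihood.
    """
    y = cohort.phenotypes["event"].to_numpy()
    grid = exposure_grid(cohort, corrected, combination_mode)
    rows = []
    for (label, kind), exposure in grid.items():
        for model_id in models:
            res = fit_logistic(
                y,
                exposure,
                model_covariates(cohort, model_id),
                exposure_label=f"{label} ({kind})",
                model_id=model_id,
            )
            rows.append(
                {
                    "exposure": label,
                    "kind": kind,
                    "model": model_id,
                    "odds_ratio": res.odds_ratio,
                    "ci_lower": res.ci95[0],
                    "ci_upper": res.ci95[1],
                    "p_value": res.p_value,
                    "beta": res.beta,
                    "se": res.se,
                    "loglik": res.loglik,
                    "n_events": res.n_events,
                    "n_total": res.n_total,
                }
            )
    return pd.DataFrame(rows)
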