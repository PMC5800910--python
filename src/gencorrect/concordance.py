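"""Harrell's C-statistic from Cox risk scores, with jackknife inference.

Harrell's C is the proportion of comparable subject pairs in which the
subject with the earlier event carries the higher risk score, tied scores
counting 1/2.  A pair is comparable when the smaller follow-up time belongs
to an event (pairs whose smaller time is censored, and tied event times,
carry no ordering information; a tie between an event and a censoring at
the same time is comparable, the event subject needing the higher score).

Standard errors come from the leave-one-out jackknife over subjects, which
is cheap here because removing subject *i* only removes *i*'s own pair
contributions.  The raw-vs-corrected comparison uses the *paired* jackknife
on the per-subject difference of concordance indices (both scores evaluated
on the same subjects), with a two-sided normal p-value; a subject-resampling
bootstrap is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

from .cohort import Cohort
from .correction import CorrectedLevels
from .risk import exposure_grid

__all__ = [
    "ConcordanceResult",
    "CComparison",
    "fit_cox",
    "harrell_c",
    "compare_c",
    "run_c_suite",
]

_Z95 = float(stats.norm.ppf(0.975))


@njit(cache=False)
def _pair_counts(time, event, score):  # pragma: no cover - exercised via harrell_c
    """Per-subject comparable-pair and concordance-credit counts."""
    n = time.shape[0]
    comparable = np.zeros(n)
    concordant = np.zeros(n)
    for i in range(n):
        ti = time[i]
        ei = event[i]
        si = score[i]
        for j in range(i + 1, n):
            tj = time[j]
            ej = event[j]
            sj = score[j]
            if ti < tj:
                if ei == 0:
                    continue
                hi, lo = si, sj  # subject i fails first: needs higher score
            elif tj < ti:
                if ej == 0:
                    continue
                hi, lo = sj, si
            else:
                if ei + ej != 1:
                    continue  # tied times: only event-vs-censored informative
                if ei == 1:
                    hi, lo = si, sj
                else:
                    hi, lo = sj, si
            if hi > lo:
                w = 1.0
            elif hi == lo:
                w = 0.5
            else:
                w = 0.0
            comparable[i] += 1.0
            comparable[j] += 1.0
            concordant[i] += w
            concordant[j] += w
    return comparable, concordant


def _counts(time, event, score):
    time = np.ascontiguousarray(time, dtype=np.float64)
    event = np.ascontiguousarray(event, dtype=np.int64)
    score = np.ascontiguousarray(score, dtype=np.float64)
    if not (time.shape == event.shape == score.shape):
        raise ValueError("time, event and score must have equal length")
    if (time <= 0).any():
        raise ValueError("follow-up times must be positive")
    return _pair_counts(time, event, score)


def _jackknife_values(comparable, concordant):
    total_comp = comparable.sum() / 2.0
    total_conc = concordant.sum() / 2.0
    denom = total_comp - comparable
    with np.errstate(invalid="ignore", divide="ignore"):
        loo = (total_conc - concordant) / denom
    loo = np.where(denom > 0, loo, total_conc / total_comp if total_comp else np.nan)
    return total_comp, total_conc, loo


@dataclass(frozen=True)
class ConcordanceResult:
    """Harrell's C with jackknife SE and truncated normal 95% CI."""

    c_statistic: float
    se: float
    ci95: tuple[float, float]
    n_comparable_pairs: int
    n_concordant: float  # ties counted 1/2
    exposure: str = ""


@dataclass(frozen=True)
class CComparison:
    """Paired comparison of two concordance indices on the same subjects."""

    c_a: float
    c_b: float
    delta: float  # c_b - c_a
    se: float
    p_value: float
    method: str


def harrell_c(scores, time, event, exposure: str = "") -> ConcordanceResult:
    """Harrell's concordance index of a risk score for censored outcomes."""
    comparable, concordant = _counts(time, event, scores)
    total_comp, total_conc, loo = _jackknife_values(comparable, concordant)
    if total_comp == 0:
        raise ValueError("no comparable pairs (no usable events)")
    c = total_conc / total_comp
    n = comparable.shape[0]
    se = float(np.sqrt((n - 1) / n * np.sum((loo - loo.mean()) ** 2)))
    ci = (max(0.0, c - _Z95 * se), min(1.0, c + _Z95 * se))
    return ConcordanceResult(
        c_statistic=float(c),
        se=se,
        ci95=ci,
        n_comparable_pairs=int(round(total_comp)),
        n_concordant=float(total_conc),
        exposure=exposure,
    )


def compare_c(
    scores_a,
    scores_b,
    time,
    event,
    method: str = "jackknife",
    n_boot: int = 1000,
    seed: int = 0,
) -> CComparison:
    """Test ``C(scores_b) - C(scores_a)`` on the same subjects.

    Default: paired leave-one-out jackknife SE of the difference with a
    two-sided normal p (deterministic).  ``method="bootstrap"``: resample
    subjects with replacement, percentile-based two-sided p.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if not (scores_a.shape == scores_b.shape == time.shape):
        raise ValueError("score vectors must cover the same subjects")
    comp_a, conc_a = _counts(time, event, scores_a)
    comp_b, conc_b = _counts(time, event, scores_b)
    tc_a, tn_a, loo_a = _jackknife_values(comp_a, conc_a)
    tc_b, tn_b, loo_b = _jackknife_values(comp_b, conc_b)
    if tc_a == 0 or tc_b == 0:
        raise ValueError("no comparable pairs")
    c_a = tn_a / tc_a
    c_b = tn_b / tc_b
    delta = float(c_b - c_a)

    if method == "jackknife":
        d = loo_b - loo_a
        n = d.shape[0]
        se = float(np.sqrt((n - 1) / n * np.sum((d - d.mean()) ** 2)))
        if se == 0.0:
            p = 1.0 if delta == 0.0 else 0.0
        else:
            p = float(2.0 * stats.norm.sf(abs(delta) / se))
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        n = time.shape[0]
        deltas = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            ca = harrell_c(scores_a[idx], time[idx], event[idx]).c_statistic
            cb = harrell_c(scores_b[idx], time[idx], event[idx]).c_statistic
            deltas[b] = cb - ca
        se = float(deltas.std(ddof=1))
        # two-sided percentile p for H0: delta = 0
        frac = float(np.mean(deltas <= 0.0))
        p = float(min(1.0, 2.0 * min(frac, 1.0 - frac)))
    else:
        raise ValueError(f"unknown method {method!r}")
    return CComparison(
        c_a=float(c_a), c_b=float(c_b), delta=delta, se=se, p_value=p, method=method
    )


def fit_cox(
    time,
    event,
    exposure,
    covariates: pd.DataFrame | None = None,
):
    """Cox proportional-hazards fit (Efron ties); returns the linear predictor.

    The per-subject linear predictor (log partial hazard) is the risk score
    fed to :func:`harrell_c`.  Also returns the fitted lifelines model.
    """
    from lifelines import CoxPHFitter

    df = pd.DataFrame({"time": np.asarray(time, dtype=float),
                       "event": np.asarray(event, dtype=int),
                       "exposure": np.asarray(exposure, dtype=float)})
    if df["event"].sum() == 0:
        raise ValueError("no events: Cox model undefined")
    if (df["time"] <= 0).any():
        raise ValueError("follow-up times must be positive")
    if covariates is not None:
        for c in covariates.columns:
            df[c] = np.asarray(covariates[c], dtype=float)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    lp = cph.predict_log_partial_hazard(df).to_numpy()
    return lp, cph


def run_c_suite(
    cohort: Cohort,
    corrected: CorrectedLevels,
    combination_mode: str = "sum",
    cox_scores: bool = True,
) -> pd.DataFrame:
    """Discrimination grid: C for each exposure raw vs corrected + paired tests.

    For each of AFP, CA19-9, CEA and the combination, computes Harrell's C of
    the (Cox-derived, when ``cox_scores``) risk score for the raw and the
    genetically corrected exposure, and the paired jackknife comparison.
    Returns a tidy DataFrame with one row per exposure.
    """
    ph = cohort.phenotypes
    time = ph["followup_years"].to_numpy(dtype=float)
    event = ph["event"].to_numpy(dtype=int)
    grid = exposure_grid(cohort, corrected, combination_mode)
    rows = []
    for label in ("AFP", "CA19-9", "CEA", "combination"):
        scores = {}
        for kind in ("raw", "corrected"):
            x = grid[(label, kind)]
            scores[kind] = fit_cox(time, event, x)[0] if cox_scores else x
        res_raw = harrell_c(scores["raw"], time, event, exposure=f"{label} (raw)")
        res_corr = harrell_c(
            scores["corrected"], time, event, exposure=f"{label} (corrected)"
        )
        comp = compare_c(scores["raw"], scores["corrected"], time, event)
        rows.append(
            {
                "exposure": label,
                "c_raw": res_raw.c_statistic,
                "c_raw_ci_lower": res_raw.ci95[0],
                "c_raw_ci_upper": res_raw.ci95[1],
                "c_corrected": res_corr.c_statistic,
                "c_corrected_ci_lower": res_corr.ci95[0],
                "c_corrected_ci_upper": res_corr.ci95[1],
                "delta": comp.delta,
                "p_value": comp.p_value,
            }
        )
    return pd.DataFrame(rows)
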