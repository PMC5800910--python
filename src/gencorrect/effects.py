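"""Per-SNP multiplicative allelic-effect estimation.

Each SNP's effect on a biomarker is estimated marginally by ordinary least
squares of the natural-log level on the effect-allele count; the slope is
back-transformed (``a = exp(beta)``) to the ratio scale and, together with
the allele frequency, normalized into a mean-one genotype-effect triple.
Orientation is flipped (count -> 2 - count) when the slope is negative so
the reported allelic effect is always >= 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .cohort import BIOMARKER_COLUMNS, Cohort
from .panel import (
    CorrectionPanel,
    SnpEffectRecord,
    normalize_empirical,
    normalize_genotype_effects,
)

__all__ = [
    "AllelicEffectEstimate",
    "estimate_allelic_effect",
    "normalize_genotype_effects",
    "normalize_empirical",
    "fit_panel",
    "PanelEstimator",
]


@dataclass(frozen=True)
class AllelicEffectEstimate:
    """Back-transformed OLS estimate of one SNP's per-allele effect."""

    rsid: str
    allelic_effect: float
    se_log: float
    n_used: int
    effect_allele: str
    flipped: bool  # orientation reversed relative to the input counts

    @property
    def log_effect(self) -> float:
        return float(np.log(self.allelic_effect))


def estimate_allelic_effect(
    levels,
    counts,
    rsid: str = "",
    effect_allele: str = "*",
    other_allele: str | None = None,
) -> AllelicEffectEstimate:
    """OLS of log(level) on effect-allele count, back-transformed to a ratio.

    Subjects with a missing level or count are dropped.  Requires at least 3
    usable subjects and at least two distinct counts; a monomorphic genotype
    raises.  When the fitted slope is negative, the orientation is flipped so
    the reported effect is >= 1 and the effect allele swapped.
    """
    levels = np.asarray(levels, dtype=float)
    counts = np.asarray(counts, dtype=float)
    keep = ~(np.isnan(levels) | np.isnan(counts))
    levels, counts = levels[keep], counts[keep]
    if levels.size < 3:
        raise ValueError(f"{rsid or 'SNP'}: need >= 3 subjects with level and genotype")
    if (levels <= 0).any():
        raise ValueError(f"{rsid or 'SNP'}: non-positive level (flooring is upstream)")
    if np.unique(counts).size < 2:
        raise ValueError(f"{rsid or 'SNP'}: no variation in genotype counts")
    logy = np.log(levels)
    if np.ptp(logy) == 0.0:  # constant levels: slope exactly zero
        return AllelicEffectEstimate(
            rsid=rsid, allelic_effect=1.0, se_log=0.0, n_used=int(levels.size),
            effect_allele=effect_allele, flipped=False,
        )
    fit = sm.OLS(logy, sm.add_constant(counts)).fit()
    beta, se = float(fit.params[1]), float(fit.bse[1])
    flipped = beta < 0
    if flipped:
        beta = -beta
        effect_allele, other_allele = (
            other_allele or "*",
            effect_allele if effect_allele != "*" else None,
        )
    return AllelicEffectEstimate(
        rsid=rsid,
        allelic_effect=float(np.exp(beta)),
        se_log=se,
        n_used=int(levels.size),
        effect_allele=effect_allele,
        flipped=flipped,
    )


def fit_panel(
    cohort: Cohort,
    biomarker: str,
    rsids: Sequence[str] | None = None,
    *,
    empirical_freqs: bool = False,
) -> CorrectionPanel:
    """Fit a correction panel for one biomarker from cohort data.

    SNPs are fitted marginally (one regression per SNP).  Each estimate is
    normalized into a mean-one :class:`SnpEffectRecord` using the observed
    effect-allele frequency (HWE weights by default, observed genotype
    proportions with ``empirical_freqs=True``).
    """
    est = PanelEstimator(biomarker=biomarker, rsids=rsids, empirical_freqs=empirical_freqs)
    est.fit(cohort.genotypes, cohort.biomarker(biomarker))
    return est.panel_


class PanelEstimator(BaseEstimator):
    """Estimate a biomarker's SNP-effect panel from genotype counts and levels.

    scikit-learn-style estimator: ``fit(X, y)`` with ``X`` a subjects-by-rsid
    DataFrame of effect-allele counts and ``y`` the positive biomarker
    levels.  Fitted attributes: ``estimates_`` (per-SNP
    :class:`AllelicEffectEstimate`), ``panel_`` (a
    :class:`~gencorrect.panel.CorrectionPanel` with mean-one triples) and
    ``freqs_`` (effect-allele frequencies used for normalization).

    Parameters
    ----------
    biomarker : str
        Panel label (``"AFP"``, ``"CA19-9"`` or ``"CEA"`` by convention).
    rsids : sequence of str, optional
        Columns of ``X`` to fit; default all columns.
    empirical_freqs : bool
        Normalize against observed genotype proportions instead of HWE
        weights at the estimated allele frequency.
    joint : bool
        Sensitivity mode: estimate all slopes in one multiple regression
        instead of marginally (per-SNP simple regressions, the default).
    """

    def __init__(
        self,
        biomarker: str = "AFP",
        rsids: Sequence[str] | None = None,
        empirical_freqs: bool = False,
        joint: bool = False,
    ):
        self.biomarker = biomarker
        self.rsids = rsids
        self.empirical_freqs = empirical_freqs
        self.joint = joint

    def fit(self, X: pd.DataFrame, y) -> "PanelEstimator":
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a subjects-by-rsid DataFrame of counts")
        rsids = list(self.rsids) if self.rsids is not None else list(X.columns)
        missing = [r for r in rsids if r not in X.columns]
        if missing:
            raise ValueError(f"rsid(s) not genotyped in cohort: {missing}")
        y = np.asarray(y, dtype=float)

        if self.joint:
            slopes = self._fit_joint(X[rsids], y)
        estimates, records, freqs = [], [], {}
        for rsid in rsids:
            counts = X[rsid].to_numpy(dtype=float)
            est = estimate_allelic_effect(y, counts, rsid=rsid)
            if self.joint:
                beta = slopes[rsid]
                est = AllelicEffectEstimate(
                    rsid=rsid,
                    allelic_effect=float(np.exp(abs(beta))),
                    se_log=est.se_log,
                    n_used=est.n_used,
                    effect_allele=est.effect_allele,
                    flipped=beta < 0,
                )
            ok = ~np.isnan(counts)
            c = counts[ok]
            if est.flipped:
                c = 2.0 - c
            p_hat = float(c.mean() / 2.0)
            a = est.allelic_effect
            if self.empirical_freqs:
                f = np.bincount(c.astype(int), minlength=3) / c.size
                triple = normalize_empirical(a, f)
            else:
                triple = normalize_genotype_effects(a, p_hat)
            freqs[rsid] = p_hat
            estimates.append(est)
            records.append(
                SnpEffectRecord(
                    rsid=rsid,
                    chrom="",
                    position_bp=0,
                    effect_allele=est.effect_allele,
                    effect_allele_freq=p_hat,
                    allelic_effect=a,
                    genotype_effects=triple,
                    hwe_normalized=not self.empirical_freqs,
                )
            )
        self.estimates_ = estimates
        self.freqs_ = freqs
        self.panel_ = CorrectionPanel(biomarker=self.biomarker, snps=tuple(records))
        return self

    def _fit_joint(self, X: pd.DataFrame, y: np.ndarray) -> dict[str, float]:
        mat = X.to_numpy(dtype=float)
        keep = ~(np.isnan(y) | np.isnan(mat).any(axis=1))
        fit = sm.OLS(np.log(y[keep]), sm.add_constant(mat[keep])).fit()
        return {rsid: float(b) for rsid, b in zip(X.columns, fit.params[1:])}
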