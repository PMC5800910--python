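"""Genetic correction: divide measured levels by the combined genetic effect.

A subject's combined genetic effect for one biomarker is the product of that
panel's genotype-effect multipliers selected by the subject's effect-allele
counts (multiplicative model across SNPs).  The genetically corrected level
is the measured level divided by this product.  Because the multipliers are
mean-one under Hardy-Weinberg equilibrium, correction leaves the population
mean approximately unchanged while removing the heritable, non-disease
component of between-subject variation.

Missing genotypes contribute a multiplier of 1 (population-mean imputation
under the mean-one normalization); the number of imputed SNPs is reported
per subject, and a strict mode drops such subjects instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import BIOMARKER_COLUMNS, DETECTION_FLOOR, Cohort
from .panel import CorrectionPanel, load_snp_panel, panels_by_biomarker

__all__ = [
    "CorrectedLevels",
    "combined_genetic_effect",
    "correct_levels",
    "GeneticCorrector",
]


def combined_genetic_effect(
    genotype_counts: Mapping[str, float] | pd.DataFrame,
    panel: CorrectionPanel,
) -> float | pd.Series:
    """Product of the panel's genotype-effect multipliers for given counts.

    Accepts a single subject's ``{rsid: count}`` mapping (returns a float)
    or a subjects-by-rsid DataFrame (returns a Series).  A missing count
    contributes a factor of 1; counts outside {0, 1, 2} raise.
    """
    if len(panel) == 0:
        raise ValueError("panel is empty")
    if isinstance(genotype_counts, pd.DataFrame):
        g = np.ones(len(genotype_counts))
        for snp in panel.snps:
            counts = genotype_counts[snp.rsid].to_numpy(dtype=float)
            _check_counts(counts, snp.rsid)
            triple = np.asarray(snp.genotype_effects)
            filled = np.nan_to_num(counts).astype(int)
            g *= np.where(np.isnan(counts), 1.0, triple[filled])
        return pd.Series(g, index=genotype_counts.index, name=panel.biomarker)
    g = 1.0
    for snp in panel.snps:
        count = genotype_counts.get(snp.rsid)
        if count is None or (isinstance(count, float) and np.isnan(count)):
            continue
        g *= snp.effect_for_count(int(count))
    return g


def _check_counts(counts: np.ndarray, rsid: str) -> None:
    bad = ~(np.isnan(counts) | np.isin(counts, (0.0, 1.0, 2.0)))
    if bad.any():
        raise ValueError(f"{rsid}: genotype counts outside {{0, 1, 2}}")


@dataclass
class CorrectedLevels:
    """Raw level, genetic multiplier and corrected level per subject per marker.

    ``tables[biomarker]`` has columns ``raw``, ``genetic_multiplier``,
    ``corrected``, ``n_imputed_snps`` and ``below_floor`` (corrected value
    fell under the detection floor; kept as computed, flagged only).
    """

    tables: dict[str, pd.DataFrame]

    def __getitem__(self, biomarker: str) -> pd.DataFrame:
        return self.tables[biomarker]

    @property
    def biomarkers(self) -> tuple[str, ...]:
        return tuple(self.tables)

    def corrected(self, biomarker: str) -> pd.Series:
        return self.tables[biomarker]["corrected"]

    def raw(self, biomarker: str) -> pd.Series:
        return self.tables[biomarker]["raw"]

    def summary(self) -> pd.DataFrame:
        """Mean raw and corrected level per marker with percent change."""
        rows = []
        for m, t in self.tables.items():
            mean_raw = float(t["raw"].mean())
            mean_corr = float(t["corrected"].mean())
            rows.append(
                {
                    "biomarker": m,
                    "mean_raw": mean_raw,
                    "mean_corrected": mean_corr,
                    "percent_change": 100.0 * (mean_raw - mean_corr) / mean_raw,
                    "n_missing_raw": int(t["raw"].isna().sum()),
                }
            )
        return pd.DataFrame(rows).set_index("biomarker")


class GeneticCorrector(BaseEstimator, TransformerMixin):
    """Transformer computing genetically corrected biomarker levels.

    ``fit`` checks that the panels' SNPs are genotyped in the cohort and
    freezes them; ``transform`` divides each measured level by the subject's
    combined genetic effect.  Operates on :class:`~gencorrect.cohort.Cohort`
    objects.

    Parameters
    ----------
    panels : sequence of CorrectionPanel, optional
        Panels to apply; default is the packaged three-biomarker panel.
    missing : {"impute", "drop"}
        Treat a missing genotype as multiplier 1 (default) or drop the
        subject (corrected level set missing) when any panel SNP is absent.
    """

    def __init__(self, panels: Sequence[CorrectionPanel] | None = None,
                 missing: str = "impute"):
        self.panels = panels
        self.missing = missing

    def fit(self, X: Cohort, y=None) -> "GeneticCorrector":
        if self.missing not in ("impute", "drop"):
            raise ValueError("missing must be 'impute' or 'drop'")
        panels = list(self.panels) if self.panels is not None else load_snp_panel()
        absent = {
            p.biomarker: [r for r in p.rsids if r not in X.genotypes.columns]
            for p in panels
        }
        absent = {k: v for k, v in absent.items() if v}
        if absent:
            raise ValueError(f"panel SNPs not genotyped in cohort: {absent}")
        self.panels_ = panels
        return self

    def transform(self, X: Cohort) -> CorrectedLevels:
        if not hasattr(self, "panels_"):
            raise RuntimeError("GeneticCorrector must be fitted before transform")
        tables = {}
        for panel in self.panels_:
            m = panel.biomarker
            raw = X.biomarker(m).astype(float)
            g = combined_genetic_effect(X.genotypes[list(panel.rsids)], panel)
            n_imputed = X.genotypes[list(panel.rsids)].isna().sum(axis=1).astype(int)
            corrected = raw / g
            if self.missing == "drop":
                corrected = corrected.where(n_imputed == 0)
            tables[m] = pd.DataFrame(
                {
                    "raw": raw,
                    "genetic_multiplier": g,
                    "corrected": corrected,
                    "n_imputed_snps": n_imputed,
                    "below_floor": corrected < DETECTION_FLOOR,
                }
            )
        return CorrectedLevels(tables=tables)


def correct_levels(
    cohort: Cohort,
    panels: Sequence[CorrectionPanel] | None = None,
    missing: str = "impute",
) -> CorrectedLevels:
    """Genetically correct all biomarkers of a cohort (functional wrapper)."""
    return GeneticCorrector(panels=panels, missing=missing).fit(cohort).transform(cohort)
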