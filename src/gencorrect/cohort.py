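"""Cohort container and phenotype/genotype file IO.

A cohort couples a phenotype table (one row per subject: serum AFP/CA19-9/CEA,
covariates, the digestive-cancer event indicator, follow-up time and cancer
site) with a genotype table of effect-allele counts (subjects x rsids,
values 0/1/2 or missing).  Phenotypes travel as CSV/TSV with an ``NA``
missing sentinel; genotypes as an rsid-by-subject TSV matrix or a VCF.

Biomarker values below the assay's standard-curve limit of 0.01 are floored
to 0.005 at read time, mirroring how the source laboratory reported
below-detection measurements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import CorrectionPanel

__all__ = [
    "BIOMARKER_COLUMNS",
    "CANCER_SITES",
    "Cohort",
    "read_cohort",
    "write_cohort",
    "DETECTION_FLOOR",
    "DETECTION_THRESHOLD",
]

#: Phenotype column per biomarker label.
BIOMARKER_COLUMNS = {"AFP": "afp", "CA19-9": "ca19_9", "CEA": "cea"}

CANCER_SITES = ("liver", "stomach", "colorectal", "esophagus", "pancreas", "none")

#: Measurements below DETECTION_THRESHOLD are recorded as DETECTION_FLOOR.
DETECTION_FLOOR = 0.005
DETECTION_THRESHOLD = 0.01

PHENOTYPE_COLUMNS = (
    "subject_id",
    "afp",
    "ca19_9",
    "cea",
    "age",
    "sex",
    "bmi",
    "smoking",
    "drinking",
    "physical_activity",
    "family_history",
    "event",
    "followup_years",
    "cancer_site",
)

_CATEGORICAL_LEVELS = {
    "sex": ("male", "female"),
    "smoking": ("ever", "never"),
    "drinking": ("ever", "never"),
    "physical_activity": ("yes", "no"),
    "family_history": ("yes", "no"),
    "cancer_site": CANCER_SITES,
}


@dataclass
class Cohort:
    """Phenotypes plus genotype effect-allele counts, indexed by subject id.

    ``genotypes`` holds float counts with NaN for missing.  ``latent`` is an
    optional genotype-free level table retained by the simulator as an oracle
    for correction tests; it has no on-disk representation.
    """

    phenotypes: pd.DataFrame
    genotypes: pd.DataFrame
    latent: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.phenotypes)

    @property
    def n_events(self) -> int:
        return int(self.phenotypes["event"].sum())

    def biomarker(self, name: str) -> pd.Series:
        return self.phenotypes[BIOMARKER_COLUMNS[name]]

    def validate(self) -> "Cohort":
        ph = self.phenotypes
        missing = [c for c in PHENOTYPE_COLUMNS if c != "subject_id" and c not in ph]
        if missing:
            raise ValueError(f"phenotype table lacks columns {missing}")
        if not ph.index.is_unique:
            raise ValueError("duplicate subject ids")
        for col in BIOMARKER_COLUMNS.values():
            vals = ph[col].dropna()
            if (vals < 0).any():
                raise ValueError(f"negative {col} value")
            if (vals < DETECTION_FLOOR - 1e-15).any():
                raise ValueError(f"{col} below the detection floor {DETECTION_FLOOR}")
        if not (ph["followup_years"] > 0).all():
            raise ValueError("follow-up time must be positive for every subject")
        if not ph["event"].isin([0, 1]).all():
            raise ValueError("event indicator must be 0/1")
        bad_site = ~ph["cancer_site"].isin(CANCER_SITES)
        if bad_site.any():
            raise ValueError(f"unknown cancer site(s): {sorted(ph.loc[bad_site, 'cancer_site'].unique())}")
        if ((ph["event"] == 1) & (ph["cancer_site"] == "none")).any():
            raise ValueError("event=1 requires a cancer site")
        gt = self.genotypes.to_numpy(dtype=float)
        ok = np.isnan(gt) | np.isin(gt, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("genotype counts must be 0, 1, 2 or missing")
        if not self.genotypes.index.equals(ph.index):
            raise ValueError("genotype and phenotype tables index different subjects")
        return self


def _floor_biomarkers(ph: pd.DataFrame) -> pd.DataFrame:
    ph = ph.copy()
    for col in BIOMARKER_COLUMNS.values():
        vals = ph[col]
        if (vals.dropna() < 0).any():
            raise ValueError(f"negative {col} measurement")
        ph[col] = vals.where(vals.isna() | (vals >= DETECTION_THRESHOLD), DETECTION_FLOOR)
    return ph


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","


def _read_genotype_matrix(path: Path) -> pd.DataFrame:
    # rows = rsid, columns = subjects; transpose to subjects x rsids
    mat = pd.read_csv(path, sep=_sep_for(path), index_col=0, na_values=["NA"])
    gt = mat.T
    gt.index = gt.index.astype(str)
    gt.index.name = "subject_id"
    gt.columns.name = None
    return gt.astype(float)


def _count_from_gt(alleles, effect_is_alt: bool) -> float:
    if any(a is None for a in alleles):
        return np.nan
    dose = sum(1 for a in alleles if a == 1)
    return float(dose if effect_is_alt else len(alleles) - dose)


def _read_vcf(path: Path, panels: Sequence[CorrectionPanel]) -> pd.DataFrame:
    import pysam

    records = {}
    for panel in panels:
        for snp in panel.snps:
            records.setdefault(snp.rsid, snp)
    columns = {}
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            rsid = rec.id
            if rsid not in records:
                continue
            snp = records[rsid]
            ref, alt = rec.ref, (rec.alts[0] if rec.alts else None)
            if snp.effect_allele == alt:
                effect_is_alt = True
            elif snp.effect_allele == ref:
                effect_is_alt = False
            elif snp.effect_allele == "*" and snp.other_allele in (ref, alt):
                # effect allele is "whichever allele is not other_allele"
                effect_is_alt = snp.other_allele == ref
            else:
                warnings.warn(
                    f"{rsid}: neither VCF allele ({ref}/{alt}) matches the panel "
                    f"effect allele {snp.effect_allele!r}; genotypes set missing"
                )
                columns[rsid] = pd.Series(np.nan, index=samples)
                continue
            counts = {
                s: _count_from_gt(rec.samples[s].get("GT", (None,)), effect_is_alt)
                for s in samples
            }
            columns[rsid] = pd.Series(counts)
    gt = pd.DataFrame(columns)
    gt.index = gt.index.astype(str)
    gt.index.name = "subject_id"
    return gt


def read_cohort(
    phenotype_path: str | Path,
    genotype_path: str | Path,
    panels: Sequence[CorrectionPanel] | None = None,
) -> Cohort:
    """Read a cohort from a phenotype CSV/TSV and a genotype TSV matrix or VCF.

    Biomarker values below 0.01 are floored to 0.005; negative values raise.
    VCF genotypes (``.vcf``/``.vcf.gz``) are converted to effect-allele
    counts using the panels' effect alleles, flipping the ALT dosage when the
    effect allele is REF.  Subjects present in the phenotypes but absent from
    the genotypes are kept with all-missing counts (with a warning).
    """
    phenotype_path = Path(phenotype_path)
    genotype_path = Path(genotype_path)
    ph = pd.read_csv(
        phenotype_path,
        sep=_sep_for(phenotype_path),
        na_values=["NA"],
        float_precision="round_trip",
    )
    ph["subject_id"] = ph["subject_id"].astype(str)
    ph = ph.set_index("subject_id")
    ph = _floor_biomarkers(ph)
    ph["event"] = ph["event"].astype(int)

    if genotype_path.name.endswith((".vcf", ".vcf.gz")):
        if panels is None:
            raise ValueError("reading genotypes from VCF requires the correction panels")
        gt = _read_vcf(genotype_path, panels)
    else:
        gt = _read_genotype_matrix(genotype_path)

    absent = ph.index.difference(gt.index)
    if len(absent):
        warnings.warn(
            f"{len(absent)} phenotype subject(s) missing from genotypes; "
            "counts recorded as missing"
        )
    gt = gt.reindex(ph.index)
    return Cohort(phenotypes=ph, genotypes=gt).validate()


def write_cohort(
    cohort: Cohort,
    phenotype_path: str | Path,
    genotype_path: str | Path,
) -> None:
    """Write a cohort as a phenotype TSV/CSV plus an rsid-by-subject TSV matrix.

    The written pair round-trips through :func:`read_cohort` identically:
    floats use shortest-repr formatting, missing values the ``NA`` sentinel,
    and genotype counts integer cells.
    """
    phenotype_path = Path(phenotype_path)
    genotype_path = Path(genotype_path)
    ph = cohort.phenotypes.reset_index()
    ph.to_csv(phenotype_path, sep=_sep_for(phenotype_path), index=False, na_rep="NA")
    mat = cohort.genotypes.T.astype("Int64")
    mat.index = mat.index.rename("rsid")  # rename copies: cohort stays untouched
    mat.to_csv(genotype_path, sep=_sep_for(genotype_path), na_rep="NA")
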