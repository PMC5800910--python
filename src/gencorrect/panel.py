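"""SNP-effect panels for multiplicative genetic correction of serum tumor biomarkers.

A panel lists, for one biomarker (AFP, CA19-9 or CEA), the variants whose
genotype shifts the marker's baseline level.  Each variant carries a
multiplicative per-allele effect ``a`` on the geometric-mean level and the
population frequency ``p`` of the level-increasing (effect) allele.  The raw
genotype multipliers ``(1, a, a^2)`` for 0/1/2 effect-allele copies are
rescaled so that their Hardy-Weinberg-weighted population mean is exactly 1
("mean-one normalization"), which makes the combined genetic effect of a
random individual average to 1 and leaves the population-mean level
unchanged by correction.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "BIOMARKERS",
    "SnpEffectRecord",
    "CorrectionPanel",
    "normalize_genotype_effects",
    "normalize_empirical",
    "load_snp_panel",
    "panels_by_biomarker",
]

#: Canonical biomarker labels, in reporting order.
BIOMARKERS = ("AFP", "CA19-9", "CEA")

_NORM_TOL = 1e-9


def normalize_genotype_effects(a: float, p: float) -> tuple[float, float, float]:
    """Normalize multiplicative genotype effects to Hardy-Weinberg mean one.

    Raw multipliers ``(1, a, a^2)`` for 0/1/2 copies of the effect allele are
    divided by ``m = p^2 a^2 + 2 p (1-p) a + (1-p)^2`` so that the
    HWE-weighted mean ``p^2 e2 + 2p(1-p) e1 + (1-p)^2 e0`` equals 1 exactly.

    Parameters
    ----------
    a : float
        Multiplicative per-allele effect, > 0.
    p : float
        Effect-allele frequency, strictly inside (0, 1); at the boundary the
        normalization is defined only up to a constant and is rejected.

    Returns
    -------
    (e0, e1, e2) : tuple of float
        Normalized multipliers for 0, 1 and 2 effect-allele copies.
    """
    if not a > 0:
        raise ValueError(f"allelic effect must be positive, got {a}")
    if not 0.0 < p < 1.0:
        raise ValueError(f"effect-allele frequency must lie strictly in (0, 1), got {p}")
    m = p * p * a * a + 2.0 * p * (1.0 - p) * a + (1.0 - p) ** 2
    return (1.0 / m, a / m, a * a / m)


def normalize_empirical(
    a: float, genotype_freqs: Sequence[float]
) -> tuple[float, float, float]:
    """Normalize ``(1, a, a^2)`` against observed genotype frequencies.

    Variant of :func:`normalize_genotype_effects` for cohorts that are not in
    Hardy-Weinberg equilibrium: the triple is scaled so that
    ``f0*e0 + f1*e1 + f2*e2 = 1`` exactly, where ``(f0, f1, f2)`` are the
    observed proportions of 0/1/2 effect-allele copies.
    """
    if not a > 0:
        raise ValueError(f"allelic effect must be positive, got {a}")
    f0, f1, f2 = (float(f) for f in genotype_freqs)
    if min(f0, f1, f2) < 0:
        raise ValueError(f"genotype frequencies must be non-negative, got {genotype_freqs}")
    if abs(f0 + f1 + f2 - 1.0) > _NORM_TOL:
        raise ValueError(f"genotype frequencies must sum to 1, got {f0 + f1 + f2}")
    m = f0 + f1 * a + f2 * a * a
    return (1.0 / m, a / m, a * a / m)


@dataclass(frozen=True)
class SnpEffectRecord:
    """One panel variant: identity, effect allele, and normalized effects.

    ``effect_allele`` is the base of the level-increasing allele, or ``"*"``
    when only the decreasing allele's base is known (then ``other_allele``
    holds that base and the effect allele is "any allele other than it").
    ``genotype_effects`` maps 0/1/2 effect-allele copies to mean-one
    multipliers.
    """

    rsid: str
    chrom: str
    position_bp: int
    effect_allele: str
    effect_allele_freq: float
    allelic_effect: float
    genotype_effects: tuple[float, float, float]
    other_allele: str | None = None
    notes: tuple[str, ...] = ()
    #: False for triples normalized against observed (possibly non-HWE)
    #: genotype proportions; disables the HWE mean-one validation.
    hwe_normalized: bool = True

    def __post_init__(self) -> None:
        if not self.allelic_effect > 0:
            raise ValueError(f"{self.rsid}: allelic effect must be > 0")
        if not 0.0 <= self.effect_allele_freq <= 1.0:
            raise ValueError(f"{self.rsid}: effect-allele frequency outside [0, 1]")
        e0, e1, e2 = self.genotype_effects
        if min(e0, e1, e2) <= 0:
            raise ValueError(f"{self.rsid}: genotype effects must be positive")
        p = self.effect_allele_freq
        mean = p * p * e2 + 2 * p * (1 - p) * e1 + (1 - p) ** 2 * e0
        if self.hwe_normalized and 0.0 < p < 1.0 and abs(mean - 1.0) > 1e-6:
            raise ValueError(
                f"{self.rsid}: genotype effects are not mean-one under HWE "
                f"(weighted mean {mean:.6f})"
            )

    def effect_for_count(self, count: int) -> float:
        """Multiplier for ``count`` copies of the effect allele."""
        if count not in (0, 1, 2):
            raise ValueError(f"{self.rsid}: genotype count must be 0, 1 or 2, got {count}")
        return self.genotype_effects[count]

    @classmethod
    def from_allelic_effect(
        cls,
        rsid: str,
        a: float,
        p: float,
        *,
        chrom: str = "",
        position_bp: int = 0,
        effect_allele: str = "*",
        other_allele: str | None = None,
        notes: Sequence[str] = (),
    ) -> "SnpEffectRecord":
        """Build a record with the triple filled in by the normalization op."""
        return cls(
            rsid=rsid,
            chrom=chrom,
            position_bp=position_bp,
            effect_allele=effect_allele,
            effect_allele_freq=p,
            allelic_effect=a,
            genotype_effects=normalize_genotype_effects(a, p),
            other_allele=other_allele,
            notes=tuple(notes),
        )


@dataclass(frozen=True)
class CorrectionPanel:
    """The variants defining the combined genetic multiplier of one biomarker."""

    biomarker: str
    snps: tuple[SnpEffectRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "snps", tuple(self.snps))
        rsids = [s.rsid for s in self.snps]
        dups = {r for r in rsids if rsids.count(r) > 1}
        if dups:
            raise ValueError(
                f"panel {self.biomarker!r}: duplicate rsid(s) {sorted(dups)}"
            )

    @property
    def rsids(self) -> tuple[str, ...]:
        return tuple(s.rsid for s in self.snps)

    def __len__(self) -> int:
        return len(self.snps)

    def __iter__(self):
        return iter(self.snps)


def _record_from_mapping(row: dict) -> SnpEffectRecord:
    listed = row.get("listed_allele")
    if row.get("effect_allele_is_listed", True):
        effect_allele = row.get("effect_allele", listed)
        other = row.get("other_allele")
    else:
        effect_allele = row.get("effect_allele", "*")
        other = row.get("other_allele", listed)
    a = float(row["allelic_effect"])
    p = float(row["effect_allele_freq"])
    if "genotype_effects" in row:
        triple = tuple(float(x) for x in row["genotype_effects"])
    else:
        triple = normalize_genotype_effects(a, p)
    return SnpEffectRecord(
        rsid=str(row["rsid"]),
        chrom=str(row.get("chrom", "")),
        position_bp=int(row.get("position_bp", 0)),
        effect_allele=str(effect_allele) if effect_allele else "*",
        effect_allele_freq=p,
        allelic_effect=a,
        genotype_effects=triple,
        other_allele=str(other) if other else None,
        notes=tuple(row.get("notes", ())),
    )


def load_snp_panel(source: str | Path | None = None) -> list[CorrectionPanel]:
    """Load correction panels from a YAML panel file.

    With ``source=None`` the packaged default panel is used: 2 AFP SNPs,
    4 CA19-9 SNPs and 5 CEA SNPs with their published allelic effects and
    frequencies.  Genotype-effect triples absent from the file are filled in
    via :func:`normalize_genotype_effects`.
    """
    if source is None:
        text = (
            importlib.resources.files("gencorrect.data")
            .joinpath("snp_panel.yaml")
            .read_text()
        )
    else:
        text = Path(source).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "panels" not in doc:
        raise ValueError("panel file must contain a top-level 'panels' mapping")
    panels = []
    for biomarker, rows in doc["panels"].items():
        snps = tuple(_record_from_mapping(row) for row in rows)
        panels.append(CorrectionPanel(biomarker=str(biomarker), snps=snps))
    return panels


def panels_by_biomarker(
    panels: Sequence[CorrectionPanel] | None = None,
) -> dict[str, CorrectionPanel]:
    """Return panels keyed by biomarker label (default: packaged panel)."""
    if panels is None:
        panels = load_snp_panel()
    return {p.biomarker: p for p in panels}


def printed_reference_triples(source: str | Path | None = None) -> dict:
    """Published 2-dp genotype-effect triples, keyed ``(biomarker, rsid)``.

    Reference metadata for validation only; computation always uses the
    exactly renormalized triples.
    """
    if source is None:
        text = (
            importlib.resources.files("gencorrect.data")
            .joinpath("snp_panel.yaml")
            .read_text()
        )
    else:
        text = Path(source).read_text()
    doc = yaml.safe_load(text)
    out = {}
    for biomarker, rows in doc["panels"].items():
        for row in rows:
            if "printed_triple" in row:
                out[(biomarker, row["rsid"])] = tuple(row["printed_triple"])
    return out
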