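"""Population- and family-level statistics for conversion genotypes.

Hardy-Weinberg testing on the three-class genotype table, phenotype
classification of neutrophil subset percentages, rank-based genotype-
phenotype association, and Mendelian-consistency checking of pedigrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

GENOTYPE_CLASSES = ("ref_hom", "ectopic_het", "null")
#: reference (intact) allele dosage per genotype class
REF_DOSAGE = {"ref_hom": 2, "ectopic_het": 1, "null": 0}


@dataclass(frozen=True)
class GenotypeCounts:
    n_ref_hom: int
    n_ectopic_het: int
    n_null: int

    def __post_init__(self) -> None:
        if min(self.n_ref_hom, self.n_ectopic_het, self.n_null) < 0:
            raise ValueError("genotype counts must be non-negative")
        if self.total == 0:
            raise ValueError("at least one observation is required")

    @property
    def total(self) -> int:
        return self.n_ref_hom + self.n_ectopic_het + self.n_null

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n_ref_hom, self.n_ectopic_het, self.n_null)


@dataclass(frozen=True)
class HweResult:
    """Chi-square goodness of fit (1 df) of genotype counts to Hardy-Weinberg
    expectations, plus the observed/expected heterozygosity ratio."""

    conversion_allele_freq: float
    expected: tuple[float, float, float]
    chi_square: float
    p_value: float
    het_ratio: Optional[float]
    monomorphic: bool


def hwe_test(counts: GenotypeCounts) -> HweResult:
    """Test genotype counts against Hardy-Weinberg proportions.

    The conversion-allele frequency is estimated by allele counting,
    q = (het + 2 null) / 2n; expectations are n((1-q)^2, 2q(1-q), q^2).
    Monomorphic tables return chi-square 0 with the heterozygosity ratio
    undefined.
    """
    n = counts.total
    q = (counts.n_ectopic_het + 2 * counts.n_null) / (2 * n)
    if q in (0.0, 1.0):
        expected = (n * (1 - q) ** 2, 0.0, n * q**2)
        return HweResult(q, expected, 0.0, 1.0, None, monomorphic=True)
    expected = (n * (1 - q) ** 2, n * 2 * q * (1 - q), n * q**2)
    chi2 = sum(
        (o - e) ** 2 / e for o, e in zip(counts.as_tuple(), expected) if e > 0
    )
    p = float(sps.chi2.sf(chi2, df=1))
    het_ratio = (counts.n_ectopic_het / n) / (2 * q * (1 - q))
    return HweResult(q, expected, float(chi2), p, het_ratio, monomorphic=False)


def genotype_prevalence(counts: GenotypeCounts) -> dict[str, float]:
    """Per-class prevalence in percent of the cohort."""
    n = counts.total
    return {
        cls: 100.0 * c / n for cls, c in zip(GENOTYPE_CLASSES, counts.as_tuple())
    }


@dataclass(frozen=True)
class PhenotypeThresholds:
    """Class boundaries for flow-cytometry subset percentages.

    The atypical-intermediate rule (>20% CD177int) is the one explicitly
    published; the null and hi/hi-neg boundaries approximate the visual
    clusters and are configurable.
    """

    atypical_int_pct: float = 20.0
    null_total_pct: float = 1.0
    hi_dominance_pct: float = 65.0


DEFAULT_THRESHOLDS = PhenotypeThresholds()


def classify_phenotype(rec, thresholds: PhenotypeThresholds = DEFAULT_THRESHOLDS) -> str:
    """hi / hi_neg / null / atypical_int from subset percentages.

    ``rec`` needs ``pct_hi``/``pct_int`` attributes (a PhenotypeRecord or any
    row-like object).
    """
    if rec.pct_int > thresholds.atypical_int_pct:
        return "atypical_int"
    if rec.pct_hi + rec.pct_int < thresholds.null_total_pct:
        return "null"
    return "hi" if rec.pct_hi >= thresholds.hi_dominance_pct else "hi_neg"


@dataclass(frozen=True)
class AssociationResult:
    """Rank statistics relating intact-allele dosage to phenotype."""

    spearman: dict[str, tuple[float, float]]  # variable -> (rho, p)
    kruskal: dict[str, tuple[float, float]]  # variable -> (H, p)
    class_summary: pd.DataFrame = field(repr=False)


def associate(cohort: pd.DataFrame) -> AssociationResult:
    """Genotype-phenotype association on a cohort table.

    Expects columns ``exon7_class`` plus any of ``pct_hi``, ``pct_neg``,
    ``mfi``.  Reference-allele dosage (2/1/0) is rank-correlated (Spearman)
    with each phenotype variable, and a Kruskal-Wallis test compares classes.
    Expected signs: positive for pct_hi and mfi, negative for pct_neg.
    """
    classes = [c for c in cohort["exon7_class"].unique() if c in REF_DOSAGE]
    if len(classes) < 2:
        raise ValueError("association needs at least two genotype classes")
    data = cohort[cohort["exon7_class"].isin(REF_DOSAGE)].copy()
    dosage = data["exon7_class"].map(REF_DOSAGE).to_numpy()
    spearman: dict[str, tuple[float, float]] = {}
    kruskal: dict[str, tuple[float, float]] = {}
    variables = [v for v in ("pct_hi", "pct_neg", "mfi") if v in data.columns]
    for var in variables:
        y = data[var].to_numpy(dtype=float)
        rho, p = sps.spearmanr(dosage, y)
        spearman[var] = (float(rho), float(p))
        groups = [
            data.loc[data["exon7_class"] == cls, var].to_numpy(dtype=float)
            for cls in classes
        ]
        if all(len(g) > 0 for g in groups) and len(groups) > 1:
            try:
                h, hp = sps.kruskal(*groups)
                kruskal[var] = (float(h), float(hp))
            except ValueError:  # all values identical
                kruskal[var] = (0.0, 1.0)
    summary = (
        data.groupby("exon7_class")[variables].agg(["mean", "std", "count"])
    )
    return AssociationResult(spearman=spearman, kruskal=kruskal, class_summary=summary)


@dataclass(frozen=True)
class MendelianViolation:
    member_id: str
    reason: str


@dataclass(frozen=True)
class MendelianReport:
    violations: tuple[MendelianViolation, ...]
    skipped: tuple[str, ...]  # offspring with missing parental genotypes

    def __iter__(self):
        return iter(self.violations)

    def __len__(self) -> int:
        return len(self.violations)


def _allele_keys(genotype, resolution: str):
    if resolution == "tract":
        return tuple(a.converted_exons for a in genotype.alleles)
    if resolution == "exon7":
        return tuple(a.converted_at(7) for a in genotype.alleles)
    raise ValueError(f"unknown resolution {resolution!r}")


def mendelian_check(ped, *, resolution: str = "tract") -> MendelianReport:
    """Flag offspring whose allele pair cannot be formed from one allele of
    each parent.

    ``resolution="tract"`` compares full conversion tracts (simulated truth);
    ``"exon7"`` compares only the exon-7 conversion state, the quantity a
    sequencing-based genotype call observes.
    """
    violations: list[MendelianViolation] = []
    skipped: list[str] = []
    by_id = {m.member_id: m for m in ped.members}
    for child in ped.members:
        if child.father_id is None and child.mother_id is None:
            continue
        father = by_id.get(child.father_id)
        mother = by_id.get(child.mother_id)
        if father is None or mother is None or father.genotype is None or mother.genotype is None:
            skipped.append(child.member_id)
            continue
        child_pair = tuple(sorted(_allele_keys(child.genotype, resolution)))
        possible = {
            tuple(sorted((fa, ma)))
            for fa in _allele_keys(father.genotype, resolution)
            for ma in _allele_keys(mother.genotype, resolution)
        }
        if child_pair not in possible:
            violations.append(
                MendelianViolation(
                    member_id=child.member_id,
                    reason=f"allele pair {child_pair} not producible from parents",
                )
            )
    return MendelianReport(violations=tuple(violations), skipped=tuple(skipped))


def uniformity_of_pvalues(pvalues: np.ndarray) -> tuple[float, float]:
    """Kolmogorov-Smirnov distance and p-value of p-values against U(0,1)."""
    stat, p = sps.kstest(np.asarray(pvalues, dtype=float), "uniform")
    return float(stat), float(p)
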