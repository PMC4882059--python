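"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates amplicon deep sequencing of a diploid CD177 locus in
the presence of the CD177P1 pseudogene.  Each individual carries two gene
alleles (each either intact or carrying a contiguous pseudogene-derived
conversion tract within exons 4-9) and two intact pseudogene copies, so every
exon 4-9 segment is present in exactly four homologous copies per genome.
Reads from the four copies pool together, which quantizes the expected
variant-allele fraction at a PSV to d/4 where d is the number of
pseudogene-derived copies: 2/4 for an unconverted genome, 3/4 with one
converted gene allele, 4/4 with both converted.

Also simulated: MLPA probe peak heights (multiplicative log-normal noise),
sorted-subset transcripts (chimeric / stop-carrying flags, pseudogene-locus
transcripts omitted as degraded), neutrophil phenotype fractions linked to
genotype, and Mendelian pedigrees.  Saliva read profiles reuse the neutrophil
genotype exactly (germline model; the study found perfect concordance).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .locus import LocusModel, SiteRecord, load_builtin_cd177_model
from .mlpa import MlpaRun, Probe, ProbePanel, expected_probe_copies

#: Exons the pseudogene can donate (homology block).
CONVERTIBLE_EXONS = (4, 5, 6, 7, 8, 9)

#: Phenotype group implied by each conversion-genotype class.
PHENOTYPE_GROUP_BY_CLASS = {"ref_hom": "hi", "ectopic_het": "hi_neg", "null": "null"}


@dataclass(frozen=True)
class GeneAllele:
    """One gene allele; ``converted_exons`` is a contiguous run within 4-9
    (empty tuple = intact)."""

    converted_exons: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        ex = self.converted_exons
        if any(e not in CONVERTIBLE_EXONS for e in ex):
            raise ValueError(f"conversion tract outside exons 4-9: {ex}")
        if list(ex) != sorted(ex) or any(b - a != 1 for a, b in zip(ex, ex[1:])):
            raise ValueError(f"conversion tract must be a contiguous exon run: {ex}")

    @property
    def intact(self) -> bool:
        return not self.converted_exons

    def converted_at(self, exon_index: int) -> bool:
        return exon_index in self.converted_exons


INTACT = GeneAllele()
#: Default ectopic tract: exon 7 only.
ECTOPIC_EXON7 = GeneAllele((7,))
#: The second observed tract class: exons 5-7.
TRACT_EXON5_7 = GeneAllele((5, 6, 7))


@dataclass(frozen=True)
class ConversionGenotype:
    """Diploid gene-locus genotype; both pseudogene copies are fixed intact,
    so total homologous copy number per exon-4-9 segment is always four."""

    allele1: GeneAllele = INTACT
    allele2: GeneAllele = INTACT
    #: variant-allele copies (0-2, among gene alleles) per SNP site id
    snp_dosage: Mapping[str, int] = field(default_factory=dict)

    @property
    def alleles(self) -> tuple[GeneAllele, GeneAllele]:
        return (self.allele1, self.allele2)

    def converted_count(self, exon_index: int) -> int:
        return sum(a.converted_at(exon_index) for a in self.alleles)

    def gene_copies(self, exon_index: int) -> int:
        """Gene-derived copies of this exon's sequence (0, 1 or 2)."""
        return 2 - self.converted_count(exon_index)

    @property
    def exon7_class(self) -> str:
        return {2: "ref_hom", 1: "ectopic_het", 0: "null"}[self.gene_copies(7)]

    @property
    def is_null(self) -> bool:
        return self.gene_copies(7) == 0


def genotype_from_class(exon7_class: str) -> ConversionGenotype:
    """Minimal genotype (exon-7-only tracts) consistent with a called class."""
    if exon7_class == "ref_hom":
        return ConversionGenotype(INTACT, INTACT)
    if exon7_class == "ectopic_het":
        return ConversionGenotype(INTACT, ECTOPIC_EXON7)
    if exon7_class == "null":
        return ConversionGenotype(ECTOPIC_EXON7, ECTOPIC_EXON7)
    raise ValueError(f"cannot build a genotype for class {exon7_class!r}")


def format_tract(allele: GeneAllele) -> str:
    if allele.intact:
        return "."
    ex = allele.converted_exons
    return str(ex[0]) if len(ex) == 1 else f"{ex[0]}-{ex[-1]}"


def parse_tract(text: str) -> GeneAllele:
    if text in (".", "", "intact"):
        return INTACT
    if "-" in text:
        lo, hi = (int(x) for x in text.split("-"))
        return GeneAllele(tuple(range(lo, hi + 1)))
    return GeneAllele((int(text),))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    Defaults follow the study design: ~9,000x amplicon depth, a
    conversion-allele frequency of 0.16 (the null prevalence of 2.6% in the
    535-donor cohort implies q = sqrt(0.026) under random mating), and
    phenotype class means ordered ref_hom > ectopic_het with nulls at 0% hi.
    """

    n_samples: int = 500
    conversion_allele_freq: float = 0.16
    depth: int = 9000
    error_rate: float = 0.005
    mlpa_cv: float = 0.04
    pct_hi_mean: Mapping[str, float] = field(
        default_factory=lambda: {"ref_hom": 85.0, "ectopic_het": 45.0}
    )
    pct_hi_sd: float = 10.0
    pct_int_mean: float = 3.0
    pct_int_sd: float = 2.0
    atypical_rate: float = 0.07
    atypical_int_range: tuple[float, float] = (22.0, 45.0)
    mfi_mean: Mapping[str, float] = field(
        default_factory=lambda: {"ref_hom": 5000.0, "ectopic_het": 2500.0, "null": 30.0}
    )
    mfi_cv: float = 0.2
    snp_frequencies: Optional[Mapping[str, float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.conversion_allele_freq <= 1.0:
            raise ValueError("conversion_allele_freq must be in [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def noiseless(self) -> "SimulationConfig":
        """All dispersion knobs at zero (read error, MLPA and phenotype noise)."""
        return self.replace(
            error_rate=0.0, mlpa_cv=0.0, pct_hi_sd=0.0, pct_int_sd=0.0,
            atypical_rate=0.0, mfi_cv=0.0,
        )

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["pct_hi_mean"] = dict(d["pct_hi_mean"])
        d["mfi_mean"] = dict(d["mfi_mean"])
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        d = json.loads(text)
        d["atypical_int_range"] = tuple(d["atypical_int_range"])
        return cls(**d)


@dataclass(frozen=True)
class SampleReadProfile:
    """Per-site (ref_count, var_count) for one sample/tissue."""

    sample_id: str
    tissue: str
    counts: Mapping[str, tuple[int, int]]

    def depth(self, site_id: str) -> int:
        ref, var = self.counts[site_id]
        return ref + var

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sample_id": self.sample_id, "tissue": self.tissue, "site_id": s,
             "ref_count": rc, "var_count": vc}
            for s, (rc, vc) in self.counts.items()
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class PhenotypeRecord:
    pct_neg: float
    pct_int: float
    pct_hi: float
    mfi: float
    label: str

    def __post_init__(self) -> None:
        for v in (self.pct_neg, self.pct_int, self.pct_hi):
            if not 0.0 <= v <= 100.0:
                raise ValueError("percentages must lie in [0, 100]")
        if abs(self.pct_neg + self.pct_int + self.pct_hi - 100.0) > 1e-6:
            raise ValueError("subset percentages must sum to 100")


@dataclass(frozen=True)
class Transcript:
    bases: Mapping[str, str]  # site_id -> base, catalogued coding sites
    chimeric: bool
    stop_containing: bool


@dataclass(frozen=True)
class TranscriptSet:
    cell_subset: str  # "hi" | "neg"
    transcripts: tuple[Transcript, ...]


@dataclass(frozen=True)
class PedigreeMember:
    member_id: str
    family_id: str
    sex: str
    father_id: Optional[str]
    mother_id: Optional[str]
    genotype: ConversionGenotype
    phenotype: Optional[PhenotypeRecord] = None


@dataclass(frozen=True)
class Pedigree:
    family_id: str
    members: tuple[PedigreeMember, ...]

    def member(self, member_id: str) -> PedigreeMember:
        for m in self.members:
            if m.member_id == member_id:
                return m
        raise KeyError(member_id)

    def offspring(self) -> tuple[PedigreeMember, ...]:
        return tuple(m for m in self.members if m.father_id is not None)


# ---------------------------------------------------------------------------
# read-dosage model
# ---------------------------------------------------------------------------

def expected_variant_fraction(
    genotype: ConversionGenotype,
    site: SiteRecord,
    error_rate: float = 0.0,
) -> float:
    """Expected VAF at a catalogued site under the four-copy dosage model.

    For exons 1-3 the read pool is the two gene copies; for exons 4-9 it is
    all four homologous copies (two gene + two pseudogene).  PSV sites count
    pseudogene-derived copies (the two pseudogene copies plus converted gene
    alleles); SNP sites count gene alleles carrying the variant base, with
    converted alleles reverting to the pseudogene (reference) base.
    A symmetric base-flip error rate e maps a true fraction f to
    ``f(1-e) + (1-f)e``.
    """
    exon = site.exon_index
    pool = 2 if exon <= 3 else 4
    if site.site_class == "PSV":
        var_copies = 2 + genotype.converted_count(exon)
    else:
        dosage = genotype.snp_dosage.get(site.site_id, 0)
        if exon >= 4:
            dosage = min(dosage, genotype.gene_copies(exon))
        var_copies = dosage
    f = var_copies / pool
    return f * (1.0 - error_rate) + (1.0 - f) * error_rate


def simulate_reads(
    genotype: ConversionGenotype,
    model: LocusModel,
    cfg: SimulationConfig,
    *,
    rng: Optional[np.random.Generator] = None,
    sample_id: str = "S0",
    tissue: str = "neutrophil",
) -> SampleReadProfile:
    """Binomial read sampling at every catalogued site."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    counts: dict[str, tuple[int, int]] = {}
    for site in model.sites:
        p = expected_variant_fraction(genotype, site, cfg.error_rate)
        var = int(rng.binomial(cfg.depth, p))
        counts[site.site_id] = (cfg.depth - var, var)
    return SampleReadProfile(sample_id=sample_id, tissue=tissue, counts=counts)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def _snp_frequencies(cfg: SimulationConfig, model: LocusModel) -> dict[str, float]:
    """Per-SNP variant allele frequencies.

    Unless configured, derived from the catalog's printed carrier prevalence
    (fraction of subjects with >=1 variant copy, k/n): under random mating the
    allele frequency solving 1-(1-p)^2 = k/n is p = 1 - sqrt(1 - k/n).
    """
    if cfg.snp_frequencies is not None:
        return dict(cfg.snp_frequencies)
    freqs = {}
    for site in model.snp_sites():
        k, n = (int(x) for x in site.carrier_prevalence.split("/"))
        carrier = min(k / n, 0.99)
        freqs[site.site_id] = 1.0 - float(np.sqrt(1.0 - carrier))
    return freqs


def _draw_genotype(
    rng: np.random.Generator, q: float, snp_freqs: Mapping[str, float]
) -> ConversionGenotype:
    converted = rng.random(2) < q
    if converted.all():
        # allelic conversion: each allele's tract starts before exon 5 or 7
        alleles = tuple(
            TRACT_EXON5_7 if rng.random() < 0.5 else ECTOPIC_EXON7 for _ in range(2)
        )
    else:
        alleles = tuple(ECTOPIC_EXON7 if c else INTACT for c in converted)
    dosage = {
        sid: int(rng.binomial(2, p)) for sid, p in snp_freqs.items()
    }
    dosage = {sid: d for sid, d in dosage.items() if d}
    return ConversionGenotype(alleles[0], alleles[1], dosage)


def simulate_cohort(
    cfg: SimulationConfig, model: Optional[LocusModel] = None
) -> tuple[list[ConversionGenotype], pd.DataFrame]:
    """Draw genotypes under Hardy-Weinberg for the conversion allele.

    Returns the genotypes and a truth table (sample_id, per-allele tract,
    exon-7 class).
    """
    model = load_builtin_cd177_model() if model is None else model
    rng = np.random.default_rng(cfg.seed)
    snp_freqs = _snp_frequencies(cfg, model)
    genotypes, rows = [], []
    for i in range(cfg.n_samples):
        gt = _draw_genotype(rng, cfg.conversion_allele_freq, snp_freqs)
        genotypes.append(gt)
        rows.append(
            {
                "sample_id": f"S{i:05d}",
                "allele1_tract": format_tract(gt.allele1),
                "allele2_tract": format_tract(gt.allele2),
                "exon7_class": gt.exon7_class,
            }
        )
    return genotypes, pd.DataFrame(rows)


def simulate_cohort_reads(
    cfg: SimulationConfig,
    model: Optional[LocusModel] = None,
    tissues: Sequence[str] = ("neutrophil",),
) -> tuple[list[ConversionGenotype], pd.DataFrame, list[SampleReadProfile]]:
    """Cohort genotypes plus read profiles (one per sample and tissue).

    Saliva and neutrophil profiles are independent draws from the same
    germline genotype.
    """
    model = load_builtin_cd177_model() if model is None else model
    genotypes, truth = simulate_cohort(cfg, model)
    rng = np.random.default_rng(cfg.seed + 1)
    profiles = [
        simulate_reads(gt, model, cfg, rng=rng, sample_id=sid, tissue=tissue)
        for gt, sid in zip(genotypes, truth["sample_id"])
        for tissue in tissues
    ]
    return genotypes, truth, profiles


# ---------------------------------------------------------------------------
# MLPA
# ---------------------------------------------------------------------------

def simulate_mlpa(
    genotype: ConversionGenotype,
    panel: ProbePanel,
    cfg: SimulationConfig,
    *,
    rng: Optional[np.random.Generator] = None,
    sample_id: str = "S0",
) -> MlpaRun:
    """Peak heights proportional to target copy number, with per-probe
    hybridization efficiency and multiplicative log-normal noise at the
    configured coefficient of variation."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    heights = {}
    for probe in panel.probes:
        copies = expected_probe_copies(genotype, probe)
        noise = float(np.exp(rng.normal(0.0, cfg.mlpa_cv))) if cfg.mlpa_cv > 0 else 1.0
        heights[probe.probe_id] = probe.efficiency * copies * noise
    return MlpaRun(sample_id=sample_id, heights=heights)


# ---------------------------------------------------------------------------
# transcripts
# ---------------------------------------------------------------------------

def _allele_transcript(
    genotype: ConversionGenotype,
    allele: GeneAllele,
    allele_rank: int,
    model: LocusModel,
) -> Transcript:
    bases = {}
    for site in model.sites:
        if site.c_pos is None:
            continue
        if site.site_class == "PSV" and allele.converted_at(site.exon_index):
            bases[site.site_id] = site.var_base
        elif site.site_class == "SNP":
            dosage = genotype.snp_dosage.get(site.site_id, 0)
            carries = allele_rank < dosage and not allele.converted_at(site.exon_index)
            bases[site.site_id] = site.var_base if carries else site.ref_base
        else:
            bases[site.site_id] = site.ref_base
    from .locus import STOP_SITE_ID

    stop = bases[STOP_SITE_ID] == model.site(STOP_SITE_ID).var_base
    return Transcript(bases=bases, chimeric=not allele.intact, stop_containing=stop)


def simulate_transcripts(
    genotype: ConversionGenotype,
    subset: str,
    model: Optional[LocusModel] = None,
) -> TranscriptSet:
    """Transcript haplotypes recovered from a sorted neutrophil subset.

    The hi subset expresses only intact-allele transcripts (conversion
    carriers' chimeric transcripts bear the premature stop and are confined to
    the neg subset); the neg subset of a conversion carrier yields both.
    Pseudogene-locus transcripts never appear (modelled as degraded).
    """
    if subset not in ("hi", "neg"):
        raise ValueError(f"subset must be 'hi' or 'neg', got {subset!r}")
    model = load_builtin_cd177_model() if model is None else model
    transcripts = [
        _allele_transcript(genotype, allele, rank, model)
        for rank, allele in enumerate(genotype.alleles)
    ]
    if subset == "hi":
        transcripts = [t for t in transcripts if not t.stop_containing]
        if not transcripts:
            raise ValueError("hi-subset transcripts requested for a null genotype")
    unique: dict[tuple, Transcript] = {}
    for t in transcripts:
        key = (tuple(sorted(t.bases.items())), t.chimeric, t.stop_containing)
        unique[key] = t
    return TranscriptSet(cell_subset=subset, transcripts=tuple(unique.values()))


# ---------------------------------------------------------------------------
# phenotype
# ---------------------------------------------------------------------------

def simulate_phenotype(
    genotype: ConversionGenotype,
    cfg: SimulationConfig,
    *,
    rng: Optional[np.random.Generator] = None,
) -> PhenotypeRecord:
    """Neutrophil subset percentages and CD177 MFI linked to genotype.

    Nulls are fixed at 100% negative.  Expressors draw pct_hi from a clipped
    normal with class means ordered ref_hom > ectopic_het; a configurable
    atypical mode produces a large intermediate subset independent of
    genotype.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    cls = genotype.exon7_class
    mfi_mu = cfg.mfi_mean[cls]
    mfi = max(0.0, mfi_mu * (1.0 + (rng.normal(0.0, cfg.mfi_cv) if cfg.mfi_cv > 0 else 0.0)))
    if cls == "null":
        return PhenotypeRecord(pct_neg=100.0, pct_int=0.0, pct_hi=0.0, mfi=mfi, label="null")
    atypical = rng.random() < cfg.atypical_rate
    if atypical:
        pct_int = float(rng.uniform(*cfg.atypical_int_range))
    else:
        noise = rng.normal(0.0, cfg.pct_int_sd) if cfg.pct_int_sd > 0 else 0.0
        pct_int = float(np.clip(cfg.pct_int_mean + noise, 0.0, 20.0))
    noise = rng.normal(0.0, cfg.pct_hi_sd) if cfg.pct_hi_sd > 0 else 0.0
    pct_hi = float(np.clip(cfg.pct_hi_mean[cls] + noise, 0.0, 100.0 - pct_int))
    label = "atypical_int" if atypical else PHENOTYPE_GROUP_BY_CLASS[cls]
    pct_int = round(pct_int, 6)
    pct_hi = round(pct_hi, 6)
    return PhenotypeRecord(
        pct_neg=round(100.0 - pct_int - pct_hi, 6),
        pct_int=pct_int,
        pct_hi=pct_hi,
        mfi=mfi,
        label=label,
    )


# ---------------------------------------------------------------------------
# pedigrees
# ---------------------------------------------------------------------------

def simulate_pedigree(
    founder_genotypes: tuple[ConversionGenotype, ConversionGenotype],
    n_offspring: int,
    cfg: SimulationConfig,
    *,
    rng: Optional[np.random.Generator] = None,
    family_id: str = "FAM1",
) -> Pedigree:
    """Two founders plus offspring; each offspring receives one gene-locus
    allele, drawn uniformly, from each parent."""
    if len(founder_genotypes) != 2:
        raise ValueError("exactly two founders are required")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    father_gt, mother_gt = founder_genotypes
    members = [
        PedigreeMember(f"{family_id}.F", family_id, "male", None, None,
                       father_gt, simulate_phenotype(father_gt, cfg, rng=rng)),
        PedigreeMember(f"{family_id}.M", family_id, "female", None, None,
                       mother_gt, simulate_phenotype(mother_gt, cfg, rng=rng)),
    ]
    for k in range(n_offspring):
        a = father_gt.alleles[int(rng.integers(2))]
        b = mother_gt.alleles[int(rng.integers(2))]
        child = ConversionGenotype(a, b)
        members.append(
            PedigreeMember(
                f"{family_id}.C{k + 1}", family_id,
                "female" if rng.random() < 0.5 else "male",
                f"{family_id}.F", f"{family_id}.M",
                child, simulate_phenotype(child, cfg, rng=rng),
            )
        )
    return Pedigree(family_id=family_id, members=tuple(members))


def fig5_family_configurations() -> tuple[tuple[ConversionGenotype, ConversionGenotype], ...]:
    """Founder-genotype pairs mirroring the four published family structures:
    hom-ref x hom-ref, hom-ref x het (x2), het x het."""
    ref = ConversionGenotype(INTACT, INTACT)
    het = ConversionGenotype(INTACT, ECTOPIC_EXON7)
    return ((ref, ref), (het, ref), (het, ref), (het, het))
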