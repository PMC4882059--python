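"""Conversion-genotype inference from quantized variant-read fractions.

At ~9,000x amplicon depth the variant-allele fraction (VAF) at a paralogous
sequence variant is tightly quantized at multiples of 1/4 (the four
homologous copies of each exon 4-9 segment).  The caller assigns each site
the unique level in {0, 25, 50, 75, 100}% whose error-adjusted expected
fraction lies inside an exact (Clopper-Pearson) binomial confidence interval;
if more than one level fits, the site is ambiguous.  The exon-7 PSV levels
map directly to conversion state: 50% -> both gene alleles intact (ref_hom),
75% -> one ectopically converted allele (ectopic_het), 100% -> both alleles
converted (null).  A supermajority rule across the five exon-7 PSVs tolerates
one dropout; conflicting confident levels leave the sample unresolved rather
than miscalled.

Also here: PSV-vs-SNP site classification from cohort gDNA levels plus cDNA
evidence, conversion-breakpoint interval inference from per-exon gene copy
counts, neutrophil/saliva germline concordance, and exhaustive two-locus
haplotype enumeration under the four-copy model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from scipy import special

from .locus import EXON7_PSV_IDS, LocusModel, SiteRecord
from .simulate import SampleReadProfile

LEVELS = (0, 25, 50, 75, 100)
DEFAULT_CONFIDENCE = 0.99
DEFAULT_ERROR_RATE = 0.005
#: exon-7 PSV level -> conversion class
CLASS_BY_LEVEL = {50: "ref_hom", 75: "ectopic_het", 100: "null"}
#: minimum number of agreeing exon-7 PSVs for a confident class
MIN_AGREEING_SITES = 4


class InsufficientSitesError(ValueError):
    """Profile does not cover enough exon-7 PSV sites."""


class HaplotypeInconsistencyError(ValueError):
    """No four-copy base assignment reproduces the observed levels."""


@dataclass(frozen=True)
class SiteCall:
    site_id: str
    depth: int
    vaf: float
    ci_low: float
    ci_high: float
    level: Optional[int]  # percent in LEVELS; None = ambiguous

    @property
    def ambiguous(self) -> bool:
        return self.level is None


def clopper_pearson(k: int, n: int, confidence: float) -> tuple[float, float]:
    """Exact binomial confidence interval for k successes in n trials."""
    if n <= 0:
        raise ValueError("depth must be positive")
    alpha = 1.0 - confidence
    low = 0.0 if k == 0 else float(special.betaincinv(k, n - k + 1, alpha / 2))
    high = 1.0 if k == n else float(special.betaincinv(k + 1, n - k, 1 - alpha / 2))
    return low, high


def adjust_for_error(fraction: float, error_rate: float) -> float:
    """Expected observed fraction under a symmetric base-flip error rate."""
    return fraction * (1.0 - error_rate) + (1.0 - fraction) * error_rate


def call_site(
    ref_count: int,
    var_count: int,
    *,
    site_id: str = "",
    confidence: float = DEFAULT_CONFIDENCE,
    error_rate: float = DEFAULT_ERROR_RATE,
) -> SiteCall:
    """Quantize one site's VAF onto the dosage levels.

    The level is assigned only when exactly one level's error-adjusted
    expected fraction falls inside the Clopper-Pearson interval.
    """
    if ref_count < 0 or var_count < 0:
        raise ValueError("read counts must be non-negative")
    depth = ref_count + var_count
    if depth == 0:
        raise ValueError(f"site {site_id or '?'}: zero depth (missing data)")
    vaf = var_count / depth
    lo, hi = clopper_pearson(var_count, depth, confidence)
    inside = [
        lvl for lvl in LEVELS if lo <= adjust_for_error(lvl / 100.0, error_rate) <= hi
    ]
    level = inside[0] if len(inside) == 1 else None
    return SiteCall(
        site_id=site_id, depth=depth, vaf=vaf, ci_low=lo, ci_high=hi, level=level
    )


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    exon7_class: str  # ref_hom | ectopic_het | null | unresolved
    #: gene-derived copy count per PSV-bearing exon (None when undetermined)
    gene_copies: Mapping[int, Optional[int]]
    site_calls: Mapping[str, SiteCall]
    flags: tuple[str, ...]

    @property
    def resolved(self) -> bool:
        return self.exon7_class != "unresolved"


def _gene_copies_from_level(level: int) -> Optional[int]:
    # variant fraction v over four copies leaves 4(1 - v) gene-base copies,
    # all of which are unconverted gene alleles (0, 1 or 2).
    copies = 4 - level // 25
    return copies if 0 <= copies <= 2 else None


def call_genotype(
    profile: SampleReadProfile,
    model: LocusModel,
    *,
    confidence: float = DEFAULT_CONFIDENCE,
    error_rate: float = DEFAULT_ERROR_RATE,
    min_agreeing: int = MIN_AGREEING_SITES,
) -> GenotypeCall:
    """Call a sample's conversion genotype from its read profile.

    Raises :class:`InsufficientSitesError` when fewer than ``min_agreeing``
    exon-7 PSVs are covered.  Conflicting confident levels among the exon-7
    PSVs, or too few agreeing sites, produce class ``unresolved`` with a
    concordance flag — never a wrong confident class.
    """
    present = [sid for sid in EXON7_PSV_IDS if sid in profile.counts]
    if len(present) < min_agreeing:
        raise InsufficientSitesError(
            f"{profile.sample_id}: {len(present)}/{len(EXON7_PSV_IDS)} exon-7 PSVs "
            f"covered; need at least {min_agreeing}"
        )
    site_calls: dict[str, SiteCall] = {}
    for sid, (ref, var) in profile.counts.items():
        site_calls[sid] = call_site(
            ref, var, site_id=sid, confidence=confidence, error_rate=error_rate
        )

    flags: list[str] = []
    exon7_levels = [site_calls[sid].level for sid in present]
    confident = [lvl for lvl in exon7_levels if lvl is not None]
    votes: dict[int, int] = {}
    for lvl in confident:
        votes[lvl] = votes.get(lvl, 0) + 1
    if any(lvl not in CLASS_BY_LEVEL for lvl in confident):
        flags.append("unexpected_exon7_level")
    if len(set(confident)) > 1:
        flags.append("exon7_psv_discordant")
    if len(confident) < len(present):
        flags.append("exon7_psv_ambiguous")
    top = max(votes, key=votes.get) if votes else None
    if (
        top is not None
        and top in CLASS_BY_LEVEL
        and votes[top] >= min_agreeing
        and all(lvl == top for lvl in confident)
    ):
        exon7_class = CLASS_BY_LEVEL[top]
    else:
        exon7_class = "unresolved"

    gene_copies: dict[int, Optional[int]] = {}
    for exon in (4, 5, 7):
        levels = {
            site_calls[s.site_id].level
        for s in model.psv_sites(exon)
            if s.site_id in site_calls
        }
        levels.discard(None)
        if len(levels) == 1:
            gene_copies[exon] = _gene_copies_from_level(levels.pop())
        else:
            gene_copies[exon] = None
            if levels:
                flags.append(f"exon{exon}_psv_discordant")
    return GenotypeCall(
        sample_id=profile.sample_id,
        exon7_class=exon7_class,
        gene_copies=gene_copies,
        site_calls=site_calls,
        flags=tuple(flags),
    )


def classify_site(
    site: SiteRecord,
    cohort_gdna_levels: Iterable[Optional[int]],
    cdna_evidence: Iterable[str],
) -> str:
    """Classify a catalogued site as gene SNP vs gene/pseudogene PSV.

    A site in exons 1-3 has no pseudogene counterpart and is a SNP; so is any
    site whose variant base appears in intact-allele cDNA.  A site whose gDNA
    levels across the cohort include quarter-dosage values (25 or 75) while
    its variant base is absent from intact-allele transcripts behaves like a
    fixed gene/pseudogene difference (PSV).  Anything else stays unknown.
    """
    if site.exon_index <= 3:
        return "SNP"
    cdna_bases = set(cdna_evidence)
    if site.var_base in cdna_bases:
        return "SNP"
    levels = {lvl for lvl in cohort_gdna_levels if lvl is not None}
    if 25 in levels or 75 in levels:
        return "PSV"
    return "unknown"


@dataclass(frozen=True)
class BreakpointInterval:
    """Half-open interval (between catalogued exons) containing a conversion
    breakpoint; ``scope`` is "sample" (both alleles, null subjects) or
    "allele" (heterozygotes)."""

    left_exon: int
    right_exon: int
    scope: str = "sample"

    def __post_init__(self) -> None:
        if self.left_exon >= self.right_exon:
            raise ValueError("interval bounds must be ordered")


@dataclass(frozen=True)
class BreakpointResult:
    intervals: tuple[BreakpointInterval, ...]
    complex_event: bool

    def __bool__(self) -> bool:
        return bool(self.intervals)


def infer_breakpoint(
    gene_copy_counts: Mapping[int, int], *, scope: str = "sample"
) -> BreakpointResult:
    """Localize the conversion breakpoint from ordered per-exon gene dosage.

    The breakpoint lies between the last upstream exon retaining its expected
    gene copy count and the first downstream exon with a deficit.  A deficit
    followed by restoration is a complex event and is returned flagged, with
    every transition interval reported.
    """
    exons = sorted(gene_copy_counts)
    if len(exons) < 2:
        raise ValueError("copy counts for at least two ordered exons are required")
    intervals: list[BreakpointInterval] = []
    complex_event = False
    dropped = False
    for left, right in zip(exons, exons[1:]):
        a, b = gene_copy_counts[left], gene_copy_counts[right]
        if b < a:
            intervals.append(BreakpointInterval(left, right, scope))
            dropped = True
        elif b > a:
            intervals.append(BreakpointInterval(left, right, scope))
            if dropped:
                complex_event = True
    return BreakpointResult(intervals=tuple(intervals), complex_event=complex_event)


@dataclass(frozen=True)
class ConcordanceReport:
    sample_id: str
    per_site: Mapping[str, tuple[Optional[int], Optional[int]]]
    n_compared: int
    n_agree: int
    germline: bool
    flags: tuple[str, ...]


def germline_concordance(
    neutrophil: SampleReadProfile,
    saliva: SampleReadProfile,
    *,
    confidence: float = DEFAULT_CONFIDENCE,
    error_rate: float = DEFAULT_ERROR_RATE,
) -> ConcordanceReport:
    """Compare quantized levels between two tissues of one individual.

    The verdict is germline iff every site resolvable in both tissues agrees;
    any disagreement raises a somatic-difference flag.
    """
    if neutrophil.sample_id != saliva.sample_id:
        raise ValueError("profiles must come from the same sample")
    if neutrophil.tissue == saliva.tissue:
        raise ValueError("germline check requires two distinct tissues")
    per_site: dict[str, tuple[Optional[int], Optional[int]]] = {}
    n_compared = n_agree = 0
    for sid in sorted(set(neutrophil.counts) & set(saliva.counts)):
        ln = call_site(*neutrophil.counts[sid], site_id=sid,
                       confidence=confidence, error_rate=error_rate).level
        ls = call_site(*saliva.counts[sid], site_id=sid,
                       confidence=confidence, error_rate=error_rate).level
        per_site[sid] = (ln, ls)
        if ln is not None and ls is not None:
            n_compared += 1
            n_agree += ln == ls
    germline = n_compared > 0 and n_agree == n_compared
    flags = () if germline else ("somatic_difference",)
    return ConcordanceReport(
        sample_id=neutrophil.sample_id,
        per_site=per_site,
        n_compared=n_compared,
        n_agree=n_agree,
        germline=germline,
        flags=flags,
    )


@dataclass(frozen=True)
class HaplotypeConfig:
    """Bases at (exon-4 locus, exon-7 locus) for the two gene and two
    pseudogene chromosomal slots, order-normalized within each pair."""

    gene: tuple[tuple[str, str], tuple[str, str]]
    pseudogene: tuple[tuple[str, str], tuple[str, str]]


def enumerate_haplotypes(
    exon4_ref_level: int,
    exon7_ref_level: int,
    *,
    exon4_bases: tuple[str, str] = ("C", "G"),
    exon7_bases: tuple[str, str] = ("A", "T"),
) -> tuple[HaplotypeConfig, ...]:
    """All four-copy base assignments matching two-locus reference levels.

    Levels are reference-allele read percentages (quantized to quarters) at
    one exon-4 PSV and one exon-7 PSV.  Model constraints: the pseudogene
    slots are fixed for the pseudogene base at exon 7 (the population is
    homozygous for it), and a pseudogene-derived base at exon 4 of a *gene*
    slot implies the pseudogene base at exon 7 of the same slot, because
    conversion tracts are contiguous and the observed tracts all reach exon 7.

    Raises :class:`HaplotypeInconsistencyError` when no assignment fits.
    """
    ref4, var4 = exon4_bases
    ref7, var7 = exon7_bases
    for lvl in (exon4_ref_level, exon7_ref_level):
        if lvl not in LEVELS:
            raise ValueError(f"levels must be quantized percentages, got {lvl}")
    gene_slot_options = [
        (b4, b7)
        for b4 in (ref4, var4)
        for b7 in (ref7, var7)
        if not (b4 == var4 and b7 == ref7)  # tract covering exon 4 reaches exon 7
    ]
    p1_slot_options = [(b4, var7) for b4 in (ref4, var4)]
    found = set()
    for g1 in gene_slot_options:
        for g2 in gene_slot_options:
            for p1 in p1_slot_options:
                for p2 in p1_slot_options:
                    slots = (g1, g2, p1, p2)
                    ref4_pct = 25 * sum(s[0] == ref4 for s in slots)
                    ref7_pct = 25 * sum(s[1] == ref7 for s in slots)
                    if (ref4_pct, ref7_pct) == (exon4_ref_level, exon7_ref_level):
                        found.add(
                            HaplotypeConfig(
                                gene=tuple(sorted((g1, g2))),
                                pseudogene=tuple(sorted((p1, p2))),
                            )
                        )
    if not found:
        raise HaplotypeInconsistencyError(
            f"no four-copy arrangement yields exon4={exon4_ref_level}%, "
            f"exon7={exon7_ref_level}% reference reads"
        )
    return tuple(sorted(found, key=lambda c: (c.gene, c.pseudogene)))
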