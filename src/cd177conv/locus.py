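"""The CD177 / CD177P1 locus model.

*CD177* is a nine-exon gene on human chromosome 19 encoding a GPI-anchored
neutrophil surface antigen (HNA-2a).  Roughly 10 kb away lies *CD177P1*, a
pseudogene comprising sequences homologous to *CD177* exons 4-9.  Because the
two loci are nearly identical over that span, short-read data from both map
together and fixed gene/pseudogene differences (paralogous sequence variants,
PSVs) appear as "variants" whose read fraction is quantized by copy dosage.

This module houses:

* a coordinate system: gene-relative 1-based ``g.`` positions, a piecewise
  exon map to CDS (``c.``) coordinates, and the exon table;
* the catalog of 17 protein-coding variant sites with their g./c. positions,
  ref/var bases, PSV-vs-SNP classification and amino-acid consequences;
* packaged reference sequences for the gene and the pseudogene homology
  block.  Bases not pinned by the catalog are synthetic filler generated once
  from a fixed seed, so codon contexts are stable across installs.

Coordinates are 1-based; exon intervals are half-open ``[start, end)``.
The catalog is oriented so that the *gene* base is the base observed in
reference-allele transcripts (the corrected orientation); the historical
database orientation, where it differs, is kept in ``db_note``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Optional

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

GENE_NAME = "CD177"
PSEUDOGENE_NAME = "CD177P1"
GENE_LENGTH = 8800
#: g. position of the first base of the pseudogene homology block (exon 4 start).
PSEUDOGENE_G_OFFSET = 1940
#: Fixed seed for the synthetic filler sequence outside catalogued codons.
FILLER_SEED = 19432361

_BASES = ("A", "C", "G", "T")


class CoordinateError(ValueError):
    """A g./c. position outside the coding exon map."""


class NonCodingSiteError(ValueError):
    """Consequence annotation requested for a site with no CDS coordinate."""


@dataclass(frozen=True)
class Exon:
    """One exon: g. interval, CDS interval (both half-open, 1-based)."""

    index: int
    g_start: int
    g_end: int
    c_start: int
    c_end: int
    has_pseudogene_counterpart: bool

    @property
    def g_offset(self) -> int:
        """Constant ``g - c`` offset within this exon."""
        return self.g_start - self.c_start

    def contains_g(self, g_pos: int) -> bool:
        return self.g_start <= g_pos < self.g_end

    def contains_c(self, c_pos: int) -> bool:
        return self.c_start <= c_pos < self.c_end


@dataclass(frozen=True)
class SiteRecord:
    """One catalogued coding variant site.

    ``ref_base`` is the gene (reference-transcript) base, ``var_base`` the
    alternative observed in reads; for PSV sites the var base is the
    pseudogene-derived base.  ``aa_change`` is computed from the packaged
    sequence; ``db_note`` records the printed/database label where the two
    disagree (historical mis-orientation of the reference assembly).
    """

    site_id: str
    g_pos: int
    c_pos: Optional[int]
    exon_index: int
    ref_base: str
    var_base: str
    site_class: str  # "SNP" | "PSV" | "unknown"
    aa_change: str
    rsid: str
    carrier_prevalence: str
    hg38_pos: int
    db_note: str

    def __post_init__(self) -> None:
        if self.ref_base == self.var_base:
            raise ValueError(f"{self.site_id}: ref and var base identical")
        if self.site_class == "PSV" and self.exon_index < 4:
            raise ValueError(
                f"{self.site_id}: PSV class requires a pseudogene counterpart "
                f"(exons 4-9), got exon {self.exon_index}"
            )


@dataclass(frozen=True)
class CodonConsequence:
    codon_index: int
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    is_stop_gain: bool

    @property
    def label(self) -> str:
        alt = "X" if self.alt_aa == "*" else self.alt_aa
        return f"{self.ref_aa}{self.codon_index}{alt}"

    @property
    def is_synonymous(self) -> bool:
        return self.ref_aa == self.alt_aa


# Exon boundaries chosen as the smallest layout consistent with every
# catalogued (g., c.) pair; CDS totals 1311 nt = 437 codons.
_EXON_TABLE = (
    (1, 41, 101, 1, 61, False),
    (2, 189, 279, 61, 151, False),
    (3, 751, 931, 151, 331, False),
    (4, 1941, 2085, 331, 475, True),
    (5, 2292, 2468, 475, 651, True),
    (6, 6624, 6739, 651, 766, True),
    (7, 7476, 7620, 766, 910, True),
    (8, 7856, 8047, 910, 1101, True),
    (9, 8445, 8656, 1101, 1312, True),
)

# site_id, g, c, exon, ref, var, class, aa(computed), rsid, prevalence, hg38, db_note
_SITE_TABLE = (
    ("g.49", 49, 9, 1, "G", "C", "SNP", "A3A", "rs45441892", "23/39", 43353721, "A3P"),
    ("g.220", 220, 92, 2, "A", "T", "SNP", "H31L", "rs45553433", "2/39", 43353892, "H31L"),
    ("g.242", 242, 114, 2, "G", "A", "SNP", "L38L", "rs45571738", "7/39", 43353914, "L38L"),
    ("g.1991", 1991, 381, 4, "C", "G", "PSV", "P127P", "novel", "39/39", 43355663, "P128A"),
    ("g.2368", 2368, 551, 5, "G", "T", "PSV", "G184V", "rs12981714", "38/39", 43356040, "db orientation T->G V184G"),
    ("g.2427", 2427, 610, 5, "A", "G", "PSV", "N204D", "rs12980412", "38/39", 43356099, "db orientation G->A D204N"),
    ("g.2431", 2431, 614, 5, "G", "T", "PSV", "R205M", "rs12981771", "38/39", 43356103, "db orientation T->G M205R"),
    ("g.6683", 6683, 710, 6, "T", "C", "SNP", "M237T", "rs57802244", "1/39", 43360355, "M237T"),
    ("g.6724", 6724, 751, 6, "C", "A", "SNP", "L251I", "rs10425835", "27/39", 43360396, "L251I"),
    ("g.7492", 7492, 782, 7, "G", "C", "PSV", "G261A", "novel", "39/39", 43361164, "G261A"),
    ("g.7496", 7496, 786, 7, "A", "C", "PSV", "T262T", "novel", "39/39", 43361168, "T262T"),
    ("g.7497", 7497, 787, 7, "A", "T", "PSV", "K263X", "novel", "39/39", 43361169, "K263X"),
    ("g.7500", 7500, 790, 7, "G", "A", "PSV", "G264S", "rs200145410", "39/39", 43361172, "G264S"),
    ("g.7501", 7501, 791, 7, "G", "T", "SNP", "G264V", "rs200006364", "10/39", 43361173, "G264V"),
    # printed cDNA position 798 contradicts the exon-7 offset shared by the
    # other five exon-7 sites (and the genomic spacing and the T267A label);
    # 799 (codon 267, position 1) is the self-consistent value.
    ("g.7509", 7509, 799, 7, "A", "G", "PSV", "T267A", "rs201266439", "39/39", 43361181, "printed cDNA pos 798"),
    ("g.7968", 7968, 1022, 8, "G", "A", "SNP", "S341N", "rs17856829", "15/39", 43361540, "A348T"),
    ("g.8625", 8625, 1281, 9, "G", "A", "SNP", "G427G", "rs78718189", "4/39", 43362297, "G431R"),
)

# Codon contexts pinned so every catalogued site sits in a fixed codon and the
# exon-7 stop-gain context is AAA -> TAA.  Codon 1 = start, codon 437 = stop.
_PINNED_CODONS = {
    1: "ATG",
    3: "GCG",
    31: "CAC",
    38: "CTG",
    127: "CCC",
    184: "GGG",
    204: "AAT",
    205: "AGG",
    237: "ATG",
    251: "CTA",
    261: "GGA",
    262: "ACA",
    263: "AAA",
    264: "GGT",
    267: "ACA",
    341: "AGC",
    427: "GGG",
    437: "TAA",
}

_STOPS = {"TAA", "TAG", "TGA"}

#: The five exon-7 PSVs used for conversion-genotype calling.
EXON7_PSV_IDS = ("g.7492", "g.7496", "g.7497", "g.7500", "g.7509")
#: The premature-stop PSV (K263X when pseudogene-derived).
STOP_SITE_ID = "g.7497"


@dataclass(frozen=True)
class LocusModel:
    """Gene/pseudogene structure, site catalog and sequences."""

    gene_name: str
    pseudogene_name: str
    exons: tuple[Exon, ...]
    sites: tuple[SiteRecord, ...]
    gene_seq: str
    pseudogene_seq: str
    pseudogene_g_offset: int

    # -- coordinate map -------------------------------------------------
    def exon_of_g(self, g_pos: int) -> Exon:
        for exon in self.exons:
            if exon.contains_g(g_pos):
                return exon
        raise CoordinateError(f"g.{g_pos} is not within a coding exon")

    def exon_of_c(self, c_pos: int) -> Exon:
        for exon in self.exons:
            if exon.contains_c(c_pos):
                return exon
        raise CoordinateError(f"c.{c_pos} is outside the CDS")

    def g_to_c(self, g_pos: int) -> int:
        return g_pos - self.exon_of_g(g_pos).g_offset

    def c_to_g(self, c_pos: int) -> int:
        return c_pos + self.exon_of_c(c_pos).g_offset

    # -- catalog access -------------------------------------------------
    def site(self, site_id: str) -> SiteRecord:
        for s in self.sites:
            if s.site_id == site_id:
                return s
        raise KeyError(site_id)

    def site_ids(self) -> tuple[str, ...]:
        return tuple(s.site_id for s in self.sites)

    def psv_sites(self, exon_index: Optional[int] = None) -> tuple[SiteRecord, ...]:
        return tuple(
            s
            for s in self.sites
            if s.site_class == "PSV"
            and (exon_index is None or s.exon_index == exon_index)
        )

    def snp_sites(self) -> tuple[SiteRecord, ...]:
        return tuple(s for s in self.sites if s.site_class == "SNP")

    @property
    def cds_length(self) -> int:
        return self.exons[-1].c_end - 1

    def cds_sequence(self) -> str:
        return "".join(
            self.gene_seq[e.g_start - 1 : e.g_end - 1] for e in self.exons
        )

    def codon(self, codon_index: int) -> str:
        c_start = 3 * (codon_index - 1) + 1
        if c_start < 1 or c_start + 2 > self.cds_length:
            raise CoordinateError(f"codon {codon_index} outside CDS")
        cds = self.cds_sequence()
        return cds[c_start - 1 : c_start + 2]

    def pseudogene_base(self, site: SiteRecord) -> Optional[str]:
        """Base carried by the pseudogene at a catalogued site (None if the
        site lies outside the homology block, i.e. exons 1-3)."""
        if site.exon_index < 4:
            return None
        return self.pseudogene_seq[site.g_pos - self.pseudogene_g_offset - 1]


def _build_exons() -> tuple[Exon, ...]:
    return tuple(Exon(*row) for row in _EXON_TABLE)


def _build_sites() -> tuple[SiteRecord, ...]:
    return tuple(SiteRecord(*row) for row in _SITE_TABLE)


def build_gene_sequence(seed: int = FILLER_SEED) -> str:
    """Deterministically generate the packaged gene sequence.

    Filler bases come from a seeded RNG; coding positions are then adjusted so
    the open reading frame holds (no internal stops) and every catalogued
    codon context is pinned.
    """
    rng = np.random.default_rng(seed)
    arr = rng.choice(np.array(list("ACGT")), size=GENE_LENGTH).tolist()
    exons = _build_exons()

    def c2g(c_pos: int) -> int:
        for exon in exons:
            if exon.contains_c(c_pos):
                return c_pos + exon.g_offset
        raise AssertionError(c_pos)

    def set_codon(idx: int, codon: str) -> None:
        for k, base in enumerate(codon):
            arr[c2g(3 * (idx - 1) + 1 + k) - 1] = base

    def get_codon(idx: int) -> str:
        return "".join(arr[c2g(3 * (idx - 1) + 1 + k) - 1] for k in range(3))

    n_codons = (exons[-1].c_end - 1) // 3
    for idx in range(2, n_codons):  # scrub internal in-frame stops
        if idx not in _PINNED_CODONS and get_codon(idx) in _STOPS:
            set_codon(idx, get_codon(idx)[:2] + "C")
    for idx, codon in _PINNED_CODONS.items():
        set_codon(idx, codon)
    return "".join(arr)


def build_pseudogene_sequence(gene_seq: str) -> str:
    """Pseudogene homology block: gene exons 4-9 span with the pseudogene base
    substituted at every PSV site."""
    exons = _build_exons()
    start = exons[3].g_start  # exon 4
    end = exons[-1].g_end - 1  # last base of exon 9
    block = list(gene_seq[start - 1 : end])
    for row in _SITE_TABLE:
        site_id, g_pos, _c, exon, _ref, var = row[:6]
        site_class = row[6]
        if site_class == "PSV":
            block[g_pos - start] = var
    return "".join(block)


def _data_path(name: str):
    return resources.files("cd177conv.data").joinpath(name)


@lru_cache(maxsize=1)
def load_builtin_cd177_model() -> LocusModel:
    """Load the packaged CD177/CD177P1 model (exons, 17-site catalog, FASTA)."""
    seqs = {
        rec.id: str(rec.seq)
        for rec in SeqIO.parse(_data_path("cd177_locus.fasta").open(), "fasta")
    }
    model = LocusModel(
        gene_name=GENE_NAME,
        pseudogene_name=PSEUDOGENE_NAME,
        exons=_build_exons(),
        sites=_build_sites(),
        gene_seq=seqs[GENE_NAME],
        pseudogene_seq=seqs[PSEUDOGENE_NAME],
        pseudogene_g_offset=PSEUDOGENE_G_OFFSET,
    )
    validate_model(model)
    return model


def validate_model(model: LocusModel) -> None:
    """Assert the structural invariants of a locus model."""
    exons = model.exons
    for a, b in zip(exons, exons[1:]):
        if not (a.g_end <= b.g_start and a.c_end == b.c_start):
            raise ValueError(f"exons {a.index}/{b.index} overlap or leave a CDS gap")
        if (a.g_end - a.g_start) != (a.c_end - a.c_start):
            raise ValueError(f"exon {a.index}: g and c spans differ")
    homologous = tuple(e.index for e in exons if e.has_pseudogene_counterpart)
    if homologous != (4, 5, 6, 7, 8, 9):
        raise ValueError("pseudogene homology must cover exactly exons 4-9")
    for site in model.sites:
        exon = model.exon_of_g(site.g_pos)
        if exon.index != site.exon_index:
            raise ValueError(f"{site.site_id}: exon mismatch")
        if site.c_pos is not None and model.g_to_c(site.g_pos) != site.c_pos:
            raise ValueError(f"{site.site_id}: c. coordinate mismatch")
        if model.gene_seq[site.g_pos - 1] != site.ref_base:
            raise ValueError(f"{site.site_id}: packaged sequence disagrees with catalog")
        pbase = model.pseudogene_base(site)
        expected = site.var_base if site.site_class == "PSV" else site.ref_base
        if pbase is not None and pbase != expected:
            raise ValueError(f"{site.site_id}: pseudogene base mismatch")
    # round trip over the full CDS
    for c in range(1, model.cds_length + 1):
        if model.g_to_c(model.c_to_g(c)) != c:
            raise ValueError(f"c.{c}: coordinate round-trip failed")


def g_to_c(model: LocusModel, g_pos: int) -> int:
    """Map a gene-relative g. position to its CDS coordinate."""
    return model.g_to_c(g_pos)


def c_to_g(model: LocusModel, c_pos: int) -> int:
    """Inverse of :func:`g_to_c`."""
    return model.c_to_g(c_pos)


def annotate_consequence(model: LocusModel, site: SiteRecord) -> CodonConsequence:
    """Codon-level consequence of a catalogued substitution.

    Raises :class:`NonCodingSiteError` for sites without a CDS coordinate.
    The codon index is ``ceil(c_pos / 3)``.
    """
    if site.c_pos is None:
        raise NonCodingSiteError(f"{site.site_id} has no CDS coordinate")
    codon_index = (site.c_pos + 2) // 3
    ref_codon = model.codon(codon_index)
    offset = (site.c_pos - 1) % 3
    if ref_codon[offset] != site.ref_base:
        raise ValueError(f"{site.site_id}: sequence/catalog ref base mismatch")
    alt_codon = ref_codon[:offset] + site.var_base + ref_codon[offset + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    return CodonConsequence(
        codon_index=codon_index,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        is_stop_gain=(alt_aa == "*" and ref_aa != "*"),
    )
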