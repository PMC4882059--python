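"""MLPA probe-ratio normalization and copy-number calling.

Multiplex ligation-dependent probe amplification reports target copy number
through probe peak heights.  The panel mirrors the published probe design:
an exon-2 probe reads out the gene only (exon 2 has no pseudogene
counterpart), probes in exons 4, 5, 7 and 9 bind both gene and pseudogene
(four copies in an unrearranged genome), and two probes are specific to the
pseudogene-derived sequence of exons 5 and 7.  Gene conversion moves sequence
between paralogs without changing total copy number, so shared probes stay at
ratio 1.0 while pseudogene-specific probes gain one copy per converted gene
allele.

Normalization is the standard two-step ratio: peak heights are divided by the
mean control-probe height within the sample, then by the mean of that
quantity across declared control (unrearranged) samples.  Copy states use the
published thresholds: ratio < 0.75 deleted, > 1.25 duplicated.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

ROLE_GENE_ONLY = "gene_only"
ROLE_SHARED = "shared"
ROLE_P1_SPECIFIC = "p1_specific"
ROLE_CONTROL = "control"

DELETION_THRESHOLD = 0.75
DUPLICATION_THRESHOLD = 1.25


class FailedRunError(ValueError):
    """Zero or missing control-probe signal."""


@dataclass(frozen=True)
class Probe:
    probe_id: str
    exon: Optional[int]
    role: str
    #: target copies in an unrearranged diploid genome
    diploid_copies: int
    #: fixed relative hybridization/amplification efficiency
    efficiency: float = 1.0


@dataclass(frozen=True)
class ProbePanel:
    probes: tuple[Probe, ...]

    def __post_init__(self) -> None:
        if len(self.control_ids()) < 2:
            raise ValueError("a probe panel needs at least two control probes")

    def control_ids(self) -> tuple[str, ...]:
        return tuple(p.probe_id for p in self.probes if p.role == ROLE_CONTROL)

    def probe(self, probe_id: str) -> Probe:
        for p in self.probes:
            if p.probe_id == probe_id:
                return p
        raise KeyError(probe_id)

    def by_role(self, role: str) -> tuple[Probe, ...]:
        return tuple(p for p in self.probes if p.role == role)


def default_probe_panel() -> ProbePanel:
    """The published probe layout: gene-only exon 2; shared exons 4, 5, 7, 9;
    pseudogene-specific exons 5 and 7; three reference-locus controls."""
    return ProbePanel(
        probes=(
            Probe("EX2", 2, ROLE_GENE_ONLY, 2, efficiency=1.10),
            Probe("EX4", 4, ROLE_SHARED, 4, efficiency=0.95),
            Probe("EX5", 5, ROLE_SHARED, 4, efficiency=1.05),
            Probe("EX5P1", 5, ROLE_P1_SPECIFIC, 2, efficiency=0.90),
            Probe("EX7", 7, ROLE_SHARED, 4, efficiency=1.00),
            Probe("EX7P1", 7, ROLE_P1_SPECIFIC, 2, efficiency=1.15),
            Probe("EX9", 9, ROLE_SHARED, 4, efficiency=0.85),
            Probe("C1", None, ROLE_CONTROL, 2, efficiency=1.00),
            Probe("C2", None, ROLE_CONTROL, 2, efficiency=1.20),
            Probe("C3", None, ROLE_CONTROL, 2, efficiency=0.80),
        )
    )


def expected_probe_copies(genotype, probe: Probe) -> int:
    """Target copy number of a probe under a conversion genotype.

    ``genotype`` needs ``gene_copies(exon)`` / ``converted_count(exon)``.
    Gene-only probes count gene-derived copies; shared probes count all
    homologous copies (constant four in the homology block — conversion is
    copy-neutral); pseudogene-specific probes count the two pseudogene copies
    plus any converted gene alleles.
    """
    if probe.role == ROLE_CONTROL:
        return 2
    if probe.exon is None:
        raise ValueError(f"probe {probe.probe_id}: non-control probe needs an exon")
    if probe.role == ROLE_GENE_ONLY:
        return genotype.gene_copies(probe.exon) if probe.exon >= 4 else 2
    if probe.role == ROLE_SHARED:
        return 4 if probe.exon >= 4 else 2
    if probe.role == ROLE_P1_SPECIFIC:
        return 2 + genotype.converted_count(probe.exon)
    raise ValueError(f"unknown probe role {probe.role!r}")


@dataclass(frozen=True)
class MlpaRun:
    """Raw peak heights for one sample, plus (after normalization) per-probe
    ratios, categorical copy states and integerized copy counts."""

    sample_id: str
    heights: Mapping[str, float]
    ratios: Optional[Mapping[str, float]] = None
    copy_states: Optional[Mapping[str, str]] = None
    copy_counts: Optional[Mapping[str, int]] = None


def call_copy_state(
    ratio: float,
    *,
    deletion_threshold: float = DELETION_THRESHOLD,
    duplication_threshold: float = DUPLICATION_THRESHOLD,
) -> str:
    """deleted / normal / duplicated at the configured ratio thresholds."""
    if not ratio > 0:
        raise ValueError(f"normalized ratio must be positive, got {ratio}")
    if ratio < deletion_threshold:
        return "deleted"
    if ratio > duplication_threshold:
        return "duplicated"
    return "normal"


def _control_relative(run: MlpaRun, panel: ProbePanel) -> dict[str, float]:
    ctl = panel.control_ids()
    try:
        mean_ctl = sum(run.heights[c] for c in ctl) / len(ctl)
    except KeyError as exc:
        raise FailedRunError(f"{run.sample_id}: missing control probe {exc}") from exc
    if mean_ctl <= 0:
        raise FailedRunError(f"{run.sample_id}: zero control-probe signal")
    return {pid: h / mean_ctl for pid, h in run.heights.items()}


def normalize(
    runs: Sequence[MlpaRun],
    panel: ProbePanel,
    control_sample_ids: Iterable[str],
    *,
    deletion_threshold: float = DELETION_THRESHOLD,
    duplication_threshold: float = DUPLICATION_THRESHOLD,
) -> list[MlpaRun]:
    """Two-step normalization against control probes, then control samples.

    Control samples are declared unrearranged (one gene and one pseudogene
    copy per chromosome); their per-probe ratios average 1 by construction.
    Returns new runs carrying ratios, copy states and integerized copy counts
    (ratio x unrearranged copy number, rounded).
    """
    control_ids = set(control_sample_ids)
    if not control_ids:
        raise ValueError("at least one control sample is required")
    missing = control_ids - {r.sample_id for r in runs}
    if missing:
        raise ValueError(f"control samples absent from runs: {sorted(missing)}")
    rel = {run.sample_id: _control_relative(run, panel) for run in runs}
    ctl_runs = [rel[sid] for sid in sorted(control_ids)]
    denom = {
        p.probe_id: sum(c[p.probe_id] for c in ctl_runs) / len(ctl_runs)
        for p in panel.probes
    }
    out = []
    for run in runs:
        ratios, states, counts = {}, {}, {}
        for probe in panel.probes:
            r = rel[run.sample_id][probe.probe_id] / denom[probe.probe_id]
            ratios[probe.probe_id] = r
            states[probe.probe_id] = call_copy_state(
                r,
                deletion_threshold=deletion_threshold,
                duplication_threshold=duplication_threshold,
            )
            counts[probe.probe_id] = int(round(r * probe.diploid_copies))
        out.append(replace(run, ratios=ratios, copy_states=states, copy_counts=counts))
    return out


@dataclass(frozen=True)
class IntegrationReport:
    sample_id: str
    consistent: bool
    issues: tuple[str, ...]


def _p1_probe(panel: ProbePanel, exon: int) -> Optional[Probe]:
    for p in panel.by_role(ROLE_P1_SPECIFIC):
        if p.exon == exon:
            return p
    return None


def integrate(genotype_call, run: MlpaRun, panel: ProbePanel) -> IntegrationReport:
    """Cross-check a PSV genotype call against normalized MLPA states.

    Consistency requires: the pseudogene-specific exon-7 probe state matches
    the converted-allele count (0 -> normal, 1 -> duplicated, 2 -> duplicated
    with four copies), the exon-5 pseudogene probe matches the exon-5 tract
    when per-exon copy counts are available, and shared probes are normal.
    ``genotype_call`` needs ``exon7_class`` and ``gene_copies`` attributes.
    """
    if run.copy_states is None or run.copy_counts is None:
        raise ValueError("run must be normalized before integration")
    issues: list[str] = []
    cls = genotype_call.exon7_class
    p1e7 = _p1_probe(panel, 7)
    if p1e7 is None:
        raise ValueError("panel lacks a pseudogene-specific exon-7 probe")
    state = run.copy_states[p1e7.probe_id]
    count = run.copy_counts[p1e7.probe_id]
    expected_counts = {"ref_hom": 2, "ectopic_het": 3, "null": 4}
    if cls in expected_counts:
        expected_state = "normal" if cls == "ref_hom" else "duplicated"
        if state != expected_state:
            issues.append(
                f"{p1e7.probe_id}: state {state}, expected {expected_state} for {cls}"
            )
        if count != expected_counts[cls]:
            issues.append(
                f"{p1e7.probe_id}: {count} copies, expected {expected_counts[cls]} for {cls}"
            )
    else:
        issues.append(f"genotype class {cls!r} cannot be cross-checked")
    p1e5 = _p1_probe(panel, 5)
    gene_copies_e5 = (genotype_call.gene_copies or {}).get(5)
    if p1e5 is not None and gene_copies_e5 is not None:
        expected_e5 = 2 + (2 - gene_copies_e5)
        if run.copy_counts[p1e5.probe_id] != expected_e5:
            issues.append(
                f"{p1e5.probe_id}: {run.copy_counts[p1e5.probe_id]} copies, "
                f"expected {expected_e5} from exon-5 gene dosage"
            )
    for probe in panel.by_role(ROLE_SHARED):
        if run.copy_states[probe.probe_id] != "normal":
            issues.append(
                f"{probe.probe_id}: shared probe {run.copy_states[probe.probe_id]}, "
                "expected normal (conversion is copy-neutral)"
            )
    return IntegrationReport(
        sample_id=run.sample_id, consistent=not issues, issues=tuple(issues)
    )
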