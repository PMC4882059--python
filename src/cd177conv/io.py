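"""Versioned TSV schemas and VCF export.

Every table written by the pipeline starts with a schema comment line
(``# schema: cd177conv/<name>/<version>``); readers refuse files whose schema
tag or column set does not match — a mismatch is an error, never a silent
coercion.  Allele-count tables are the pipeline's entry point (read alignment
is upstream and out of scope).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .locus import LocusModel
from .mlpa import MlpaRun
from .simulate import Pedigree, SampleReadProfile

SCHEMAS = {
    "counts": ("cd177conv/counts/1",
               ["sample_id", "tissue", "site_id", "ref_count", "var_count"]),
    "truth": ("cd177conv/truth/1",
              ["sample_id", "allele1_tract", "allele2_tract", "exon7_class"]),
    "mlpa": ("cd177conv/mlpa/1", ["sample_id", "probe_id", "peak_height"]),
    "phenotype": ("cd177conv/phenotype/1",
                  ["sample_id", "pct_neg", "pct_int", "pct_hi", "mfi", "label"]),
    "pedigree": ("cd177conv/pedigree/1",
                 ["family_id", "member_id", "father_id", "mother_id", "sex",
                  "exon7_class"]),
    "calls": ("cd177conv/calls/1",
              ["sample_id", "exon7_class", "gene_copies_exon4",
               "gene_copies_exon5", "gene_copies_exon7", "flags"]),
}


class SchemaError(ValueError):
    """File does not conform to its declared (or expected) schema."""


def write_table(df: pd.DataFrame, path: Path, schema: str) -> None:
    tag, columns = SCHEMAS[schema]
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{schema}: missing columns {missing}")
    with open(path, "w") as fh:
        fh.write(f"# schema: {tag}\n")
        df[columns].to_csv(fh, sep="\t", index=False)


def read_table(path: Path, schema: str) -> pd.DataFrame:
    tag, columns = SCHEMAS[schema]
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    if first != f"# schema: {tag}":
        raise SchemaError(
            f"{path}: expected schema line '# schema: {tag}', got {first!r}"
        )
    df = pd.read_csv(path, sep="\t", skiprows=1, dtype=str, keep_default_na=False)
    if list(df.columns) != columns:
        raise SchemaError(f"{path}: columns {list(df.columns)} != {columns}")
    return _coerce(df, schema, path)


_INT_COLUMNS = {"counts": ["ref_count", "var_count"]}
_FLOAT_COLUMNS = {
    "mlpa": ["peak_height"],
    "phenotype": ["pct_neg", "pct_int", "pct_hi", "mfi"],
}


def _coerce(df: pd.DataFrame, schema: str, path: Path) -> pd.DataFrame:
    bad_lines: list[int] = []
    for col in _INT_COLUMNS.get(schema, []):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() | (converted < 0) | (converted % 1 != 0)
        bad_lines.extend(df.index[bad] + 3)  # +schema line +header +1-based
        df[col] = converted.fillna(-1).astype(int)
    for col in _FLOAT_COLUMNS.get(schema, []):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad_lines.extend(df.index[converted.isna()] + 3)
        df[col] = converted
    if bad_lines:
        raise SchemaError(
            f"{path}: malformed values on line(s) {sorted(set(bad_lines))[:20]}"
        )
    return df


def profiles_to_frame(profiles: Iterable[SampleReadProfile]) -> pd.DataFrame:
    return pd.concat([p.to_frame() for p in profiles], ignore_index=True)


def frame_to_profiles(df: pd.DataFrame) -> list[SampleReadProfile]:
    profiles = []
    for (sid, tissue), grp in df.groupby(["sample_id", "tissue"], sort=True):
        counts = {
            row.site_id: (int(row.ref_count), int(row.var_count))
            for row in grp.itertuples()
        }
        profiles.append(SampleReadProfile(sample_id=sid, tissue=tissue, counts=counts))
    return profiles


def mlpa_runs_to_frame(runs: Iterable[MlpaRun]) -> pd.DataFrame:
    rows = [
        {"sample_id": r.sample_id, "probe_id": pid, "peak_height": h}
        for r in runs
        for pid, h in r.heights.items()
    ]
    return pd.DataFrame(rows)


def frame_to_mlpa_runs(df: pd.DataFrame) -> list[MlpaRun]:
    return [
        MlpaRun(sample_id=sid,
                heights={r.probe_id: float(r.peak_height) for r in grp.itertuples()})
        for sid, grp in df.groupby("sample_id", sort=True)
    ]


def pedigrees_to_frame(pedigrees: Iterable[Pedigree]) -> pd.DataFrame:
    rows = []
    for ped in pedigrees:
        for m in ped.members:
            rows.append(
                {
                    "family_id": m.family_id,
                    "member_id": m.member_id,
                    "father_id": m.father_id or ".",
                    "mother_id": m.mother_id or ".",
                    "sex": m.sex,
                    "exon7_class": m.genotype.exon7_class,
                }
            )
    return pd.DataFrame(rows)


def file_sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_metadata(path: Path, *, seed: int, config_json: str,
                   outputs: Sequence[str]) -> None:
    meta = {
        "seed": seed,
        "config": json.loads(config_json),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "outputs": list(outputs),
        "schemas": {k: v[0] for k, v in SCHEMAS.items()},
    }
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def write_vcf(
    path: Path,
    profiles: Sequence[SampleReadProfile],
    model: LocusModel,
    *,
    tissue: str = "neutrophil",
) -> None:
    """Export catalogued sites as a cohort VCF with per-sample depth and
    variant-allele-fraction FORMAT fields.

    CHROM is the packaged gene contig; POS are gene-relative g. coordinates.
    """
    samples = sorted({p.sample_id for p in profiles if p.tissue == tissue})
    by_sample = {
        p.sample_id: p for p in profiles if p.tissue == tissue
    }
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={model.gene_name},length={len(model.gene_seq)}>",
        '##INFO=<ID=EXON,Number=1,Type=Integer,Description="Exon index">',
        '##INFO=<ID=SCLASS,Number=1,Type=String,Description="Site class (SNP/PSV)">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=VF,Number=1,Type=Float,Description="Variant allele fraction">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for site in sorted(model.sites, key=lambda s: s.g_pos):
        cells = []
        for sid in samples:
            counts = by_sample[sid].counts.get(site.site_id)
            if counts is None:
                cells.append(".:.")
                continue
            ref, var = counts
            depth = ref + var
            vf = var / depth if depth else 0.0
            cells.append(f"{depth}:{vf:.4f}")
        ident = site.rsid if site.rsid.startswith("rs") else site.site_id
        lines.append(
            f"{model.gene_name}\t{site.g_pos}\t{ident}\t{site.ref_base}\t"
            f"{site.var_base}\t.\tPASS\tEXON={site.exon_index};"
            f"SCLASS={site.site_class}\tDP:VF\t" + "\t".join(cells)
        )
    Path(path).write_text("\n".join(lines) + "\n")
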