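"""Regenerate the packaged locus data files (FASTA + site-catalog TSV).

The sequences are deterministic (fixed filler seed with pinned codon
contexts); this script exists so the shipped files can be rebuilt and
verified.  Run from the repository root:

    python scripts/build_locus_data.py
"""

from pathlib import Path

from cd177conv.locus import (
    GENE_NAME,
    PSEUDOGENE_NAME,
    _SITE_TABLE,
    build_gene_sequence,
    build_pseudogene_sequence,
)

DATA_DIR = Path(__file__).resolve().parents[1] / "src" / "cd177conv" / "data"


def wrap(seq: str, width: int = 70) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def main() -> None:
    DATA_DIR.mkdir(parents=True, exist_ok=True)
    gene = build_gene_sequence()
    pseudo = build_pseudogene_sequence(gene)
    fasta = (
        f">{GENE_NAME} synthetic reference, gene-relative g. coordinates\n"
        f"{wrap(gene)}\n"
        f">{PSEUDOGENE_NAME} synthetic homology block (gene exons 4-9, PSV bases)\n"
        f"{wrap(pseudo)}\n"
    )
    (DATA_DIR / "cd177_locus.fasta").write_text(fasta)

    header = (
        "site_id\tg_pos\tc_pos\texon\tref_base\tvar_base\tsite_class\t"
        "aa_change\trsid\tcarrier_prevalence\thg38_pos\tdb_note"
    )
    lines = ["# schema: cd177conv/sites/1", header]
    for row in _SITE_TABLE:
        lines.append("\t".join(str(x) for x in row))
    (DATA_DIR / "cd177_sites.tsv").write_text("\n".join(lines) + "\n")
    print(f"wrote {DATA_DIR / 'cd177_locus.fasta'} ({len(gene)} + {len(pseudo)} nt)")
    print(f"wrote {DATA_DIR / 'cd177_sites.tsv'} ({len(_SITE_TABLE)} sites)")


if __name__ == "__main__":
    main()
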