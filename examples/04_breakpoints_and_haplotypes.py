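"""Breakpoint localization and two-locus haplotype enumeration.

Per-exon gene copy counts (read off the PSV levels at exons 4, 5 and 7)
localize where a conversion tract begins; the two observed double-conversion
patterns place the crossover between exons 4-5 or 5-7.  Separately, all
four-copy base assignments consistent with a pair of quantized levels at an
exon-4 and an exon-7 PSV are enumerated.
"""

from cd177conv import enumerate_haplotypes, infer_breakpoint

for counts in ({4: 2, 5: 0, 7: 0}, {4: 2, 5: 2, 7: 0}, {4: 2, 5: 2, 7: 2}):
    res = infer_breakpoint(counts)
    where = [(i.left_exon, i.right_exon) for i in res.intervals] or "none"
    print(f"gene copies {counts} -> breakpoint interval(s): {where}")

print()
for ref4, ref7 in ((50, 50), (75, 50), (100, 0)):
    configs = enumerate_haplotypes(ref4, ref7)
    print(f"exon4 ref {ref4}%, exon7 ref {ref7}%: {len(configs)} configuration(s)")
    for c in configs:
        print(f"  gene slots {c.gene}  pseudogene slots {c.pseudogene}")
print("\n(C/A are the gene bases at the exon-4/exon-7 loci; G/T the "
      "pseudogene-derived bases.)")
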