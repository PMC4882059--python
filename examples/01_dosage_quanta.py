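"""Quantized read dosage at exon-7 PSVs.

Builds the three conversion genotypes and prints the expected variant-read
fraction at each exon-7 paralogous sequence variant.  Because every exon-7
segment exists in four homologous copies (two gene + two pseudogene), the
fraction is quantized at quarters: 50% with both gene alleles intact, 75%
with one converted allele, 100% with both converted (the null genotype).
"""

from cd177conv import ConversionGenotype, expected_variant_fraction, load_builtin_cd177_model
from cd177conv.locus import EXON7_PSV_IDS
from cd177conv.simulate import ECTOPIC_EXON7, INTACT

model = load_builtin_cd177_model()
genotypes = {
    "intact/intact (ref_hom)": ConversionGenotype(INTACT, INTACT),
    "intact/converted (ectopic_het)": ConversionGenotype(INTACT, ECTOPIC_EXON7),
    "converted/converted (null)": ConversionGenotype(ECTOPIC_EXON7, ECTOPIC_EXON7),
}
print(f"exon-7 PSVs: {', '.join(EXON7_PSV_IDS)}")
for name, gt in genotypes.items():
    fracs = {
        100 * expected_variant_fraction(gt, model.site(sid)) for sid in EXON7_PSV_IDS
    }
    print(f"{name:32s} expected variant reads: {fracs.pop():.0f}%")
print("\nThe three quanta are what the genotyper reads back off deep sequencing.")
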