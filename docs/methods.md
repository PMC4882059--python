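# Methods

## The locus model

The packaged model represents *CD177* as nine exons in gene-relative, 1-based
`g.` coordinates (half-open intervals), with a piecewise-constant offset map
to CDS (`c.`) coordinates and a 17-site catalog of coding variants. The
pseudogene *CD177P1* is represented as a homology block covering exons 4–9;
at the nine catalogued PSV positions (g.1991 in exon 4; g.2368, g.2427,
g.2431 in exon 5; g.7492, g.7496, g.7497, g.7500, g.7509 in exon 7) it
carries the divergent base, and the reference base elsewhere.

Exon boundaries are the smallest layout consistent with every catalogued
(g., c.) pair; the CDS totals 1311 nt (437 codons). Bases not pinned by the
catalog are synthetic filler drawn once from a fixed seed and shipped as a
packaged FASTA, with in-frame stops scrubbed outside pinned codons so codon
arithmetic is well defined; the codon context at c.787 is pinned to AAA so
the exon-7 A>T substitution yields the K263X stop. The packaged FASTA is
byte-reproducible from `cd177conv.locus.build_gene_sequence()` (a test
asserts this).

Catalog orientation follows the corrected reading of the locus: the "ref"
base at each PSV is the base observed in reference-allele transcripts, with
the historical database orientation retained in a `db_note` field. Two
catalog caveats, both recorded per-site: (i) the g.7509 cDNA coordinate is
stored as 799 — the printed 798 is inconsistent with the g−c offset shared by
the five other exon-7 sites, with the genomic spacing, and with the site's
own T267A consequence, all of which give 799; (ii) several printed
amino-acid labels (A3P, P128A, A348T, G431R) cannot be produced by a
substitution at their printed cDNA positions (third codon positions), so the
catalog's `aa_change` is computed from the packaged sequence and the printed
label is kept as an annotation.

## The dosage model

A diploid genome carries two gene alleles — each intact or bearing one
contiguous conversion tract within exons 4–9 — and two intact pseudogene
copies, so each exon 4–9 segment is present in exactly four homologous
copies (conversion is copy-neutral). Reads pool across the copies:

* **PSV sites** (exons 4–9): expected VAF = (2 + converted gene alleles)/4,
  hence the 50/75/100% quanta at exon 7.
* **SNP sites in exons 1–3**: dosage over the two gene copies (0/50/100%).
* **SNP sites in exons 4–9**: dosage over four copies; pseudogene copies are
  modelled as carrying the reference base, so a heterozygous SNP reads at
  25%, and a converted allele reverts to the reference base inside its tract.

Sequencing error is a symmetric base flip at rate *e* (default 0.005),
shifting a true fraction *f* to *f*(1−*e*) + (1−*f*)*e*. The study gives the
depth (>9,000×) but no error model; a symmetric flip is the simplest model
that perturbs both tails, and 0.5% is typical of amplicon short-read data.
Read counts are Binomial(depth, adjusted *f*) per site.

## Quantized genotype calling

Per site, an exact Clopper–Pearson interval (default confidence 0.99) is
computed for the variant count; the site's level is the unique member of
{0, 25, 50, 75, 100}% whose error-adjusted expected fraction lies inside the
interval, else the site is ambiguous. An explicit interval rule makes the
visual "quantized read fraction" argument testable, and is monotone in the
variant count. At depth 9,000 the interval half-width is ≈1.2 percentage
points, ~10× smaller than the 25-point level spacing, so miscalls are
vanishingly rare; the acceptance suite verifies ≥99.9% class recovery with
zero wrong confident calls on 10⁴ simulated samples.

A genotype call aggregates the five exon-7 PSVs with a supermajority rule
(≥4 agreeing confident levels, and no confident dissenter): concordant
levels map 50→ref_hom, 75→ectopic_het, 100→null; anything else is
`unresolved` with flags. The rule tolerates one dropout while keeping errors
one-sided (unresolved, never wrong). Per-exon gene dosage is derived
analogously at exons 4, 5 and 7 as 4 × (1 − VAF) and feeds breakpoint
inference: the breakpoint interval lies between the last exon retaining the
expected gene dosage and the first exon with a deficit; non-monotone
patterns (deficit then restoration) are returned flagged as complex rather
than silently interpreted.

The 75% level is attributed to one converted gene allele rather than a
pseudogene duplication; MLPA integration is the structural tiebreaker when
available.

## Site classification and haplotype enumeration

A catalogued site is classified SNP if it lies in exons 1–3 (no pseudogene
counterpart) or its variant base appears in intact-allele cDNA; PSV if
cohort gDNA levels include quarter-dosage values (25/75%) while the variant
is absent from intact-allele transcripts; otherwise unknown. This mirrors
the gDNA-vs-cDNA argument for distinguishing paralog divergence from true
polymorphism, and inherits its limits — a rare SNP in the homology block
with no sequenced carrier cDNA can masquerade as a PSV.

Two-locus haplotype enumeration assigns bases to the four chromosomal slots
(two gene, two pseudogene) at one exon-4 and one exon-7 PSV, subject to two
model constraints: the pseudogene is homozygous for its divergent exon-7
base (the population-level observation that reference reads never exceed
50% at exon 7), and a pseudogene-derived base at exon 4 of a *gene* slot
implies the pseudogene base at exon 7 on the same slot, because conversion
tracts are contiguous and the observed tracts all terminate at or beyond
exon 7. Under these constraints the ubiquitous 50%/50% pattern has the
unique solution gene C/C + A/A, pseudogene G/G + T/T, and 75%/50% requires
exon-4 heterozygosity of the pseudogene itself. The enumeration is verified
against an unpruned brute force over all 2⁸ assignments.

## MLPA

Peak height is modelled as (probe efficiency) × (target copies) ×
log-normal noise with σ equal to the configured CV (default 0.04). The
two-step normalization — within-sample division by the mean control-probe
height, then per-probe division by the mean across declared control
samples — cancels probe efficiencies exactly, so the noiseless pipeline is
an integer-ratio oracle: normalized ratio = target copies / unrearranged
copies. Copy states use the published 0.75/1.25 thresholds (configurable);
integer copy counts are the rounded product of ratio and unrearranged copy
number. Controls are samples whose PSV genotype is ref_hom; at least three
are required (configurable). Integration with a genotype call checks the
pseudogene-specific exon-7 probe (2/3/4 copies for ref_hom/het/null), the
exon-5 pseudogene probe against the exon-5 gene dosage when available, and
that shared probes are normal.

## Cohort statistics

Hardy-Weinberg: allele frequency by counting, q̂ = (het + 2·null)/2n;
chi-square goodness of fit with 1 df; and the observed/expected
heterozygosity ratio het/n ÷ 2q̂(1−q̂). The figure-level "Hardy-Weinberg
ratio (0.9998)" quoted for the original cohort has no printed definition, so
the module reports both standard statistics instead of guessing a formula;
no test asserts that number. Phenotype classification uses the published
>20% intermediate rule for the atypical class; the null boundary
(hi+int < 1%) and the hi/hi-neg split (pct_hi ≥ 65%) approximate visual
cluster boundaries and are configurable. Association uses rank statistics
(Spearman of intact-allele dosage 2/1/0 against pct_hi, pct_neg and MFI;
Kruskal–Wallis across classes) because the published plots show
untransformed percentages with no stated model. Mendelian checking flags an
offspring whose allele pair cannot be assembled from one allele of each
parent, at either full-tract resolution (simulation truth) or exon-7
resolution (what a sequencing call observes); offspring with missing
parental genotypes are skipped with a warning.

## The generator's defaults, and what they do not capture

Defaults: n = 500 samples, conversion-allele frequency q = 0.16 (implied by
the 2.6% null prevalence in the 535-donor cohort under random mating), depth
9,000×, error 0.005, MLPA CV 4%, phenotype means pct_hi 85% (ref_hom) vs 45%
(ectopic het) with SD 10, intermediate subset mean 3% and a 7% atypical rate
producing >20% intermediate cells independent of genotype, MFI means
5000/2500/30. Ectopic tracts default to exon 7 only; double-conversion
genomes draw each allele's tract from {exon 7, exons 5–7}, the two observed
breakpoint classes. Saliva profiles reuse the neutrophil genotype exactly
(pure germline model — the study found perfect tissue concordance), so
passing germline-concordance tests demonstrates the comparison logic, not
robustness to real somatic mosaicism. Other simplifications: no
amplicon-specific coverage variation or strand bias (a single depth for all
sites), no linkage between SNPs (drawn independently at frequencies derived
from the printed carrier prevalences), conversion tracts aligned to exon
boundaries, and no *de novo* conversion events in pedigrees. Tests passing
on these data show the inference is correct under the stated model, not that
the model exhausts real amplicon data.

## Numerical and design choices

* Clopper–Pearson bounds via the regularized incomplete-beta inverse; the
  test suite checks them against binomial-cdf bisection.
* Determinism: every stochastic entry point takes a seed or an explicit
  numpy Generator; fixed seed ⇒ byte-identical outputs (tested at file
  level through the CLI).
* Degenerate inputs are errors, not coercions: zero depth, equal tissue
  labels, monomorphic association tables, non-contiguous tracts, empty or
  mis-versioned TSVs, non-positive MLPA ratios.
* Problem sizes in the test suite (10⁴ samples for recovery, 10⁴ MLPA
  replicates, 10³ HWE cohorts) match the targets the checks are stated for
  while keeping the default run fast.
* The CLI is a thin veneer: `simulate` writes the five tables plus a JSON
  metadata sidecar (seed, config hash); `genotype` consumes the counts
  table (read alignment is out of scope) and optionally exports a VCF on
  the packaged contig; `report` aggregates prevalence, HWE, association,
  MLPA consistency and Mendelian checks, marking absent inputs explicitly.

## Known limitations

* Breakpoints are resolvable only between exons bearing catalogued PSVs
  (4, 5, 7); tracts beginning inside introns or beyond exon 7 are not
  distinguishable.
* The PSV/SNP classifier needs cDNA from at least one variant carrier to
  rescue homology-block SNPs from misclassification as PSVs.
* MLPA integration assumes the default panel's probe roles; custom panels
  must declare a pseudogene-specific exon-7 probe to be checkable.
* Genotype classes treat the pseudogene as fixed; a genuine pseudogene
  deletion or duplication would violate the four-copy assumption and
  surface only as unresolved calls or MLPA inconsistencies.
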