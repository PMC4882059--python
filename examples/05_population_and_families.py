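"""Population structure and inheritance.

Simulates a 535-donor cohort, tests the genotype table for Hardy-Weinberg
equilibrium, correlates intact-allele dosage with the simulated neutrophil
phenotype, and verifies Mendelian transmission in pedigrees built from the
four published family configurations.
"""

import numpy as np
import pandas as pd

from cd177conv import (
    GenotypeCounts,
    SimulationConfig,
    associate,
    hwe_test,
    mendelian_check,
    simulate_cohort,
    simulate_pedigree,
    simulate_phenotype,
)
from cd177conv.simulate import fig5_family_configurations

cfg = SimulationConfig(n_samples=535, conversion_allele_freq=0.16, seed=11,
                       atypical_rate=0.0)
genotypes, truth = simulate_cohort(cfg)
counts = truth["exon7_class"].value_counts()
g = GenotypeCounts(int(counts.get("ref_hom", 0)),
                   int(counts.get("ectopic_het", 0)),
                   int(counts.get("null", 0)))
res = hwe_test(g)
print(f"genotype counts: {g.as_tuple()}  (n={g.total})")
print(f"conversion-allele frequency: {res.conversion_allele_freq:.3f}")
print(f"HWE chi-square={res.chi_square:.3f} p={res.p_value:.3f} "
      f"het ratio={res.het_ratio:.3f}")

rng = np.random.default_rng(12)
rows = []
for gt, sid in zip(genotypes, truth["sample_id"]):
    rec = simulate_phenotype(gt, cfg, rng=rng)
    rows.append({"sample_id": sid, "exon7_class": gt.exon7_class,
                 "pct_hi": rec.pct_hi, "pct_neg": rec.pct_neg, "mfi": rec.mfi})
assoc = associate(pd.DataFrame(rows))
for var, (rho, p) in assoc.spearman.items():
    print(f"Spearman(dosage, {var}): rho={rho:+.3f} p={p:.2e}")

ped_rng = np.random.default_rng(13)
total_violations = 0
for k, founders in enumerate(fig5_family_configurations()):
    ped = simulate_pedigree(founders, 3, cfg, rng=ped_rng, family_id=f"FAM{k+1}")
    total_violations += len(mendelian_check(ped))
print(f"\nMendelian violations across 4 families: {total_violations}")
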