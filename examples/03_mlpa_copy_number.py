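"""MLPA copy-number confirmation of conversion genotypes.

Simulates probe peak heights for three unrearranged controls plus one
single-conversion and one double-conversion genome (4% multiplicative noise),
runs the two-step normalization, and prints the pseudogene-specific exon-7
probe ratios.  A converted gene allele adds one copy of pseudogene-derived
exon-7 sequence: ratio 1.5 (3 copies) for the heterozygote, 2.0 (4 copies)
for the null — while shared probes stay at 1.0 because conversion is
copy-neutral.
"""

import numpy as np

from cd177conv import SimulationConfig, genotype_from_class, normalize, simulate_mlpa
from cd177conv.mlpa import default_probe_panel

panel = default_probe_panel()
cfg = SimulationConfig(seed=7, mlpa_cv=0.04)
rng = np.random.default_rng(7)
genotypes = {
    "ctl1": "ref_hom", "ctl2": "ref_hom", "ctl3": "ref_hom",
    "het": "ectopic_het", "null": "null",
}
runs = [
    simulate_mlpa(genotype_from_class(cls), panel, cfg, rng=rng, sample_id=sid)
    for sid, cls in genotypes.items()
]
for run in normalize(runs, panel, ["ctl1", "ctl2", "ctl3"]):
    r7 = run.ratios["EX7P1"]
    print(f"{run.sample_id:5s} EX7P1 ratio={r7:5.2f} copies={run.copy_counts['EX7P1']} "
          f"state={run.copy_states['EX7P1']:10s} "
          f"shared EX7 ratio={run.ratios['EX7']:5.2f}")
print("\nDuplicated pseudogene exon-7 signal independently confirms the "
      "sequencing-based genotype.")
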