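"""Generate a synthetic clonal phenology trial and look at its design.

The generator emulates a two-year field study: 19 founder trees crossed
into 34 full-sib families, 120 genotypes clonally replicated into 564
trees, ordinal phenology surveys every 2-5 days, and one DBH measurement.
`truth.json`-style generative parameters ride along for recovery scoring.
"""

import numpy as np

import phenoqg as pq

dataset = pq.generate_dataset(pq.GeneratorConfig())

ped = dataset.trial.pedigree
counts = dataset.trial.clone_map.ramet_counts
print(f"pedigree records : {len(ped)} ({ped.founder_count} founders)")
print(f"genotypes        : {len(counts)}")
print(f"trees (ramets)   : {counts.sum()}  (per genotype: min {counts.min()}, "
      f"median {np.median(counts.values):.0f}, max {counts.max()})")
print(f"survey rows      : {len(dataset.survey)}")

truth = dataset.trial.truth
print("\ngenerative heritabilities (latent scale):")
for trait, h2 in truth["heritability"].items():
    print(f"  {trait:>4}: {h2:.2f}")
print("\nThe ordinal surveys observe latent transition days piecewise-"
      "constantly;\nthe analysis has to recover the genetics from those "
      "coarse scores.")
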