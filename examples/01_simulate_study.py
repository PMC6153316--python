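"""Generate a synthetic hepatocyte compound screen with known ground truth.

The generator emulates a dose x time toxicogenomics design: each compound is
profiled at control/low/middle/high doses and 2, 8, 24 h with duplicate
arrays, matched vehicle controls, array-level batch shifts and Gaussian
noise.  Planted response genes, confounder genes (hit by negative-control
compounds too) and enriched gene sets give every downstream stage a truth to
recover.
"""

import toxtempo as tt

cfg = tt.SimConfig(n_genes=1000, n_steatotic_compounds=6, n_negative_controls=2,
                   n_response_genes=100, n_confounder_genes=30, seed=1)
study, truth, collection = tt.generate_study(cfg)

print(f"study: {len(study.gene_ids)} genes x {len(study.samples)} samples")
print(f"compounds: {study.steatotic_compounds} + negatives {study.negative_control_compounds}")
print(f"planted: {len(truth.response_genes)} response genes, "
      f"{len(truth.confounder_genes)} confounder genes, "
      f"{len(truth.enriched_sets)} enriched sets {truth.enriched_sets}")
print(f"compound classes: {truth.compound_clusters}")

tt.write_simulation(study, truth, collection, "scratch/example_study")
print("written to scratch/example_study (matrix.tsv, samples.tsv, truth.json, sets.gmt)")

# The sample table is the design: every treated cell has a matched control
# sharing compound, time and batch, which is what makes fold changes and
# batch-free contrasts possible.
print(study.samples.head(8).to_string(index=False))
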