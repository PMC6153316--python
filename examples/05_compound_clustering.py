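"""Cluster compounds by their 24 h fold-change signatures.

Features are the log2 fold changes of the deregulated genes at 24 h across
doses; Ward.D2 agglomeration on Euclidean distances, elbow (maximum SER
curvature) choice of k.  Compounds seen at fewer than two timepoints are
excluded up front.
"""

import toxtempo as tt

study, truth, _ = tt.generate_study(tt.SimConfig(
    n_genes=600, n_steatotic_compounds=12, n_negative_controls=2,
    n_compound_clusters=3, n_response_genes=100, n_confounder_genes=20,
    seed=2))

normalized = tt.quantile_normalize(study)
fold_changes = tt.compute_fold_changes(tt.average_replicates(normalized))
deg = tt.run_deg(normalized)

features = tt.build_features(
    fold_changes[fold_changes["compound"].isin(set(study.steatotic_compounds))],
    time_filter=[24], genes=deg.final_genes, min_timepoints=2,
)
print(f"feature matrix: {features.matrix.shape[0]} compounds x "
      f"{features.matrix.shape[1]} (gene, dose, time) features")

solution = tt.cluster_compounds(features, k_range=(1, 10))
print(f"elbow-selected k = {solution.chosen_k} "
      f"(planted classes: {len(set(truth.compound_clusters.values()))})")
for k in sorted(solution.ser_by_k):
    print(f"  SER(k={k}) = {solution.ser_by_k[k]:8.1f}")

for lab in sorted(set(solution.labels.values())):
    members = sorted(c for c, l in solution.labels.items() if l == lab)
    planted = {truth.compound_clusters[c] for c in members}
    print(f"cluster {lab}: {members} (planted class(es) {planted})")

print("\ndendrogram (newick):")
print(tt.to_newick(solution.merges, solution.compounds))
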