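"""Detect 10-kb genomic miRNA clusters and 5p/3p duplex pairs."""

from sharkmir.cluster import all_duplex_pairs, clusters_table, find_clusters
from sharkmir.synthetic_fixtures import SimConfig, build_genome

sim = build_genome(SimConfig(seed=4, n_hairpins=8, n_duplex=2, n_known=0,
                             cluster_pairs=2))
clusters = find_clusters(sim.loci, window=10_000)
print(clusters_table(clusters).to_string(index=False))
pairs = all_duplex_pairs(clusters)
print(f"\n{len(clusters)} clusters (plan: {sim.expected_clusters}); "
      f"{len(pairs)} duplex pairs (plan: {sim.expected_duplex_pairs})")
# Loci within 10,000 bp on one chromosome join a cluster (single linkage);
# two mature miRNAs cleaved from one precursor form a 5p/3p duplex pair,
# and a two-member cluster that is exactly one duplex is flagged.
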