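"""Prepare a count table for compositional analysis.

Counts are prevalence-filtered (>= 2 reads in >= 5% of samples), depth
filtered (>= 2000 reads), agglomerated to genus level, and CLR-transformed
with a single pseudo-count (half the smallest nonzero relative abundance)
replacing zeros.  Aitchison distance is the Euclidean distance between
CLR rows.
"""

import compng as c

counts, taxonomy, metadata, labels = c.generate_dataset(c.SimConfig(seed=1))

kept = c.filter_samples(c.filter_taxa(counts), min_depth=2000)
print(f"after filtering: {kept.n_samples} samples x {kept.n_features} ASVs")

genus = c.agglomerate(kept, taxonomy, "genus")
print(f"genus table:     {genus.n_features} genera "
      f"(per-sample totals conserved: "
      f"{(genus.depths() == kept.depths()).all()})")

clr = c.clr_transform(genus)
print(f"pseudo-count delta = {clr.pseudocount:.3g} "
      f"(half the minimum nonzero relative abundance)")
print(f"max |row sum| of CLR matrix = "
      f"{abs(clr.data.sum(axis=1)).max():.2e}  (CLR rows are centered)")

dist = c.aitchison_distance(clr)
ids = clr.sample_ids
print(f"Aitchison distance {ids[0]} vs {ids[1]}: "
      f"{dist[ids[0], ids[1]]:.3f} CLR units")
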