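"""Seasonality tests on Aitchison distances.

One-way PERMANOVA tests whether community centroids differ among
seasons; PERMDISP tests whether seasons differ merely in dispersion
(deviation from group centroid).  p-values come from 9999 seeded label
permutations, p = (b+1)/(m+1).
"""

import compng as c

counts, taxonomy, metadata, _ = c.generate_dataset(c.SimConfig(seed=1))
kept = c.filter_samples(c.filter_taxa(counts))
clr = c.clr_transform(c.agglomerate(kept, taxonomy, "genus"))
dist = c.aitchison_distance(clr)
season = metadata.data["season"].loc[clr.sample_ids]

pmv = c.permanova_oneway(dist, season, n_perm=9999, seed=1)
pdp = c.permdisp(dist, season, n_perm=9999, seed=1)
print(f"PERMANOVA pseudo-F = {pmv.statistic:.2f}, p = {pmv.p:.4f} "
      f"({pmv.method}, {pmv.n_perm} permutations)")
print(f"PERMDISP  F        = {pdp.statistic:.2f}, p = {pdp.p:.4f}")
print(f"group sizes: {pmv.group_sizes}")
# A significant PERMANOVA with a significant PERMDISP means seasonal
# differences may partly reflect unequal within-season spread, not only
# different community centroids.
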