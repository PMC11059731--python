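"""Microscopy vs metabarcoding concordance.

FISH-IR probe counts (probe % of AAP cells x total AAP abundance / 100)
are compared by Spearman rank correlation with metabarcoding
pseudoabundances (taxon relative abundance % x total AAP abundance /
100).  High rho means the two independent methods agree on relative
abundance patterns of the probed groups.
"""

import compng as c

counts, taxonomy, metadata, _ = c.generate_dataset(
    c.SimConfig(seed=1, fish_noise_sd=2.0))

for probe, (rank, taxon) in c.FISH_PROBE_TAXA.items():
    glommed = c.agglomerate(counts, taxonomy, rank)
    match = [f for f in glommed.feature_ids if f.split(";")[-1] == taxon]
    rel_pct = glommed.data[match].sum(axis=1) / glommed.depths() * 100
    res = c.concordance(metadata.data[probe], rel_pct,
                        metadata.data["AAP_abs"], group=probe)
    print(f"{probe:7s} ({rank} {taxon}): rho = {res.rho:.3f}, "
          f"p = {res.p:.2e}, n = {res.n}")
# At 2 percentage points of microscopy noise the synthetic survey sits in
# the strong-positive regime (rho well above 0.7) reported for field
# comparisons of these two quantification approaches.
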