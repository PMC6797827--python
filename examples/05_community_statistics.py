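"""Community statistics on a synthetic high-CO2 / low-CO2 OTU table.

Generates a Dirichlet-multinomial table in which the high-CO2 (HC) group
has lower richness and a shifted composition, then runs the full chain:
rarefaction, Bray-Curtis distances, PERMANOVA and SIMPER.
"""

import mofette as m

table, truth = m.gen_otu_tables(
    n_hc=6, n_lc=7, richness_hc=400, richness_lc=800, pool_size=900,
    effect_size=4.0, n_effect_otus=10, depth=5000, seed=7,
)

depth = int(table.sample_totals().min())
rare = m.rarefy(table, depth, seed=7)
rich = m.observed_richness(rare).groupby(rare.groups).mean()
dist = m.bray_curtis(rare)
res = m.permanova(dist, rare.groups, n_permutations=999, seed=7)
sim = m.simper(rare)

print(f"rarefied to {depth} reads/sample")
print(f"mean observed richness: HC {rich['HC']:.0f}, LC {rich['LC']:.0f}")
print(f"PERMANOVA: pseudo-F {res.pseudo_F:.2f}, R2 {res.R2:.2f}, p {res.p_value:.3g}")
print(f"mean between-group dissimilarity: {sim.overall_mean_dissimilarity_pct:.0f}%")
print("top SIMPER OTUs (%Con, %Cum):")
print(sim.table.head(5)[["pct_con", "pct_cum"]].round(2))
print("truth-shifted OTUs in top 10:",
      len(set(sim.table.index[:10]) & set(truth.group_effects)))

# A significant PERMANOVA p with moderate R2 plus a SIMPER ranking that
# recovers the truly shifted OTUs mirrors how group differences between
# CO2-exposure classes are established from 16S OTU tables.
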