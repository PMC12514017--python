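"""Link an interaction map to regional gene expression: PLS with spin-test
significance and bootstrap gene ratios.

The expression matrix carries a planted 20-gene set whose regional maps
correlate (r = 0.8) with the interaction map; everything else is spatially
smooth noise. The spin test rotates region centroids on the registration
sphere, so significance is judged against maps with the same spatial
autocorrelation.
"""

import numpy as np

import protectomap as pm

geom = pm.generate_geometry(200, seed=3)
ccfg = pm.CohortConfig(n_regions=200, atrophy_regions=frozenset(range(1, 51)),
                       seed=3)
y = pm.true_interaction_map(ccfg, geom)
ecfg = pm.ExpressionConfig(n_genes=500, planted_coupling=0.8, seed=3)
expr, planted = pm.generate_expression(ecfg, geom, y)

model = pm.pls_fit(expr, y.to_numpy(), n_components=3)
nulls = pm.spin_permutations(geom, n_perm=1000, seed=4)
p_spin = pm.lv_significance(model, expr, y.to_numpy(), nulls)

for k in range(3):
    r, _ = pm.region_score_correlation(model, y.to_numpy(), k + 1)
    print(f"LV{k + 1}: {100 * model.var_explained[k]:5.1f}% of interaction "
          f"variance, spin p = {p_spin[k]:.4f}, score-map r = {r:.2f}")

boot = pm.bootstrap_gene_weights(expr, y.to_numpy(), (1,), n_boot=1000, seed=5)
ranked = boot.ranked_scores(1)
top10 = ranked.head(10)
hits = sum(g in planted for g in top10.index)
print(f"top-10 bootstrap ratios: {hits}/10 are planted genes")
print(top10.round(2).to_string())

# Reading: LV1 is significant against spatial nulls and its top
# bootstrap-ratio genes recover the planted coupled set; later components
# are not distinguishable from spatially autocorrelated noise.
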