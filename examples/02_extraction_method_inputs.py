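"""Tailor thresholded expression into six model-extraction-method inputs.

From one cluster-specific thresholding run, builds the evidence
structures that fastCORE, iMAT, MBA, mCADRE, INIT and GIMME consume:
core lists, core/non-core partitions, high/medium sets, ubiquity
scores and reaction weight vectors.
"""

import clustercore as cc

fixture = cc.generate_fixture(cc.FixtureSpec(seed=0))
enz, _ = cc.compute_enzyme_expression(fixture.expression, fixture.catalog)
profiles = cc.bin_profiles(enz)
clustering = cc.cluster_profiles(profiles, enz, 4)
thresholds = cc.standep_thresholds(enz, clustering)
core = cc.standep_core(enz, clustering, thresholds, fixture.catalog,
                       protect=["R0000"])  # treat R0000 like a biomass reaction

bundle = cc.build_mem_bundle(enz, clustering, thresholds, fixture.catalog,
                             core, protect=["R0000"])

ctx = enz.data.columns[0]
print(f"context {ctx}:")
print(f"  fastCORE core list: {len(bundle.fastcore_core[ctx])} reactions")
imat_core, imat_noncore = bundle.imat[ctx]
print(f"  iMAT: {len(imat_core)} core / {len(imat_noncore)} non-core "
      f"({len(fixture.catalog.gene_free_reactions)} gene-free reactions in neither)")
high, medium = bundle.mba[ctx]
print(f"  MBA: {len(high)} high / {len(medium)} medium expression reactions")

U = bundle.ubiquity
gene_free = sorted(fixture.catalog.gene_free_reactions)
print(f"\nubiquity scores (mCADRE): matrix {U.shape[0]} reactions x {U.shape[1]} contexts")
print(f"  gene-associated range: [{U.drop(index=gene_free).min().min():.3f}, "
      f"{U.drop(index=gene_free).max().max():.3f}]  (gene-free sentinel: "
      f"{U.loc[gene_free[0], ctx]:.0f})")
print(f"  protected reaction R0000 score: {U.loc['R0000', ctx]:.0f}")

W = bundle.init_weights
print(f"\nINIT weights: range [{W.min().min():.3f}, {W.max().max():.3f}] "
      f"(isoenzyme sums may exceed 1; gene-free reactions weigh 0)")
print(f"GIMME uses the identical vector with activity threshold "
      f"{bundle.gimme.threshold:.0f}")
print(
    "\nA ubiquity score of 1 marks an enzyme at or above its cluster threshold;\n"
    "scores decay linearly toward 0 at the most below-threshold enzyme in the\n"
    "dataset. Weights are threshold distances scaled into [-1, 1]."
)
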