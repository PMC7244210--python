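"""Identify per-context core reactions under four thresholding schemes.

Builds a synthetic 40-context expression matrix with a planted
low-but-tightly-expressed housekeeping cluster, converts it to enzyme
expression, clusters the enzyme profiles, and compares how much of the
housekeeping reference each scheme's core reaction lists retain.
"""

import clustercore as cc

fixture = cc.generate_fixture(cc.FixtureSpec(seed=0))
print(
    f"fixture: {fixture.expression.data.shape[0]} genes x "
    f"{fixture.expression.data.shape[1]} contexts, "
    f"{len(fixture.catalog)} reactions, "
    f"{len(fixture.hk_reactions)} housekeeping reactions"
)

enz, report = cc.compute_enzyme_expression(fixture.expression, fixture.catalog)
print(f"enzyme expression: {enz.data.shape[0]} enzymes "
      f"({len(report.dropped_enzymes)} dropped)")

profiles = cc.bin_profiles(enz)
clustering = cc.cluster_profiles(profiles, enz, 4)
thresholds = cc.standep_thresholds(enz, clustering)
print("\nper-cluster statistics and resolved cutoffs (log10 units):")
print(clustering.cluster_stats.join(thresholds.table).round(3).to_string())
print(f"dataset mean M = {clustering.M:.3f}, SD = {clustering.Delta:.3f}")

cores = {
    "cluster-specific": cc.standep_core(enz, clustering, thresholds, fixture.catalog),
    "global top-25%": cc.global_core(enz, fixture.catalog),
    "localT1": cc.localT1_core(enz, fixture.catalog),
    "localT2": cc.localT2_core(enz, fixture.catalog),
}
print("\nhousekeeping coverage of core reaction lists (mean over contexts):")
for name, core in cores.items():
    cov = cc.housekeeping_coverage(core, fixture.hk_reactions)
    sizes = core.sizes()
    print(f"  {name:18s} coverage={cov.mean:5.3f}  "
          f"core size {min(sizes.values())}-{max(sizes.values())}")
print(
    "\nThe housekeeping cluster sits ~1.5 decades below the dataset mean, so a\n"
    "global percentile cutoff removes it entirely; its own cluster threshold\n"
    "is permissive (high normalised value) and keeps it in nearly every context."
)
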