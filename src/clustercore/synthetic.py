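"""Synthetic multi-context expression data with planted cluster structure.

The generator emulates the situation the thresholding method was built
for: a transcriptome measured across many contexts (cell lines,
tissues) in which groups of genes share an expression *pattern*.  Each
planted cluster draws one log10 context factor per context from
Normal(mean, sd_between) and every member gene adds small independent
noise on top, so co-clustered genes co-vary across contexts — the
co-regulation that pattern-based clustering assumes — while the
marginal per-gene distribution stays Normal(mean_log10, sd_log10)
(log-normal abundances, the scale all statistics here operate on).
Dropout is drawn per *context*: in a dropped context the whole
cluster is unexpressed (zero), the way a silenced pathway behaves;
the marginal zero rate per gene equals ``dropout_rate``.  A toy reaction catalog wires the genes into
single-gene enzymes, AND-complexes (subunits drawn from one cluster,
as co-regulated complexes are), isoenzyme pairs and a few gene-free
reactions.

The default fixture plants four ecologically distinct clusters:

* ``high_variable`` — highly expressed, highly variable (context-
  specific machinery, ~600 FPKM median, 1.1 decades SD);
* ``moderate`` — moderately expressed, moderate spread;
* ``housekeeping`` — *low but tightly expressed* (~0.5 FPKM, 0.08
  decades SD, no dropout): constitutive maintenance genes that a
  global percentile cutoff misses;
* ``rare`` — very low, patchily expressed (50% of contexts silenced):
  genes active in few contexts.  Its distance below the dataset mean
  hands it the largest raw threshold, so it — not the housekeeping
  cluster — takes the Theta=100 dataset-mean special case.

Sizes (40 contexts, 4 x 50 genes, 300 reactions) keep a full pipeline
run in seconds.

:func:`selection_fixture_spec` builds a different layout meant for
exercising the cluster-count selection rule: K tight, well-separated
clusters where the mid-scale cluster carries the largest
within-cluster noise, so cutting the tree deeper than K splits *that*
cluster — whose threshold barely moves — and the core lists stay
stable above K.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import ReactionCatalog, catalog_from_rules
from .errors import InputError
from .expression import ExpressionMatrix

__all__ = [
    "ClusterSpec",
    "FixtureSpec",
    "Fixture",
    "generate_fixture",
    "selection_fixture_spec",
]


@dataclass(frozen=True)
class ClusterSpec:
    """One planted expression-pattern cluster."""

    n_genes: int
    mean_log10: float
    sd_log10: float  # marginal SD of a member gene's log10 values
    dropout_rate: float = 0.0
    gene_noise_log10: float = 0.01  # per-gene residual around the context factor
    housekeeping: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise InputError("cluster must contain at least one gene")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise InputError("dropout_rate must lie in [0, 1]")
        if self.sd_log10 < 0 or self.gene_noise_log10 < 0:
            raise InputError("sd_log10 and gene_noise_log10 must be nonnegative")

    @property
    def sd_between(self) -> float:
        """SD of the shared context factor; the marginal SD decomposes
        as sd_log10**2 = sd_between**2 + gene_noise**2 (noise is capped
        at sd_log10 for very tight clusters)."""
        noise = min(self.gene_noise_log10, self.sd_log10)
        return float(np.sqrt(self.sd_log10**2 - noise**2))


DEFAULT_CLUSTERS: tuple[ClusterSpec, ...] = (
    ClusterSpec(50, 3.8, 0.80, 0.05, name="high_variable"),
    ClusterSpec(50, 1.2, 0.35, 0.10, name="moderate"),
    ClusterSpec(50, -0.3, 0.08, 0.00, housekeeping=True, name="housekeeping"),
    ClusterSpec(50, -0.65, 0.08, 0.50, name="rare"),
)


@dataclass(frozen=True)
class FixtureSpec:
    """Full recipe for one synthetic dataset (deterministic per seed)."""

    n_contexts: int = 40
    clusters: tuple[ClusterSpec, ...] = DEFAULT_CLUSTERS
    n_reactions: int = 300
    frac_and_complexes: float = 0.20
    frac_isoenzymes: float = 0.15
    frac_gene_free: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.frac_and_complexes, self.frac_isoenzymes, self.frac_gene_free)
        if any(not 0.0 <= f <= 1.0 for f in fracs) or sum(fracs) > 1.0:
            raise InputError("catalog fractions must lie in [0,1] and sum <= 1")
        if self.n_contexts < 1 or self.n_reactions < 1:
            raise InputError("n_contexts and n_reactions must be positive")
        if not self.clusters:
            raise InputError("at least one cluster is required")


@dataclass
class Fixture:
    """Generated dataset plus the planted ground truth."""

    expression: ExpressionMatrix
    catalog: ReactionCatalog
    hk_genes: set[str]
    hk_reactions: set[str]
    gene_labels: dict[str, int]
    enzyme_labels: dict[str, int]
    spec: FixtureSpec = field(repr=False, default=None)


def selection_fixture_spec(
    n_clusters: int = 4, seed: int = 0, n_contexts: int = 40
) -> FixtureSpec:
    """Fixture layout for testing the cluster-count selection rule.

    Plants ``n_clusters`` (4 or 5) tight clusters at well-separated
    means.  The mid-scale cluster gets the largest per-gene noise so
    the agglomerative tree splits it first when cut deeper than the
    planted count; because its threshold sits mid-scale, those splits
    barely change the core lists and the Jaccard stability trace stays
    high above the planted count.
    """
    if not 2 <= n_clusters <= 5:
        raise InputError("selection fixture supports 2..5 planted clusters")
    layout = [
        # (mean, dropout, gene_noise, hk, name)
        (3.0, 0.05, 0.01, False, "high"),
        (1.2, 0.10, 0.05, False, "moderate"),
        (-0.3, 0.00, 0.01, True, "housekeeping"),
        (-1.5, 0.50, 0.005, False, "rare"),
        (2.0, 0.10, 0.01, False, "mid_high"),
    ][:n_clusters]
    clusters = tuple(
        ClusterSpec(50, mean, 0.10, dropout, noise, housekeeping=hk, name=name)
        for (mean, dropout, noise, hk, name) in layout
    )
    return FixtureSpec(n_contexts=n_contexts, clusters=clusters, seed=seed)


def generate_fixture(spec: FixtureSpec | None = None) -> Fixture:
    """Draw one synthetic expression matrix + reaction catalog.

    Values are linear-scale abundances 10**Normal(mean, sd) with
    dropout zeros at the planted rate.  The catalog is wired within
    clusters, so every enzyme has a well-defined planted label (the
    index of its cluster in ``spec.clusters``).
    """
    if spec is None:
        spec = FixtureSpec()
    rng = np.random.default_rng(spec.seed)
    contexts = [f"ctx{k:02d}" for k in range(spec.n_contexts)]

    gene_labels: dict[str, int] = {}
    blocks = []
    gene_ids: list[str] = []
    genes_by_cluster: list[list[str]] = []
    for ci, cl in enumerate(spec.clusters):
        names = [f"g{ci}_{j:03d}" for j in range(cl.n_genes)]
        genes_by_cluster.append(names)
        gene_ids.extend(names)
        for g in names:
            gene_labels[g] = ci
        factor = rng.normal(cl.mean_log10, cl.sd_between, size=spec.n_contexts)
        noise_sd = min(cl.gene_noise_log10, cl.sd_log10)
        logs = factor[None, :] + rng.normal(
            0.0, noise_sd, size=(cl.n_genes, spec.n_contexts)
        )
        vals = 10.0 ** logs
        if cl.dropout_rate > 0:
            dropped = rng.random(spec.n_contexts) < cl.dropout_rate
            vals[:, dropped] = 0.0
        blocks.append(vals)
    expr = ExpressionMatrix(
        pd.DataFrame(np.vstack(blocks), index=gene_ids, columns=contexts)
    )

    n = spec.n_reactions
    n_free = round(spec.frac_gene_free * n)
    n_and = round(spec.frac_and_complexes * n)
    n_iso = round(spec.frac_isoenzymes * n)
    n_single = n - n_free - n_and - n_iso
    kinds = ["single"] * n_single + ["and"] * n_and + ["iso"] * n_iso + ["free"] * n_free
    n_clusters = len(spec.clusters)
    triples = []
    cluster_cycle = 0
    for r, kind in enumerate(kinds):
        rid = f"R{r:04d}"
        if kind == "free":
            triples.append((rid, "exchange", ""))
            continue
        ci = cluster_cycle % n_clusters
        cluster_cycle += 1
        pool = genes_by_cluster[ci]
        subsystem = spec.clusters[ci].name or f"cluster{ci}"
        if kind == "single":
            g = pool[int(rng.integers(len(pool)))]
            rule = g
        elif kind == "and":
            k = int(rng.integers(2, 4))  # 2- or 3-subunit complex
            k = min(k, len(pool))
            idx = rng.choice(len(pool), size=k, replace=False)
            rule = " and ".join(pool[i] for i in idx)
        else:  # isoenzyme pair
            if len(pool) < 2:
                rule = pool[0]
            else:
                idx = rng.choice(len(pool), size=2, replace=False)
                rule = f"{pool[idx[0]]} or {pool[idx[1]]}"
        triples.append((rid, subsystem, rule))
    catalog = catalog_from_rules(triples)

    enzyme_labels = {
        eid: gene_labels[next(iter(genes))]
        for eid, genes in catalog.enzymes.items()
    }
    hk_idx = {ci for ci, cl in enumerate(spec.clusters) if cl.housekeeping}
    hk_genes = {g for g, ci in gene_labels.items() if ci in hk_idx}
    hk_enzymes = {e for e, ci in enzyme_labels.items() if ci in hk_idx}
    hk_reactions = {
        rxn.id
        for rxn in catalog.reactions
        if rxn.enzyme_ids and set(rxn.enzyme_ids) <= hk_enzymes
    }
    return Fixture(
        expression=expr,
        catalog=catalog,
        hk_genes=hk_genes,
        hk_reactions=hk_reactions,
        gene_labels=gene_labels,
        enzyme_labels=enzyme_labels,
        spec=spec,
    )
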