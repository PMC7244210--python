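"""Evaluation statistics: coverage, enrichment, similarity, Gini.

These are the statistics used to judge a thresholding scheme: how
much of a reference housekeeping list its core sets retain, which
clusters are enriched for housekeeping reactions (upper-tail
hypergeometric test with Benjamini-Hochberg correction), how similar
two reaction sets are (Jaccard), how self-consistent an extracted
model is with its core list, and a Gini-coefficient classifier for
housekeeping genes (low inequality of expression across contexts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Set

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .catalog import ReactionCatalog
from .clustering import ClusteringResult
from .errors import InputError
from .expression import ExpressionMatrix
from .thresholds import CoreReactionSets

__all__ = [
    "jaccard",
    "CoverageReport",
    "housekeeping_coverage",
    "cluster_enrichment",
    "self_consistency",
    "GiniResult",
    "gini_housekeeping",
]


def jaccard(a: Set[str], b: Set[str]) -> float:
    """Intersection over union; two empty sets count as identical (1)."""
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


@dataclass
class CoverageReport:
    """Per-context fraction of a reference id list that is captured."""

    fractions: pd.Series  # index: context ids
    denominator: int

    @property
    def mean(self) -> float:
        return float(self.fractions.mean())

    def to_dict(self) -> dict:
        return {
            "denominator": self.denominator,
            "mean": self.mean,
            "per_context": self.fractions.to_dict(),
        }


def housekeeping_coverage(
    sets: Mapping[str, Set[str]] | CoreReactionSets,
    reference: Set[str],
) -> CoverageReport:
    """Fraction of the reference list present in each context's set."""
    if isinstance(sets, CoreReactionSets):
        sets = sets.sets
    if not reference:
        raise InputError("reference set is empty")
    fractions = pd.Series(
        {c: len(s & reference) / len(reference) for c, s in sets.items()},
        dtype=float,
    )
    return CoverageReport(fractions=fractions, denominator=len(reference))


def cluster_enrichment(
    clustering: ClusteringResult,
    hk_reactions: Set[str],
    catalog: ReactionCatalog,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Housekeeping over-representation per cluster.

    A cluster's reactions are those catalysed by any of its member
    enzymes (a reaction with isoenzymes in several clusters counts in
    each).  The population is the union of all clustered enzymes'
    reactions.  The p-value is the upper-tail hypergeometric
    probability of drawing at least the observed number of
    housekeeping reactions; q-values are Benjamini-Hochberg across
    clusters, and a cluster is enriched when q <= alpha.
    """
    enz2rxn = catalog.enzymes_to_reactions()
    cluster_rxns: dict[int, set[str]] = {}
    population: set[str] = set()
    for c in clustering.clusters:
        rxns: set[str] = set()
        for e in clustering.members(c):
            rxns.update(enz2rxn.get(e, ()))
        cluster_rxns[int(c)] = rxns
        population |= rxns
    N = len(population)
    K = len(population & hk_reactions)
    rows = {}
    for c, rxns in cluster_rxns.items():
        n = len(rxns)
        k = len(rxns & hk_reactions)
        p = 1.0 if n == 0 else float(hypergeom.sf(k - 1, N, K, n))
        rows[c] = {
            "hk_count": k,
            "cluster_size": n,
            "population_size": N,
            "population_hk": K,
            "hypergeometric_p": min(p, 1.0),
        }
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    if len(table) == 1:
        table["bh_fdr_q"] = table["hypergeometric_p"]
    else:
        table["bh_fdr_q"] = multipletests(
            table["hypergeometric_p"].to_numpy(), method="fdr_bh"
        )[1]
    table["enriched"] = table["bh_fdr_q"] <= alpha
    return table


def self_consistency(
    core: CoreReactionSets | Mapping[str, Set[str]],
    model_reactions: Mapping[str, Set[str]],
) -> pd.DataFrame:
    """Per-context overlap of extracted models with their core lists.

    For each context: ``fraction`` = |model ∩ core| / |model| (how much
    of the model the expression evidence supports) plus the Jaccard
    similarity of the two sets.
    """
    core_sets = core.sets if isinstance(core, CoreReactionSets) else core
    rows = {}
    for context, model in model_reactions.items():
        if context not in core_sets:
            raise InputError(f"no core set for context {context!r}")
        if not model:
            raise InputError(f"model set for context {context!r} is empty")
        c = core_sets[context]
        rows[context] = {
            "fraction": len(model & c) / len(model),
            "jaccard": jaccard(set(model), set(c)),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class GiniResult:
    """Per-gene normalised Gini coefficients and the implied HK call."""

    gini: pd.Series
    housekeeping: set[str]
    excluded: tuple[str, ...] = ()
    cutoff: float = 0.24


def gini_housekeeping(
    expr: ExpressionMatrix, cutoff: float = 0.24
) -> GiniResult:
    """Classify housekeeping genes by expression equality across contexts.

    The Gini coefficient of each gene's linear-scale expression vector
    is normalised by n/(n-1) (small-sample correction), so a gene
    expressed in exactly one context scores 1 and a constant gene
    scores 0.  Genes with normalised Gini <= ``cutoff`` (default 0.24)
    are called housekeeping; all-zero genes are undefined and reported
    as excluded.
    """
    values = expr.data.to_numpy(dtype=float)
    n = values.shape[1]
    if n < 2:
        raise InputError("Gini classification needs at least two contexts")
    totals = values.sum(axis=1)
    nonzero = totals > 0
    x = np.sort(values[nonzero], axis=1)
    ranks = np.arange(1, n + 1)
    # G = 2*sum(i*x_(i)) / (n*sum(x)) - (n+1)/n, then * n/(n-1)
    g = (2.0 * (x * ranks).sum(axis=1) / (n * totals[nonzero]) - (n + 1.0) / n)
    g_norm = g * n / (n - 1.0)
    index = expr.data.index[nonzero]
    gini = pd.Series(g_norm, index=index, name="gini")
    housekeeping = set(index[g_norm <= cutoff])
    excluded = tuple(expr.data.index[~nonzero])
    return GiniResult(
        gini=gini, housekeeping=housekeeping, excluded=excluded, cutoff=cutoff
    )
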