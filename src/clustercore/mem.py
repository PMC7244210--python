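"""Tailoring thresholded expression into model-extraction-method inputs.

Six extraction algorithms (fastCORE, iMAT, MBA, mCADRE, INIT, GIMME)
each consume expression evidence in a different shape.  This module
builds those inputs from the cluster-specific thresholds; it does not
run the extractors.

All constructions start from the *threshold distance*

    D_{c,i} = x_{i,c} - cutoff_c        (log10 units)

of enzyme expression x from its cluster's resolved cutoff.  From D:

* mCADRE's ubiquity score per reaction: U = 1 where D >= 0, else
  U = 1 - D / min(D) with min(D) the most negative distance in the
  whole matrix, so U lies in [0, 1]; gene-free reactions get the
  sentinel -1.
* INIT reaction weights: enzyme weight D / max|D| (in [-1, 1]), summed
  over isoenzymes per reaction; gene-free reactions weigh 0.
* GIMME uses the identical weight vector with an activity threshold
  fixed at 1.
* MBA's high/medium sets: enzymes above 110% / within 90–110% of the
  cutoff (multiplicative band on the linear abundance scale).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .catalog import ReactionCatalog
from .clustering import ClusteringResult
from .errors import DegenerateDataWarning, InputError
from .expression import EnzymeExpressionMatrix
from .thresholds import CoreReactionSets, ThresholdSet

__all__ = [
    "GimmeInput",
    "MEMInputBundle",
    "threshold_distances",
    "ubiquity_scores",
    "init_weights",
    "gimme_vector",
    "mba_sets",
    "imat_sets",
    "build_mem_bundle",
    "write_mem_bundle",
]


def threshold_distances(
    enz: EnzymeExpressionMatrix,
    clustering: ClusteringResult,
    thresholds: ThresholdSet,
    zero_floor: float | None = None,
) -> pd.DataFrame:
    """Enzymes x contexts distances D = log10(x) - cluster cutoff.

    Zero-expression entries have no log value; they are placed at a
    floor of one decade below the smallest positive value in the
    matrix (override with ``zero_floor``, in log10 units), keeping
    them strictly below every cutoff that any expressed value attains.
    """
    missing = [e for e in enz.data.index if e not in clustering.assignment]
    if missing:
        raise InputError(f"enzymes without cluster assignment: {missing[:5]}")
    values = enz.data.to_numpy()
    pos = values[values > 0]
    if pos.size == 0:
        raise InputError("enzyme expression matrix has no positive values")
    if zero_floor is None:
        zero_floor = float(np.log10(pos.min())) - 1.0
    with np.errstate(divide="ignore"):
        logv = np.log10(values, where=values > 0, out=np.full_like(values, zero_floor))
    cutoffs = np.array(
        [thresholds.cutoff_of(clustering.assignment[e]) for e in enz.data.index]
    )
    return pd.DataFrame(
        logv - cutoffs[:, None], index=enz.data.index, columns=enz.data.columns
    )


def _enzymes_to_reaction_frame(
    enzyme_frame: pd.DataFrame,
    catalog: ReactionCatalog,
    combine: str,
    gene_free_value: float,
    protected: Iterable[str],
    protected_value: float,
    empty_value: float,
) -> pd.DataFrame:
    """Collapse an enzymes x contexts frame to reactions x contexts."""
    have = set(enzyme_frame.index)
    protected = set(protected)
    out = np.empty((len(catalog.reactions), enzyme_frame.shape[1]))
    for i, rxn in enumerate(catalog.reactions):
        if not rxn.enzyme_ids:
            out[i] = gene_free_value
            continue
        eids = [e for e in rxn.enzyme_ids if e in have]
        if not eids:
            out[i] = empty_value  # enzymes dropped during gene mapping
            continue
        block = enzyme_frame.loc[eids].to_numpy()
        out[i] = block.max(axis=0) if combine == "max" else block.sum(axis=0)
    frame = pd.DataFrame(
        out, index=catalog.reaction_ids, columns=enzyme_frame.columns
    )
    for rid in protected:
        frame.loc[rid] = protected_value
    return frame


def ubiquity_scores(
    D: pd.DataFrame,
    catalog: ReactionCatalog,
    protected: Iterable[str] = (),
) -> pd.DataFrame:
    """Reactions x contexts ubiquity scores in [0, 1] (gene-free: -1).

    Enzyme scores: 1 where D >= 0; 1 - D/min(D) where D < 0, the min
    taken over every negative entry of the matrix (so the most distant
    enzyme anywhere scores exactly 0).  A reaction inherits its best
    (maximum) enzyme score; protected reactions are pinned at 1.
    """
    values = D.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise InputError("threshold distances must be finite")
    neg = values[values < 0]
    if neg.size == 0:
        warnings.warn(
            "no enzyme lies below threshold anywhere; all gene-associated "
            "ubiquity scores are 1",
            DegenerateDataWarning,
            stacklevel=2,
        )
        U = np.ones_like(values)
    else:
        dmin = neg.min()
        U = np.where(values >= 0, 1.0, 1.0 - values / dmin)
    enzyme_U = pd.DataFrame(U, index=D.index, columns=D.columns)
    return _enzymes_to_reaction_frame(
        enzyme_U,
        catalog,
        combine="max",
        gene_free_value=-1.0,
        protected=protected,
        protected_value=1.0,
        empty_value=0.0,
    )


def init_weights(
    D: pd.DataFrame,
    catalog: ReactionCatalog,
    protected: Iterable[str] = (),
) -> pd.DataFrame:
    """Reactions x contexts INIT weights.

    Enzyme weights D / max|D| lie in [-1, 1]; a reaction sums its
    isoenzymes' weights (sums may leave [-1, 1] and are not clipped).
    Gene-free reactions weigh 0; protected reactions 1.
    """
    values = D.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise InputError("threshold distances must be finite")
    dmax = np.abs(values).max()
    if dmax == 0.0:
        warnings.warn(
            "all threshold distances are zero; all weights are 0",
            DegenerateDataWarning,
            stacklevel=2,
        )
        W = np.zeros_like(values)
    else:
        W = values / dmax
    enzyme_W = pd.DataFrame(W, index=D.index, columns=D.columns)
    return _enzymes_to_reaction_frame(
        enzyme_W,
        catalog,
        combine="sum",
        gene_free_value=0.0,
        protected=protected,
        protected_value=1.0,
        empty_value=0.0,
    )


@dataclass
class GimmeInput:
    """GIMME reaction expression vectors plus its activity threshold."""

    weights: pd.DataFrame  # reactions x contexts
    threshold: float = 1.0


def gimme_vector(
    D: pd.DataFrame,
    catalog: ReactionCatalog,
    protected: Iterable[str] = (),
) -> GimmeInput:
    """GIMME input: the INIT weight construction with threshold 1."""
    return GimmeInput(weights=init_weights(D, catalog, protected), threshold=1.0)


def mba_sets(
    enz: EnzymeExpressionMatrix,
    clustering: ClusteringResult,
    thresholds: ThresholdSet,
    catalog: ReactionCatalog,
    band: float = 0.10,
    scale: str = "linear",
    protect: Iterable[str] = (),
) -> dict[str, tuple[set[str], set[str]]]:
    """MBA high/medium expression reaction sets per context.

    An enzyme is *high* above 110% of its cluster cutoff and *medium*
    between 90% and 110% (``band`` = 0.10); the margin is
    multiplicative on the linear abundance scale by default
    (``scale="log"`` applies ±``band`` decades to the log10 cutoff
    instead).  A reaction with both a high and a medium enzyme goes to
    the high set only; protected reactions are always high.
    """
    if not 0.0 < band < 1.0:
        raise InputError("band must lie in (0, 1)")
    if scale not in {"linear", "log"}:
        raise InputError(f"unknown scale {scale!r}")
    missing = [e for e in enz.data.index if e not in clustering.assignment]
    if missing:
        raise InputError(f"enzymes without cluster assignment: {missing[:5]}")
    cutoffs = np.array(
        [thresholds.cutoff_of(clustering.assignment[e]) for e in enz.data.index]
    )
    values = enz.data.to_numpy()
    if scale == "linear":
        lin_cut = 10.0 ** cutoffs[:, None]
        high = values > (1.0 + band) * lin_cut
        medium = (values > (1.0 - band) * lin_cut) & ~high
    else:
        with np.errstate(divide="ignore"):
            logv = np.log10(
                values, where=values > 0, out=np.full_like(values, -np.inf)
            )
        high = logv > cutoffs[:, None] + band
        medium = (logv > cutoffs[:, None] - band) & ~high
    protect = set(protect)
    have = {e: i for i, e in enumerate(enz.data.index)}
    out: dict[str, tuple[set[str], set[str]]] = {}
    for j, context in enumerate(enz.data.columns):
        hi: set[str] = set()
        med: set[str] = set()
        for rxn in catalog.reactions:
            idx = [have[e] for e in rxn.enzyme_ids if e in have]
            if not idx:
                continue
            if any(high[i, j] for i in idx):
                hi.add(rxn.id)
            elif any(medium[i, j] for i in idx):
                med.add(rxn.id)
        hi |= protect
        med -= hi
        out[str(context)] = (hi, med)
    return out


def imat_sets(
    core: CoreReactionSets, catalog: ReactionCatalog
) -> dict[str, tuple[set[str], set[str]]]:
    """iMAT (core, noncore) reaction sets per context.

    Noncore = all catalog reactions minus the core minus gene-free
    reactions (reactions without gene association belong to neither
    set); the core already includes any protected reactions.
    """
    all_rxns = set(catalog.reaction_ids)
    out: dict[str, tuple[set[str], set[str]]] = {}
    for context, core_set in core.sets.items():
        noncore = all_rxns - core_set - catalog.gene_free_reactions
        out[context] = (set(core_set), noncore)
    return out


@dataclass
class MEMInputBundle:
    """Inputs for all six extraction methods, from one thresholding run."""

    fastcore_core: dict[str, set[str]]
    imat: dict[str, tuple[set[str], set[str]]]
    mba: dict[str, tuple[set[str], set[str]]]
    ubiquity: pd.DataFrame
    init_weights: pd.DataFrame
    gimme: GimmeInput
    method: str = "cluster-specific"
    parameters: dict = field(default_factory=dict)


def build_mem_bundle(
    enz: EnzymeExpressionMatrix,
    clustering: ClusteringResult,
    thresholds: ThresholdSet,
    catalog: ReactionCatalog,
    core: CoreReactionSets,
    protect: Iterable[str] = (),
    band: float = 0.10,
) -> MEMInputBundle:
    """Assemble every extraction-method input from one thresholding run."""
    D = threshold_distances(enz, clustering, thresholds)
    protect = list(protect)
    return MEMInputBundle(
        fastcore_core={c: set(s) for c, s in core.sets.items()},
        imat=imat_sets(core, catalog),
        mba=mba_sets(enz, clustering, thresholds, catalog, band=band, protect=protect),
        ubiquity=ubiquity_scores(D, catalog, protected=protect),
        init_weights=init_weights(D, catalog, protected=protect),
        gimme=gimme_vector(D, catalog, protected=protect),
        method=core.method,
        parameters={"band": band, "protected": protect},
    )


def write_mem_bundle(bundle: MEMInputBundle, out_dir: str | Path) -> None:
    """Serialise a bundle: matrices as TSV, reaction sets as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.ubiquity.to_csv(out / "ubiquity.tsv", sep="\t", index_label="reaction")
    bundle.init_weights.to_csv(
        out / "init_weights.tsv", sep="\t", index_label="reaction"
    )
    bundle.gimme.weights.to_csv(
        out / "gimme_weights.tsv", sep="\t", index_label="reaction"
    )
    doc = {
        "method": bundle.method,
        "parameters": bundle.parameters,
        "gimme_threshold": bundle.gimme.threshold,
        "fastcore_core": {c: sorted(s) for c, s in bundle.fastcore_core.items()},
        "imat": {
            c: {"core": sorted(a), "noncore": sorted(b)}
            for c, (a, b) in bundle.imat.items()
        },
        "mba": {
            c: {"high": sorted(a), "medium": sorted(b)}
            for c, (a, b) in bundle.mba.items()
        },
    }
    (out / "mem_sets.json").write_text(json.dumps(doc, indent=1))
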