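"""Cluster-specific and baseline thresholding of enzyme expression.

The cluster-specific scheme assigns every cluster c of co-patterned
enzymes its own activity threshold from two data-dependent statistics
of the pooled log10 values:

    theta_c = f(sigma_c) + g(mu_c)
    f(sigma_c) = (sigma_c - Delta) / max_c(sigma_c - Delta)
    g(mu_c)    = -(mu_c - M)

where mu_c / sigma_c are the cluster mean / SD and M / Delta the
dataset mean / SD.  Tightly expressed clusters (sigma_c far below
Delta) and lowly expressed clusters (mu_c below M) both earn a larger
raw threshold theta_c.  The raw values are normalised affinely onto
[0, 100]:

    Theta_c = (theta_c - min(theta_c)) * 100 / max(theta_c - min(theta_c))

and read as a *top percentile*: an enzyme of cluster c is active in a
context when its log10 value strictly exceeds the (100 - Theta_c)-th
percentile of the cluster's pooled values.  A high Theta_c is thus a
*permissive* cutoff — almost every expressed context qualifies — which
is how constitutively-but-lowly expressed (housekeeping-like) clusters
are retained.  The cluster with Theta_c = 100 is special-cased to the
dataset mean M as its cutoff.

Three baseline schemes are provided for comparison: a single global
top-percentile cutoff, and two per-enzyme ("local") schemes anchored
at each enzyme's cross-context mean with one (localT1) or two
(localT2) unconditional percentile bounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .catalog import ReactionCatalog
from .clustering import ClusteringResult, _log10_positive
from .errors import DegenerateDataWarning, InputError
from .expression import EnzymeExpressionMatrix

__all__ = [
    "ThresholdSet",
    "CoreReactionSets",
    "top_percentile_cutoff",
    "raw_cluster_thresholds",
    "normalize_thresholds",
    "resolve_cutoffs",
    "standep_thresholds",
    "standep_core",
    "global_core",
    "localT1_core",
    "localT2_core",
]

_THETA_MAX = 100.0 - 1e-9  # Theta at or above this hits the mean special case


def top_percentile_cutoff(values: np.ndarray, top: float) -> float:
    """Cutoff for "the top ``top`` percent" of ``values``.

    Defined as the quantile at probability (100 - top)/100 with linear
    interpolation; values *strictly above* the cutoff are in the top
    slice.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise InputError("cannot take a percentile of an empty set")
    if not 0.0 <= top <= 100.0:
        raise InputError("top percentile must lie in [0, 100]")
    return float(np.quantile(values, (100.0 - top) / 100.0))


@dataclass
class ThresholdSet:
    """Per-cluster raw/normalised thresholds and resolved cutoffs.

    ``table`` is indexed by cluster id with columns ``theta_raw``,
    ``theta_norm``, ``cutoff`` (log10 expression units) and
    ``special_mean`` (True where theta_norm = 100 and the cutoff is
    the dataset mean).
    """

    table: pd.DataFrame
    method: str = "cluster-specific"
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"theta_raw", "theta_norm", "cutoff", "special_mean"}
        if not required <= set(self.table.columns):
            raise InputError(f"threshold table needs columns {sorted(required)}")

    def cutoff_of(self, cluster: int) -> float:
        return float(self.table.loc[cluster, "cutoff"])

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "parameters": self.parameters,
            "clusters": {
                str(c): row.to_dict() for c, row in self.table.iterrows()
            },
        }


@dataclass
class CoreReactionSets:
    """Per-context active reaction identifiers, with provenance.

    ``provenance[context][reaction]`` lists the activating enzymes
    (the literal ``"protected"`` marks reactions force-included via the
    protected list).
    """

    sets: dict[str, set[str]]
    provenance: dict[str, dict[str, tuple[str, ...]]]
    method: str

    @property
    def context_ids(self) -> list[str]:
        return list(self.sets)

    def sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sets.items()}

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "sets": {c: sorted(s) for c, s in self.sets.items()},
        }


def raw_cluster_thresholds(clustering: ClusteringResult) -> pd.Series:
    """Raw per-cluster thresholds theta_c = f(sigma_c) + g(mu_c)."""
    stats = clustering.cluster_stats
    if stats.empty:
        raise InputError("clustering has no clusters")
    if stats[["mu", "sigma"]].isna().any().any():
        raise InputError(
            "cluster(s) without positive expression values have undefined "
            "statistics; cannot compute thresholds"
        )
    sd_diff = stats["sigma"] - clustering.Delta
    denom = float(sd_diff.max())
    if denom == 0.0:
        warnings.warn(
            "all cluster standard deviations equal the dataset's; the "
            "standard-deviation term is set to 0 for every cluster",
            DegenerateDataWarning,
            stacklevel=2,
        )
        f = pd.Series(0.0, index=stats.index)
    else:
        if denom < 0.0:
            warnings.warn(
                "every cluster is tighter than the dataset (max(sigma_c - "
                "Delta) < 0); the standard-deviation term keeps its sign "
                "as defined",
                DegenerateDataWarning,
                stacklevel=2,
            )
        f = sd_diff / denom
    g = -(stats["mu"] - clustering.M)
    theta = (f + g).astype(float)
    theta.name = "theta_raw"
    return theta


def normalize_thresholds(theta: pd.Series) -> pd.Series:
    """Affine map of the raw thresholds onto [0, 100].

    The minimum maps to 0 and the maximum to 100.  When every theta_c
    coincides the map is degenerate; all clusters are then assigned
    100 — i.e. every cluster takes the dataset-mean cutoff — and a
    warning is emitted.
    """
    if len(theta) < 2:
        raise InputError("normalization needs at least two clusters")
    tmin, tmax = float(theta.min()), float(theta.max())
    if tmax == tmin:
        warnings.warn(
            "all raw thresholds identical; every cluster falls back to "
            "the dataset-mean cutoff",
            DegenerateDataWarning,
            stacklevel=2,
        )
        out = pd.Series(100.0, index=theta.index)
    else:
        out = (theta - tmin) * 100.0 / (tmax - tmin)
    out.name = "theta_norm"
    return out


def _cluster_log_values(
    clustering: ClusteringResult, enz: EnzymeExpressionMatrix
) -> dict[int, np.ndarray]:
    """Pooled positive log10 values per cluster (members x contexts)."""
    data = enz.data
    out: dict[int, np.ndarray] = {}
    index = pd.Index(list(clustering.assignment))
    labels = np.array([clustering.assignment[e] for e in index])
    values = data.loc[index].to_numpy()
    for c in clustering.clusters:
        out[int(c)] = _log10_positive(values[labels == c])
    return out


def resolve_cutoffs(
    theta_norm: pd.Series,
    clustering: ClusteringResult,
    enz: EnzymeExpressionMatrix,
    theta_raw: pd.Series | None = None,
) -> ThresholdSet:
    """Resolve normalised thresholds to log10 expression cutoffs.

    Theta_c < 100: the cutoff is the top-Theta_c-percentile value of
    the cluster's pooled positive log10 values (so Theta_c = 0 resolves
    to the cluster maximum and nothing qualifies).  Theta_c = 100: the
    cutoff is the dataset mean M, flagged ``special_mean``.
    """
    if ((theta_norm < -1e-9) | (theta_norm > 100 + 1e-9)).any():
        raise InputError("normalised thresholds must lie in [0, 100]")
    theta_norm = theta_norm.clip(0.0, 100.0)
    pooled = _cluster_log_values(clustering, enz)
    rows = {}
    for c, Theta in theta_norm.items():
        c = int(c)
        vals = pooled.get(c)
        if vals is None or vals.size == 0:
            raise InputError(f"cluster {c} has no positive expression values")
        special = Theta >= _THETA_MAX
        cutoff = clustering.M if special else top_percentile_cutoff(vals, Theta)
        rows[c] = {
            "theta_raw": float("nan") if theta_raw is None else float(theta_raw[c]),
            "theta_norm": float(Theta),
            "cutoff": float(cutoff),
            "special_mean": bool(special),
        }
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    return ThresholdSet(table=table, method="cluster-specific")


def standep_thresholds(
    enz: EnzymeExpressionMatrix, clustering: ClusteringResult
) -> ThresholdSet:
    """Convenience chain: raw thresholds → normalisation → cutoffs."""
    theta = raw_cluster_thresholds(clustering)
    Theta = normalize_thresholds(theta)
    return resolve_cutoffs(Theta, clustering, enz, theta_raw=theta)


# ----------------------------------------------------------------------
# core-set construction


def _cores_from_active(
    active: pd.DataFrame,
    catalog: ReactionCatalog,
    protect: Iterable[str],
    method: str,
) -> CoreReactionSets:
    """Lift an enzymes x contexts activity mask to per-context reaction sets."""
    protect = list(protect)
    active_ids = active.index
    have = set(active_ids)
    sets: dict[str, set[str]] = {}
    provenance: dict[str, dict[str, tuple[str, ...]]] = {}
    mask = active.to_numpy(dtype=bool)
    eid_pos = {e: i for i, e in enumerate(active_ids)}
    for j, context in enumerate(active.columns):
        core: set[str] = set()
        prov: dict[str, tuple[str, ...]] = {}
        col = mask[:, j]
        for rxn in catalog.reactions:
            activators = tuple(
                e for e in rxn.enzyme_ids if e in have and col[eid_pos[e]]
            )
            if activators:
                core.add(rxn.id)
                prov[rxn.id] = activators
        for rid in protect:
            if rid not in core:
                prov[rid] = ("protected",)
            core.add(rid)
        sets[str(context)] = core
        provenance[str(context)] = prov
    return CoreReactionSets(sets=sets, provenance=provenance, method=method)


def standep_core(
    enz: EnzymeExpressionMatrix,
    clustering: ClusteringResult,
    thresholds: ThresholdSet,
    catalog: ReactionCatalog,
    protect: Iterable[str] = (),
) -> CoreReactionSets:
    """Per-context core reactions under the cluster-specific thresholds.

    An enzyme is active in a context when its log10 value strictly
    exceeds its cluster's cutoff (zero expression never activates); a
    reaction is core when at least one of its enzymes is active.
    Protected reactions (e.g. biomass) are appended to every context.
    """
    missing = [e for e in enz.data.index if e not in clustering.assignment]
    if missing:
        raise InputError(f"enzymes without cluster assignment: {missing[:5]}")
    cutoffs = np.array(
        [thresholds.cutoff_of(clustering.assignment[e]) for e in enz.data.index]
    )
    values = enz.data.to_numpy()
    with np.errstate(divide="ignore"):
        logv = np.log10(values, where=values > 0, out=np.full_like(values, -np.inf))
    active = pd.DataFrame(
        logv > cutoffs[:, None], index=enz.data.index, columns=enz.data.columns
    )
    return _cores_from_active(active, catalog, protect, method="cluster-specific")


def global_core(
    enz: EnzymeExpressionMatrix,
    catalog: ReactionCatalog,
    top_percentile: float = 25.0,
    protect: Iterable[str] = (),
) -> CoreReactionSets:
    """Single dataset-wide cutoff: the top ``top_percentile`` percent of
    all positive log10 values qualify as active."""
    values = enz.data.to_numpy()
    logs = _log10_positive(values)
    if logs.size == 0:
        raise InputError("enzyme expression matrix has no positive values")
    cutoff = top_percentile_cutoff(logs, top_percentile)
    with np.errstate(divide="ignore"):
        logv = np.log10(values, where=values > 0, out=np.full_like(values, -np.inf))
    active = pd.DataFrame(
        logv > cutoff, index=enz.data.index, columns=enz.data.columns
    )
    return _cores_from_active(active, catalog, protect, method="global")


def _local_log_stats(
    enz: EnzymeExpressionMatrix,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(log-values with -inf at zeros, per-enzyme mean over positive
    log10 values with NaN for all-zero enzymes, pooled positive logs)."""
    values = enz.data.to_numpy()
    with np.errstate(divide="ignore"):
        logv = np.log10(values, where=values > 0, out=np.full_like(values, -np.inf))
    masked = np.where(values > 0, logv, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        means = np.nanmean(masked, axis=1)
    return logv, means, _log10_positive(values)


def localT1_core(
    enz: EnzymeExpressionMatrix,
    catalog: ReactionCatalog,
    lower_top_percentile: float = 75.0,
    variant: str = "methods",
    protect: Iterable[str] = (),
) -> CoreReactionSets:
    """Per-enzyme ("local") thresholds with one dataset-wide lower bound.

    ``variant="methods"`` (default): an enzyme whose cross-context mean
    falls below the dataset's lower-bound percentile is inactive in
    every context; any other enzyme is active wherever its value
    exceeds its own mean.  ``variant="results"``: no unconditional
    inactivation — each enzyme's cutoff is max(own mean, lower bound).
    """
    if variant not in {"methods", "results"}:
        raise InputError(f"unknown localT1 variant {variant!r}")
    logv, means, pooled = _local_log_stats(enz)
    if pooled.size == 0:
        raise InputError("enzyme expression matrix has no positive values")
    bound = top_percentile_cutoff(pooled, lower_top_percentile)
    with np.errstate(invalid="ignore"):
        if variant == "methods":
            eligible = means >= bound  # NaN mean -> inactive everywhere
            active_arr = eligible[:, None] & (logv > means[:, None])
        else:
            cut = np.fmax(means, bound)  # NaN mean -> bound
            cut = np.where(np.isnan(means), bound, cut)
            active_arr = logv > cut[:, None]
    active = pd.DataFrame(active_arr, index=enz.data.index, columns=enz.data.columns)
    return _cores_from_active(active, catalog, protect, method=f"localT1-{variant}")


def localT2_core(
    enz: EnzymeExpressionMatrix,
    catalog: ReactionCatalog,
    upper_top_percentile: float = 25.0,
    lower_top_percentile: float = 75.0,
    protect: Iterable[str] = (),
) -> CoreReactionSets:
    """Per-enzyme thresholds with unconditional upper and lower bounds.

    Enzymes whose cross-context mean exceeds the dataset's upper-bound
    percentile are active in *every* context (even where measured 0);
    those below the lower bound are inactive everywhere; the mid-band
    enzymes are active wherever their value exceeds their own mean.
    """
    logv, means, pooled = _local_log_stats(enz)
    if pooled.size == 0:
        raise InputError("enzyme expression matrix has no positive values")
    lower = top_percentile_cutoff(pooled, lower_top_percentile)
    upper = top_percentile_cutoff(pooled, upper_top_percentile)
    if lower >= upper:
        raise InputError(
            f"lower bound ({lower:.4g}) must fall below upper bound "
            f"({upper:.4g}); check the percentile parameters"
        )
    with np.errstate(invalid="ignore"):
        always = means > upper
        never = ~(means >= lower)  # includes NaN means
        mid = ~always & ~never
        active_arr = always[:, None] | (mid[:, None] & (logv > means[:, None]))
    active = pd.DataFrame(active_arr, index=enz.data.index, columns=enz.data.columns)
    return _cores_from_active(active, catalog, protect, method="localT2")
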