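"""Binned expression profiles and hierarchical clustering of enzymes.

Each enzyme's expression across contexts is summarised as a histogram
of its log10 values over uniform bins spanning the positive data range
(zeros are excluded — the profile encodes *in how many contexts, and
at what level, the enzyme is expressed*).  Enzymes are then clustered
hierarchically on these count profiles (Euclidean distance, complete
linkage by default), so enzymes with similar expression *patterns* —
not merely similar mean levels — end up together and can share a
threshold.

The number of clusters N is selected by stability of the resulting
core reaction lists: N is increased until the core lists at N and N+1
agree above a Jaccard-similarity cut (0.90 by default) and stay in
agreement for all larger N examined.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .errors import InputError
from .expression import EnzymeExpressionMatrix

__all__ = [
    "BinnedProfileMatrix",
    "ClusteringResult",
    "SelectionResult",
    "bin_profiles",
    "cluster_profiles",
    "clustering_from_assignment",
    "select_cluster_count",
]

DEFAULT_N_BINS = 60  # ~0.13 decades per bin over a typical 8-decade range


@dataclass
class BinnedProfileMatrix:
    """Enzymes x bins counts of log10 expression values."""

    enzyme_ids: list[str]
    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.enzyme_ids), len(self.bin_edges) - 1):
            raise InputError("profile counts shape does not match ids/edges")
        if not np.all(np.diff(self.bin_edges) > 0):
            raise InputError("bin edges must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        cols = [f"bin{i:03d}" for i in range(self.counts.shape[1])]
        return pd.DataFrame(self.counts, index=self.enzyme_ids, columns=cols)


@dataclass
class ClusteringResult:
    """Cluster assignment plus the log10 statistics the thresholds use.

    ``mu`` / ``sigma`` are the mean / SD of each cluster's pooled
    positive log10 values (all member enzymes x contexts); ``M`` /
    ``Delta`` are the same statistics over the whole matrix.
    """

    n_clusters: int
    assignment: dict[str, int]
    cluster_stats: pd.DataFrame  # index: cluster id; columns mu, sigma, n_members, n_values
    M: float
    Delta: float
    distance: str = "euclidean"
    linkage: str = "complete"

    def __post_init__(self) -> None:
        labels = set(self.assignment.values())
        if not labels:
            raise InputError("empty cluster assignment")
        if labels - set(self.cluster_stats.index):
            raise InputError("cluster_stats missing some assigned clusters")

    @property
    def clusters(self) -> list[int]:
        return list(self.cluster_stats.index)

    def members(self, cluster: int) -> list[str]:
        return [e for e, c in self.assignment.items() if c == cluster]

    def to_dict(self) -> dict:
        return {
            "n_clusters": self.n_clusters,
            "assignment": self.assignment,
            "cluster_stats": {
                str(c): row.to_dict() for c, row in self.cluster_stats.iterrows()
            },
            "M": self.M,
            "Delta": self.Delta,
            "distance": self.distance,
            "linkage": self.linkage,
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "ClusteringResult":
        stats = pd.DataFrame.from_dict(d["cluster_stats"], orient="index")
        stats.index = stats.index.astype(int)
        return cls(
            n_clusters=d["n_clusters"],
            assignment={e: int(c) for e, c in d["assignment"].items()},
            cluster_stats=stats.sort_index(),
            M=d["M"],
            Delta=d["Delta"],
            distance=d.get("distance", "euclidean"),
            linkage=d.get("linkage", "complete"),
        )


def _log10_positive(values: np.ndarray) -> np.ndarray:
    """log10 of the positive entries, as a flat array."""
    pos = values[values > 0]
    return np.log10(pos)


def bin_profiles(
    enz: EnzymeExpressionMatrix, n_bins: int = DEFAULT_N_BINS
) -> BinnedProfileMatrix:
    """Histogram each enzyme's log10 values over shared uniform bins.

    Bins span [log10(min positive), log10(max)] of the whole matrix;
    zero-expression contexts are not counted, so row sums can fall
    short of the number of contexts.
    """
    if n_bins < 1:
        raise InputError("n_bins must be positive")
    values = enz.data.to_numpy()
    pos = values[values > 0]
    if pos.size == 0:
        raise InputError("enzyme expression matrix has no positive values")
    lo = float(np.log10(pos.min()))
    hi = float(np.log10(pos.max()))
    if hi <= lo:  # single distinct positive value
        hi = lo + 1e-9
    edges = np.linspace(lo, hi, n_bins + 1)
    counts = np.zeros((values.shape[0], n_bins), dtype=int)
    logv = np.where(values > 0, np.log10(np.where(values > 0, values, 1.0)), np.nan)
    for i in range(values.shape[0]):
        row = logv[i]
        row = row[~np.isnan(row)]
        counts[i], _ = np.histogram(row, bins=edges)
    return BinnedProfileMatrix(list(enz.data.index), edges, counts)


def _stats_of(values: np.ndarray) -> tuple[float, float, int]:
    logs = _log10_positive(values)
    if logs.size == 0:
        return float("nan"), float("nan"), 0
    return float(logs.mean()), float(logs.std(ddof=0)), int(logs.size)


def cluster_profiles(
    profiles: BinnedProfileMatrix,
    enz: EnzymeExpressionMatrix,
    n_clusters: int,
    distance: str = "euclidean",
    linkage: str = "complete",
) -> ClusteringResult:
    """Cut the agglomerative tree of binned profiles at ``n_clusters``.

    Cluster labels are arbitrary but deterministic for a given input
    order.  Statistics (mu, sigma per cluster; M, Delta overall) are
    computed on the pooled positive log10 values of member enzymes —
    the same transform used for binning.
    """
    n_enzymes = len(profiles.enzyme_ids)
    if n_clusters < 1:
        raise InputError("n_clusters must be >= 1")
    if n_clusters > n_enzymes:
        raise InputError(
            f"n_clusters={n_clusters} exceeds the {n_enzymes} enzymes"
        )
    if list(enz.data.index) != profiles.enzyme_ids:
        enzdata = enz.data.loc[profiles.enzyme_ids]
    else:
        enzdata = enz.data
    if n_enzymes == 1:
        labels = np.array([1])
    else:
        Z = hierarchy.linkage(
            profiles.counts.astype(float), method=linkage, metric=distance
        )
        labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    assignment = dict(zip(profiles.enzyme_ids, (int(c) for c in labels)))
    values = enzdata.to_numpy()
    rows = {}
    for c in sorted(set(labels.tolist())):
        member_mask = labels == c
        mu, sigma, n_values = _stats_of(values[member_mask])
        rows[int(c)] = {
            "mu": mu,
            "sigma": sigma,
            "n_members": int(member_mask.sum()),
            "n_values": n_values,
        }
    stats = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    mu_all, sd_all, _ = _stats_of(values)
    return ClusteringResult(
        n_clusters=len(rows),
        assignment=assignment,
        cluster_stats=stats,
        M=mu_all,
        Delta=sd_all,
        distance=distance,
        linkage=linkage,
    )


def clustering_from_assignment(
    enz: EnzymeExpressionMatrix,
    assignment: dict[str, int],
    distance: str = "none",
    linkage: str = "none",
) -> ClusteringResult:
    """Wrap an externally supplied enzyme→cluster assignment.

    Computes the same per-cluster and dataset log10 statistics that
    :func:`cluster_profiles` would, so any partition — planted labels,
    a clustering imported from elsewhere — can feed the thresholding
    chain.
    """
    missing = [e for e in enz.data.index if e not in assignment]
    if missing:
        raise InputError(f"assignment missing enzymes: {missing[:5]}")
    values = enz.data.to_numpy()
    labels = np.array([assignment[e] for e in enz.data.index])
    rows = {}
    for c in sorted(set(labels.tolist())):
        mu, sigma, n_values = _stats_of(values[labels == c])
        rows[int(c)] = {
            "mu": mu,
            "sigma": sigma,
            "n_members": int((labels == c).sum()),
            "n_values": n_values,
        }
    stats = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    mu_all, sd_all, _ = _stats_of(values)
    return ClusteringResult(
        n_clusters=len(rows),
        assignment={e: int(assignment[e]) for e in enz.data.index},
        cluster_stats=stats,
        M=mu_all,
        Delta=sd_all,
        distance=distance,
        linkage=linkage,
    )


@dataclass
class SelectionResult:
    """Chosen cluster count plus the stability trace behind the choice."""

    chosen_n: int
    trace: dict[int, float] = field(default_factory=dict)
    satisfied: bool = True  # False when no N met the stability rule


def select_cluster_count(
    enz: EnzymeExpressionMatrix,
    core_fn: Callable[[EnzymeExpressionMatrix, ClusteringResult], dict[str, set[str]]],
    n_range: Sequence[int] | range,
    jaccard_cut: float = 0.90,
    n_bins: int = DEFAULT_N_BINS,
    distance: str = "euclidean",
    linkage: str = "complete",
) -> SelectionResult:
    """Pick the number of clusters by core-list stability.

    For each N in ``n_range`` the per-context core reaction sets at N
    and N+1 (built by ``core_fn``) are compared by Jaccard similarity,
    averaged over contexts.  The chosen N is the smallest whose
    similarity exceeds ``jaccard_cut`` and stays above it for every
    larger N tested; if none qualifies the maximum of the range is
    returned with ``satisfied=False`` and a warning.

    ``core_fn(enz, clustering)`` must return ``{context: set of
    reaction ids}`` — see :func:`clustercore.thresholds.standep_core`.
    """
    from .evaluate import jaccard  # local import to avoid a cycle

    ns = sorted(set(int(n) for n in n_range))
    if not ns:
        raise InputError("empty n_range")
    n_enzymes = enz.data.shape[0]
    if ns[0] < 2 or ns[-1] > n_enzymes - 1:
        raise InputError(f"n_range must lie within [2, {n_enzymes - 1}]")
    profiles = bin_profiles(enz, n_bins=n_bins)

    cores_cache: dict[int, dict[str, set[str]]] = {}

    def cores_at(n: int) -> dict[str, set[str]]:
        if n not in cores_cache:
            clustering = cluster_profiles(
                profiles, enz, n, distance=distance, linkage=linkage
            )
            cores_cache[n] = core_fn(enz, clustering)
        return cores_cache[n]

    trace: dict[int, float] = {}
    for n in ns:
        a, b = cores_at(n), cores_at(n + 1)
        sims = [jaccard(a[c], b[c]) for c in a]
        trace[n] = float(np.mean(sims))
    chosen = None
    for n in ns:
        if all(trace[m] > jaccard_cut for m in ns if m >= n):
            chosen = n
            break
    if chosen is None:
        warnings.warn(
            f"no cluster count in {ns[0]}..{ns[-1]} reached Jaccard "
            f"stability > {jaccard_cut}; returning the maximum",
            stacklevel=2,
        )
        return SelectionResult(chosen_n=ns[-1], trace=trace, satisfied=False)
    return SelectionResult(chosen_n=chosen, trace=trace, satisfied=True)
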