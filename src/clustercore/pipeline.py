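"""End-to-end pipeline: expression + model in, artifacts out.

One :class:`RunConfig` fully determines a run; the config (and a hash
of it) is written into the output directory's manifest so any run can
be reproduced byte-identically from its artifacts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .catalog import ReactionCatalog, load_model
from .clustering import (
    DEFAULT_N_BINS,
    bin_profiles,
    cluster_profiles,
    select_cluster_count,
)
from .errors import InputError
from .evaluate import cluster_enrichment, housekeeping_coverage
from .expression import compute_enzyme_expression, read_expression
from .mem import build_mem_bundle, write_mem_bundle
from .synthetic import FixtureSpec, generate_fixture
from .thresholds import (
    CoreReactionSets,
    global_core,
    localT1_core,
    localT2_core,
    standep_core,
    standep_thresholds,
)

__all__ = ["RunConfig", "run_pipeline"]

METHODS = ("standep", "global", "localT1", "localT2")


@dataclass
class RunConfig:
    """Everything one pipeline run depends on.

    ``expression``/``model`` may be None, in which case a synthetic
    fixture (seeded by ``seed``) supplies both — useful for smoke runs
    and demos.
    """

    out_dir: str
    expression: str | None = None
    model: str | None = None
    model_format: str | None = None
    protect_file: str | None = None
    hk_reactions_file: str | None = None
    method: str = "standep"
    n_bins: int = DEFAULT_N_BINS
    distance: str = "euclidean"
    linkage: str = "complete"
    n_clusters: int | None = 4
    select_range: tuple[int, int] | None = None
    jaccard_cut: float = 0.90
    top_percentile: float = 25.0
    lower_top_percentile: float = 75.0
    upper_top_percentile: float = 25.0
    localT1_variant: str = "methods"
    mba_band: float = 0.10
    missing_gene_policy: str = "drop_enzyme"
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _read_id_list(path: str | None) -> list[str]:
    if not path:
        return []
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]


def _write_cores(core: CoreReactionSets, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    (out / "cores.json").write_text(json.dumps(core.to_dict(), indent=1))
    for context, rxns in core.sets.items():
        (out / f"{context}.txt").write_text("\n".join(sorted(rxns)) + "\n")
    rows = [
        {"context": c, "reaction": r, "enzymes": ";".join(enzs)}
        for c, prov in core.provenance.items()
        for r, enzs in sorted(prov.items())
    ]
    pd.DataFrame(rows).to_csv(out / "provenance.tsv", sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write all artifacts under ``config.out_dir``.

    Returns a manifest dict (also written as ``manifest.json``) naming
    each artifact.  Any stage error propagates as a package exception
    naming the offending entity.
    """
    if config.method not in METHODS:
        raise InputError(f"unknown method {config.method!r}; pick from {METHODS}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    # -- inputs -----------------------------------------------------
    hk_reference: set[str] = set(_read_id_list(config.hk_reactions_file))
    protect = _read_id_list(config.protect_file)
    if config.expression is None or config.model is None:
        fixture = generate_fixture(FixtureSpec(seed=config.seed))
        expr, catalog = fixture.expression, fixture.catalog
        expr.to_tsv(out / "expression.tsv")
        catalog.save_json(out / "catalog.json")
        artifacts["expression"] = "expression.tsv"
        if not hk_reference:
            hk_reference = fixture.hk_reactions
    else:
        expr = read_expression(config.expression)
        catalog = load_model(config.model, format=config.model_format)
        catalog.save_json(out / "catalog.json")
    artifacts["catalog"] = "catalog.json"

    # -- enzyme expression ------------------------------------------
    enz, report = compute_enzyme_expression(
        expr, catalog, missing_gene_policy=config.missing_gene_policy
    )
    enz.to_tsv(out / "enzyme_expression.tsv")
    (out / "mapping_report.json").write_text(json.dumps(report.to_dict(), indent=1))
    artifacts["enzyme_expression"] = "enzyme_expression.tsv"

    # -- clustering -------------------------------------------------
    if config.select_range is not None:
        lo, hi = config.select_range

        def _core_fn(e, clustering):
            ths = standep_thresholds(e, clustering)
            return standep_core(e, clustering, ths, catalog, protect=protect).sets

        selection = select_cluster_count(
            enz,
            _core_fn,
            range(lo, hi + 1),
            jaccard_cut=config.jaccard_cut,
            n_bins=config.n_bins,
            distance=config.distance,
            linkage=config.linkage,
        )
        n_clusters = selection.chosen_n
        (out / "cluster_selection.json").write_text(
            json.dumps(
                {
                    "chosen_n": selection.chosen_n,
                    "satisfied": selection.satisfied,
                    "trace": {str(k): v for k, v in selection.trace.items()},
                },
                indent=1,
            )
        )
        artifacts["cluster_selection"] = "cluster_selection.json"
    else:
        n_clusters = config.n_clusters or 4
    profiles = bin_profiles(enz, n_bins=config.n_bins)
    profiles.to_frame().to_csv(out / "profiles.tsv", sep="\t", index_label="enzyme")
    clustering = cluster_profiles(
        profiles, enz, n_clusters, distance=config.distance, linkage=config.linkage
    )
    clustering.save_json(out / "clustering.json")
    artifacts["clustering"] = "clustering.json"

    # -- thresholds and cores ---------------------------------------
    thresholds = standep_thresholds(enz, clustering)
    (out / "thresholds.json").write_text(json.dumps(thresholds.to_dict(), indent=1))
    artifacts["thresholds"] = "thresholds.json"
    if config.method == "standep":
        core = standep_core(enz, clustering, thresholds, catalog, protect=protect)
    elif config.method == "global":
        core = global_core(
            enz, catalog, top_percentile=config.top_percentile, protect=protect
        )
    elif config.method == "localT1":
        core = localT1_core(
            enz,
            catalog,
            lower_top_percentile=config.lower_top_percentile,
            variant=config.localT1_variant,
            protect=protect,
        )
    else:
        core = localT2_core(
            enz,
            catalog,
            upper_top_percentile=config.upper_top_percentile,
            lower_top_percentile=config.lower_top_percentile,
            protect=protect,
        )
    _write_cores(core, out / f"cores_{config.method}")
    artifacts["cores"] = f"cores_{config.method}/cores.json"

    # -- extraction-method inputs -----------------------------------
    bundle = build_mem_bundle(
        enz, clustering, thresholds, catalog, core,
        protect=protect, band=config.mba_band,
    )
    write_mem_bundle(bundle, out / "mem")
    artifacts["mem_bundle"] = "mem/mem_sets.json"

    # -- evaluation -------------------------------------------------
    if hk_reference:
        coverage = housekeeping_coverage(core, hk_reference)
        enrichment = cluster_enrichment(clustering, hk_reference, catalog)
        (out / "evaluation.json").write_text(
            json.dumps(
                {
                    "housekeeping_coverage": coverage.to_dict(),
                    "enrichment": {
                        str(c): row.to_dict() for c, row in enrichment.iterrows()
                    },
                },
                indent=1,
            )
        )
        artifacts["evaluation"] = "evaluation.json"

    manifest = {
        "package": "clustercore",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "n_clusters": int(n_clusters),
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
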