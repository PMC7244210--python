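"""Gene- and enzyme-level expression matrices.

An enzyme complex requires all of its subunits, so its effective
expression in a context is the minimum expression among its member
genes; a single-gene enzyme inherits the gene's value unchanged.
Isoenzymes are kept as separate rows.  Matrices are genes (or enzymes)
x contexts of nonnegative abundances (FPKM/TPM-like units).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .catalog import ReactionCatalog
from .errors import InputError

__all__ = [
    "ExpressionMatrix",
    "EnzymeExpressionMatrix",
    "EnzymeMappingReport",
    "read_expression",
    "compute_enzyme_expression",
    "reaction_expression",
]


def _validate_matrix(data: pd.DataFrame, what: str) -> None:
    if data.index.has_duplicates:
        dupes = data.index[data.index.duplicated()].unique()[:5].tolist()
        raise InputError(f"duplicate {what} ids: {dupes}")
    if data.columns.has_duplicates:
        raise InputError("duplicate context ids")
    values = data.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise InputError(f"{what} matrix must be numeric")
    if np.isnan(values).any():
        raise InputError(f"{what} matrix contains NaN")
    if (values < 0).any():
        raise InputError(f"{what} matrix contains negative values")


@dataclass
class ExpressionMatrix:
    """Genes x contexts abundance table (nonnegative, unique ids)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        _validate_matrix(self.data, "gene")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def context_ids(self) -> list[str]:
        return list(self.data.columns)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene")


@dataclass
class EnzymeExpressionMatrix:
    """Enzymes x contexts matrix of AND-minimum expression values."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        _validate_matrix(self.data, "enzyme")

    @property
    def enzyme_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def context_ids(self) -> list[str]:
        return list(self.data.columns)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="enzyme")


@dataclass
class EnzymeMappingReport:
    """Bookkeeping from the gene→enzyme mapping step."""

    policy: str
    n_genes_matched: int
    missing_genes: frozenset[str] = field(default_factory=frozenset)
    dropped_enzymes: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "policy": self.policy,
            "n_genes_matched": self.n_genes_matched,
            "missing_genes": sorted(self.missing_genes),
            "dropped_enzymes": list(self.dropped_enzymes),
        }


def read_expression(path: str | Path, sep: str | None = None) -> ExpressionMatrix:
    """Read a delimited expression table (first column gene id, header
    row of context ids; gzip accepted; delimiter sniffed when ``sep``
    is omitted).  Duplicate gene rows are reduced by their elementwise
    maximum — any measured transcript counts as evidence for the gene.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c",
                     index_col=0)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        df = df.groupby(level=0, sort=False).max()
    try:
        return ExpressionMatrix(df)
    except InputError:
        raise
    except Exception as exc:
        raise InputError(f"cannot interpret {path} as an expression table") from exc


def compute_enzyme_expression(
    expr: ExpressionMatrix,
    catalog: ReactionCatalog,
    missing_gene_policy: str = "drop_enzyme",
    case_fold: bool = False,
) -> tuple[EnzymeExpressionMatrix, EnzymeMappingReport]:
    """Convert gene expression to enzyme expression (min over AND genes).

    Parameters
    ----------
    missing_gene_policy:
        ``"drop_enzyme"`` (default): an enzyme with any gene absent from
        the expression matrix is excluded and reported — the analysis is
        restricted to genes present in both model and data.
        ``"treat_zero"``: absent genes count as zero expression, which
        zeroes the whole AND-minimum.
    case_fold:
        Match gene identifiers case-insensitively.
    """
    if missing_gene_policy not in {"drop_enzyme", "treat_zero"}:
        raise InputError(f"unknown missing_gene_policy {missing_gene_policy!r}")
    index = expr.data.index
    if case_fold:
        lookup: dict[str, str] = {}
        for g in index:
            lookup.setdefault(g.lower(), g)
        resolve = lambda g: lookup.get(g.lower())
    else:
        present = set(index)
        resolve = lambda g: g if g in present else None

    values = expr.data
    n_contexts = values.shape[1]
    rows: dict[str, np.ndarray] = {}
    missing: set[str] = set()
    dropped: list[str] = []
    matched_genes: set[str] = set()
    for eid, genes in catalog.enzymes.items():
        resolved = []
        absent = False
        for g in genes:
            hit = resolve(g)
            if hit is None:
                missing.add(g)
                absent = True
            else:
                resolved.append(hit)
        matched_genes.update(resolved)
        if absent:
            if missing_gene_policy == "drop_enzyme":
                dropped.append(eid)
                continue
            rows[eid] = np.zeros(n_contexts)
            continue
        rows[eid] = values.loc[resolved].to_numpy().min(axis=0)
    if not matched_genes:
        raise InputError("no catalog gene is present in the expression matrix")
    if not rows:
        raise InputError("every enzyme was dropped: no fully measured enzyme")
    enz = pd.DataFrame.from_dict(rows, orient="index", columns=values.columns)
    report = EnzymeMappingReport(
        policy=missing_gene_policy,
        n_genes_matched=len(matched_genes),
        missing_genes=frozenset(missing),
        dropped_enzymes=tuple(dropped),
    )
    return EnzymeExpressionMatrix(enz), report


def reaction_expression(
    enz: EnzymeExpressionMatrix,
    catalog: ReactionCatalog,
    combine: str = "max",
) -> pd.DataFrame:
    """Collapse enzyme expression to reactions (max or sum over isoenzymes).

    Gene-free reactions — and reactions whose enzymes were all dropped
    during gene mapping — carry NaN as the no-data sentinel.
    """
    if combine not in {"max", "sum"}:
        raise InputError(f"unknown combine {combine!r}")
    have = set(enz.data.index)
    out = np.full((len(catalog.reactions), enz.data.shape[1]), np.nan)
    for i, rxn in enumerate(catalog.reactions):
        eids = [e for e in rxn.enzyme_ids if e in have]
        if not eids:
            continue
        block = enz.data.loc[eids].to_numpy()
        out[i] = block.max(axis=0) if combine == "max" else block.sum(axis=0)
    return pd.DataFrame(out, index=catalog.reaction_ids, columns=enz.data.columns)
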