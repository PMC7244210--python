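"""Reaction catalogs: GPR rules decomposed into enzyme gene sets.

A genome-scale metabolic model ties each reaction to genes through a
boolean gene-protein-reaction (GPR) rule, where AND joins the subunits
of one enzyme complex and OR separates isoenzymes.  Everything
downstream of model loading works at the level of *enzymes*: one
AND-clause of the rule's disjunctive normal form (DNF).  Loading a
model therefore means expanding every GPR to DNF and deduplicating
identical gene sets into shared enzyme records.  OR relationships are
deliberately not resolved — every isoenzyme stays a separate enzyme of
the same reaction.  Enzyme-complex stoichiometry is ignored (it is not
curated for most reconstructions).

Enzyme identifiers are canonical: the sorted member gene IDs joined by
``"&"``, so two reactions catalysed by the same complex share one
enzyme record.
"""

from __future__ import annotations

import ast
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

from .errors import GPRExpansionError, GPRParseError, InputError

__all__ = [
    "Reaction",
    "ReactionCatalog",
    "enzyme_id",
    "gpr_to_gene_sets",
    "catalog_from_rules",
    "load_model",
]

#: Hard cap on DNF clauses per reaction; nested GPRs can blow up
#: exponentially and real reconstructions stay far below this.
DEFAULT_MAX_CLAUSES = 256


class Reaction(NamedTuple):
    id: str
    subsystem: str
    enzyme_ids: tuple[str, ...]


def enzyme_id(genes: Iterable[str]) -> str:
    """Canonical enzyme identifier: sorted gene IDs joined by ``&``."""
    return "&".join(sorted(genes))


def _dnf(node: ast.AST, cap: int, context: str) -> list[frozenset[str]]:
    if isinstance(node, ast.Name):
        return [frozenset([node.id])]
    if isinstance(node, ast.BoolOp):
        parts = [_dnf(v, cap, context) for v in node.values]
        if isinstance(node.op, ast.Or):
            clauses = [c for part in parts for c in part]
        else:  # AND distributes over the children's clause lists
            clauses = [frozenset()]
            for part in parts:
                clauses = [a | b for a in clauses for b in part]
                if len(clauses) > cap:
                    raise GPRExpansionError(
                        f"GPR of {context} expands to more than {cap} "
                        f"DNF clauses"
                    )
        if len(clauses) > cap:
            raise GPRExpansionError(
                f"GPR of {context} expands to more than {cap} DNF clauses"
            )
        seen: set[frozenset[str]] = set()
        out = []
        for c in clauses:
            if c not in seen:
                seen.add(c)
                out.append(c)
        return out
    raise GPRParseError(f"unsupported GPR syntax in {context}: {node!r}")


def gpr_to_gene_sets(
    rule: str, max_clauses: int = DEFAULT_MAX_CLAUSES, context: str = "rule"
) -> list[frozenset[str]]:
    """Expand a GPR rule string into its DNF clauses (one per enzyme).

    Returns an empty list for an empty rule.  Clause order follows the
    rule text; exact duplicate clauses are merged.  ``context`` names
    the reaction in error messages.
    """
    if rule is None or not rule.strip():
        return []
    try:
        from cobra.core.gene import GPR

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gpr = GPR.from_string(rule)
    except Exception as exc:  # pragma: no cover - cobra raises rarely
        raise GPRParseError(f"cannot parse GPR of {context}: {rule!r}") from exc
    if gpr.body is None:
        raise GPRParseError(f"cannot parse GPR of {context}: {rule!r}")
    return _dnf(gpr.body, max_clauses, context)


@dataclass
class ReactionCatalog:
    """Reactions, their enzymes (DNF clauses) and gene-free reactions."""

    reactions: list[Reaction]
    enzymes: dict[str, frozenset[str]]
    gene_free_reactions: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------
    def validate(self) -> None:
        seen_rids: set[str] = set()
        for rxn in self.reactions:
            if rxn.id in seen_rids:
                raise InputError(f"duplicate reaction id {rxn.id!r}")
            seen_rids.add(rxn.id)
            for eid in rxn.enzyme_ids:
                if eid not in self.enzymes:
                    raise InputError(
                        f"reaction {rxn.id} references unknown enzyme {eid}"
                    )
            if (len(rxn.enzyme_ids) == 0) != (rxn.id in self.gene_free_reactions):
                raise InputError(
                    f"reaction {rxn.id}: gene_free flag inconsistent with "
                    f"its enzyme list"
                )
        for eid, genes in self.enzymes.items():
            if not genes:
                raise InputError(f"enzyme {eid!r} has an empty gene set")
            if eid != enzyme_id(genes):
                raise InputError(f"enzyme id {eid!r} is not canonical")

    # -- views ------------------------------------------------------
    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for gs in self.enzymes.values():
            out |= gs
        return out

    def enzymes_to_reactions(self) -> dict[str, list[str]]:
        """Map each enzyme id to the reactions it catalyses."""
        out: dict[str, list[str]] = {eid: [] for eid in self.enzymes}
        for rxn in self.reactions:
            for eid in rxn.enzyme_ids:
                out[eid].append(rxn.id)
        return out

    def __iter__(self) -> Iterator[Reaction]:
        return iter(self.reactions)

    def __len__(self) -> int:
        return len(self.reactions)

    # -- serialization ----------------------------------------------
    def to_dict(self) -> dict:
        return {
            "reactions": [
                {"id": r.id, "subsystem": r.subsystem, "enzymes": list(r.enzyme_ids)}
                for r in self.reactions
            ],
            "enzymes": {eid: sorted(gs) for eid, gs in self.enzymes.items()},
            "gene_free_reactions": sorted(self.gene_free_reactions),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReactionCatalog":
        return cls(
            reactions=[
                Reaction(r["id"], r.get("subsystem", ""), tuple(r["enzymes"]))
                for r in d["reactions"]
            ],
            enzymes={eid: frozenset(gs) for eid, gs in d["enzymes"].items()},
            gene_free_reactions=set(d.get("gene_free_reactions", [])),
        )

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def to_model_json(self, path: str | Path, model_id: str = "model") -> None:
        """Write the catalog as a loadable JSON model (GPR rules
        reconstructed as OR-of-AND clauses)."""
        reactions = []
        for r in self.reactions:
            clauses = []
            for eid in r.enzyme_ids:
                genes = sorted(self.enzymes[eid])
                clause = " and ".join(genes)
                clauses.append(f"({clause})" if len(genes) > 1 else clause)
            reactions.append(
                {
                    "id": r.id,
                    "subsystem": r.subsystem,
                    "gene_reaction_rule": " or ".join(clauses),
                }
            )
        doc = {"id": model_id, "reactions": reactions}
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def load_json(cls, path: str | Path) -> "ReactionCatalog":
        return cls.from_dict(json.loads(Path(path).read_text()))


def catalog_from_rules(
    rules: Iterable[tuple[str, str, str]],
    max_clauses: int = DEFAULT_MAX_CLAUSES,
) -> ReactionCatalog:
    """Build a catalog from ``(reaction_id, subsystem, gpr_rule)`` triples."""
    reactions: list[Reaction] = []
    enzymes: dict[str, frozenset[str]] = {}
    gene_free: set[str] = set()
    for rid, subsystem, rule in rules:
        clauses = gpr_to_gene_sets(rule, max_clauses, context=f"reaction {rid}")
        eids = []
        for genes in clauses:
            eid = enzyme_id(genes)
            enzymes.setdefault(eid, genes)
            eids.append(eid)
        if not eids:
            gene_free.add(rid)
        reactions.append(Reaction(rid, subsystem or "", tuple(eids)))
    return ReactionCatalog(reactions, enzymes, gene_free)


def load_model(
    path: str | Path,
    format: str | None = None,
    max_clauses: int = DEFAULT_MAX_CLAUSES,
) -> ReactionCatalog:
    """Read a metabolic model and decompose its GPRs into enzymes.

    Parameters
    ----------
    path:
        SBML (level 3, FBC gene associations) or JSON model file.  The
        JSON dialect only needs ``{"reactions": [{"id", "subsystem",
        "gene_reaction_rule"}]}``; files written by cobrapy qualify.
    format:
        ``"sbml"`` or ``"json"``; inferred from the suffix when omitted.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        if suffix in {".xml", ".sbml"}:
            format = "sbml"
        elif suffix == ".json":
            format = "json"
        else:
            raise InputError(f"cannot infer model format from {path.name!r}")
    if format == "sbml":
        import cobra.io

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = cobra.io.read_sbml_model(str(path))
        triples = [
            (r.id, r.subsystem or "", r.gene_reaction_rule) for r in model.reactions
        ]
    elif format == "json":
        doc = json.loads(path.read_text())
        try:
            triples = [
                (r["id"], r.get("subsystem") or "", r.get("gene_reaction_rule", ""))
                for r in doc["reactions"]
            ]
        except (KeyError, TypeError) as exc:
            raise InputError(
                f"{path} is not a JSON model (needs reactions[].id and "
                f"gene_reaction_rule fields)"
            ) from exc
    else:
        raise InputError(f"unknown model format {format!r}")
    return catalog_from_rules(triples, max_clauses=max_clauses)
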