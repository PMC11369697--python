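"""Metabolic model and omics-table I/O.

Reads a documented subset of the BiGG JSON dialect (``metabolites``,
``reactions`` with stoichiometry/bounds/GPR/objective, ``genes``), parses
gene-protein-reaction (GPR) boolean rules into OR-of-ANDs normal form, and
maps protein abundances onto reactions.

Identifier conventions are the model's own: callers supplying external
interaction tables (STITCH-like scores, direct labels) must already use model
metabolite and gene ids.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Reaction",
    "MetabolicModel",
    "Condition",
    "GprError",
    "ModelValidationError",
    "parse_gpr",
    "gpr_is_active",
    "read_model",
    "write_model",
    "read_conditions",
    "write_conditions",
    "read_abundance",
    "write_abundance",
    "reaction_enzyme_abundance",
    "map_pairs_to_proteins",
]


class ModelValidationError(ValueError):
    """A model file parsed but violates a structural invariant."""


class GprError(ValueError):
    """Syntax error in a gene-protein-reaction rule."""


# ---------------------------------------------------------------------------
# GPR rules
# ---------------------------------------------------------------------------

_TOKEN = re.compile(r"\s*(\(|\)|\b[Aa][Nn][Dd]\b|\b[Oo][Rr]\b|[^\s()]+)")

# DNF: frozenset of AND-units, each unit a frozenset of gene ids.
Gpr = frozenset


def parse_gpr(rule: str) -> frozenset[frozenset[str]]:
    """Parse a boolean GPR rule into OR-of-ANDs normal form.

    Each element of the result is one enzyme unit (an AND of gene ids,
    i.e. a complex); alternative units are isozymes. The empty rule
    denotes a spontaneous reaction and parses to the empty set.

    >>> sorted(map(sorted, parse_gpr("(g1 and g2) or g3")))
    [['g1', 'g2'], ['g3']]
    """
    tokens: list[tuple[str, int]] = []
    pos = 0
    rule = rule or ""
    while pos < len(rule):
        m = _TOKEN.match(rule, pos)
        if m is None:  # only trailing whitespace remains
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    if not tokens:
        return frozenset()

    idx = 0

    def peek() -> str | None:
        return tokens[idx][0] if idx < len(tokens) else None

    def fail(msg: str) -> GprError:
        at = tokens[idx][1] if idx < len(tokens) else len(rule)
        return GprError(f"{msg} at position {at} in rule {rule!r}")

    def parse_or() -> frozenset[frozenset[str]]:
        nonlocal idx
        units = parse_and()
        while peek() is not None and peek().lower() == "or":
            idx += 1
            units = units | parse_and()
        return units

    def parse_and() -> frozenset[frozenset[str]]:
        nonlocal idx
        units = parse_atom()
        while peek() is not None and peek().lower() == "and":
            idx += 1
            rhs = parse_atom()
            # distribute: (A or B) and (C or D) -> AC or AD or BC or BD
            units = frozenset(u | v for u in units for v in rhs)
        return units

    def parse_atom() -> frozenset[frozenset[str]]:
        nonlocal idx
        tok = peek()
        if tok is None:
            raise fail("unexpected end of rule")
        if tok == "(":
            idx += 1
            inner = parse_or()
            if peek() != ")":
                raise fail("unbalanced parenthesis, expected ')'")
            idx += 1
            return inner
        if tok == ")" or tok.lower() in ("and", "or"):
            raise fail(f"unexpected token {tok!r}")
        idx += 1
        return frozenset({frozenset({tok})})

    result = parse_or()
    if idx != len(tokens):
        raise fail(f"stray token {tokens[idx][0]!r}")
    return result


def gpr_is_active(gpr: frozenset[frozenset[str]], knockouts: Iterable[str]) -> bool:
    """True iff at least one enzyme unit survives the knockouts.

    An empty GPR (spontaneous reaction) is always active.
    """
    ko = set(knockouts)
    if not gpr:
        return True
    return any(not (unit & ko) for unit in gpr)


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Reaction:
    id: str
    stoich: dict[str, float]
    lower_bound: float
    upper_bound: float
    gpr: str = ""
    objective_weight: float = 0.0

    @property
    def gpr_units(self) -> frozenset[frozenset[str]]:
        return parse_gpr(self.gpr)

    def genes(self) -> list[str]:
        seen: list[str] = []
        for unit in sorted(self.gpr_units, key=lambda u: sorted(u)):
            for g in sorted(unit):
                if g not in seen:
                    seen.append(g)
        return seen


@dataclass(frozen=True)
class MetabolicModel:
    """Stoichiometric model: metabolites, reactions, genes, GPR rules."""

    metabolites: tuple[tuple[str, str], ...]  # (id, compartment), file order
    reactions: tuple[Reaction, ...]
    genes: tuple[str, ...]
    id: str = "model"

    def __post_init__(self) -> None:
        met_ids = {m for m, _ in self.metabolites}
        if len(met_ids) != len(self.metabolites):
            raise ModelValidationError("duplicate metabolite ids")
        for m, comp in self.metabolites:
            if not comp:
                raise ModelValidationError(f"metabolite {m!r} has empty compartment")
        for rxn in self.reactions:
            for met in rxn.stoich:
                if met not in met_ids:
                    raise ModelValidationError(
                        f"reaction {rxn.id!r} references undeclared metabolite {met!r}"
                    )
            if rxn.lower_bound > rxn.upper_bound:
                raise ModelValidationError(
                    f"reaction {rxn.id!r}: lower_bound {rxn.lower_bound} > "
                    f"upper_bound {rxn.upper_bound}"
                )
        if not any(r.objective_weight != 0 for r in self.reactions):
            raise ModelValidationError("no reaction carries an objective weight")

    # -- lookups ----------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m for m, _ in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def compartments(self) -> list[str]:
        out: list[str] = []
        for _, c in self.metabolites:
            if c not in out:
                out.append(c)
        return out

    def compartment_of(self, met_id: str) -> str:
        for m, c in self.metabolites:
            if m == met_id:
                return c
        raise KeyError(met_id)

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    @property
    def biomass_id(self) -> str:
        for r in self.reactions:
            if r.objective_weight != 0:
                return r.id
        raise ModelValidationError("no objective reaction")

    def stoichiometric_matrix(self) -> pd.DataFrame:
        """Dense S (metabolite x reaction) as a DataFrame."""
        S = pd.DataFrame(
            0.0, index=self.metabolite_ids, columns=self.reaction_ids
        )
        for r in self.reactions:
            for met, coef in r.stoich.items():
                S.loc[met, r.id] = coef
        return S

    def with_reactions(self, reactions: Sequence[Reaction]) -> "MetabolicModel":
        return replace(self, reactions=tuple(reactions))


@dataclass(frozen=True)
class Condition:
    """One experimental condition: growth, uptake bounds, knockouts."""

    id: str
    growth_rate: float | None = None
    uptake_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    knockouts: frozenset[str] = frozenset()
    measured_flux_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.growth_rate is not None and self.growth_rate < 0:
            raise ValueError(f"condition {self.id!r}: negative growth rate")
        for name, bounds in (
            ("uptake_bounds", self.uptake_bounds),
            ("measured_flux_bounds", self.measured_flux_bounds),
        ):
            for rxn, (lb, ub) in bounds.items():
                if lb > ub:
                    raise ValueError(
                        f"condition {self.id!r}: {name}[{rxn!r}] has lb {lb} > ub {ub}"
                    )
        object.__setattr__(self, "knockouts", frozenset(self.knockouts))


# ---------------------------------------------------------------------------
# Model JSON (BiGG dialect subset)
# ---------------------------------------------------------------------------


def read_model(path: str | Path, dialect: str = "bigg-json") -> MetabolicModel:
    """Read a metabolic model from a BiGG-style JSON file.

    Supported subset: ``metabolites`` [{id, compartment}], ``reactions``
    [{id, metabolites, lower_bound, upper_bound, gene_reaction_rule,
    objective_coefficient}], optional ``genes`` [{id}] and model ``id``.
    Reaction and metabolite order is the file order.
    """
    if dialect != "bigg-json":
        raise ValueError(f"unsupported model dialect {dialect!r}")
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelValidationError(f"{path}: not valid JSON ({exc})") from exc

    try:
        mets = tuple((m["id"], m.get("compartment", "")) for m in doc["metabolites"])
    except (KeyError, TypeError) as exc:
        raise ModelValidationError(f"{path}: malformed metabolites record ({exc})") from exc
    rxns = []
    for rec in doc.get("reactions", []):
        try:
            rxns.append(
                Reaction(
                    id=rec["id"],
                    stoich={k: float(v) for k, v in rec["metabolites"].items()},
                    lower_bound=float(rec["lower_bound"]),
                    upper_bound=float(rec["upper_bound"]),
                    gpr=rec.get("gene_reaction_rule", "") or "",
                    objective_weight=float(rec.get("objective_coefficient", 0.0)),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ModelValidationError(
                f"{path}: malformed reaction record {rec.get('id', '?')!r} ({exc})"
            ) from exc
    genes = tuple(g["id"] for g in doc.get("genes", []))
    if not genes:
        seen: list[str] = []
        for r in rxns:
            for g in r.genes():
                if g not in seen:
                    seen.append(g)
        genes = tuple(seen)
    return MetabolicModel(
        metabolites=mets, reactions=tuple(rxns), genes=genes, id=doc.get("id", path.stem)
    )


def write_model(model: MetabolicModel, path: str | Path) -> None:
    doc = {
        "id": model.id,
        "metabolites": [
            {"id": m, "compartment": c} for m, c in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "metabolites": dict(r.stoich),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": r.gpr,
                "objective_coefficient": r.objective_weight,
            }
            for r in model.reactions
        ],
        "genes": [{"id": g} for g in model.genes],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


# ---------------------------------------------------------------------------
# Conditions JSON
# ---------------------------------------------------------------------------


def read_conditions(path: str | Path) -> list[Condition]:
    doc = json.loads(Path(path).read_text())
    conds = []
    for rec in doc:
        conds.append(
            Condition(
                id=rec["id"],
                growth_rate=rec.get("growth_rate"),
                uptake_bounds={
                    k: (float(v[0]), float(v[1]))
                    for k, v in rec.get("uptake_bounds", {}).items()
                },
                knockouts=frozenset(rec.get("knockouts", [])),
                measured_flux_bounds={
                    k: (float(v[0]), float(v[1]))
                    for k, v in rec.get("measured_flux_bounds", {}).items()
                },
            )
        )
    return conds


def write_conditions(conditions: Sequence[Condition], path: str | Path) -> None:
    doc = [
        {
            "id": c.id,
            "growth_rate": c.growth_rate,
            "uptake_bounds": {k: list(v) for k, v in sorted(c.uptake_bounds.items())},
            "knockouts": sorted(c.knockouts),
            "measured_flux_bounds": {
                k: list(v) for k, v in sorted(c.measured_flux_bounds.items())
            },
        }
        for c in conditions
    ]
    Path(path).write_text(json.dumps(doc, indent=1))


# ---------------------------------------------------------------------------
# Abundance tables (protein x condition TSV)
# ---------------------------------------------------------------------------


def read_abundance(path: str | Path) -> pd.DataFrame:
    """Protein-by-condition abundance table from TSV (first column = protein id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ValueError(f"{path}: negative abundance entries")
    return df


def write_abundance(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="protein")


# ---------------------------------------------------------------------------
# Protein abundance -> reaction-level enzyme abundance
# ---------------------------------------------------------------------------


def reaction_enzyme_abundance(
    model: MetabolicModel,
    abundance: pd.DataFrame,
    policy: str = "min-over-complex_sum-over-isozymes",
) -> pd.DataFrame:
    """Aggregate gene abundances to one enzyme abundance per reaction.

    Default policy follows the standard proteomics convention: a complex
    (AND-unit) is limited by its scarcest subunit (minimum); isozymes
    (alternative units) act in parallel (sum). Reactions without a GPR or
    with no measured gene in any unit are NaN and excluded downstream.
    """
    if policy != "min-over-complex_sum-over-isozymes":
        raise ValueError(f"unknown policy {policy!r}")
    conditions = list(abundance.columns)
    out = pd.DataFrame(np.nan, index=model.reaction_ids, columns=conditions)
    for rxn in model.reactions:
        units = rxn.gpr_units
        if not units:
            continue
        total = np.full(len(conditions), np.nan)
        for unit in units:
            members = sorted(unit)
            if any(g not in abundance.index for g in members):
                continue  # unmeasured subunit: complex abundance unknown
            unit_ab = abundance.loc[members].min(axis=0).to_numpy(dtype=float)
            total = np.where(np.isnan(total), unit_ab, total + unit_ab)
        out.loc[rxn.id] = total
    return out


def map_pairs_to_proteins(
    model: MetabolicModel,
    met_reaction_pairs: Iterable[tuple[str, str]],
) -> list[tuple[str, str, str]]:
    """Expand (metabolite, reaction) pairs to (metabolite, protein, reaction).

    One triple per gene in the reaction's GPR; reactions without a GPR emit
    nothing. Order is deterministic (input order, then sorted gene order).
    """
    rxn_by_id = {r.id: r for r in model.reactions}
    triples: list[tuple[str, str, str]] = []
    for met, rxn_id in met_reaction_pairs:
        rxn = rxn_by_id[rxn_id]
        for gene in rxn.genes():
            triples.append((met, gene, rxn_id))
    return triples
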