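"""Reaction knowledgebase: rules, constraints, enzymes, precedence, pathways.

A rule pack is a JSON document with top-level keys ``rules``, ``enzymes``,
``precedence``, ``pathways`` and ``records``. Each biotransformation rule
couples one SMIRKS reaction transform (atom-mapped reactant -> product)
with separately encoded applicability constraints: required or forbidden
SMARTS substructures, and simple property predicates (mass, logP, heavy
atom count). Precedence relations implement relative reasoning: when a
dominant rule applies to a substrate, its suppressed competitor
contributes no products for that substrate at that step.

Two fixture packs ship with the package (``human_gut`` and ``env``); the
format accommodates arbitrarily large packs.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, Field, ValidationError, field_validator
from rdkit import Chem
from rdkit.Chem import AllChem

from .chem import StandardMolecule

__all__ = [
    "Constraint",
    "BiotransformationRule",
    "PrecedenceRule",
    "Enzyme",
    "PathwayMapping",
    "BiotransformationRecord",
    "Knowledgebase",
    "SchemaError",
    "RuleCompileError",
    "CrossReferenceError",
    "load_rule_pack",
    "load_packaged_pack",
    "save_rule_pack",
    "rule_applies",
    "validate_knowledgebase",
]

BIOSYSTEMS = ("human", "gut", "env")


class SchemaError(ValueError):
    """Rule-pack document violates the schema; message carries the path."""


class RuleCompileError(ValueError):
    """A SMIRKS or SMARTS string in the pack failed to compile."""

    def __init__(self, rule_id: str, message: str):
        super().__init__(f"{rule_id}: {message}")
        self.rule_id = rule_id


class CrossReferenceError(ValueError):
    """A rule, enzyme or precedence entry references a missing id."""


class Constraint(BaseModel):
    """One applicability constraint attached to a rule (conjunctive)."""

    kind: Literal["smarts_required", "smarts_forbidden", "property_predicate"]
    smarts: Optional[str] = None
    property: Optional[Literal["mass", "alogp", "heavy_atom_count"]] = None
    comparator: Optional[Literal["le", "ge", "lt", "gt", "eq"]] = None
    threshold: Optional[float] = None

    @field_validator("threshold")
    @classmethod
    def _finite(cls, v):
        if v is not None and not (v == v and abs(v) != float("inf")):
            raise ValueError("threshold must be finite")
        return v

    def model_post_init(self, __context) -> None:
        if self.kind in ("smarts_required", "smarts_forbidden"):
            if not self.smarts:
                raise ValueError(f"{self.kind} constraint needs a smarts field")
        else:
            if self.property is None or self.comparator is None or self.threshold is None:
                raise ValueError("property_predicate needs property, comparator, threshold")

    def holds(self, mol: StandardMolecule) -> bool:
        if self.kind == "property_predicate":
            value = {
                "mass": mol.mono_mass,
                "alogp": mol.alogp,
                "heavy_atom_count": mol.mol.GetNumHeavyAtoms(),
            }[self.property]
            return {
                "le": value <= self.threshold,
                "ge": value >= self.threshold,
                "lt": value < self.threshold,
                "gt": value > self.threshold,
                "eq": value == self.threshold,
            }[self.comparator]
        pattern = _compile_smarts(self.smarts)
        matched = mol.mol.HasSubstructMatch(pattern)
        return matched if self.kind == "smarts_required" else not matched


class BiotransformationRule(BaseModel):
    """One SMIRKS transform with constraints, enzymes and scope."""

    id: str
    name: str
    smirks: str
    constraints: list[Constraint] = Field(default_factory=list)
    enzymes: list[str] = Field(default_factory=list)
    biosystems: list[Literal["human", "gut", "env"]]
    reaction_type: str
    priority_tier: int = Field(default=0, ge=0)
    # declared product-minus-substrate heavy-atom delta for the principal
    # product, used by mass-balance checks (None = unchecked)
    formula_delta: Optional[str] = None

    @field_validator("biosystems")
    @classmethod
    def _nonempty(cls, v):
        if not v:
            raise ValueError("biosystems must be non-empty")
        return v

    @property
    def reaction(self) -> AllChem.ChemicalReaction:
        return _compile_smirks(self.id, self.smirks)


class PrecedenceRule(BaseModel):
    """Relative-reasoning pair: *dominant* suppresses *suppressed*."""

    dominant: str
    suppressed: str
    biosystems: list[Literal["human", "gut", "env"]] = Field(
        default_factory=lambda: list(BIOSYSTEMS)
    )

    def model_post_init(self, __context) -> None:
        if self.dominant == self.suppressed:
            raise ValueError("a rule cannot take precedence over itself")


class Enzyme(BaseModel):
    id: str
    name: str
    ec_number: Optional[str] = None
    family: Optional[str] = None


class PathwayMapping(BaseModel):
    """A named pathway with member enzymes and chemical-class gates.

    ``class_smarts`` patterns define the chemical class routed through
    this pathway. If ``exclusive`` is true, molecules of the class may
    only undergo rules catalysed by the pathway's member enzymes.
    """

    name: str
    biosystem: Literal["human", "gut", "env"]
    enzymes: list[str] = Field(default_factory=list)
    class_smarts: list[str] = Field(default_factory=list)
    exclusive: bool = True


class BiotransformationRecord(BaseModel):
    """A curated, experimentally confirmed biotransformation."""

    substrate_inchikey: str
    substrate_smiles: str
    product_inchikeys: list[str] = Field(min_length=1)
    product_smiles: list[str] = Field(min_length=1)
    enzyme: str
    reaction_type: str
    citations: list[str] = Field(min_length=1)


class Knowledgebase(BaseModel):
    """A loaded, compiled, cross-reference-checked rule pack."""

    name: str = "unnamed"
    rules: list[BiotransformationRule] = Field(default_factory=list)
    enzymes: list[Enzyme] = Field(default_factory=list)
    precedence: list[PrecedenceRule] = Field(default_factory=list)
    pathways: list[PathwayMapping] = Field(default_factory=list)
    records: list[BiotransformationRecord] = Field(default_factory=list)
    config: dict = Field(default_factory=dict)

    def rule(self, rule_id: str) -> BiotransformationRule:
        for r in self.rules:
            if r.id == rule_id:
                return r
        raise KeyError(rule_id)

    def enzyme(self, enzyme_id: str) -> Enzyme:
        for e in self.enzymes:
            if e.id == enzyme_id:
                return e
        raise KeyError(enzyme_id)

    def rules_for(self, biosystem: str | None = None,
                  reaction_types: set[str] | None = None) -> list[BiotransformationRule]:
        out = []
        for r in self.rules:
            if biosystem is not None and biosystem not in r.biosystems:
                continue
            if reaction_types is not None and r.reaction_type not in reaction_types:
                continue
            out.append(r)
        return sorted(out, key=lambda r: r.id)

    def precedence_for(self, biosystem: str | None = None) -> list[PrecedenceRule]:
        if biosystem is None:
            return list(self.precedence)
        return [p for p in self.precedence if biosystem in p.biosystems]


@lru_cache(maxsize=4096)
def _compile_smarts(smarts: str) -> Chem.Mol:
    patt = Chem.MolFromSmarts(smarts)
    if patt is None:
        raise ValueError(f"SMARTS does not compile: {smarts!r}")
    return patt


@lru_cache(maxsize=1024)
def _compile_smirks(rule_id: str, smirks: str) -> AllChem.ChemicalReaction:
    try:
        rxn = AllChem.ReactionFromSmarts(smirks)
    except Exception as exc:
        raise RuleCompileError(rule_id, f"SMIRKS does not compile: {exc}") from exc
    if rxn is None or rxn.GetNumReactantTemplates() != 1:
        raise RuleCompileError(rule_id, "SMIRKS must have exactly one reactant template")
    mapped = sum(
        1
        for a in rxn.GetReactantTemplate(0).GetAtoms()
        if a.GetAtomMapNum() > 0
    )
    if mapped < 1:
        raise RuleCompileError(rule_id, "SMIRKS has no mapped atoms")
    rxn.Initialize()
    return rxn


def _compile_and_check(kb: Knowledgebase) -> None:
    enzyme_ids = {e.id for e in kb.enzymes}
    if len(enzyme_ids) != len(kb.enzymes):
        raise SchemaError("/enzymes: duplicate enzyme ids")
    rule_ids = {r.id for r in kb.rules}
    if len(rule_ids) != len(kb.rules):
        raise SchemaError("/rules: duplicate rule ids")

    for r in kb.rules:
        _compile_smirks(r.id, r.smirks)
        for c in r.constraints:
            if c.smarts is not None:
                try:
                    _compile_smarts(c.smarts)
                except ValueError as exc:
                    raise RuleCompileError(r.id, str(exc)) from exc
        for ez in r.enzymes:
            if ez not in enzyme_ids:
                raise CrossReferenceError(f"rule {r.id!r} references unknown enzyme {ez!r}")
    for p in kb.precedence:
        for rid in (p.dominant, p.suppressed):
            if rid not in rule_ids:
                raise CrossReferenceError(f"precedence references unknown rule {rid!r}")
    for pw in kb.pathways:
        for ez in pw.enzymes:
            if ez not in enzyme_ids:
                raise CrossReferenceError(
                    f"pathway {pw.name!r} references unknown enzyme {ez!r}"
                )
        for s in pw.class_smarts:
            _compile_smarts(s)


def load_rule_pack(path: str | Path) -> Knowledgebase:
    """Load, validate and compile a rule-pack JSON document."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"/: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict):
        raise SchemaError("/: rule pack must be a JSON object")
    try:
        kb = Knowledgebase.model_validate(doc)
    except ValidationError as exc:
        first = exc.errors()[0]
        pointer = "/" + "/".join(str(p) for p in first["loc"])
        raise SchemaError(f"{pointer}: {first['msg']}") from exc
    _compile_and_check(kb)
    return kb


def load_packaged_pack(name: str) -> Knowledgebase:
    """Load one of the packs shipped with the package (``human_gut``, ``env``)."""
    ref = resources.files("xenometab.data") / f"{name}.json"
    with resources.as_file(ref) as path:
        return load_rule_pack(path)


def save_rule_pack(kb: Knowledgebase, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(kb.model_dump(exclude_none=True), indent=2, sort_keys=True) + "\n")
    return path


def rule_applies(mol: StandardMolecule, rule: BiotransformationRule) -> bool:
    """True iff the rule's reactant pattern matches and all constraints hold."""
    template = rule.reaction.GetReactantTemplate(0)
    if not mol.mol.HasSubstructMatch(template):
        return False
    return all(c.holds(mol) for c in rule.constraints)


def _precedence_cycles(kb: Knowledgebase) -> list[list[str]]:
    graph: dict[str, set[str]] = {}
    for p in kb.precedence:
        graph.setdefault(p.dominant, set()).add(p.suppressed)
    cycles: list[list[str]] = []
    seen_cycles: set[frozenset[str]] = set()

    def dfs(node: str, stack: list[str]) -> None:
        for nxt in sorted(graph.get(node, ())):
            if nxt in stack:
                cyc = stack[stack.index(nxt):] + [nxt]
                key = frozenset(cyc)
                if key not in seen_cycles:
                    seen_cycles.add(key)
                    cycles.append(cyc)
            else:
                dfs(nxt, stack + [nxt])

    for start in sorted(graph):
        dfs(start, [start])
    return cycles


def validate_knowledgebase(kb: Knowledgebase) -> list[dict]:
    """Lint a loaded pack; returns a list of issue dicts (empty = clean).

    Checks: precedence cycles, enzymes attached to zero rules, and rules
    with no biosystem overlap with any pathway/module scope (never
    selectable).
    """
    issues: list[dict] = []
    for cyc in _precedence_cycles(kb):
        issues.append({
            "kind": "precedence_cycle",
            "detail": " > ".join(cyc),
        })
    used_enzymes = {ez for r in kb.rules for ez in r.enzymes}
    used_enzymes |= {ez for pw in kb.pathways for ez in pw.enzymes}
    for e in sorted(kb.enzymes, key=lambda e: e.id):
        if e.id not in used_enzymes:
            issues.append({"kind": "orphan_enzyme", "detail": e.id})
    return issues
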