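"""Rule application, relative reasoning and metabolic-tree construction.

The engine applies SMIRKS transforms at every matching site of a
substrate, standardizes and deduplicates the products by InChIKey, then
prunes the candidate set by relative reasoning: a precedence pair A > B
removes every candidate produced by rule B whenever rule A is applicable
to the same substrate at the same step. Multi-step prediction is a
breadth-first expansion with a global visited set, so a metabolite is
expanded at most once no matter how many parents converge on it.

Absolute reasoning is a threshold over per-rule priority tiers; every
packaged rule sits in tier 0 with the same likelihood, so the default
threshold accepts everything. The hook is kept for packs that carry
informative scores.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

from rdkit import Chem

from .chem import StandardMolecule, StructureError, standardize
from .kb import (
    BiotransformationRule,
    Knowledgebase,
    PrecedenceRule,
    rule_applies,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Biotransformation",
    "MetabolicTree",
    "TreeEdge",
    "ParameterError",
    "ReasoningError",
    "MAX_STEPS_CAP",
    "apply_rule",
    "candidate_biotransformations",
    "filter_by_precedence",
    "predict_tree",
]

MAX_STEPS_CAP = 12  # hard cap on multi-step expansion depth


class ParameterError(ValueError):
    """An engine parameter is out of its allowed range."""


class ReasoningError(RuntimeError):
    """Relative reasoning could not reach a fixpoint (precedence cycle)."""


@dataclass(frozen=True)
class Biotransformation:
    """One applied reaction event: substrate -> one or more products."""

    substrate_inchikey: str
    products: tuple[StandardMolecule, ...]
    rule_id: str
    enzymes: tuple[str, ...]
    biosystem: str
    step: int = 1

    def __post_init__(self):
        if not self.products:
            raise ValueError("a biotransformation must have at least one product")
        if any(p.inchikey == self.substrate_inchikey for p in self.products):
            raise ValueError("a product cannot equal the substrate")


@dataclass(frozen=True)
class TreeEdge:
    parent: str  # InChIKey
    child: str  # InChIKey
    rule_id: str
    rule_name: str
    enzymes: tuple[str, ...]
    biosystem: str
    step: int
    reaction_type: str = ""


@dataclass
class MetabolicTree:
    """Rooted multi-parent graph of metabolites with edge provenance."""

    root: StandardMolecule
    nodes: dict[str, StandardMolecule] = field(default_factory=dict)
    edges: list[TreeEdge] = field(default_factory=list)

    def __post_init__(self):
        self.nodes.setdefault(self.root.inchikey, self.root)

    @property
    def metabolites(self) -> list[StandardMolecule]:
        """All non-root nodes, sorted by (first step reached, InChIKey)."""
        first_step: dict[str, int] = {}
        for e in self.edges:
            first_step[e.child] = min(first_step.get(e.child, e.step), e.step)
        keys = sorted(
            (k for k in self.nodes if k != self.root.inchikey),
            key=lambda k: (first_step.get(k, 0), k),
        )
        return [self.nodes[k] for k in keys]

    def parents_of(self, inchikey: str) -> list[TreeEdge]:
        return [e for e in self.edges if e.child == inchikey]

    def add(self, parent_key: str, transformation: Biotransformation,
            rule_name: str = "", reaction_type: str = "") -> None:
        for product in transformation.products:
            self.nodes.setdefault(product.inchikey, product)
            edge = TreeEdge(
                parent=parent_key,
                child=product.inchikey,
                rule_id=transformation.rule_id,
                rule_name=rule_name or transformation.rule_id,
                enzymes=transformation.enzymes,
                biosystem=transformation.biosystem,
                step=transformation.step,
                reaction_type=reaction_type,
            )
            if edge not in self.edges:
                self.edges.append(edge)

    def sort(self) -> None:
        self.edges.sort(key=lambda e: (e.step, e.rule_id, e.parent, e.child))

    def pathway_to(self, inchikey: str) -> list[TreeEdge]:
        """Shortest provenance chain from the root to a node.

        Follows, at each node, the incoming edge with the smallest step
        index (ties broken by rule id) — deterministic and minimal.
        """
        path: list[TreeEdge] = []
        key = inchikey
        guard = 0
        while key != self.root.inchikey:
            incoming = sorted(
                self.parents_of(key), key=lambda e: (e.step, e.rule_id, e.parent)
            )
            if not incoming:
                raise KeyError(f"{inchikey} not reachable from root")
            edge = incoming[0]
            path.append(edge)
            key = edge.parent
            guard += 1
            if guard > len(self.edges) + 1:
                raise ReasoningError("cycle in tree edges")
        return list(reversed(path))

    def to_json(self) -> str:
        doc = {
            "root": self.root.inchikey,
            "nodes": [
                {
                    "inchikey": k,
                    "smiles": m.smiles,
                    "formula": m.formula,
                    "mono_mass": m.mono_mass,
                }
                for k, m in sorted(self.nodes.items())
            ],
            "edges": [
                {
                    "parent": e.parent,
                    "child": e.child,
                    "rule_id": e.rule_id,
                    "rule_name": e.rule_name,
                    "enzymes": list(e.enzymes),
                    "biosystem": e.biosystem,
                    "step": e.step,
                    "reaction_type": e.reaction_type,
                }
                for e in sorted(
                    self.edges, key=lambda e: (e.step, e.rule_id, e.parent, e.child)
                )
            ],
        }
        return json.dumps(doc, indent=2, sort_keys=True)


def apply_rule(
    mol: StandardMolecule,
    rule: BiotransformationRule,
    step: int = 1,
    min_heavy_atoms: int = 2,
) -> Biotransformation | None:
    """Apply one rule at every matching site of the substrate.

    Every embedding of the reactant pattern is transformed; all product
    fragments with at least ``min_heavy_atoms`` heavy atoms are kept
    (cleavage co-products included), standardized, and deduplicated by
    InChIKey across sites. Products identical to the substrate are
    dropped; unsanitizable site products are skipped with a warning.
    Returns None when nothing survives.
    """
    if not rule_applies(mol, rule):
        return None
    products: dict[str, StandardMolecule] = {}
    for site_products in rule.reaction.RunReactants((mol.mol,)):
        for raw in site_products:
            try:
                frag = Chem.Mol(raw)
                Chem.SanitizeMol(frag)
            except Exception as exc:
                logger.warning(
                    "rule %s on %s: unsanitizable site product skipped (%s)",
                    rule.id, mol.inchikey, exc,
                )
                continue
            if frag.GetNumHeavyAtoms() < min_heavy_atoms:
                continue
            try:
                std = standardize(frag)
            except StructureError as exc:
                logger.warning(
                    "rule %s on %s: product rejected in standardization (%s)",
                    rule.id, mol.inchikey, exc,
                )
                continue
            if std.inchikey == mol.inchikey:
                continue
            products.setdefault(std.inchikey, std)
    if not products:
        return None
    ordered = tuple(products[k] for k in sorted(products))
    return Biotransformation(
        substrate_inchikey=mol.inchikey,
        products=ordered,
        rule_id=rule.id,
        enzymes=tuple(rule.enzymes),
        biosystem=rule.biosystems[0],
        step=step,
    )


def _pathway_gate(
    mol: StandardMolecule, kb: Knowledgebase, rules: Sequence[BiotransformationRule]
) -> list[BiotransformationRule]:
    """Restrict class-gated molecules to their pathway's rules.

    If the molecule matches the chemical-class SMARTS of an exclusive
    pathway, only rules catalysed by that pathway's member enzymes remain
    eligible (e.g. glycerophospholipids route solely through
    glycerophospholipid metabolism, never conjugation).
    """
    from .kb import _compile_smarts

    allowed_enzymes: set[str] | None = None
    for pw in kb.pathways:
        if not pw.exclusive or not pw.class_smarts:
            continue
        if any(mol.mol.HasSubstructMatch(_compile_smarts(s)) for s in pw.class_smarts):
            allowed = set(pw.enzymes)
            allowed_enzymes = allowed if allowed_enzymes is None else allowed_enzymes | allowed
    if allowed_enzymes is None:
        return list(rules)
    return [r for r in rules if set(r.enzymes) & allowed_enzymes]


def filter_by_precedence(
    candidates: Sequence[Biotransformation],
    precedence: Sequence[PrecedenceRule],
) -> list[Biotransformation]:
    """Relative reasoning over one substrate's one-step candidates.

    For every pair (dominant > suppressed): if the dominant rule applies
    to the substrate (i.e. produced a candidate), candidates of the
    suppressed rule are removed. Suppression keys on applicability, not
    on survival, so chains (A > B, B > C) suppress transitively: B is
    removed because A applies, and C is removed because B applies.
    """
    applicable = {c.rule_id for c in candidates}
    active = [
        p for p in precedence
        if p.dominant in applicable and p.suppressed in applicable
    ]
    # a cycle among co-applicable rules would suppress every member;
    # that is a pack defect the loader normally rejects
    graph: dict[str, set[str]] = {}
    for p in active:
        graph.setdefault(p.dominant, set()).add(p.suppressed)

    def _reaches(start: str, goal: str, seen: set[str]) -> bool:
        for nxt in graph.get(start, ()):
            if nxt == goal or (nxt not in seen and _reaches(nxt, goal, seen | {nxt})):
                return True
        return False

    for node in graph:
        if _reaches(node, node, {node}):
            raise ReasoningError("precedence cycle among co-applicable rules")

    drop = {p.suppressed for p in active}
    retained = [c for c in candidates if c.rule_id not in drop]
    return sorted(retained, key=lambda c: (c.rule_id, c.products[0].inchikey))


def candidate_biotransformations(
    mol: StandardMolecule,
    kb: Knowledgebase,
    rules: Sequence[BiotransformationRule] | None = None,
    precedence: Sequence[PrecedenceRule] | None = None,
    step: int = 1,
    tier_threshold: int | None = None,
) -> list[Biotransformation]:
    """All retained biotransformations of one substrate at one step.

    Applies every eligible rule (after the chemical-class pathway gate and
    the absolute-reasoning tier threshold), then prunes by relative
    reasoning. Output is deterministically ordered by (rule id, first
    product InChIKey).
    """
    if rules is None:
        rules = kb.rules
    if precedence is None:
        precedence = kb.precedence
    eligible = _pathway_gate(mol, kb, rules)
    if tier_threshold is not None:
        eligible = [r for r in eligible if r.priority_tier <= tier_threshold]
    candidates = []
    for rule in sorted(eligible, key=lambda r: r.id):
        bt = apply_rule(mol, rule, step=step)
        if bt is not None:
            candidates.append(bt)
    return filter_by_precedence(candidates, precedence)


def predict_tree(
    mol: StandardMolecule,
    kb: Knowledgebase,
    nsteps: int = 1,
    rules: Sequence[BiotransformationRule] | None = None,
    precedence: Sequence[PrecedenceRule] | None = None,
) -> MetabolicTree:
    """Breadth-first multi-step expansion into a metabolic tree.

    Each round expands only the molecules first produced in the previous
    round; a molecule is never expanded twice (visited set on InChIKey).
    Convergent products gain an additional parent edge rather than a
    duplicate node.
    """
    if nsteps < 0:
        raise ParameterError("nsteps must be >= 0")
    cap = int(kb.config.get("max_steps_cap", MAX_STEPS_CAP))
    if nsteps > cap:
        raise ParameterError(f"nsteps {nsteps} exceeds the configured cap of {cap}")
    tree = MetabolicTree(root=mol)
    expanded: set[str] = set()
    frontier = [mol]
    for step in range(1, nsteps + 1):
        next_frontier: list[StandardMolecule] = []
        for substrate in sorted(frontier, key=lambda m: m.inchikey):
            if substrate.inchikey in expanded:
                continue
            expanded.add(substrate.inchikey)
            for bt in candidate_biotransformations(
                substrate, kb, rules=rules, precedence=precedence, step=step
            ):
                known_before = set(tree.nodes)
                rule = kb.rule(bt.rule_id)
                tree.add(substrate.inchikey, bt, rule_name=rule.name,
                         reaction_type=rule.reaction_type)
                for product in bt.products:
                    if product.inchikey not in known_before and product.inchikey not in expanded:
                        next_frontier.append(product)
        frontier = next_frontier
        if not frontier:
            break
    tree.sort()
    return tree
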