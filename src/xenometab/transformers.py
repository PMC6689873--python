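"""The five metabolism prediction modules and the human super-transformers.

Module ids (also the CLI option strings, case-sensitive):

``ecbased``
    EC-classified (non-CYP450) enzymatic reactions: hydrolases such as
    carboxylesterases, epoxide hydrolases and phospholipases.
``cyp450``
    CYP450 (phase I) oxidative metabolism, gated by the CYP substrate
    pre-filter and its pluggable reactivity classifier.
``phaseII``
    Conjugation (glucuronidation, sulfation, methylation, acetylation),
    gated by the rule-based phase II pre-filter and, when supplied, the
    trained substrate classifier.
``hgut``
    Human gut microbial metabolism (deconjugation, demethylation,
    reductive reactions).
``envmicro``
    Environmental microbial degradation (separate rule pack and
    precedence set).
``allHuman``
    The union of the four human-related modules at every step.
``superbio``
    A fixed 12-slot ordered pipeline over the human modules, opening
    with hydrolysis (when applicable) and closing with conjugation;
    conjugates are terminal and are not expanded further.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .chem import StandardMolecule
from .filters import cyp_prefilter, phase2_prefilter, predict_phase2
from .kb import BiotransformationRule, Knowledgebase, load_packaged_pack
from .reasoning import (
    MAX_STEPS_CAP,
    Biotransformation,
    MetabolicTree,
    ParameterError,
    candidate_biotransformations,
    predict_tree,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MODULE_IDS",
    "HUMAN_MODULE_IDS",
    "SUPERBIO_SLOTS",
    "TransformerConfig",
    "run_module",
    "run_allhuman",
    "run_superbio",
    "run_env",
    "default_packs",
]

HUMAN_MODULE_IDS = ("ecbased", "cyp450", "phaseII", "hgut")
MODULE_IDS = HUMAN_MODULE_IDS + ("envmicro", "allHuman", "superbio")

# enzyme families selecting each single module's rule subset
_MODULE_FAMILIES = {
    "ecbased": {"CES", "EH", "PL"},
    "cyp450": {"CYP450"},
    "phaseII": {"UGT", "SULT", "MT", "NAT"},
}
_CONJUGATION_TYPES = {"glucuronidation", "sulfation", "methylation", "acetylation"}

# Ordered superbio pipeline: (slot index, module id, reaction-type
# restriction or None). Opens with hydrolysis, passes through oxidative
# and gut slots, and closes with one round of each conjugation chemistry.
SUPERBIO_SLOTS: tuple[tuple[int, str, frozenset[str] | None], ...] = (
    (1, "ecbased", frozenset({"hydrolysis"})),
    (2, "hgut", frozenset({"deconjugation"})),
    (3, "hgut", frozenset({"reduction", "ring_cleavage"})),
    (4, "ecbased", frozenset({"oxidation"})),
    (5, "cyp450", None),
    (6, "ecbased", None),
    (7, "cyp450", None),
    (8, "hgut", None),
    (9, "ecbased", None),
    (10, "phaseII", frozenset({"methylation", "acetylation"})),
    (11, "phaseII", frozenset({"sulfation"})),
    (12, "phaseII", frozenset({"glucuronidation"})),
)


@dataclass(frozen=True)
class TransformerConfig:
    """Binding of a module id to its rule subset, filters and parameters."""

    module_id: str
    default_steps: int = 1
    cyp_classifier: object | None = None
    phase2_classifier: object | None = None
    phase2_threshold: float = 0.5

    def __post_init__(self):
        if self.module_id not in MODULE_IDS:
            raise ParameterError(f"unknown module id {self.module_id!r}")


_PACK_CACHE: dict[str, Knowledgebase] = {}


def default_packs() -> dict[str, Knowledgebase]:
    """The packaged human/gut and environmental rule packs (cached)."""
    if not _PACK_CACHE:
        _PACK_CACHE["human_gut"] = load_packaged_pack("human_gut")
        _PACK_CACHE["env"] = load_packaged_pack("env")
    return dict(_PACK_CACHE)


def module_rules(
    kb: Knowledgebase, module_id: str,
    reaction_types: frozenset[str] | None = None,
) -> list[BiotransformationRule]:
    """The rule subset a single module draws from."""
    if module_id == "envmicro":
        rules = kb.rules_for(biosystem="env")
    elif module_id == "hgut":
        rules = kb.rules_for(biosystem="gut")
    elif module_id in _MODULE_FAMILIES:
        families = _MODULE_FAMILIES[module_id]
        enzyme_family = {e.id: (e.family or "") for e in kb.enzymes}
        rules = [
            r
            for r in kb.rules_for(biosystem="human")
            if any(enzyme_family.get(ez) in families for ez in r.enzymes)
        ]
    else:
        raise ParameterError(f"unknown module id {module_id!r}")
    if reaction_types is not None:
        rules = [r for r in rules if r.reaction_type in reaction_types]
    return sorted(rules, key=lambda r: r.id)


def _substrate_allowed(
    mol: StandardMolecule, module_id: str, config: TransformerConfig | None
) -> tuple[bool, str]:
    config = config or TransformerConfig(module_id)
    if module_id == "cyp450":
        decision = cyp_prefilter(mol, classifier=config.cyp_classifier)
        if not decision.eligible:
            return False, decision.reason
        if decision.reactivity is not None and not any(decision.reactivity.values()):
            return False, "no CYP450 isozyme predicted reactive"
    elif module_id == "phaseII":
        if not phase2_prefilter(mol):
            return False, "rejected by phase II rule-based pre-filter"
        if config.phase2_classifier is not None:
            prob = predict_phase2(mol, config.phase2_classifier)
            if prob < config.phase2_threshold:
                return False, f"phase II classifier probability {prob:.3f} below threshold"
    return True, ""


def run_module(
    mol: StandardMolecule,
    module_id: str,
    nsteps: int = 1,
    kb: Knowledgebase | None = None,
    config: TransformerConfig | None = None,
) -> MetabolicTree:
    """Run one single-module prediction for ``nsteps`` steps.

    The cyp450 and phaseII modules consult their substrate filters first;
    a filtered-out substrate yields a root-only tree with the reason
    logged.
    """
    if module_id == "allHuman":
        return run_allhuman(mol, nsteps, kb=kb, config=config)
    if module_id == "superbio":
        return run_superbio(mol, kb=kb, config=config)
    if module_id == "envmicro":
        return run_env(mol, nsteps, kb=kb)
    if module_id not in HUMAN_MODULE_IDS:
        raise ParameterError(f"unknown module id {module_id!r}")
    kb = kb or default_packs()["human_gut"]
    ok, reason = _substrate_allowed(mol, module_id, config)
    if not ok:
        logger.info("substrate %s filtered out of %s: %s", mol.inchikey, module_id, reason)
        return MetabolicTree(root=mol)
    scope = "gut" if module_id == "hgut" else "human"
    return predict_tree(
        mol, kb, nsteps=nsteps,
        rules=module_rules(kb, module_id),
        precedence=kb.precedence_for(scope),
    )


def _human_step_candidates(
    substrate: StandardMolecule,
    kb: Knowledgebase,
    step: int,
    config: TransformerConfig | None,
    slots: Sequence[tuple[str, frozenset[str] | None]] | None = None,
) -> list[tuple[Biotransformation, str]]:
    """Union of per-module candidates for one substrate at one step.

    Each module is gated by its own substrate filter; relative reasoning
    runs over the pooled candidate set so cross-module precedence (e.g.
    gut deconjugation over demethylation) still applies.
    """
    from .reasoning import filter_by_precedence

    if slots is None:
        slots = [(m, None) for m in HUMAN_MODULE_IDS]
    pooled: dict[tuple[str, tuple[str, ...]], tuple[Biotransformation, str]] = {}
    for module_id, rtypes in slots:
        ok, _reason = _substrate_allowed(substrate, module_id, config)
        if not ok:
            continue
        scope = "gut" if module_id == "hgut" else "human"
        for bt in candidate_biotransformations(
            substrate, kb,
            rules=module_rules(kb, module_id, reaction_types=rtypes),
            precedence=kb.precedence_for(scope),
            step=step,
        ):
            key = (bt.rule_id, tuple(p.inchikey for p in bt.products))
            pooled.setdefault(key, (bt, module_id))
    merged = filter_by_precedence([bt for bt, _ in pooled.values()], kb.precedence)
    by_key = {
        (bt.rule_id, tuple(p.inchikey for p in bt.products)): mod
        for (bt, mod) in pooled.values()
    }
    return [
        (bt, by_key[(bt.rule_id, tuple(p.inchikey for p in bt.products))])
        for bt in merged
    ]


def run_allhuman(
    mol: StandardMolecule,
    nsteps: int = 1,
    kb: Knowledgebase | None = None,
    config: TransformerConfig | None = None,
) -> MetabolicTree:
    """All four human modules at every step, deduplicated by InChIKey."""
    if nsteps < 0:
        raise ParameterError("nsteps must be >= 0")
    kb = kb or default_packs()["human_gut"]
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
            for bt, _module in _human_step_candidates(substrate, kb, step, config):
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


def run_superbio(
    mol: StandardMolecule,
    kb: Knowledgebase | None = None,
    config: TransformerConfig | None = None,
    max_slots: int | None = None,
) -> MetabolicTree:
    """Ordered 12-slot human pipeline; conjugates are terminal.

    Each slot applies one module (optionally restricted to certain
    reaction types) to every non-terminal metabolite currently in the
    tree; step indices record the slot number, so the depth never exceeds
    12. Conjugation products (slots 10-12) are not expanded further —
    a single conjugation round closes the pipeline.
    """
    kb = kb or default_packs()["human_gut"]
    tree = MetabolicTree(root=mol)
    terminal: set[str] = set()
    done: set[tuple[int, str]] = set()
    slots = SUPERBIO_SLOTS if max_slots is None else SUPERBIO_SLOTS[:max_slots]
    for slot_index, module_id, rtypes in slots:
        substrates = [
            tree.nodes[k] for k in sorted(tree.nodes) if k not in terminal
        ]
        for substrate in substrates:
            if (slot_index, substrate.inchikey) in done:
                continue
            done.add((slot_index, substrate.inchikey))
            for bt, _module in _human_step_candidates(
                substrate, kb, slot_index, config, slots=[(module_id, rtypes)]
            ):
                bt = Biotransformation(
                    substrate_inchikey=bt.substrate_inchikey,
                    products=bt.products,
                    rule_id=bt.rule_id,
                    enzymes=bt.enzymes,
                    biosystem=bt.biosystem,
                    step=slot_index,
                )
                rule = kb.rule(bt.rule_id)
                tree.add(substrate.inchikey, bt, rule_name=rule.name,
                         reaction_type=rule.reaction_type)
                if rule.reaction_type in _CONJUGATION_TYPES:
                    terminal.update(p.inchikey for p in bt.products)
    tree.sort()
    return tree


def run_env(
    mol: StandardMolecule,
    nsteps: int = 1,
    kb: Knowledgebase | None = None,
) -> MetabolicTree:
    """Environmental microbial degradation with its own precedence set."""
    kb = kb or default_packs()["env"]
    return predict_tree(
        mol, kb, nsteps=nsteps,
        rules=kb.rules_for(biosystem="env"),
        precedence=kb.precedence_for("env"),
    )
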