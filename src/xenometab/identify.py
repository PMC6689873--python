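"""MS-driven metabolite identification.

Given a parent compound and a list of target neutral monoisotopic masses
(or molecular formulas), the identifier expands the metabolic tree one
step at a time under a chosen scope (``allHuman``, ``superbio`` or
``envmicro``), checks each round's new metabolites against all
still-unmatched targets, and stops as soon as every target has at least
one match or the step budget is exhausted. Positive-mode [M+H]+ ion m/z
values are converted to neutral masses by subtracting the protonation
offset of 1.00727 Da.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from rdkit import Chem

from .chem import StandardMolecule
from .kb import Knowledgebase
from .reasoning import MetabolicTree, TreeEdge
from .transformers import (
    SUPERBIO_SLOTS,
    run_allhuman,
    run_env,
    run_superbio,
)

__all__ = [
    "PROTON_OFFSET_DA",
    "DEFAULT_MASS_TOLERANCE_DA",
    "DEFAULT_MAX_STEPS",
    "IdentificationQuery",
    "IdentificationMatch",
    "IdentificationResult",
    "neutral_mass_from_ion",
    "identify",
    "write_identification",
]

# offset between a positive-mode protonated molecular ion and the neutral
PROTON_OFFSET_DA = 1.00727
DEFAULT_MASS_TOLERANCE_DA = 0.01
DEFAULT_MAX_STEPS = 1

IDENTIFY_SCOPES = ("allHuman", "superbio", "envmicro")


def neutral_mass_from_ion(mz: float, adduct: str = "[M+H]+") -> float:
    """Neutral monoisotopic mass of a protonated molecular ion."""
    if adduct != "[M+H]+":
        raise ValueError(f"unsupported adduct {adduct!r}; only [M+H]+ is handled")
    if mz <= PROTON_OFFSET_DA:
        raise ValueError(f"m/z {mz} is not above the proton offset {PROTON_OFFSET_DA}")
    return mz - PROTON_OFFSET_DA


@dataclass(frozen=True)
class IdentificationQuery:
    start: StandardMolecule
    masses: tuple[float, ...] = ()
    formulas: tuple[str, ...] = ()
    tolerance: float = DEFAULT_MASS_TOLERANCE_DA
    max_steps: int = DEFAULT_MAX_STEPS
    scope: str = "allHuman"

    def __post_init__(self):
        if not self.masses and not self.formulas:
            raise ValueError("at least one mass or formula target is required")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.scope not in IDENTIFY_SCOPES:
            raise ValueError(
                f"scope must be one of {IDENTIFY_SCOPES}, got {self.scope!r}"
            )


@dataclass(frozen=True)
class IdentificationMatch:
    metabolite: StandardMolecule
    pathway: tuple[TreeEdge, ...]
    step_count: int
    delta: float  # observed minus target mass (0.0 for formula targets)


@dataclass
class IdentificationResult:
    query: IdentificationQuery
    matches: dict[str, list[IdentificationMatch]] = field(default_factory=dict)
    tree: MetabolicTree | None = None

    def target_labels(self) -> list[str]:
        return list(self.matches)


def _target_label(value: float | str) -> str:
    return f"{value:.5f}" if isinstance(value, float) else str(value)


def _expand(query: IdentificationQuery, steps: int, kb: Knowledgebase | None) -> MetabolicTree:
    if query.scope == "allHuman":
        return run_allhuman(query.start, nsteps=steps, kb=kb)
    if query.scope == "superbio":
        return run_superbio(query.start, kb=kb, max_slots=steps)
    return run_env(query.start, nsteps=steps, kb=kb)


def identify(query: IdentificationQuery, kb: Knowledgebase | None = None) -> IdentificationResult:
    """Search predicted metabolites for the query's mass/formula targets.

    Expansion proceeds round by round (for ``superbio``, slot by slot)
    and stops early once every target has at least one match; all
    isobaric matches found up to and including that round are reported.
    The parent molecule itself is never counted as a match. Unmatched
    targets yield empty lists.
    """
    mass_targets = [(_target_label(m), float(m)) for m in query.masses]
    formula_targets = [(_target_label(f), str(f)) for f in query.formulas]
    result = IdentificationResult(query=query)
    for label, _ in mass_targets + formula_targets:
        result.matches[label] = []

    seen: set[str] = {query.start.inchikey}
    tree = MetabolicTree(root=query.start)
    for step in range(1, query.max_steps + 1):
        tree = _expand(query, step, kb)
        new_keys = sorted(k for k in tree.nodes if k not in seen)
        seen.update(new_keys)
        for key in new_keys:
            metabolite = tree.nodes[key]
            pathway = tuple(tree.pathway_to(key))
            for label, target_mass in mass_targets:
                if abs(metabolite.mono_mass - target_mass) <= query.tolerance:
                    result.matches[label].append(
                        IdentificationMatch(
                            metabolite=metabolite,
                            pathway=pathway,
                            step_count=len(pathway),
                            delta=round(metabolite.mono_mass - target_mass, 5),
                        )
                    )
            for label, formula in formula_targets:
                if metabolite.formula == formula:
                    result.matches[label].append(
                        IdentificationMatch(
                            metabolite=metabolite,
                            pathway=pathway,
                            step_count=len(pathway),
                            delta=0.0,
                        )
                    )
        if all(result.matches[label] for label, _ in mass_targets + formula_targets):
            break
    result.tree = tree
    for label in result.matches:
        result.matches[label].sort(
            key=lambda m: (m.step_count, m.metabolite.inchikey)
        )
    return result


def write_identification(result: IdentificationResult, path: str | Path) -> Path:
    """Write matched metabolites to SDF, one record per match.

    The pathway is stored as a numbered data field with one
    ``reaction name [enzyme1; enzyme2]`` line per step, in step order.
    Deterministic: records sorted by (target label, step count, InChIKey).
    """
    path = Path(path)
    writer = Chem.SDWriter(str(path))
    try:
        for label in sorted(result.matches):
            for match in result.matches[label]:
                mol = Chem.MolFromSmiles(match.metabolite.smiles)
                if mol is None:
                    continue
                mol.SetProp("_Name", match.metabolite.inchikey)
                mol.SetProp("Target", label)
                mol.SetProp("InChI", match.metabolite.inchi)
                mol.SetProp("InChIKey", match.metabolite.inchikey)
                mol.SetProp("Molecular formula", match.metabolite.formula)
                mol.SetProp("Monoisotopic mass", f"{match.metabolite.mono_mass:.5f}")
                mol.SetProp("Mass delta", f"{match.delta:+.5f}")
                mol.SetProp("Steps", str(match.step_count))
                pathway_lines = [
                    f"{i + 1}. {edge.rule_name} [{'; '.join(edge.enzymes)}]"
                    for i, edge in enumerate(match.pathway)
                ]
                mol.SetProp("Pathway", "\n".join(pathway_lines))
                writer.write(mol)
    finally:
        writer.close()
    return path
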