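"""Annotation assembly: metabolic tree -> annotated metabolite records.

Each predicted metabolite is annotated with nine groups of information:
(1) three chemical identifiers (metabolite ID, InChI, InChIKey), (2) the
molecular formula, (3) the monoisotopic mass, (4) the reaction type that
produced it, (5) the biosystem, (6) the parent compound identifiers,
(7) the parent monoisotopic mass, (8) the metabolite's and parent's
ALogP, and (9) the metabolite's and parent's synonyms (populated from a
small offline name table; empty when unknown).

Metabolite IDs are deterministic: ``BTM`` + a zero-padded ordinal
assigned by sorted traversal (root first, then metabolites ordered by
first step reached and InChIKey), so identical inputs always produce
identical IDs.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

from .reasoning import MetabolicTree

__all__ = ["ANNOTATION_COLUMNS", "annotate_tree", "synonyms_for"]

ANNOTATION_COLUMNS = [
    "metabolite_id",
    "smiles",
    "inchi",
    "inchikey",
    "molecular_formula",
    "monoisotopic_mass",
    "reaction",
    "reaction_type",
    "biosystem",
    "step",
    "enzymes",
    "parent_id",
    "parent_inchikey",
    "parent_monoisotopic_mass",
    "alogp",
    "parent_alogp",
    "synonyms",
]


@lru_cache(maxsize=1)
def _synonym_table() -> dict[str, list[str]]:
    ref = resources.files("xenometab.data") / "synonyms.json"
    return json.loads(ref.read_text())


def synonyms_for(inchikey: str) -> list[str]:
    return list(_synonym_table().get(inchikey, []))


def annotate_tree(tree: MetabolicTree, include_root: bool = True) -> list[dict]:
    """Flatten a metabolic tree into annotated records (one per node).

    Convergent metabolites (several parents) are reported once, under the
    provenance of their minimal pathway; all parents remain available in
    the tree's edge list.
    """
    ordering = [tree.root] + tree.metabolites
    ids = {m.inchikey: f"BTM{i:05d}" for i, m in enumerate(ordering)}
    records: list[dict] = []
    for mol in ordering:
        is_root = mol.inchikey == tree.root.inchikey
        if is_root and not include_root:
            continue
        if is_root:
            edge = None
        else:
            edge = tree.pathway_to(mol.inchikey)[-1]
        parent = tree.nodes[edge.parent] if edge else None
        records.append({
            "metabolite_id": ids[mol.inchikey],
            "smiles": mol.smiles,
            "inchi": mol.inchi,
            "inchikey": mol.inchikey,
            "molecular_formula": mol.formula,
            "monoisotopic_mass": f"{mol.mono_mass:.5f}",
            "reaction": edge.rule_name if edge else "",
            "reaction_type": edge.reaction_type if edge else "",
            "biosystem": edge.biosystem if edge else "",
            "step": edge.step if edge else 0,
            "enzymes": "; ".join(edge.enzymes) if edge else "",
            "parent_id": ids[parent.inchikey] if parent else "",
            "parent_inchikey": parent.inchikey if parent else "",
            "parent_monoisotopic_mass": f"{parent.mono_mass:.5f}" if parent else "",
            "alogp": f"{mol.alogp:.4f}",
            "parent_alogp": f"{parent.alogp:.4f}" if parent else "",
            "synonyms": "; ".join(synonyms_for(mol.inchikey)),
        })
    return records
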