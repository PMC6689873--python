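"""Deterministic fixture molecules and expected-product manifests.

Every packaged rule is covered by at least one positive fixture
substrate; negative controls match no rule in any module. Expected
products are computed by a deliberately naive brute-force oracle that
enumerates every embedding of a rule's reactant pattern, transforms it,
and deduplicates by InChIKey — independent of the reasoning engine's own
application path, so the two can be compared in tests.

``random_fixture_smiles`` assembles small drug-like molecules from a
seeded grammar of scaffolds and substituents for property-based checks.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from rdkit import Chem

from .chem import StandardMolecule, standardize
from .kb import BiotransformationRule, Knowledgebase

__all__ = [
    "FIXTURE_MOLECULES",
    "NEGATIVE_CONTROLS",
    "FixtureMolecule",
    "enumerate_products_bruteforce",
    "generate_fixtures",
    "random_fixture_smiles",
]


@dataclass(frozen=True)
class FixtureMolecule:
    name: str
    smiles: str
    # rule ids this molecule is a positive substrate for (constraint-aware)
    rule_ids: tuple[str, ...]
    pack: str = "human_gut"


# Positive fixtures: each packaged rule appears in >=1 entry.
FIXTURE_MOLECULES: tuple[FixtureMolecule, ...] = (
    FixtureMolecule("benzene", "c1ccccc1", ("aromatic_hydroxylation",)),
    FixtureMolecule("toluene", "Cc1ccccc1",
                    ("aromatic_hydroxylation", "benzylic_hydroxylation")),
    FixtureMolecule("phenol", "Oc1ccccc1",
                    ("aromatic_hydroxylation", "o_glucuronidation", "o_sulfation")),
    FixtureMolecule("catechol", "Oc1ccccc1O",
                    ("aromatic_hydroxylation", "catechol_o_methylation",
                     "o_glucuronidation", "o_sulfation",
                     "gut_catechol_dehydroxylation")),
    FixtureMolecule("aniline", "Nc1ccccc1",
                    ("aromatic_hydroxylation", "aromatic_n_acetylation")),
    FixtureMolecule("acetaminophen", "CC(=O)Nc1ccc(O)cc1",
                    ("aromatic_hydroxylation", "quinone_imine_formation",
                     "o_glucuronidation", "o_sulfation")),
    FixtureMolecule("n_methylpiperidine", "CN1CCCCC1",
                    ("n_demethylation_alicyclic",)),
    FixtureMolecule("parathion_analogue", "CCOP(=S)(OCC)Oc1ccc([N+](=O)[O-])cc1",
                    ("phosphorothioate_o_dearylation", "oxidative_desulfurization",
                     "aromatic_hydroxylation")),
    FixtureMolecule("ethyl_benzoate", "CCOC(=O)c1ccccc1",
                    ("ester_hydrolysis", "aromatic_hydroxylation")),
    FixtureMolecule("styrene_oxide", "C1OC1c1ccccc1",
                    ("epoxide_hydrolysis", "aromatic_hydroxylation")),
    FixtureMolecule("glyceryl_mixed_triester", "CC(=O)OCC(COC(=O)CCC)OC(=O)CC",
                    ("ester_hydrolysis",)),
    FixtureMolecule("short_chain_pc",
                    "CC(=O)OCC(COP(=O)(O)OCCN)OC(=O)C",
                    ("glycerophospholipid_hydrolysis", "ester_hydrolysis")),
    FixtureMolecule("phenyl_glucoside", "OCC1OC(Oc2ccccc2)C(O)C(O)C1O",
                    ("gut_o_deglycosylation", "o_glucuronidation",
                     "o_sulfation", "aromatic_hydroxylation")),
    FixtureMolecule("anisole", "COc1ccccc1",
                    ("gut_o_demethylation", "aromatic_hydroxylation")),
    FixtureMolecule(
        "kaempferol_dimethyl_ether_glucoside",
        "COc1ccc(-c2oc3cc(OC)cc(O)c3c(=O)c2OC2OC(CO)C(O)C(O)C2O)cc1",
        ("gut_o_deglycosylation", "gut_o_demethylation",
         "o_glucuronidation", "o_sulfation"),
    ),
    FixtureMolecule(
        "kaempferol_dimethyl_ether",
        "COc1ccc(-c2oc3cc(OC)cc(O)c3c(=O)c2O)cc1",
        ("gut_o_demethylation_c7", "gut_o_demethylation",
         "o_glucuronidation", "o_sulfation"),
    ),
    FixtureMolecule("epicatechin", "Oc1cc(O)c2c(c1)OC(c1ccc(O)c(O)c1)C(O)C2",
                    ("o_glucuronidation", "o_sulfation", "catechol_o_methylation",
                     "gut_catechol_dehydroxylation", "aromatic_hydroxylation")),
    # environmental pack substrates
    FixtureMolecule("env_triester", "CC(=O)OCC(COC(=O)CCC)OC(=O)CC",
                    ("env_ester_cleavage",), pack="env"),
    FixtureMolecule("env_nitrobenzene", "O=[N+]([O-])c1ccccc1",
                    ("env_nitro_reduction", "env_aromatic_hydroxylation"),
                    pack="env"),
    FixtureMolecule("env_parathion_analogue",
                    "CCOP(=S)(OCC)Oc1ccc([N+](=O)[O-])cc1",
                    ("env_phosphorothioate_hydrolysis", "env_nitro_reduction",
                     "env_aromatic_hydroxylation"), pack="env"),
)

# match no packaged rule in any module
NEGATIVE_CONTROLS: tuple[FixtureMolecule, ...] = (
    FixtureMolecule("neopentane", "CC(C)(C)C", ()),
    FixtureMolecule("cyclohexane", "C1CCCCC1", ()),
    FixtureMolecule("perfluoroethane", "FC(F)(F)C(F)(F)F", ()),
)


def enumerate_products_bruteforce(
    mol: StandardMolecule, rule: BiotransformationRule, min_heavy_atoms: int = 2
) -> set[str]:
    """Naive oracle: run the SMIRKS at all embeddings, dedup by InChIKey.

    Constraint gating mirrors the rule contract (all required SMARTS
    match, no forbidden SMARTS, all predicates hold); the transform and
    bookkeeping are done directly on RDKit primitives with no shared code
    path with :func:`xenometab.reasoning.apply_rule`.
    """
    for c in rule.constraints:
        if not c.holds(mol):
            return set()
    rxn = rule.reaction
    if not mol.mol.HasSubstructMatch(rxn.GetReactantTemplate(0)):
        return set()
    keys: set[str] = set()
    for embedding in rxn.RunReactants((mol.mol,)):
        for product in embedding:
            try:
                Chem.SanitizeMol(product)
            except Exception:
                continue
            if product.GetNumHeavyAtoms() < min_heavy_atoms:
                continue
            try:
                std = standardize(product)
            except Exception:
                continue
            if std.inchikey != mol.inchikey:
                keys.add(std.inchikey)
    return keys


def generate_fixtures(seed: int, kb_by_pack: dict[str, Knowledgebase]) -> dict:
    """Deterministic fixture set with expected-product manifests.

    Returns ``{"molecules": [...], "negatives": [...], "manifest":
    {(name, rule_id): sorted InChIKeys}}``; identical for identical
    seeds. The seed feeds only the randomized molecule battery appended
    under ``"random"``.
    """
    manifest: dict[tuple[str, str], tuple[str, ...]] = {}
    for fixture in FIXTURE_MOLECULES:
        kb = kb_by_pack[fixture.pack]
        mol = standardize(fixture.smiles, label=fixture.name)
        for rule_id in fixture.rule_ids:
            keys = enumerate_products_bruteforce(mol, kb.rule(rule_id))
            manifest[(fixture.name, rule_id)] = tuple(sorted(keys))
    return {
        "molecules": list(FIXTURE_MOLECULES),
        "negatives": list(NEGATIVE_CONTROLS),
        "manifest": manifest,
        "random": random_fixture_smiles(seed),
    }


_SCAFFOLDS = (
    "c1ccccc1{0}",
    "c1ccc(O)cc1{0}",
    "c1ccncc1{0}",
    "C1CCCCC1{0}",
    "c1ccc2ccccc2c1{0}",
    "c1ccc(N)cc1{0}",
)
_SUBSTITUENTS = ("", "C", "CC", "O", "OC", "N", "C(=O)OC", "C(=O)O", "CO", "C=C")


def random_fixture_smiles(seed: int, n: int = 100) -> list[str]:
    """``n`` small valid molecules assembled from a seeded grammar."""
    rng = random.Random(seed)
    out: list[str] = []
    while len(out) < n:
        scaffold = rng.choice(_SCAFFOLDS)
        sub = rng.choice(_SUBSTITUENTS)
        smi = scaffold.format(sub)
        if Chem.MolFromSmiles(smi) is not None:
            out.append(smi)
    return out
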