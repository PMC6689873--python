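"""Substrate-eligibility filters for the CYP450 and phase II modules.

The CYP450 filter is a heuristic pre-screen: inorganic structures and a
configurable list of excluded chemical classes (glycerolipids,
glycerophospholipids) are out of scope, and a pluggable reactivity
classifier assigns per-isozyme reactivity over the nine major CYP450s.
The default classifier is permissive (every isozyme reactive) so that the
rule engine alone decides; a trained model can be plugged in through the
same interface.

The phase II filter has two stages. A rule-based pre-filter rejects five
excluded lipid/cofactor classes, molecules heavier than 900 Da, and
molecules carrying none of the 64 conjugatable structural motifs shipped
with the package. An optional machine-learning stage then classifies the
survivors with a random forest over a 32-descriptor feature vector: nine
constitutional descriptors and 23 binary structural flags, including the
canonical amine and carboxyl SMARTS.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Callable, Protocol, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

from .chem import StandardMolecule

__all__ = [
    "CYP_ISOZYMES",
    "PHASE2_MASS_LIMIT_DA",
    "AMINE_SMARTS",
    "CARBOXYL_SMARTS",
    "CypFilterDecision",
    "CypReactivityClassifier",
    "PermissiveCypClassifier",
    "TrainingError",
    "cyp_prefilter",
    "phase2_prefilter",
    "phase2_features",
    "phase2_feature_names",
    "phase2_motifs",
    "train_phase2_model",
    "predict_phase2",
    "evaluate_phase2_model",
]

CYP_ISOZYMES = (
    "1A2", "2A6", "2B6", "2C8", "2C9", "2C18/2C19", "2D6", "2E1", "3A4",
)

PHASE2_MASS_LIMIT_DA = 900.0

# canonical structural-flag patterns for the phase II featurizer
AMINE_SMARTS = "[NX3+0,NX4+;!$([N]~[!#6]);!$([N]*~[#7,#8,#15,#16])]"
CARBOXYL_SMARTS = "[#8;A;X2H1,X1-][#6]([#6,#1;A])=O"


class TrainingError(ValueError):
    """The training set cannot support fitting (e.g. a single class)."""


@dataclass(frozen=True)
class CypFilterDecision:
    eligible: bool
    reason: str = ""
    reactivity: dict[str, bool] | None = None

    def __post_init__(self):
        if not self.eligible and not self.reason:
            raise ValueError("ineligible decisions must carry a reason")


class CypReactivityClassifier(Protocol):
    """Interface for per-isozyme CYP450 reactivity prediction."""

    def predict(self, mol: StandardMolecule) -> dict[str, bool]: ...


class PermissiveCypClassifier:
    """Default reactivity model: every isozyme is considered reactive."""

    def predict(self, mol: StandardMolecule) -> dict[str, bool]:
        return {iso: True for iso in CYP_ISOZYMES}


@lru_cache(maxsize=1)
def _excluded_classes() -> dict:
    ref = resources.files("xenometab.data") / "excluded_classes.json"
    return json.loads(ref.read_text())


@lru_cache(maxsize=1)
def phase2_motifs() -> list[dict]:
    """The packaged 64-entry conjugatable-motif SMARTS list."""
    ref = resources.files("xenometab.data") / "phase2_motifs.json"
    return json.loads(ref.read_text())["motifs"]


@lru_cache(maxsize=256)
def _patt(smarts: str) -> Chem.Mol:
    p = Chem.MolFromSmarts(smarts)
    if p is None:
        raise ValueError(f"SMARTS does not compile: {smarts!r}")
    return p


def _matches_class(mol: StandardMolecule, class_name: str) -> bool:
    smarts = _excluded_classes()["classes"][class_name]
    return mol.mol.HasSubstructMatch(_patt(smarts))


def cyp_prefilter(
    mol: StandardMolecule,
    classifier: CypReactivityClassifier | None = None,
) -> CypFilterDecision:
    """Heuristic CYP450 substrate screen plus pluggable reactivity model."""
    if not any(a.GetAtomicNum() == 6 for a in mol.mol.GetAtoms()):
        return CypFilterDecision(False, "inorganic: no carbon atom")
    # CO2, carbonate-style one-carbon oxides are treated as inorganic
    if mol.mol.GetNumHeavyAtoms() <= 3 and all(
        a.GetAtomicNum() in (6, 8) for a in mol.mol.GetAtoms()
    ) and not any(b.GetBondType() == Chem.BondType.SINGLE
                  and b.GetBeginAtom().GetAtomicNum() == 6
                  and b.GetEndAtom().GetAtomicNum() == 6
                  for b in mol.mol.GetBonds()):
        if sum(a.GetAtomicNum() == 6 for a in mol.mol.GetAtoms()) == 1:
            return CypFilterDecision(False, "inorganic: simple carbon oxide")
    for cls in _excluded_classes()["cyp_excluded"]:
        if _matches_class(mol, cls):
            return CypFilterDecision(False, f"excluded chemical class: {cls}")
    clf = classifier or PermissiveCypClassifier()
    return CypFilterDecision(True, "", clf.predict(mol))


def phase2_prefilter(mol: StandardMolecule) -> bool:
    """Rule-based phase II substrate pre-screen.

    Rejects the five excluded classes (ether lipids, glycerolipids,
    glycerophospholipids, sphingolipids, acyl-CoA conjugates), molecules
    above 900 Da, and molecules with none of the 64 packaged motifs.
    """
    for cls in _excluded_classes()["phase2_excluded"]:
        if _matches_class(mol, cls):
            return False
    if mol.mono_mass > PHASE2_MASS_LIMIT_DA:
        return False
    return any(
        mol.mol.HasSubstructMatch(_patt(m["smarts"])) for m in phase2_motifs()
    )


# ---------------------------------------------------------------------------
# 32-descriptor featurizer: 9 constitutional + 23 binary structural flags

_CONSTITUTIONAL: tuple[tuple[str, Callable], ...] = (
    ("mono_mass", lambda m: Descriptors.ExactMolWt(m)),
    ("alogp", lambda m: Crippen.MolLogP(m)),
    ("hbond_donors", lambda m: rdMolDescriptors.CalcNumHBD(m)),
    ("hbond_acceptors", lambda m: rdMolDescriptors.CalcNumHBA(m)),
    ("rotatable_bonds", lambda m: rdMolDescriptors.CalcNumRotatableBonds(m)),
    ("heavy_atoms", lambda m: m.GetNumHeavyAtoms()),
    ("rings", lambda m: rdMolDescriptors.CalcNumRings(m)),
    ("aromatic_rings", lambda m: rdMolDescriptors.CalcNumAromaticRings(m)),
    ("tpsa", lambda m: rdMolDescriptors.CalcTPSA(m)),
)

# 23 binary flags; the amine and carboxyl patterns are the canonical ones
_STRUCTURAL_FLAGS: tuple[tuple[str, str], ...] = (
    ("amine", AMINE_SMARTS),
    ("carboxyl", CARBOXYL_SMARTS),
    ("aliphatic_hydroxyl", "[CX4][OX2H1]"),
    ("phenol", "[c][OX2H1]"),
    ("catechol", "[OX2H1][c][c][OX2H1]"),
    ("thiol", "[#6][SX2H1]"),
    ("aromatic_amine", "[c][NX3;H2,H1]"),
    ("amide", "[CX3](=[OX1])[NX3]"),
    ("ester", "[CX3](=O)[OX2][#6]"),
    ("ketone", "[#6][CX3](=O)[#6]"),
    ("aldehyde", "[CX3H1](=O)[#6]"),
    ("ether", "[#6][OX2][#6]"),
    ("n_heterocycle", "[n]"),
    ("o_heterocycle", "[o]"),
    ("s_heterocycle", "[s]"),
    ("nitro", "[NX3+](=O)[O-]"),
    ("nitrile", "[CX2]#[NX1]"),
    ("halogen", "[F,Cl,Br,I]"),
    ("alkene", "[CX3]=[CX3]"),
    ("sulfonamide", "[SX4](=O)(=O)[NX3]"),
    ("carbamate", "[NX3][CX3](=[OX1])[OX2][#6]"),
    ("urea", "[NX3][CX3](=[OX1])[NX3]"),
    ("aromatic_ring", "c1ccccc1"),
)

N_CONSTITUTIONAL = len(_CONSTITUTIONAL)
N_FLAGS = len(_STRUCTURAL_FLAGS)
assert N_CONSTITUTIONAL == 9 and N_FLAGS == 23


def phase2_feature_names() -> list[str]:
    return [n for n, _ in _CONSTITUTIONAL] + [n for n, _ in _STRUCTURAL_FLAGS]


def phase2_features(mol: StandardMolecule) -> np.ndarray:
    """Deterministic 32-vector: 9 constitutional values + 23 binary flags."""
    # rounded so additive descriptors are invariant to atom ordering
    values = [round(float(fn(mol.mol)), 6) for _, fn in _CONSTITUTIONAL]
    flags = [
        1.0 if mol.mol.HasSubstructMatch(_patt(s)) else 0.0
        for _, s in _STRUCTURAL_FLAGS
    ]
    return np.asarray(values + flags, dtype=float)


# ---------------------------------------------------------------------------
# random-forest harness

def train_phase2_model(
    molecules: Sequence[StandardMolecule],
    labels: Sequence[int],
    seed: int = 0,
    n_estimators: int = 200,
):
    """Fit the phase II substrate random forest over the 32 descriptors."""
    from sklearn.ensemble import RandomForestClassifier

    y = np.asarray(labels, dtype=int)
    if len(set(y.tolist())) < 2:
        raise TrainingError("training set must contain both classes")
    X = np.vstack([phase2_features(m) for m in molecules])
    clf = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    )
    clf.fit(X, y)
    return clf


def predict_phase2(mol: StandardMolecule, classifier) -> float:
    """Probability that the molecule is a phase II substrate."""
    X = phase2_features(mol).reshape(1, -1)
    return float(classifier.predict_proba(X)[0, 1])


def evaluate_phase2_model(
    molecules: Sequence[StandardMolecule],
    labels: Sequence[int],
    seed: int = 0,
    n_splits: int = 10,
    n_estimators: int = 200,
) -> dict[str, float]:
    """10-fold cross-validated weighted F1 and ROC area for the harness."""
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.metrics import f1_score, roc_auc_score
    from sklearn.model_selection import StratifiedKFold

    y = np.asarray(labels, dtype=int)
    if len(set(y.tolist())) < 2:
        raise TrainingError("evaluation set must contain both classes")
    X = np.vstack([phase2_features(m) for m in molecules])
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    y_pred = np.zeros_like(y, dtype=int)
    y_prob = np.zeros(len(y), dtype=float)
    for train_idx, test_idx in skf.split(X, y):
        clf = RandomForestClassifier(
            n_estimators=n_estimators, random_state=seed, n_jobs=1
        )
        clf.fit(X[train_idx], y[train_idx])
        y_pred[test_idx] = clf.predict(X[test_idx])
        y_prob[test_idx] = clf.predict_proba(X[test_idx])[:, 1]
    return {
        "weighted_f1": float(f1_score(y, y_pred, average="weighted")),
        "roc_auc": float(roc_auc_score(y, y_prob)),
    }
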