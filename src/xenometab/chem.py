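"""Molecule parsing, validation, standardization and structure I/O.

Every other part of the package works on :class:`StandardMolecule` objects:
single-fragment organic structures whose charges have been neutralized
(with a short exception list of groups that are legitimately charge
separated, such as nitro), with identifiers and basic physicochemical
properties computed once at construction.

Structure identity throughout the package is the full standard InChIKey.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "StandardMolecule",
    "RawStructure",
    "ParseIssue",
    "StructureError",
    "MixtureRejected",
    "InorganicRejected",
    "InvalidStructure",
    "FormulaError",
    "parse_input",
    "standardize",
    "monoisotopic_mass",
    "write_structures",
]


class StructureError(ValueError):
    """Base class for structure validation failures."""


class MixtureRejected(StructureError):
    """Input contained more than one connected component (mixture/salt)."""


class InorganicRejected(StructureError):
    """Input contained no carbon atom."""


class InvalidStructure(StructureError):
    """Structure could not be sanitized (e.g. impossible valence)."""


class FormulaError(ValueError):
    """Molecular formula could not be interpreted."""


@dataclass(frozen=True)
class RawStructure:
    """An as-parsed structure prior to standardization."""

    mol: Chem.Mol
    label: str = ""
    index: int = 0

    @property
    def heavy_atom_count(self) -> int:
        return self.mol.GetNumHeavyAtoms()


@dataclass(frozen=True)
class ParseIssue:
    """A per-record parse failure inside a batch input."""

    index: int
    message: str


@dataclass(frozen=True)
class StandardMolecule:
    """A validated, standardized single-fragment organic structure.

    Attributes
    ----------
    mol:
        RDKit molecule with perceived aromaticity, implicit hydrogens.
    smiles, inchi, inchikey:
        Canonical identifiers; ``inchikey`` is the deduplication key used
        everywhere in the package.
    formula:
        Hill-order molecular formula.
    mono_mass:
        Monoisotopic (most-abundant-isotope) mass in Da.
    alogp:
        Crippen logP estimate (unitless).
    label:
        Optional user-supplied name carried through from the input.
    """

    mol: Chem.Mol = field(compare=False, repr=False)
    smiles: str
    inchi: str = field(compare=False)
    inchikey: str
    formula: str
    mono_mass: float
    alogp: float = field(compare=False)
    label: str = field(default="", compare=False)

    def __hash__(self) -> int:  # identity is the InChIKey
        return hash(self.inchikey)

    def relabel(self, label: str) -> "StandardMolecule":
        return StandardMolecule(
            mol=self.mol, smiles=self.smiles, inchi=self.inchi,
            inchikey=self.inchikey, formula=self.formula,
            mono_mass=self.mono_mass, alogp=self.alogp, label=label,
        )


_FORMATS = ("smiles", "inchi", "mol", "sdf")


def _infer_format(source: str) -> str:
    p = source.lower()
    if p.endswith(".sdf"):
        return "sdf"
    if p.endswith(".mol"):
        return "mol"
    if source.startswith("InChI="):
        return "inchi"
    return "smiles"


def parse_input(
    source: str | Path,
    format: str | None = None,
) -> tuple[list[RawStructure], list[ParseIssue]]:
    """Parse one or more structures from a string or file.

    ``source`` is a SMILES string, an InChI string, a MOL/SDF file path, or
    raw MOL-block text. SDF files may hold multiple records; unparseable
    records are reported as :class:`ParseIssue` entries (with their record
    index) without aborting the batch. Record order is preserved.
    """
    src = str(source)
    fmt = (format or _infer_format(src)).lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unknown input format {fmt!r}")

    structures: list[RawStructure] = []
    issues: list[ParseIssue] = []

    if fmt == "smiles":
        text = Path(src).read_text() if Path(src).is_file() else src
        records = [ln for ln in text.splitlines() if ln.strip()] or ([] if not text.strip() else [text])
        if not records and text.strip():
            records = [text.strip()]
        for i, line in enumerate(records):
            parts = line.split(maxsplit=1)
            mol = Chem.MolFromSmiles(parts[0])
            if mol is None:
                issues.append(ParseIssue(i, f"unparseable SMILES: {parts[0]!r}"))
                continue
            label = parts[1].strip() if len(parts) > 1 else ""
            structures.append(RawStructure(mol=mol, label=label, index=i))
    elif fmt == "inchi":
        text = Path(src).read_text().strip() if Path(src).is_file() else src
        mol = Chem.MolFromInchi(text)
        if mol is None:
            issues.append(ParseIssue(0, f"unparseable InChI: {text!r}"))
        else:
            structures.append(RawStructure(mol=mol, index=0))
    elif fmt == "mol":
        block = Path(src).read_text() if Path(src).is_file() else src
        mol = Chem.MolFromMolBlock(block)
        if mol is None:
            issues.append(ParseIssue(0, "unparseable MOL block"))
        else:
            name = block.splitlines()[0].strip() if block.splitlines() else ""
            structures.append(RawStructure(mol=mol, label=name, index=0))
    else:  # sdf
        supplier = Chem.SDMolSupplier(src, sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                issues.append(ParseIssue(i, f"unparseable SDF record {i}"))
                continue
            label = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
            structures.append(RawStructure(mol=mol, label=label, index=i))
    return structures, issues


# Charge-separated groups that standardization must not "fix". The RDKit
# Uncharger already refuses to break balanced zwitterionic motifs such as
# nitro, N-oxides and quaternary ammonium centres; the patterns are kept
# explicit so the policy is inspectable and testable.
NEUTRALIZATION_EXEMPT_SMARTS: dict[str, str] = {
    "nitro": "[NX3+](=O)[O-]",
    "n_oxide": "[NX4+][O-]",
    "quaternary_ammonium": "[NX4+;!$([NX4+][O-])]",
}

_uncharger = rdMolStandardize.Uncharger()


def standardize(raw: RawStructure | Chem.Mol | str, label: str | None = None) -> StandardMolecule:
    """Validate and standardize a raw structure.

    Steps: reject mixtures (multi-fragment inputs) and carbon-free
    structures; neutralize charged functional groups except the exempt
    list (nitro, N-oxide, quaternary ammonium); sanitize (valence check,
    aromaticity perception); compute identifiers, Hill formula,
    monoisotopic mass and Crippen logP. Stereochemistry present in the
    input is preserved. Idempotent by InChIKey.
    """
    if isinstance(raw, str):
        mol = Chem.MolFromSmiles(raw)
        if mol is None:
            raise InvalidStructure(f"unparseable SMILES: {raw!r}")
        raw = RawStructure(mol=mol, label=label or "")
    elif isinstance(raw, Chem.Mol):
        raw = RawStructure(mol=raw, label=label or "")

    mol = Chem.Mol(raw.mol)
    frags = Chem.GetMolFrags(mol)
    if len(frags) > 1:
        raise MixtureRejected(
            f"input has {len(frags)} fragments; mixtures and salts are not accepted"
        )
    if not any(a.GetAtomicNum() == 6 for a in mol.GetAtoms()):
        raise InorganicRejected("structure contains no carbon")

    try:
        Chem.SanitizeMol(mol)
        mol = _uncharger.uncharge(mol)
        Chem.SanitizeMol(mol)
    except (Chem.AtomValenceException, Chem.KekulizeException, Exception) as exc:
        raise InvalidStructure(str(exc)) from exc

    Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
    smiles = Chem.MolToSmiles(mol)
    inchi = Chem.MolToInchi(mol)
    if not inchi:
        raise InvalidStructure("InChI generation failed")
    return StandardMolecule(
        mol=mol,
        smiles=smiles,
        inchi=inchi,
        inchikey=Chem.InchiToInchiKey(inchi),
        formula=rdMolDescriptors.CalcMolFormula(mol),
        mono_mass=round(Descriptors.ExactMolWt(mol), 5),
        alogp=round(Crippen.MolLogP(mol), 4),
        label=raw.label or (label or ""),
    )


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
_PERIODIC_TABLE = Chem.GetPeriodicTable()


def monoisotopic_mass(formula: str) -> float:
    """Monoisotopic mass (Da) of a Hill molecular formula.

    Sums the most-abundant-isotope atomic mass for every element, to five
    decimal places. Charge suffixes (``+``/``-``) are ignored for the
    elemental sum.
    """
    body = formula.strip().rstrip("+-")
    if not body:
        raise FormulaError("empty formula")
    pos = 0
    total = 0.0
    for m in _FORMULA_TOKEN.finditer(body):
        if m.start() != pos:
            raise FormulaError(f"cannot parse formula {formula!r} at {body[pos:]!r}")
        pos = m.end()
        sym, count = m.group(1), int(m.group(2) or 1)
        if count <= 0:
            raise FormulaError(f"non-positive count for {sym} in {formula!r}")
        try:
            mass = _PERIODIC_TABLE.GetMostCommonIsotopeMass(sym)
        except Exception as exc:
            raise FormulaError(f"unknown element {sym!r} in {formula!r}") from exc
        if mass <= 0:
            raise FormulaError(f"unknown element {sym!r} in {formula!r}")
        total += mass * count
    if pos != len(body):
        raise FormulaError(f"cannot parse formula {formula!r}")
    return round(total, 5)


def formula_delta_mass(delta: str) -> float:
    """Mass (Da) of a signed elemental delta such as ``+C6H8O6`` or ``-S+O``.

    The delta describes the stoichiometric change from substrate to the
    summed product set of a rule; segments are added or subtracted
    elementwise.
    """
    total = 0.0
    for sign, body in re.findall(r"([+-])([A-Za-z0-9]+)", delta.replace(" ", "")):
        total += (1 if sign == "+" else -1) * monoisotopic_mass(body)
    if not re.fullmatch(r"(?:[+-][A-Za-z0-9]+)+", delta.replace(" ", "")):
        raise FormulaError(f"cannot parse delta {delta!r}")
    return round(total, 5)


def write_structures(
    records: Sequence[dict],
    format: str,
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> Path:
    """Write annotated metabolite records to SDF, CSV or JSON.

    Each record is a mapping with at least ``smiles`` plus annotation
    fields. Output ordering is byte-stable: records are sorted by their
    ``metabolite_id`` field (falling back to InChIKey). SDF carries every
    annotation as a named data field; CSV writes one row per record with
    a fixed header; JSON writes the record list verbatim.
    """
    fmt = format.lower()
    path = Path(path)
    ordered = sorted(
        records, key=lambda r: (str(r.get("metabolite_id", "")), str(r.get("inchikey", "")))
    )
    if fmt == "sdf":
        writer = Chem.SDWriter(str(path))
        writer.SetForceV3000(False)
        try:
            for rec in ordered:
                mol = Chem.MolFromSmiles(rec["smiles"])
                if mol is None:
                    continue
                mol.SetProp("_Name", str(rec.get("metabolite_id", "")))
                for key, value in rec.items():
                    if key == "smiles":
                        continue
                    mol.SetProp(key, "" if value is None else str(value))
                writer.write(mol)
        finally:
            writer.close()
    elif fmt == "csv":
        if columns is None:
            columns = []
            for rec in ordered:
                for key in rec:
                    if key not in columns:
                        columns.append(key)
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=columns, extrasaction="ignore")
            writer.writeheader()
            for rec in ordered:
                writer.writerow({k: ("" if v is None else v) for k, v in rec.items()})
    elif fmt == "json":
        path.write_text(json.dumps(ordered, indent=2, sort_keys=True) + "\n")
    else:
        raise ValueError(f"unknown output format {format!r}")
    return path
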