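"""Parsing, standardization, mass computation and structure I/O."""

import pytest
from hypothesis import given, settings, strategies as st

from xenometab.chem import (
    FormulaError,
    InorganicRejected,
    MixtureRejected,
    formula_delta_mass,
    monoisotopic_mass,
    parse_input,
    standardize,
    write_structures,
)
from xenometab.fixtures import random_fixture_smiles


class TestParseInput:
    def test_single_smiles(self):
        structures, issues = parse_input("CCO", format="smiles")
        assert len(structures) == 1 and not issues
        assert structures[0].heavy_atom_count == 3

    def test_inchi_of_ethanol(self):
        structures, _ = parse_input(
            "InChI=1S/C2H6O/c1-2-3/h3H,2H2,1H3", format="inchi"
        )
        std = standardize(structures[0])
        assert std.inchikey == "LFQSCWFLJHTTHZ-UHFFFAOYSA-N"

    def test_sdf_error_isolation(self, tmp_path):
        sdf = tmp_path / "batch.sdf"
        records = [{"smiles": s, "metabolite_id": f"M{i}"}
                   for i, s in enumerate(["CCO", "c1ccccc1", "CC(=O)O"])]
        write_structures(records, "sdf", sdf)
        # splice in a structurally broken record (counts line lies)
        blocks = sdf.read_text().split("$$$$\n")
        broken = "broken\n\n\n  2  1  0  0  0  0  0  0  0  0999 V2000\nM  END\n"
        blocks.insert(1, broken)
        sdf.write_text("$$$$\n".join(blocks))
        structures, issues = parse_input(str(sdf), format="sdf")
        assert len(structures) == 3
        assert len(issues) == 1 and issues[0].index == 1

    def test_empty_input_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.smi"
        p.write_text("")
        structures, issues = parse_input(str(p), format="smiles")
        assert structures == [] and issues == []


class TestStandardize:
    def test_benzene_unchanged(self):
        std = standardize("c1ccccc1")
        assert std.formula == "C6H6"
        assert std.smiles == "c1ccccc1"

    def test_phenolate_neutralized(self):
        std = standardize("[O-]c1ccccc1")
        assert std.formula == "C6H6O"
        assert std.inchikey == standardize("Oc1ccccc1").inchikey

    def test_nitro_group_left_charge_separated(self):
        std = standardize("[O-][N+](=O)c1ccccc1")
        charges = sorted(a.GetFormalCharge() for a in std.mol.GetAtoms())
        assert charges[0] == -1 and charges[-1] == 1

    def test_quaternary_ammonium_preserved(self):
        std = standardize("C[N+](C)(C)Cc1ccccc1")
        assert any(a.GetFormalCharge() == 1 for a in std.mol.GetAtoms())

    def test_mixture_rejected(self):
        with pytest.raises(MixtureRejected):
            standardize("CCO.CC")

    def test_inorganic_rejected(self):
        with pytest.raises(InorganicRejected):
            standardize("O")

    def test_idempotent_by_inchikey(self):
        first = standardize("[O-]c1ccc(CC(=O)[O-])cc1")
        second = standardize(first.smiles)
        assert first.inchikey == second.inchikey


class TestMonoisotopicMass:
    @pytest.mark.parametrize(
        "formula,expected",
        [
            ("H2O", 18.01056),
            ("C15H14O6", 290.07904),   # epicatechin
            ("C21H22O12", 466.11113),  # epicatechin glucuronide
        ],
    )
    def test_reference_masses(self, formula, expected):
        assert monoisotopic_mass(formula) == pytest.approx(expected, abs=1e-4)

    def test_unknown_element(self):
        with pytest.raises(FormulaError):
            monoisotopic_mass("C2Xx5")

    def test_formula_delta_mass(self):
        assert formula_delta_mass("+C6H8O6") == pytest.approx(176.03209, abs=1e-4)
        assert formula_delta_mass("-S+O") == pytest.approx(
            monoisotopic_mass("O") - monoisotopic_mass("S"), abs=1e-5
        )

    def test_structure_mass_matches_formula_mass(self, mol):
        for smi in ["CC(=O)Nc1ccc(O)cc1", "Oc1ccccc1", "CCOP(=S)(OCC)Oc1ccccc1"]:
            m = mol(smi)
            assert m.mono_mass == pytest.approx(
                monoisotopic_mass(m.formula), abs=1e-4
            )


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.sampled_from(random_fixture_smiles(7)))
def test_standardize_idempotent_property(smiles):
    once = standardize(smiles)
    twice = standardize(once.smiles)
    assert once.inchikey == twice.inchikey
    assert once.formula == twice.formula


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.sampled_from(random_fixture_smiles(11)))
def test_mass_consistent_with_formula_property(smiles):
    std = standardize(smiles)
    assert std.mono_mass == pytest.approx(monoisotopic_mass(std.formula), abs=1e-4)


class TestWriteStructures:
    def test_sdf_roundtrip_preserves_inchikey(self, tmp_path):
        smiles = random_fixture_smiles(3, n=20)
        records = []
        keys = []
        for i, smi in enumerate(sorted(set(smiles))):
            std = standardize(smi)
            keys.append(std.inchikey)
            records.append({"smiles": std.smiles, "metabolite_id": f"BTM{i:05d}",
                            "inchikey": std.inchikey})
        out = tmp_path / "round.sdf"
        write_structures(records, "sdf", out)
        structures, issues = parse_input(str(out), format="sdf")
        assert not issues
        assert sorted(standardize(s).inchikey for s in structures) == sorted(keys)

    def test_empty_csv_has_header(self, tmp_path):
        out = tmp_path / "empty.csv"
        write_structures([], "csv", out, columns=["metabolite_id", "inchikey"])
        assert out.read_text().strip() == "metabolite_id,inchikey"

    def test_deterministic_bytes(self, tmp_path):
        records = [
            {"smiles": "CCO", "metabolite_id": "BTM00001", "note": "b"},
            {"smiles": "c1ccccc1", "metabolite_id": "BTM00000", "note": "a"},
        ]
        p1, p2 = tmp_path / "a.sdf", tmp_path / "b.sdf"
        write_structures(records, "sdf", p1)
        write_structures(records, "sdf", p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_annotated_sdf_carries_data_fields(self, tmp_path):
        record = {
            "smiles": "Oc1ccccc1",
            "metabolite_id": "BTM00001",
            "inchi": "x", "inchikey": "y", "molecular_formula": "C6H6O",
            "monoisotopic_mass": "94.04186", "reaction_type": "oxidation",
            "biosystem": "human", "parent_id": "BTM00000",
            "parent_inchikey": "z",
        }
        out = tmp_path / "one.sdf"
        write_structures([record], "sdf", out)
        text = out.read_text()
        for key in record:
            if key != "smiles":
                assert f"<{key}>" in text
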