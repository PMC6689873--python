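"""MS-driven metabolite identification."""

import pytest

from conftest import EPICATECHIN
from xenometab.chem import monoisotopic_mass
from xenometab.identify import (
    DEFAULT_MASS_TOLERANCE_DA,
    DEFAULT_MAX_STEPS,
    PROTON_OFFSET_DA,
    IdentificationQuery,
    identify,
    neutral_mass_from_ion,
    write_identification,
)
from xenometab.transformers import run_allhuman

GLUCURONIDE_MASS = 466.11113  # epicatechin + C6H8O6


class TestNeutralMass:
    def test_epicatechin_ion(self):
        assert neutral_mass_from_ion(291.08631) == pytest.approx(290.07904, abs=1e-5)

    def test_exact_inverse_of_offset(self):
        for x in (0.5, 100.0, 968.8596):
            assert neutral_mass_from_ion(PROTON_OFFSET_DA + x) == pytest.approx(x, abs=1e-12)

    def test_below_offset_rejected(self):
        with pytest.raises(ValueError):
            neutral_mass_from_ion(0.9)


class TestDefaults:
    def test_documented_defaults(self, mol):
        q = IdentificationQuery(start=mol(EPICATECHIN), masses=(290.0,))
        assert q.tolerance == DEFAULT_MASS_TOLERANCE_DA == 0.01
        assert q.max_steps == DEFAULT_MAX_STEPS == 1
        assert q.scope == "allHuman"

    def test_invalid_queries_rejected(self, mol):
        m = mol(EPICATECHIN)
        with pytest.raises(ValueError):
            IdentificationQuery(start=m)
        with pytest.raises(ValueError):
            IdentificationQuery(start=m, masses=(290.0,), tolerance=0.0)
        with pytest.raises(ValueError):
            IdentificationQuery(start=m, masses=(290.0,), scope="cyp450")


class TestIdentify:
    def test_epicatechin_glucuronide_found(self, mol):
        q = IdentificationQuery(start=mol(EPICATECHIN), masses=(GLUCURONIDE_MASS,))
        result = identify(q)
        matches = result.matches[f"{GLUCURONIDE_MASS:.5f}"]
        assert matches
        for m in matches:
            assert abs(m.metabolite.mono_mass - GLUCURONIDE_MASS) <= q.tolerance
            assert m.pathway[0].parent == mol(EPICATECHIN).inchikey
            assert "glucuronidation" in {e.reaction_type for e in m.pathway}

    def test_absurd_mass_empty_not_error(self, mol):
        q = IdentificationQuery(start=mol(EPICATECHIN), masses=(9999.0,))
        result = identify(q)
        assert result.matches["9999.00000"] == []

    def test_formula_query_matches_mass_query(self, mol):
        m = mol(EPICATECHIN)
        by_mass = identify(IdentificationQuery(start=m, masses=(GLUCURONIDE_MASS,)))
        by_formula = identify(IdentificationQuery(start=m, formulas=("C21H22O12",)))
        keys_mass = {x.metabolite.inchikey for v in by_mass.matches.values() for x in v}
        keys_formula = {
            x.metabolite.inchikey for v in by_formula.matches.values() for x in v
        }
        assert keys_mass == keys_formula

    def test_parent_never_matches(self, mol):
        m = mol(EPICATECHIN)
        q = IdentificationQuery(start=m, masses=(m.mono_mass,), max_steps=1)
        result = identify(q)
        assert all(
            x.metabolite.inchikey != m.inchikey
            for v in result.matches.values() for x in v
        )

    def test_matches_respect_tolerance_against_bruteforce(self, mol):
        """Every reported match is in band; a full-tree scan finds no more."""
        m = mol(EPICATECHIN)
        targets = (GLUCURONIDE_MASS, 304.09469, 274.08412)
        q = IdentificationQuery(start=m, masses=targets, max_steps=2)
        result = identify(q)
        full = run_allhuman(m, 2)
        for label, target in zip(result.target_labels(), targets):
            reported = {x.metabolite.inchikey for x in result.matches[label]}
            qualifying = {
                k for k, node in full.nodes.items()
                if k != m.inchikey and abs(node.mono_mass - target) <= q.tolerance
            }
            assert reported == qualifying

    def test_early_stop_prefix_property(self, mol):
        m = mol(EPICATECHIN)
        shallow = identify(
            IdentificationQuery(start=m, masses=(GLUCURONIDE_MASS,), max_steps=1)
        )
        deep = identify(
            IdentificationQuery(start=m, masses=(GLUCURONIDE_MASS,), max_steps=2)
        )
        key = f"{GLUCURONIDE_MASS:.5f}"
        shallow_keys = {x.metabolite.inchikey for x in shallow.matches[key]}
        deep_keys = {x.metabolite.inchikey for x in deep.matches[key]}
        assert shallow_keys == deep_keys  # matched at step 1, no extra rounds run


class TestWriteIdentification:
    def test_sdf_pathway_lines_ordered(self, mol, tmp_path):
        m = mol(EPICATECHIN)
        # methylated catechol then glucuronide: a genuine 2-step match
        target = round(m.mono_mass + 14.01565 + 176.03209, 5)
        q = IdentificationQuery(start=m, masses=(target,), max_steps=2)
        result = identify(q)
        out = tmp_path / "ident.sdf"
        write_identification(result, out)
        text = out.read_text()
        assert "<Pathway>" in text
        block = text.split("<Pathway>")[1].split("\n\n")[0]
        lines = [l for l in block.strip().splitlines() if l and l[0].isdigit()]
        assert len(lines) == 2 and lines[0].startswith("1.") and lines[1].startswith("2.")

    def test_zero_matches_valid_empty_sdf(self, mol, tmp_path):
        q = IdentificationQuery(start=mol(EPICATECHIN), masses=(9999.0,))
        out = tmp_path / "none.sdf"
        write_identification(identify(q), out)
        assert out.read_text() == ""

    def test_byte_identical_reruns(self, mol, tmp_path):
        q = IdentificationQuery(start=mol(EPICATECHIN), masses=(GLUCURONIDE_MASS,))
        a, b = tmp_path / "a.sdf", tmp_path / "b.sdf"
        write_identification(identify(q), a)
        write_identification(identify(q), b)
        assert a.read_bytes() == b.read_bytes()
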