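"""Rule application, relative reasoning, and metabolic-tree expansion."""

import pytest

from conftest import KAEMPFEROL_DME_GLUCOSIDE, TRIESTER
from xenometab.chem import formula_delta_mass
from xenometab.fixtures import (
    FIXTURE_MOLECULES,
    enumerate_products_bruteforce,
)
from xenometab.kb import PrecedenceRule
from xenometab.reasoning import (
    ParameterError,
    apply_rule,
    candidate_biotransformations,
    filter_by_precedence,
    predict_tree,
)


class TestApplyRule:
    def test_symmetric_sites_collapse_to_one_product(self, human_kb, mol):
        bt = apply_rule(mol("c1ccccc1"), human_kb.rule("aromatic_hydroxylation"))
        assert len(bt.products) == 1
        assert bt.products[0].formula == "C6H6O"

    def test_glucuronidation_mass_shift(self, human_kb, mol):
        phenol = mol("Oc1ccccc1")
        bt = apply_rule(phenol, human_kb.rule("o_glucuronidation"))
        assert len(bt.products) == 1
        shift = bt.products[0].mono_mass - phenol.mono_mass
        assert shift == pytest.approx(176.03209, abs=1e-4)

    def test_three_site_cleavage_gives_six_products(self, env_kb, mol):
        bt = apply_rule(mol(TRIESTER), env_kb.rule("env_ester_cleavage"))
        assert len(bt.products) == 6

    def test_inapplicable_rule_returns_none(self, human_kb, mol):
        assert apply_rule(mol("CC(C)(C)C"), human_kb.rule("o_sulfation")) is None

    def test_products_never_equal_substrate(self, human_kb, mol):
        phenol = mol("Oc1ccccc1")
        for rule in human_kb.rules:
            bt = apply_rule(phenol, rule)
            if bt is not None:
                assert all(p.inchikey != phenol.inchikey for p in bt.products)


class TestOracleEquivalence:
    @pytest.mark.parametrize("fixture", FIXTURE_MOLECULES, ids=lambda f: f.name)
    def test_apply_rule_matches_bruteforce(self, fixture, packs, mol):
        """Engine output equals naive per-embedding enumeration + dedup."""
        kb = packs[fixture.pack]
        substrate = mol(fixture.smiles)
        for rule in kb.rules:
            expected = enumerate_products_bruteforce(substrate, rule)
            bt = apply_rule(substrate, rule)
            got = set() if bt is None else {p.inchikey for p in bt.products}
            assert got == expected, rule.id


class TestMassBalance:
    @pytest.mark.parametrize("fixture", FIXTURE_MOLECULES, ids=lambda f: f.name)
    def test_declared_stoichiometry(self, fixture, packs, mol):
        """Per-site product-sum mass equals substrate plus the rule's delta."""
        from rdkit import Chem
        from xenometab.chem import standardize

        kb = packs[fixture.pack]
        substrate = mol(fixture.smiles)
        for rule_id in fixture.rule_ids:
            rule = kb.rule(rule_id)
            if rule.formula_delta is None:
                continue
            embeddings = rule.reaction.RunReactants((substrate.mol,))
            assert embeddings, rule_id
            site = embeddings[0]
            total = 0.0
            for product in site:
                Chem.SanitizeMol(product)
                if product.GetNumHeavyAtoms() < 2:
                    continue
                total += standardize(product).mono_mass
            expected = substrate.mono_mass + formula_delta_mass(rule.formula_delta)
            assert total == pytest.approx(expected, abs=1e-3), rule_id


class TestRelativeReasoning:
    def test_deglycosylation_suppresses_demethylation(self, human_kb, mol):
        """Glycosylated polyphenols deconjugate before any O-demethylation."""
        kdg = mol(KAEMPFEROL_DME_GLUCOSIDE)
        candidates = candidate_biotransformations(
            kdg, human_kb, rules=human_kb.rules_for("gut"),
            precedence=human_kb.precedence_for("gut"),
        )
        assert {c.rule_id for c in candidates} == {"gut_o_deglycosylation"}

    def test_c7_regiopreference_after_deglycosylation(self, human_kb, mol):
        tree = predict_tree(
            mol(KAEMPFEROL_DME_GLUCOSIDE), human_kb, nsteps=2,
            rules=human_kb.rules_for("gut"),
            precedence=human_kb.precedence_for("gut"),
        )
        step2_rules = {e.rule_id for e in tree.edges if e.step == 2}
        assert step2_rules == {"gut_o_demethylation_c7"}
        # exactly one regiochemical product at step 2
        assert len({e.child for e in tree.edges if e.step == 2}) == 1

    def test_empty_precedence_is_noop(self, human_kb, mol):
        phenol = mol("Oc1ccccc1")
        candidates = candidate_biotransformations(
            phenol, human_kb, precedence=[]
        )
        assert filter_by_precedence(candidates, []) == candidates

    def test_dominance_requires_dominant_to_apply(self, human_kb, mol):
        anisole = mol("COc1ccccc1")  # demethylation applies, deglycosylation not
        candidates = candidate_biotransformations(
            anisole, human_kb, rules=human_kb.rules_for("gut"),
            precedence=human_kb.precedence_for("gut"),
        )
        assert {c.rule_id for c in candidates} == {"gut_o_demethylation"}


class TestPredictTree:
    def test_zero_steps_root_only(self, human_kb, mol):
        tree = predict_tree(mol("Oc1ccccc1"), human_kb, nsteps=0)
        assert len(tree.nodes) == 1 and tree.edges == []

    def test_edges_carry_provenance(self, human_kb, mol):
        tree = predict_tree(mol("Oc1ccccc1"), human_kb, nsteps=1)
        assert tree.edges
        for edge in tree.edges:
            assert edge.rule_id and edge.enzymes and edge.step == 1

    def test_convergent_product_single_node_two_parents(self, human_kb, mol):
        # catechol and resorcinol both hydroxylate to pyrogallol-type triols;
        # within one tree, a convergent metabolite keeps one node, >1 parents
        tree = predict_tree(mol("Oc1ccccc1"), human_kb, nsteps=2)
        multi_parent = [
            k for k in tree.nodes
            if len({e.parent for e in tree.parents_of(k)}) > 1
        ]
        assert multi_parent, "expected at least one convergent metabolite"
        keys = list(tree.nodes)
        assert len(keys) == len(set(keys))

    def test_step_cap_enforced(self, human_kb, mol):
        with pytest.raises(ParameterError):
            predict_tree(mol("Oc1ccccc1"), human_kb, nsteps=13)

    def test_monotone_in_steps(self, human_kb, mol):
        m = mol("Cc1ccccc1O")
        rules = human_kb.rules_for("human")
        n1 = set(predict_tree(m, human_kb, 1, rules=rules).nodes)
        n2 = set(predict_tree(m, human_kb, 2, rules=rules).nodes)
        assert n1 <= n2

    def test_serialization_deterministic(self, human_kb, mol):
        t1 = predict_tree(mol("Oc1ccccc1O"), human_kb, nsteps=2)
        t2 = predict_tree(mol("Oc1ccccc1O"), human_kb, nsteps=2)
        assert t1.to_json() == t2.to_json()


def test_precedence_cycle_raises(human_kb, mol):
    from xenometab.reasoning import ReasoningError

    catechol = mol("Oc1ccccc1O")
    candidates = candidate_biotransformations(catechol, human_kb, precedence=[])
    ids = sorted({c.rule_id for c in candidates})
    assert len(ids) >= 2
    cyc = [
        PrecedenceRule(dominant=ids[0], suppressed=ids[1]),
        PrecedenceRule(dominant=ids[1], suppressed=ids[0]),
    ]
    with pytest.raises(ReasoningError):
        filter_by_precedence(candidates, cyc)
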