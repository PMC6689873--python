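# xenometab

Rule-based prediction of xenobiotic metabolism, with an MS-driven
metabolite identification tool.

`xenometab` is for researchers in drug metabolism, food/polyphenol
chemistry, exposomics and environmental fate who need to enumerate the
plausible enzymatic transformation products of a small molecule — and,
given untargeted LC–MS data, to propose which predicted metabolites
explain observed masses.

## What it does

The engine couples three components:

1. **A reaction knowledgebase** (JSON rule packs). Each biotransformation
   rule is one atom-mapped **SMIRKS** transform plus separately encoded
   constraints: required/forbidden **SMARTS** substructures and property
   predicates (e.g. monoisotopic mass ≤ 900 Da for conjugation). Rules
   carry enzymes, biosystem scope (human tissue, human gut microbiome,
   environmental microbiome), a reaction type and a priority tier.
   Precedence relations and chemical-class→pathway gates are part of the
   pack.

2. **A reasoning engine.** A rule is applied at *every* matching site of
   the substrate; each site's full product set is kept (cleavage
   co-products included), standardized, and deduplicated by InChIKey.
   *Relative reasoning* then prunes competing reactions: a precedence
   pair A > B removes B's products whenever A applies to the same
   substrate, transitively along chains. *Absolute reasoning* is a
   threshold over per-rule tiers; all packaged rules share tier 0 (equal
   likelihood), so the hook is a no-op by default. Multi-step prediction
   is breadth-first with a global visited set, producing a rooted
   multi-parent **metabolic tree** with per-edge provenance (rule,
   enzymes, biosystem, step).

3. **Substrate filters.** The CYP450 module pre-screens substrates
   (inorganics and excluded lipid classes are out of scope) and exposes
   a pluggable per-isozyme reactivity classifier over the nine major
   CYP450s (permissive by default). The phase II module pre-screens with
   a rule-based filter (five excluded lipid/cofactor classes, ≤ 900 Da,
   ≥ 1 of 64 conjugatable structural motifs) and optionally a random
   forest over a 32-descriptor vector: 9 constitutional descriptors and
   23 binary structural flags, including the canonical amine SMARTS
   `[NX3+0,NX4+;!$([N]~[!#6]);!$([N]*~[#7,#8,#15,#16])]` and carboxyl
   SMARTS `[#8;A;X2H1,X1-][#6]([#6,#1;A])=O`.

Prediction modules: `ecbased`, `cyp450`, `phaseII`, `hgut`, `envmicro`,
plus `allHuman` (union of the four human modules at every step) and
`superbio` (a fixed 12-slot ordered pipeline that opens with hydrolysis
and closes with conjugation; conjugates are terminal).

The identification tool converts positive-mode [M+H]+ ions to neutral
masses (m/z − 1.00727 Da), expands the metabolic tree step by step
(default: 1 step, 0.01 Da tolerance), reports every metabolite within
tolerance of each target mass (or matching each formula) together with
its pathway from the parent compound, and stops early once every target
has a match.

## Worked example

Predict one step of CYP450 metabolism for acetaminophen:

```python
from xenometab import standardize, run_module
from xenometab.annotate import annotate_tree

tree = run_module(standardize("CC(=O)Nc1ccc(O)cc1"), "cyp450", nsteps=1)
for r in annotate_tree(tree):
    print(r["metabolite_id"], r["molecular_formula"], r["monoisotopic_mass"],
          r["reaction"] or "-", r["synonyms"] or "-")
```

prints

```
BTM00000 C8H9NO2 151.06333 - acetaminophen; paracetamol
BTM00001 C8H9NO3 167.05824 Aromatic hydroxylation -
BTM00002 C8H9NO3 167.05824 Aromatic hydroxylation -
BTM00003 C8H7NO2 149.04768 Oxidation of 4-hydroxyanilide to quinone imine NAPQI; N-acetyl-p-benzoquinone imine
```

`BTM00000` is the parent; the two C8H9NO3 records are the distinct
ring-hydroxylation regioisomers (+15.99491 Da), and `BTM00003` is the
reactive quinone imine NAPQI (−2 H). The same run is available from the
shell, writing an annotated SDF or CSV:

```sh
xenometab predict -i "CC(=O)Nc1ccc(O)cc1" -m cyp450 -s 1 -o out.sdf
```

Identify which predicted epicatechin metabolites explain a neutral mass
of 466.111 Da (one metabolism step, 0.01 Da tolerance):

```sh
xenometab identify -i "Oc1cc(O)c2c(c1)OC(c1ccc(O)c(O)c1)C(O)C2" \
    --masses masses.txt -o ident.sdf
# -> 5 matches for 1/1 targets written to ident.sdf
```

The five records are the regioisomeric epicatechin glucuronides
(C21H22O12, 466.11113 Da = 290.07904 + 176.03209), each carrying its
pathway (`1. O-glucuronidation [UGT1A1]`) as SDF data fields.

## Rule packs

Two fixture packs ship with the package under `src/xenometab/data/`:
`human_gut.json` (17 rules spanning oxidation, hydrolysis, dealkylation,
gut deconjugation/demethylation/reduction and the four conjugation
chemistries, with precedence pairs and a glycerophospholipid pathway
gate) and `env.json` (4 environmental microbial rules with their own
precedence set). The JSON schema — top-level `rules`, `enzymes`,
`precedence`, `pathways`, `records` — accommodates arbitrarily large
packs; `xenometab.kb.load_rule_pack` validates, compiles and
cross-checks any conforming document.

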