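# Methods

## Standardization model

Every structure entering the engine becomes a `StandardMolecule`:
exactly one connected component (mixtures and salts are rejected rather
than counter-ion-stripped, so the caller always knows which species was
modelled), at least one carbon, charges neutralized by the RDKit
Uncharger with a fixed exception list — nitro, N-oxide and quaternary
ammonium groups stay charge-separated because neutralizing them would
change the covalent structure. Stereochemistry supplied in the input is
preserved; reactions never assign new stereocenters (the packaged rules
are constitutional). Identity everywhere — product deduplication,
visited sets, tree nodes, output ordering — is the full standard
InChIKey, chosen because it is deterministic and independent of atom
numbering. Monoisotopic masses are sums of most-abundant-isotope atomic
masses (RDKit periodic table, ≥ 6 decimals), reported to 5 decimal
places; AlogP is the Crippen estimate.

Tautomer canonicalization and pKa-based protonation-state modelling are
deliberately out of scope; inputs are taken at face value after the
neutralization pass.

## Rule model

A biotransformation rule is an atom-mapped SMIRKS transform plus a
conjunctive constraint list: `smarts_required`, `smarts_forbidden`, and
property predicates over monoisotopic mass, AlogP or heavy-atom count.
Disjunctive applicability is expressed by splitting a generic reaction
into sibling rules rather than by OR-ing constraints — this keeps each
rule's applicability test a pure conjunction and lets precedence
relations refer to the specific subtype. Each rule declares a
`formula_delta` (e.g. `+C6H8O6` for glucuronidation, `+SO3` for
sulfation, `-CH2` for O-demethylation, `-S+O` for oxidative
desulfurization), the elementwise change from substrate to the summed
per-site product set; the test suite verifies every declared delta by
mass balance.

### Rule application

`apply_rule` runs the transform at every embedding of the reactant
pattern. All product fragments with ≥ 2 heavy atoms are kept — including
cleavage co-products such as formaldehyde from N-demethylation or the
leaving acid of an ester — because downstream MS matching benefits from
by-products that single-product engines drop. Products are standardized
and deduplicated by InChIKey across sites (benzene hydroxylates at six
symmetric positions but yields one phenol), products identical to the
substrate are discarded, and unsanitizable site products are skipped
with a logged warning rather than failing the run.

### Reasoning

Relative reasoning: a precedence pair `A > B` removes every candidate
produced by `B` when `A` *applies* to the substrate at that step.
Suppression keys on applicability, not survival, so chains
(`A > B`, `B > C`) suppress transitively in one pass; a cycle among
co-applicable rules raises an error (the pack linter reports cycles at
load time). The packaged precedence encodes two observed behaviors of
gut polyphenol metabolism: glycosylated polyphenols deconjugate before
any other gut transformation, and O-demethylation of flavonoids prefers
the C-7 position (the C-7-specific rule dominates the generic aryl
demethylation).

Absolute reasoning is a threshold over per-rule priority tiers. All
packaged rules sit in tier 0 — equal likelihood — so the default
threshold retains everything; the hook accepts informative scores from
future packs without an interface change.

Chemical-class pathway gates: a molecule matching an exclusive
pathway's class SMARTS (the packaged example is glycerophospholipids)
may only undergo rules catalysed by that pathway's member enzymes, so
phospholipids hydrolyse via phospholipase rather than conjugating.

### Tree construction

`predict_tree` is breadth-first: round *k* expands only molecules first
produced in round *k−1*; a molecule is expanded at most once globally
(visited set on InChIKey), so convergent metabolites acquire additional
parent edges rather than re-expanding once per parent — the cheaper of
the two defensible conventions, and the one that keeps node counts
bounded under reversible rule pairs (demethylation/methylation). The
step cap defaults to 12. All node and edge collections are sorted by
(step, rule id, InChIKey) before serialization, so identical inputs
give byte-identical output.

## Modules

Single modules select rule subsets by enzyme family (`ecbased`:
esterases/epoxide hydrolases/phospholipases; `cyp450`: CYP450s;
`phaseII`: UGT/SULT/methyl-/acetyltransferases) or biosystem (`hgut`:
gut; `envmicro`: env). `allHuman` pools the four human modules' candidates
at every step — each gated by its own substrate filter — and runs
relative reasoning over the pooled set, so gut deconjugation precedence
still suppresses competing chemistry contributed by another module.

`superbio` is an ordered 12-slot pipeline. Only the endpoints are
externally constrained — hydrolysis first (when applicable),
conjugation last — so the interior order is a package design choice,
recorded here as configuration, not as a claim: EC hydrolysis → gut
deconjugation → gut reduction → EC oxidation → CYP450 → EC → CYP450 →
gut → EC → methylation/acetylation → sulfation → glucuronidation. Each
slot applies its module to every non-terminal metabolite in the tree;
step indices record slot numbers, bounding depth at 12. Conjugation
products are terminal — a single conjugation round closes the pipeline —
which keeps the metabolite set a subset of the free 12-step union.

## Filters

CYP450 pre-filter: inorganics (no carbon; simple carbon oxides) and the
pack-configured excluded classes (glycerolipids, glycerophospholipids)
are out of scope. The per-isozyme reactivity classifier is an
interface; the shipped default is permissive (all nine isozymes
reactive) so that rule applicability alone decides, and the package
makes no accuracy claim for it. A trained model can be plugged in
without touching the engine.

Phase II pre-filter: five excluded classes (ether lipids,
glycerolipids, glycerophospholipids, sphingolipids, acyl-CoA
conjugates — matched by stand-in SMARTS patterns written for this
package), molecular weight ≤ 900 Da, and at least one of 64
conjugatable structural motifs. The 64-entry motif list shipped in
`data/phase2_motifs.json` is this package's own inventory of
conjugatable and metabolically relevant groups (hydroxyls, phenols,
catechols, amines, carboxyls, thiols, N-heterocycles, glycosides, …);
the count is fixed at 64 and every entry is a compiled, tested SMARTS.

Featurizer: 9 constitutional descriptors — monoisotopic mass, AlogP,
H-bond donors, H-bond acceptors, rotatable bonds, heavy atoms, rings,
aromatic rings, TPSA — plus 23 binary structural flags led by the
canonical amine and carboxyl SMARTS. Only "mass, AlogP and H-bond
counts" are externally fixed; the remaining choices are this package's
and are frozen in `phase2_feature_names()`. Constitutional values are
rounded to 6 decimals so additive descriptors are invariant to atom
ordering. The random-forest harness (scikit-learn, fixed seed, 0.5
decision threshold) is evaluated by 10-fold stratified cross-validation
reporting weighted F1 and ROC AUC. No trained model ships with the
package: without one, the phase II module falls back to
prefilter-only gating.

## Identification

Neutral masses come from [M+H]+ ions by subtracting 1.00727 Da (the
proton mass at the precision the offset is defined); other adducts are
out of scope. Matching is absolute and inclusive (|Δm| ≤ tolerance, Da;
no ppm mode), defaults one step and 0.01 Da. Formula targets compare
neutral Hill formulas exactly. Expansion is round-by-round (slot by
slot under `superbio`) with early stop once every target has a match;
matches found in the final round after a target is satisfied are still
reported, and all isobaric/regiochemical matches per target are kept.
The parent compound itself is never a match, including at step 0.

## Synthetic data and fixtures

The fixture battery (`xenometab.fixtures`) covers every packaged rule
with at least one positive substrate — real, literature-familiar
chemistry at fixture scale: acetaminophen for quinone-imine formation,
a parathion-like phosphorothioate for dearylation/desulfurization, a
flavonoid dimethyl-ether glucoside for the deconjugation/C-7
precedence chain, a mixed glyceryl triester whose three distinct esters
exercise multi-site two-product cleavage, epicatechin for the
conjugation chemistries. Negative controls (branched/cyclic alkanes,
perfluoroethane) match no rule in any module. Expected products are
computed by a deliberately naive brute-force enumerator (per-embedding
transform + InChIKey dedup) that shares no code path with the engine's
`apply_rule`, so oracle-equivalence tests are meaningful.

`random_fixture_smiles(seed)` assembles 100 small aromatic/alicyclic
molecules from a seeded scaffold-plus-substituent grammar for
property-based checks (standardization idempotence, mass/formula
consistency, step monotonicity). What these fixtures do *not* emulate:
the breadth of a production rule inventory (hundreds of rules), curated
substrate/non-substrate training sets, stereospecific metabolism, or MS
noise — passing tests demonstrate engine correctness on the packaged
chemistry, not predictive coverage on arbitrary drugs.

Problem sizes throughout (17 + 4 rules, ~20 fixture substrates, 120
synthetic training molecules, 30–100 random fixtures per property) were
chosen to exercise every engine behavior with fast, deterministic runs.

## Numerical and degenerate-input choices

- Masses compared at 1e-4 Da (structure vs formula) and 1e-3 Da (mass
  balance, accumulated over multi-fragment sums); reported to 5 d.p.
- Ties everywhere broken lexicographically by (step, rule id,
  InChIKey); metabolite IDs (`BTM#####`) assigned by that traversal.
- Empty inputs: zero-record files are valid (CSV keeps its header);
  unparseable batch records are reported per-index without aborting.
- Pathway reconstruction for convergent nodes follows the minimal
  (earliest-step, then lexicographic) incoming edge chain.
- `nsteps = 0` is legal and returns a root-only tree.

## Known limitations

- The packaged rule inventory is a fixture-scale subset; recall on
  arbitrary xenobiotics is limited by pack coverage, not engine logic.
- The permissive CYP classifier over-predicts eligibility by design.
- Excluded-class SMARTS are intentionally broad stand-ins; borderline
  lipids may be misclassified by the pre-filters.
- Single-fragment policy means salts must be desalted upstream.
- Only [M+H]+ is supported in ion-mass conversion; isotope patterns and
  MS/MS fragmentation are out of scope.
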