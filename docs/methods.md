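# Methods

## Screening model

The package screens one proband against a modified form of the NCCN
BRCA1/2 testing criteria, v3.2019. The modification drops every item a
structured lay interview cannot elicit — known familial BRCA1/2 variants,
all prostate-cancer-grade arms (Gleason score, metastatic status),
triple-negative receptor status, tumor-profiling findings,
treatment-eligibility indications, and Ashkenazi Jewish ancestry — plus
ancestry-dependent items that are rarely informative in the deployment
population. These ten items are not deleted: they are carried as OMITTED
criteria that always evaluate to NOT_ASKED, so every result sheet shows
exactly which parts of the guideline were out of scope for the interview.
The seven retained criteria (A1–A7, see README) consume only facts the
interview collects: sex, vital status, ages, and per-member cancer
diagnoses with site and age.

Because the published guideline text leaves the retained thresholds
partly implicit, they are encoded explicitly and exposed as configuration:
A1 age cap 45; A2 window 46–50 (the 41–50 figure seen in one omitted
prostate arm is not applied to A2, whose standard non-prostate window is
46–50); A3 relative-breast-cancer cap 50; limited-family-history
parameters below. A rule-set config file (YAML/JSON) can switch any
retained criterion to OMITTED and override any threshold; omitted-by-
default items have no predicate and cannot be activated.

### Interpretation rules for incomplete data

Screening must not assert what was never elicited, so:

- an **unknown diagnosis age** fails every age-bounded condition
  ("breast ≤ 50" needs a known age ≤ 50) but satisfies any-age conditions;
- an **unknown sex** never satisfies a sex condition (ovarian arms require
  recorded female sex, male-breast arms recorded male sex);
- **unknown parents** terminate kinship path search (treated as founders);
  no hidden relationship is inferred.

### Kinship

Degree of relationship is defined through the relatedness coefficient
r — the sum over simple common-ancestor paths of (1/2)^edges — rather than
through edge counts, so full siblings are first-degree despite their
two-edge path. Values off the {1/2, 1/4, 1/8} grid (consanguinity, e.g.
double first cousins with r = 1/4) classify by the r value itself, since r
is the quantity the guideline's risk logic proxies. Half-relatives emerge
naturally from path counting (a half-aunt is third-degree via her single
path). "Close blood relative" in A2/A3 spans degrees 1–3; the
family-history clause A7 uses first- and second-degree relatives only,
matching the narrower family-history scope of the guideline clause it
encodes. A7 evaluates each such relative with the pedigree re-rooted at
them (degrees, lineage sides and close-relative sets recomputed), checking
A1–A6 only, so recursion depth is exactly one.

### Limited family history

A2 can be satisfied by an uninformative family structure. The package
renders this footnote concept concretely: the family history is *limited*
iff on the maternal side or on the paternal side fewer than 2 female
first- or second-degree relatives are known to have reached age 46
(current age or age at death; unknown ages do not count). Full sisters and
nieces sit on both lineages and count toward both tallies; the proband's
descendants count toward neither. Both the threshold count and the age are
config keys.

## Interview

The interview is a deterministic finite-state script with two phases,
mirroring counseling practice: family structure first (paternal
grandparents, maternal grandparents, father, mother, paternal then
maternal uncles/aunts, first cousins per uncle/aunt, siblings, children,
nieces/nephews per sibling — grandparents and parents are always created
so the kinship skeleton exists even when details are unknown), then each
member's medical history, proband first. Cousins are elicited per
uncle/aunt and nieces/nephews per sibling so parent links are structural,
never guessed. Answers are free text with a declared parser (age 0–130 or
"unknown"; count 0–12; yes/no) or numbered single choice; sex-incompatible
cancer sites are removed from the choice list. A parse failure re-issues
the prompt with a clarification; more than 3 consecutive failures flag the
session for human assistance (it remains resumable). Prompt wording lives
in an editable JSON message catalog; all logic is keyed to prompt ids, so
rewording never changes results. The persona (name, occupation in the
greeting) is cosmetic by construction. Member ids are assigned R01, R02, …
in elicitation order, and the canonical pedigree JSON sorts members by id,
which makes generator/interview round-trips byte-comparable.

## Synthetic data

The generator draws families over exactly the relation slots the interview
can reach, with per-slot count ranges (siblings 0–4, uncles/aunts 0–3 per
side, cousins 0–3 per uncle/aunt, children 0–3, nieces/nephews 0–2 per
sibling), generational age offsets, and lifetime cancer incidences chosen
as order-of-magnitude population-plausible constants for test coverage,
not as epidemiological claims: breast 0.10 in females and 0.001 in males,
ovarian 0.015, pancreatic 0.012, prostate 0.04, other 0.05; 15% of breast
cases add a second primary; 10% of relative ages and diagnosis ages are
recorded as unknown. Each draw also emits the exact interview answer
sequence that reproduces the pedigree, so interview fidelity is tested as
a round trip from an independently constructed graph. What the generator
does **not** emulate: consanguinity, multiple marriages/half-siblings,
unknown-sex members, age-dependent penetrance, or recall error — passing
randomized tests therefore demonstrates logical correctness of the
engine on interview-shaped families, not clinical performance on real
histories (half-relatives and consanguinity are covered by constructed
unit fixtures instead).

The three bundled scenario fixtures are synthetic reconstructions
engineered to exercise the three distinct screening routes — positive
through the proband's own early-onset breast cancer, positive through
family history alone (an ovarian-affected mother), and a sporadic-looking
family (later-onset breast cancer, one unrelated-site cancer in a
grandmother) that meets no active criterion. They are shipped as JSON with
`synthetic` metadata and are regenerated verbatim by
`scenario_fixture_documents()`.

## Verification design

Two fully independent evaluation paths exist. The engine computes kinship
by combining upward ancestor paths and evaluates predicate functions with
evidence collection. The naive oracle recomputes relatedness by exhaustive
DFS over all simple up-then-down parent-link paths and re-checks each
criterion's text by plain iteration over members and diagnoses, sharing
no code path, indexing or caching with the engine. Tests assert exact
criterion-by-criterion agreement on 1,000 generated pedigrees, plus a
named-relationship table (parent/sibling first; aunt/half-sibling second;
first cousin/great-grandparent third; spouse unrelated), monotonicity
(adding a diagnosis never turns MET into NOT_MET, 500 trials), and
byte-identical interview and transcript replays (100 seeds). These sizes
run the whole suite in well under a minute on one core.

## Numerical and degenerate-input choices

- Relatedness uses exact rational arithmetic (`fractions.Fraction`);
  no floating-point tolerance is involved anywhere in classification.
- r is capped at 1 (relevant only under pathological inbreeding input).
- Validation returns a violation list rather than raising, and checks the
  full invariant set from scratch: single proband, resolvable and
  sex-consistent parent links, acyclicity, connectivity to the proband,
  age bounds 0–130, diagnosis age ≤ current age when both known, and
  per-site primary indices consecutive from 1.
- A single-member pedigree is valid; its close-relative set is empty and
  its family history is limited.
- PED export is intentionally lossy (no diagnosis detail); phenotype 0 is
  reserved for members whose history was never taken.

## Known limitations

- The retained criteria are an explicit encoding of the modified
  guideline, not the full NCCN checklist; carrier-probability models
  (BRCAPRO etc.) and management recommendations are out of scope.
- The interview enumerates a fixed relative set; relatives outside it
  (e.g. great-grandparents, half-siblings) are screenable only through
  pedigree JSON input, not the interview.
- Relation labels for structurally ambiguous members are composed
  mechanically ("half-sister (maternal)", "third-degree relative").
- The message catalog ships in English only.
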