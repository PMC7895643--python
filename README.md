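# hbocscreen

Preliminary screening for hereditary breast and ovarian cancer (HBOC) as a
deterministic, fully testable pipeline: a scripted family-history interview,
a pedigree graph with clinical kinship computations, and a rule engine for a
modified version of the NCCN BRCA1/2 testing criteria (v3.2019).

## Who this is for

Genetic-counseling services triage which patients should be offered formal
counseling and BRCA1/2 testing by checking personal and family cancer
history against the NCCN testing criteria. That triage is routine,
pattern-driven work: establish the family structure, record each member's
cancer history, check the criteria. `hbocscreen` automates it as a
terminal chatbot-style interview plus a non-interactive screening engine,
for developers and researchers building or evaluating such triage tools.

## The model

A pedigree is a directed acyclic graph of parent links anchored at the
proband. Genetic closeness is the **relatedness coefficient**

r(a,b) = Σ over simple common-ancestor paths (1/2)^(number of edges)

so a parent has r = 1/2, a full sibling r = 1/4 + 1/4 = 1/2, an aunt
r = 1/4, a first cousin r = 1/8. Clinical **degree of relationship** follows
from r (first = 1/2, second = 1/4, third = 1/8), and a **close blood
relative** is any first-, second- or third-degree relative of the proband.

The rule set retains seven elicitable criteria:

| id | condition |
|----|-----------|
| A1 | proband breast cancer at age ≤ 45 |
| A2 | proband breast cancer at 46–50 and (second breast primary, or ≥ 1 close blood relative with breast/ovarian/pancreatic cancer, or limited/unknown family history) |
| A3 | proband breast cancer at any age and ≥ 1 close blood relative with breast cancer ≤ 50, ovarian cancer, male breast cancer, or pancreatic cancer |
| A4 | proband ovarian (incl. fallopian tube / primary peritoneal) cancer |
| A5 | proband male breast cancer |
| A6 | proband pancreatic cancer |
| A7 | a first- or second-degree relative meets any of A1–A6 as if they were the proband |

Ten further guideline items (known familial variant, prostate-grade arms,
triple-negative status, tumor profiling, treatment eligibility, ancestry)
cannot be elicited by a structured lay interview; they are carried as
OMITTED criteria that always report **NOT ASKED**, so the result sheet is
explicit about what was not assessed. The screening is positive (criteria
met) iff at least one active criterion is MET.

## Worked example

Screen a bundled scenario — a healthy 52-year-old proband whose mother had
ovarian cancer at 61:

```python
from hbocscreen import (evaluate, default_ruleset, scenario_fixtures,
                        render_family_history, render_screening_sheet)

ped, _ = scenario_fixtures()[1]
rs = default_ruleset()
result = evaluate(ped, rs)
print(render_family_history(ped)[0])
print(render_screening_sheet(result, rs)[0])
```

prints (abridged):

```
Family history
father | M | 78 y | -
mother | F | 74 y | ovarian (61 y)
brother | M | 49 y | -
daughter | F | 26 y | -

BRCA1/2 testing criteria screening (modified-nccn-brca v3.2019)
[NOT MET] A1: Personal history of breast cancer diagnosed at age <= 45
...
[MET] A7: A first- or second-degree blood relative meeting any of the personal-history criteria above
[NOT ASKED] O1: Individual from a family with a known BRCA1/2 pathogenic or likely pathogenic variant, ...
...
FINAL RESULT: criteria met
```

The proband meets no personal-history criterion, but her mother — evaluated
as if she were the proband — meets the ovarian-cancer criterion, so the
family-history clause A7 fires and the screening is positive.

The same pipeline runs from the shell:

```
hboc-screen interview --out bundle/        # scripted terminal interview
hboc-screen evaluate pedigree.json         # non-interactive screening
hboc-screen replay bundle/transcript.json  # deterministic re-derivation
hboc-screen simulate --seed 7              # synthetic pedigree + answers
hboc-screen fixtures                       # write the scenario fixtures
```

Every interview writes a replayable transcript; replaying it reproduces
the pedigree and the screening result byte-for-byte.

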