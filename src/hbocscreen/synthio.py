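"""Synthetic pedigrees, scenario fixtures, and the naive evaluation oracle.

``generate_pedigree`` draws a family whose structure uses only the relation
slots the scripted interview can reach (grandparents, parents, uncles/aunts,
first cousins, siblings, children, nieces/nephews) and emits, alongside the
pedigree, the exact answer sequence that reproduces it through the
interview — so interview fidelity is testable as a round trip.

``scenario_fixtures`` ships three constructed screening scenarios: criteria
met through the proband's own history, met through family history only, and
a sporadic-looking family that meets no active criterion.  They are
synthetic stand-ins engineered to exercise those three routes; the fixture
metadata records this.

``naive_oracle`` re-evaluates every active criterion by exhaustive
iteration — relatedness by brute-force DFS over all simple up-then-down
paths, criteria by plain loops over members and diagnoses — sharing no
indexing or caching with the main engine, so engine/oracle agreement is a
meaningful check.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources

from .criteria import Mode, RuleSet, ScreeningResult, Status, default_ruleset
from .pedigree import (
    CancerDiagnosis,
    Degree,
    Pedigree,
    Person,
    Sex,
    Side,
    Site,
    Vital,
)

# ---------------------------------------------------------------------------
# simulation config


@dataclass(frozen=True)
class SimConfig:
    """Controls for the synthetic family generator.

    Counts are inclusive (lo, hi) ranges per relation slot; incidences are
    lifetime probabilities per site (breast is sex-specific); diagnosis
    ages are drawn uniformly from the site's range clipped to the person's
    age.  ``unknown_age_fraction`` is the chance a relative's age (or a
    diagnosis age) is recorded as unknown.
    """

    seed: int = 0
    siblings: tuple[int, int] = (0, 4)
    uncles_aunts_per_side: tuple[int, int] = (0, 3)
    cousins_per_uncle_aunt: tuple[int, int] = (0, 3)
    children: tuple[int, int] = (0, 3)
    nieces_nephews_per_sibling: tuple[int, int] = (0, 2)
    incidence: dict = field(default_factory=lambda: {
        "breast_female": 0.10,
        "breast_male": 0.001,
        "ovarian": 0.015,
        "pancreatic": 0.012,
        "prostate": 0.04,
        "other": 0.05,
    })
    diagnosis_age_range: dict = field(default_factory=lambda: {
        "breast": (30, 75),
        "ovarian": (35, 75),
        "pancreatic": (45, 80),
        "prostate": (55, 80),
        "other": (30, 80),
    })
    second_breast_primary_prob: float = 0.15
    unknown_age_fraction: float = 0.10

    def validate(self) -> None:
        for k, p in self.incidence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"incidence {k}={p} outside [0,1]")
        for name in ("siblings", "uncles_aunts_per_side",
                     "cousins_per_uncle_aunt", "children",
                     "nieces_nephews_per_sibling"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"range {name}=({lo},{hi}) is empty")


# ---------------------------------------------------------------------------
# family plan: an intermediate the pedigree AND the answer sequence share


@dataclass
class _PlanMember:
    relation_slot: str
    sex: Sex
    alive: Vital
    age: int | None
    diagnoses: list[tuple[Site, int | None]] = field(default_factory=list)
    children: list["_PlanMember"] = field(default_factory=list)  # cousins / nieces


@dataclass
class _FamilyPlan:
    proband: _PlanMember
    pat_grandfather: _PlanMember
    pat_grandmother: _PlanMember
    mat_grandfather: _PlanMember
    mat_grandmother: _PlanMember
    father: _PlanMember
    mother: _PlanMember
    pat_uncles_aunts: list[_PlanMember]
    mat_uncles_aunts: list[_PlanMember]
    siblings: list[_PlanMember]
    children: list[_PlanMember]

    def fixed_slots(self) -> list[_PlanMember]:
        return [self.pat_grandfather, self.pat_grandmother,
                self.mat_grandfather, self.mat_grandmother,
                self.father, self.mother]

    def interview_order(self) -> list[_PlanMember]:
        """All members in the order the interview creates them."""
        out = [self.proband] + self.fixed_slots()
        out += self.pat_uncles_aunts + self.mat_uncles_aunts
        for ua in self.pat_uncles_aunts + self.mat_uncles_aunts:
            out += ua.children
        out += self.siblings
        out += self.children
        for sib in self.siblings:
            out += sib.children
        return out


def _answers_from_plan(plan: _FamilyPlan) -> list[str]:
    """The raw answer sequence reproducing ``plan`` through the interview."""
    a: list[str] = []

    def age_answer(m: _PlanMember) -> str:
        return "unknown" if m.age is None else str(m.age)

    def details(m: _PlanMember, with_sex: bool) -> None:
        if with_sex:
            a.append(m.sex.value)
        a.append(m.alive.value)
        a.append(age_answer(m))

    a.append(plan.proband.sex.value)
    a.append(age_answer(plan.proband))
    for slot in plan.fixed_slots():
        details(slot, with_sex=False)
    for group in (plan.pat_uncles_aunts, plan.mat_uncles_aunts):
        a.append(str(len(group)))
        for m in group:
            details(m, with_sex=True)
    for ua in plan.pat_uncles_aunts + plan.mat_uncles_aunts:
        a.append(str(len(ua.children)))
        for m in ua.children:
            details(m, with_sex=True)
    a.append(str(len(plan.siblings)))
    for m in plan.siblings:
        details(m, with_sex=True)
    a.append(str(len(plan.children)))
    for m in plan.children:
        details(m, with_sex=True)
    for sib in plan.siblings:
        a.append(str(len(sib.children)))
        for m in sib.children:
            details(m, with_sex=True)
    # medical histories, interview member order
    for m in plan.interview_order():
        if not m.diagnoses:
            a.append("no")
            continue
        a.append("yes")
        for i, (site, dx_age) in enumerate(m.diagnoses):
            a.append(site.value)
            a.append("unknown" if dx_age is None else str(dx_age))
            a.append("yes" if i < len(m.diagnoses) - 1 else "no")
    return a


def _pedigree_from_plan(plan: _FamilyPlan) -> Pedigree:
    """Build the pedigree directly, assigning ids as the interview would."""
    order = plan.interview_order()
    ids = {id(m): f"R{i:02d}" for i, m in enumerate(order, start=1)}

    def pid(m: _PlanMember | None) -> str | None:
        return None if m is None else ids[id(m)]

    parent_of: dict[int, tuple[_PlanMember | None, _PlanMember | None]] = {}
    parent_of[id(plan.proband)] = (plan.mother, plan.father)
    parent_of[id(plan.father)] = (plan.pat_grandmother, plan.pat_grandfather)
    parent_of[id(plan.mother)] = (plan.mat_grandmother, plan.mat_grandfather)
    for ua in plan.pat_uncles_aunts:
        parent_of[id(ua)] = (plan.pat_grandmother, plan.pat_grandfather)
    for ua in plan.mat_uncles_aunts:
        parent_of[id(ua)] = (plan.mat_grandmother, plan.mat_grandfather)
    for sib in plan.siblings:
        parent_of[id(sib)] = (plan.mother, plan.father)
    for single_parent_group, owner in (
        [(ua.children, ua) for ua in plan.pat_uncles_aunts + plan.mat_uncles_aunts]
        + [(plan.children, plan.proband)]
        + [(sib.children, sib) for sib in plan.siblings]
    ):
        for child in single_parent_group:
            if owner.sex is Sex.MALE:
                parent_of[id(child)] = (None, owner)
            else:
                parent_of[id(child)] = (owner, None)

    persons = []
    for m in order:
        mo, fa = parent_of.get(id(m), (None, None))
        persons.append(Person(
            person_id=ids[id(m)],
            sex=m.sex,
            alive=m.alive,
            age_years=m.age,
            mother_id=pid(mo),
            father_id=pid(fa),
            diagnoses=tuple(
                CancerDiagnosis(site=s, age_at_diagnosis=ag, primary_index=i)
                for s, ag, i in _indexed(m.diagnoses)),
            is_proband=(m is plan.proband),
        ))
    return Pedigree.from_persons(persons)


def _indexed(diagnoses: list[tuple[Site, int | None]]):
    counts: dict[Site, int] = {}
    for site, age in diagnoses:
        counts[site] = counts.get(site, 0) + 1
        yield site, age, counts[site]


# ---------------------------------------------------------------------------
# random generation


def _sample_member(rng: random.Random, cfg: SimConfig, slot: str, sex: Sex,
                   age: int | None) -> _PlanMember:
    if age is not None:
        age = max(0, min(130, age))
    alive = Vital.ALIVE
    if age is not None:
        p_dead = min(0.9, max(0.02, (age - 45) / 90))
        if rng.random() < p_dead:
            alive = Vital.DECEASED
    if rng.random() < 0.03:
        alive = Vital.UNKNOWN
    known_age = age
    if age is not None and slot != "proband" and \
            rng.random() < cfg.unknown_age_fraction:
        known_age = None
    m = _PlanMember(relation_slot=slot, sex=sex, alive=alive, age=known_age)
    _sample_diagnoses(rng, cfg, m, true_age=age)
    return m


def _sample_diagnoses(rng: random.Random, cfg: SimConfig, m: _PlanMember,
                      true_age: int | None) -> None:
    def draw_age(site: Site) -> int | None:
        lo, hi = cfg.diagnosis_age_range[site.value]
        if true_age is not None:
            hi = min(hi, true_age)
            lo = min(lo, hi)
        dx_age = rng.randint(lo, hi)
        if rng.random() < cfg.unknown_age_fraction:
            return None
        return dx_age

    inc = cfg.incidence
    p_breast = inc["breast_female"] if m.sex is Sex.FEMALE else inc["breast_male"]
    if rng.random() < p_breast:
        m.diagnoses.append((Site.BREAST, draw_age(Site.BREAST)))
        if rng.random() < cfg.second_breast_primary_prob:
            m.diagnoses.append((Site.BREAST, draw_age(Site.BREAST)))
    if m.sex is Sex.FEMALE and rng.random() < inc["ovarian"]:
        m.diagnoses.append((Site.OVARIAN, draw_age(Site.OVARIAN)))
    if rng.random() < inc["pancreatic"]:
        m.diagnoses.append((Site.PANCREATIC, draw_age(Site.PANCREATIC)))
    if m.sex is Sex.MALE and rng.random() < inc["prostate"]:
        m.diagnoses.append((Site.PROSTATE, draw_age(Site.PROSTATE)))
    if rng.random() < inc["other"]:
        m.diagnoses.append((Site.OTHER, draw_age(Site.OTHER)))


def _generate_plan(cfg: SimConfig) -> _FamilyPlan:
    rng = random.Random(cfg.seed)
    coin = lambda: rng.choice([Sex.FEMALE, Sex.MALE])
    pro_age = rng.randint(25, 75)
    proband = _sample_member(rng, cfg, "proband", coin(), pro_age)
    proband.alive = Vital.ALIVE
    proband.age = pro_age  # the proband's own age is always known

    father_age = pro_age + rng.randint(18, 35)
    mother_age = pro_age + rng.randint(18, 35)
    father = _sample_member(rng, cfg, "father", Sex.MALE, father_age)
    mother = _sample_member(rng, cfg, "mother", Sex.FEMALE, mother_age)
    pat_gf = _sample_member(rng, cfg, "pat_grandfather", Sex.MALE,
                            father_age + rng.randint(18, 35))
    pat_gm = _sample_member(rng, cfg, "pat_grandmother", Sex.FEMALE,
                            father_age + rng.randint(18, 35))
    mat_gf = _sample_member(rng, cfg, "mat_grandfather", Sex.MALE,
                            mother_age + rng.randint(18, 35))
    mat_gm = _sample_member(rng, cfg, "mat_grandmother", Sex.FEMALE,
                            mother_age + rng.randint(18, 35))

    def group(slot: str, rng_range: tuple[int, int], base_age: int,
              spread: int) -> list[_PlanMember]:
        n = rng.randint(*rng_range)
        return [_sample_member(rng, cfg, slot, coin(),
                               base_age + rng.randint(-spread, spread))
                for _ in range(n)]

    pat_uas = group("pat_uncle_aunt", cfg.uncles_aunts_per_side, father_age, 10)
    mat_uas = group("mat_uncle_aunt", cfg.uncles_aunts_per_side, mother_age, 10)
    for ua in pat_uas + mat_uas:
        n = rng.randint(*cfg.cousins_per_uncle_aunt)
        base = (ua.age if ua.age is not None else pro_age + 25) - rng.randint(18, 35)
        ua.children = [_sample_member(rng, cfg, "cousin", coin(),
                                      base + rng.randint(-8, 8))
                       for _ in range(n)]
    siblings = group("sibling", cfg.siblings, pro_age, 10)
    children = [_sample_member(rng, cfg, "child", coin(),
                               max(0, pro_age - rng.randint(16, 40)))
                for _ in range(rng.randint(*cfg.children))]
    for sib in siblings:
        n = rng.randint(*cfg.nieces_nephews_per_sibling)
        base = (sib.age if sib.age is not None else pro_age) - rng.randint(16, 40)
        sib.children = [_sample_member(rng, cfg, "niece_nephew", coin(),
                                       max(0, base + rng.randint(-5, 5)))
                        for _ in range(n)]
    return _FamilyPlan(
        proband=proband,
        pat_grandfather=pat_gf, pat_grandmother=pat_gm,
        mat_grandfather=mat_gf, mat_grandmother=mat_gm,
        father=father, mother=mother,
        pat_uncles_aunts=pat_uas, mat_uncles_aunts=mat_uas,
        siblings=siblings, children=children,
    )


def generate_pedigree(config: SimConfig | None = None
                      ) -> tuple[Pedigree, list[str]]:
    """Generate one synthetic pedigree plus its interview answer sequence.

    Identical (config, seed) gives byte-identical output; the answer
    sequence replayed through the interview reconstructs this pedigree
    exactly.
    """
    cfg = config or SimConfig()
    cfg.validate()
    plan = _generate_plan(cfg)
    return _pedigree_from_plan(plan), _answers_from_plan(plan)


# ---------------------------------------------------------------------------
# scenario fixtures


def _fixture_plans() -> list[tuple[_FamilyPlan, bool, list[str], str]]:
    def member(slot, sex, alive, age, dxs=()):
        return _PlanMember(relation_slot=slot, sex=sex, alive=alive, age=age,
                           diagnoses=list(dxs))

    # scenario 1: met through the proband's own early-onset breast cancer
    s1 = _FamilyPlan(
        proband=member("proband", Sex.FEMALE, Vital.ALIVE, 45,
                       [(Site.BREAST, 43)]),
        pat_grandfather=member("pat_grandfather", Sex.MALE, Vital.DECEASED, 84),
        pat_grandmother=member("pat_grandmother", Sex.FEMALE, Vital.DECEASED, 88),
        mat_grandfather=member("mat_grandfather", Sex.MALE, Vital.DECEASED, 79),
        mat_grandmother=member("mat_grandmother", Sex.FEMALE, Vital.DECEASED, 91),
        father=member("father", Sex.MALE, Vital.ALIVE, 72),
        mother=member("mother", Sex.FEMALE, Vital.ALIVE, 70),
        pat_uncles_aunts=[], mat_uncles_aunts=[],
        siblings=[member("sibling", Sex.FEMALE, Vital.ALIVE, 48)],
        children=[],
    )
    # scenario 2: proband healthy; met through the mother's ovarian cancer
    s2 = _FamilyPlan(
        proband=member("proband", Sex.FEMALE, Vital.ALIVE, 52),
        pat_grandfather=member("pat_grandfather", Sex.MALE, Vital.DECEASED, 86),
        pat_grandmother=member("pat_grandmother", Sex.FEMALE, Vital.ALIVE, 94),
        mat_grandfather=member("mat_grandfather", Sex.MALE, Vital.DECEASED, 81),
        mat_grandmother=member("mat_grandmother", Sex.FEMALE, Vital.DECEASED, 77),
        father=member("father", Sex.MALE, Vital.ALIVE, 78),
        mother=member("mother", Sex.FEMALE, Vital.ALIVE, 74,
                      [(Site.OVARIAN, 61)]),
        pat_uncles_aunts=[member("pat_uncle_aunt", Sex.FEMALE, Vital.ALIVE, 75)],
        mat_uncles_aunts=[],
        siblings=[member("sibling", Sex.MALE, Vital.ALIVE, 49)],
        children=[member("child", Sex.FEMALE, Vital.ALIVE, 26)],
    )
    # scenario 3: later-onset breast cancer, sporadic-looking family; not met
    s3 = _FamilyPlan(
        proband=member("proband", Sex.FEMALE, Vital.ALIVE, 55,
                       [(Site.BREAST, 54)]),
        pat_grandfather=member("pat_grandfather", Sex.MALE, Vital.DECEASED, 82),
        pat_grandmother=member("pat_grandmother", Sex.FEMALE, Vital.ALIVE, 92),
        mat_grandfather=member("mat_grandfather", Sex.MALE, Vital.DECEASED, 85),
        mat_grandmother=member("mat_grandmother", Sex.FEMALE, Vital.DECEASED, 85,
                               [(Site.OTHER, 80)]),
        father=member("father", Sex.MALE, Vital.ALIVE, 80),
        mother=member("mother", Sex.FEMALE, Vital.ALIVE, 78),
        pat_uncles_aunts=[member("pat_uncle_aunt", Sex.FEMALE, Vital.ALIVE, 77)],
        mat_uncles_aunts=[member("mat_uncle_aunt", Sex.MALE, Vital.ALIVE, 74)],
        siblings=[],
        children=[member("child", Sex.MALE, Vital.ALIVE, 28)],
    )
    return [
        (s1, True, ["A1"], "criteria met through the proband's own history"),
        (s2, True, ["A7"], "criteria met through family history only"),
        (s3, False, [], "sporadic-looking history; no active criterion met"),
    ]


def scenario_fixtures() -> list[tuple[Pedigree, bool]]:
    """The three screening scenarios with their expected overall outcomes."""
    return [(_pedigree_from_plan(plan), expected)
            for plan, expected, _, _ in _fixture_plans()]


def scenario_fixture_documents() -> list[dict]:
    """Fixture documents (pedigree + expectation metadata) for shipping."""
    docs = []
    for i, (plan, expected, met, note) in enumerate(_fixture_plans(), start=1):
        ped = _pedigree_from_plan(plan)
        docs.append({
            "scenario": i,
            "synthetic": True,
            "note": ("synthetic reconstruction of a screening scenario: "
                     + note),
            "pedigree": ped.to_dict(),
            "expected": {"overall": expected, "met_criteria": met},
            "answers": _answers_from_plan(plan),
        })
    return docs


def load_shipped_fixture(scenario: int) -> dict:
    name = f"scenario{scenario}_synthetic.json"
    text = resources.files("hbocscreen.data.fixtures").joinpath(name) \
        .read_text(encoding="utf-8")
    return json.loads(text)


# ---------------------------------------------------------------------------
# the naive oracle


def _brute_paths(ped: Pedigree, a: str, b: str) -> list[int]:
    """Lengths of all simple up-then-down parent-link paths from a to b."""
    parents = {pid: {x for x in (p.mother_id, p.father_id)
                     if x is not None and x in ped.persons}
               for pid, p in ped.persons.items()}
    children: dict[str, set[str]] = {pid: set() for pid in ped.persons}
    for pid, ps in parents.items():
        for parent in ps:
            children[parent].add(pid)

    lengths: list[int] = []

    def dfs(node: str, visited: tuple[str, ...], climbing: bool) -> None:
        if node == b and len(visited) > 1:
            lengths.append(len(visited) - 1)
            return
        nxt = set(children[node])
        if climbing:
            for parent in parents[node]:
                if parent not in visited:
                    dfs(parent, visited + (parent,), True)
        for child in nxt:
            if child not in visited:
                dfs(child, visited + (child,), False)

    dfs(a, (a,), True)
    return lengths


def brute_relatedness(ped: Pedigree, a: str, b: str) -> Fraction:
    return min(Fraction(1),
               sum((Fraction(1, 2) ** n for n in _brute_paths(ped, a, b)),
                   Fraction(0)))


def brute_degree(ped: Pedigree, a: str, b: str) -> Degree:
    r = brute_relatedness(ped, a, b)
    if r == 0:
        return Degree.UNRELATED
    for frac, deg in ((Fraction(1, 2), Degree.FIRST),
                      (Fraction(1, 4), Degree.SECOND),
                      (Fraction(1, 8), Degree.THIRD)):
        if r == frac:
            return deg
    if r < Fraction(1, 8):
        return Degree.DISTANT
    return Degree.FIRST if r > Fraction(1, 4) else Degree.SECOND


def _brute_sides(ped: Pedigree, anchor: str, b: str) -> set[str]:
    """Which of the anchor's parents the blood paths to ``b`` pass through."""
    parents = {pid: [x for x in (p.mother_id, p.father_id)
                     if x is not None and x in ped.persons]
               for pid, p in ped.persons.items()}
    anchor_p = ped[anchor]
    sides: set[str] = set()
    children: dict[str, set[str]] = {pid: set() for pid in ped.persons}
    for pid, ps in parents.items():
        for parent in ps:
            children[parent].add(pid)

    def dfs(node, visited, climbing, first_step):
        if node == b and len(visited) > 1:
            if first_step == anchor_p.mother_id:
                sides.add("maternal")
            elif first_step == anchor_p.father_id:
                sides.add("paternal")
            else:
                sides.add("descendant")
            return
        if climbing:
            for parent in parents[node]:
                if parent not in visited:
                    dfs(parent, visited + (parent,),
                        True, first_step or parent)
        for child in children[node]:
            if child not in visited:
                dfs(child, visited + (child,),
                    False, first_step if first_step else "down")

    dfs(anchor, (anchor,), True, None)
    return sides


def _oracle_limited_history(ped: Pedigree, anchor: str, rs: RuleSet) -> bool:
    th = rs.thresholds
    tallies = {"maternal": 0, "paternal": 0}
    for pid, p in ped.persons.items():
        if pid == anchor or p.sex is not Sex.FEMALE:
            continue
        if brute_degree(ped, anchor, pid) not in (Degree.FIRST, Degree.SECOND):
            continue
        if p.age_years is None or p.age_years < th.lfh_female_age:
            continue
        sides = _brute_sides(ped, anchor, pid) - {"descendant", "down"}
        for s in sides:
            tallies[s] += 1
    return min(tallies.values()) < th.lfh_min_females


def _oracle_close_relatives(ped: Pedigree, anchor: str) -> list[str]:
    close = (Degree.FIRST, Degree.SECOND, Degree.THIRD)
    return [pid for pid in ped.persons
            if pid != anchor and brute_degree(ped, anchor, pid) in close]


def _oracle_personal(ped: Pedigree, anchor: str, cid: str, rs: RuleSet) -> bool:
    """Re-check one personal-history criterion (A1-A6) for ``anchor``."""
    th = rs.thresholds
    p = ped[anchor]
    breast = [d for d in p.diagnoses if d.site is Site.BREAST]
    if cid == "A1":
        return any(d.age_at_diagnosis is not None
                   and d.age_at_diagnosis <= th.a1_age_max for d in breast)
    if cid == "A2":
        in_window = any(
            d.age_at_diagnosis is not None
            and th.a2_age_min <= d.age_at_diagnosis <= th.a2_age_max
            for d in breast)
        if not in_window:
            return False
        if len({d.primary_index for d in breast}) >= 2:
            return True
        for pid in _oracle_close_relatives(ped, anchor):
            rel = ped[pid]
            for d in rel.diagnoses:
                if d.site is Site.BREAST or d.site is Site.PANCREATIC:
                    return True
                if d.site is Site.OVARIAN and rel.sex is Sex.FEMALE:
                    return True
        return _oracle_limited_history(ped, anchor, rs)
    if cid == "A3":
        if not breast:
            return False
        for pid in _oracle_close_relatives(ped, anchor):
            rel = ped[pid]
            for d in rel.diagnoses:
                if d.site is Site.BREAST and d.age_at_diagnosis is not None \
                        and d.age_at_diagnosis <= th.a3_relative_age_max:
                    return True
                if d.site is Site.BREAST and rel.sex is Sex.MALE:
                    return True
                if d.site is Site.OVARIAN and rel.sex is Sex.FEMALE:
                    return True
                if d.site is Site.PANCREATIC:
                    return True
        return False
    if cid == "A4":
        return p.sex is Sex.FEMALE and any(
            d.site is Site.OVARIAN for d in p.diagnoses)
    if cid == "A5":
        return p.sex is Sex.MALE and bool(breast)
    if cid == "A6":
        return any(d.site is Site.PANCREATIC for d in p.diagnoses)
    raise ValueError(cid)


def naive_oracle(ped: Pedigree, ruleset: RuleSet | None = None
                 ) -> ScreeningResult:
    """Exhaustive re-evaluation of the rule set, independent of the engine."""
    rs = ruleset or default_ruleset()
    anchor = ped.proband_id
    statuses: dict[str, Status] = {}
    for c in rs.criteria:
        if c.mode is Mode.OMITTED:
            statuses[c.criterion_id] = Status.NOT_ASKED
            continue
        if c.criterion_id == "A7":
            met = False
            personal_ids = [x for x in rs.active_ids()
                            if x in ("A1", "A2", "A3", "A4", "A5", "A6")]
            for pid in ped.persons:
                if pid == anchor:
                    continue
                if brute_degree(ped, anchor, pid) not in (Degree.FIRST,
                                                          Degree.SECOND):
                    continue
                if any(_oracle_personal(ped, pid, x, rs) for x in personal_ids):
                    met = True
                    break
        else:
            met = _oracle_personal(ped, anchor, c.criterion_id, rs)
        statuses[c.criterion_id] = Status.MET if met else Status.NOT_MET
    return ScreeningResult(
        statuses=statuses,
        overall=any(s is Status.MET for s in statuses.values()),
        evidence={},
        ruleset_name=rs.name,
        ruleset_version=rs.version,
        proband_id=anchor,
    )
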