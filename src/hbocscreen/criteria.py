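"""Modified NCCN BRCA1/2 testing criteria (v3.2019) as a deterministic rule set.

The rule set keeps seven ACTIVE personal/family-history criteria and carries
ten OMITTED criteria that a structured-interview screener cannot elicit
(known familial variant, prostate-grade arms, tumour profiling, receptor
status, ancestry).  OMITTED criteria always evaluate to NOT_ASKED so the
result sheet shows exactly which guideline items were out of reach, rather
than silently dropping them.

Age semantics: an unknown diagnosis age fails every age-bounded condition
(screening must not assert what was not elicited) but satisfies any-age
conditions.  Sex semantics: ovarian arms require recorded female sex,
male-breast arms recorded male sex; unknown sex never satisfies a sex
condition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Callable, Mapping, Sequence

import yaml

from .pedigree import (
    CancerDiagnosis,
    Degree,
    Pedigree,
    PedigreeError,
    Person,
    Sex,
    Side,
    Site,
    validate_pedigree,
)


class Mode(str, Enum):
    ACTIVE = "ACTIVE"
    OMITTED = "OMITTED"


class Status(str, Enum):
    MET = "MET"
    NOT_MET = "NOT_MET"
    NOT_ASKED = "NOT_ASKED"


@dataclass(frozen=True)
class Thresholds:
    """Numeric knobs of the retained criteria.

    a1_age_max: latest proband breast-cancer diagnosis age for the
        early-onset criterion (<= 45).
    a2_age_min/a2_age_max: proband breast-cancer diagnosis window of the
        46-50 criterion.
    a3_relative_age_max: relative breast-cancer age cap in the
        any-age-proband criterion (<= 50).
    lfh_min_females / lfh_female_age: "limited family history" holds on a
        lineage side with fewer than ``lfh_min_females`` females of first
        or second degree known to have reached ``lfh_female_age`` years.
    """

    a1_age_max: int = 45
    a2_age_min: int = 46
    a2_age_max: int = 50
    a3_relative_age_max: int = 50
    lfh_min_females: int = 2
    lfh_female_age: int = 46

    def to_dict(self) -> dict:
        return {
            "a1_age_max": self.a1_age_max,
            "a2_age_min": self.a2_age_min,
            "a2_age_max": self.a2_age_max,
            "a3_relative_age_max": self.a3_relative_age_max,
            "lfh_min_females": self.lfh_min_females,
            "lfh_female_age": self.lfh_female_age,
        }


@dataclass(frozen=True)
class Criterion:
    criterion_id: str
    description: str
    mode: Mode
    # predicate(pedigree, ruleset) -> (met, evidence rows); None for OMITTED
    predicate: Callable[[Pedigree, "RuleSet"], tuple[bool, list[dict]]] | None = None


@dataclass(frozen=True)
class RuleSet:
    name: str
    version: str
    criteria: tuple[Criterion, ...]
    thresholds: Thresholds = field(default_factory=Thresholds)

    def __post_init__(self):
        ids = [c.criterion_id for c in self.criteria]
        if len(ids) != len(set(ids)):
            raise ValueError("criterion_id values must be unique in a RuleSet")

    def __iter__(self):
        return iter(self.criteria)

    def get(self, criterion_id: str) -> Criterion:
        for c in self.criteria:
            if c.criterion_id == criterion_id:
                return c
        raise KeyError(criterion_id)

    def active_ids(self) -> list[str]:
        return [c.criterion_id for c in self.criteria if c.mode is Mode.ACTIVE]

    def omitted_ids(self) -> list[str]:
        return [c.criterion_id for c in self.criteria if c.mode is Mode.OMITTED]


@dataclass(frozen=True)
class ScreeningResult:
    """Per-criterion statuses plus overall determination and evidence."""

    statuses: Mapping[str, Status]
    overall: bool
    evidence: Mapping[str, tuple[dict, ...]]
    ruleset_name: str
    ruleset_version: str
    proband_id: str

    def to_dict(self) -> dict:
        return {
            "ruleset": {"name": self.ruleset_name, "version": self.ruleset_version},
            "proband_id": self.proband_id,
            "statuses": {k: v.value for k, v in self.statuses.items()},
            "evidence": {k: list(v) for k, v in sorted(self.evidence.items())},
            "overall": self.overall,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent) + "\n"


# ---------------------------------------------------------------------------
# predicate helpers

def _dx_evidence(person: Person, dx: CancerDiagnosis, ped: Pedigree) -> dict:
    row = {
        "person_id": person.person_id,
        "site": dx.site.value,
        "age_at_diagnosis": dx.age_at_diagnosis,
        "primary_index": dx.primary_index,
    }
    if not person.is_proband:
        row["lineage_side"] = ped.lineage_side(person.person_id).value
    return row


def _breast_dx(p: Person) -> list[CancerDiagnosis]:
    return [dx for dx in p.diagnoses if dx.site is Site.BREAST]


def _has_site(p: Person, site: Site) -> bool:
    return any(dx.site is site for dx in p.diagnoses)


def _ovarian_dx(p: Person) -> list[CancerDiagnosis]:
    # fallopian tube / primary peritoneal are coded as ovarian at entry
    if p.sex is not Sex.FEMALE:
        return []
    return [dx for dx in p.diagnoses if dx.site is Site.OVARIAN]


def _male_breast_dx(p: Person) -> list[CancerDiagnosis]:
    if p.sex is not Sex.MALE:
        return []
    return _breast_dx(p)


def limited_family_history(ped: Pedigree, thresholds: Thresholds | None = None) -> bool:
    """Family structure too sparse to be informative on some lineage side.

    True iff on the maternal side or on the paternal side fewer than
    ``lfh_min_females`` female first- or second-degree relatives of the
    proband are known to have reached ``lfh_female_age`` years (current age
    or age at death; unknown ages do not count).  Full sisters and nieces
    (lineage side "both") inform both sides and count toward each tally;
    descendants count toward neither.
    """
    th = thresholds or Thresholds()
    counts = {Side.MATERNAL: 0, Side.PATERNAL: 0}
    pro = ped.proband_id
    for pid, p in ped.persons.items():
        if pid == pro or p.sex is not Sex.FEMALE:
            continue
        if ped.relationship_degree(pro, pid) not in (Degree.FIRST, Degree.SECOND):
            continue
        if p.age_years is None or p.age_years < th.lfh_female_age:
            continue
        side = ped.lineage_side(pid)
        if side in (Side.MATERNAL, Side.PATERNAL):
            counts[side] += 1
        elif side is Side.BOTH:
            counts[Side.MATERNAL] += 1
            counts[Side.PATERNAL] += 1
    return min(counts.values()) < th.lfh_min_females


# ---------------------------------------------------------------------------
# the seven retained predicates

def _a1(ped: Pedigree, rs: "RuleSet") -> tuple[bool, list[dict]]:
    th = rs.thresholds
    pro = ped.proband
    ev = [
        _dx_evidence(pro, dx, ped)
        for dx in _breast_dx(pro)
        if dx.age_at_diagnosis is not None and dx.age_at_diagnosis <= th.a1_age_max
    ]
    return bool(ev), ev


def _a2(ped: Pedigree, rs: "RuleSet") -> tuple[bool, list[dict]]:
    th = rs.thresholds
    pro = ped.proband
    window = [
        dx for dx in _breast_dx(pro)
        if dx.age_at_diagnosis is not None
        and th.a2_age_min <= dx.age_at_diagnosis <= th.a2_age_max
    ]
    if not window:
        return False, []
    ev = [_dx_evidence(pro, dx, ped) for dx in window]
    # arm 1: a second breast primary at any age
    if len({dx.primary_index for dx in _breast_dx(pro)}) >= 2:
        extra = [_dx_evidence(pro, dx, ped) for dx in _breast_dx(pro)
                 if dx not in window]
        return True, ev + extra
    # arm 2: >= 1 close blood relative with breast, ovarian or pancreatic cancer
    for pid in sorted(ped.close_blood_relatives()):
        rel = ped[pid]
        hits = (_breast_dx(rel) + _ovarian_dx(rel)
                + [dx for dx in rel.diagnoses if dx.site is Site.PANCREATIC])
        if hits:
            return True, ev + [_dx_evidence(rel, hits[0], ped)]
    # arm 3: limited or unknown family history
    if limited_family_history(ped, th):
        return True, ev + [{"person_id": pro.person_id,
                            "note": "limited family history"}]
    return False, []


def _a3(ped: Pedigree, rs: "RuleSet") -> tuple[bool, list[dict]]:
    th = rs.thresholds
    pro = ped.proband
    breast = _breast_dx(pro)
    if not breast:
        return False, []
    ev = [_dx_evidence(pro, breast[0], ped)]
    for pid in sorted(ped.close_blood_relatives()):
        rel = ped[pid]
        young_breast = [
            dx for dx in _breast_dx(rel)
            if dx.age_at_diagnosis is not None
            and dx.age_at_diagnosis <= th.a3_relative_age_max
        ]
        hits = (young_breast + _ovarian_dx(rel) + _male_breast_dx(rel)
                + [dx for dx in rel.diagnoses if dx.site is Site.PANCREATIC])
        if hits:
            return True, ev + [_dx_evidence(rel, hits[0], ped)]
    return False, []


def _a4(ped: Pedigree, rs: "RuleSet") -> tuple[bool, list[dict]]:
    pro = ped.proband
    ev = [_dx_evidence(pro, dx, ped) for dx in _ovarian_dx(pro)]
    return bool(ev), ev


def _a5(ped: Pedigree, rs: "RuleSet") -> tuple[bool, list[dict]]:
    pro = ped.proband
    ev = [_dx_evidence(pro, dx, ped) for dx in _male_breast_dx(pro)]
    return bool(ev), ev


def _a6(ped: Pedigree, rs: "RuleSet") -> tuple[bool, list[dict]]:
    pro = ped.proband
    ev = [_dx_evidence(pro, dx, ped)
          for dx in pro.diagnoses if dx.site is Site.PANCREATIC]
    return bool(ev), ev


def _a7(ped: Pedigree, rs: "RuleSet") -> tuple[bool, list[dict]]:
    """A first- or second-degree relative would themselves qualify on A1-A6."""
    pro = ped.proband_id
    ev: list[dict] = []
    for pid in sorted(ped.persons):
        if pid == pro:
            continue
        if ped.relationship_degree(pro, pid) not in (Degree.FIRST, Degree.SECOND):
            continue
        sub = evaluate_as_proband(ped, pid, rs)
        met = [cid for cid, st in sub.statuses.items() if st is Status.MET]
        if met:
            ev.append({
                "person_id": pid,
                "lineage_side": ped.lineage_side(pid).value,
                "qualifies_via": met,
            })
    return bool(ev), ev


_ACTIVE_SPECS: list[tuple[str, str, Callable]] = [
    ("A1", "Personal history of breast cancer diagnosed at age <= 45", _a1),
    ("A2", "Personal history of breast cancer diagnosed at age 46-50 with a "
           "second breast primary, a close blood relative with breast, "
           "ovarian or pancreatic cancer, or a limited/unknown family "
           "history", _a2),
    ("A3", "Personal history of breast cancer at any age with a close blood "
           "relative with breast cancer diagnosed <= 50, ovarian cancer, "
           "male breast cancer, or pancreatic cancer", _a3),
    ("A4", "Personal history of ovarian cancer (including fallopian tube or "
           "primary peritoneal cancer) at any age", _a4),
    ("A5", "Personal history of male breast cancer at any age", _a5),
    ("A6", "Personal history of pancreatic cancer at any age", _a6),
    ("A7", "A first- or second-degree blood relative meeting any of the "
           "personal-history criteria above", _a7),
]

_OMITTED_SPECS: list[tuple[str, str]] = [
    ("O1", "Individual from a family with a known BRCA1/2 pathogenic or "
           "likely pathogenic variant, including variants found on research "
           "testing"),
    ("O2", "Breast cancer diagnosed at 41-50 with >= 1 close blood relative "
           "with high-grade (Gleason score >= 7) prostate cancer"),
    ("O3", "Triple-negative breast cancer diagnosed at <= 60"),
    ("O4", "Breast cancer at any age with >= 1 close blood relative with "
           "metastatic prostate cancer, or >= 2 additional breast cancer "
           "diagnoses at any age in close blood relatives"),
    ("O5", "Personal history of metastatic prostate cancer"),
    ("O6", "Personal history of high-grade prostate cancer (Gleason score "
           ">= 7) with the qualifying family-history combinations"),
    ("O7", "BRCA1/2 pathogenic/likely pathogenic variant detected by tumor "
           "profiling in the absence of germline analysis"),
    ("O8", "Individuals with BRCA-related cancer who may benefit from "
           "genetic testing to determine targeted-treatment eligibility"),
    ("O9", "Personal history of breast cancer with Ashkenazi Jewish "
           "ancestry"),
    ("O10", "Personal history of high-grade prostate cancer (Gleason score "
            ">= 7) with Ashkenazi Jewish ancestry"),
]

DEFAULT_RULESET_NAME = "modified-nccn-brca"
DEFAULT_RULESET_VERSION = "3.2019"


def default_ruleset(thresholds: Thresholds | None = None,
                    mode_overrides: Mapping[str, Mode] | None = None) -> RuleSet:
    """The default rule set: 7 ACTIVE criteria plus 10 OMITTED (NOT_ASKED).

    ``mode_overrides`` switches individual criteria between ACTIVE and
    OMITTED (an OMITTED-by-default criterion has no predicate and cannot be
    activated; requesting that raises ValueError).
    """
    overrides = dict(mode_overrides or {})
    crits: list[Criterion] = []
    for cid, desc, pred in _ACTIVE_SPECS:
        mode = Mode(overrides.pop(cid, Mode.ACTIVE))
        crits.append(Criterion(cid, desc, mode,
                               pred if mode is Mode.ACTIVE else None))
    for cid, desc in _OMITTED_SPECS:
        mode = Mode(overrides.pop(cid, Mode.OMITTED))
        if mode is Mode.ACTIVE:
            raise ValueError(
                f"criterion {cid} has no elicitable predicate and cannot be ACTIVE")
        crits.append(Criterion(cid, desc, Mode.OMITTED, None))
    if overrides:
        raise ValueError(f"unknown criterion ids in overrides: {sorted(overrides)}")
    return RuleSet(
        name=DEFAULT_RULESET_NAME,
        version=DEFAULT_RULESET_VERSION,
        criteria=tuple(crits),
        thresholds=thresholds or Thresholds(),
    )


# ---------------------------------------------------------------------------
# evaluation

def evaluate(ped: Pedigree, ruleset: RuleSet | None = None) -> ScreeningResult:
    """Evaluate every criterion independently; pure and deterministic."""
    rs = ruleset or default_ruleset()
    violations = validate_pedigree(ped)
    if violations:
        raise PedigreeError(
            "cannot evaluate an invalid pedigree: " + "; ".join(violations))
    return _evaluate_checked(ped, rs, include_family_clause=True)


def _evaluate_checked(ped: Pedigree, rs: RuleSet,
                      include_family_clause: bool) -> ScreeningResult:
    statuses: dict[str, Status] = {}
    evidence: dict[str, tuple[dict, ...]] = {}
    for c in rs.criteria:
        if c.mode is Mode.OMITTED:
            statuses[c.criterion_id] = Status.NOT_ASKED
            continue
        if c.criterion_id == "A7" and not include_family_clause:
            continue
        met, ev = c.predicate(ped, rs)
        statuses[c.criterion_id] = Status.MET if met else Status.NOT_MET
        if met:
            evidence[c.criterion_id] = tuple(ev)
    return ScreeningResult(
        statuses=statuses,
        overall=any(s is Status.MET for s in statuses.values()),
        evidence=evidence,
        ruleset_name=rs.name,
        ruleset_version=rs.version,
        proband_id=ped.proband_id,
    )


def evaluate_as_proband(ped: Pedigree, person: str,
                        ruleset: RuleSet | None = None) -> ScreeningResult:
    """Evaluate the personal-history criteria as if ``person`` were the proband.

    Re-roots the pedigree at ``person`` (degrees, sides and close-relative
    sets are recomputed from the new anchor) and evaluates A1-A6 only; the
    family-history clause A7 is excluded so the recursion depth is one.
    Persons related to the proband only by marriage are rejected.
    """
    rs = ruleset or default_ruleset()
    target = ped[person]  # raises on unknown id
    if person != ped.proband_id:
        if ped.relatedness_coefficient(ped.proband_id, person) == 0:
            raise PedigreeError(
                f"{person!r} is related to the proband only by marriage")
    rerooted = Pedigree(
        persons={
            pid: replace(p, is_proband=(pid == person))
            for pid, p in ped.persons.items()
        },
        proband_id=person,
    )
    return _evaluate_checked(rerooted, rs, include_family_clause=False)


# ---------------------------------------------------------------------------
# rule-set configuration files (YAML or JSON)

def ruleset_to_config(rs: RuleSet) -> dict:
    return {
        "name": rs.name,
        "version": rs.version,
        "criteria": {c.criterion_id: c.mode.value for c in rs.criteria},
        "thresholds": rs.thresholds.to_dict(),
    }


def ruleset_from_config(config: Mapping) -> RuleSet:
    th = Thresholds(**config.get("thresholds", {}))
    overrides = {cid: Mode(m) for cid, m in config.get("criteria", {}).items()}
    rs = default_ruleset(thresholds=th, mode_overrides=overrides)
    return replace(
        rs,
        name=config.get("name", rs.name),
        version=config.get("version", rs.version),
    )


def load_ruleset(path) -> RuleSet:
    """Load a rule-set config (YAML or JSON; JSON is a YAML subset)."""
    with open(path, "r", encoding="utf-8") as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, Mapping):
        raise ValueError(f"rule-set config {path} is not a mapping")
    return ruleset_from_config(config)


def save_ruleset(rs: RuleSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(ruleset_to_config(rs), fh, sort_keys=False)
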