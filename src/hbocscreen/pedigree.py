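"""Proband-anchored pedigree graph and kinship computations.

The pedigree is a directed acyclic graph of parent links anchored at a
proband (the individual being screened).  Genetic closeness between the
proband and a relative is measured by the relatedness coefficient *r*, the
expected fraction of DNA shared identical-by-descent:

    r(a, b) = sum over all simple common-ancestor paths of (1/2)^(edges)

A path climbs from ``a`` to a common ancestor and descends to ``b``,
visiting no vertex twice; paths through different common-ancestor couples
are counted separately (full siblings: two paths of length 2, r = 1/2).
Clinical degree-of-relationship classes follow from r: first degree
(r = 1/2), second (1/4), third (1/8).  "Close blood relative" in the
screening criteria means degrees one through three.

Unknown parents terminate path search (founders); relatives by marriage
have r = 0 and are never blood relatives.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field, replace
from enum import Enum
from fractions import Fraction
from typing import Iterable, Iterator, Mapping

import networkx as nx

MAX_AGE = 130


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"


class Vital(str, Enum):
    ALIVE = "alive"
    DECEASED = "deceased"
    UNKNOWN = "unknown"


class Site(str, Enum):
    """Cancer site groups the screening criteria distinguish.

    ``OVARIAN`` includes fallopian-tube and primary peritoneal carcinoma.
    """

    BREAST = "breast"
    OVARIAN = "ovarian"
    PANCREATIC = "pancreatic"
    PROSTATE = "prostate"
    OTHER = "other"


class Degree(str, Enum):
    FIRST = "first"
    SECOND = "second"
    THIRD = "third"
    DISTANT = "distant"
    UNRELATED = "unrelated"


class Side(str, Enum):
    MATERNAL = "maternal"
    PATERNAL = "paternal"
    BOTH = "both"
    SELF_OR_DESCENDANT = "self_or_descendant"
    UNRELATED = "unrelated"


class PedigreeError(ValueError):
    """Raised for operations on ill-formed pedigrees or unknown ids."""


@dataclass(frozen=True)
class CancerDiagnosis:
    """One primary cancer diagnosis.

    ``age_at_diagnosis`` is ``None`` when the age was not elicited.
    ``primary_index`` distinguishes independent primaries of the same site
    (1 = first primary; bilateral and metachronous breast cancers both get
    their own index).
    """

    site: Site
    age_at_diagnosis: int | None = None
    primary_index: int = 1

    def to_dict(self) -> dict:
        return {
            "site": self.site.value,
            "age_at_diagnosis": self.age_at_diagnosis,
            "primary_index": self.primary_index,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CancerDiagnosis":
        return cls(
            site=Site(d["site"]),
            age_at_diagnosis=d.get("age_at_diagnosis"),
            primary_index=int(d.get("primary_index", 1)),
        )


@dataclass(frozen=True)
class Person:
    """One pedigree member.

    ``age_years`` is the current age if alive, the age at death if
    deceased, ``None`` when unknown.  ``cancer_history_known`` is false for
    members whose medical history was never elicited (export-relevant only).
    """

    person_id: str
    sex: Sex = Sex.UNKNOWN
    alive: Vital = Vital.UNKNOWN
    age_years: int | None = None
    mother_id: str | None = None
    father_id: str | None = None
    diagnoses: tuple[CancerDiagnosis, ...] = ()
    is_proband: bool = False
    cancer_history_known: bool = True

    def __post_init__(self):
        object.__setattr__(self, "diagnoses", tuple(self.diagnoses))

    def to_dict(self) -> dict:
        d = {
            "person_id": self.person_id,
            "sex": self.sex.value,
            "alive": self.alive.value,
            "age_years": self.age_years,
            "mother_id": self.mother_id,
            "father_id": self.father_id,
            "diagnoses": [dx.to_dict() for dx in self.diagnoses],
            "is_proband": self.is_proband,
        }
        if not self.cancer_history_known:
            d["cancer_history_known"] = False
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "Person":
        return cls(
            person_id=str(d["person_id"]),
            sex=Sex(d.get("sex", "unknown")),
            alive=Vital(d.get("alive", "unknown")),
            age_years=d.get("age_years"),
            mother_id=d.get("mother_id"),
            father_id=d.get("father_id"),
            diagnoses=tuple(
                CancerDiagnosis.from_dict(x) for x in d.get("diagnoses", ())
            ),
            is_proband=bool(d.get("is_proband", False)),
            cancer_history_known=bool(d.get("cancer_history_known", True)),
        )


@dataclass(frozen=True)
class Pedigree:
    """Immutable collection of persons anchored at ``proband_id``.

    Construction does not validate; call :func:`validate_pedigree` (or
    :meth:`validate`) to obtain the list of invariant violations.
    """

    persons: Mapping[str, Person]
    proband_id: str

    def __post_init__(self):
        object.__setattr__(self, "persons", dict(self.persons))

    # -- construction -------------------------------------------------

    @classmethod
    def from_persons(cls, persons: Iterable[Person]) -> "Pedigree":
        by_id: dict[str, Person] = {}
        proband = None
        for p in persons:
            if p.person_id in by_id:
                raise PedigreeError(f"duplicate person_id {p.person_id!r}")
            by_id[p.person_id] = p
            if p.is_proband:
                proband = p.person_id
        if proband is None:
            raise PedigreeError("no proband in pedigree")
        return cls(persons=by_id, proband_id=proband)

    def add_person(self, person: Person) -> "Pedigree":
        if person.person_id in self.persons:
            raise PedigreeError(f"duplicate person_id {person.person_id!r}")
        new = dict(self.persons)
        new[person.person_id] = person
        proband = person.person_id if person.is_proband else self.proband_id
        return Pedigree(persons=new, proband_id=proband)

    def __len__(self) -> int:
        return len(self.persons)

    def __contains__(self, person_id: str) -> bool:
        return person_id in self.persons

    def __getitem__(self, person_id: str) -> Person:
        try:
            return self.persons[person_id]
        except KeyError:
            raise PedigreeError(f"unknown person_id {person_id!r}") from None

    def member_ids(self) -> list[str]:
        return sorted(self.persons)

    @property
    def proband(self) -> Person:
        return self[self.proband_id]

    # -- validation ----------------------------------------------------

    def validate(self) -> list[str]:
        return validate_pedigree(self)

    # -- kinship -------------------------------------------------------

    def _parents(self, pid: str) -> list[str]:
        p = self[pid]
        return [q for q in (p.mother_id, p.father_id)
                if q is not None and q in self.persons]

    def _ancestor_paths(self, start: str) -> dict[str, list[tuple[str, ...]]]:
        """All simple upward paths from ``start``, keyed by endpoint ancestor.

        Paths include the trivial path (start,) so ancestor-descendant
        pairs are handled uniformly.
        """
        out: dict[str, list[tuple[str, ...]]] = defaultdict(list)
        stack: list[tuple[str, tuple[str, ...]]] = [(start, (start,))]
        while stack:
            pid, path = stack.pop()
            out[pid].append(path)
            for parent in self._parents(pid):
                if parent not in path:  # guard against cyclic input
                    stack.append((parent, path + (parent,)))
        return out

    def relatedness_coefficient(self, a: str, b: str) -> Fraction:
        """Coefficient of relationship r between two distinct members."""
        if a == b:
            raise PedigreeError("relatedness_coefficient requires a != b")
        up_a = self._ancestor_paths(a)
        up_b = self._ancestor_paths(b)
        r = Fraction(0)
        for anc in up_a.keys() & up_b.keys():
            for pa in up_a[anc]:
                for pb in up_b[anc]:
                    if set(pa) & set(pb) == {anc}:
                        r += Fraction(1, 2) ** (len(pa) + len(pb) - 2)
        return min(r, Fraction(1))

    def relationship_degree(self, a: str, b: str) -> Degree:
        r = self.relatedness_coefficient(a, b)
        if r == 0:
            return Degree.UNRELATED
        if r == Fraction(1, 2):
            return Degree.FIRST
        if r == Fraction(1, 4):
            return Degree.SECOND
        if r == Fraction(1, 8):
            return Degree.THIRD
        if r < Fraction(1, 8):
            return Degree.DISTANT
        # r off the grid but above 1/8 (e.g. inbred lines): classify by the
        # nearest not-closer clinical class via the r value itself.
        if r > Fraction(1, 4):
            return Degree.FIRST
        return Degree.SECOND

    def close_blood_relatives(self, of: str | None = None) -> set[str]:
        """Members at first, second or third degree to ``of`` (default proband)."""
        anchor = self.proband_id if of is None else of
        close = {Degree.FIRST, Degree.SECOND, Degree.THIRD}
        return {
            pid for pid in self.persons
            if pid != anchor and self.relationship_degree(anchor, pid) in close
        }

    def lineage_side(self, b: str) -> Side:
        pro = self.proband_id
        if b == pro:
            return Side.SELF_OR_DESCENDANT
        self[b]  # raise on unknown id
        if pro in self._ancestor_paths(b):
            return Side.SELF_OR_DESCENDANT
        up_p = self._ancestor_paths(pro)
        up_b = self._ancestor_paths(b)
        mother = self.proband.mother_id
        father = self.proband.father_id
        sides: set[Side] = set()
        for anc in up_p.keys() & up_b.keys():
            for pa in up_p[anc]:
                for pb in up_b[anc]:
                    if set(pa) & set(pb) != {anc}:
                        continue
                    first_step = pa[1]  # len(pa) >= 2: b is not a descendant
                    if first_step == mother:
                        sides.add(Side.MATERNAL)
                    elif first_step == father:
                        sides.add(Side.PATERNAL)
        if not sides:
            return Side.UNRELATED
        if sides == {Side.MATERNAL}:
            return Side.MATERNAL
        if sides == {Side.PATERNAL}:
            return Side.PATERNAL
        return Side.BOTH

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "proband_id": self.proband_id,
            "persons": [self.persons[pid].to_dict()
                        for pid in sorted(self.persons)],
        }

    def to_json(self, indent: int = 2) -> str:
        """Canonical JSON (persons sorted by id) for diff/replay testing."""
        return json.dumps(self.to_dict(), indent=indent, sort_keys=False) + "\n"

    @classmethod
    def from_dict(cls, d: Mapping) -> "Pedigree":
        persons = {p["person_id"]: Person.from_dict(p) for p in d["persons"]}
        return cls(persons=persons, proband_id=str(d["proband_id"]))

    @classmethod
    def from_json(cls, text: str) -> "Pedigree":
        try:
            d = json.loads(text)
        except json.JSONDecodeError as e:
            raise PedigreeError(f"malformed pedigree JSON: {e}") from None
        if not isinstance(d, dict) or "persons" not in d or "proband_id" not in d:
            raise PedigreeError(
                "pedigree JSON must be an object with 'proband_id' and 'persons'")
        try:
            return cls.from_dict(d)
        except (KeyError, ValueError, TypeError) as e:
            raise PedigreeError(f"invalid pedigree document: {e}") from None

    def to_ped(self, family_id: str = "FAM1") -> str:
        """PLINK-style 6-column PED export (lossy: no diagnosis detail).

        SEX 1 = male, 2 = female, 0 = unknown.  PHENOTYPE 2 with >= 1
        cancer diagnosis, 1 with none, 0 when the history was never taken.
        """
        sex_code = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
        rows = []
        for pid in sorted(self.persons):
            p = self.persons[pid]
            if not p.cancer_history_known:
                pheno = "0"
            else:
                pheno = "2" if p.diagnoses else "1"
            rows.append("\t".join([
                family_id, pid,
                p.father_id or "0", p.mother_id or "0",
                sex_code[p.sex], pheno,
            ]))
        return "\n".join(rows) + "\n"

    def to_dot(self) -> str:
        """Graphviz DOT export of parent->child edges (layout not attempted)."""
        lines = ["digraph pedigree {"]
        shape = {Sex.MALE: "box", Sex.FEMALE: "ellipse", Sex.UNKNOWN: "diamond"}
        for pid in sorted(self.persons):
            p = self.persons[pid]
            style = ', style=bold' if p.is_proband else ""
            lines.append(f'  "{pid}" [shape={shape[p.sex]}{style}];')
        for pid in sorted(self.persons):
            p = self.persons[pid]
            for parent in (p.father_id, p.mother_id):
                if parent is not None and parent in self.persons:
                    lines.append(f'  "{parent}" -> "{pid}";')
        lines.append("}")
        return "\n".join(lines) + "\n"


def validate_pedigree(ped: Pedigree) -> list[str]:
    """Re-check every pedigree and person invariant; return violations.

    An empty list means the pedigree is well-formed.  Violations name the
    person(s) involved and are returned, never raised.
    """
    v: list[str] = []
    persons = ped.persons

    probands = [pid for pid, p in persons.items() if p.is_proband]
    if len(probands) != 1:
        v.append(f"expected exactly one proband, found {len(probands)}: {sorted(probands)}")
    if ped.proband_id not in persons:
        v.append(f"proband_id {ped.proband_id!r} not in pedigree")
    elif probands and ped.proband_id not in probands:
        v.append(f"proband_id {ped.proband_id!r} does not carry is_proband")

    for pid, p in persons.items():
        if p.age_years is not None and not (0 <= p.age_years <= MAX_AGE):
            v.append(f"{pid}: age_years {p.age_years} outside [0, {MAX_AGE}]")
        for ref, label, bad_sex in (
            (p.mother_id, "mother", Sex.MALE),
            (p.father_id, "father", Sex.FEMALE),
        ):
            if ref is None:
                continue
            if ref not in persons:
                v.append(f"{pid}: {label}_id {ref!r} does not resolve")
            elif persons[ref].sex == bad_sex:
                v.append(f"{pid}: {label}_id {ref!r} refers to a {bad_sex.value} person")
            if ref == pid:
                v.append(f"{pid}: is their own {label}")
        # diagnosis invariants
        seen_idx: dict[Site, list[int]] = defaultdict(list)
        for dx in p.diagnoses:
            if dx.age_at_diagnosis is not None:
                if dx.age_at_diagnosis < 0:
                    v.append(f"{pid}: negative age_at_diagnosis")
                if p.age_years is not None and dx.age_at_diagnosis > p.age_years:
                    v.append(
                        f"{pid}: {dx.site.value} diagnosed at {dx.age_at_diagnosis}"
                        f" after age_years {p.age_years}")
            seen_idx[dx.site].append(dx.primary_index)
        for site, idxs in seen_idx.items():
            if sorted(idxs) != list(range(1, len(idxs) + 1)):
                v.append(
                    f"{pid}: primary_index values for {site.value} not"
                    f" consecutive from 1: {sorted(idxs)}")

    # graph-level invariants via networkx
    g = nx.DiGraph()
    g.add_nodes_from(persons)
    for pid, p in persons.items():
        for ref in (p.mother_id, p.father_id):
            if ref is not None and ref in persons:
                g.add_edge(ref, pid)  # parent -> child
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        members = sorted({a for a, _ in cycle})
        v.append(f"parent links contain a cycle through {members}")
    if ped.proband_id in persons:
        reachable = nx.node_connected_component(g.to_undirected(), ped.proband_id) \
            if len(persons) else set()
        stranded = sorted(set(persons) - reachable)
        for pid in stranded:
            v.append(f"{pid}: not connected to the proband")
    return v


# module-level functional aliases matching the operation surface

def add_person(ped: Pedigree, person: Person) -> Pedigree:
    return ped.add_person(person)


def relatedness_coefficient(ped: Pedigree, a: str, b: str) -> Fraction:
    return ped.relatedness_coefficient(a, b)


def relationship_degree(ped: Pedigree, a: str, b: str) -> Degree:
    return ped.relationship_degree(a, b)


def close_blood_relatives(ped: Pedigree, of: str | None = None) -> set[str]:
    return ped.close_blood_relatives(of)


def lineage_side(ped: Pedigree, b: str) -> Side:
    return ped.lineage_side(b)
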