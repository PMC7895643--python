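"""Deterministic two-phase scripted interview.

The interview mirrors how a genetic counselor takes a family history: the
family *structure* is established first (grandparents, parents, uncles and
aunts, cousins, siblings, children, nieces and nephews, in that fixed
order), and only then is each member's medical history elicited, proband
first.  Answers are either free text with a declared parser (age, count,
yes/no) or a numbered single choice.  Every submission — including parse
failures — is recorded in the transcript, and replaying a transcript's raw
answers reproduces the identical pedigree.

The script never asks about prostate grade, receptor status, ancestry or
known familial variants: those inputs belong to the rule set's NOT_ASKED
criteria by construction.

Prompt wording lives in an editable message catalog keyed by ``prompt_id``;
all logic is keyed to the id, so editing wording never changes results.
The persona (the counselor's name and occupation shown in the greeting) is
cosmetic and never influences elicitation or screening.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Callable, Generator, Iterable, Mapping, Sequence

from .pedigree import CancerDiagnosis, Pedigree, Person, Sex, Site, Vital

MAX_RETRIES = 3
COUNT_MAX = 12


class Phase(str, Enum):
    GREETING = "greeting"
    PROBAND_BASICS = "proband_basics"
    FAMILY_STRUCTURE = "family_structure"
    MEMBER_HISTORIES = "member_histories"
    SUMMARY = "summary"
    DONE = "done"


class AnswerMode(str, Enum):
    FREE_TEXT = "free_text"
    SINGLE_CHOICE = "single_choice"


@dataclass(frozen=True)
class Persona:
    """Cosmetic counselor identity; affects greeting text only."""

    name: str = "AI"
    age: int = 26
    occupation: str = "genetic counselor working in a general hospital"
    greeting: str = "Nice to meet you."


DEFAULT_PERSONA = Persona()


@dataclass(frozen=True)
class Prompt:
    prompt_id: str
    text: str
    answer_mode: AnswerMode
    target: str  # "<person_id>.<field>" or "count:<group>"
    choices: tuple[str, ...] = ()
    parser: str | None = None  # free_text: "age" | "count" | "yesno"
    clarification: str | None = None

    def display_text(self) -> str:
        lines = []
        if self.clarification:
            lines.append(self.clarification)
        lines.append(self.text)
        for i, choice in enumerate(self.choices, start=1):
            lines.append(f"  {i}. {choice}")
        return "\n".join(lines)


@dataclass(frozen=True)
class Completion:
    """Terminal interview outcome carrying the finished pedigree."""

    pedigree: Pedigree
    closing_text: str


class ParseFailure(ValueError):
    pass


class SessionSuspended(RuntimeError):
    """More than MAX_RETRIES consecutive parse failures on one prompt."""


# ---------------------------------------------------------------------------
# answer parsers

def _parse_age(raw: str) -> int | None:
    s = raw.strip().lower()
    if s in ("unknown", "?", "don't know", "dont know"):
        return None
    try:
        v = int(s)
    except ValueError:
        raise ParseFailure(raw)
    if not 0 <= v <= 130:
        raise ParseFailure(raw)
    return v


def _parse_count(raw: str) -> int:
    try:
        v = int(raw.strip())
    except ValueError:
        raise ParseFailure(raw)
    if not 0 <= v <= COUNT_MAX:
        raise ParseFailure(raw)
    return v


def _parse_yesno(raw: str) -> bool:
    s = raw.strip().lower()
    if s in ("yes", "y"):
        return True
    if s in ("no", "n"):
        return False
    raise ParseFailure(raw)


_FREE_TEXT_PARSERS: dict[str, Callable[[str], object]] = {
    "age": _parse_age,
    "count": _parse_count,
    "yesno": _parse_yesno,
}


def parse_answer(prompt: Prompt, raw: str):
    """Parse a raw submission according to the prompt's declared mode."""
    if prompt.answer_mode is AnswerMode.SINGLE_CHOICE:
        s = raw.strip().lower()
        labels = [c.lower() for c in prompt.choices]
        if s in labels:
            return prompt.choices[labels.index(s)]
        try:
            idx = int(s)
        except ValueError:
            raise ParseFailure(raw) from None
        if 1 <= idx <= len(prompt.choices):
            return prompt.choices[idx - 1]
        raise ParseFailure(raw)
    return _FREE_TEXT_PARSERS[prompt.parser](raw)


# ---------------------------------------------------------------------------
# message catalog

def default_catalog() -> dict[str, str]:
    text = resources.files("hbocscreen.data").joinpath("messages.json").read_text(
        encoding="utf-8")
    return json.loads(text)


def load_catalog(path) -> dict[str, str]:
    with open(path, "r", encoding="utf-8") as fh:
        cat = json.load(fh)
    missing = set(default_catalog()) - set(cat)
    if missing:
        raise ValueError(f"message catalog missing keys: {sorted(missing)}")
    return cat


# ---------------------------------------------------------------------------
# interview state

@dataclass
class TranscriptEntry:
    index: int
    prompt_id: str
    prompt_text: str
    target: str
    raw_answer: str
    parsed_value: object
    accepted: bool
    timestamp: str

    def to_dict(self) -> dict:
        return {
            "index": self.index,
            "prompt_id": self.prompt_id,
            "prompt_text": self.prompt_text,
            "target": self.target,
            "raw_answer": self.raw_answer,
            "parsed_value": self.parsed_value,
            "accepted": self.accepted,
            "timestamp": self.timestamp,
        }


@dataclass
class _Member:
    """Mutable working record for one pedigree member during elicitation."""

    person_id: str
    relation: str            # human label used in prompt wording
    sex: Sex = Sex.UNKNOWN
    alive: Vital = Vital.UNKNOWN
    age_years: int | None = None
    mother_id: str | None = None
    father_id: str | None = None
    diagnoses: list[CancerDiagnosis] = field(default_factory=list)
    is_proband: bool = False

    def to_person(self) -> Person:
        return Person(
            person_id=self.person_id,
            sex=self.sex,
            alive=self.alive,
            age_years=self.age_years,
            mother_id=self.mother_id,
            father_id=self.father_id,
            diagnoses=tuple(self.diagnoses),
            is_proband=self.is_proband,
        )


class InterviewState:
    """Deterministic finite-state interview session.

    Drive with :func:`start_session` and :func:`submit_answer`.  The
    transcript records every submission; ``suspended`` flags a session that
    exceeded the retry limit and should be handed to a human (submitting a
    valid answer afterwards resumes it).
    """

    def __init__(self, persona: Persona | None = None,
                 catalog: Mapping[str, str] | None = None,
                 clock: Callable[[], str] | None = None):
        self.persona = persona or DEFAULT_PERSONA
        self.catalog = dict(catalog or default_catalog())
        self.clock = clock or (lambda: "")
        self.phase = Phase.GREETING
        self.members: list[_Member] = []
        self.transcript: list[TranscriptEntry] = []
        self.pending: Prompt | None = None
        self.retries = 0
        self.suspended = False
        self.completion: Completion | None = None
        self._script: Generator[Prompt, object, Completion] | None = None
        self._next_id = 1

    # -- id and member bookkeeping

    def _new_member(self, relation: str, **kw) -> _Member:
        m = _Member(person_id=f"R{self._next_id:02d}", relation=relation, **kw)
        self._next_id += 1
        self.members.append(m)
        return m

    def build_pedigree(self) -> Pedigree:
        return Pedigree.from_persons(m.to_person() for m in self.members)

    # -- rendering helper

    def _msg(self, key: str, **fields) -> str:
        p = self.persona
        fields.setdefault("persona_name", p.name)
        fields.setdefault("persona_age", p.age)
        fields.setdefault("persona_occupation", p.occupation)
        fields.setdefault("persona_greeting", p.greeting)
        return self.catalog[key].format(**fields)


# ---------------------------------------------------------------------------
# the script itself (a generator yielding prompts, receiving parsed values)

_SEX_CHOICES = ("female", "male", "unknown")
_ALIVE_CHOICES = ("alive", "deceased", "unknown")


def _site_choices(sex: Sex) -> tuple[str, ...]:
    sites = [Site.BREAST, Site.OVARIAN, Site.PANCREATIC, Site.PROSTATE, Site.OTHER]
    if sex is Sex.MALE:
        sites.remove(Site.OVARIAN)
    elif sex is Sex.FEMALE:
        sites.remove(Site.PROSTATE)
    return tuple(s.value for s in sites)


def _script(st: InterviewState) -> Generator[Prompt, object, Completion]:
    def ask(prompt_id, target, *, mode=AnswerMode.FREE_TEXT, choices=(),
            parser=None, prefix="", **fields):
        return Prompt(
            prompt_id=prompt_id,
            text=prefix + st._msg(prompt_id, **fields),
            answer_mode=mode,
            target=target,
            choices=tuple(choices),
            parser=parser,
        )

    def ask_member_details(m: _Member, with_sex: bool):
        if with_sex:
            sex = yield ask("member_sex", f"{m.person_id}.sex",
                            mode=AnswerMode.SINGLE_CHOICE, choices=_SEX_CHOICES,
                            relation=m.relation)
            m.sex = Sex(sex)
        alive = yield ask("member_alive", f"{m.person_id}.alive",
                          mode=AnswerMode.SINGLE_CHOICE, choices=_ALIVE_CHOICES,
                          relation=m.relation)
        m.alive = Vital(alive)
        age = yield ask("member_age", f"{m.person_id}.age_years",
                        parser="age", relation=m.relation)
        m.age_years = age

    # ---- greeting + proband basics
    proband = st._new_member("you", is_proband=True, alive=Vital.ALIVE)
    sex = yield ask("proband_sex", f"{proband.person_id}.sex",
                    mode=AnswerMode.SINGLE_CHOICE, choices=_SEX_CHOICES,
                    prefix=st._msg("greeting"))
    proband.sex = Sex(sex)
    st.phase = Phase.PROBAND_BASICS
    age = yield ask("proband_age", f"{proband.person_id}.age_years", parser="age")
    proband.age_years = age

    # ---- family structure
    st.phase = Phase.FAMILY_STRUCTURE
    pat_gf = st._new_member("your paternal grandfather", sex=Sex.MALE)
    pat_gm = st._new_member("your paternal grandmother", sex=Sex.FEMALE)
    mat_gf = st._new_member("your maternal grandfather", sex=Sex.MALE)
    mat_gm = st._new_member("your maternal grandmother", sex=Sex.FEMALE)
    for slot in (pat_gf, pat_gm, mat_gf, mat_gm):
        yield from ask_member_details(slot, with_sex=False)
    father = st._new_member("your father", sex=Sex.MALE,
                            father_id=pat_gf.person_id, mother_id=pat_gm.person_id)
    mother = st._new_member("your mother", sex=Sex.FEMALE,
                            father_id=mat_gf.person_id, mother_id=mat_gm.person_id)
    yield from ask_member_details(father, with_sex=False)
    yield from ask_member_details(mother, with_sex=False)
    proband.father_id = father.person_id
    proband.mother_id = mother.person_id

    uncles_aunts: list[_Member] = []
    for group, grandpa, grandma, label in (
        ("uncles_aunts_paternal", pat_gf, pat_gm, "paternal uncle/aunt"),
        ("uncles_aunts_maternal", mat_gf, mat_gm, "maternal uncle/aunt"),
    ):
        n = yield ask(f"count_{group}", f"count:{group}", parser="count")
        for i in range(1, n + 1):
            m = st._new_member(f"your {label} {i}",
                               father_id=grandpa.person_id,
                               mother_id=grandma.person_id)
            yield from ask_member_details(m, with_sex=True)
            uncles_aunts.append(m)

    # first cousins, per uncle/aunt in elicitation order
    for ua in uncles_aunts:
        n = yield ask("count_cousins", f"count:cousins:{ua.person_id}",
                      parser="count", relation=ua.relation)
        for i in range(1, n + 1):
            m = st._new_member(f"child {i} of {ua.relation}")
            if ua.sex is Sex.MALE:
                m.father_id = ua.person_id
            else:
                m.mother_id = ua.person_id
            yield from ask_member_details(m, with_sex=True)

    n_sib = yield ask("count_siblings", "count:siblings", parser="count")
    siblings: list[_Member] = []
    for i in range(1, n_sib + 1):
        m = st._new_member(f"your sibling {i}",
                           father_id=father.person_id, mother_id=mother.person_id)
        yield from ask_member_details(m, with_sex=True)
        siblings.append(m)

    n_child = yield ask("count_children", "count:children", parser="count")
    for i in range(1, n_child + 1):
        m = st._new_member(f"your child {i}")
        if proband.sex is Sex.MALE:
            m.father_id = proband.person_id
        else:
            m.mother_id = proband.person_id
        yield from ask_member_details(m, with_sex=True)

    for sib in siblings:
        n = yield ask("count_nieces_nephews",
                      f"count:nieces_nephews:{sib.person_id}",
                      parser="count", relation=sib.relation)
        for i in range(1, n + 1):
            m = st._new_member(f"child {i} of {sib.relation}")
            if sib.sex is Sex.MALE:
                m.father_id = sib.person_id
            else:
                m.mother_id = sib.person_id
            yield from ask_member_details(m, with_sex=True)

    # ---- member histories: proband first, then relatives in elicitation order
    st.phase = Phase.MEMBER_HISTORIES
    for m in st.members:
        suffix = "self" if m.is_proband else "member"
        has_cancer = yield ask(f"cancer_any_{suffix}",
                               f"{m.person_id}.has_cancer",
                               parser="yesno", relation=m.relation)
        more = bool(has_cancer)
        site_counts: dict[Site, int] = {}
        while more:
            site_raw = yield ask(f"cancer_site_{suffix}",
                                 f"{m.person_id}.diagnosis_site",
                                 mode=AnswerMode.SINGLE_CHOICE,
                                 choices=_site_choices(m.sex),
                                 relation=m.relation)
            site = Site(site_raw)
            dx_age = yield ask(f"cancer_age_{suffix}",
                               f"{m.person_id}.diagnosis_age",
                               parser="age", relation=m.relation)
            site_counts[site] = site_counts.get(site, 0) + 1
            m.diagnoses.append(CancerDiagnosis(
                site=site, age_at_diagnosis=dx_age,
                primary_index=site_counts[site]))
            more = yield ask(f"cancer_more_{suffix}",
                             f"{m.person_id}.more_diagnoses",
                             parser="yesno", relation=m.relation)

    st.phase = Phase.SUMMARY
    pedigree = st.build_pedigree()
    st.phase = Phase.DONE
    return Completion(pedigree=pedigree, closing_text=st._msg("closing"))


# ---------------------------------------------------------------------------
# session driving

def start_session(persona: Persona | None = None,
                  catalog: Mapping[str, str] | None = None,
                  clock: Callable[[], str] | None = None
                  ) -> tuple[InterviewState, Prompt]:
    """Open a session; returns the state and the greeting prompt."""
    st = InterviewState(persona=persona, catalog=catalog, clock=clock)
    st._script = _script(st)
    st.pending = next(st._script)
    return st, st.pending


def submit_answer(st: InterviewState, raw: str
                  ) -> tuple[InterviewState, Prompt | Completion]:
    """Parse one raw answer and advance the interview.

    On parse failure the same prompt is re-issued with a clarification and
    the failure is recorded; after more than MAX_RETRIES consecutive
    failures the session is flagged ``suspended`` (a later valid answer
    still resumes it).
    """
    if st.phase is Phase.DONE:
        raise RuntimeError("interview already complete")
    prompt = st.pending
    try:
        parsed = parse_answer(prompt, raw)
    except ParseFailure:
        st.retries += 1
        st.transcript.append(TranscriptEntry(
            index=len(st.transcript), prompt_id=prompt.prompt_id,
            prompt_text=prompt.text, target=prompt.target,
            raw_answer=raw, parsed_value=None, accepted=False,
            timestamp=st.clock()))
        if st.retries > MAX_RETRIES:
            st.suspended = True
        clarify_key = ("clarify_choice"
                       if prompt.answer_mode is AnswerMode.SINGLE_CHOICE
                       else f"clarify_{prompt.parser}")
        st.pending = Prompt(
            prompt_id=prompt.prompt_id, text=prompt.text,
            answer_mode=prompt.answer_mode, target=prompt.target,
            choices=prompt.choices, parser=prompt.parser,
            clarification=st._msg(clarify_key))
        return st, st.pending

    st.retries = 0
    st.suspended = False
    st.transcript.append(TranscriptEntry(
        index=len(st.transcript), prompt_id=prompt.prompt_id,
        prompt_text=prompt.text, target=prompt.target,
        raw_answer=raw, parsed_value=parsed, accepted=True,
        timestamp=st.clock()))
    try:
        st.pending = st._script.send(parsed)
        return st, st.pending
    except StopIteration as stop:
        st.pending = None
        st.completion = stop.value
        return st, st.completion


def replay_answers(raw_answers: Iterable[str],
                   persona: Persona | None = None,
                   catalog: Mapping[str, str] | None = None,
                   expected_prompt_ids: Sequence[str] | None = None
                   ) -> tuple[InterviewState, Completion | None]:
    """Feed stored raw answers through a fresh session.

    With ``expected_prompt_ids`` (from a stored transcript) each issued
    prompt id is checked against the recording; a mismatch raises
    ValueError.  Returns the completion, or None if the answers ran out
    before the script finished (a truncated/suspended session).
    """
    st, prompt = start_session(persona=persona, catalog=catalog)
    outcome: Completion | None = None
    for i, raw in enumerate(raw_answers):
        if outcome is not None:
            raise ValueError("answers remain after interview completion")
        if expected_prompt_ids is not None:
            if i >= len(expected_prompt_ids) or \
                    prompt.prompt_id != expected_prompt_ids[i]:
                raise ValueError(
                    f"transcript/prompt mismatch at answer {i}: session asks "
                    f"{prompt.prompt_id!r}")
        st, nxt = submit_answer(st, raw)
        if isinstance(nxt, Completion):
            outcome = nxt
        else:
            prompt = nxt
    return st, outcome


def transcript_to_json(st: InterviewState, indent: int = 2) -> str:
    return json.dumps([e.to_dict() for e in st.transcript], indent=indent) + "\n"


def replay_transcript(entries: Sequence[Mapping],
                      persona: Persona | None = None,
                      catalog: Mapping[str, str] | None = None
                      ) -> tuple[InterviewState, Completion | None]:
    """Replay a stored transcript (list of entry dicts) from its raw answers."""
    raws = [e["raw_answer"] for e in entries]
    ids = [e["prompt_id"] for e in entries]
    return replay_answers(raws, persona=persona, catalog=catalog,
                          expected_prompt_ids=ids)
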