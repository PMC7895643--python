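"""Render the three screening outputs: medical history, family history, result sheet.

Each renderer builds one intermediate structure and derives a plain-text
view and a JSON twin from it, so the two never diverge; renderers are pure
readers and cannot alter evaluation outcomes.  Met / unmet / not-asked
statuses are tagged in brackets (the on-screen original used red / black /
gray font); ANSI color is optional and off by default so output is
diff-stable.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

from .criteria import Mode, RuleSet, ScreeningResult, Status
from .pedigree import Degree, Pedigree, Person, Sex, Side

SEX_CODE = {Sex.FEMALE: "F", Sex.MALE: "M", Sex.UNKNOWN: "U"}
_STATUS_TAG = {Status.MET: "[MET]", Status.NOT_MET: "[NOT MET]",
               Status.NOT_ASKED: "[NOT ASKED]"}
_ANSI = {Status.MET: "\x1b[31m", Status.NOT_MET: "", Status.NOT_ASKED: "\x1b[90m"}
_RESET = "\x1b[0m"


# ---------------------------------------------------------------------------
# relation labels, derived solely from pedigree structure

def _sexed(sex: Sex, female: str, male: str, neutral: str) -> str:
    if sex is Sex.FEMALE:
        return female
    if sex is Sex.MALE:
        return male
    return neutral


def _shared_parents(a: Person, b: Person) -> int:
    n = 0
    if a.mother_id is not None and a.mother_id == b.mother_id:
        n += 1
    if a.father_id is not None and a.father_id == b.father_id:
        n += 1
    return n


def relation_label(ped: Pedigree, pid: str) -> str:
    """Human relation label of ``pid`` with respect to the proband."""
    pro = ped.proband
    if pid == pro.person_id:
        return "proband"
    p = ped[pid]
    if pid == pro.father_id:
        return "father"
    if pid == pro.mother_id:
        return "mother"

    parents_of = lambda q: [x for x in (q.mother_id, q.father_id) if x is not None]
    pro_parents = {x: lab for x, lab in
                   ((pro.father_id, "paternal"), (pro.mother_id, "maternal"))
                   if x is not None}

    # grandparents / great-grandparents
    for par_id, side in pro_parents.items():
        par = ped[par_id]
        if pid in parents_of(par):
            return f"{side} " + _sexed(p.sex, "grandmother", "grandfather",
                                       "grandparent")
        for gp_id in parents_of(par):
            if pid in parents_of(ped[gp_id]):
                return f"{side} " + _sexed(p.sex, "great-grandmother",
                                           "great-grandfather",
                                           "great-grandparent")

    # descendants
    if pro.person_id in parents_of(p):
        return _sexed(p.sex, "daughter", "son", "child")
    for q_id, q in ped.persons.items():
        if pro.person_id in parents_of(q) and q_id in parents_of(p):
            return _sexed(p.sex, "granddaughter", "grandson", "grandchild")

    # siblings
    shared = _shared_parents(p, pro)
    if shared == 2:
        return _sexed(p.sex, "sister", "brother", "sibling")
    if shared == 1:
        side = "maternal" if p.mother_id == pro.mother_id else "paternal"
        return _sexed(p.sex, f"half-sister ({side})", f"half-brother ({side})",
                      f"half-sibling ({side})")

    # uncles/aunts and first cousins
    for par_id, side in pro_parents.items():
        par = ped[par_id]
        if _shared_parents(p, par) >= 1:
            prefix = "" if _shared_parents(p, par) == 2 else "half-"
            return f"{side} " + _sexed(p.sex, f"{prefix}aunt", f"{prefix}uncle",
                                       f"{prefix}uncle/aunt")
        for q_id in parents_of(p):
            if _shared_parents(ped[q_id], par) >= 1:
                return f"first cousin ({side})"

    # nieces/nephews
    for q_id in parents_of(p):
        if _shared_parents(ped[q_id], pro) >= 1:
            return _sexed(p.sex, "niece", "nephew", "niece/nephew")

    deg = ped.relationship_degree(pro.person_id, pid)
    if deg is Degree.UNRELATED:
        return "relative by marriage"
    return f"{deg.value}-degree relative"


# ---------------------------------------------------------------------------
# family history (one row per non-proband member)

def _age_text(age: int | None) -> str:
    return "unknown" if age is None else f"{age} y"


def _dx_text(p: Person) -> list[str]:
    out = []
    for dx in p.diagnoses:
        age = "age unknown" if dx.age_at_diagnosis is None \
            else f"{dx.age_at_diagnosis} y"
        out.append(f"{dx.site.value} ({age})")
    return out


_SIDE_ORDER = {Side.PATERNAL: 0, Side.MATERNAL: 1, Side.BOTH: 2,
               Side.SELF_OR_DESCENDANT: 3, Side.UNRELATED: 4}


def family_history_rows(ped: Pedigree) -> list[dict]:
    """One row per non-proband member: paternal line, maternal line,
    siblings (and other both-side kin), descendants, then in-laws."""
    pids = [pid for pid in sorted(ped.persons) if pid != ped.proband_id]
    pids.sort(key=lambda pid: (_SIDE_ORDER[ped.lineage_side(pid)], pid))
    return [
        {
            "relation": relation_label(ped, pid),
            "sex": SEX_CODE[ped[pid].sex],
            "age": _age_text(ped[pid].age_years),
            "diagnoses": _dx_text(ped[pid]),
        }
        for pid in pids
    ]


def render_family_history(ped: Pedigree) -> tuple[str, list[dict]]:
    """Text table plus its JSON twin (F/M sex codes, ages in years 'y')."""
    rows = family_history_rows(ped)
    lines = ["Family history"]
    for r in rows:
        dx = "; ".join(r["diagnoses"]) if r["diagnoses"] else "-"
        lines.append(f"{r['relation']} | {r['sex']} | {r['age']} | {dx}")
    return "\n".join(lines) + "\n", rows


def parse_family_history_text(text: str) -> list[dict]:
    """Recover the JSON rows from the text table (inverse of the renderer)."""
    rows = []
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        relation, sex, age, dx = line.split(" | ")
        rows.append({
            "relation": relation,
            "sex": sex,
            "age": age,
            "diagnoses": [] if dx == "-" else dx.split("; "),
        })
    return rows


# ---------------------------------------------------------------------------
# medical history (proband)

def medical_history_doc(ped: Pedigree) -> dict:
    pro = ped.proband
    return {
        "person_id": pro.person_id,
        "sex": SEX_CODE[pro.sex],
        "age": _age_text(pro.age_years),
        "diagnoses": [dx.to_dict() for dx in pro.diagnoses],
    }


def render_medical_history(ped: Pedigree) -> tuple[str, dict]:
    doc = medical_history_doc(ped)
    pro = ped.proband
    lines = ["Medical history",
             f"Proband: {doc['sex']}, {doc['age']}"]
    if not pro.diagnoses:
        lines.append("no cancer history")
    else:
        for dx in pro.diagnoses:
            age = "age unknown" if dx.age_at_diagnosis is None \
                else f"diagnosed at {dx.age_at_diagnosis} y"
            lines.append(f"{dx.site.value} ({age}), primary {dx.primary_index}")
    return "\n".join(lines) + "\n", doc


# ---------------------------------------------------------------------------
# screening result sheet

def screening_sheet_doc(result: ScreeningResult, ruleset: RuleSet) -> dict:
    rs_ids = [c.criterion_id for c in ruleset.criteria]
    if set(rs_ids) != set(result.statuses):
        raise ValueError(
            "result/ruleset criterion ids do not match: "
            f"{sorted(set(rs_ids) ^ set(result.statuses))}")
    return {
        "ruleset": {"name": result.ruleset_name,
                    "version": result.ruleset_version},
        "criteria": [
            {
                "criterion_id": c.criterion_id,
                "description": c.description,
                "status": result.statuses[c.criterion_id].value,
            }
            for c in ruleset.criteria
        ],
        "overall": result.overall,
        "final_text": "criteria met" if result.overall else "criteria not met",
    }


def render_screening_sheet(result: ScreeningResult, ruleset: RuleSet,
                           color: bool = False) -> tuple[str, dict]:
    doc = screening_sheet_doc(result, ruleset)
    lines = [f"BRCA1/2 testing criteria screening "
             f"({doc['ruleset']['name']} v{doc['ruleset']['version']})"]
    for row in doc["criteria"]:
        status = Status(row["status"])
        tag = _STATUS_TAG[status]
        line = f"{tag} {row['criterion_id']}: {row['description']}"
        if color and _ANSI[status]:
            line = _ANSI[status] + line + _RESET
        lines.append(line)
    lines.append("=" * 40)
    final = f"FINAL RESULT: {doc['final_text']}"
    if color:
        final = "\x1b[43m" + final + _RESET  # yellow highlight
    lines.append(final)
    return "\n".join(lines) + "\n", doc


# ---------------------------------------------------------------------------
# report bundle

BUNDLE_FILES = (
    "medical_history.txt", "medical_history.json",
    "family_history.txt", "family_history.json",
    "screening_result.txt", "screening_result.json",
)


def write_report_bundle(outdir, ped: Pedigree, result: ScreeningResult,
                        ruleset: RuleSet,
                        config_echo: Mapping | None = None,
                        color: bool = False) -> Path:
    """Write the three text+JSON report pairs and a manifest; returns the dir."""
    from . import __version__

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    med_txt, med_doc = render_medical_history(ped)
    fam_txt, fam_doc = render_family_history(ped)
    sheet_txt, sheet_doc = render_screening_sheet(result, ruleset, color=color)
    sheet_doc = dict(sheet_doc)
    sheet_doc["evidence"] = {k: list(v) for k, v in sorted(result.evidence.items())}
    pairs = {
        "medical_history": (med_txt, med_doc),
        "family_history": (fam_txt, fam_doc),
        "screening_result": (sheet_txt, sheet_doc),
    }
    for stem, (txt, doc) in pairs.items():
        (out / f"{stem}.txt").write_text(txt, encoding="utf-8")
        (out / f"{stem}.json").write_text(
            json.dumps(doc, indent=2) + "\n", encoding="utf-8")
    manifest = {
        "artifact": {"name": "hbocscreen", "version": __version__},
        "ruleset": {"name": ruleset.name, "version": ruleset.version},
        "config": dict(config_echo or {}),
        "files": list(BUNDLE_FILES),
        "overall": result.overall,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return out
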