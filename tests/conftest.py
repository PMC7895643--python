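import pytest

from hbocscreen import CancerDiagnosis, Pedigree, Person, Sex, Site, Vital


def P(pid, sex="female", alive="alive", age=None, mother=None, father=None,
      dx=(), proband=False):
    """Terse person builder: dx is a list of (site, age[, primary_index])."""
    diagnoses = []
    counts = {}
    for item in dx:
        site, dx_age = item[0], item[1]
        idx = item[2] if len(item) > 2 else counts.get(site, 0) + 1
        counts[site] = idx
        diagnoses.append(CancerDiagnosis(site=Site(site),
                                         age_at_diagnosis=dx_age,
                                         primary_index=idx))
    return Person(person_id=pid, sex=Sex(sex), alive=Vital(alive),
                  age_years=age, mother_id=mother, father_id=father,
                  diagnoses=tuple(diagnoses), is_proband=proband)


def build(*persons):
    return Pedigree.from_persons(persons)


@pytest.fixture
def trio():
    """Proband with two healthy parents, ages known."""
    return build(
        P("R01", "female", age=40, mother="R03", father="R02", proband=True),
        P("R02", "male", age=72),
        P("R03", "female", age=70),
    )


@pytest.fixture
def extended():
    """Three-generation family exercising every named relationship class.

    pgf2 = paternal great-grandfather; aunt = father's full sister;
    half = maternal half-sibling; uncle = mother's full brother whose wife
    (inlaw) is a blood relative of nobody; cousin = their child.
    """
    return build(
        P("pro", "female", age=40, mother="mo", father="fa", proband=True),
        P("fa", "male", age=70, mother="pgm", father="pgf"),
        P("mo", "female", age=68, mother="mgm", father="mgf"),
        P("pgf", "male", alive="deceased", age=90, father="pggf"),
        P("pgm", "female", alive="deceased", age=88),
        P("mgf", "male", alive="deceased", age=85),
        P("mgm", "female", age=92),
        P("pggf", "male", alive="deceased", age=96),
        P("aunt", "female", age=66, mother="pgm", father="pgf"),
        P("uncle", "male", age=64, mother="mgm", father="mgf"),
        P("inlaw", "female", age=60),
        P("cousin", "male", age=30, mother="inlaw", father="uncle"),
        P("half", "male", age=20, mother="mo"),
        P("sib", "female", age=43, mother="mo", father="fa"),
        P("child", "female", age=12, mother="pro"),
    )
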