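"""Rule-set composition, predicate logic, and engine/oracle equivalence."""

import random
from dataclasses import replace

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hbocscreen import (
    CancerDiagnosis,
    Mode,
    Pedigree,
    PedigreeError,
    SimConfig,
    Site,
    Status,
    default_ruleset,
    evaluate,
    evaluate_as_proband,
    generate_pedigree,
    limited_family_history,
    naive_oracle,
    ruleset_from_config,
    ruleset_to_config,
)
from conftest import P, build


def statuses(ped, rs=None):
    return evaluate(ped, rs or default_ruleset()).statuses


def proband_with_family(**proband_kw):
    """A proband in a family rich enough not to count as limited history."""
    kw = dict(age=60, mother="mo", father="fa", proband=True)
    kw.update(proband_kw)
    return build(
        P("pro", "female", **kw),
        P("fa", "male", age=85, mother="pgm"),
        P("mo", "female", age=82, mother="mgm"),
        P("pgm", "female", age=95, alive="deceased"),
        P("mgm", "female", age=90, alive="deceased"),
    ).add_person(P("sis", "female", age=62, mother="mo", father="fa"))


class TestRuleSetComposition:
    def test_default_has_seven_active_and_ten_omitted(self):
        rs = default_ruleset()
        assert len(rs.active_ids()) == 7
        assert len(rs.omitted_ids()) == 10
        assert rs.version == "3.2019"

    def test_omitted_always_not_asked(self, trio):
        result = evaluate(trio)
        rs = default_ruleset()
        for cid in rs.omitted_ids():
            assert result.statuses[cid] is Status.NOT_ASKED
        assert set(rs.omitted_ids()) == {
            cid for cid, s in result.statuses.items() if s is Status.NOT_ASKED}

    def test_config_round_trip(self):
        rs = default_ruleset()
        again = ruleset_from_config(ruleset_to_config(rs))
        assert ruleset_to_config(again) == ruleset_to_config(rs)

    def test_mode_override_deactivates_criterion(self, trio):
        rs = ruleset_from_config({"criteria": {"A1": "OMITTED"}})
        result = evaluate(trio, rs)
        assert result.statuses["A1"] is Status.NOT_ASKED

    def test_omitted_criterion_cannot_be_activated(self):
        with pytest.raises(ValueError):
            ruleset_from_config({"criteria": {"O1": "ACTIVE"}})


class TestBoundaries:
    """Age-window edges of the breast-cancer criteria."""

    def test_breast_at_45_meets_early_onset(self):
        ped = proband_with_family(dx=[("breast", 45)])
        s = statuses(ped)
        assert s["A1"] is Status.MET

    def test_breast_at_46_with_second_primary_meets_window(self):
        ped = proband_with_family(dx=[("breast", 46), ("breast", 52)])
        s = statuses(ped)
        assert s["A1"] is Status.NOT_MET
        assert s["A2"] is Status.MET

    def test_breast_at_50_still_in_window(self):
        ped = proband_with_family(dx=[("breast", 50), ("breast", 55)])
        assert statuses(ped)["A2"] is Status.MET

    def test_breast_at_51_meets_neither_age_rule(self):
        ped = proband_with_family(dx=[("breast", 51)])
        s = statuses(ped)
        assert s["A1"] is Status.NOT_MET
        assert s["A2"] is Status.NOT_MET

    def test_unknown_diagnosis_age_fails_age_bounded_conditions(self):
        ped = proband_with_family(dx=[("breast", None)])
        s = statuses(ped)
        assert s["A1"] is Status.NOT_MET
        assert s["A2"] is Status.NOT_MET
        # but any-age conditions are satisfied by an age-unknown diagnosis
        ped2 = proband_with_family(dx=[("pancreatic", None)])
        assert statuses(ped2)["A6"] is Status.MET


class TestPredicates:
    def test_no_cancer_anywhere_meets_nothing(self):
        ped = proband_with_family()
        result = evaluate(ped)
        assert not result.overall
        assert all(s is not Status.MET for s in result.statuses.values())

    def test_early_breast_with_no_relatives_meets_a1(self):
        ped = build(P("pro", "female", age=50, dx=[("breast", 44)],
                      proband=True))
        result = evaluate(ped)
        assert result.statuses["A1"] is Status.MET and result.overall

    def test_relative_ovarian_fires_family_arms(self):
        ped = proband_with_family(dx=[("breast", 58)])
        ped = Pedigree(
            persons={**ped.persons,
                     "mo": replace(ped["mo"], diagnoses=(
                         CancerDiagnosis(Site.OVARIAN, 61),))},
            proband_id="pro")
        s = statuses(ped)
        assert s["A3"] is Status.MET    # ovarian-relative arm
        assert s["A7"] is Status.MET    # mother herself qualifies
        assert evaluate(ped).overall

    def test_male_breast_and_ovarian_sex_conditions(self):
        male = build(P("pro", "male", age=60, dx=[("breast", 58)], proband=True))
        assert statuses(male)["A5"] is Status.MET
        unknown_sex = build(P("pro", "unknown", age=60, dx=[("breast", 58)],
                              proband=True))
        s = statuses(unknown_sex)
        assert s["A5"] is Status.NOT_MET
        ovarian_unknown = build(P("pro", "unknown", age=60,
                                  dx=[("ovarian", 50)], proband=True))
        assert statuses(ovarian_unknown)["A4"] is Status.NOT_MET

    def test_limited_history_completes_a2(self):
        # 46-50 breast cancer, paternal side essentially unknown
        ped = build(
            P("pro", "female", age=50, mother="mo", father="fa",
              dx=[("breast", 48)], proband=True),
            P("fa", "male"), P("mo", "female", age=80),
        )
        assert limited_family_history(ped)
        assert statuses(ped)["A2"] is Status.MET

    def test_evidence_names_people_and_diagnoses(self):
        ped = proband_with_family(dx=[("breast", 43)])
        result = evaluate(ped)
        ev = result.evidence["A1"]
        assert ev[0]["person_id"] == "pro" and ev[0]["site"] == "breast"

    def test_invalid_pedigree_rejected_with_violations(self):
        ped = build(P("pro", proband=True, age=40, dx=[("breast", 55)]))
        with pytest.raises(PedigreeError, match="after age_years"):
            evaluate(ped)


class TestLimitedFamilyHistory:
    def test_no_relatives_is_limited(self):
        assert limited_family_history(
            build(P("pro", proband=True, age=48)))

    def test_two_older_women_each_side_not_limited(self):
        ped = build(
            P("pro", "female", age=48, mother="mo", father="fa", proband=True),
            P("mo", "female", age=70), P("fa", "male", age=72),
            P("mgm", "female", age=90),
            P("pgm", "female", age=88),
            P("paunt", "female", age=60, mother="pgm", father="pgf"),
            P("pgf", "male", alive="deceased", age=85),
        )
        ped = Pedigree(
            persons={**ped.persons,
                     "mo": replace(ped["mo"], mother_id="mgm"),
                     "fa": replace(ped["fa"], mother_id="pgm",
                                   father_id="pgf")},
            proband_id="pro")
        assert ped.validate() == []
        assert not limited_family_history(ped)

    def test_one_side_sparse_is_limited(self):
        ped = build(
            P("pro", "female", age=48, mother="mo", proband=True),
            P("mo", "female", age=70),
        )
        assert limited_family_history(ped)  # paternal side has nobody

    def test_unknown_age_does_not_count(self):
        ped = build(
            P("pro", "female", age=48, mother="mo", father="fa", proband=True),
            P("mo", "female", age=None), P("fa", "male", age=None),
        )
        assert limited_family_history(ped)


class TestEvaluateAsProband:
    def test_reroot_at_self_is_identity(self, extended):
        base = evaluate(extended)
        rerooted = evaluate_as_proband(extended, "pro")
        for cid in ("A1", "A2", "A3", "A4", "A5", "A6"):
            assert rerooted.statuses[cid] is base.statuses[cid]
        assert "A7" not in rerooted.statuses

    def test_reroot_at_affected_mother(self):
        ped = proband_with_family()
        ped = Pedigree(
            persons={**ped.persons,
                     "mo": replace(ped["mo"], diagnoses=(
                         CancerDiagnosis(Site.OVARIAN, 61),))},
            proband_id="pro")
        result = evaluate_as_proband(ped, "mo")
        assert result.statuses["A4"] is Status.MET

    def test_marriage_only_member_rejected(self, extended):
        with pytest.raises(PedigreeError, match="marriage"):
            evaluate_as_proband(extended, "inlaw")


class TestEngineProperties:
    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_oracle_equivalence(self, seed):
        ped, _ = generate_pedigree(SimConfig(seed=seed))
        assert evaluate(ped).statuses == naive_oracle(ped).statuses

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_adding_a_diagnosis_never_unmeets(self, seed):
        ped, _ = generate_pedigree(SimConfig(seed=seed))
        before = evaluate(ped).statuses
        rng = random.Random(seed)
        pid = rng.choice(sorted(ped.persons))
        person = ped[pid]
        site = rng.choice(list(Site))
        idx = sum(1 for d in person.diagnoses if d.site is site) + 1
        age = None if person.age_years is None else rng.randint(
            0, person.age_years)
        bigger = Pedigree(
            persons={**ped.persons, pid: replace(
                person,
                diagnoses=person.diagnoses + (
                    CancerDiagnosis(site, age, idx),))},
            proband_id=ped.proband_id)
        after = evaluate(bigger).statuses
        for cid, s in before.items():
            if s is Status.MET:
                assert after[cid] is Status.MET

    def test_evaluate_is_referentially_transparent(self):
        ped, _ = generate_pedigree(SimConfig(seed=42))
        r1, r2 = evaluate(ped), evaluate(ped)
        assert r1.to_json() == r2.to_json()
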