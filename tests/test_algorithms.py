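import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hfpheno.algorithms import (
    AlgorithmBranch,
    AlgorithmSpec,
    ConditionGroup,
    MatchResult,
    determine_index_date,
    evaluate_algorithm,
    evaluate_apc,
    run_panel,
    sample_study_population,
)
from hfpheno.conditions import ConditionEvent, ConditionId as C
from hfpheno.records import (
    ClinicalRecordBundle,
    DiagnosisRecord,
    DpcField,
    DrugRecord,
    LabAnalyte,
    LabRecord,
    SourceTag,
)
from oracle_utils import brute_force_match, random_bundle

D = dt.date
DAY0 = D(2021, 3, 10)


def day(offset):
    return DAY0 + dt.timedelta(days=offset)


def patient(diagnoses=(), labs=(), drugs=()):
    b = ClinicalRecordBundle("P1", "H1")
    for source, offset, kwargs in diagnoses:
        b.diagnoses.append(
            DiagnosisRecord("P1", "H1", source, "I500", day(offset), **kwargs)
        )
    for analyte, value, offset in labs:
        b.labs.append(LabRecord("P1", "H1", analyte, value, day(offset)))
    for code, offset in drugs:
        b.drugs.append(DrugRecord("P1", "H1", SourceTag.SSMIX2, code, day(offset)))
    return b


class TestRegistry:
    def test_ids_and_windows(self, registry):
        assert set(registry) == {"APC"} | {f"ALG{i}" for i in range(1, 19)}
        assert registry["ALG9"].half_window_days == 30
        assert registry["APC"].half_window_days == 30
        assert registry["ALG3"].half_window_days == 7
        assert registry["ALG11"].half_window_days == 7
        for alg in ("ALG1", "ALG2", "ALG4", "ALG5", "ALG6", "ALG7", "ALG8",
                    "ALG10", "ALG12", "ALG13", "ALG14", "ALG15", "ALG16",
                    "ALG17", "ALG18"):
            assert registry[alg].half_window_days == 14

    def test_window_variants_share_branches(self, registry):
        assert registry["ALG3"].branches == registry["ALG2"].branches
        assert registry["ALG11"].branches == registry["ALG10"].branches

    def test_echo_variants_append_a_procedure_group(self, registry):
        mp1 = ConditionGroup(frozenset({C.MEDPRACTICE1}))
        for narrow, base in (("ALG4", "ALG2"), ("ALG12", "ALG10")):
            for b_narrow, b_base in zip(
                registry[narrow].branches, registry[base].branches
            ):
                assert b_narrow.groups == b_base.groups + (mp1,)

    def test_alg13_structure(self, registry):
        (branch,) = registry["ALG13"].branches
        assert [g.any_of for g in branch.groups] == [
            frozenset({C.DISEASE1, C.DISEASE3, C.DISEASE5}),
            frozenset({C.BLOOD1, C.BLOOD4}),
            frozenset({C.DRUG6}),
        ]

    def test_drug4_and_5_is_two_singleton_groups(self, registry):
        third = registry["ALG2"].branches[2]
        assert ConditionGroup(frozenset({C.DRUG4})) in third.groups
        assert ConditionGroup(frozenset({C.DRUG5})) in third.groups

    def test_branch_needs_exactly_one_disease_group(self):
        with pytest.raises(ValueError):
            AlgorithmBranch((ConditionGroup(frozenset({C.BLOOD1})),))


class TestIndexDate:
    def test_earliest_of_two(self):
        events = [
            ConditionEvent(C.DISEASE1, D(2021, 3, 15), SourceTag.DPC, None),
            ConditionEvent(C.DISEASE1, D(2021, 3, 10), SourceTag.DPC, None),
        ]
        assert determine_index_date(events) == D(2021, 3, 10)

    def test_empty_is_none(self):
        assert determine_index_date([]) is None

    def test_tie_collapses_to_one_date(self):
        events = [
            ConditionEvent(C.DISEASE1, D(2021, 3, 10), SourceTag.DPC, None),
            ConditionEvent(C.DISEASE5, D(2021, 3, 10), SourceTag.CLAIMS, None),
        ]
        assert determine_index_date(events) == D(2021, 3, 10)


class TestEvaluate:
    def test_alg8_matches_via_high_bnp_branch(self, registry, codeset):
        b = patient(
            diagnoses=[(SourceTag.DPC, 0, dict(dpc_field=DpcField.MAIN))],
            labs=[(LabAnalyte.BNP, 450.0, 5)],
        )
        r = evaluate_algorithm(b, registry["ALG8"], codeset)
        assert r.matched and r.satisfied_branch == 1 and r.index_date == DAY0

    def test_event_one_day_outside_window_fails(self, registry, codeset):
        b = patient(
            diagnoses=[(SourceTag.DPC, 0, dict(dpc_field=DpcField.MAIN))],
            labs=[(LabAnalyte.BNP, 450.0, 15)],
        )
        assert not evaluate_algorithm(b, registry["ALG8"], codeset).matched

    def test_event_on_window_boundary_matches(self, registry, codeset):
        b = patient(
            diagnoses=[(SourceTag.DPC, 0, dict(dpc_field=DpcField.MAIN))],
            labs=[(LabAnalyte.BNP, 450.0, 14)],
        )
        assert evaluate_algorithm(b, registry["ALG8"], codeset).matched

    def test_loop_diuretic_moderate_bnp_matches_alg10_not_alg1(self, registry, codeset):
        b = patient(
            diagnoses=[(SourceTag.SSMIX2, 0, dict(suspected=False))],
            labs=[(LabAnalyte.BNP, 150.0, 3)],
            drugs=[("C03CA01", -2)],
        )
        assert evaluate_algorithm(b, registry["ALG10"], codeset).matched
        assert not evaluate_algorithm(b, registry["ALG1"], codeset).matched

    def test_index_fixed_by_first_disease_date(self, registry, codeset):
        """An earlier disease record sets the index even if a later one
        would bring the lab into window."""
        b = patient(
            diagnoses=[
                (SourceTag.SSMIX2, -30, dict(suspected=False)),
                (SourceTag.SSMIX2, 0, dict(suspected=False)),
            ],
            labs=[(LabAnalyte.BNP, 450.0, 5)],
        )
        r = evaluate_algorithm(b, registry["ALG2"], codeset)
        assert r.index_date == day(-30)
        assert not r.matched

    def test_evidence_lies_inside_window(self, registry, codeset):
        b = patient(
            diagnoses=[(SourceTag.SSMIX2, 0, dict(suspected=False))],
            labs=[(LabAnalyte.BNP, 450.0, -10), (LabAnalyte.BNP, 90.0, 0)],
        )
        r = evaluate_algorithm(b, registry["ALG2"], codeset)
        assert r.matched
        w = registry["ALG2"].half_window_days
        for e in r.evidence:
            assert abs((e.date - r.index_date).days) <= w

    def test_match_without_index_is_rejected(self):
        with pytest.raises(ValueError):
            MatchResult("P1", "H1", "ALG1", matched=True)


class TestApc:
    def test_claims_only_patient_uses_fallback_index(self, registry, codeset):
        b = patient(
            diagnoses=[(SourceTag.CLAIMS, 0, {})],
            labs=[(LabAnalyte.NTPROBNP, 500.0, 20)],
        )
        r = evaluate_apc(b, codeset)
        assert r.matched and r.index_fallback_used and r.index_date == DAY0

    def test_suspected_ssmix2_plus_bnp_29_days_before(self, registry, codeset):
        b = patient(
            diagnoses=[(SourceTag.SSMIX2, 0, dict(suspected=True))],
            labs=[(LabAnalyte.BNP, 120.0, -29)],
        )
        r = evaluate_apc(b, codeset)
        assert r.matched and not r.index_fallback_used

    def test_bnp_below_every_threshold_fails(self, registry, codeset):
        b = patient(
            diagnoses=[(SourceTag.SSMIX2, 0, dict(suspected=False))],
            labs=[(LabAnalyte.BNP, 99.0, 0)],
        )
        assert not evaluate_apc(b, codeset).matched

    def test_apc_index_prefers_d123_over_earlier_claims(self, registry, codeset):
        """The APC index is the first DISEASE1-3 date even when a claims
        diagnosis predates it."""
        b = patient(
            diagnoses=[
                (SourceTag.CLAIMS, -20, {}),
                (SourceTag.SSMIX2, 0, dict(suspected=True)),
            ],
            labs=[(LabAnalyte.BNP, 150.0, 25)],
        )
        r = evaluate_apc(b, codeset)
        assert r.index_date == DAY0 and not r.index_fallback_used
        assert r.matched


class TestSampling:
    def make_matches(self, per_hospital):
        out = []
        for hid, n in per_hospital.items():
            for i in range(n):
                out.append(MatchResult(f"P{i}", hid, "APC", True,
                                       index_date=DAY0, satisfied_branch=1))
        return out

    def test_small_hospitals_fully_included(self):
        matches = self.make_matches({"H1": 150, "H2": 80, "H3": 120})
        sample = sample_study_population(matches, 100, seed=1)
        by_h = {h: sum(1 for hh, _ in sample if hh == h) for h in ("H1", "H2", "H3")}
        assert by_h == {"H1": 100, "H2": 80, "H3": 100}

    def test_min_larger_than_any_hospital_returns_everyone(self):
        matches = self.make_matches({"H1": 30, "H2": 40})
        assert len(sample_study_population(matches, 1000, seed=5)) == 70

    def test_same_seed_same_sample(self):
        matches = self.make_matches({"H1": 300})
        s1 = sample_study_population(matches, 100, seed=9)
        s2 = sample_study_population(matches, 100, seed=9)
        assert s1 == s2

    def test_unmatched_cases_never_sampled(self):
        matches = self.make_matches({"H1": 50})
        matches.append(MatchResult("PX", "H1", "APC", False))
        sample = sample_study_population(matches, 100, seed=0)
        assert ("H1", "PX") not in sample


@pytest.fixture(scope="module")
def panel(codeset):
    from hfpheno.synthetic import default_archetypes, generate_cohort

    bundles, _ = generate_cohort(default_archetypes(), 400, seed=11)
    return run_panel(bundles, codeset, min_per_hospital=100, seed=3)


class TestPanel:
    def test_possible_cases_within_sample(self, panel):
        sampled = set(panel.sampled_cases)
        for alg_id in panel.algorithm_results:
            assert panel.possible_cases(alg_id) <= sampled

    def test_window_monotonicity(self, panel):
        assert panel.possible_cases("ALG3") <= panel.possible_cases("ALG2")
        assert panel.possible_cases("ALG11") <= panel.possible_cases("ALG10")

    def test_conjunct_monotonicity(self, panel):
        assert panel.possible_cases("ALG4") <= panel.possible_cases("ALG2")
        for narrowed in ("ALG12", "ALG13", "ALG14"):
            assert panel.possible_cases(narrowed) <= panel.possible_cases("ALG10")


@given(seed=st.integers(0, 100_000))
@settings(max_examples=150)
def test_engine_agrees_with_brute_force_enumeration(seed, registry, codeset):
    """Group-wise evaluation equals exhaustive (branch, event-combination)
    enumeration on small random bundles, for the screen and all 18
    algorithms."""
    bundle = random_bundle(np.random.default_rng(seed))
    for spec in registry.values():
        expected_match, expected_index = brute_force_match(bundle, spec, codeset)
        got = evaluate_algorithm(bundle, spec, codeset)
        assert got.matched == expected_match, (seed, spec.algorithm_id)
        assert got.index_date == expected_index, (seed, spec.algorithm_id)


@given(seed=st.integers(0, 100_000))
@settings(max_examples=50)
def test_evaluation_is_deterministic(seed, registry, codeset):
    bundle = random_bundle(np.random.default_rng(seed))
    for spec in registry.values():
        assert evaluate_algorithm(bundle, spec, codeset) == evaluate_algorithm(
            bundle, spec, codeset
        )
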