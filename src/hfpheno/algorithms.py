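"""The APC screen and the 18 case-identification algorithms.

Each algorithm is a disjunction of branches; a branch is a conjunction of
condition groups, each group satisfied when at least one member condition
has an event inside the algorithm's symmetric day window around the index
date.  The index date is the first date of the algorithm's disease
conditions (admission date in DPC, start date in SS-MIX2/claims).  Windows
are closed intervals: "within 28 days of the index date" means 14 days
before and after, inclusive at both ends.

The All Possible Cases (APC) screen — an HF diagnosis in any source plus
BNP >= 100 or NT-proBNP >= 400 pg/ml within +/-30 days — anchors the study
population and the sensitivity denominator; its index date is the first
DISEASE1-3 date.  Patients whose only HF diagnosis is in claims have no
DISEASE1-3 date; for them the earliest claims (DISEASE5) date is used as a
fallback index and flagged in the result.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .conditions import ConditionEvent, ConditionId as C, all_events
from .records import ClinicalRecordBundle, CodeSetConfig

__all__ = [
    "ConditionGroup",
    "AlgorithmBranch",
    "AlgorithmSpec",
    "MatchResult",
    "PanelResult",
    "builtin_registry",
    "determine_index_date",
    "evaluate_algorithm",
    "evaluate_apc",
    "sample_study_population",
    "run_panel",
    "ALGORITHM_IDS",
]

ALGORITHM_IDS = ("APC",) + tuple(f"ALG{i}" for i in range(1, 19))


@dataclass(frozen=True)
class ConditionGroup:
    """Disjunction over conditions: satisfied by one in-window event of any member."""

    any_of: frozenset[C]

    def __post_init__(self) -> None:
        if not self.any_of:
            raise ValueError("condition group must be non-empty")


@dataclass(frozen=True)
class AlgorithmBranch:
    """Conjunction of groups; 'Drug 4 and 5' is two singleton groups."""

    groups: tuple[ConditionGroup, ...]

    def __post_init__(self) -> None:
        n_disease = sum(
            1 for g in self.groups if all(c.is_disease for c in g.any_of)
        )
        if n_disease != 1:
            raise ValueError("a branch must contain exactly one disease group")

    @property
    def disease_group(self) -> ConditionGroup:
        return next(g for g in self.groups if all(c.is_disease for c in g.any_of))


@dataclass(frozen=True)
class AlgorithmSpec:
    """One declarative algorithm: branches, window half-width and index rule.

    ``index_conditions`` defaults to the union of disease conditions across
    branches; APC overrides it (index over DISEASE1-3, fallback DISEASE5).
    """

    algorithm_id: str
    branches: tuple[AlgorithmBranch, ...]
    half_window_days: int
    index_conditions: frozenset[C] | None = None
    index_fallback: frozenset[C] = frozenset()

    def __post_init__(self) -> None:
        if self.half_window_days not in (7, 14, 30):
            raise ValueError(f"unsupported half window {self.half_window_days}")
        if not self.branches:
            raise ValueError("algorithm needs at least one branch")

    @property
    def disease_group(self) -> frozenset[C]:
        """Disease conditions whose first event defines the index date."""
        if self.index_conditions is not None:
            return self.index_conditions
        out: set[C] = set()
        for b in self.branches:
            out |= b.disease_group.any_of
        return frozenset(out)


@dataclass(frozen=True)
class MatchResult:
    patient_id: str
    hospital_id: str
    algorithm_id: str
    matched: bool
    index_date: dt.date | None = None
    satisfied_branch: int | None = None  # 1-based branch ordinal
    evidence: tuple[ConditionEvent, ...] = ()
    index_fallback_used: bool = False

    def __post_init__(self) -> None:
        if self.matched and (self.index_date is None or self.satisfied_branch is None):
            raise ValueError("a match must carry an index date and branch")


def determine_index_date(disease_events: Iterable[ConditionEvent]) -> dt.date | None:
    """First (earliest) date among the algorithm's disease events; None when empty."""
    dates = [e.date for e in disease_events]
    return min(dates) if dates else None


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

def _g(*cids: C) -> ConditionGroup:
    return ConditionGroup(frozenset(cids))


_D145 = _g(C.DISEASE1, C.DISEASE4, C.DISEASE5)
_D135 = _g(C.DISEASE1, C.DISEASE3, C.DISEASE5)
_HIGH = _g(C.BLOOD2, C.BLOOD5)          # high BNP or high NT-proBNP
_MID = _g(C.BLOOD3, C.BLOOD6)           # moderate band
_ANY = _g(C.BLOOD1, C.BLOOD4)           # at or above the lower thresholds
_DR123 = _g(C.DRUG1, C.DRUG2, C.DRUG3)
_DR1678 = _g(C.DRUG1, C.DRUG6, C.DRUG7, C.DRUG8)
_MP1 = _g(C.MEDPRACTICE1)


def _three_branch(
    disease: ConditionGroup,
    high: ConditionGroup,
    mid: ConditionGroup,
    extra: ConditionGroup | None = None,
) -> tuple[AlgorithmBranch, ...]:
    """The recurring branch shape: [disease, high-lab] or [disease, mid-lab, drugs]."""
    tail = (extra,) if extra is not None else ()
    return (
        AlgorithmBranch((disease, high) + tail),
        AlgorithmBranch((disease, mid, _DR123) + tail),
        AlgorithmBranch((disease, mid, _g(C.DRUG4), _g(C.DRUG5)) + tail),
    )


def _single_branch(disease: ConditionGroup, blood: ConditionGroup,
                   drugs: ConditionGroup, extra: ConditionGroup | None = None
                   ) -> tuple[AlgorithmBranch, ...]:
    tail = (extra,) if extra is not None else ()
    return (AlgorithmBranch((disease, blood, drugs) + tail),)


def builtin_registry() -> dict[str, AlgorithmSpec]:
    """The APC screen plus Algorithms 1-18, keyed 'APC', 'ALG1'..'ALG18'."""
    specs = {
        "APC": AlgorithmSpec(
            "APC",
            (AlgorithmBranch((_D135, _ANY)),),
            half_window_days=30,
            index_conditions=frozenset({C.DISEASE1, C.DISEASE2, C.DISEASE3}),
            index_fallback=frozenset({C.DISEASE5}),
        ),
        "ALG1": AlgorithmSpec(
            "ALG1", _three_branch(_D145, _g(C.BLOOD2), _g(C.BLOOD3)), 14
        ),
        "ALG2": AlgorithmSpec("ALG2", _three_branch(_D135, _HIGH, _MID), 14),
        "ALG3": AlgorithmSpec("ALG3", _three_branch(_D135, _HIGH, _MID), 7),
        "ALG4": AlgorithmSpec(
            "ALG4", _three_branch(_D135, _HIGH, _MID, extra=_MP1), 14
        ),
        "ALG5": AlgorithmSpec("ALG5", _three_branch(_g(C.DISEASE1), _HIGH, _MID), 14),
        "ALG6": AlgorithmSpec("ALG6", _three_branch(_g(C.DISEASE6), _HIGH, _MID), 14),
        "ALG7": AlgorithmSpec(
            "ALG7", _three_branch(_g(C.DISEASE2, C.DISEASE4), _HIGH, _MID), 14
        ),
        "ALG8": AlgorithmSpec("ALG8", _three_branch(_g(C.DISEASE2), _HIGH, _MID), 14),
        "ALG9": AlgorithmSpec(
            "ALG9", _single_branch(_D145, _g(C.BLOOD1), _DR1678), 30
        ),
        "ALG10": AlgorithmSpec("ALG10", _single_branch(_D135, _ANY, _DR1678), 14),
        "ALG11": AlgorithmSpec("ALG11", _single_branch(_D135, _ANY, _DR1678), 7),
        "ALG12": AlgorithmSpec(
            "ALG12", _single_branch(_D135, _ANY, _DR1678, extra=_MP1), 14
        ),
        "ALG13": AlgorithmSpec("ALG13", _single_branch(_D135, _ANY, _g(C.DRUG6)), 14),
        "ALG14": AlgorithmSpec("ALG14", _single_branch(_D135, _ANY, _g(C.DRUG1)), 14),
        "ALG15": AlgorithmSpec(
            "ALG15", _single_branch(_g(C.DISEASE1), _ANY, _DR1678), 14
        ),
        "ALG16": AlgorithmSpec(
            "ALG16", _single_branch(_g(C.DISEASE6), _ANY, _DR1678), 14
        ),
        "ALG17": AlgorithmSpec(
            "ALG17", _single_branch(_g(C.DISEASE2, C.DISEASE4), _ANY, _DR1678), 14
        ),
        "ALG18": AlgorithmSpec(
            "ALG18", _single_branch(_g(C.DISEASE2), _ANY, _DR1678), 14
        ),
    }
    assert tuple(specs) == ALGORITHM_IDS
    return specs


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def evaluate_algorithm(
    bundle: ClinicalRecordBundle,
    spec: AlgorithmSpec,
    config: CodeSetConfig,
    events: Mapping[C, list[ConditionEvent]] | None = None,
) -> MatchResult:
    """Evaluate one algorithm on one patient.

    The index date is fixed first (earliest disease event); branches are
    then tried in printed order, each group needing one event within the
    closed window [index - w, index + w].  ``events`` may carry a
    precomputed condition-event cache to amortize panel evaluation.
    """
    if events is None:
        events = all_events(bundle, config)

    index_events = [e for cid in spec.disease_group for e in events[cid]]
    fallback_used = False
    if not index_events and spec.index_fallback:
        index_events = [e for cid in spec.index_fallback for e in events[cid]]
        fallback_used = bool(index_events)
    index_date = determine_index_date(index_events)
    if index_date is None:
        return MatchResult(bundle.patient_id, bundle.hospital_id, spec.algorithm_id, False)

    w = spec.half_window_days

    def in_window(e: ConditionEvent) -> bool:
        return abs((e.date - index_date).days) <= w

    for ordinal, branch in enumerate(spec.branches, start=1):
        evidence = []
        for group in branch.groups:
            hits = [e for cid in sorted(group.any_of, key=lambda c: c.value)
                    for e in events[cid] if in_window(e)]
            if not hits:
                evidence = None
                break
            evidence.append(min(hits, key=lambda e: e.date))
        if evidence is not None:
            return MatchResult(
                bundle.patient_id,
                bundle.hospital_id,
                spec.algorithm_id,
                True,
                index_date=index_date,
                satisfied_branch=ordinal,
                evidence=tuple(evidence),
                index_fallback_used=fallback_used,
            )
    return MatchResult(
        bundle.patient_id,
        bundle.hospital_id,
        spec.algorithm_id,
        False,
        index_date=index_date,
        index_fallback_used=fallback_used,
    )


def evaluate_apc(
    bundle: ClinicalRecordBundle,
    config: CodeSetConfig,
    events: Mapping[C, list[ConditionEvent]] | None = None,
) -> MatchResult:
    """Evaluate the All Possible Cases screen on one patient."""
    return evaluate_algorithm(bundle, builtin_registry()["APC"], config, events)


def sample_study_population(
    apc_matches: Sequence[MatchResult],
    min_per_hospital: int,
    seed: int,
) -> list[tuple[str, str]]:
    """Randomly sample the study population from the APC-matched cases.

    Uniform sampling without replacement within each hospital; a hospital
    with at most ``min_per_hospital`` matched cases contributes them all.
    Returns sorted (hospital_id, patient_id) keys; deterministic given seed.
    """
    if min_per_hospital < 1:
        raise ValueError("min_per_hospital must be >= 1")
    by_hospital: dict[str, list[tuple[str, str]]] = {}
    for m in apc_matches:
        if m.matched:
            by_hospital.setdefault(m.hospital_id, []).append(
                (m.hospital_id, m.patient_id)
            )
    rng = np.random.default_rng(seed)
    sampled: list[tuple[str, str]] = []
    for hospital in sorted(by_hospital):
        cases = sorted(by_hospital[hospital])
        if len(cases) <= min_per_hospital:
            sampled.extend(cases)
        else:
            idx = rng.choice(len(cases), size=min_per_hospital, replace=False)
            sampled.extend(cases[i] for i in sorted(idx))
    return sorted(sampled)


@dataclass
class PanelResult:
    """APC screen over the whole cohort plus per-algorithm results on the sample."""

    apc_results: list[MatchResult]
    sampled_cases: list[tuple[str, str]]
    algorithm_results: dict[str, list[MatchResult]] = field(default_factory=dict)

    def possible_cases(self, algorithm_id: str) -> set[tuple[str, str]]:
        return {
            (m.hospital_id, m.patient_id)
            for m in self.algorithm_results[algorithm_id]
            if m.matched
        }


def run_panel(
    bundles: Sequence[ClinicalRecordBundle],
    config: CodeSetConfig,
    registry: Mapping[str, AlgorithmSpec] | None = None,
    min_per_hospital: int = 100,
    seed: int = 0,
) -> PanelResult:
    """Screen every bundle with APC, sample the study population, then run
    Algorithms 1-18 on the sampled cases."""
    if registry is None:
        registry = builtin_registry()
    caches = {b.key: all_events(b, config) for b in bundles}
    apc = [
        evaluate_algorithm(b, registry["APC"], config, caches[b.key]) for b in bundles
    ]
    sampled = sample_study_population(apc, min_per_hospital, seed)
    sampled_set = set(sampled)
    sampled_bundles = [b for b in bundles if b.key in sampled_set]
    result = PanelResult(apc_results=apc, sampled_cases=sampled)
    for alg_id, spec in registry.items():
        if alg_id == "APC":
            continue
        result.algorithm_results[alg_id] = [
            evaluate_algorithm(b, spec, config, caches[b.key]) for b in sampled_bundles
        ]
    return result
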