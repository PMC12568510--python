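"""Independent oracles and randomized inputs for the test suite.

The brute-force evaluator re-decides algorithm matches by exhaustive
enumeration of (branch, event-combination) tuples instead of the engine's
group-wise filtering; the exact-interval oracle inverts the binomial CDF by
bisection instead of using beta quantiles.
"""

from __future__ import annotations

import datetime as dt
from itertools import product

import numpy as np
from scipy.stats import binom

from hfpheno.algorithms import AlgorithmSpec
from hfpheno.conditions import match_condition, ConditionId
from hfpheno.records import (
    ClinicalRecordBundle,
    CodeSetConfig,
    DiagnosisRecord,
    DpcField,
    DrugRecord,
    LabAnalyte,
    LabRecord,
    ProcedureRecord,
    SourceTag,
)

ANCHOR = dt.date(2021, 3, 15)


def brute_force_match(
    bundle: ClinicalRecordBundle, spec: AlgorithmSpec, config: CodeSetConfig
) -> tuple[bool, dt.date | None]:
    """Naive enumeration: try every combination of one event per group."""
    events = {cid: match_condition(bundle, cid, config) for cid in ConditionId}
    index_pool = [e for cid in spec.disease_group for e in events[cid]]
    if not index_pool and spec.index_fallback:
        index_pool = [e for cid in spec.index_fallback for e in events[cid]]
    if not index_pool:
        return False, None
    index_date = min(e.date for e in index_pool)
    w = spec.half_window_days
    for branch in spec.branches:
        pools = [
            [e for cid in group.any_of for e in events[cid]] for group in branch.groups
        ]
        if any(not pool for pool in pools):
            continue
        for combo in product(*pools):
            if all(abs((e.date - index_date).days) <= w for e in combo):
                return True, index_date
    return False, index_date


def clopper_pearson_by_inversion(
    k: int, n: int, level: float = 0.95, tol: float = 1e-10
) -> tuple[float, float]:
    """Exact central interval via bisection on the binomial tails (percent)."""
    alpha = 1.0 - level

    def bisect(f, lo, hi):
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if f(mid):
                hi = mid
            else:
                lo = mid
            if hi - lo < tol:
                break
        return 0.5 * (lo + hi)

    low = 0.0 if k == 0 else bisect(lambda p: binom.sf(k - 1, n, p) > alpha / 2, 0.0, 1.0)
    high = 1.0 if k == n else bisect(lambda p: binom.cdf(k, n, p) < alpha / 2, 0.0, 1.0)
    return 100.0 * low, 100.0 * high


# codes and values chosen to exercise matches, near-misses and boundaries
_ICD = ["I500", "I110", "I509", "J189", "N179"]
_DRUGS = ["C01CE91", "C01CA07", "C03DA01", "C01AA05", "C03AA03", "C03CA01",
          "C03XA01", "C01CE02", "A10BA02"]
_LAB_VALUES = [50.0, 99.9, 100.0, 150.0, 399.9, 400.0, 450.0, 2999.9, 3000.0, 5000.0]


def random_bundle(
    rng: np.random.Generator, max_events: int = 12, spread_days: int = 40
) -> ClinicalRecordBundle:
    """A small random bundle mixing qualifying and non-qualifying records."""
    b = ClinicalRecordBundle(patient_id="P0", hospital_id="H1")
    for _ in range(int(rng.integers(0, max_events + 1))):
        day = ANCHOR + dt.timedelta(days=int(rng.integers(-spread_days, spread_days + 1)))
        kind = rng.random()
        if kind < 0.4:
            source = SourceTag(str(rng.choice([s.value for s in SourceTag])))
            dpc_field = (
                DpcField(str(rng.choice([f.value for f in DpcField])))
                if source is SourceTag.DPC
                else None
            )
            discharge = (
                day + dt.timedelta(days=int(rng.integers(0, 10)))
                if source is SourceTag.DPC and rng.random() < 0.8
                else None
            )
            b.diagnoses.append(
                DiagnosisRecord(
                    "P0", "H1", source, str(rng.choice(_ICD)), day,
                    suspected=bool(rng.random() < 0.3),
                    dpc_field=dpc_field, discharge_date=discharge,
                )
            )
        elif kind < 0.65:
            b.labs.append(
                LabRecord(
                    "P0", "H1",
                    LabAnalyte.BNP if rng.random() < 0.6 else LabAnalyte.NTPROBNP,
                    float(rng.choice(_LAB_VALUES)), day,
                )
            )
        elif kind < 0.9:
            b.drugs.append(
                DrugRecord(
                    "P0", "H1",
                    SourceTag(str(rng.choice([s.value for s in SourceTag]))),
                    str(rng.choice(_DRUGS)), day,
                )
            )
        else:
            b.procedures.append(
                ProcedureRecord(
                    "P0", "H1",
                    SourceTag.DPC if rng.random() < 0.5 else SourceTag.CLAIMS,
                    str(rng.choice(["160074710", "999999999"])), day,
                )
            )
    return b
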