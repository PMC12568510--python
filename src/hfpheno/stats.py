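"""Validity statistics for the identification algorithms.

The design is anchored on the APC screen: the sampled APC population is
fully adjudicated, every adjudicated true case is assumed captured by APC
(100% APC sensitivity), and each algorithm's confusion counts are assembled
within that population.  Point estimates (PPV, sensitivity, NPV,
specificity) carry Clopper-Pearson exact 95% intervals; reviewer agreement
is summarized by the Fleiss-Cohen (quadratic-weight) kappa with its
large-sample standard error.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta

from .adjudication import AdjudicatedCase, AnalysisMode, CaseCategory, as_true
from .algorithms import MatchResult

__all__ = [
    "ConfusionCounts",
    "ValidityEstimate",
    "AgreementTable",
    "KappaResult",
    "assemble_confusion",
    "clopper_pearson",
    "validity_measures",
    "agreement_table",
    "weighted_kappa",
    "report_tables",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up, applied only at presentation time."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-algorithm confusion counts within the sampled APC population.

    ``tn`` is derived by subtracting tp, fp and fn from the total patient
    count of the participating hospitals over the study period; it is None
    when that total is not supplied.
    """

    algorithm_id: str
    mode: AnalysisMode
    tp: int
    fp: int
    fn: int
    tn: int | None = None

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0 or (self.tn is not None and self.tn < 0):
            raise ValueError("confusion counts must be non-negative")

    @property
    def possible_cases(self) -> int:
        return self.tp + self.fp

    @property
    def true_cases(self) -> int:
        return self.tp + self.fn


def assemble_confusion(
    matches: Sequence[MatchResult],
    adjudications: Iterable[AdjudicatedCase],
    mode: AnalysisMode,
    total_population: int | None = None,
) -> ConfusionCounts:
    """Cross one algorithm's match results with the final review categories.

    ``matches`` covers the sampled APC population for a single algorithm.
    tp = matched and adjudicated true; fp = matched, not true; fn = not
    matched but true (true cases are assumed fully captured by APC).
    """
    if not matches:
        raise ValueError("no match results supplied")
    algorithm_ids = {m.algorithm_id for m in matches}
    if len(algorithm_ids) != 1:
        raise ValueError(f"matches span several algorithms: {sorted(algorithm_ids)}")
    final = {c.key: c.final for c in adjudications}
    tp = fp = fn = 0
    for m in matches:
        key = (m.hospital_id, m.patient_id)
        if key not in final:
            if m.matched:
                raise ValueError(
                    f"matched case {key} has no adjudication"
                )
            raise ValueError(f"sampled case {key} has no adjudication")
        truth = as_true(final[key], mode)
        if m.matched and truth:
            tp += 1
        elif m.matched:
            fp += 1
        elif truth:
            fn += 1
    tn = None
    if total_population is not None:
        tn = total_population - tp - fp - fn
        if tn < 0:
            raise ValueError(
                f"total_population {total_population} smaller than tp+fp+fn {tp + fp + fn}"
            )
    return ConfusionCounts(algorithm_ids.pop(), mode, tp=tp, fp=fp, fn=fn, tn=tn)


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact central binomial interval, returned as percentages.

    Obtained from beta quantiles: low = B(alpha/2; k, n-k+1),
    high = B(1-alpha/2; k+1, n-k), with the degenerate bounds 0 at k=0 and
    100 at k=n.
    """
    if not (0 <= k <= n) or n < 1:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    alpha = 1.0 - level
    low = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(beta.ppf(1 - alpha / 2, k + 1, n - k))
    return 100.0 * low, 100.0 * high


@dataclass(frozen=True)
class ValidityEstimate:
    """One binomial validity measure with its exact interval (percent scale)."""

    measure: str  # PPV | SENSITIVITY | NPV | SPECIFICITY
    numerator: int
    denominator: int
    point: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.point <= self.ci_high):
            raise ValueError("interval must contain the point estimate")


_MEASURES = {
    "PPV": lambda c: (c.tp, c.tp + c.fp),
    "SENSITIVITY": lambda c: (c.tp, c.tp + c.fn),
    "NPV": lambda c: (c.tn, c.fn + c.tn) if c.tn is not None else None,
    "SPECIFICITY": lambda c: (c.tn, c.fp + c.tn) if c.tn is not None else None,
}


def validity_measures(
    counts: ConfusionCounts, level: float = 0.95
) -> dict[str, ValidityEstimate | None]:
    """PPV, sensitivity and (when tn is available) NPV and specificity.

    The sensitivity denominator tp+fn is the number of adjudicated true
    cases in the sampled APC population, i.e. APC sensitivity is taken as
    100%.  A zero denominator yields None for that measure rather than a
    silent zero.
    """
    out: dict[str, ValidityEstimate | None] = {}
    for name, fetch in _MEASURES.items():
        kn = fetch(counts)
        if kn is None or kn[1] == 0:
            out[name] = None
            continue
        k, n = kn
        low, high = clopper_pearson(k, n, level)
        out[name] = ValidityEstimate(
            measure=name,
            numerator=k,
            denominator=n,
            point=100.0 * k / n,
            ci_low=low,
            ci_high=high,
        )
    return out


# ---------------------------------------------------------------------------
# Inter-reviewer agreement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgreementTable:
    """k x k cross-classification of the two reviewers' category labels."""

    counts: np.ndarray  # rows: reviewer A, columns: reviewer B

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("agreement table must be square")
        if (c < 0).any():
            raise ValueError("agreement counts must be non-negative")

    @property
    def n(self) -> int:
        return int(np.asarray(self.counts).sum())


def agreement_table(cases: Iterable[AdjudicatedCase]) -> AgreementTable:
    """Pooled 4x4 reviewer-agreement table in CaseCategory order."""
    k = len(CaseCategory)
    counts = np.zeros((k, k), dtype=int)
    for c in cases:
        counts[c.reviewer_a.value, c.reviewer_b.value] += 1
    return AgreementTable(counts)


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    se: float
    ci_low: float
    ci_high: float
    n: int


def weighted_kappa(table: AgreementTable | np.ndarray, level: float = 0.95) -> KappaResult:
    """Fleiss-Cohen weighted kappa with quadratic weights.

    Weights w_ij = 1 - ((i - j)/(k - 1))^2 over the ordered categories;
    kappa = (Po_w - Pe_w)/(1 - Pe_w) with Po_w and Pe_w the weighted
    observed and chance-expected agreement.  The standard error is the
    Fleiss-Cohen-Everitt large-sample formula and the interval the normal
    approximation truncated to [-1, 1].
    """
    counts = np.asarray(table.counts if isinstance(table, AgreementTable) else table,
                        dtype=float)
    n = counts.sum()
    if n < 2:
        raise ValueError("agreement table needs at least two cases")
    k = counts.shape[0]
    p = counts / n
    pi, pj = p.sum(axis=1), p.sum(axis=0)
    idx = np.arange(k)
    w = 1.0 - ((idx[:, None] - idx[None, :]) / (k - 1)) ** 2
    po = float((p * w).sum())
    pe = float((np.outer(pi, pj) * w).sum())
    if pe >= 1.0:
        raise ValueError("degenerate agreement table: chance agreement is 1")
    kappa = (po - pe) / (1.0 - pe)
    # Fleiss, Cohen & Everitt large-sample variance of weighted kappa
    w_row = w @ pj          # E[w | reviewer A category i]
    w_col = pi @ w          # E[w | reviewer B category j]
    term = (p * (w - (w_row[:, None] + w_col[None, :]) * (1.0 - kappa)) ** 2).sum()
    var = (term - (kappa - pe * (1.0 - kappa)) ** 2) / (n * (1.0 - pe) ** 2)
    se = float(np.sqrt(max(var, 0.0)))
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2)
    return KappaResult(
        kappa=float(kappa),
        se=se,
        ci_low=max(-1.0, kappa - z * se),
        ci_high=min(1.0, kappa + z * se),
        n=int(n),
    )


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

def _format_row(counts: ConfusionCounts, apc_row: bool, level: float) -> dict:
    m = validity_measures(counts, level)
    row = {
        "algorithm": counts.algorithm_id,
        "mode": counts.mode.value,
        "possible_cases": counts.possible_cases,
        "tp": counts.tp,
        "fp": counts.fp,
        "fn": counts.fn,
    }
    ppv = m["PPV"]
    row.update(
        ppv=round_half_up(ppv.point) if ppv else np.nan,
        ppv_low=round_half_up(ppv.ci_low) if ppv else np.nan,
        ppv_high=round_half_up(ppv.ci_high) if ppv else np.nan,
    )
    if apc_row:
        # the APC screen anchors the denominator: sensitivity fixed at 100%
        row.update(sensitivity=100.0, sensitivity_low=np.nan, sensitivity_high=np.nan)
    else:
        sen = m["SENSITIVITY"]
        row.update(
            sensitivity=round_half_up(sen.point) if sen else np.nan,
            sensitivity_low=round_half_up(sen.ci_low) if sen else np.nan,
            sensitivity_high=round_half_up(sen.ci_high) if sen else np.nan,
        )
    for name in ("NPV", "SPECIFICITY"):
        est = m[name]
        key = name.lower()
        row.update(
            {
                key: round_half_up(est.point) if est else np.nan,
                f"{key}_low": round_half_up(est.ci_low) if est else np.nan,
                f"{key}_high": round_half_up(est.ci_high) if est else np.nan,
            }
        )
    return row


def report_tables(
    panel,
    adjudications: Iterable[AdjudicatedCase],
    modes: Sequence[AnalysisMode] = (AnalysisMode.PRIMARY, AnalysisMode.SENSITIVITY),
    total_population: int | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """One validity row per algorithm per mode, mirroring the published layout.

    ``panel`` is a :class:`~hfpheno.algorithms.PanelResult`.  The APC row is
    built from the sampled population itself: every sampled case is
    APC-matched, its PPV is the adjudicated true fraction and its
    sensitivity is 100% by construction.
    """
    adjudications = list(adjudications)
    final = {c.key: c.final for c in adjudications}
    sampled = list(panel.sampled_cases)
    missing = [k for k in sampled if k not in final]
    if missing:
        raise ValueError(f"sampled case {missing[0]} has no adjudication")
    rows = []
    for mode in modes:
        n_true = sum(1 for key in sampled if as_true(final[key], mode))
        apc_counts = ConfusionCounts(
            "APC",
            mode,
            tp=n_true,
            fp=len(sampled) - n_true,
            fn=0,
            tn=(total_population - len(sampled)) if total_population is not None else None,
        )
        rows.append(_format_row(apc_counts, apc_row=True, level=level))
        for alg_id, matches in panel.algorithm_results.items():
            counts = assemble_confusion(matches, adjudications, mode, total_population)
            rows.append(_format_row(counts, apc_row=False, level=level))
    return pd.DataFrame(rows)
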