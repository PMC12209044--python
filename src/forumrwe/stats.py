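"""Risk ratios, log-scale confidence intervals and inclusion rules.

For one treatment–symptom combination with ``n_I`` improving and ``n_W``
worsening users, the perception risk ratio is

    RR = n_I / n_W

with ``RR = inf`` when ``n_W = 0`` and ``RR = 0`` when ``n_I = 0``.  Its 95%
confidence interval is computed on the log scale,

    CI = exp[ ln(RR) ± z * sqrt(1/n_I + 1/n_W - 2/(n_I + n_W)) ],

with ``z = 1.9599``, and is undefined (reported absent) when either count is
zero.  A combination is *included* when more than ``min_users`` users
discussed it with directional sentiment (strictly ``n > 20`` by default) and
*significant* when its CI exists and excludes 1.0.  No multiple-comparison
correction is applied: the analysis is exploratory by design, and results
are not meant to be read in isolation.

Note the RR here is a ratio of perception counts, not a cohort risk ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

from .corpus import Catalog, FeatureKind, FeatureMention, SentimentLabel
from .pairing import UserVerdict, Verdict

__all__ = [
    "Z_95",
    "CombinationStats",
    "SentimentRatios",
    "risk_ratio",
    "confidence_interval",
    "flag_combination",
    "combination_stats",
    "overall_sentiment_ratios",
    "invert_counts",
    "round_half_away",
    "format_rr",
    "AmbiguousCountsError",
    "NoCountsSolutionError",
    "DEFAULT_MIN_USERS_COMBINATION",
    "DEFAULT_MIN_USERS_OVERALL",
]

#: The normal quantile as printed in the interval formula (not 1.959964).
Z_95 = 1.9599

DEFAULT_MIN_USERS_COMBINATION = 20
DEFAULT_MIN_USERS_OVERALL = 100


class NoCountsSolutionError(ValueError):
    """No integer split of n reproduces the printed ratio."""


class AmbiguousCountsError(ValueError):
    """More than one integer split reproduces the printed ratio."""

    def __init__(self, candidates: list[tuple[int, int]]):
        self.candidates = candidates
        super().__init__(f"ambiguous inversion; candidates: {candidates}")


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (5.195 → 5.20, -0.125 → -0.13)."""
    if not math.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def format_rr(rr: float, ndigits: int = 2) -> str:
    """Render a risk ratio the way results tables print it: ``inf``, ``0`` or 2 dp."""
    if math.isinf(rr):
        return "inf"
    if rr == 0:
        return "0"
    return f"{round_half_away(rr, ndigits):.{ndigits}f}"


def risk_ratio(n_I: int, n_W: int) -> float:
    """``n_I / n_W``; infinity when ``n_W = 0``, zero when ``n_I = 0``.

    Both counts zero is a domain error: no directional sentiment exists.
    """
    if n_I < 0 or n_W < 0:
        raise ValueError("counts must be nonnegative")
    if n_I == 0 and n_W == 0:
        raise ValueError("risk ratio undefined when both counts are zero")
    if n_W == 0:
        return math.inf
    return n_I / n_W


def confidence_interval(n_I: int, n_W: int, z: float = Z_95) -> tuple[float, float]:
    """95% CI for the risk ratio on the log scale; requires both counts ≥ 1."""
    if n_I < 1 or n_W < 1:
        raise ValueError("confidence interval requires n_I >= 1 and n_W >= 1")
    se = math.sqrt(1.0 / n_I + 1.0 / n_W - 2.0 / (n_I + n_W))
    log_rr = math.log(n_I / n_W)
    return (math.exp(log_rr - z * se), math.exp(log_rr + z * se))


def log_rr_standard_error(n_I: int, n_W: int) -> float:
    """The standard-error term of the interval formula, on the log scale."""
    if n_I < 1 or n_W < 1:
        raise ValueError("standard error requires n_I >= 1 and n_W >= 1")
    return math.sqrt(1.0 / n_I + 1.0 / n_W - 2.0 / (n_I + n_W))


def invert_counts(rr_printed: float, n_total: int, ndigits: int = 2) -> tuple[int, int]:
    """Recover the integer counts behind a printed ``(RR, n)`` pair.

    Searches all splits ``n_I + n_W = n_total`` with both counts ≥ 1 for the
    one whose ratio rounds (half away from zero) to ``rr_printed`` at
    ``ndigits`` decimals.  Raises :class:`NoCountsSolutionError` when no
    split matches and :class:`AmbiguousCountsError` (listing the candidates)
    when several do.
    """
    if not (rr_printed > 0 and math.isfinite(rr_printed)):
        raise ValueError("rr_printed must be finite and positive")
    if n_total < 2:
        raise ValueError("n_total must be at least 2")
    target = round_half_away(rr_printed, ndigits)
    candidates = [
        (n_I, n_total - n_I)
        for n_I in range(1, n_total)
        if abs(round_half_away(n_I / (n_total - n_I), ndigits) - target) < 10 ** -(ndigits + 4)
    ]
    if not candidates:
        raise NoCountsSolutionError(
            f"no integer split of {n_total} has ratio {rr_printed:.{ndigits}f}"
        )
    if len(candidates) > 1:
        raise AmbiguousCountsError(candidates)
    return candidates[0]


@dataclass(frozen=True)
class CombinationStats:
    """Per-combination counts, RR, CI and the inclusion/significance flags."""

    treatment_id: str
    symptom_id: str
    n_I: int
    n_W: int
    rr: float
    ci_low: float | None
    ci_high: float | None
    included: bool = False
    significant: bool = False
    n_neutral: int = 0
    n_excluded: int = 0

    @property
    def n(self) -> int:
        return self.n_I + self.n_W


def flag_combination(
    stats: CombinationStats, min_users: int = DEFAULT_MIN_USERS_COMBINATION
) -> CombinationStats:
    """Set inclusion (strictly more than ``min_users`` directional users) and
    significance (CI exists and excludes 1.0)."""
    included = stats.n > min_users
    significant = (
        stats.ci_low is not None
        and stats.ci_high is not None
        and (stats.ci_low > 1.0 or stats.ci_high < 1.0)
    )
    return replace(stats, included=included, significant=significant)


def combination_stats(
    verdicts: Iterable[UserVerdict],
    min_users: int = DEFAULT_MIN_USERS_COMBINATION,
    z: float = Z_95,
) -> list[CombinationStats]:
    """Aggregate user verdicts into flagged per-combination statistics.

    Neutral verdicts never enter ``n`` (the RR uses directional counts only)
    but are carried for discussion-volume reporting; excluded users likewise.
    Combinations with no directional verdict at all get ``rr = nan``.
    """
    counts: dict[tuple[str, str], dict[Verdict, int]] = {}
    for v in verdicts:
        combo = counts.setdefault((v.treatment_id, v.symptom_id), {})
        combo[v.verdict] = combo.get(v.verdict, 0) + 1
    out: list[CombinationStats] = []
    for (t, s), combo in sorted(counts.items()):
        n_I = combo.get(Verdict.IMPROVED, 0)
        n_W = combo.get(Verdict.WORSENED, 0)
        if n_I == 0 and n_W == 0:
            rr: float = math.nan
        else:
            rr = risk_ratio(n_I, n_W)
        ci = confidence_interval(n_I, n_W, z) if (n_I >= 1 and n_W >= 1) else None
        stats = CombinationStats(
            treatment_id=t,
            symptom_id=s,
            n_I=n_I,
            n_W=n_W,
            rr=rr,
            ci_low=ci[0] if ci else None,
            ci_high=ci[1] if ci else None,
            n_neutral=combo.get(Verdict.NEUTRAL, 0),
            n_excluded=combo.get(Verdict.EXCLUDED, 0),
        )
        out.append(flag_combination(stats, min_users))
    return out


@dataclass(frozen=True)
class SentimentRatios:
    """Per-feature sentiment mix: one contribution per user per sentiment."""

    feature_id: str
    kind: FeatureKind
    n_improving: int
    n_neutral: int
    n_worsening: int
    total_users: int
    included: bool

    @property
    def proportions(self) -> tuple[float, float, float]:
        total = self.n_improving + self.n_neutral + self.n_worsening
        if total == 0:
            return (math.nan, math.nan, math.nan)
        return (
            self.n_improving / total,
            self.n_neutral / total,
            self.n_worsening / total,
        )


def overall_sentiment_ratios(
    mentions: Iterable[FeatureMention],
    catalog: Catalog,
    min_users_treatment: int = DEFAULT_MIN_USERS_OVERALL,
) -> list[SentimentRatios]:
    """Overall sentiment mix per feature across all (first-person) mentions.

    Each user contributes at most once to each sentiment bucket of a feature;
    ``total_users`` counts distinct users mentioning the feature.  Treatments
    with ``total_users`` not strictly above ``min_users_treatment`` are
    marked excluded from the headline report; symptoms are unrestricted.
    """
    users: dict[str, dict[SentimentLabel, set[str]]] = {}
    for m in mentions:
        buckets = users.setdefault(
            m.feature_id, {s: set() for s in SentimentLabel}
        )
        buckets[m.sentiment].add(m.user_id)
    out: list[SentimentRatios] = []
    for fid in sorted(users):
        buckets = users[fid]
        kind = catalog.kind_of(fid)
        total = len(set().union(*buckets.values()))
        included = True
        if kind is FeatureKind.TREATMENT:
            included = total > min_users_treatment
        out.append(
            SentimentRatios(
                feature_id=fid,
                kind=kind,
                n_improving=len(buckets[SentimentLabel.IMPROVING]),
                n_neutral=len(buckets[SentimentLabel.NEUTRAL]),
                n_worsening=len(buckets[SentimentLabel.WORSENING]),
                total_users=total,
                included=included,
            )
        )
    return out
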