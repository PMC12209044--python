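"""Treatment–symptom co-mention pairing and sentiment resolution.

Two features mentioned within two sentences of each other in one document
are assumed to be discussed in relation to each other.  Each treatment–
symptom co-mention is resolved into an association instance from the two
sentiment labels; contradictory labels abandon the assumption:

====================  ==================  ============
treatment sentiment   symptom sentiment   resolution
====================  ==================  ============
improving             improving           improved
worsening             worsening           worsened
improving             worsening           abandoned
worsening             improving           abandoned
improving             neutral             improved
worsening             neutral             worsened
neutral               improving           improved
neutral               worsening           worsened
neutral               neutral             neutral
====================  ==================  ============

Instances are then aggregated to one verdict per (user, treatment, symptom):
the user is the counting unit downstream, and a user whose surviving
instances point both ways is excluded from that combination, mirroring the
mention-level abandonment rule at the user level.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import groupby
from typing import Iterable

from .corpus import Catalog, FeatureKind, FeatureMention, SentimentLabel

__all__ = [
    "Resolution",
    "Verdict",
    "PairInstance",
    "UserVerdict",
    "find_comentions",
    "resolve_sentiment",
    "extract_pair_instances",
    "aggregate_user_verdicts",
    "instance_verdicts",
    "treatment_combinations",
    "DEFAULT_WINDOW",
]

DEFAULT_WINDOW = 2


class Resolution(str, Enum):
    IMPROVED = "improved"
    WORSENED = "worsened"
    NEUTRAL = "neutral"
    ABANDONED = "abandoned"


class Verdict(str, Enum):
    IMPROVED = "improved"
    WORSENED = "worsened"
    NEUTRAL = "neutral"
    EXCLUDED = "excluded"


_S = SentimentLabel
_RESOLUTION_TABLE: dict[tuple[SentimentLabel, SentimentLabel], Resolution] = {
    (_S.IMPROVING, _S.IMPROVING): Resolution.IMPROVED,
    (_S.WORSENING, _S.WORSENING): Resolution.WORSENED,
    (_S.IMPROVING, _S.WORSENING): Resolution.ABANDONED,
    (_S.WORSENING, _S.IMPROVING): Resolution.ABANDONED,
    (_S.IMPROVING, _S.NEUTRAL): Resolution.IMPROVED,
    (_S.WORSENING, _S.NEUTRAL): Resolution.WORSENED,
    (_S.NEUTRAL, _S.IMPROVING): Resolution.IMPROVED,
    (_S.NEUTRAL, _S.WORSENING): Resolution.WORSENED,
    (_S.NEUTRAL, _S.NEUTRAL): Resolution.NEUTRAL,
}


def resolve_sentiment(
    treatment_sentiment: SentimentLabel, symptom_sentiment: SentimentLabel
) -> Resolution:
    """Resolve one co-mention's sentiment combination into an instance class."""
    return _RESOLUTION_TABLE[(treatment_sentiment, symptom_sentiment)]


@dataclass(frozen=True)
class PairInstance:
    """One resolved treatment→symptom co-mention within a document."""

    user_id: str
    treatment_id: str
    symptom_id: str
    resolved: Resolution
    doc_id: str
    gap: int


@dataclass(frozen=True)
class UserVerdict:
    """One user's overall verdict for one treatment–symptom combination."""

    user_id: str
    treatment_id: str
    symptom_id: str
    verdict: Verdict


def _check_single_doc(mentions: list[FeatureMention]) -> None:
    doc_ids = {m.doc_id for m in mentions}
    if len(doc_ids) > 1:
        raise ValueError(f"mentions span multiple documents: {sorted(doc_ids)}")


def find_comentions(
    mentions: Iterable[FeatureMention],
    catalog: Catalog,
    window: int = DEFAULT_WINDOW,
) -> list[tuple[FeatureMention, FeatureMention, int]]:
    """All (treatment mention, symptom mention, gap) pairs within ``window``
    sentences of each other, inside one document.

    The same sentence counts (gap 0); mentions from more than one document
    raise ``ValueError``.  A mention may participate in multiple pairs.
    """
    ms = list(mentions)
    _check_single_doc(ms)
    treatments = [m for m in ms if catalog.kind_of(m.feature_id) is FeatureKind.TREATMENT]
    symptoms = [m for m in ms if catalog.kind_of(m.feature_id) is FeatureKind.SYMPTOM]
    out: list[tuple[FeatureMention, FeatureMention, int]] = []
    for t in treatments:
        for s in symptoms:
            gap = abs(t.sentence_index - s.sentence_index)
            if gap <= window:
                out.append((t, s, gap))
    return out


def treatment_combinations(
    mentions: Iterable[FeatureMention],
    catalog: Catalog,
    window: int = DEFAULT_WINDOW,
) -> list[tuple[str, str, str]]:
    """Unordered distinct-treatment co-mention events within one document.

    Returns ``(user_id, treatment_a, treatment_b)`` with ``a < b``
    canonically, one tuple per co-occurring mention pair; self-pairs are
    excluded and de-duplication to unique users happens downstream.
    """
    ms = list(mentions)
    _check_single_doc(ms)
    treatments = [m for m in ms if catalog.kind_of(m.feature_id) is FeatureKind.TREATMENT]
    out: list[tuple[str, str, str]] = []
    for i, a in enumerate(treatments):
        for b in treatments[i + 1 :]:
            if a.feature_id == b.feature_id:
                continue
            if abs(a.sentence_index - b.sentence_index) <= window:
                x, y = sorted((a.feature_id, b.feature_id))
                out.append((a.user_id, x, y))
    return out


def extract_pair_instances(
    mentions: Iterable[FeatureMention],
    catalog: Catalog,
    window: int = DEFAULT_WINDOW,
) -> list[PairInstance]:
    """Resolve every in-window treatment–symptom co-mention across a corpus'
    mentions (grouped per document) into :class:`PairInstance` records."""
    by_doc: dict[str, list[FeatureMention]] = {}
    for m in mentions:
        by_doc.setdefault(m.doc_id, []).append(m)
    instances: list[PairInstance] = []
    for doc_id in sorted(by_doc):
        for t, s, gap in find_comentions(by_doc[doc_id], catalog, window):
            instances.append(
                PairInstance(
                    user_id=t.user_id,
                    treatment_id=t.feature_id,
                    symptom_id=s.feature_id,
                    resolved=resolve_sentiment(t.sentiment, s.sentiment),
                    doc_id=doc_id,
                    gap=gap,
                )
            )
    return instances


def aggregate_user_verdicts(instances: Iterable[PairInstance]) -> list[UserVerdict]:
    """Collapse instances to at most one verdict per (user, treatment, symptom).

    Abandoned instances are discarded first.  If the surviving instances for
    a combination include both improved and worsened, the user is excluded
    from that combination; otherwise the verdict is improved if any instance
    improved, worsened if any worsened, else neutral.  A combination whose
    instances were all abandoned yields no verdict.
    """
    key = lambda i: (i.user_id, i.treatment_id, i.symptom_id)
    verdicts: list[UserVerdict] = []
    for (user, t, s), grp in groupby(sorted(instances, key=key), key=key):
        kept = {i.resolved for i in grp if i.resolved is not Resolution.ABANDONED}
        if not kept:
            continue
        if Resolution.IMPROVED in kept and Resolution.WORSENED in kept:
            verdict = Verdict.EXCLUDED
        elif Resolution.IMPROVED in kept:
            verdict = Verdict.IMPROVED
        elif Resolution.WORSENED in kept:
            verdict = Verdict.WORSENED
        else:
            verdict = Verdict.NEUTRAL
        verdicts.append(UserVerdict(user, t, s, verdict))
    return verdicts


def instance_verdicts(instances: Iterable[PairInstance]) -> list[UserVerdict]:
    """Instance-level counting mode: every non-abandoned instance contributes
    one verdict-like record (no per-user de-duplication or exclusion).

    Provided because the source phrasing is ambiguous between counting raw
    instances and counting users; user-level counting is the default
    elsewhere.
    """
    out: list[UserVerdict] = []
    for i in instances:
        if i.resolved is Resolution.ABANDONED:
            continue
        out.append(
            UserVerdict(i.user_id, i.treatment_id, i.symptom_id, Verdict(i.resolved.value))
        )
    return out
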