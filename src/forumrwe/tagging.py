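"""Feature-mention tagging: pluggable contract, lexicon reference tagger,
first-person filter and an evaluation harness.

The tagging stage maps documents to :class:`~forumrwe.corpus.FeatureMention`
records.  In production settings this slot is typically filled by trained
text classifiers; here the contract is any deterministic callable
``(Document, Catalog) -> list[FeatureMention]``, and the shipped reference
implementation is a transparent lexicon tagger:

* a feature is mentioned in a sentence when one of its synonyms matches
  case-insensitively at word boundaries;
* the mention's sentiment is the label of the nearest sentiment cue word in
  the same sentence (distance measured between character spans; a tie
  between different labels, or no cue at all, yields neutral);
* a sentence reports someone else's experience (``first_person=False``)
  exactly when it opens with a configured third-person marker phrase.

The evaluation harness computes per-feature precision/recall and
per-sentiment accuracy against gold annotations, matching mentions on
``(doc_id, sentence_index, feature_id)``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from .corpus import (
    Catalog,
    Corpus,
    Document,
    FeatureMention,
    SentimentLabel,
)

__all__ = [
    "TaggerContract",
    "LexiconTagger",
    "lexicon_tag",
    "tag_corpus",
    "filter_first_person",
    "TaggerMetrics",
    "evaluate_tagger",
]

TaggerContract = Callable[[Document, Catalog], list[FeatureMention]]


def _word_pattern(phrase: str) -> re.Pattern[str]:
    return re.compile(r"(?<!\w)" + re.escape(phrase.lower()) + r"(?!\w)")


def _span_gap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Character gap between two non-overlapping spans (0 if they touch/overlap)."""
    return max(0, a[0] - b[1], b[0] - a[1])


class LexiconTagger:
    """Deterministic surface-form tagger over a validated catalog."""

    def __init__(self, catalog: Catalog):
        self.catalog = catalog
        self._feature_patterns: list[tuple[str, list[re.Pattern[str]]]] = [
            (f.feature_id, [_word_pattern(s) for s in f.synonyms])
            for f in catalog.features
        ]
        self._cue_patterns: list[tuple[SentimentLabel, re.Pattern[str]]] = [
            (SentimentLabel(label), _word_pattern(cue))
            for label, cues in sorted(catalog.cue_lexicons.items())
            for cue in cues
        ]
        self._markers = [m.lower() for m in catalog.third_person_markers]

    def __call__(self, document: Document, catalog: Catalog | None = None) -> list[FeatureMention]:
        return self.tag(document)

    def tag(self, document: Document) -> list[FeatureMention]:
        mentions: list[FeatureMention] = []
        for idx, sentence in enumerate(document.sentences):
            low = sentence.lower()
            first_person = not any(low.startswith(m) for m in self._markers)
            cues = [
                (label, m.span())
                for label, pat in self._cue_patterns
                for m in pat.finditer(low)
            ]
            hits: list[tuple[int, str, tuple[int, int]]] = []
            for feature_id, patterns in self._feature_patterns:
                best: tuple[int, int] | None = None
                for pat in patterns:
                    m = pat.search(low)
                    if m and (best is None or m.start() < best[0]):
                        best = m.span()
                if best is not None:
                    hits.append((best[0], feature_id, best))
            for anchor, feature_id, span in sorted(hits):
                mentions.append(
                    FeatureMention(
                        doc_id=document.doc_id,
                        sentence_index=idx,
                        feature_id=feature_id,
                        user_id=document.user_id,
                        sentiment=self._nearest_cue(span, cues),
                        first_person=first_person,
                    )
                )
        return mentions

    @staticmethod
    def _nearest_cue(
        span: tuple[int, int],
        cues: Sequence[tuple[SentimentLabel, tuple[int, int]]],
    ) -> SentimentLabel:
        if not cues:
            return SentimentLabel.NEUTRAL
        best = min(_span_gap(span, c_span) for _, c_span in cues)
        labels = {label for label, c_span in cues if _span_gap(span, c_span) == best}
        if len(labels) != 1:
            return SentimentLabel.NEUTRAL  # ambiguous → neutral
        return labels.pop()


def lexicon_tag(document: Document, catalog: Catalog) -> list[FeatureMention]:
    """Tag one document with the reference lexicon tagger (functional form)."""
    return LexiconTagger(catalog).tag(document)


def tag_corpus(corpus: Corpus, tagger: TaggerContract | None = None) -> list[FeatureMention]:
    """Apply a tagger to every document; default is the lexicon tagger."""
    tag = LexiconTagger(corpus.catalog) if tagger is None else tagger
    out: list[FeatureMention] = []
    for doc in corpus.documents:
        out.extend(tag(doc, corpus.catalog))
    return out


def filter_first_person(mentions: Iterable[FeatureMention]) -> list[FeatureMention]:
    """Drop mentions describing someone else's experience; order preserved."""
    return [m for m in mentions if m.first_person]


@dataclass(frozen=True)
class TaggerMetrics:
    """Precision/recall per feature and sentiment accuracy over matched mentions.

    ``precision``/``recall`` map feature_id to a value in [0, 1], or NaN when
    the denominator is empty (no predictions / no gold for that feature).
    """

    precision: dict[str, float]
    recall: dict[str, float]
    sentiment_accuracy: float
    n_predicted: int
    n_gold: int
    n_matched: int

    @property
    def micro_precision(self) -> float:
        return self.n_matched / self.n_predicted if self.n_predicted else math.nan

    @property
    def micro_recall(self) -> float:
        return self.n_matched / self.n_gold if self.n_gold else math.nan


def _key(m: FeatureMention) -> tuple[str, int, str]:
    return (m.doc_id, m.sentence_index, m.feature_id)


def evaluate_tagger(
    predicted: Iterable[FeatureMention], gold: Iterable[FeatureMention]
) -> TaggerMetrics:
    """Score predicted mentions against gold annotations.

    A true positive is a predicted mention whose ``(doc_id, sentence_index,
    feature_id)`` key appears in the gold set; sentiment accuracy is computed
    over matched mentions only.  Predicted and gold must refer to overlapping
    corpora (disjoint document sets raise ``ValueError``).
    """
    pred = {_key(m): m for m in predicted}
    gld = {_key(m): m for m in gold}
    if pred and gld:
        pred_docs = {k[0] for k in pred}
        gold_docs = {k[0] for k in gld}
        if not pred_docs & gold_docs:
            raise ValueError("predicted and gold mentions refer to disjoint corpora")

    features = sorted({k[2] for k in pred} | {k[2] for k in gld})
    matched = set(pred) & set(gld)
    precision: dict[str, float] = {}
    recall: dict[str, float] = {}
    for fid in features:
        n_pred = sum(1 for k in pred if k[2] == fid)
        n_gold = sum(1 for k in gld if k[2] == fid)
        n_tp = sum(1 for k in matched if k[2] == fid)
        precision[fid] = n_tp / n_pred if n_pred else math.nan
        recall[fid] = n_tp / n_gold if n_gold else math.nan
    if matched:
        acc = sum(1 for k in matched if pred[k].sentiment == gld[k].sentiment) / len(matched)
    else:
        acc = math.nan
    return TaggerMetrics(
        precision=precision,
        recall=recall,
        sentiment_accuracy=acc,
        n_predicted=len(pred),
        n_gold=len(gld),
        n_matched=len(matched),
    )
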