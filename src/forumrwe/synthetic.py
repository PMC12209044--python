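"""Synthetic forum generator with known ground truth.

Emulates, at desk scale, a patient forum in which users discuss treatments
and symptoms with improving/worsening/neutral sentiment: per-user documents,
treatment–symptom co-mentions at controlled sentence distances, contradictory
sentiment noise, third-person (someone else's experience) sentences, and
treatment–treatment co-mentions for the combination network.  Every embedded
mention is recorded as a gold annotation, so downstream stages can be tested
for exact recovery.

The generative model is deliberately simple and fully parameterised:

* each user independently produces, per configured treatment–symptom pair,
  at most one co-mention with probability ``p_comention``;
* a produced co-mention is improving with probability ``p_improving``,
  worsening with ``p_worsening``, else neutral — both mentions of the pair
  carry that sentiment, except with probability ``conflict_rate`` the pair is
  emitted with contradictory sentiments (which downstream abandonment
  discards);
* the sentence gap between the two mentions is drawn from a distribution
  over {0, 1, 2, >2}, where >2 exercises the window's exclusion branch;
* any mention sentence is third-person with probability
  ``third_person_rate``.

Filler vocabulary is disjoint from every catalog synonym and sentiment cue,
so the reference lexicon tagger recovers the gold annotations exactly and
pairing/statistics tests are isolated from tagging noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .corpus import (
    Catalog,
    Corpus,
    Document,
    FeatureDef,
    FeatureMention,
    SentimentLabel,
    load_catalog,
)

__all__ = [
    "PairGroundTruth",
    "ComboGroundTruth",
    "GeneratorConfig",
    "default_config",
    "generate_corpus",
    "embed_mention",
    "FILLER_VOCABULARY",
]

# Disjoint from all default-catalog synonyms, cue words and marker phrases.
FILLER_VOCABULARY: tuple[str, ...] = (
    "honestly", "today", "anyway", "update", "morning", "routine", "sharing",
    "journey", "recently", "wondering", "question", "thread", "forum",
    "reading", "started", "tracking", "noticed", "thinking", "planning",
    "appointment", "visit", "again", "lately", "overall", "really", "slowly",
    "finally", "together", "evening", "checking",
)

_GAPS = (0, 1, 2, 3)  # 3 encodes "more than two sentences apart"


@dataclass(frozen=True)
class PairGroundTruth:
    """True generative parameters for one treatment→symptom combination.

    ``true_rr`` is the ratio of the improving and worsening instance
    probabilities — the quantity the pipeline's risk ratio estimates.
    """

    treatment_id: str
    symptom_id: str
    p_comention: float
    p_improving: float
    p_worsening: float

    def __post_init__(self) -> None:
        for name in ("p_comention", "p_improving", "p_worsening"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.p_improving + self.p_worsening > 1.0 + 1e-12:
            raise ValueError("p_improving + p_worsening must not exceed 1")

    @property
    def true_rr(self) -> float:
        if self.p_worsening == 0.0:
            return math.inf
        return self.p_improving / self.p_worsening


@dataclass(frozen=True)
class ComboGroundTruth:
    """True co-mention probability for one treatment–treatment combination."""

    treatment_a: str
    treatment_b: str
    p_comention: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_comention <= 1.0:
            raise ValueError("p_comention must be in [0, 1]")
        if self.treatment_a == self.treatment_b:
            raise ValueError("combination must join two distinct treatments")


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic corpus.

    ``distance_distribution`` gives probabilities over sentence gaps
    {0, 1, 2, >2} for related mention pairs; ``seed`` is mandatory so every
    corpus is reproducible.
    """

    seed: int
    n_users: int = 1000
    docs_per_user_mean: float = 5.0
    sentences_per_doc_mean: float = 6.0
    pair_truths: list[PairGroundTruth] = field(default_factory=list)
    combo_truths: list[ComboGroundTruth] = field(default_factory=list)
    distance_distribution: tuple[float, float, float, float] = (0.2, 0.35, 0.25, 0.2)
    conflict_rate: float = 0.05
    third_person_rate: float = 0.1
    prob_post: float = 0.12  # remaining documents are comments

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if abs(sum(self.distance_distribution) - 1.0) > 1e-9:
            raise ValueError("distance_distribution must sum to 1")
        for name in ("conflict_rate", "third_person_rate", "prob_post"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_users < 0:
            raise ValueError("n_users must be nonnegative")


def default_pair_truths() -> list[PairGroundTruth]:
    """Desk-scale ground truth echoing the kinds of combinations the method
    targets: clearly improving, clearly worsening and mixed pairs."""
    return [
        PairGroundTruth("metformin", "menstrual_irregularities", 0.25, 0.60, 0.05),
        PairGroundTruth("spironolactone", "menstrual_irregularities", 0.10, 0.45, 0.15),
        PairGroundTruth("inositol", "anxiety", 0.15, 0.55, 0.10),
        PairGroundTruth("inositol", "mood_issues", 0.10, 0.50, 0.05),
        PairGroundTruth("cocp", "depression", 0.12, 0.05, 0.60),
        PairGroundTruth("dieting", "body_weight", 0.20, 0.60, 0.12),
        PairGroundTruth("intermittent_fasting", "body_weight", 0.10, 0.65, 0.02),
        PairGroundTruth("exercise", "cravings", 0.08, 0.50, 0.05),
        PairGroundTruth("metformin", "irritated_bowel", 0.20, 0.05, 0.55),
    ]


def default_combo_truths() -> list[ComboGroundTruth]:
    return [
        ComboGroundTruth("metformin", "spironolactone", 0.20),
        ComboGroundTruth("metformin", "exercise", 0.12),
        ComboGroundTruth("inositol", "metformin", 0.08),
        ComboGroundTruth("inositol", "vitamin_d", 0.06),
        ComboGroundTruth("low_carb_diet", "exercise", 0.05),
    ]


def default_config(seed: int, **overrides) -> GeneratorConfig:
    """The default study conditions: 1,000 users, ~5 documents each."""
    cfg = GeneratorConfig(
        seed=seed,
        pair_truths=default_pair_truths(),
        combo_truths=default_combo_truths(),
    )
    return replace(cfg, **overrides) if overrides else cfg


def _filler_sentence(rng: np.random.Generator) -> str:
    k = int(rng.integers(4, 9))
    words = [FILLER_VOCABULARY[int(i)] for i in rng.integers(0, len(FILLER_VOCABULARY), k)]
    return (" ".join(words)).capitalize() + "."


def _filler_words(rng: np.random.Generator, k: int) -> list[str]:
    return [FILLER_VOCABULARY[int(i)] for i in rng.integers(0, len(FILLER_VOCABULARY), k)]


def _pick(rng: np.random.Generator, seq: Sequence[str]) -> str:
    return seq[int(rng.integers(0, len(seq)))]


def embed_mention(
    feature: FeatureDef,
    sentiment: SentimentLabel,
    first_person: bool,
    catalog: Catalog,
    rng: np.random.Generator,
) -> str:
    """Build one sentence containing exactly one synonym of ``feature`` and,
    when the sentiment is not neutral, exactly one matching cue word.

    Third-person sentences open with a configured third-person marker phrase
    so the first-person filter can identify them.
    """
    words: list[str] = []
    if not first_person:
        words.append(_pick(rng, catalog.third_person_markers))
    words += _filler_words(rng, int(rng.integers(1, 3)))
    words.append(_pick(rng, feature.synonyms))
    if sentiment is not SentimentLabel.NEUTRAL:
        words.append(_pick(rng, catalog.cue_lexicons[sentiment.value]))
    words += _filler_words(rng, int(rng.integers(1, 4)))
    text = " ".join(words)
    if first_person:
        text = text.capitalize()
    return text + "."


def _dual_mention_sentence(
    feat_a: FeatureDef,
    sent_a: SentimentLabel,
    feat_b: FeatureDef,
    sent_b: SentimentLabel,
    first_person: bool,
    catalog: Catalog,
    rng: np.random.Generator,
) -> str:
    """One sentence mentioning two features (gap 0), each cue placed directly
    after its own synonym so nearest-cue tagging resolves unambiguously."""
    words: list[str] = []
    if not first_person:
        words.append(_pick(rng, catalog.third_person_markers))
    words += _filler_words(rng, 1)
    words.append(_pick(rng, feat_a.synonyms))
    if sent_a is not SentimentLabel.NEUTRAL:
        words.append(_pick(rng, catalog.cue_lexicons[sent_a.value]))
    words += _filler_words(rng, int(rng.integers(2, 4)))
    words.append(_pick(rng, feat_b.synonyms))
    if sent_b is not SentimentLabel.NEUTRAL:
        words.append(_pick(rng, catalog.cue_lexicons[sent_b.value]))
    words += _filler_words(rng, 1)
    text = " ".join(words)
    if first_person:
        text = text.capitalize()
    return text + "."


class _DocBuilder:
    __slots__ = ("doc_id", "user_id", "doc_type", "sentences", "has_mentions")

    def __init__(self, doc_id: str, user_id: str, doc_type: str):
        self.doc_id = doc_id
        self.user_id = user_id
        self.doc_type = doc_type
        self.sentences: list[str] = []
        self.has_mentions = False


def _sample_sentiments(
    truth: PairGroundTruth, config: GeneratorConfig, rng: np.random.Generator
) -> tuple[SentimentLabel, SentimentLabel]:
    if config.conflict_rate > 0 and rng.random() < config.conflict_rate:
        if rng.random() < 0.5:
            return SentimentLabel.IMPROVING, SentimentLabel.WORSENING
        return SentimentLabel.WORSENING, SentimentLabel.IMPROVING
    r = rng.random()
    if r < truth.p_improving:
        s = SentimentLabel.IMPROVING
    elif r < truth.p_improving + truth.p_worsening:
        s = SentimentLabel.WORSENING
    else:
        s = SentimentLabel.NEUTRAL
    return s, s


def generate_corpus(
    config: GeneratorConfig, catalog: Catalog | None = None
) -> tuple[Corpus, list[PairGroundTruth]]:
    """Generate a corpus under ``config`` and echo its ground truth.

    Identical seeds yield byte-identical corpora.  Every embedded mention is
    recorded in ``corpus.gold_mentions``; filler sentences contain no catalog
    surface forms.  Pairs referencing feature ids absent from the catalog
    raise ``ValueError``.
    """
    cat = catalog if catalog is not None else load_catalog()
    for t in config.pair_truths:
        for fid, kind in ((t.treatment_id, "treatment"), (t.symptom_id, "symptom")):
            if fid not in cat:
                raise ValueError(f"pair ground truth references unknown feature {fid!r}")
        if cat.kind_of(t.treatment_id).value != "treatment":
            raise ValueError(f"{t.treatment_id!r} is not a treatment")
        if cat.kind_of(t.symptom_id).value != "symptom":
            raise ValueError(f"{t.symptom_id!r} is not a symptom")
    for c in config.combo_truths:
        for fid in (c.treatment_a, c.treatment_b):
            if fid not in cat or cat.kind_of(fid).value != "treatment":
                raise ValueError(f"combo ground truth references non-treatment {fid!r}")

    rng = np.random.default_rng(config.seed)
    gap_probs = np.asarray(config.distance_distribution, dtype=float)

    documents: list[Document] = []
    mentions: list[FeatureMention] = []

    for u in range(config.n_users):
        user_id = f"u{u:05d}"
        n_docs = 1 + int(rng.poisson(max(config.docs_per_user_mean - 1.0, 0.0)))
        builders: list[_DocBuilder] = []
        for k in range(n_docs):
            doc_type = "post" if rng.random() < config.prob_post else "comment"
            b = _DocBuilder(f"{user_id}_d{k:02d}", user_id, doc_type)
            n_base = 1 + int(rng.poisson(max(config.sentences_per_doc_mean - 1.0, 0.0)))
            b.sentences = [_filler_sentence(rng) for _ in range(n_base)]
            builders.append(b)

        def _emit_block(
            feat_a: FeatureDef,
            sent_a: SentimentLabel,
            feat_b: FeatureDef,
            sent_b: SentimentLabel,
        ) -> None:
            """Append a two-mention block at a sampled sentence gap."""
            gap = int(_GAPS[int(rng.choice(4, p=gap_probs))])
            b = builders[int(rng.integers(0, len(builders)))]
            if b.has_mentions:
                # Keep distinct blocks out of each other's pairing window.
                b.sentences.extend(_filler_sentence(rng) for _ in range(3))
            if rng.random() < 0.5:  # randomise which feature comes first
                feat_a, sent_a, feat_b, sent_b = feat_b, sent_b, feat_a, sent_a
            if gap == 0:
                fp = rng.random() >= config.third_person_rate
                idx = len(b.sentences)
                b.sentences.append(
                    _dual_mention_sentence(feat_a, sent_a, feat_b, sent_b, fp, cat, rng)
                )
                for feat, sent in ((feat_a, sent_a), (feat_b, sent_b)):
                    mentions.append(
                        FeatureMention(b.doc_id, idx, feat.feature_id, user_id, sent, fp)
                    )
            else:
                fp_a = rng.random() >= config.third_person_rate
                idx_a = len(b.sentences)
                b.sentences.append(embed_mention(feat_a, sent_a, fp_a, cat, rng))
                b.sentences.extend(_filler_sentence(rng) for _ in range(gap - 1))
                fp_b = rng.random() >= config.third_person_rate
                idx_b = len(b.sentences)
                b.sentences.append(embed_mention(feat_b, sent_b, fp_b, cat, rng))
                mentions.append(
                    FeatureMention(b.doc_id, idx_a, feat_a.feature_id, user_id, sent_a, fp_a)
                )
                mentions.append(
                    FeatureMention(b.doc_id, idx_b, feat_b.feature_id, user_id, sent_b, fp_b)
                )
            b.has_mentions = True

        for truth in config.pair_truths:
            if rng.random() >= truth.p_comention:
                continue
            s_t, s_s = _sample_sentiments(truth, config, rng)
            _emit_block(cat[truth.treatment_id], s_t, cat[truth.symptom_id], s_s)

        for combo in config.combo_truths:
            if rng.random() >= combo.p_comention:
                continue
            _emit_block(
                cat[combo.treatment_a],
                SentimentLabel.NEUTRAL,
                cat[combo.treatment_b],
                SentimentLabel.NEUTRAL,
            )

        documents.extend(
            Document(b.doc_id, b.user_id, b.doc_type, tuple(b.sentences))
            for b in builders
        )

    corpus = Corpus(documents=documents, catalog=cat, gold_mentions=mentions)
    return corpus, list(config.pair_truths)
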