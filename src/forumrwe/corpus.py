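"""Domain types and I/O for forum corpora and feature catalogs.

A *corpus* is a set of forum documents (posts and comments), each carrying an
ordered list of pre-split sentences, optionally annotated with gold-standard
feature mentions.  A *catalog* describes the features of interest — treatments
and symptoms — with their surface-form lexicons, category grouping and, for
symptoms, a short account of what each sentiment label means for that
condition.  Sentence segmentation is deliberately upstream of this package:
documents arrive with sentences already split, which makes the two-sentence
co-mention window deterministic.

File formats are plain text: documents as JSON-lines (one document per line,
gold mentions embedded) and the catalog as a single JSON file, UTF-8
throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

__all__ = [
    "SentimentLabel",
    "FeatureKind",
    "FeatureDef",
    "Document",
    "FeatureMention",
    "Catalog",
    "Corpus",
    "CatalogViolation",
    "CorpusParseError",
    "CorpusValidationError",
    "load_catalog",
    "write_catalog",
    "validate_catalog",
    "read_corpus",
    "write_corpus",
]

TREATMENT_CATEGORIES = ("prescribed", "contraceptive", "lifestyle", "supplement")
CATEGORIES = TREATMENT_CATEGORIES + ("none",)


class SentimentLabel(str, Enum):
    """Perceived direction of a feature mention: improving, worsening or neutral."""

    IMPROVING = "improving"
    WORSENING = "worsening"
    NEUTRAL = "neutral"


class FeatureKind(str, Enum):
    TREATMENT = "treatment"
    SYMPTOM = "symptom"


class CorpusParseError(ValueError):
    """A corpus or catalog file could not be parsed; names the offending line."""


class CorpusValidationError(ValueError):
    """A structurally valid file violated a corpus invariant."""


@dataclass(frozen=True)
class FeatureDef:
    """One catalog entry: a treatment or symptom and its surface forms.

    Parameters
    ----------
    feature_id
        Stable token identifying the feature; unique within a catalog.
    kind
        Whether the feature is a treatment or a symptom.
    display_name
        Human-readable name used in reports.
    category
        One of ``prescribed | contraceptive | lifestyle | supplement`` for
        treatments; ``none`` for symptoms.
    synonyms
        Surface forms recognised for this feature (matched case-insensitively
        at word boundaries).
    sentiment_semantics
        For symptoms, a mapping ``{"neutral": ..., "improving": ...,
        "worsening": ...}`` describing what each sentiment label means for
        this condition; ``None`` for treatments.
    """

    feature_id: str
    kind: FeatureKind
    display_name: str
    category: str
    synonyms: tuple[str, ...]
    sentiment_semantics: dict[str, str] | None = None

    def to_dict(self) -> dict:
        d = {
            "feature_id": self.feature_id,
            "kind": self.kind.value,
            "display_name": self.display_name,
            "category": self.category,
            "synonyms": list(self.synonyms),
        }
        if self.sentiment_semantics is not None:
            d["sentiment_semantics"] = dict(self.sentiment_semantics)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureDef":
        return cls(
            feature_id=d["feature_id"],
            kind=FeatureKind(d["kind"]),
            display_name=d.get("display_name", d["feature_id"]),
            category=d.get("category", "none"),
            synonyms=tuple(d.get("synonyms", ())),
            sentiment_semantics=d.get("sentiment_semantics"),
        )


@dataclass(frozen=True)
class Document:
    """One forum post or comment with pre-split sentences."""

    doc_id: str
    user_id: str
    doc_type: str  # "post" | "comment"
    sentences: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.doc_type not in ("post", "comment"):
            raise CorpusValidationError(
                f"document {self.doc_id!r}: doc_type must be 'post' or 'comment', "
                f"got {self.doc_type!r}"
            )
        if not self.sentences or any(not s for s in self.sentences):
            raise CorpusValidationError(
                f"document {self.doc_id!r}: sentences must be a non-empty list of "
                "non-empty strings"
            )


@dataclass(frozen=True, order=True)
class FeatureMention:
    """One labelled occurrence of a feature in a sentence.

    ``sentence_index`` is 0-based into the owning document's sentence list.
    ``first_person`` is False when the sentence reports someone else's
    experience (and such mentions are dropped before any analysis).
    """

    doc_id: str
    sentence_index: int
    feature_id: str
    user_id: str
    sentiment: SentimentLabel
    first_person: bool = True

    def to_dict(self) -> dict:
        return {
            "sentence_index": self.sentence_index,
            "feature_id": self.feature_id,
            "sentiment": self.sentiment.value,
            "first_person": self.first_person,
        }


@dataclass(frozen=True)
class CatalogViolation:
    feature_id: str
    rule: str
    message: str


@dataclass
class Catalog:
    """A feature catalog plus the sentiment-cue and third-person lexicons."""

    features: list[FeatureDef]
    cue_lexicons: dict[str, list[str]] = field(default_factory=dict)
    third_person_markers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_id = {f.feature_id: f for f in self.features}

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._by_id

    def __getitem__(self, feature_id: str) -> FeatureDef:
        return self._by_id[feature_id]

    def __iter__(self):
        return iter(self.features)

    def kind_of(self, feature_id: str) -> FeatureKind:
        return self._by_id[feature_id].kind

    @property
    def treatments(self) -> list[FeatureDef]:
        return [f for f in self.features if f.kind is FeatureKind.TREATMENT]

    @property
    def symptoms(self) -> list[FeatureDef]:
        return [f for f in self.features if f.kind is FeatureKind.SYMPTOM]

    def to_dict(self) -> dict:
        return {
            "features": [f.to_dict() for f in self.features],
            "cue_lexicons": {k: list(v) for k, v in self.cue_lexicons.items()},
            "third_person_markers": list(self.third_person_markers),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Catalog":
        return cls(
            features=[FeatureDef.from_dict(x) for x in d["features"]],
            cue_lexicons={k: list(v) for k, v in d.get("cue_lexicons", {}).items()},
            third_person_markers=list(d.get("third_person_markers", [])),
        )


CatalogLike = Union[Catalog, str, Path, None]


def _coerce_catalog(catalog: CatalogLike) -> Catalog:
    if catalog is None:
        return load_catalog()
    if isinstance(catalog, Catalog):
        return catalog
    return load_catalog(catalog)


def load_catalog(path: str | Path | None = None) -> Catalog:
    """Load a catalog JSON file; with no argument, the packaged default catalog.

    The default catalog covers the treatments and conditions reported in the
    study this package operationalises (four treatment categories —
    prescribed, contraceptive, lifestyle, supplement — and twenty symptom
    labels with their sentiment semantics).
    """
    if path is None:
        text = (
            resources.files("forumrwe").joinpath("data/default_catalog.json").read_text("utf-8")
        )
    else:
        text = Path(path).read_text("utf-8")
    try:
        d = json.loads(text)
    except json.JSONDecodeError as exc:
        raise CorpusParseError(f"catalog {path}: line {exc.lineno}: {exc.msg}") from exc
    return Catalog.from_dict(d)


def write_catalog(catalog: Catalog, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(
        json.dumps(catalog.to_dict(), indent=1, ensure_ascii=False, sort_keys=True) + "\n",
        "utf-8",
    )
    return path


import re as _re


def _word_pattern(phrase: str) -> "_re.Pattern[str]":
    return _re.compile(r"(?<!\w)" + _re.escape(phrase.lower()) + r"(?!\w)")


def validate_catalog(catalog: Catalog | Iterable[FeatureDef]) -> list[CatalogViolation]:
    """Check catalog invariants; violations are returned as data, never raised.

    Rules: unique ``feature_id``; treatments carry a real treatment category;
    symptoms carry category ``none``; every feature has at least one synonym;
    and no feature's synonym occurs at word boundaries inside another
    feature's synonym (cross-feature collisions would make surface matching
    ambiguous).
    """
    features = list(catalog.features if isinstance(catalog, Catalog) else catalog)
    violations: list[CatalogViolation] = []
    seen: set[str] = set()
    for f in features:
        if f.feature_id in seen:
            violations.append(
                CatalogViolation(f.feature_id, "unique-id", "duplicate feature_id")
            )
        seen.add(f.feature_id)
        if f.kind is FeatureKind.TREATMENT and f.category not in TREATMENT_CATEGORIES:
            violations.append(
                CatalogViolation(
                    f.feature_id,
                    "treatment-category",
                    f"treatment category must be one of {TREATMENT_CATEGORIES}, "
                    f"got {f.category!r}",
                )
            )
        if f.kind is FeatureKind.SYMPTOM and f.category != "none":
            violations.append(
                CatalogViolation(
                    f.feature_id,
                    "symptom-category",
                    f"symptoms carry category 'none', got {f.category!r}",
                )
            )
        if not f.synonyms:
            violations.append(
                CatalogViolation(f.feature_id, "nonempty-synonyms", "no synonyms")
            )
    for f in features:
        for syn in f.synonyms:
            pat = _word_pattern(syn)
            for g in features:
                if g.feature_id == f.feature_id:
                    continue
                for other in g.synonyms:
                    if pat.search(other.lower()):
                        violations.append(
                            CatalogViolation(
                                g.feature_id,
                                "synonym-collision",
                                f"synonym {other!r} contains {f.feature_id!r} "
                                f"synonym {syn!r}",
                            )
                        )
    return violations


@dataclass
class Corpus:
    """Documents + catalog + optional gold mention annotations.

    Gold mentions, when present, are kept sorted by
    ``(doc_id, sentence_index, feature_id)`` and must resolve against the
    documents and the catalog.
    """

    documents: list[Document]
    catalog: Catalog
    gold_mentions: list[FeatureMention] | None = None

    def __post_init__(self) -> None:
        if self.gold_mentions is not None:
            self.gold_mentions = sorted(
                self.gold_mentions,
                key=lambda m: (m.doc_id, m.sentence_index, m.feature_id),
            )
        self.validate()

    def validate(self) -> None:
        by_id: dict[str, Document] = {}
        for doc in self.documents:
            if doc.doc_id in by_id:
                raise CorpusValidationError(f"duplicate doc_id {doc.doc_id!r}")
            by_id[doc.doc_id] = doc
        for m in self.gold_mentions or ():
            doc = by_id.get(m.doc_id)
            if doc is None:
                raise CorpusValidationError(
                    f"mention references unknown doc_id {m.doc_id!r}"
                )
            if m.user_id != doc.user_id:
                raise CorpusValidationError(
                    f"mention in {m.doc_id!r} carries user {m.user_id!r} but the "
                    f"document belongs to {doc.user_id!r}"
                )
            if not (0 <= m.sentence_index < len(doc.sentences)):
                raise CorpusValidationError(
                    f"mention in {m.doc_id!r}: sentence_index {m.sentence_index} "
                    f"out of range (document has {len(doc.sentences)} sentences)"
                )
            if m.feature_id not in self.catalog:
                raise CorpusValidationError(
                    f"mention in {m.doc_id!r}: feature_id {m.feature_id!r} not in catalog"
                )

    def mentions_by_doc(self) -> dict[str, list[FeatureMention]]:
        out: dict[str, list[FeatureMention]] = {d.doc_id: [] for d in self.documents}
        for m in self.gold_mentions or ():
            out[m.doc_id].append(m)
        return out


def read_corpus(path: str | Path, catalog: CatalogLike = None) -> Corpus:
    """Read a JSON-lines corpus file, validating it against ``catalog``.

    Each line holds one document object with fields ``doc_id``, ``user_id``,
    ``doc_type``, ``sentences`` and, optionally, ``gold_mentions``.  An empty
    file yields an empty corpus.  Malformed lines raise
    :class:`CorpusParseError` naming the line number; invariant violations
    raise :class:`CorpusValidationError`.
    """
    cat = _coerce_catalog(catalog)
    documents: list[Document] = []
    mentions: list[FeatureMention] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusParseError(f"{path}: line {lineno}: {exc.msg}") from exc
            try:
                doc = Document(
                    doc_id=rec["doc_id"],
                    user_id=rec["user_id"],
                    doc_type=rec.get("doc_type", "post"),
                    sentences=tuple(rec["sentences"]),
                )
            except KeyError as exc:
                raise CorpusParseError(
                    f"{path}: line {lineno}: missing field {exc.args[0]!r}"
                ) from exc
            documents.append(doc)
            for md in rec.get("gold_mentions", ()):
                mentions.append(
                    FeatureMention(
                        doc_id=doc.doc_id,
                        user_id=doc.user_id,
                        sentence_index=int(md["sentence_index"]),
                        feature_id=md["feature_id"],
                        sentiment=SentimentLabel(md["sentiment"]),
                        first_person=bool(md.get("first_person", True)),
                    )
                )
    return Corpus(documents=documents, catalog=cat, gold_mentions=mentions or None)


def write_corpus(corpus: Corpus, path: str | Path) -> Path:
    """Write a corpus as JSON-lines; round-trips through :func:`read_corpus`."""
    path = Path(path)
    by_doc = corpus.mentions_by_doc() if corpus.gold_mentions is not None else None
    with open(path, "w", encoding="utf-8") as fh:
        for doc in corpus.documents:
            rec: dict = {
                "doc_id": doc.doc_id,
                "user_id": doc.user_id,
                "doc_type": doc.doc_type,
                "sentences": list(doc.sentences),
            }
            if by_doc is not None:
                rec["gold_mentions"] = [
                    m.to_dict()
                    for m in sorted(
                        by_doc[doc.doc_id],
                        key=lambda m: (m.sentence_index, m.feature_id),
                    )
                ]
            fh.write(json.dumps(rec, ensure_ascii=False, sort_keys=True) + "\n")
    return path
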