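from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st

from forumrwe import (
    FeatureKind,
    FeatureMention,
    PairInstance,
    Resolution,
    SentimentLabel,
    UserVerdict,
    Verdict,
    aggregate_user_verdicts,
    find_comentions,
    load_catalog,
    resolve_sentiment,
    treatment_combinations,
)
from forumrwe.pairing import extract_pair_instances, instance_verdicts

CATALOG = load_catalog()
_FEATURES = [f.feature_id for f in CATALOG.features]

I, W, N = SentimentLabel.IMPROVING, SentimentLabel.WORSENING, SentimentLabel.NEUTRAL


def _mention(idx, feature_id, sentiment=N, doc="d", user="u"):
    return FeatureMention(doc, idx, feature_id, user, sentiment, True)


mention_lists = st.lists(
    st.builds(
        _mention,
        idx=st.integers(min_value=0, max_value=10),
        feature_id=st.sampled_from(_FEATURES),
        sentiment=st.sampled_from(list(SentimentLabel)),
    ),
    max_size=30,
)


def brute_force_comentions(mentions, window):
    out = []
    for t in mentions:
        for s in mentions:
            if (
                CATALOG.kind_of(t.feature_id) is FeatureKind.TREATMENT
                and CATALOG.kind_of(s.feature_id) is FeatureKind.SYMPTOM
                and abs(t.sentence_index - s.sentence_index) <= window
            ):
                out.append((t, s, abs(t.sentence_index - s.sentence_index)))
    return out


def brute_force_combinations(mentions, window):
    out = []
    n = len(mentions)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = mentions[i], mentions[j]
            if (
                CATALOG.kind_of(a.feature_id) is FeatureKind.TREATMENT
                and CATALOG.kind_of(b.feature_id) is FeatureKind.TREATMENT
                and a.feature_id != b.feature_id
                and abs(a.sentence_index - b.sentence_index) <= window
            ):
                out.append((a.user_id,) + tuple(sorted((a.feature_id, b.feature_id))))
    return out


def test_window_boundary():
    t = _mention(0, "metformin", I)
    near = _mention(2, "acne", I)
    far = _mention(3, "acne", I)
    (pair,) = find_comentions([t, near], CATALOG)
    assert pair[2] == 2
    assert find_comentions([t, far], CATALOG) == []


def test_same_sentence_counts_as_gap_zero():
    pairs = find_comentions([_mention(4, "inositol", I), _mention(4, "anxiety", I)], CATALOG)
    assert [p[2] for p in pairs] == [0]


def test_mixed_documents_rejected():
    with pytest.raises(ValueError, match="multiple documents"):
        find_comentions([_mention(0, "acne", doc="a"), _mention(0, "acne", doc="b")], CATALOG)
    with pytest.raises(ValueError, match="multiple documents"):
        treatment_combinations(
            [_mention(0, "metformin", doc="a"), _mention(0, "exercise", doc="b")], CATALOG
        )


@settings(max_examples=150, derandomize=True)
@given(mention_lists)
def test_comentions_match_brute_force(mentions):
    got = find_comentions(mentions, CATALOG)
    expected = brute_force_comentions(mentions, 2)
    assert Counter((id(t), id(s), g) for t, s, g in got) == Counter(
        (id(t), id(s), g) for t, s, g in expected
    )


@settings(max_examples=150, derandomize=True)
@given(mention_lists)
def test_combinations_match_brute_force(mentions):
    assert Counter(treatment_combinations(mentions, CATALOG)) == Counter(
        brute_force_combinations(mentions, 2)
    )


@settings(max_examples=60, derandomize=True)
@given(mention_lists, st.integers(min_value=0, max_value=9))
def test_window_monotonicity(mentions, window):
    smaller = {(id(t), id(s)) for t, s, _ in find_comentions(mentions, CATALOG, window)}
    larger = {(id(t), id(s)) for t, s, _ in find_comentions(mentions, CATALOG, window + 1)}
    assert smaller <= larger


def test_self_pairs_excluded():
    ms = [_mention(0, "metformin"), _mention(1, "metformin")]
    assert treatment_combinations(ms, CATALOG) == []


def test_resolution_table_exhaustive():
    expected = {
        (I, I): Resolution.IMPROVED,
        (W, W): Resolution.WORSENED,
        (I, W): Resolution.ABANDONED,
        (W, I): Resolution.ABANDONED,
        (I, N): Resolution.IMPROVED,
        (W, N): Resolution.WORSENED,
        (N, I): Resolution.IMPROVED,
        (N, W): Resolution.WORSENED,
        (N, N): Resolution.NEUTRAL,
    }
    for t in SentimentLabel:
        for s in SentimentLabel:
            assert resolve_sentiment(t, s) is expected[(t, s)]


def test_abandonment_iff_contradictory():
    for t in SentimentLabel:
        for s in SentimentLabel:
            abandoned = resolve_sentiment(t, s) is Resolution.ABANDONED
            assert abandoned == ({t, s} == {I, W})


def _instance(user, resolved, doc="d", t="metformin", s="acne"):
    return PairInstance(user, t, s, resolved, doc, 1)


def test_aggregate_single_instance_verdicts():
    (v,) = aggregate_user_verdicts([_instance("u", Resolution.IMPROVED)])
    assert v.verdict is Verdict.IMPROVED
    (v,) = aggregate_user_verdicts([_instance("u", Resolution.NEUTRAL)] * 5)
    assert v.verdict is Verdict.NEUTRAL


def test_aggregate_contradictory_user_excluded():
    (v,) = aggregate_user_verdicts(
        [_instance("u", Resolution.IMPROVED, doc="d1"),
         _instance("u", Resolution.WORSENED, doc="d2")]
    )
    assert v.verdict is Verdict.EXCLUDED


def test_aggregate_abandoned_discarded():
    (v,) = aggregate_user_verdicts(
        [_instance("u", Resolution.ABANDONED), _instance("u", Resolution.WORSENED)]
    )
    assert v.verdict is Verdict.WORSENED
    assert aggregate_user_verdicts([_instance("u", Resolution.ABANDONED)]) == []


def test_aggregate_direction_beats_neutral():
    (v,) = aggregate_user_verdicts(
        [_instance("u", Resolution.NEUTRAL), _instance("u", Resolution.IMPROVED)]
    )
    assert v.verdict is Verdict.IMPROVED


def test_instances_partition_without_loss(small_corpus):
    """Every in-window co-mention becomes exactly one instance of one class."""
    corpus, _ = small_corpus
    instances = extract_pair_instances(corpus.gold_mentions, corpus.catalog)
    by_class = Counter(i.resolved for i in instances)
    assert sum(by_class.values()) == len(instances)
    assert set(by_class) <= set(Resolution)
    # and per-document pairing equals the brute force on that document
    by_doc = {}
    for m in corpus.gold_mentions:
        by_doc.setdefault(m.doc_id, []).append(m)
    n_pairs = sum(len(brute_force_comentions(ms, 2)) for ms in by_doc.values())
    assert n_pairs == len(instances)


def test_instance_level_mode_counts_every_instance():
    instances = [
        _instance("u", Resolution.IMPROVED, doc="d1"),
        _instance("u", Resolution.IMPROVED, doc="d2"),
        _instance("u", Resolution.ABANDONED, doc="d3"),
    ]
    assert len(aggregate_user_verdicts(instances)) == 1
    ivs = instance_verdicts(instances)
    assert len(ivs) == 2
    assert all(v.verdict is Verdict.IMPROVED for v in ivs)
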