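import pytest

from forumrwe import (
    Corpus,
    Document,
    FeatureMention,
    SentimentLabel,
    default_config,
    generate_corpus,
    load_catalog,
)


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def small_corpus(catalog):
    """A 200-user corpus under the default study conditions."""
    corpus, truths = generate_corpus(default_config(123, n_users=200), catalog)
    return corpus, truths


@pytest.fixture()
def tiny_corpus(catalog):
    """Three hand-written documents with gold mentions."""
    docs = [
        Document("d1", "alice", "post",
                 ("I started metformin and it helped.",
                  "Honestly sharing an update.",
                  "My irregular periods improved a lot.")),
        Document("d2", "bob", "comment",
                 ("Thinking about spironolactone.",)),
        Document("d3", "carol", "comment",
                 ("My sister said inositol helped her anxiety.",
                  "Café-style journaling notes — über useful.")),
    ]
    mentions = [
        FeatureMention("d1", 0, "metformin", "alice", SentimentLabel.IMPROVING, True),
        FeatureMention("d1", 2, "menstrual_irregularities", "alice", SentimentLabel.IMPROVING, True),
        FeatureMention("d2", 0, "spironolactone", "bob", SentimentLabel.NEUTRAL, True),
        FeatureMention("d3", 0, "inositol", "carol", SentimentLabel.IMPROVING, False),
        FeatureMention("d3", 0, "anxiety", "carol", SentimentLabel.IMPROVING, False),
    ]
    return Corpus(documents=docs, catalog=catalog, gold_mentions=mentions)
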