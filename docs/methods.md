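# Methods

This note documents the analysis model, the synthetic-data model, the
numerical choices and the known limitations of `forumrwe`.

## The association model

The package estimates *perceived* treatment effects from forum text under one
central proximity assumption: when a treatment feature and a symptom feature
are mentioned within `window = 2` sentences of each other in one document,
they are being discussed in relation to each other. The window is an absolute
0-based sentence-index difference, so the same sentence is distance 0 and the
window never spans documents. Pairing is non-exclusive: a mention may
participate in several pairs, since no competition rule is defensible from
proximity alone.

Each co-mention resolves through the 3×3 sentiment table (see
`forumrwe.pairing`): agreement keeps the shared direction, a neutral label
defers to the directional one, two neutrals stay neutral, and the two
contradictory cells *abandon* the assumption — a contradiction is read as
evidence the two features were not being discussed in relation to each other,
not as a mixed outcome.

**Counting unit.** The default counts users, not raw instances: instances are
collapsed to at most one verdict per (user, treatment, symptom). A user whose
surviving instances point both ways is excluded from that combination — the
mention-level abandonment logic lifted to the user level — and a user whose
instances were all abandoned contributes nothing (abandonment means no
assumption was made, so no neutral verdict is invented). Counting every
instance instead is a supported variant (`count_unit="instance"`); it changes
the interpretation of `n` from "users discussing" to "discussions", and the
user-level reading was chosen as the default because the inclusion rule is
phrased in users.

**Statistics.** For a combination with `n_I` improving and `n_W` worsening
users, `RR = n_I/n_W` and the 95% CI is
`exp[ln(RR) ± z·sqrt(1/n_I + 1/n_W − 2/(n_I+n_W))]` with `z = 1.9599` — the
constant is deliberately the 4-decimal value used in the source analysis
rather than 1.959964, because the published intervals reproduce exactly under
it. One-sided combinations (`n_W = 0` → `RR = inf`; `n_I = 0` → `RR = 0`)
have no defined interval: they are reported without a CI and can never be
flagged significant. Both inclusion thresholds are strict: a combination
needs `n > 20` directional users, a treatment needs `> 100` commenting users
to enter the overall sentiment table (symptoms are unrestricted). No
multiple-comparison correction is applied, by design: the analysis is
exploratory, and individual rows should not be read in isolation.

A useful non-obvious fact, encoded as a property test: the CI's log-width is
*not* monotone in each count separately — growing only the dominant count can
widen the interval, because the variance term `1/n_I + 1/n_W − 2/(n_I+n_W)`
is governed by the smaller count. Width does shrink strictly when both counts
grow, or when the scarcer side grows.

`invert_counts` exists for validation against printed tables: given a
2-decimal `RR` and `n`, it searches all integer splits for the unique one
that reprints the ratio (rounding half away from zero, the convention used
for all reported values), raising a listing error when the inversion is
ambiguous. Reported values are rounded to 2 decimals and compared at ±0.005.

## Tagging

Production deployments of this analysis use trained classifiers; the package
ships a transparent lexicon reference tagger instead and treats tagging as a
contract: any deterministic `(Document, Catalog) -> mentions` callable.
The reference rules: case-insensitive word-boundary synonym match (one
mention per sentence–feature pair, anchored at the earliest match); sentiment
from the nearest sentiment-cue word in the sentence, measured between
character spans, with ties between different labels — or no cue — yielding
neutral; and third-person detection by sentence-initial marker phrases from a
configurable list (a transparent rule was preferred over an opaque
heuristic). Mentions whose sentence reports someone else's experience are
removed before any pairing, so only self-reported experience is analysed.
Real-corpus tagging quality is a property of whatever tagger is plugged in;
`evaluate_tagger` reproduces the standard metric definitions (per-feature
precision/recall matched on (document, sentence, feature), sentiment accuracy
over matches) but the package makes no claim about classifier performance on
real text.

## The catalog

The shipped catalog holds the ~40 named features reconstructable from the
reported analysis — 22 treatments in four categories and 20 condition labels
with per-condition sentiment semantics (what "improving" means for, say,
amenorrhea is "cycles returning"). The full label sets of the original
dataset (157 treatments, 75 symptoms) were never published, so users with
richer lexicons should extend the catalog JSON. `validate_catalog` enforces,
beyond the structural rules, a cross-feature synonym-collision rule (no
synonym may occur at word boundaries inside another feature's synonym), which
keeps surface matching unambiguous.

## The synthetic forum

The generator emulates the *statistical* structure the pipeline consumes, not
forum language. Per user: a 1 + Poisson number of documents (mean 5), each
with 1 + Poisson base filler sentences (mean 6); per configured
treatment–symptom pair, one co-mention with probability `p_comention`, its
sentiment improving/worsening/neutral with probabilities
(`p_improving`, `p_worsening`, remainder), both mentions carrying that
sentiment — or, with probability `conflict_rate`, contradictory sentiments;
a sentence gap drawn from a distribution over {0, 1, 2, >2} (the >2 mass
exercises the window's exclusion branch); and treatment–treatment co-mention
blocks (neutral sentiment) for the combination network. Mention sentences are
third-person with probability `third_person_rate`.

Default study conditions: 1,000 users, ~5 documents/user — a deliberate
~1:100 scale-down of the ~100,000-user corpus the method was designed for —
with gap distribution (0.2, 0.35, 0.25, 0.2), `conflict_rate = 0.05`,
`third_person_rate = 0.1`, and nine ground-truth pairs spanning strong
improvement, strong worsening and mixed perception, plus five
treatment-combination pairs with metformin–spironolactone the most frequent.
The gap and volume parameters are engineering choices (no distributional
facts about real sentence gaps or posting volume are available), picked once
to look like short multi-topic forum writing.

Construction guarantees worth knowing when reading tests:

* Filler vocabulary is disjoint from every synonym and cue, and mention
  blocks within one document are separated by three filler sentences, so the
  lexicon tagger recovers the gold annotations *exactly* and per-pair counts
  are exactly binomial — tagging noise is eliminated by design, isolating
  pairing/statistics behaviour.
* Gap-0 sentences place each cue directly after its own synonym with filler
  between the two features, so nearest-cue assignment is unambiguous.
* Co-mention sentiments are emitted as matched pairs (both improving, both
  worsening, both neutral, or a contradiction); the mixed
  neutral/directional cells of the resolution table are exercised by unit
  tests rather than by generated corpora, which keeps gold labels identical
  to what lexicon semantics imply in shared sentences.

Consequently, passing tests demonstrate the pipeline's correctness and its
statistical calibration under the generative model; they say nothing about
tagging quality, segmentation quality or sentiment nuance in real forum
text.

**Parameter recovery.** With contradictions off and all gaps in-window, each
pair's estimated `log RR` is required to fall within 3 CI standard errors of
`log(p_improving/p_worsening)` for ≥95% of pair×seed checks (20 seeds ×
1,000 users; third-person thinning removes mentions symmetrically and leaves
the ratio unbiased). Desk-scale sizes keep the full suite under a minute.

## Numerical and I/O choices

* Rounding is half-away-from-zero via `decimal`, matching how results tables
  are conventionally printed; float repr is used as the decimal source.
* All randomness flows from one `numpy` `default_rng(seed)`; identical seeds
  give byte-identical corpora, and report rendering sorts rows and rebuilds
  the graph with sorted insertion so GraphML/CSV outputs are byte-stable.
* Corpora are JSON-lines (one document per line, gold mentions embedded),
  catalogs JSON, tables CSV, the network GraphML + CSV; everything UTF-8.
  Sentence segmentation is upstream by design: documents carry pre-split
  sentences so the two-sentence window is deterministic and auditable.
* Posts and comments are carried as `doc_type` for auditability but treated
  identically everywhere downstream.
* Fig-3-style node size uses distinct users mentioning the treatment (the
  manifest records this choice); edge weight counts distinct co-mentioning
  users and is therefore bounded by the smaller endpoint count.

## Limitations

Proximity is not causation: the method can associate two ideas that merely
share a paragraph, and co-administered treatments can misattribute sentiment
— risks the abandonment rule and the strict window mitigate but cannot
remove. The RR is a perception ratio from self-selected posters with no
placebo control. The synthetic corpus deliberately omits real-language
phenomena (slang, typos, sarcasm, multi-feature sentences beyond pairs,
classifier error profiles), so recovery results bound pipeline error only,
not end-to-end error on real text.
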