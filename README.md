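# forumrwe

Treatment-outcome mining from patient-forum text.

Patient forums hold large volumes of first-person experience with treatments —
what helped, what made things worse — that never reaches clinical datasets.
`forumrwe` turns a corpus of forum posts and comments, annotated with
treatment/symptom *feature mentions* and improving/worsening/neutral sentiment,
into quantitative treatment-outcome perception summaries. The package was built
around a polycystic ovary syndrome (PCOS) forum use case (its default catalog
covers PCOS treatments across four categories — prescribed, contraceptive,
lifestyle, supplement — and twenty condition labels), but the machinery is
condition-agnostic: supply your own catalog and corpus.

## Method

1. **Co-mention pairing.** A treatment mention and a symptom mention occurring
   within two sentences of each other in one document are assumed to be
   discussed in relation to each other (the same sentence counts; the window is
   configurable).
2. **Sentiment resolution.** The pair's two sentiment labels resolve into an
   association instance — *improved*, *worsened* or *neutral*. Contradictory
   labels (one improving, one worsening) **abandon** the assumption; a neutral
   label defers to the directional one.
3. **User verdicts.** Instances are collapsed to at most one verdict per
   (user, treatment, symptom); users whose surviving instances point both ways
   are excluded from that combination. (Instance-level counting is available
   behind `count_unit="instance"`.)
4. **Statistics.** For each combination with `n_I` improving and `n_W`
   worsening users,

   ```
   RR = n_I / n_W
   CI = exp[ ln(RR) ± 1.9599 · sqrt(1/n_I + 1/n_W − 2/(n_I + n_W)) ]
   ```

   `RR = inf` when `n_W = 0` and `RR = 0` when `n_I = 0` (no CI in either
   case). Combinations need strictly more than 20 directional users to be
   included; a combination is significant when its CI excludes 1.0. This RR is
   a ratio of perception counts, not a cohort risk ratio, and no
   multiple-comparison correction is applied — the analysis is exploratory.
5. **Overview surfaces.** Per-feature improving/neutral/worsening sentiment
   ratios (treatments need more than 100 commenting users to enter the
   headline table) and a treatment-combination network whose edge weights
   count distinct users co-mentioning two treatments.

Mentions describing someone else's experience (third-person sentences) are
filtered out before any analysis. Tagging is pluggable: any deterministic
`(Document, Catalog) -> list[FeatureMention]` callable can replace the shipped
lexicon reference tagger, and `evaluate_tagger` scores a tagger against gold
annotations (per-feature precision/recall, sentiment accuracy).

Because real forum dumps cannot be redistributed, the package includes a
synthetic forum generator (`forumrwe.synthetic`) with known ground truth —
controlled co-mention probabilities, sentiment rates, sentence-gap
distribution, contradiction noise and third-person rate — so the whole
pipeline is testable end to end and parameter recovery can be demonstrated.

## Worked example

```python
import forumrwe as f

corpus, truths = f.generate_corpus(f.default_config(seed=7))
results = f.TreatmentOutcomeModel(corpus, use_gold_mentions=True).fit()
print(results.summary())
```

prints (1,000 synthetic users, 4,985 documents):

```
Treatment-outcome associations (included combinations)
window = 2 sentences, min users = 20 (strict), z = 1.9599, unit = user

treatment               symptom                     n_I  n_W    n       RR            95% CI  signif
----------------------------------------------------------------------------------------------------
exercise                cravings                     31    0   31      inf            --      no
intermittent_fasting    body_weight                  39    1   40    39.00     5.63-270.28    yes
metformin               menstrual_irregularities     93    5   98    18.60     7.91-43.74     yes
inositol                mood_issues                  31    2   33    15.50     4.03-59.55     yes
metformin               irritated_bowel               5   76   81     0.07     0.03-0.15      yes
cocp                    depression                    5   42   47     0.12     0.05-0.27      yes
spironolactone          menstrual_irregularities     35    6   41     5.83     2.76-12.35     yes
dieting                 body_weight                  78   16   94     4.88     3.09-7.69      yes
inositol                anxiety                      53   16   69     3.31     2.12-5.19      yes
```

Each row is one treatment→symptom combination: `n_I`/`n_W` are the users whose
verdict was improved/worsened, `RR` their ratio, and the 95% CI decides
significance (the all-improving `exercise → cravings` row has no CI, hence no
significance claim, matching how one-sided combinations are reported). The
generative ground truth behind, e.g., `metformin → menstrual_irregularities`
is `p_improving/p_worsening = 0.60/0.05 = 12`, inside the printed CI.

`results` also exposes `combinations_frame()`, `treatment_sentiments_frame()`,
`symptom_sentiments_frame()` and a `networkx` graph of treatment combinations.

The same pipeline runs from the shell:

```bash
forum-rwe generate --seed 7 --out corpus.jsonl
forum-rwe report --corpus corpus.jsonl --out report/ --gold
# or step by step: forum-rwe tag / pair / stats, or everything: forum-rwe run
```

writing `combos.csv`, `overall_treatments.csv`, `overall_symptoms.csv`,
`network_edges.csv`, `network.graphml` and a `manifest.json` echoing the run
configuration and row counts.

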