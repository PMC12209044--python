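"""Model/Results interface over the full analysis.

:class:`TreatmentOutcomeModel` is constructed from a corpus and the analysis
settings; :meth:`~TreatmentOutcomeModel.fit` runs tagging (or the corpus'
gold annotations), the first-person filter, co-mention pairing, user-verdict
aggregation, the risk-ratio statistics, the overall sentiment ratios and the
treatment-combination network, and returns a
:class:`TreatmentOutcomeResults` carrying every intermediate and final
surface with a ``summary()`` table.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable

import pandas as pd

from .corpus import Catalog, Corpus, FeatureMention
from .network import build_network, network_edges, treatment_user_counts
from .pairing import (
    DEFAULT_WINDOW,
    PairInstance,
    UserVerdict,
    aggregate_user_verdicts,
    extract_pair_instances,
    instance_verdicts,
    treatment_combinations,
)
from .stats import (
    DEFAULT_MIN_USERS_COMBINATION,
    DEFAULT_MIN_USERS_OVERALL,
    Z_95,
    CombinationStats,
    SentimentRatios,
    combination_stats,
    format_rr,
    overall_sentiment_ratios,
)
from .tagging import TaggerContract, filter_first_person, tag_corpus

logger = logging.getLogger("forumrwe")

__all__ = ["TreatmentOutcomeModel", "TreatmentOutcomeResults"]


class TreatmentOutcomeModel:
    """Forum treatment-outcome analysis over one corpus.

    Parameters
    ----------
    corpus
        The documents, catalog and (optionally) gold mention annotations.
    window
        Maximum sentence distance for two features to count as co-mentioned
        (default 2; the same sentence is distance 0).
    min_users_combination
        A combination needs strictly more than this many users with
        directional sentiment to be included (default 20).
    min_users_overall
        A treatment needs strictly more than this many commenting users to
        enter the overall sentiment-ratio report (default 100).
    z
        Normal quantile for the 95% CI (default 1.9599).
    use_gold_mentions
        Analyse the corpus' gold annotations instead of running a tagger.
    tagger
        Tagger to use otherwise; default is the lexicon reference tagger.
    count_unit
        ``"user"`` (default): one verdict per user per combination;
        ``"instance"``: every non-abandoned instance counts.
    """

    def __init__(
        self,
        corpus: Corpus,
        *,
        window: int = DEFAULT_WINDOW,
        min_users_combination: int = DEFAULT_MIN_USERS_COMBINATION,
        min_users_overall: int = DEFAULT_MIN_USERS_OVERALL,
        z: float = Z_95,
        use_gold_mentions: bool = False,
        tagger: TaggerContract | None = None,
        count_unit: str = "user",
    ):
        if count_unit not in ("user", "instance"):
            raise ValueError("count_unit must be 'user' or 'instance'")
        if use_gold_mentions and corpus.gold_mentions is None:
            raise ValueError("corpus carries no gold mentions")
        self.corpus = corpus
        self.window = window
        self.min_users_combination = min_users_combination
        self.min_users_overall = min_users_overall
        self.z = z
        self.use_gold_mentions = use_gold_mentions
        self.tagger = tagger
        self.count_unit = count_unit

    def fit(self) -> "TreatmentOutcomeResults":
        if self.use_gold_mentions:
            mentions = list(self.corpus.gold_mentions or [])
        else:
            mentions = tag_corpus(self.corpus, self.tagger)
        logger.info("tagging: %d mentions", len(mentions))

        kept = filter_first_person(mentions)
        logger.info("first-person filter: %d of %d mentions kept", len(kept), len(mentions))

        instances = extract_pair_instances(kept, self.corpus.catalog, self.window)
        logger.info("pairing: %d treatment-symptom instances", len(instances))

        if self.count_unit == "user":
            verdicts = aggregate_user_verdicts(instances)
        else:
            verdicts = instance_verdicts(instances)
        logger.info("aggregation (%s level): %d verdicts", self.count_unit, len(verdicts))

        combos = combination_stats(verdicts, self.min_users_combination, self.z)
        ratios = overall_sentiment_ratios(
            kept, self.corpus.catalog, self.min_users_overall
        )
        logger.info("stats: %d combinations, %d feature sentiment rows", len(combos), len(ratios))

        records: list[tuple[str, str, str]] = []
        for doc_mentions in self._mentions_by_doc(kept).values():
            records.extend(
                treatment_combinations(doc_mentions, self.corpus.catalog, self.window)
            )
        graph = build_network(records, treatment_user_counts(kept, self.corpus.catalog))
        logger.info(
            "network: %d nodes, %d edges", graph.number_of_nodes(), graph.number_of_edges()
        )

        return TreatmentOutcomeResults(
            model=self,
            mentions=mentions,
            filtered_mentions=kept,
            instances=instances,
            verdicts=verdicts,
            combinations=combos,
            sentiment_ratios=ratios,
            network=graph,
        )

    @staticmethod
    def _mentions_by_doc(mentions: Iterable[FeatureMention]) -> dict[str, list[FeatureMention]]:
        out: dict[str, list[FeatureMention]] = {}
        for m in mentions:
            out.setdefault(m.doc_id, []).append(m)
        return out


class TreatmentOutcomeResults:
    """Fitted surfaces of a :class:`TreatmentOutcomeModel`."""

    def __init__(
        self,
        model: TreatmentOutcomeModel,
        mentions: list[FeatureMention],
        filtered_mentions: list[FeatureMention],
        instances: list[PairInstance],
        verdicts: list[UserVerdict],
        combinations: list[CombinationStats],
        sentiment_ratios: list[SentimentRatios],
        network,
    ):
        self.model = model
        self.mentions = mentions
        self.filtered_mentions = filtered_mentions
        self.instances = instances
        self.verdicts = verdicts
        self.combinations = combinations
        self.sentiment_ratios = sentiment_ratios
        self.network = network

    @property
    def catalog(self) -> Catalog:
        return self.model.corpus.catalog

    def combinations_frame(self) -> pd.DataFrame:
        """Per-combination table: counts, RR, CI bounds and flags."""
        cat = self.catalog
        rows = [
            {
                "treatment": c.treatment_id,
                "symptom": c.symptom_id,
                "category": cat[c.treatment_id].category,
                "n_I": c.n_I,
                "n_W": c.n_W,
                "n": c.n,
                "rr": c.rr,
                "ci_low": math.nan if c.ci_low is None else c.ci_low,
                "ci_high": math.nan if c.ci_high is None else c.ci_high,
                "included": c.included,
                "significant": c.significant,
                "n_neutral": c.n_neutral,
                "n_excluded": c.n_excluded,
            }
            for c in self.combinations
        ]
        cols = [
            "treatment", "symptom", "category", "n_I", "n_W", "n", "rr",
            "ci_low", "ci_high", "included", "significant", "n_neutral", "n_excluded",
        ]
        return pd.DataFrame(rows, columns=cols)

    def _ratio_frame(self, kind: str) -> pd.DataFrame:
        cat = self.catalog
        rows = []
        for r in self.sentiment_ratios:
            if r.kind.value != kind:
                continue
            p_imp, p_neu, p_wor = r.proportions
            rows.append(
                {
                    "feature": r.feature_id,
                    "category": cat[r.feature_id].category,
                    "n_improving": r.n_improving,
                    "n_neutral": r.n_neutral,
                    "n_worsening": r.n_worsening,
                    "total_users": r.total_users,
                    "prop_improving": p_imp,
                    "prop_neutral": p_neu,
                    "prop_worsening": p_wor,
                    "included": r.included,
                }
            )
        cols = [
            "feature", "category", "n_improving", "n_neutral", "n_worsening",
            "total_users", "prop_improving", "prop_neutral", "prop_worsening",
            "included",
        ]
        return pd.DataFrame(rows, columns=cols)

    def treatment_sentiments_frame(self) -> pd.DataFrame:
        """Overall sentiment mix per treatment (headline-report inclusion flagged)."""
        return self._ratio_frame("treatment")

    def symptom_sentiments_frame(self) -> pd.DataFrame:
        """Overall sentiment mix per symptom (no user threshold)."""
        return self._ratio_frame("symptom")

    def network_edges_frame(self) -> pd.DataFrame:
        rows = [
            {"treatment_a": e.treatment_a, "treatment_b": e.treatment_b, "n_users": e.n_users}
            for e in network_edges(self.network)
        ]
        return pd.DataFrame(rows, columns=["treatment_a", "treatment_b", "n_users"])

    def summary(self, included_only: bool = True) -> str:
        """Plain-text table of combination results, largest |log RR| first."""
        combos = [c for c in self.combinations if c.included or not included_only]

        def sort_key(c: CombinationStats) -> float:
            if math.isnan(c.rr):
                return -1.0
            if math.isinf(c.rr) or c.rr == 0:
                return math.inf
            return abs(math.log(c.rr))

        combos = sorted(combos, key=sort_key, reverse=True)
        lines = [
            "Treatment-outcome associations"
            + (" (included combinations)" if included_only else ""),
            f"window = {self.model.window} sentences, "
            f"min users = {self.model.min_users_combination} (strict), "
            f"z = {self.model.z}, unit = {self.model.count_unit}",
            "",
            f"{'treatment':<24}{'symptom':<26}{'n_I':>5}{'n_W':>5}{'n':>5}"
            f"{'RR':>9}{'95% CI':>18}  signif",
        ]
        lines.append("-" * len(lines[-1]))
        for c in combos:
            if c.ci_low is not None:
                ci = f"{c.ci_low:7.2f}-{c.ci_high:<8.2f}"
            else:
                ci = "  --    "
            lines.append(
                f"{c.treatment_id:<24}{c.symptom_id:<26}{c.n_I:>5}{c.n_W:>5}{c.n:>5}"
                f"{format_rr(c.rr) if not math.isnan(c.rr) else '--':>9}{ci:>18}  "
                f"{'yes' if c.significant else 'no'}"
            )
        if not combos:
            lines.append("(no combinations)")
        return "\n".join(lines)
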