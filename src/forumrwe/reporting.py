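"""Report assembly: CSV tables, GraphML network and a run manifest.

``run_pipeline`` executes the whole analysis from a corpus file to a report
directory; ``render_reports`` writes the result surfaces of an already
fitted model.  All outputs are deterministic given the same inputs: rows are
sorted, floats rendered with ``repr``-stable pandas formatting, and the
manifest echoes the configuration and row counts for auditability.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .corpus import Corpus, load_catalog, read_corpus
from .model import TreatmentOutcomeModel, TreatmentOutcomeResults
from .pairing import DEFAULT_WINDOW
from .stats import DEFAULT_MIN_USERS_COMBINATION, DEFAULT_MIN_USERS_OVERALL, Z_95

logger = logging.getLogger("forumrwe")

__all__ = ["RunConfig", "render_reports", "run_pipeline"]


@dataclass
class RunConfig:
    """End-to-end run settings (YAML/JSON-friendly flat record)."""

    corpus_path: str
    out_dir: str
    catalog_path: str | None = None
    window: int = DEFAULT_WINDOW
    min_users_combination: int = DEFAULT_MIN_USERS_COMBINATION
    min_users_overall: int = DEFAULT_MIN_USERS_OVERALL
    z: float = Z_95
    seed: int | None = None
    use_gold_mentions: bool = False
    count_unit: str = "user"

    def __post_init__(self) -> None:
        if self.window < 0:
            raise ValueError("window must be nonnegative")
        if self.min_users_combination < 0 or self.min_users_overall < 0:
            raise ValueError("user thresholds must be nonnegative")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown run-config fields: {sorted(unknown)}")
        return cls(**d)


def render_reports(results: TreatmentOutcomeResults, out_dir: str | Path,
                   config: RunConfig | None = None) -> dict[str, Path]:
    """Write combos.csv, overall_treatments.csv, overall_symptoms.csv,
    network_edges.csv, network.graphml and manifest.json under ``out_dir``.

    Returns the mapping of artefact name to path.  Running twice on the same
    results produces byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    combos = results.combinations_frame().sort_values(
        ["treatment", "symptom"], kind="mergesort"
    )
    treatments = results.treatment_sentiments_frame().sort_values("feature", kind="mergesort")
    symptoms = results.symptom_sentiments_frame().sort_values("feature", kind="mergesort")
    edges = results.network_edges_frame()

    for name, frame in (
        ("combos", combos),
        ("overall_treatments", treatments),
        ("overall_symptoms", symptoms),
        ("network_edges", edges),
    ):
        p = out / f"{name}.csv"
        frame.to_csv(p, index=False)
        paths[name] = p

    p = out / "network.graphml"
    # Rebuild with sorted insertion so GraphML serialisation is stable.
    g = nx.Graph()
    for node in sorted(results.network.nodes):
        g.add_node(node, **results.network.nodes[node])
    for a, b in sorted(tuple(sorted(e)) for e in results.network.edges):
        g.add_edge(a, b, **results.network.edges[a, b])
    nx.write_graphml(g, p, named_key_ids=True, edge_id_from_attribute=None)
    paths["network_graphml"] = p

    model = results.model
    manifest = {
        "config": dataclasses.asdict(config) if config is not None else None,
        "window": model.window,
        "min_users_combination": model.min_users_combination,
        "min_users_overall": model.min_users_overall,
        "z": model.z,
        "count_unit": model.count_unit,
        "node_size_semantics": "distinct users mentioning the treatment",
        "n_documents": len(model.corpus.documents),
        "n_mentions": len(results.mentions),
        "n_first_person_mentions": len(results.filtered_mentions),
        "n_instances": len(results.instances),
        "n_verdicts": len(results.verdicts),
        "rows": {
            "combos": int(len(combos)),
            "overall_treatments": int(len(treatments)),
            "overall_symptoms": int(len(symptoms)),
            "network_edges": int(len(edges)),
        },
    }
    p = out / "manifest.json"
    p.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n", "utf-8")
    paths["manifest"] = p
    return paths


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Corpus file → mentions → pairs → verdicts → stats → report files."""
    try:
        catalog = load_catalog(config.catalog_path)
        corpus = read_corpus(config.corpus_path, catalog)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'read': {exc}") from exc
    logger.info("read: %d documents", len(corpus.documents))
    model = TreatmentOutcomeModel(
        corpus,
        window=config.window,
        min_users_combination=config.min_users_combination,
        min_users_overall=config.min_users_overall,
        z=config.z,
        use_gold_mentions=config.use_gold_mentions,
        count_unit=config.count_unit,
    )
    try:
        results = model.fit()
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'fit': {exc}") from exc
    try:
        return render_reports(results, config.out_dir, config)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'report': {exc}") from exc
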