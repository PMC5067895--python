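"""High-level workflows: evaluate one ontology, analyse a versioned corpus.

These functions tie the layers together in the order a study runs them:
parse -> normalise -> raw metrics -> static/dynamic scores -> change
statistics -> version ranking -> activity PCA.  The command-line interface
is a thin wrapper around them; they are equally usable from Python.
"""

from __future__ import annotations

import json
import logging

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import corpus_stats, evolution, metrics, ontology_model, scaling
from .errors import OQuaREError
from .quality_model import DEFAULT_MODEL, QualityModelConfig, QualityReport

logger = logging.getLogger("oquare")

_ONTOLOGY_SUFFIXES = {".owl", ".rdf", ".xml", ".ttl", ".n3"}


@dataclass
class EvaluationResult:
    """Metrics, scores and aggregated report for a single version."""

    version: str
    metrics: metrics.MetricVector
    scores: scaling.ScoreVector
    report: QualityReport


def evaluate_ontology(
    path,
    normalise: bool = True,
    config: QualityModelConfig = DEFAULT_MODEL,
    version: Optional[str] = None,
) -> EvaluationResult:
    """Static-scale quality evaluation of one ontology file."""
    graph = ontology_model.read_ontology(path)
    graph = ontology_model.normalise(graph, remove_deprecated=normalise)
    version = version or Path(path).stem
    m = metrics.compute_metrics(graph)
    s = scaling.score_vector(m, scaling.StaticScale(), version=version)
    return EvaluationResult(
        version=version,
        metrics=m,
        scores=s,
        report=QualityReport.from_scores(s, config),
    )


@dataclass
class CorpusResult:
    """Everything the corpus pipeline computes, scale by scale."""

    corpus: evolution.VersionedCorpus
    skipped: list[str]
    scales: dict[str, object]  # scale name -> StaticScale | DynamicScale
    score_vectors: dict[str, list[scaling.ScoreVector]]
    change_stats: dict[str, list[tuple[str, evolution.ChangeStatistics]]]
    profiles: dict[str, list[float]]
    reports: dict[str, list[QualityReport]]
    wilcoxon: list[corpus_stats.VersionTestResult]
    activity: list[tuple[str, ontology_model.ActivityDelta]]
    pca: Optional[corpus_stats.PCAResult] = None
    pearson: list[tuple[str, str, float, float]] = field(default_factory=list)


def _ordered_sources(directory: Path) -> list[Path]:
    files = [
        p
        for p in sorted(directory.iterdir())
        if p.suffix.lower() in _ONTOLOGY_SUFFIXES
    ]
    manifest = directory / "manifest.json"
    if manifest.exists():
        with open(manifest) as fh:
            listed = json.load(fh).get("versions", [])
        by_name = {p.name: p for p in files}
        ordered = [by_name[n] for n in listed if n in by_name]
        if ordered:
            return ordered
    return files


def analyse_corpus(
    directory,
    which_scales: Sequence[str] = ("static", "dynamic"),
    normalise: bool = True,
    config: QualityModelConfig = DEFAULT_MODEL,
) -> CorpusResult:
    """Full evolution analysis of a directory of ontology versions.

    Versions are ordered by the manifest when one exists, else by filename.
    Unreadable versions are skipped with a warning; change statistics are
    then computed against the previous *processed* version.  Requires at
    least two processable versions (the dynamic scale is fitted on all of
    them).
    """
    directory = Path(directory)
    records: list[evolution.VersionRecord] = []
    graphs: list[ontology_model.OntologyGraph] = []
    skipped: list[str] = []
    for path in _ordered_sources(directory):
        try:
            graph = ontology_model.read_ontology(path)
        except OQuaREError as exc:
            logger.warning("skipping unprocessable version %s: %s", path.name, exc)
            skipped.append(path.name)
            continue
        graph = ontology_model.normalise(graph, remove_deprecated=normalise)
        graphs.append(graph)
        records.append(
            evolution.VersionRecord(
                version=path.stem, metrics=metrics.compute_metrics(graph)
            )
        )
    if len(records) < 2:
        raise OQuaREError(
            f"need at least two processable versions, got {len(records)}"
        )
    corpus = evolution.VersionedCorpus(records=records)

    scales: dict[str, object] = {}
    for name in which_scales:
        if name == "static":
            scales[name] = scaling.StaticScale()
        elif name == "dynamic":
            scales[name] = scaling.fit_dynamic_scale(
                {
                    m: [v for v in vals if v is not None]
                    for m, vals in corpus.raw_values().items()
                    if any(v is not None for v in vals)
                }
            )
        else:
            raise ValueError(f"unknown scale {name!r}")

    score_vectors = {}
    change_stats = {}
    profiles = {}
    reports = {}
    for name, scale in scales.items():
        svs = [
            scaling.score_vector(r.metrics, scale, version=r.version)
            for r in records
        ]
        score_vectors[name] = svs
        stats = evolution.corpus_change_statistics(svs)
        change_stats[name] = stats
        profiles[name] = evolution.accumulative_profile([st for _, st in stats])
        reports[name] = [QualityReport.from_scores(sv, config) for sv in svs]

    wilcoxon = corpus_stats.wilcoxon_consecutive(corpus)
    activity = [
        (records[i + 1].version, ontology_model.diff_versions(graphs[i], graphs[i + 1]))
        for i in range(len(graphs) - 1)
    ]

    pca = None
    pearson: list[tuple[str, str, float, float]] = []
    if "dynamic" in change_stats and len(activity) >= 3:
        dyn = [st for _, st in change_stats["dynamic"]]
        deltas = [d for _, d in activity]
        try:
            pca = corpus_stats.pca_activity(dyn, deltas)
            cols = {
                "Number.New.Classes": [d.n_new for d in deltas],
                "Number.Changed.Classes": [d.n_changed for d in deltas],
                "Number.Deleted.Classes": [d.n_deleted for d in deltas],
                "Dynamic.Backward.Size": [st.backward_size for st in dyn],
                "Dynamic.Forward.Size": [st.forward_size for st in dyn],
                "Dynamic.Mean.Change": [st.mean_change for st in dyn],
            }
            pearson = corpus_stats.pearson_pairs(
                {k: v for k, v in cols.items() if len(set(v)) > 1}
            )
        except (ValueError, OQuaREError) as exc:
            logger.warning("activity analysis skipped: %s", exc)

    return CorpusResult(
        corpus=corpus,
        skipped=skipped,
        scales=scales,
        score_vectors=score_vectors,
        change_stats=change_stats,
        profiles=profiles,
        reports=reports,
        wilcoxon=wilcoxon,
        activity=activity,
        pca=pca,
        pearson=pearson,
    )


def write_corpus_outputs(result: CorpusResult, out_dir) -> None:
    """Write the CSV/JSON artefacts of a corpus analysis."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    metrics.metric_table(
        [(r.version, r.metrics) for r in result.corpus.records]
    ).to_csv(out / "raw_metrics.csv")
    for name, svs in result.score_vectors.items():
        scaling.score_table(svs).to_csv(out / f"scores_{name}.csv")
    for name, stats in result.change_stats.items():
        evolution.change_table(stats).to_csv(out / f"change_stats_{name}.csv")
        pd.DataFrame(
            {
                "version": [v for v, _ in stats],
                "accumulative_mean_change": result.profiles[name],
            }
        ).to_csv(out / f"profile_{name}.csv", index=False)
    corpus_stats.wilcoxon_table(result.wilcoxon).to_csv(
        out / "wilcoxon.csv", index=False
    )
    ontology_model.activity_table(result.activity).to_csv(
        out / "activity.csv", index=False
    )
    if result.pca is not None:
        corpus_stats.pca_table(result.pca).to_csv(out / "pca_loadings.csv")
        pd.DataFrame(
            result.pearson, columns=["variable_a", "variable_b", "r", "p_value"]
        ).to_csv(out / "pearson.csv", index=False)
    dynamic = result.scales.get("dynamic")
    if dynamic is not None:
        dynamic.to_json(out / "dynamic_scale.json")
    payload = {
        "skipped": result.skipped,
        "reports": {
            name: [rep.as_dict() for rep in reps]
            for name, reps in result.reports.items()
        },
    }
    with open(out / "report.json", "w") as fh:
        json.dump(payload, fh, indent=2)
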