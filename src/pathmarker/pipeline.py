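"""End-to-end orchestration: counts -> DEGs -> enrichment -> network ->
hubs -> markers -> SVM evaluation.

The pipeline is a pure function of its inputs and the seed: rerunning with
the same config produces byte-identical artifacts and report.  Each stage
logs its parameters and writes its output table before the next stage
starts, so a failed run leaves the artifacts of every completed stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, diffexpr, enrichment, kgml, markers, network

__all__ = ["RunConfig", "RunReport", "PipelineError", "run_pipeline"]

log = logging.getLogger("pathmarker")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """Inputs and thresholds for one pipeline run.

    Defaults are the published analysis thresholds: p < 0.05 with
    FC > 2 or FC < 0.5 for differential expression, enrichment at
    p < 0.05, hub degree strictly > 30, a 50/50 stratified train/test
    split and tenfold cross-validation.
    """

    counts: str
    labels: str
    kgml_dir: str
    out_dir: str
    gmt: str | None = None
    id_map: str | None = None
    literature: str | None = None
    p_thresh: float = 0.05
    fc_up: float = 2.0
    fc_down: float = 0.5
    alpha: float = 0.05
    min_degree: int = 30
    split_fraction: float = 0.5
    folds: int = 10
    C: float = 1.0
    seed: int = 0
    normalization: str = "libsize"

    def validate(self) -> None:
        for name in ("p_thresh", "fc_up", "fc_down", "alpha", "C"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        for name in ("counts", "labels"):
            if not Path(getattr(self, name)).exists():
                raise FileNotFoundError(f"{name} file not found: {getattr(self, name)}")
        if not Path(self.kgml_dir).is_dir():
            raise FileNotFoundError(f"kgml_dir not found: {self.kgml_dir}")


@dataclass
class RunReport:
    """Machine-readable summary of a full pipeline run."""

    config: dict
    stages: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"config": self.config, "stages": self.stages},
            indent=2, sort_keys=True, default=_jsonable,
        ) + "\n"


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage in order and write all artifacts to ``out_dir``.

    Halts with :class:`PipelineError` naming the stage on any failure; an
    empty DEG/hub intersection halts before classification with a clear
    message.  Returns the run report (also written to ``report.json``).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=asdict(config))

    # --- differential expression -----------------------------------------
    log.info("stage de: p<%g, FC>%g or FC<%g, normalization=%s",
             config.p_thresh, config.fc_up, config.fc_down, config.normalization)
    counts = _load_counts(config)
    factors = _normalize(counts, config)
    de_tab = _de(counts, factors, config)
    deg_call = diffexpr.call_degs(
        de_tab, config.p_thresh, config.fc_up, config.fc_down
    )
    diffexpr.write_deg_table(de_tab, out / "de_table.tsv")
    diffexpr.write_deg_table(deg_call.table, out / "degs.tsv")
    report.stages["de"] = {
        "n_genes": int(len(counts.genes)),
        "n_samples": int(len(counts.samples)),
        "n_tumor": int((counts.labels == "tumor").sum()),
        "n_normal": int((counts.labels == "normal").sum()),
        "n_degs": int(len(deg_call.table)),
        "n_up": deg_call.n_up,
        "n_down": deg_call.n_down,
    }

    # --- enrichment -------------------------------------------------------
    enr_tab = None
    if config.gmt:
        log.info("stage enrich: alpha=%g", config.alpha)
        enr_tab = _enrich(deg_call, counts, config)
        enrichment.write_enrichment_table(enr_tab, out / "enrichment.tsv")
        report.stages["enrichment"] = {
            "n_sets": int(len(enr_tab)),
            "n_significant": int(enr_tab["significant"].sum()),
        }

    # --- KGML parsing and network ----------------------------------------
    log.info("stage network: min_degree=%d", config.min_degree)
    net, n_docs, n_skipped = _network(config)
    degrees = network.degree_table(net)
    plfit = network.powerlaw_diagnostic(degrees)
    hubs = network.hub_genes(degrees, config.min_degree)
    network.write_edge_list(net, out / "network_edges.tsv")
    network.write_degree_table(degrees, out / "degree_table.tsv")
    network.write_graphml(net, out / "network.graphml")
    report.stages["network"] = {
        "n_pathways": n_docs,
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "n_relations_skipped": n_skipped,
        "n_hubs": len(hubs),
        "powerlaw": {
            "applicable": plfit.applicable,
            "exponent": plfit.exponent,
            "r_squared": plfit.r_squared,
        },
    }

    # --- markers ----------------------------------------------------------
    log.info("stage markers: intersecting %d DEGs with %d hubs",
             len(deg_call.table), len(hubs))
    marker_tab = _markers(deg_call, hubs, degrees, config)
    markers.write_marker_table(marker_tab, out / "markers.tsv")
    report.stages["markers"] = {
        "n_markers": int(len(marker_tab)),
        "genes": sorted(marker_tab["gene"]),
        "n_confirmed": int(marker_tab["confirmed"].sum())
        if "confirmed" in marker_tab else None,
    }
    if marker_tab.empty:
        (out / "report.json").write_text(report.to_json())
        raise PipelineError(
            "stage 'markers' produced an empty DEG/hub intersection; "
            "halting before classification (report.json written)"
        )

    # --- classification ---------------------------------------------------
    log.info("stage classify: folds=%d, C=%g, split=%g, seed=%d",
             config.folds, config.C, config.split_fraction, config.seed)
    clf = _classify(counts, factors, marker_tab, config)
    (out / "model.json").write_text(
        json.dumps(clf["model"], indent=2, sort_keys=True) + "\n"
    )
    (out / "evaluation.json").write_text(
        json.dumps(clf["evaluation"], indent=2, sort_keys=True) + "\n"
    )
    _write_roc(clf["cv_report"], out / "roc_cv.tsv")
    _write_roc(clf["test_report"], out / "roc_test.tsv")
    report.stages["classify"] = clf["evaluation"]

    (out / "report.json").write_text(report.to_json())
    return report


@_stage("load")
def _load_counts(config: RunConfig) -> diffexpr.CountMatrix:
    return diffexpr.load_counts(config.counts, config.labels)


@_stage("normalize")
def _normalize(counts, config: RunConfig) -> pd.Series:
    return diffexpr.normalize(counts, config.normalization)


@_stage("de")
def _de(counts, factors, config: RunConfig) -> pd.DataFrame:
    return diffexpr.de_table(counts, factors)


@_stage("enrich")
def _enrich(deg_call, counts, config: RunConfig) -> pd.DataFrame:
    sets = enrichment.read_gmt(config.gmt)
    return enrichment.enrich(
        deg_call.genes, sets, list(counts.genes), alpha=config.alpha
    )


@_stage("network")
def _network(config: RunConfig):
    id_map = kgml.read_id_map(config.id_map) if config.id_map else {}
    paths = sorted(Path(config.kgml_dir).glob("*.xml"))
    if not paths:
        raise ValueError(f"no .xml files in {config.kgml_dir}")
    edge_lists = {}
    n_skipped = 0
    for path in paths:
        doc = kgml.parse_kgml_file(path)
        extraction = kgml.pathway_edges(doc, id_map)
        edge_lists[doc.pathway_id or path.stem] = extraction.edges
        n_skipped += extraction.n_skipped
    net = network.merge_networks(edge_lists)
    return net, len(paths), n_skipped


@_stage("markers")
def _markers(deg_call, hubs, degrees, config: RunConfig) -> pd.DataFrame:
    if not hubs:
        raise ValueError("no hub genes above the degree threshold")
    tab = markers.intersect_markers(deg_call.table, hubs, degrees)
    if config.literature:
        confirmed = [
            line.strip()
            for line in Path(config.literature).read_text().splitlines()
            if line.strip()
        ]
        tab = markers.annotate_literature(tab, confirmed)
    return tab


@_stage("classify")
def _classify(counts, factors, marker_tab, config: RunConfig) -> dict:
    marker_genes = list(marker_tab["gene"])
    expr = np.log2(diffexpr.cpm(counts, factors).loc[marker_genes] + 1.0)
    X = expr.to_numpy().T  # samples x features
    y = np.where(counts.labels.to_numpy() == "tumor", 1, -1)

    plan = classify.stratified_split(y, config.split_fraction, config.seed)
    tr, te = np.array(plan.train), np.array(plan.test)
    cv_report = classify.cross_validate(
        X[tr], y[tr], k=config.folds, seed=config.seed, C=config.C
    )
    model = classify.train_svm(X[tr], y[tr], C=config.C)
    test_report = classify.evaluate(y[te], classify.decision_values(model, X[te]))

    evaluation = {
        "split": {
            "train_total": int(tr.size),
            "train_tumor": int((y[tr] == 1).sum()),
            "train_normal": int((y[tr] == -1).sum()),
            "test_total": int(te.size),
            "test_tumor": int((y[te] == 1).sum()),
            "test_normal": int((y[te] == -1).sum()),
        },
        "cv": cv_report.to_dict(),
        "test": test_report.to_dict(),
        "margin": model.margin,
    }
    return {
        "model": model.to_dict(feature_names=marker_genes),
        "evaluation": evaluation,
        "cv_report": cv_report,
        "test_report": test_report,
    }


def _write_roc(report: classify.EvalReport, path: Path) -> None:
    lines = ["threshold\tfpr\ttpr"]
    for t, f, s in zip(report.roc_thresholds, report.roc_fpr, report.roc_tpr):
        lines.append(f"{t:g}\t{f:.6g}\t{s:.6g}")
    path.write_text("\n".join(lines) + "\n")
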