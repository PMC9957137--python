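"""End-to-end orchestration: simulate/read -> split -> select genes ->
build graph -> train -> predict -> report."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import graph as graph_mod
from . import model as model_mod
from .metrics import MetricsReport, evaluate
from .preprocess import (
    ANOVAGeneSelector,
    NodeSplit,
    make_node_splits,
    feature_normalize,
    read_dataset,
    split_reference_query,
    standardize_genes,
)
from .simulate import CountMatrix, SimConfig, simulate_counts

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    Defaults follow the recommended protocol: reference fraction p = 0.75,
    m = 2000 selected genes, k = 5 canonical components; the mutual-kNN
    neighbour count (not dictated by the protocol) defaults to 5.
    """

    sim: SimConfig | None = None
    counts_path: str | None = None
    cells_path: str | None = None
    genes_path: str | None = None
    orientation: str = "cells"
    p: float = 0.75
    m: int = 2000
    k: int = 5
    k_nn: int = 5
    n_hidden: int = 64
    n_layers: int = 2
    grid_hidden: tuple[int, ...] | None = None
    grid_layers: tuple[int, ...] | None = None
    learning_rate: float = 0.01
    step_size: int = 10
    gamma: float = 0.8
    patience: int = 2000
    max_epochs: int = 10000
    replicates: int = 1
    seed: int = 0
    out_dir: str | None = None

    def train_config(self) -> model_mod.TrainConfig:
        return model_mod.TrainConfig(
            learning_rate=self.learning_rate,
            step_size=self.step_size,
            gamma=self.gamma,
            patience=self.patience,
            max_epochs=self.max_epochs,
            seed=self.seed,
        )

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    """Everything a run produces, in memory."""

    prediction_report: MetricsReport | None
    test_report: MetricsReport | None
    predictions: pd.DataFrame
    edges: graph_mod.EdgeList
    node_split: NodeSplit
    model: model_mod.AGNNModel
    history: model_mod.TrainHistory | None
    sweep: pd.DataFrame | None
    classes: np.ndarray


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and config hash."""


def _stage(name: str, cfg: RunConfig):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise StageError(
                    f"stage {name!r} failed (config {cfg.config_hash()}): {exc}"
                ) from exc
            logger.info("stage %s: done in %.2fs", name, time.perf_counter() - self.t0)
            return False

    return _Ctx()


def _load_data(cfg: RunConfig) -> CountMatrix:
    if cfg.sim is not None:
        return simulate_counts(cfg.sim)
    if not (cfg.counts_path and cfg.cells_path and cfg.genes_path):
        raise ValueError("provide either a SimConfig or the three dataset paths")
    return read_dataset(
        cfg.counts_path, cfg.cells_path, cfg.genes_path, orientation=cfg.orientation
    )


def run_pipeline(cfg: RunConfig, data: CountMatrix | None = None) -> PipelineResult:
    """Execute the full transductive annotation pipeline.

    Metrics are computed on the prediction (query) set — the headline
    number — and on the held-out reference test set, whenever true labels
    are available for those cells.
    """
    with _stage("load", cfg):
        if data is None:
            data = _load_data(cfg)
        if data.labels is None:
            raise ValueError("the pipeline requires labelled reference cells")

    with _stage("split", cfg):
        split = split_reference_query(data, p=cfg.p, seed=cfg.seed)
        ref_idx, query_idx = split.reference_indices, split.query_indices
        r, q = ref_idx.size, query_idx.size

    with _stage("select_genes", cfg):
        selector = ANOVAGeneSelector(n_genes=cfg.m).fit(
            data.counts[ref_idx], data.labels[ref_idx]
        )
        sel = selector.selected_indices_

    with _stage("build_graph", cfg):
        FR = data.counts[np.ix_(ref_idx, sel)].astype(float)
        FQ = data.counts[np.ix_(query_idx, sel)].astype(float)
        edges = graph_mod.build_graph(
            standardize_genes(FR), standardize_genes(FQ), k=cfg.k, k_nn=cfg.k_nn
        )

    with _stage("features", cfg):
        F_all = feature_normalize(np.vstack([FR, FQ]))
        node_labels = np.concatenate([data.labels[ref_idx], data.labels[query_idx]])
        classes = np.unique(data.labels[ref_idx])
        class_index = {c: i for i, c in enumerate(classes)}
        known = np.array([lab in class_index for lab in node_labels])
        y_enc = np.array([class_index.get(lab, -1) for lab in node_labels])
        node_split = make_node_splits(split, data.labels, seed=cfg.seed)

    with _stage("train", cfg):
        tcfg = cfg.train_config()
        history: model_mod.TrainHistory | None = None
        sweep: pd.DataFrame | None = None
        if cfg.grid_hidden and cfg.grid_layers:
            best, sweep = model_mod.architecture_search(
                F_all,
                edges,
                y_enc,
                node_split.train_indices,
                node_split.val_indices,
                grid_hidden=cfg.grid_hidden,
                grid_layers=cfg.grid_layers,
                cfg=tcfg,
            )
        else:
            model0 = model_mod.init_model(
                F_all.shape[1], cfg.n_hidden, cfg.n_layers, classes.size, seed=cfg.seed
            )
            best, history = model_mod.train(
                model0,
                F_all,
                edges,
                y_enc,
                node_split.train_indices,
                node_split.val_indices,
                tcfg,
            )

    with _stage("predict", cfg):
        pred_enc = model_mod.predict(best, F_all, edges)
        predicted = classes[pred_enc]
        node_ids = [data.cell_ids[i] for i in ref_idx] + [
            data.cell_ids[i] for i in query_idx
        ]
        role = np.full(r + q, "train", dtype=object)
        role[node_split.val_indices] = "val"
        role[node_split.test_indices] = "test"
        role[node_split.prediction_indices] = "prediction"
        predictions = pd.DataFrame(
            {
                "cell_id": node_ids,
                "set": role,
                "true_label": node_labels,
                "predicted_label": predicted,
            }
        )

    with _stage("evaluate", cfg):
        pred_mask = node_split.prediction_indices
        prediction_report = (
            evaluate(node_labels[pred_mask], predicted[pred_mask], classes)
            if known[pred_mask].all()
            else None
        )
        test_mask = node_split.test_indices
        test_report = (
            evaluate(node_labels[test_mask], predicted[test_mask], classes)
            if test_mask.size
            else None
        )

    result = PipelineResult(
        prediction_report=prediction_report,
        test_report=test_report,
        predictions=predictions,
        edges=edges,
        node_split=node_split,
        model=best,
        history=history,
        sweep=sweep,
        classes=classes,
    )
    if cfg.out_dir is not None:
        _write_outputs(cfg, result)
    return result


def _write_outputs(cfg: RunConfig, result: PipelineResult) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.predictions.to_csv(out / "predictions.tsv", sep="\t", index=False)
    result.edges.write_tsv(out / "edges.tsv")
    report = {}
    if result.prediction_report is not None:
        report["prediction"] = result.prediction_report.to_dict()
    if result.test_report is not None:
        report["test"] = result.test_report.to_dict()
    (out / "metrics.json").write_text(json.dumps(report, indent=2) + "\n")
    if result.history is not None:
        result.history.to_frame().to_csv(out / "history.tsv", sep="\t", index=False)
    if result.sweep is not None:
        result.sweep.to_csv(out / "sweep.tsv", sep="\t", index=False)
    manifest = dataclasses.asdict(cfg)
    manifest["config_hash"] = cfg.config_hash()
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str) + "\n"
    )


def replicate_seeds(seed: int, n: int) -> list[int]:
    """Independent per-replicate seeds derived from one master seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31)) for s in state]


def run_replicates(cfg: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Repeat the pipeline over independently seeded simulated replicates.

    Returns a tidy per-replicate metrics table (prediction-set metrics)
    plus a summary with the median and interquartile range per metric —
    the boxplot-style view of the simulation study.
    """
    if cfg.replicates < 1:
        raise ValueError("replicates must be >= 1")
    if cfg.sim is None:
        raise ValueError("run_replicates requires a simulation configuration")
    seeds = replicate_seeds(cfg.seed, cfg.replicates)
    rows = []
    for i, s in enumerate(seeds):
        rep_cfg = dataclasses.replace(
            cfg,
            sim=dataclasses.replace(cfg.sim, seed=s),
            seed=s,
            out_dir=(
                str(Path(cfg.out_dir) / f"rep_{i:03d}") if cfg.out_dir else None
            ),
            replicates=1,
        )
        result = run_pipeline(rep_cfg)
        rep = result.prediction_report
        rows.append(
            dict(
                replicate=i,
                seed=s,
                accuracy=rep.accuracy,
                macro_precision=rep.macro_precision,
                macro_recall=rep.macro_recall,
                macro_f1=rep.macro_f1,
                mcc=rep.mcc,
            )
        )
    table = pd.DataFrame(rows)
    metric_cols = ["accuracy", "macro_precision", "macro_recall", "macro_f1", "mcc"]
    summary = pd.DataFrame(
        {
            "metric": metric_cols,
            "median": [table[c].median() for c in metric_cols],
            "q1": [table[c].quantile(0.25) for c in metric_cols],
            "q3": [table[c].quantile(0.75) for c in metric_cols],
        }
    )
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "replicates.tsv", sep="\t", index=False)
        summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    return table, summary
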