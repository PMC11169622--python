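"""High-level workflow steps shared by the CLI and the example scripts.

Each function is one stage of the workflow: simulate a fixture corpus,
curate (length filter + redundancy reduction into positive/negative
splits), split into folds, train the per-fold models, predict in CAID
format, and evaluate predictions with bootstrap CIs.  All stages write a
provenance sidecar (config hash, seeds, package version) next to their
outputs so a finished run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import __version__, evaluation, models, redundancy, synthetic
from .features import assemble_features
from .records import (
    ProteinRecord,
    filter_max_length,
    load_embeddings,
    protein_class,
    read_annotated_fasta,
    read_caid_predictions,
    write_annotated_fasta,
    write_caid_predictions,
)

__all__ = [
    "write_provenance",
    "simulate_dataset",
    "curate_dataset",
    "load_feature_tables",
    "train_crossval",
    "predict_dataset",
    "evaluate_predictions",
]


def write_provenance(directory, command: str, config: dict) -> None:
    payload = json.dumps(config, sort_keys=True, default=str)
    block = {
        "command": command,
        "version": __version__,
        "config": config,
        "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
    }
    path = Path(directory) / f"provenance_{command}.json"
    path.write_text(json.dumps(block, indent=2, sort_keys=True, default=str) + "\n")


def simulate_dataset(out_dir, config: synthetic.SyntheticConfig) -> list[ProteinRecord]:
    records = synthetic.generate_proteins(config)
    embeddings = synthetic.generate_embeddings(records, config)
    synthetic.write_fixture_dataset(out_dir, records, embeddings, config)
    write_provenance(out_dir, "simulate", dataclasses.asdict(config))
    return records


def curate_dataset(records: Sequence[ProteinRecord], out_dir,
                   max_len: int = 10_000,
                   criterion: str = "hval", cutoff: float = 0.0) -> dict:
    """Length filter, classify, and redundancy-reduce into final splits.

    Within-set reduction runs separately on positives and negatives, then
    the retained negatives are reduced against the retained positives.
    Writes both splits and a TSV removal report.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    kept = filter_max_length(records, max_len)
    positives = [r for r in kept if protein_class(r) == "positive"]
    negatives = [r for r in kept if protein_class(r) == "negative"]
    pos_result = redundancy.reduce_within(positives, criterion, cutoff)
    neg_result = redundancy.reduce_within(negatives, criterion, cutoff)
    cross_result = redundancy.reduce_against(
        neg_result.retained, pos_result.retained, criterion, cutoff
    )
    write_annotated_fasta(pos_result.retained, out_dir / "positives.fasta")
    write_annotated_fasta(cross_result.retained, out_dir / "negatives.fasta")
    removed = pos_result.removed + neg_result.removed + cross_result.removed
    redundancy.write_removal_report(removed, out_dir / "removed.tsv")
    summary = {
        "input": len(records),
        "after_length_filter": len(kept),
        "positives_in": len(positives),
        "negatives_in": len(negatives),
        "positives_retained": len(pos_result.retained),
        "negatives_after_within": len(neg_result.retained),
        "negatives_retained": len(cross_result.retained),
        "criterion": criterion,
        "cutoff": cutoff,
        "max_len": max_len,
    }
    write_provenance(out_dir, "curate", summary)
    return summary


def load_feature_tables(records: Sequence[ProteinRecord], embedding_store
                        ) -> tuple[dict, dict, dict]:
    """Assemble per-protein (features, labels, disorder) tables.

    Features are the stored embedding plus the disorder channel as the
    last column.
    """
    features, labels, disorder = {}, {}, {}
    for rec in records:
        emb = load_embeddings(embedding_store, rec.id)
        features[rec.id] = assemble_features(emb, rec.disorder_mask)
        labels[rec.id] = rec.binding_mask.astype(float)
        disorder[rec.id] = rec.disorder_mask
    return features, labels, disorder


def train_crossval(records: Sequence[ProteinRecord], embedding_store,
                   config: models.ModelConfig, k: int = 5,
                   fold_seed: int = 0, out_dir=None
                   ) -> tuple[list[models.TrainedModel], models.FoldSplit]:
    """Train one model per CV fold; optionally write checkpoints + logs."""
    features, labels, disorder = load_feature_tables(records, embedding_store)
    split = models.make_folds([r.id for r in records], k=k, seed=fold_seed)
    trained = []
    for fold in range(k):
        fold_config = dataclasses.replace(config, seed=config.seed + fold)
        model = models.train_model(features, labels, disorder, fold_config,
                                   split, val_fold=fold)
        trained.append(model)
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            model.save(out_dir / f"fold{fold}.npz")
            model.write_training_log(out_dir / f"fold{fold}_log.tsv")
    if out_dir is not None:
        (Path(out_dir) / "folds.tsv").write_text(
            "protein_id\tfold\n"
            + "".join(f"{pid}\t{f}\n" for pid, f in sorted(split.assignment.items()))
        )
        (Path(out_dir) / "cutoffs.tsv").write_text(
            "fold\tcutoff\n"
            + "".join(f"{m.fold_id}\t{m.cutoff}\n" for m in trained)
        )
        write_provenance(out_dir, "train",
                         {**dataclasses.asdict(config), "k": k,
                          "fold_seed": fold_seed})
    return trained, split


def predict_dataset(records: Sequence[ProteinRecord], embedding_store,
                    fold_models: Sequence[models.TrainedModel],
                    out_path, *, ensemble: bool = False,
                    cutoff: float | None = None) -> dict[str, np.ndarray]:
    """Score a dataset and write CAID-format predictions.

    Default inference mode uses the single best fold model (the last one,
    with its own cutoff); ``ensemble=True`` averages all fold models and
    uses their mean cutoff.  ``cutoff`` overrides either choice; labels
    obey the strict ``score > cutoff`` rule.
    """
    if not fold_models:
        raise ValueError("no models given")
    features, _, _ = load_feature_tables(records, embedding_store)
    if ensemble:
        used_cutoff = float(np.mean([m.cutoff for m in fold_models]))
        score_fn = lambda feat: models.ensemble_average(fold_models, feat)
    else:
        final = fold_models[-1]
        used_cutoff = final.cutoff
        score_fn = lambda feat: models.predict_scores(final, feat)
    if cutoff is not None:
        used_cutoff = cutoff
    scores = {rec.id: score_fn(features[rec.id]) for rec in records}
    labels = {rid: evaluation.binarize(s, used_cutoff)
              for rid, s in scores.items()}
    write_caid_predictions(records, scores, labels, out_path)
    return scores


def evaluate_predictions(records: Sequence[ProteinRecord],
                         prediction_paths: Mapping[str, object],
                         out_path=None, batch_size: int = 100,
                         n_batches: int = 1000, seed: int = 0) -> dict:
    """Bootstrap-evaluate one or more CAID prediction files against truth.

    Returns ``method -> {metric -> MetricEstimate}``; with more than one
    method also runs the pairwise CI-overlap / Welch comparison.  With an
    output path, writes one metric report per method (suffixing the
    method name) and a comparison TSV.
    """
    truth_labels = np.concatenate([r.binding_mask for r in records])
    truth_disorder = np.concatenate([r.disorder_mask for r in records])
    by_method: dict[str, dict[str, evaluation.MetricEstimate]] = {}
    for method, path in prediction_paths.items():
        preds = read_caid_predictions(path)
        missing = [r.id for r in records if r.id not in preds]
        if missing:
            raise ValueError(f"{method}: missing predictions for {missing[:3]}...")
        pred_labels = np.concatenate([preds[r.id][1] for r in records])
        by_method[method] = evaluation.bootstrap_metrics(
            truth_labels, pred_labels, truth_disorder,
            batch_size=batch_size, n_batches=n_batches, seed=seed,
        )
    comparison = None
    if out_path is not None:
        out_path = Path(out_path)
        out_path.parent.mkdir(parents=True, exist_ok=True)
        for method, estimates in by_method.items():
            target = (out_path if len(by_method) == 1 else
                      out_path.with_name(f"{out_path.stem}_{method}{out_path.suffix}"))
            evaluation.write_metric_report(estimates, target)
    if len(by_method) > 1:
        cmp_path = (Path(out_path).with_name("comparison.tsv")
                    if out_path is not None else None)
        comparison = evaluation.compare_methods(by_method, cmp_path)
    return {"estimates": by_method, "comparison": comparison}
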