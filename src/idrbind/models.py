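"""Training and inference for the disordered-residue binding classifier.

The production configuration is a single-hidden-layer feed-forward
network over per-residue features (pLM embedding + disorder bit, 1025
inputs for ProtT5), 612 hidden units, one sigmoid output, trained with
binary cross-entropy, the Adam optimizer, residue batches of 512, a
learning rate of 0.01, and early stopping with patience 5 on the
validation-fold loss.  The heavy class imbalance (binding residues are a
minority) is handled by under-sampling: all binding residues are kept and
the two non-binding groups — non-binding residues inside disordered
regions and residues outside them — are each sampled down to the binding
count, so the three groups enter training in equal abundance.

Cross-validation is protein-level: proteins are split into k folds, one
model trained per fold with that fold as validation; each model gets its
own decision cutoff chosen on its validation fold.  The five fold models
can be averaged into an ensemble, and two methods' scores can be merged
by consensus (mean score, re-selected cutoff).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import evaluation
from .nets import MLP, Adam, ConvNet, bce_from_logits

__all__ = [
    "ModelConfig",
    "FoldSplit",
    "TrainedModel",
    "EarlyStopper",
    "make_folds",
    "undersample",
    "train_model",
    "predict_scores",
    "ensemble_average",
    "consensus_combine",
    "ablate_input",
]


@dataclasses.dataclass
class ModelConfig:
    """Architecture and training hyper-parameters.

    ``input_dim`` is the feature width: 1025 for ProtT5 + disorder bit,
    2561 for ESM-2 + disorder bit, 567 for the AAindex baseline, m+1 for
    synthetic embeddings.  ``batch_size`` counts residues, not proteins.
    """

    input_dim: int
    architecture: str = "fnn"  # "fnn" | "cnn"
    hidden_units: int = 612
    conv_channels: tuple[int, int] = (128, 32)
    kernel_size: int = 5
    dropout: float = 0.0
    batch_size: int = 512
    learning_rate: float = 0.01
    patience: int = 5
    max_epochs: int = 200
    training_subset: str = "all"  # "all" | "disorder_only"
    balancing: str = "undersample"  # "undersample" | "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ("fnn", "cnn"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.training_subset not in ("all", "disorder_only"):
            raise ValueError(f"unknown training_subset {self.training_subset!r}")
        if self.balancing not in ("undersample", "none"):
            raise ValueError(f"unknown balancing {self.balancing!r}")
        for name in ("input_dim", "hidden_units", "batch_size", "patience",
                     "max_epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")


@dataclasses.dataclass(frozen=True)
class FoldSplit:
    """Protein-level assignment of ids to one of k folds (sizes differ <= 1)."""

    assignment: dict[str, int]
    k: int

    def fold_ids(self, fold: int) -> list[str]:
        return [pid for pid, f in self.assignment.items() if f == fold]

    def train_ids(self, val_fold: int) -> list[str]:
        return [pid for pid, f in self.assignment.items() if f != val_fold]


def make_folds(ids: Sequence[str], k: int = 5, seed: int = 0) -> FoldSplit:
    """Uniform random protein-level k-fold split, deterministic per seed."""
    if k < 2:
        raise ValueError("k must be >= 2")
    ids = list(ids)
    if len(ids) < k:
        raise ValueError(f"need at least {k} proteins for {k} folds")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate protein ids")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    assignment = {ids[int(j)]: int(pos % k) for pos, j in enumerate(order)}
    return FoldSplit(assignment=assignment, k=k)


def undersample(binding: np.ndarray, disorder: np.ndarray,
                seed: int = 0) -> np.ndarray:
    """Balanced residue index set: keep all binding residues, sample the rest.

    The non-binding residues form two groups — inside disordered regions
    and outside — and each is sampled (uniformly, without replacement)
    down to the binding count; a group smaller than that is kept whole.
    Returns sorted indices into the input arrays.
    """
    binding = np.asarray(binding).astype(bool)
    disorder = np.asarray(disorder).astype(bool)
    if binding.shape != disorder.shape:
        raise ValueError("binding/disorder length mismatch")
    pos = np.flatnonzero(binding)
    if len(pos) == 0:
        raise ValueError("under-sampling requires at least one binding residue")
    nb_dis = np.flatnonzero(~binding & disorder)
    nb_ord = np.flatnonzero(~binding & ~disorder)
    rng = np.random.default_rng(seed)
    keep = [pos]
    for group in (nb_dis, nb_ord):
        if len(group) > len(pos):
            keep.append(rng.choice(group, size=len(pos), replace=False))
        else:
            keep.append(group)
    return np.sort(np.concatenate(keep))


class EarlyStopper:
    """Stop after ``patience`` consecutive epochs without val-loss improvement."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = 0
        self.bad_epochs = 0

    def update(self, epoch: int, val_loss: float) -> bool:
        """Record one epoch; returns True when training should stop."""
        if val_loss < self.best:
            self.best = val_loss
            self.best_epoch = epoch
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
        return self.bad_epochs >= self.patience


@dataclasses.dataclass
class TrainedModel:
    """A fitted network plus its fold-specific decision cutoff."""

    config: ModelConfig
    weights: dict[str, np.ndarray]
    cutoff: float
    fold_id: int
    history: list[tuple[int, float, float]]  # (epoch, train_loss, val_loss)

    def _net(self):
        if self.config.architecture == "cnn":
            net = ConvNet(self.config.input_dim, self.config.conv_channels,
                          self.config.kernel_size)
        else:
            net = MLP(self.config.input_dim, self.config.hidden_units,
                      self.config.dropout)
        net.set_state(self.weights)
        return net

    def save(self, path) -> None:
        """Checkpoint: config (JSON) + weights + cutoff in one .npz."""
        meta = dataclasses.asdict(self.config)
        meta["conv_channels"] = list(meta["conv_channels"])
        np.savez(
            path,
            __meta__=json.dumps(
                {"config": meta, "cutoff": self.cutoff, "fold_id": self.fold_id,
                 "history": self.history, "format_version": 1}
            ),
            **self.weights,
        )

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            weights = {k: data[k] for k in data.files if k != "__meta__"}
        cfg = meta["config"]
        cfg["conv_channels"] = tuple(cfg["conv_channels"])
        return cls(
            config=ModelConfig(**cfg),
            weights=weights,
            cutoff=float(meta["cutoff"]),
            fold_id=int(meta["fold_id"]),
            history=[tuple(h) for h in meta["history"]],
        )

    def write_training_log(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("epoch\ttrain_loss\tval_loss\n")
            for epoch, tr, vl in self.history:
                fh.write(f"{epoch}\t{tr:.6f}\t{vl:.6f}\n")


def _gather(features: Mapping[str, np.ndarray], labels: Mapping[str, np.ndarray],
            disorder: Mapping[str, np.ndarray], ids: Sequence[str]):
    X = np.concatenate([np.asarray(features[i], dtype=float) for i in ids])
    y = np.concatenate([np.asarray(labels[i], dtype=float) for i in ids])
    d = np.concatenate([np.asarray(disorder[i]) for i in ids]).astype(bool)
    return X, y, d


def train_model(
    features: Mapping[str, np.ndarray],
    labels: Mapping[str, np.ndarray],
    disorder: Mapping[str, np.ndarray],
    config: ModelConfig,
    fold_split: FoldSplit,
    val_fold: int,
) -> TrainedModel:
    """Train one cross-validation fold model.

    ``features``/``labels``/``disorder`` map protein id to the per-residue
    feature matrix, binding labels, and disorder mask.  Proteins assigned
    to ``val_fold`` form the validation set; the rest train.  The training
    residue set honours ``config.training_subset`` (all residues or
    disordered only) and ``config.balancing`` (three-group under-sampling
    or none).  Early stopping monitors the (unbalanced) validation loss;
    the weights of the best validation epoch are returned, and the decision
    cutoff is selected on the validation fold's disordered residues.
    """
    train_ids = fold_split.train_ids(val_fold)
    val_ids = fold_split.fold_ids(val_fold)
    if not train_ids or not val_ids:
        raise ValueError(f"fold {val_fold} leaves an empty train or val set")
    if config.architecture == "cnn":
        return _train_cnn(features, labels, disorder, config, train_ids,
                          val_ids, val_fold)
    Xtr, ytr, dtr = _gather(features, labels, disorder, train_ids)
    Xva, yva, dva = _gather(features, labels, disorder, val_ids)

    if config.training_subset == "disorder_only":
        Xtr, ytr, dtr = Xtr[dtr], ytr[dtr], dtr[dtr]
        val_keep = dva
        Xva_loss, yva_loss = Xva[val_keep], yva[val_keep]
    else:
        Xva_loss, yva_loss = Xva, yva
    if config.balancing == "undersample":
        idx = undersample(ytr > 0, dtr, seed=config.seed)
        Xtr, ytr, dtr = Xtr[idx], ytr[idx], dtr[idx]
    if Xtr.shape[0] == 0:
        raise ValueError("training subset is empty")
    if Xtr.shape[1] != config.input_dim:
        raise ValueError(
            f"feature width {Xtr.shape[1]} != config.input_dim {config.input_dim}"
        )

    rng = np.random.default_rng(config.seed)
    net = MLP(config.input_dim, config.hidden_units, config.dropout, rng=rng)
    optimizer = Adam(net.params, lr=config.learning_rate)
    stopper = EarlyStopper(config.patience)
    best_state = net.get_state()
    history: list[tuple[int, float, float]] = []

    n = Xtr.shape[0]
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            loss, grads = net.loss_and_grads(Xtr[batch], ytr[batch], rng=rng)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(lr={config.learning_rate}, batch={len(batch)})"
                )
            optimizer.step(grads)
            epoch_losses.append(loss)
        val_logits = net.logits(Xva_loss)
        val_loss = bce_from_logits(val_logits, yva_loss)
        if not np.isfinite(val_loss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
        history.append((epoch, float(np.mean(epoch_losses)), float(val_loss)))
        improved = val_loss < stopper.best
        stop = stopper.update(epoch, val_loss)
        if improved:
            best_state = net.get_state()
        if stop:
            break

    net.set_state(best_state)
    val_scores = net.predict_proba(Xva)
    cutoff = _cutoff_on_validation(yva, val_scores, dva)
    return TrainedModel(
        config=config,
        weights=net.get_state(),
        cutoff=float(cutoff),
        fold_id=val_fold,
        history=history,
    )


def _cutoff_on_validation(yva, val_scores, dva) -> float:
    try:
        return evaluation.select_cutoff(
            (yva[dva] > 0).astype(int), val_scores[dva]
        )
    except ValueError:
        return 0.5  # validation fold lacks a class; neutral default


def _train_cnn(features, labels, disorder, config: ModelConfig,
               train_ids: Sequence[str], val_ids: Sequence[str],
               val_fold: int) -> TrainedModel:
    """Protein-batched training for the experimental CNN variant.

    One gradient step per protein (convolutions must not cross chain
    boundaries).  Class balance is handled at the protein level: positive
    proteins are over-sampled (with replacement) until they match the
    negative count.  ``training_subset="disorder_only"`` restricts the
    loss to disordered residues via a mask rather than dropping rows.
    """
    rng = np.random.default_rng(config.seed)
    net = ConvNet(config.input_dim, config.conv_channels,
                  config.kernel_size, rng=rng)
    optimizer = Adam(net.params, lr=config.learning_rate)
    stopper = EarlyStopper(config.patience)
    best_state = net.get_state()
    history: list[tuple[int, float, float]] = []

    pos_ids = [i for i in train_ids if np.asarray(labels[i]).sum() > 0]
    neg_ids = [i for i in train_ids if np.asarray(labels[i]).sum() == 0]
    epoch_pool = list(train_ids)
    if config.balancing != "none" and pos_ids and len(neg_ids) > len(pos_ids):
        extra = rng.choice(pos_ids, size=len(neg_ids) - len(pos_ids),
                           replace=True)
        epoch_pool = list(train_ids) + [str(e) for e in extra]

    def _protein_mask(pid):
        if config.training_subset == "disorder_only":
            return np.asarray(disorder[pid], dtype=float)
        return None

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(epoch_pool))
        epoch_losses = []
        for j in order:
            pid = epoch_pool[int(j)]
            mask = _protein_mask(pid)
            if mask is not None and mask.sum() == 0:
                continue
            loss, grads = net.loss_and_grads(
                np.asarray(features[pid], dtype=float),
                np.asarray(labels[pid], dtype=float),
                mask=mask,
            )
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite CNN loss at epoch {epoch}")
            optimizer.step(grads)
            epoch_losses.append(loss)
        val_losses, val_weights = [], []
        for pid in val_ids:
            mask = _protein_mask(pid)
            if mask is not None and mask.sum() == 0:
                continue
            y = np.asarray(labels[pid], dtype=float)
            p = np.clip(net.predict_proba(
                np.asarray(features[pid], dtype=float)), 1e-12, 1 - 1e-12)
            per_res = -(y * np.log(p) + (1 - y) * np.log(1 - p))
            w = mask if mask is not None else np.ones_like(y)
            val_losses.append(float(np.sum(w * per_res)))
            val_weights.append(float(np.sum(w)))
        val_loss = float(np.sum(val_losses) / np.sum(val_weights))
        history.append((epoch, float(np.mean(epoch_losses)), val_loss))
        improved = val_loss < stopper.best
        stop = stopper.update(epoch, val_loss)
        if improved:
            best_state = net.get_state()
        if stop:
            break

    net.set_state(best_state)
    val_scores = np.concatenate([
        net.predict_proba(np.asarray(features[pid], dtype=float))
        for pid in val_ids
    ])
    yva = np.concatenate([np.asarray(labels[pid], dtype=float)
                          for pid in val_ids])
    dva = np.concatenate([np.asarray(disorder[pid]) for pid in val_ids]
                         ).astype(bool)
    cutoff = _cutoff_on_validation(yva, val_scores, dva)
    return TrainedModel(config=config, weights=net.get_state(),
                        cutoff=float(cutoff), fold_id=val_fold,
                        history=history)


def predict_scores(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """Per-residue binding probabilities; deterministic in inference mode."""
    return model._net().predict_proba(np.asarray(features, dtype=float))


def ensemble_average(models: Sequence[TrainedModel],
                     features: np.ndarray) -> np.ndarray:
    """Mean of the raw per-residue outputs of the fold models."""
    if not models:
        raise ValueError("empty model list")
    dims = {m.config.input_dim for m in models}
    if len(dims) != 1:
        raise ValueError(f"models disagree on input_dim: {sorted(dims)}")
    return np.mean([predict_scores(m, features) for m in models], axis=0)


def consensus_combine(scores_a: np.ndarray, scores_b: np.ndarray,
                      labels_val: np.ndarray) -> tuple[np.ndarray, float]:
    """Merge two methods: element-wise mean score, cutoff re-selected.

    The combined cutoff is chosen on the validation labels with the same
    balanced-accuracy grid search used for single models.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("score length mismatch")
    combined = (a + b) / 2.0
    cutoff = evaluation.select_cutoff(np.asarray(labels_val).astype(int), combined)
    return combined, cutoff


def ablate_input(model: TrainedModel, features: np.ndarray,
                 labels: np.ndarray, disorder_mask: np.ndarray,
                 dim: int) -> float:
    """Importance of one input dimension as an MCC drop.

    Importance = MCC(model on intact features) − MCC(model with column
    ``dim`` zeroed), both evaluated on disordered residues at the model's
    cutoff.  If the MCC is undefined in both conditions (constant
    predictions) the importance is 0; if only one side is undefined the
    result is NaN.
    """
    features = np.asarray(features, dtype=float)
    if not (0 <= dim < model.config.input_dim):
        raise ValueError(f"dim {dim} out of range")
    labels = np.asarray(labels).astype(int)
    disorder_mask = np.asarray(disorder_mask).astype(bool)

    def _mcc(feat):
        scores = predict_scores(model, feat)
        preds = evaluation.binarize(scores, model.cutoff)
        counts = evaluation.confusion_counts(labels, preds, disorder_mask)
        return evaluation.metric(counts, "mcc")

    intact = _mcc(features)
    ablated_feat = features.copy()
    ablated_feat[:, dim] = 0.0
    ablated = _mcc(ablated_feat)
    if np.isnan(intact) and np.isnan(ablated):
        return 0.0
    return float(intact - ablated)
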