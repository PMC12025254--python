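"""Training loop, metrics, k-fold cross-validation, and experiment runners."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import GroupKFold, StratifiedKFold

from .model import DUFormer, ModelConfig, model_loss
from .nn import Adam, Module
from .recording import SegmentSet

METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "auc")


@dataclass
class TrainConfig:
    """Optimization hyperparameters.

    Defaults follow common practice for small EEG models: Adam at 1e-3, up
    to 100 epochs with early stopping on a 10% validation split carved from
    the training data (never from the test fold).
    """

    epochs: int = 100
    batch_size: int = 32
    lr: float = 1e-3
    weight_decay: float = 0.0
    val_fraction: float = 0.1
    patience: int = 10
    seed: int = 0

    @classmethod
    def reduced(cls, **overrides) -> "TrainConfig":
        """Desk-scale preset: fixed 10 epochs, larger batches, no early stop."""
        base = dict(epochs=10, batch_size=64, val_fraction=0.0)
        base.update(overrides)
        return cls(**base)


def _stratified_holdout(
    labels: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class random split into (train_idx, val_idx)."""
    val: list[int] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_val = max(1, int(round(fraction * len(idx))))
        val.extend(idx[:n_val].tolist())
    val_idx = np.asarray(sorted(val))
    train_idx = np.setdiff1d(np.arange(len(labels)), val_idx)
    return train_idx, val_idx


def train(
    model: Module | ModelConfig,
    train_set: SegmentSet,
    hyper: TrainConfig = TrainConfig(),
) -> tuple[Module, pd.DataFrame]:
    """Optimize the model's loss on ``train_set``.

    Accepts either a :class:`ModelConfig` (a DU-former is built from it) or
    a ready-constructed model sharing the forward contract. Deterministic
    under a fixed ``hyper.seed``. Returns the model and the per-epoch
    training curve.
    """
    if isinstance(model, ModelConfig):
        model = DUFormer(model)
    labels = train_set.labels
    if len(train_set) == 0 or len(np.unique(labels)) < 2:
        raise ValueError("training set must contain both classes")

    rng = np.random.default_rng(hyper.seed)
    x_all = train_set.segments.astype(np.float32)
    # single global scale keeps activations O(1) without erasing amplitude cues
    scale = float(x_all.std()) or 1.0
    model.input_scale = scale

    if hyper.val_fraction > 0:
        tr_idx, val_idx = _stratified_holdout(labels, hyper.val_fraction, rng)
    else:
        tr_idx, val_idx = np.arange(len(labels)), np.empty(0, dtype=int)
    x_tr, y_tr = x_all[tr_idx], labels[tr_idx]
    x_val, y_val = x_all[val_idx], labels[val_idx]

    kl_weight = getattr(getattr(model, "config", None), "kl_weight", 0.0)
    opt = Adam(model.parameters(), lr=hyper.lr, weight_decay=hyper.weight_decay)
    history = []
    best_val = np.inf
    best_state: list[np.ndarray] | None = None
    stale = 0

    for epoch in range(hyper.epochs):
        model.set_training(True)
        order = rng.permutation(len(y_tr))
        losses, hits, seen = [], 0, 0
        for start in range(0, len(order), hyper.batch_size):
            idx = order[start:start + hyper.batch_size]
            out = model.forward(x_tr[idx], rng=rng, mode="train")
            loss = model_loss(out, y_tr[idx], kl_weight)
            model.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            hits += int((out.probs.data.argmax(axis=1) == y_tr[idx]).sum())
            seen += len(idx)
        row = {
            "epoch": epoch,
            "train_loss": float(np.mean(losses)),
            "train_acc": hits / seen,
        }
        if len(val_idx):
            model.set_training(False)
            v_out = model.forward(x_val, mode="deterministic")
            v_loss = float(model_loss(v_out, y_val, kl_weight).data)
            row["val_loss"] = v_loss
            row["val_acc"] = float((v_out.probs.data.argmax(axis=1) == y_val).mean())
            if v_loss < best_val - 1e-6:
                best_val, stale = v_loss, 0
                best_state = [a.copy() for a in model.state_arrays()]
            else:
                stale += 1
            if stale >= hyper.patience:
                history.append(row)
                break
        history.append(row)

    if best_state is not None:
        model.load_state_arrays(best_state)
    model.set_training(False)
    return model, pd.DataFrame(history)


def predict_proba(model: Module, segments: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """Deterministic class probabilities (S = mu), batched."""
    model.set_training(False)
    chunks = [
        model.forward(segments[i:i + batch_size], mode="deterministic").probs.data
        for i in range(0, len(segments), batch_size)
    ]
    return np.concatenate(chunks) if chunks else np.empty((0, 2))


def evaluate(model: Module, test_set: SegmentSet) -> dict[str, float]:
    """Accuracy, precision, recall, F1 and AUC of deterministic predictions.

    AUC is undefined when the test fold holds a single class; it is then
    reported as NaN (missing), never as zero.
    """
    if len(test_set) == 0:
        raise ValueError("empty test set")
    probs = predict_proba(model, test_set.segments.astype(np.float32))
    return compute_metrics(test_set.labels, probs[:, 1])


def compute_metrics(labels: np.ndarray, scores: np.ndarray) -> dict[str, float]:
    """Binary classification metrics from positive-class scores."""
    labels = np.asarray(labels, dtype=int)
    preds = (np.asarray(scores) >= 0.5).astype(int)
    out = {
        "accuracy": float((preds == labels).mean()),
        "precision": float(precision_score(labels, preds, zero_division=0)),
        "recall": float(recall_score(labels, preds, zero_division=0)),
        "f1": float(f1_score(labels, preds, zero_division=0)),
    }
    if len(np.unique(labels)) < 2:
        out["auc"] = float("nan")
    else:
        out["auc"] = float(roc_auc_score(labels, scores))
    return out


# ---------------------------------------------------------------------------
# Cross-validation


def kfold_split(
    segments: SegmentSet,
    k: int = 10,
    seed: int = 0,
    strategy: str = "segment",
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Disjoint, exhaustive (train, test) index pairs.

    ``strategy="segment"`` stratifies folds by label (may leak overlapping
    windows of one recording across folds — see docs); ``"subject"`` keeps
    every segment of a subject in a single fold (GroupKFold).
    """
    n = len(segments)
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} segments")
    if strategy == "segment":
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return [
            (tr, te)
            for tr, te in splitter.split(np.zeros(n), segments.labels)
        ]
    if strategy == "subject":
        splitter = GroupKFold(n_splits=k)
        return [
            (tr, te)
            for tr, te in splitter.split(np.zeros(n), segments.labels, segments.subject_ids)
        ]
    raise ValueError("strategy must be 'segment' or 'subject'")


@dataclass
class CVReport:
    """Cross-validation outcome: per-fold metrics and their means."""

    per_fold: pd.DataFrame
    folds: list[tuple[np.ndarray, np.ndarray]]
    seed: int
    config: dict = field(default_factory=dict)

    @property
    def means(self) -> dict[str, float]:
        return {
            m: float(np.nanmean(self.per_fold[m].to_numpy()))
            for m in METRIC_NAMES
        }


def cross_validate(
    dataset: SegmentSet,
    model_factory: Callable[[], Module] | ModelConfig,
    hyper: TrainConfig = TrainConfig(),
    k: int = 10,
    seed: int = 0,
    strategy: str = "segment",
) -> CVReport:
    """k-fold CV: train a fresh model per fold, evaluate on the held-out fold."""
    folds = kfold_split(dataset, k=k, seed=seed, strategy=strategy)
    rows = []
    for fold_idx, (tr, te) in enumerate(folds):
        if isinstance(model_factory, ModelConfig):
            model: Module = DUFormer(model_factory)
        else:
            model = model_factory()
        model, _ = train(model, dataset.subset(tr), hyper)
        metrics = evaluate(model, dataset.subset(te))
        rows.append({"fold": fold_idx, **metrics})
    cfg = asdict(model_factory) if isinstance(model_factory, ModelConfig) else {}
    return CVReport(pd.DataFrame(rows), folds, seed, {"model": cfg, "train": asdict(hyper)})


# ---------------------------------------------------------------------------
# Experiment runners


def run_band_experiment(
    band_datasets: Mapping[str, SegmentSet],
    model_config: ModelConfig,
    hyper: TrainConfig = TrainConfig(),
    k: int = 10,
    seed: int = 0,
    strategy: str = "segment",
) -> pd.DataFrame:
    """Per-band k-fold CV table (one row per band, mean metrics)."""
    if not band_datasets:
        raise ValueError("no bands supplied")
    rows = []
    for band, dataset in band_datasets.items():
        report = cross_validate(dataset, model_config, hyper, k=k, seed=seed, strategy=strategy)
        rows.append({"band": band, **report.means})
    return pd.DataFrame(rows)


ABLATION_VARIANTS: dict[str, dict[str, bool]] = {
    "full": {},
    "no_smhsa": {"use_smhsa": False},
    "no_reparam": {"use_reparam": False},
}


def run_ablation(
    dataset: SegmentSet,
    model_config: ModelConfig,
    hyper: TrainConfig = TrainConfig(),
    k: int = 10,
    seed: int = 0,
    band: str | None = None,
) -> pd.DataFrame:
    """Evaluate {full, no-SMHSA, no-reparameterization} under identical folds."""
    rows = []
    for variant, flags in ABLATION_VARIANTS.items():
        cfg = model_config.with_ablation(**flags) if flags else model_config
        report = cross_validate(dataset, cfg, hyper, k=k, seed=seed)
        rows.append({"band": band or dataset.band, "variant": variant, **report.means})
    return pd.DataFrame(rows)


def run_comparison(
    dataset: SegmentSet,
    model_config: ModelConfig,
    hyper: TrainConfig = TrainConfig(),
    k: int = 10,
    seed: int = 0,
    baselines: Sequence[str] = ("cnn", "eegnet_like", "plain_transformer"),
) -> pd.DataFrame:
    """DU-former vs the baseline models under identical folds."""
    from .baselines import baseline_factory

    rows = []
    report = cross_validate(dataset, model_config, hyper, k=k, seed=seed)
    rows.append({"band": dataset.band, "model": "duformer", **report.means})
    for name in baselines:
        ctor = baseline_factory(name)
        report = cross_validate(
            dataset, lambda ctor=ctor: ctor(model_config), hyper, k=k, seed=seed
        )
        rows.append({"band": dataset.band, "model": name, **report.means})
    return pd.DataFrame(rows)
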