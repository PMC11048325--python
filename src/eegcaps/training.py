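"""Training and evaluation protocol.

Cross-entropy loss, Adam, stratified 10-fold cross-validation at the
recognition-cycle-sample level, and confusion-matrix metrics (accuracy and
macro-averaged precision / recall / F1, reported as percentages to two
decimals, per fold and as mean +/- sd).

Leakage control: per-feature-channel normalization statistics are fitted on
the training portion of each fold only and then applied, frozen, to the test
portion; model initialization and batch order derive from per-fold seeds
spawned from the master seed, so a whole cross-validation run is
reproducible bit-for-bit from one integer.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold

from .feature_map import NormalizationStats
from .model import EmotionCapsTransformer, ModelConfig
from .nn import Adam, Tensor, cross_entropy

__all__ = [
    "TrainConfig",
    "TrainingError",
    "TrainResult",
    "kfold_split",
    "fit_sample_normalization",
    "apply_sample_normalization",
    "train_fold",
    "evaluate",
    "metrics_from_confusion",
    "run_cv",
    "report_to_json",
]


class TrainingError(RuntimeError):
    """Raised on divergence (non-finite loss) with diagnostics attached."""


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3   # 1e-3 for DEAP-style runs, 1e-4 for SEED-style
    batch_size: int = 128
    max_epochs: int = 100
    n_folds: int = 10
    seed: int = 0
    early_stop_patience: int | None = 10
    val_fraction: float = 0.1     # training-fold carve-out used for early stopping

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def kfold_split(y: np.ndarray, n_folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shuffled, stratified, near-equal partition at the sample level."""
    y = np.asarray(y, dtype=int)
    if len(y) < n_folds:
        raise ValueError(f"need at least {n_folds} samples, got {len(y)}")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=int(seed) % (2**31))
    return [(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)]


def fit_sample_normalization(X: np.ndarray, mask: np.ndarray) -> NormalizationStats:
    """Per-feature-channel mean/sd over occupied cells of training samples.

    ``X``: (n, T, 3, 16, 18); ``mask``: (16, 18) bool of electrode cells.
    """
    vals = X[:, :, :, mask]  # (n, T, 3, n_occ)
    mean = vals.mean(axis=(0, 1, 3))
    sd = vals.std(axis=(0, 1, 3))
    return NormalizationStats(mean=mean, sd=sd, mask=np.asarray(mask, dtype=bool))


def apply_sample_normalization(X: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    out = np.zeros_like(X, dtype=np.float64)
    sd = np.where(stats.sd > 0, stats.sd, 1.0)
    mean = np.where(stats.sd > 0, stats.mean, 0.0)
    out[:, :, :, stats.mask] = (
        X[:, :, :, stats.mask] - mean[None, None, :, None]
    ) / sd[None, None, :, None]
    return out


@dataclass
class TrainResult:
    state: dict[str, np.ndarray]
    loss_curve: list[float]
    initial_loss: float
    stats: NormalizationStats | None
    train_accuracy: float
    val_curve: list[float] = field(default_factory=list)
    stopped_epoch: int | None = None


def _epoch(model, opt, X, y, batch_size, rng) -> float:
    order = rng.permutation(len(X))
    total, count = 0.0, 0
    for start in range(0, len(X), batch_size):
        idx = order[start:start + batch_size]
        logits = model.forward(X[idx])
        loss = cross_entropy(logits, y[idx])
        if not np.isfinite(loss.data):
            raise TrainingError(
                f"non-finite loss {float(loss.data)} at step {count}; "
                f"lr or initialization likely too aggressive"
            )
        opt.zero_grad()
        loss.backward()
        opt.step()
        total += float(loss.data) * len(idx)
        count += len(idx)
    return total / count


def _mean_loss(model, X, y, batch_size: int = 256) -> float:
    was = model.training
    model.eval()
    try:
        total = 0.0
        for start in range(0, len(X), batch_size):
            logits = model.forward(X[start:start + batch_size])
            total += float(cross_entropy(logits, y[start:start + batch_size]).data) \
                * (min(start + batch_size, len(X)) - start)
        return total / len(X)
    finally:
        model.train(was)


def train_fold(
    X: np.ndarray,
    y: np.ndarray,
    model_cfg: ModelConfig,
    cfg: TrainConfig,
    mask: np.ndarray | None = None,
    fold_seed: int | None = None,
) -> TrainResult:
    """Train one model on one training fold.

    Normalization statistics are fitted here, on this fold's training data
    only, and returned with the checkpoint so evaluation applies the same
    frozen transform.  The best checkpoint is the epoch with the lowest
    training loss, or the lowest validation loss when an early-stopping
    carve-out is configured.
    """
    y = np.asarray(y, dtype=int)
    seed = cfg.seed if fold_seed is None else fold_seed
    seq = np.random.SeedSequence(seed)
    batch_rng, val_rng = [np.random.default_rng(s) for s in seq.spawn(2)]

    stats = None
    if mask is not None:
        stats = fit_sample_normalization(X, mask)
        X = apply_sample_normalization(X, stats)

    X_val = y_val = None
    if cfg.early_stop_patience is not None and cfg.val_fraction > 0:
        n_val = max(1, int(round(cfg.val_fraction * len(X))))
        order = val_rng.permutation(len(X))
        val_idx, tr_idx = order[:n_val], order[n_val:]
        X_val, y_val = X[val_idx], y[val_idx]
        X, y = X[tr_idx], y[tr_idx]

    model = EmotionCapsTransformer(dataclasses.replace(model_cfg, seed=seed))
    opt = Adam(model.parameters(), lr=cfg.learning_rate)

    initial_loss = _mean_loss(model, X, y)
    best_loss = np.inf
    best_state = model.state_dict()
    loss_curve: list[float] = []
    val_curve: list[float] = []
    patience_left = cfg.early_stop_patience
    stopped = None
    for epoch in range(cfg.max_epochs):
        model.train()
        train_loss = _epoch(model, opt, X, y, cfg.batch_size, batch_rng)
        loss_curve.append(train_loss)
        monitor = train_loss
        if X_val is not None:
            val_loss = _mean_loss(model, X_val, y_val)
            val_curve.append(val_loss)
            monitor = val_loss
        if monitor < best_loss - 1e-12:
            best_loss = monitor
            best_state = model.state_dict()
            patience_left = cfg.early_stop_patience
        elif cfg.early_stop_patience is not None:
            patience_left -= 1
            if patience_left <= 0:
                stopped = epoch
                break

    model.load_state_dict(best_state)
    train_acc = float(np.mean(model.predict(X) == y))
    return TrainResult(
        state=best_state, loss_curve=loss_curve, initial_loss=initial_loss,
        stats=stats, train_accuracy=train_acc, val_curve=val_curve,
        stopped_epoch=stopped,
    )


def metrics_from_confusion(cm: np.ndarray) -> dict[str, float]:
    """Accuracy and macro precision/recall/F1 (%) from a confusion matrix.

    Rows are true classes, columns predicted.
    """
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    acc = np.trace(cm) / total
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(cm.sum(axis=0) > 0, np.diag(cm) / cm.sum(axis=0), 0.0)
        rec = np.where(cm.sum(axis=1) > 0, np.diag(cm) / cm.sum(axis=1), 0.0)
        f1 = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0.0)
    return {
        "accuracy": 100.0 * acc,
        "precision": 100.0 * prec.mean(),
        "recall": 100.0 * rec.mean(),
        "f1": 100.0 * f1.mean(),
    }


def evaluate(
    model: EmotionCapsTransformer,
    X_test: np.ndarray,
    y_test: np.ndarray,
    stats: NormalizationStats | None = None,
    n_classes: int | None = None,
) -> dict:
    """Confusion matrix and summary metrics on a held-out test set."""
    if len(X_test) == 0:
        raise ValueError("empty test set")
    y_test = np.asarray(y_test, dtype=int)
    if stats is not None:
        X_test = apply_sample_normalization(X_test, stats)
    pred = model.predict(X_test)
    k = n_classes or model.cfg.capsnet.n_classes
    labels = np.arange(k)
    cm = _sk_confusion(y_test, pred, labels=labels)
    # cross-check our arithmetic against sklearn's implementation
    own = metrics_from_confusion(cm)
    p, r, f, _ = precision_recall_fscore_support(
        y_test, pred, labels=labels, average="macro", zero_division=0
    )
    assert abs(own["precision"] - 100 * p) < 1e-9
    assert abs(own["recall"] - 100 * r) < 1e-9
    assert abs(own["f1"] - 100 * f) < 1e-9
    row_sums = cm.sum(axis=1, keepdims=True)
    cm_norm = np.where(row_sums > 0, cm / np.maximum(row_sums, 1), 0.0)
    return {
        **{key: round(v, 2) for key, v in own.items()},
        "confusion": cm.tolist(),
        "confusion_row_normalized": np.round(cm_norm, 6).tolist(),
        "n_test": int(len(y_test)),
    }


def run_cv(
    X: np.ndarray,
    y: np.ndarray,
    model_cfg: ModelConfig,
    cfg: TrainConfig,
    mask: np.ndarray | None = None,
) -> dict:
    """Full cross-validation: split -> train per fold -> evaluate -> aggregate.

    Returns a JSON-serializable report with per-fold metrics, loss curves,
    aggregate mean +/- sd, and the seeds/configs needed for an exact rerun.
    """
    y = np.asarray(y, dtype=int)
    folds = kfold_split(y, cfg.n_folds, cfg.seed)
    fold_seeds = [int(s.generate_state(1)[0] % (2**31))
                  for s in np.random.SeedSequence(cfg.seed).spawn(cfg.n_folds)]
    fold_reports = []
    for f, (tr, te) in enumerate(folds):
        res = train_fold(X[tr], y[tr], model_cfg, cfg, mask=mask, fold_seed=fold_seeds[f])
        model = EmotionCapsTransformer(dataclasses.replace(model_cfg, seed=fold_seeds[f]))
        model.load_state_dict(res.state)
        rep = evaluate(model, X[te], y[te], stats=res.stats)
        rep.update({
            "fold": f,
            "seed": fold_seeds[f],
            "initial_loss": round(res.initial_loss, 6),
            "final_train_loss": round(res.loss_curve[-1], 6),
            "train_accuracy": round(100 * res.train_accuracy, 2),
            "loss_curve": [round(v, 6) for v in res.loss_curve],
        })
        fold_reports.append(rep)

    summary = {}
    for key in ("accuracy", "precision", "recall", "f1"):
        vals = np.array([r[key] for r in fold_reports])
        summary[key] = {"mean": round(float(vals.mean()), 2),
                        "sd": round(float(vals.std()), 2)}
    return {
        "config": {
            "learning_rate": cfg.learning_rate,
            "batch_size": cfg.batch_size,
            "max_epochs": cfg.max_epochs,
            "n_folds": cfg.n_folds,
            "seed": cfg.seed,
            "early_stop_patience": cfg.early_stop_patience,
            "n_samples": int(len(y)),
            "n_classes": int(model_cfg.capsnet.n_classes),
            "use_eca": model_cfg.capsnet.use_eca,
            "use_se": model_cfg.capsnet.use_se,
            "use_transformer": model_cfg.use_transformer,
        },
        "folds": fold_reports,
        "summary": summary,
    }


def report_to_json(report: dict) -> str:
    """Canonical serialization; identical reports yield identical bytes."""
    return json.dumps(report, sort_keys=True, indent=2)
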