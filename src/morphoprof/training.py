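"""Weakly supervised treatment classification (the pretext task).

A classifier is trained to recognize the treatment applied to single cells —
a weak label, since treatments need not produce a (distinct) phenotype and
labels have no single-cell resolution. The representation learned on the way
is what downstream profiling consumes.

Training follows the screen-scale recipe at desk scale: median-balanced
epoch sampling, per-crop augmentation, mini-batches of 32, plain SGD at
learning rate 0.005 for 30 epochs, categorical cross-entropy with label
smoothing 0.1, and optional Online Label Smoothing (OLS) which blends each
epoch's predicted label distribution into the targets.

Backbones: ``toy_cnn`` trains end-to-end; ``efficientnet_b0`` trains a
linear probe (softmax head) on frozen backbone features, which keeps the
desk-scale CPU budget while preserving the feature-extraction contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import nn
from .cells import SplitAssignment, augment_crop, balanced_epoch_sample

__all__ = [
    "TrainingConfig",
    "TrainedModel",
    "train_classifier",
    "ols_update",
    "pretext_report",
    "save_model",
    "load_model",
    "AttentionMILHead",
    "train_mil_head",
]


@dataclass
class TrainingConfig:
    backbone: str = "toy_cnn"  # "toy_cnn" | "efficientnet_b0"
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 0.005
    ols_enabled: bool = False
    ols_alpha: float = 0.03
    label_smoothing: float = 0.1
    widths: tuple[int, ...] = (16, 32, 64, 64)
    augment: bool = True
    eval_cap: int = 4000  # max cells scored per partition per epoch
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.ols_alpha <= 1:
            raise ValueError("ols_alpha must be in [0, 1]")
        if not 0 <= self.label_smoothing < 1:
            raise ValueError("label_smoothing must be in [0, 1)")
        if self.backbone not in ("toy_cnn", "efficientnet_b0"):
            raise ValueError(f"unknown backbone {self.backbone!r}")


@dataclass
class TrainedModel:
    """A trained backbone plus its class list and declared feature layer."""

    backbone_name: str
    network: object  # ToyCNN, or (EfficientNetB0, Dense head) for the probe
    classes: list[str]
    feature_layer: str
    log: pd.DataFrame
    config: TrainingConfig | None = None
    # global input standardization fitted on the training crops
    input_mean: float = 0.0
    input_std: float = 1.0

    def standardize(self, crops: np.ndarray) -> np.ndarray:
        return (np.asarray(crops, dtype=np.float32) - self.input_mean) / self.input_std

    def predict_proba(self, crops: np.ndarray, batch_size: int = 64) -> np.ndarray:
        x = self.standardize(crops)
        if self.backbone_name == "toy_cnn":
            return self.network.predict_proba(x, batch_size=batch_size)
        b0, head = self.network
        feats = _b0_pooled_features(b0, x, self.feature_layer)
        return nn.softmax(head.forward(feats))

    def predict(self, crops: np.ndarray) -> np.ndarray:
        proba = self.predict_proba(crops)
        return np.array([self.classes[i] for i in proba.argmax(axis=1)])


def ols_update(
    l_hard: np.ndarray, l_soft: np.ndarray, alpha: float
) -> np.ndarray:
    """Online-label-smoothing update: ``alpha * L_hard + (1 - alpha) * L_soft``.

    At the start of training ``l_hard`` is the ground-truth label
    distribution; in later epochs it is the label produced by the previous
    update, while ``l_soft`` is the distribution predicted at the end of the
    finished epoch. Inputs must be distributions over the same classes.
    """
    l_hard = np.asarray(l_hard, dtype=float)
    l_soft = np.asarray(l_soft, dtype=float)
    if l_hard.shape != l_soft.shape:
        raise ValueError(
            f"mismatched class sets: {l_hard.shape} vs {l_soft.shape}"
        )
    return alpha * l_hard + (1.0 - alpha) * l_soft


def _smooth_onehot(labels_idx: np.ndarray, n_classes: int, smoothing: float) -> np.ndarray:
    out = np.full((len(labels_idx), n_classes), smoothing / n_classes)
    out[np.arange(len(labels_idx)), labels_idx] += 1.0 - smoothing
    return out


def _b0_pooled_features(b0, crops: np.ndarray, layer: str, batch_size: int = 16) -> np.ndarray:
    feats = []
    for i in range(0, len(crops), batch_size):
        act = b0.forward_features(crops[i : i + batch_size], layer=layer)
        feats.append(act.mean(axis=(1, 2)))
    return np.concatenate(feats) if feats else np.zeros((0, b0.feature_dim(layer)))


def _macro_f1(y_true: np.ndarray, y_pred: np.ndarray, classes: Sequence) -> float:
    from sklearn.metrics import f1_score

    present = [c for c in classes if (y_true == c).any()]
    if not present:
        return float("nan")
    return float(f1_score(y_true, y_pred, labels=present, average="macro", zero_division=0))


def train_classifier(
    cell_index: pd.DataFrame,
    crops: np.ndarray,
    split: SplitAssignment,
    cfg: TrainingConfig,
) -> TrainedModel:
    """Train the weakly supervised single-cell treatment classifier.

    ``crops`` must be aligned row-for-row with ``cell_index`` (values in
    [0, 1]). Each epoch draws a median-balanced sample of training cells,
    augments every crop and sweeps mini-batches with SGD; training and
    validation macro-F1 are logged per epoch. ``epochs=0`` returns the
    initialized model with an empty log.
    """
    cell_index = cell_index.reset_index(drop=True)
    classes = sorted(cell_index["Treatment"].unique())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to train a classifier")
    class_to_idx = {c: i for i, c in enumerate(classes)}
    n_classes = len(classes)

    tags = split.tags.loc[cell_index["Cell_Id"]].to_numpy()
    train_mask = tags == "train"
    val_mask = tags == "val"
    if not val_mask.any():
        import warnings

        warnings.warn("empty validation split; learning curves are train-only")

    train_index = cell_index.loc[train_mask].reset_index(drop=True)
    row_of_id = pd.Series(np.arange(len(cell_index)), index=cell_index["Cell_Id"])
    y_idx_all = cell_index["Treatment"].map(class_to_idx).to_numpy()

    rng = np.random.default_rng(cfg.seed)

    in_mean = float(crops[train_mask].mean()) if train_mask.any() else 0.0
    in_std = float(crops[train_mask].std()) + 1e-6 if train_mask.any() else 1.0
    xstd = ((crops - in_mean) / in_std).astype(np.float32)

    if cfg.backbone == "toy_cnn":
        model = nn.ToyCNN(
            n_channels=crops.shape[-1], n_classes=n_classes, widths=cfg.widths, seed=cfg.seed
        )
        feature_layer = nn.ToyCNN.FEATURE_LAYER
        net = model
        train_feats = None
    else:
        b0 = nn.EfficientNetB0(n_input_channels=crops.shape[-1], seed=cfg.seed)
        feature_layer = nn.EfficientNetB0.FEATURE_LAYER
        head = nn.Dense(np.random.default_rng(cfg.seed), b0.feature_dim(feature_layer), n_classes)
        net = (b0, head)
        train_feats = _b0_pooled_features(b0, xstd, feature_layer)

    # per-cell OLS label state over training cells (ground truth to start)
    labels_state = _smooth_onehot(y_idx_all, n_classes, cfg.label_smoothing)

    log_rows = []
    model_out = TrainedModel(
        backbone_name=cfg.backbone,
        network=net,
        classes=classes,
        feature_layer=feature_layer,
        log=pd.DataFrame(columns=["epoch", "loss", "train_f1", "val_f1"]),
        config=cfg,
        input_mean=in_mean,
        input_std=in_std,
    )
    if cfg.epochs == 0:
        return model_out

    if cfg.backbone == "toy_cnn":
        opt = nn.SGD(model.parameters(), lr=cfg.learning_rate)
    else:
        opt = nn.SGD(head.params, lr=cfg.learning_rate)

    eval_rng = np.random.default_rng(cfg.seed + 1)

    def _partition_eval(mask: np.ndarray) -> float:
        rows = np.flatnonzero(mask)
        if len(rows) == 0:
            return float("nan")
        if len(rows) > cfg.eval_cap:
            rows = eval_rng.choice(rows, size=cfg.eval_cap, replace=False)
        if cfg.backbone == "toy_cnn":
            proba = model.predict_proba(xstd[rows])
        else:
            proba = nn.softmax(head.forward(train_feats[rows]))
        y_pred = np.array([classes[i] for i in proba.argmax(axis=1)])
        y_true = cell_index["Treatment"].to_numpy()[rows]
        return _macro_f1(y_true, y_pred, classes)

    for epoch in range(cfg.epochs):
        epoch_seed = int(rng.integers(0, 2**31 - 1))
        epoch_ids = balanced_epoch_sample(train_index, seed=epoch_seed)
        epoch_rows = row_of_id.loc[epoch_ids].to_numpy()
        aug_rng = np.random.default_rng(epoch_seed + 1)

        losses = []
        for i in range(0, len(epoch_rows), cfg.batch_size):
            rows = epoch_rows[i : i + cfg.batch_size]
            targets = labels_state[rows]
            if cfg.backbone == "toy_cnn":
                if cfg.augment:
                    # augment in raw [0, 1] space, then standardize
                    batch = np.stack([augment_crop(crops[r], aug_rng) for r in rows])
                    batch = (batch - in_mean) / in_std
                else:
                    batch = xstd[rows]
                logits = model.forward(batch)
                loss, dlogits = nn.cross_entropy(logits, targets)
                model.backward_from_logits(dlogits)
            else:
                feats = train_feats[rows]
                logits = head.forward(feats)
                loss, dlogits = nn.cross_entropy(logits, targets)
                head.backward(dlogits)
            opt.step()
            losses.append(loss)

        if cfg.ols_enabled:
            # predicted distribution at epoch end for every training cell
            tr_rows = np.flatnonzero(train_mask)
            if cfg.backbone == "toy_cnn":
                soft = model.predict_proba(xstd[tr_rows])
            else:
                soft = nn.softmax(head.forward(train_feats[tr_rows]))
            labels_state[tr_rows] = ols_update(
                labels_state[tr_rows], soft, cfg.ols_alpha
            )

        log_rows.append(
            {
                "epoch": epoch + 1,
                "loss": float(np.mean(losses)),
                "train_f1": _partition_eval(train_mask),
                "val_f1": _partition_eval(val_mask),
            }
        )

    model_out.log = pd.DataFrame(log_rows)
    return model_out


def pretext_report(
    model: TrainedModel,
    cell_index: pd.DataFrame,
    crops: np.ndarray,
    split: SplitAssignment,
    partition: str = "val",
) -> pd.DataFrame:
    """Per-class precision/recall on one partition of the pretext task.

    Classes absent from the partition are flagged ``missing`` (precision and
    recall reported as NaN, never as zero). The frame's ``attrs['macro_f1']``
    carries the macro F1 over present classes.
    """
    cell_index = cell_index.reset_index(drop=True)
    tags = split.tags.loc[cell_index["Cell_Id"]].to_numpy()
    rows = np.flatnonzero(tags == partition)
    if len(rows) == 0:
        raise ValueError(f"partition {partition!r} is empty")
    y_true = cell_index["Treatment"].to_numpy()[rows]
    y_pred = model.predict(crops[rows])

    records = []
    for c in model.classes:
        tp = int(((y_pred == c) & (y_true == c)).sum())
        fp = int(((y_pred == c) & (y_true != c)).sum())
        fn = int(((y_pred != c) & (y_true == c)).sum())
        missing = (y_true == c).sum() == 0
        precision = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
        recall = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
        records.append(
            {
                "Treatment": c,
                "precision": float("nan") if missing else precision,
                "recall": float("nan") if missing else recall,
                "support": int((y_true == c).sum()),
                "missing": bool(missing),
            }
        )
    report = pd.DataFrame(records)
    report.attrs["macro_f1"] = _macro_f1(y_true, y_pred, model.classes)
    return report


def save_model(model: TrainedModel, path) -> None:
    """Checkpoint a toy-CNN model: weights + class list + feature layer.

    Stored as a compressed array archive with an embedded JSON header.
    """
    import json
    from pathlib import Path

    if model.backbone_name != "toy_cnn":
        raise ValueError("checkpointing is implemented for the toy_cnn backbone")
    net = model.network
    arrays = {}
    for i, (w, _) in enumerate(net.parameters()):
        arrays[f"param_{i}"] = w
    header = {
        "backbone": model.backbone_name,
        "classes": model.classes,
        "feature_layer": model.feature_layer,
        "widths": list(net.widths),
        "n_channels": net.n_channels,
        "input_mean": model.input_mean,
        "input_std": model.input_std,
    }
    np.savez_compressed(Path(path), header=json.dumps(header), **arrays)


def load_model(path) -> TrainedModel:
    """Load a :func:`save_model` checkpoint."""
    import json

    with np.load(path, allow_pickle=False) as z:
        header = json.loads(str(z["header"]))
        net = nn.ToyCNN(
            n_channels=int(header["n_channels"]),
            n_classes=len(header["classes"]),
            widths=tuple(header["widths"]),
            seed=0,
        )
        for i, (w, _) in enumerate(net.parameters()):
            w[...] = z[f"param_{i}"]
    return TrainedModel(
        backbone_name=header["backbone"],
        network=net,
        classes=list(header["classes"]),
        feature_layer=header["feature_layer"],
        log=pd.DataFrame(),
        input_mean=float(header["input_mean"]),
        input_std=float(header["input_std"]),
    )


# ---------------------------------------------------------------------------
# optional gated-attention MIL head (not part of the default pipeline)
# ---------------------------------------------------------------------------

class AttentionMILHead:
    """Gated attention pooling over bag member features + softmax classifier.

    a_i ~ exp(w^T (tanh(V h_i) * sigmoid(U h_i))); z = sum_i a_i h_i.
    Operates on frozen single-cell features.
    """

    def __init__(self, n_features: int, n_classes: int, attn_dim: int = 32, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.V = nn._he_dense(rng, n_features, attn_dim)
        self.U = nn._he_dense(rng, n_features, attn_dim)
        self.w = nn._he_dense(rng, attn_dim, 1)
        self.W = nn._he_dense(rng, n_features, n_classes)
        self.b = np.zeros(n_classes, dtype=np.float32)

    def forward(self, h: np.ndarray) -> tuple[np.ndarray, dict]:
        t = np.tanh(h @ self.V)
        s = nn.sigmoid(h @ self.U)
        g = t * s
        e = (g @ self.w)[:, 0]
        a = nn.softmax(e[None, :])[0]
        z = a @ h
        logits = z @ self.W + self.b
        return logits, {"h": h, "t": t, "s": s, "g": g, "a": a, "z": z}

    def backward(self, dlogits: np.ndarray, cache: dict, lr: float) -> None:
        h, t, s, g, a, z = (cache[k] for k in ("h", "t", "s", "g", "a", "z"))
        dW = np.outer(z, dlogits)
        db = dlogits
        dz = self.W @ dlogits
        da = h @ dz
        de = a * (da - float(a @ da))
        dg = de[:, None] * self.w[:, 0][None, :]
        dw = g.T @ de
        dt = dg * s
        ds = dg * t
        dpre_t = dt * (1 - t**2)
        dpre_s = ds * s * (1 - s)
        dV = h.T @ dpre_t
        dU = h.T @ dpre_s
        self.W -= lr * dW
        self.b -= lr * db
        self.w -= lr * dw[:, None]
        self.V -= lr * dV
        self.U -= lr * dU

    def predict_proba(self, h: np.ndarray) -> np.ndarray:
        logits, _ = self.forward(h)
        return nn.softmax(logits[None, :])[0]


def train_mil_head(
    features: np.ndarray,
    cell_ids: np.ndarray,
    bags,
    classes: Sequence[str],
    epochs: int = 50,
    learning_rate: float = 0.005,
    seed: int = 0,
) -> AttentionMILHead:
    """Train the attention-MIL classifier on frozen features (50 epochs)."""
    row_of_id = pd.Series(np.arange(len(cell_ids)), index=cell_ids)
    class_to_idx = {c: i for i, c in enumerate(classes)}
    head = AttentionMILHead(features.shape[1], len(classes), seed=seed)
    rng = np.random.default_rng(seed)
    for _ in range(epochs):
        order = rng.permutation(len(bags))
        for bi in order:
            bag = bags[bi]
            h = features[row_of_id.loc[bag.member_ids].to_numpy()]
            logits, cache = head.forward(h)
            target = np.zeros(len(classes))
            target[class_to_idx[bag.label]] = 1.0
            p = nn.softmax(logits[None, :])[0]
            head.backward(p - target, cache, lr=learning_rate)
    return head
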