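"""3D MBConv grading classifier and prognostic feature extractor.

The classifier is an EfficientNet-style backbone with every 2D operation
inflated to 3D (cubic kernels of the original size, strides replicated on
the depth axis, squeeze-excitation pooled over all three spatial axes).  At
the reference scale — compound width 2.0 / depth 3.1, the B7 scaling — the
adaptive-average-pooled feature vector has length 2560; that vector is what
feeds the survival model.  ``width_scale``/``depth_scale`` are expressed
relative to that reference so 1.0/1.0 is the full-size network and small
values give desk-scale models for testing.

Training follows cross-entropy over the four ISUP grades with Adam
(lr 1e-4), checkpointing the epoch with the best macro one-vs-rest AUC on
the validation set.
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from . import _nn
from .preprocess import PreparedSample

GRADES = (1, 2, 3, 4)

# EfficientNet-B0 stage table: (expand, channels, repeats, stride, kernel)
_BASE_STAGES = [
    (1, 16, 1, 1, 3),
    (6, 24, 2, 2, 3),
    (6, 40, 2, 2, 5),
    (6, 80, 3, 2, 3),
    (6, 112, 3, 1, 5),
    (6, 192, 4, 2, 5),
    (6, 320, 1, 1, 3),
]
_STEM_CHANNELS = 32
_HEAD_CHANNELS = 1280
_B7_WIDTH = 2.0
_B7_DEPTH = 3.1


def _round_filters(channels: int, width: float, divisor: int = 8) -> int:
    c = channels * width
    new = max(divisor, int(c + divisor / 2) // divisor * divisor)
    if new < 0.9 * c:
        new += divisor
    return int(new)


def _round_repeats(repeats: int, depth: float) -> int:
    return int(math.ceil(depth * repeats))


class GraderModel:
    """3D MBConv ISUP-grade classifier.

    Parameters
    ----------
    width_scale, depth_scale:
        Multipliers relative to the full-size (B7) network; must be > 0.
    in_channels:
        2 — the CT crop and the binary tumor mask.
    """

    def __init__(self, width_scale: float = 1.0, depth_scale: float = 1.0,
                 in_channels: int = 2, n_classes: int = 4, seed: int = 0):
        if width_scale <= 0 or depth_scale <= 0:
            raise ValueError("scales must be positive")
        rng = np.random.default_rng(seed)
        width = _B7_WIDTH * width_scale
        depth = _B7_DEPTH * depth_scale

        layers: list[_nn.Layer] = []
        stem = _round_filters(_STEM_CHANNELS, width)
        layers += [_nn.Conv3d(in_channels, stem, 3, stride=2, rng=rng),
                   _nn.BatchNorm(stem, spatial=True), _nn.SiLU()]
        c_in = stem
        stride_product = 2
        for expand, channels, repeats, stride, kernel in _BASE_STAGES:
            c_out = _round_filters(channels, width)
            for r in range(_round_repeats(repeats, depth)):
                s = stride if r == 0 else 1
                stride_product *= s if r == 0 else 1
                layers.append(_nn.MBConv(c_in, c_out, kernel, s, expand, rng))
                c_in = c_out
        head = _round_filters(_HEAD_CHANNELS, width)
        layers += [_nn.Conv3d(c_in, head, 1, rng=rng),
                   _nn.BatchNorm(head, spatial=True), _nn.SiLU(),
                   _nn.GlobalAvgPool3d()]
        self.backbone = _nn.Sequential(layers)
        self.head = _nn.Linear(head, n_classes, rng)
        self.feature_dim = head
        self.n_classes = n_classes
        self.in_channels = in_channels
        self.min_spatial = stride_product
        self.width_scale, self.depth_scale = width_scale, depth_scale

    # -- forward ------------------------------------------------------------
    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 4:
            x = x[None]
        if x.ndim != 5 or x.shape[1] != self.in_channels:
            raise ValueError("input must be (N, C, D, H, W)")
        if min(x.shape[2:]) < self.min_spatial:
            raise ValueError(
                f"spatial extents must be >= {self.min_spatial} "
                f"(total stride product), got {x.shape[2:]}")
        return x

    def features(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Flattened adaptive-average-pooled features, shape (N, feature_dim)."""
        return self.backbone.forward(self._check_input(x), train)

    def logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.head.forward(self.features(x, train), train)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return _nn.softmax(self.logits(x, train=False))

    def params(self) -> list[_nn.Param]:
        return self.backbone.params() + self.head.params()

    def state_arrays(self) -> list[np.ndarray]:
        return ([p.value for p in self.params()]
                + self.backbone.buffers() + self.head.buffers())

    def backward(self, grad_logits: np.ndarray) -> None:
        self.backbone.backward(self.head.backward(grad_logits))


def build_grader(width_scale: float = 1.0, depth_scale: float = 1.0,
                 seed: int = 0) -> GraderModel:
    return GraderModel(width_scale, depth_scale, seed=seed)


def cross_entropy_loss(probs, true_class: int) -> float:
    """Multiclass cross-entropy ``-log p_true`` for one prediction.

    ``probs`` is a length-4 simplex vector and ``true_class`` a 1-based ISUP
    grade.  Probabilities are clamped at 1e-12 so an exact zero at the true
    class yields a large finite loss instead of an overflow.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 1 or not np.isclose(probs.sum(), 1.0, atol=1e-6):
        raise ValueError("probs must be a simplex vector")
    if not 1 <= true_class <= probs.size:
        raise ValueError("true_class out of range")
    p = probs[true_class - 1]
    if p <= 0:
        warnings.warn("zero probability at the true class; clamping")
    return float(-np.log(max(p, 1e-12)))


def _stack(samples: list[PreparedSample]):
    x = np.stack([s.channels for s in samples]).astype(np.float32)
    y = np.array([s.grade for s in samples])
    return x, y


def _mean_ovr_auc(probs: np.ndarray, y: np.ndarray) -> float:
    """Macro one-vs-rest AUC over the grades present in ``y``."""
    present = np.unique(y)
    if present.size < 2:
        raise ValueError("validation set must contain at least 2 classes for AUC")
    aucs = []
    for g in present:
        aucs.append(roc_auc_score((y == g).astype(int), probs[:, g - 1]))
    return float(np.mean(aucs))


def train_grader(model: GraderModel, train_set: list[PreparedSample],
                 val_set: list[PreparedSample], epochs: int = 50,
                 lr: float = 1e-4, batch_size: int = 2,
                 seed: int = 0) -> tuple[GraderModel, pd.DataFrame]:
    """Train with cross-entropy/Adam, keeping the best validation-AUC epoch.

    Returns the model restored to its best checkpoint and a per-epoch log
    with columns ``epoch``, ``train_loss``, ``val_auc``.
    """
    if not train_set or not val_set:
        raise ValueError("train and validation sets must be non-empty")
    x_tr, y_tr = _stack(train_set)
    x_va, y_va = _stack(val_set)
    if np.unique(y_va).size < 2:
        raise ValueError("validation set must contain at least 2 classes")
    onehot = np.eye(model.n_classes, dtype=np.float32)[y_tr - 1]
    params = model.params()
    state = model.state_arrays()
    opt = _nn.Adam(params, lr)
    rng = np.random.default_rng(seed)
    best_auc, best_state, log = -np.inf, _nn.snapshot(state), []
    for epoch in range(epochs):
        order = rng.permutation(len(train_set))
        losses = []
        for start in range(0, len(order), batch_size):
            idx = order[start:start + batch_size]
            opt.zero_grad()
            logits = model.logits(x_tr[idx], train=True)
            loss, grad = _nn.cross_entropy_logits(logits, onehot[idx])
            model.backward(grad)
            opt.step()
            losses.append(loss)
        val_auc = _mean_ovr_auc(model.predict_proba(x_va), y_va)
        log.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                    "val_auc": val_auc})
        if val_auc > best_auc:
            best_auc = val_auc
            best_state = _nn.snapshot(state)
    _nn.restore(state, best_state)
    return model, pd.DataFrame(log)


# -- feature extraction ----------------------------------------------------

def extract_features(model: GraderModel, sample: PreparedSample) -> np.ndarray:
    """Inference-mode pooled feature vector for one sample (deterministic)."""
    return model.features(sample.channels[None], train=False)[0]


def extract_feature_table(model: GraderModel,
                          samples: list[PreparedSample]) -> pd.DataFrame:
    """One row per sample: patient_id index + ``feature_dim`` columns f0..fK."""
    rows = model.features(np.stack([s.channels for s in samples]), train=False)
    cols = [f"f{i:04d}" for i in range(model.feature_dim)]
    df = pd.DataFrame(rows, columns=cols)
    df.insert(0, "patient_id", [s.patient_id for s in samples])
    return df


def save_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def load_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# -- evaluation ------------------------------------------------------------

@dataclass
class ClassificationReport:
    confusion: np.ndarray                      # rows: truth, cols: prediction
    precision: dict[int, float]
    recall: dict[int, float]
    f1: dict[int, float]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    mean_auc: float | None
    missing_classes: tuple[int, ...] = ()


def classification_report(pred_probs, true_classes) -> ClassificationReport:
    """Per-grade precision/recall/F1 from the confusion matrix, macro averages,
    and macro one-vs-rest AUC.

    A grade absent from both truth and predictions has undefined metrics; it
    is reported as NaN and excluded from the macro averages with a warning.
    """
    probs = np.asarray(pred_probs, dtype=float)
    y = np.asarray(true_classes, dtype=int)
    if probs.shape[0] != y.shape[0]:
        raise ValueError("length mismatch")
    pred = probs.argmax(axis=1) + 1
    k = probs.shape[1]
    conf = np.zeros((k, k), dtype=int)
    for t, p in zip(y, pred):
        conf[t - 1, p - 1] += 1
    precision, recall, f1, missing = {}, {}, {}, []
    for g in range(1, k + 1):
        tp = conf[g - 1, g - 1]
        fp = conf[:, g - 1].sum() - tp
        fn = conf[g - 1].sum() - tp
        if tp + fp + fn == 0:
            precision[g] = recall[g] = f1[g] = float("nan")
            missing.append(g)
            continue
        precision[g] = tp / (tp + fp) if tp + fp else 0.0
        recall[g] = tp / (tp + fn) if tp + fn else 0.0
        denom = precision[g] + recall[g]
        f1[g] = 2 * precision[g] * recall[g] / denom if denom else 0.0
    if missing:
        warnings.warn(f"classes absent from truth and predictions: {missing}; "
                      "excluded from macro averages")
    rep = [g for g in range(1, k + 1) if g not in missing]
    try:
        mean_auc = _mean_ovr_auc(probs, y)
    except ValueError:
        mean_auc = None
    return ClassificationReport(
        confusion=conf,
        precision=precision, recall=recall, f1=f1,
        macro_precision=float(np.mean([precision[g] for g in rep])),
        macro_recall=float(np.mean([recall[g] for g in rep])),
        macro_f1=float(np.mean([f1[g] for g in rep])),
        mean_auc=mean_auc,
        missing_classes=tuple(missing),
    )
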