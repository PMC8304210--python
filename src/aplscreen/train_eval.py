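"""Training protocol and evaluation statistics for the leukocyte classifier.

Implements the stratified 5-fold protocol (three folds train, one
validation, one test, rotated so every fold is tested exactly once),
flip/rotation augmentation with minority oversampling, from-scratch SGD
training with the step learning-rate schedule, one-vs-rest classification
metrics with support-weighted averaging, ROC/AUC, and the Friedman /
Nemenyi rank comparison used to compare classifiers across matched
measurements.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2
from sklearn.model_selection import StratifiedKFold

from .compact_net.layers import F32, SGDMomentum, softmax_cross_entropy
from .compact_net.model import CLASS_NAMES, CompactNet, CompactNetConfig, build_model

logger = logging.getLogger("aplscreen.train")

__all__ = [
    "FoldSplit", "TrainConfig", "ConfusionMatrix", "MetricSet", "RankComparison",
    "stratified_kfold", "augment", "oversample_minority", "lr_at_epoch",
    "train_model", "confusion", "metrics_from_confusion", "roc_auc",
    "roc_curve_points", "friedman_test", "nemenyi_cd", "cross_validate",
]


# ---------------------------------------------------------------------------
# fold protocol
# ---------------------------------------------------------------------------

@dataclass
class FoldSplit:
    """Per-sample fold ids plus the train/val/test role rotation."""

    fold_of_sample: np.ndarray
    k: int = 5

    @property
    def round_roles(self) -> list[dict]:
        """Round r tests fold r, validates fold (r+1) % k, trains the rest."""
        roles = []
        for r in range(self.k):
            val = (r + 1) % self.k
            train = [f for f in range(self.k) if f not in (r, val)]
            roles.append({"train": train, "val": val, "test": r})
        return roles

    def indices(self, round_idx: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        roles = self.round_roles[round_idx]
        train = np.flatnonzero(np.isin(self.fold_of_sample, roles["train"]))
        val = np.flatnonzero(self.fold_of_sample == roles["val"])
        test = np.flatnonzero(self.fold_of_sample == roles["test"])
        return train, val, test


def stratified_kfold(labels, k: int = 5, seed: int = 0) -> FoldSplit:
    """Assign each sample to one of ``k`` folds, stratified by class.

    Per-class fold counts differ by at most one; deterministic given seed.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    for cls, cnt in zip(classes, counts):
        if cnt < k:
            raise ValueError(f"class {cls!r} has only {cnt} samples; needs >= {k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold = np.full(len(labels), -1, dtype=np.int64)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        fold[test_idx] = f
    return FoldSplit(fold_of_sample=fold, k=k)


# ---------------------------------------------------------------------------
# augmentation and imbalance handling
# ---------------------------------------------------------------------------

def augment(crop: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random horizontal/vertical flip plus rotation by a multiple of 90°.

    Right-angle rotations avoid interpolation artifacts and border fill, so
    the augmented crop stays a pixel-exact rearrangement of the original.
    """
    out = crop
    if rng.random() < 0.5:
        out = out[:, ::-1]
    if rng.random() < 0.5:
        out = out[::-1, :]
    out = np.rot90(out, k=int(rng.integers(0, 4)))
    return np.ascontiguousarray(out)


def oversample_minority(labels, rng: np.random.Generator) -> np.ndarray:
    """Index list where every class reaches the majority-class frequency.

    Balanced input yields a plain permutation; minority classes are sampled
    with replacement up to the majority size.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    target = counts.max()
    picked = []
    for cls, cnt in zip(classes, counts):
        idx = np.flatnonzero(labels == cls)
        if cnt == target:
            picked.append(idx)
        else:
            picked.append(np.concatenate([idx, rng.choice(idx, size=target - cnt,
                                                          replace=True)]))
    out = np.concatenate(picked)
    rng.shuffle(out)
    return out


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """From-scratch SGD recipe: momentum 0.9, initial learning rate 5e-3
    divided by 5 every 10 epochs."""

    optimizer: str = "sgd"
    momentum: float = 0.9
    initial_lr: float = 5e-3
    lr_decay_factor: float = 5.0
    lr_decay_every: int = 10
    epochs: int = 30
    batch_size: int = 32
    seed: int = 0
    augment: bool = True
    oversample: bool = True
    early_stop_val_acc: float | None = None


def lr_at_epoch(tc: TrainConfig, epoch: int) -> float:
    return tc.initial_lr / tc.lr_decay_factor ** (epoch // tc.lr_decay_every)


def _accuracy(model: CompactNet, crops: np.ndarray, labels: np.ndarray,
              batch_size: int) -> float:
    # inference has no gradient memory cost, so evaluate in larger batches
    return float((model.predict(crops, batch_size=max(batch_size, 32)) == labels).mean())


def train_model(
    config: CompactNetConfig,
    tc: TrainConfig,
    train_crops: np.ndarray,
    train_labels: np.ndarray,
    val_crops: np.ndarray | None = None,
    val_labels: np.ndarray | None = None,
) -> tuple[CompactNet, list[dict]]:
    """Train from scratch; return the best-validation checkpoint and a log.

    Input normalization statistics (per-channel mean/std of the training
    crops scaled to [0,1]) are frozen into the model. Checkpoint selection
    is by best validation accuracy, earliest epoch on ties; without a
    validation set the final weights are returned.
    """
    root = np.random.SeedSequence(tc.seed)
    ss_init, ss_epochs = root.spawn(2)
    model = build_model(config, rng=np.random.default_rng(ss_init))

    x01 = train_crops.astype(F32) / F32(255.0)
    model.input_mean = x01.mean(axis=(0, 1, 2))
    model.input_std = np.maximum(x01.std(axis=(0, 1, 2)), F32(1e-3))
    del x01

    train_labels = np.asarray(train_labels, dtype=np.int64)
    opt = SGDMomentum(model.params(), lr=tc.initial_lr, momentum=tc.momentum)
    log: list[dict] = []
    best_acc, best_state = -1.0, None
    epoch_seeds = ss_epochs.spawn(tc.epochs)
    for epoch in range(tc.epochs):
        rng = np.random.default_rng(epoch_seeds[epoch])
        opt.lr = lr_at_epoch(tc, epoch)
        if tc.oversample:
            order = oversample_minority(train_labels, rng)
        else:
            order = rng.permutation(len(train_labels))
        losses = []
        for start in range(0, len(order), tc.batch_size):
            idx = order[start:start + tc.batch_size]
            batch = np.stack([augment(train_crops[i], rng) if tc.augment
                              else train_crops[i] for i in idx])
            x = model.prepare_input(batch)
            logits = model.forward(x, train=True)
            loss, grad = softmax_cross_entropy(logits, train_labels[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    "inspect the learning rate and input scaling")
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            losses.append(loss)
        entry = {"epoch": epoch, "lr": opt.lr, "train_loss": float(np.mean(losses))}
        if val_crops is not None:
            val_acc = _accuracy(model, val_crops, val_labels, tc.batch_size)
            entry["val_acc"] = val_acc
            if val_acc > best_acc:
                best_acc = val_acc
                best_state = [p.data.copy() for p in model.params()]
        logger.info("epoch %d: lr %.2e, train loss %.4f%s", epoch, opt.lr,
                    entry["train_loss"],
                    f", val acc {entry['val_acc']:.4f}" if "val_acc" in entry else "")
        log.append(entry)
        if (tc.early_stop_val_acc is not None and val_crops is not None
                and best_acc >= tc.early_stop_val_acc):
            break
    if best_state is not None:
        for p, data in zip(model.params(), best_state):
            p.data[...] = data
    model.release_buffers()
    return model, log


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """Rows: true class; columns: predicted class."""

    counts: np.ndarray
    class_names: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=np.int64)
        n = len(self.class_names)
        if c.shape != (n, n):
            raise ValueError(f"expected {n}x{n} counts, got {c.shape}")
        if np.any(c < 0):
            raise ValueError("confusion counts must be non-negative")
        self.counts = c

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def supports(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def n_misclassified(self) -> int:
        return int(self.total - np.trace(self.counts))


def confusion(y_true, y_pred, class_names: tuple[str, ...] = CLASS_NAMES) -> ConfusionMatrix:
    """Tally a confusion matrix; labels may be indices or class names."""
    name_to_idx = {n: i for i, n in enumerate(class_names)}

    def to_idx(v):
        if isinstance(v, str):
            if v not in name_to_idx:
                raise ValueError(f"unknown class label {v!r}")
            return name_to_idx[v]
        v = int(v)
        if not 0 <= v < len(class_names):
            raise ValueError(f"class index {v} out of range")
        return v

    yt = [to_idx(v) for v in np.asarray(y_true).tolist()]
    yp = [to_idx(v) for v in np.asarray(y_pred).tolist()]
    if len(yt) != len(yp):
        raise ValueError("y_true and y_pred must have equal length")
    counts = np.zeros((len(class_names), len(class_names)), dtype=np.int64)
    for t, p in zip(yt, yp):
        counts[t, p] += 1
    return ConfusionMatrix(counts=counts, class_names=class_names)


@dataclass
class MetricSet:
    """One-vs-rest metrics per class plus support-weighted averages.

    ``per_class[metric]`` is an array over classes; ``weighted[metric]``
    averages the per-class values by true-class support, skipping classes
    whose metric is undefined (zero denominator).
    """

    per_class: dict[str, np.ndarray]
    weighted: dict[str, float]
    supports: np.ndarray
    beta: float = 1.0
    class_names: tuple[str, ...] = CLASS_NAMES


def metrics_from_confusion(cm: ConfusionMatrix, beta: float = 1.0) -> MetricSet:
    """Sensitivity/specificity family from a confusion matrix.

    Per class c (one vs rest): TP = cm[c,c], FN = row - TP, FP = col - TP,
    TN = remainder. TPR = TP/(TP+FN), TNR = TN/(TN+FP), FPR = FP/(TN+FP),
    FNR = FN/(TP+FN), Precision = TP/(TP+FP) and
    F_beta = (1+beta^2) * P * TPR / (beta^2 * P + TPR).
    """
    c = cm.counts
    total = cm.total
    if total <= 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(c).astype(float)
    fn = c.sum(axis=1) - tp
    fp = c.sum(axis=0) - tp
    tn = total - tp - fn - fp

    def ratio(num, den, name):
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(den > 0, num / np.where(den > 0, den, 1), np.nan)
        if np.any(den == 0):
            warnings.warn(f"{name} undefined for classes with zero denominator; "
                          "reported as NaN and excluded from the weighted average")
        return out

    tpr = ratio(tp, tp + fn, "TPR")
    tnr = ratio(tn, tn + fp, "TNR")
    fpr = ratio(fp, tn + fp, "FPR")
    fnr = ratio(fn, tp + fn, "FNR")
    precision = ratio(tp, tp + fp, "Precision")
    with np.errstate(invalid="ignore", divide="ignore"):
        fbeta_den = beta ** 2 * precision + tpr
        fbeta = np.where(fbeta_den > 0,
                         (1 + beta ** 2) * precision * tpr / np.where(fbeta_den > 0, fbeta_den, 1),
                         np.nan)
    per_class = {"tpr": tpr, "tnr": tnr, "fpr": fpr, "fnr": fnr,
                 "precision": precision, "fbeta": fbeta,
                 "tp": tp, "fp": fp, "tn": tn, "fn": fn}
    supports = cm.supports.astype(float)

    def weighted_mean(values):
        ok = ~np.isnan(values)
        if not ok.any() or supports[ok].sum() == 0:
            return float("nan")
        return float((values[ok] * supports[ok]).sum() / supports[ok].sum())

    weighted = {k: weighted_mean(v) for k, v in per_class.items()
                if k in ("tpr", "tnr", "fpr", "fnr", "precision", "fbeta")}
    return MetricSet(per_class=per_class, weighted=weighted, supports=cm.supports,
                     beta=beta, class_names=cm.class_names)


def roc_auc(scores: np.ndarray, y_true, class_names: tuple[str, ...] = CLASS_NAMES
            ) -> tuple[np.ndarray, float]:
    """One-vs-rest AUC per class plus the support-weighted average.

    Computed as the normalized Mann-Whitney U statistic of the class score
    (identical to the trapezoidal area under the threshold-swept ROC
    curve, with ties handled by mid-ranks). Classes absent from ``y_true``
    get NaN.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y_true, dtype=np.int64)
    if scores.ndim != 2 or scores.shape[1] != len(class_names):
        raise ValueError("scores must be n_samples x n_classes")
    aucs = np.full(len(class_names), np.nan)
    supports = np.zeros(len(class_names))
    for c in range(len(class_names)):
        pos = y == c
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        supports[c] = n_pos
        if n_pos == 0 or n_neg == 0:
            continue
        from scipy.stats import rankdata
        ranks = rankdata(scores[:, c])
        u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
        aucs[c] = u / (n_pos * n_neg)
    ok = ~np.isnan(aucs)
    weighted = float((aucs[ok] * supports[ok]).sum() / supports[ok].sum()) if ok.any() else float("nan")
    return aucs, weighted


# ---------------------------------------------------------------------------
# rank statistics for model comparison
# ---------------------------------------------------------------------------

@dataclass
class RankComparison:
    measurements: np.ndarray
    average_ranks: np.ndarray
    friedman_statistic: float
    p_value: float
    cd: float | None = None
    alpha: float = 0.05


def roc_curve_points(scores: np.ndarray, y_true, class_idx: int) -> "pd.DataFrame":
    """One-vs-rest ROC curve (fpr, tpr, threshold) for one class, suitable
    for CSV export; the trapezoidal area under it equals :func:`roc_auc`."""
    import pandas as pd
    from sklearn.metrics import roc_curve as _sk_roc_curve
    y = np.asarray(y_true, dtype=np.int64)
    fpr, tpr, thr = _sk_roc_curve((y == class_idx).astype(int),
                                  np.asarray(scores, dtype=float)[:, class_idx])
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def friedman_test(measurements: np.ndarray) -> RankComparison:
    """Friedman rank test over a k-model x N-measurement table.

    Higher measurements rank better (rank 1 = best). Mid-ranks are used
    for ties; the chi-square statistic is
    12N/(k(k+1)) * sum_j (Rbar_j - (k+1)/2)^2 with k-1 degrees of freedom.
    """
    from scipy.stats import rankdata
    m = np.asarray(measurements, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2:
        raise ValueError("need a k x N table with k >= 2 models")
    k, n = m.shape
    if n < 2:
        raise ValueError("need at least 2 measurements per model")
    # rank within each measurement; best (largest) gets rank 1
    ranks = np.empty_like(m)
    for j in range(n):
        ranks[:, j] = rankdata(-m[:, j])
    avg = ranks.mean(axis=1)
    stat = 12.0 * n / (k * (k + 1)) * float(((avg - (k + 1) / 2) ** 2).sum())
    p = float(chi2.sf(stat, k - 1)) if stat > 0 else 1.0
    return RankComparison(measurements=m, average_ranks=avg,
                          friedman_statistic=float(stat), p_value=p)


# Studentized-range constants q_alpha / sqrt(2) for the Nemenyi test
# (two-tailed, infinite df), k = 2..10.
_NEMENYI_Q = {
    0.05: {2: 1.960, 3: 2.343, 4: 2.569, 5: 2.728, 6: 2.850,
           7: 2.949, 8: 3.031, 9: 3.102, 10: 3.164},
    0.10: {2: 1.645, 3: 2.052, 4: 2.291, 5: 2.459, 6: 2.589,
           7: 2.693, 8: 2.780, 9: 2.855, 10: 2.920},
}


def nemenyi_cd(k: int, n_measurements: int, alpha: float = 0.05) -> float:
    """Critical distance in average rank for the post-hoc Nemenyi test:
    CD = q_alpha(k) * sqrt(k(k+1) / (6N))."""
    table = _NEMENYI_Q.get(round(alpha, 2))
    if table is None or k not in table:
        raise ValueError(f"no tabulated constant for k={k}, alpha={alpha}")
    if n_measurements < 1:
        raise ValueError("need at least one measurement")
    return float(table[k] * np.sqrt(k * (k + 1) / (6.0 * n_measurements)))


# ---------------------------------------------------------------------------
# full protocol
# ---------------------------------------------------------------------------

def cross_validate(
    crops: np.ndarray,
    labels: np.ndarray,
    config: CompactNetConfig,
    tc: TrainConfig,
    k: int = 5,
    n_rounds: int | None = None,
) -> dict:
    """Run the k-fold rotation end to end.

    Returns per-round confusion matrices and metric sets plus the
    mean ± sd of each weighted metric across rounds (the reporting format
    used for cross-validated results).
    """
    labels = np.asarray(labels, dtype=np.int64)
    split = stratified_kfold(labels, k=k, seed=tc.seed)
    rounds = []
    for r in range(n_rounds if n_rounds is not None else k):
        tr, va, te = split.indices(r)
        model, log = train_model(config, tc, crops[tr], labels[tr],
                                 crops[va], labels[va])
        pred = model.predict(crops[te], batch_size=tc.batch_size)
        proba = model.predict_proba(crops[te], batch_size=tc.batch_size)
        cm = confusion(labels[te], pred)
        ms = metrics_from_confusion(cm)
        aucs, wauc = roc_auc(proba, labels[te])
        rounds.append({"round": r, "confusion": cm, "metrics": ms,
                       "auc_per_class": aucs, "auc_weighted": wauc, "log": log})
    summary = {}
    for key in ("tpr", "tnr", "fpr", "fnr", "precision", "fbeta"):
        vals = np.array([rd["metrics"].weighted[key] for rd in rounds])
        summary[key] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1))
                        if len(vals) > 1 else 0.0}
    aucv = np.array([rd["auc_weighted"] for rd in rounds])
    summary["auc"] = {"mean": float(aucv.mean()),
                      "sd": float(aucv.std(ddof=1)) if len(aucv) > 1 else 0.0}
    return {"rounds": rounds, "summary": summary, "split": split}
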