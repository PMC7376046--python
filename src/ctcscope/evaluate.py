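"""Leakage-safe five-fold cross-validation and metrics.

The protocol matches small-data practice for rare-cell classification:
the *original* (unaugmented) crops are shuffled and stratified into k
disjoint folds; for each fold the remaining originals are augmented, the
augmented pool is split 80/20 into train/validation *by origin* (so no
origin contributes to both), the model is trained, and predictions are
taken on the held-out fold's originals only.  No crop derived from a test
origin can ever reach training — asserted at run time as a hard failure.

Metrics: per-fold and pooled confusion matrices ([WBC, CTC] order, rows
true), accuracy, precision/recall/F-score for the CTC class, ROC/AUC
(both pooled over concatenated folds and the mean of per-fold AUCs, since
either aggregation is common), mean learning history, and a t-SNE
embedding of the training crops for visual cluster inspection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.manifold import TSNE
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .classify import CLASS_ORDER, TrainConfig, build_model
from .classify import predict as _predict
from .classify import train as _train
from .dataset import AugmentSpec, CellCrop, augment
from .errors import (DegenerateMetricWarning, LeakageError, ParameterError,
                     UndefinedAUCError)
from .synthgen import CTC, WBC


@dataclass
class FoldPlan:
    """Assignment of original crop ids to k disjoint folds."""

    k: int
    assignments: dict[str, int]
    seed: int

    def fold_ids(self, f: int) -> set[str]:
        return {cid for cid, ff in self.assignments.items() if ff == f}


@dataclass
class FoldResult:
    confusion: np.ndarray
    accuracy: float
    precision: float
    recall: float
    f_score: float
    auc: float | None
    scores: np.ndarray
    truths: np.ndarray
    history: dict


@dataclass
class EvalReport:
    folds: list[FoldResult]
    pooled_confusion: np.ndarray
    pooled_accuracy: float
    pooled_f_score: float
    pooled_roc: np.ndarray
    pooled_auc: float
    mean_auc: float
    mean_history: dict = field(default_factory=dict)


def make_folds(original_crops: list[CellCrop], k: int = 5,
               seed: int = 0) -> FoldPlan:
    """Stratified shuffled split of originals into k near-equal folds.

    Per-class counts are spread as evenly as possible and each class's
    remainder goes to the currently smallest folds, so total fold sizes
    differ by at most one whenever k divides evenly.
    """
    if len(original_crops) < k:
        raise ParameterError(
            f"need at least k={k} originals, got {len(original_crops)}")
    for c in original_crops:
        if c.origin_id != c.crop_id:
            raise ParameterError(
                f"fold plans take unaugmented crops only; {c.crop_id} "
                f"derives from {c.origin_id}")
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[str]] = {}
    for c in original_crops:
        by_class.setdefault(c.label, []).append(c.crop_id)

    assignments: dict[str, int] = {}
    load = np.zeros(k, dtype=int)
    for cls in sorted(by_class, key=lambda c: -len(by_class[c])):
        ids = list(by_class[cls])
        rng.shuffle(ids)
        base, extra = divmod(len(ids), k)
        counts = np.full(k, base)
        # remainder to the currently least-loaded folds (stable order)
        for f in np.argsort(load, kind="stable")[:extra]:
            counts[f] += 1
        pos = 0
        for f in range(k):
            for cid in ids[pos:pos + counts[f]]:
                assignments[cid] = f
            pos += counts[f]
        load += counts
    return FoldPlan(k=k, assignments=assignments, seed=seed)


def f_score(cm: np.ndarray, positive: str = CTC) -> float:
    """F1 for the positive class of a 2x2 confusion matrix.

    Matrix layout: rows true, cols predicted, order [WBC, CTC].  Degenerate
    cases (no positive predictions and no positive truths reachable) return
    0.0 with a :class:`DegenerateMetricWarning`.
    """
    cm = np.asarray(cm)
    if cm.shape != (2, 2):
        raise ParameterError("confusion matrix must be 2x2")
    p = CLASS_ORDER.index(positive)
    tp = cm[p, p]
    fp = cm[1 - p, p]
    fn = cm[p, 1 - p]
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    if precision + recall == 0:
        warnings.warn("degenerate precision+recall = 0; F-score set to 0",
                      DegenerateMetricWarning)
        return 0.0
    return 2 * precision * recall / (precision + recall)


def roc_auc(scores, truths):
    """ROC points and trapezoidal AUC for CTC-probability scores.

    ``truths`` are class labels (or 0/1 with 1 = CTC).  Thresholds sweep the
    unique scores with ties grouped; the AUC equals the normalized
    Mann-Whitney U statistic.  Raises :class:`UndefinedAUCError` if only one
    class is present.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([t == CTC if isinstance(t, str) else bool(t)
                    for t in truths])
    if y.all() or not y.any():
        raise UndefinedAUCError("ROC/AUC undefined for single-class truths")
    fpr, tpr, thr = _sk_roc_curve(y.astype(int), scores,
                                  drop_intermediate=False)
    points = np.column_stack([fpr, tpr, thr])
    return points, float(_sk_auc(fpr, tpr))


def pooled_and_mean_auc(fold_scores: list, fold_truths: list):
    """(AUC of concatenated folds, mean of per-fold AUCs).

    Folds whose truths are single-class are skipped from the mean with a
    warning; the pooled AUC uses every prediction.
    """
    all_s = np.concatenate([np.asarray(s, dtype=float) for s in fold_scores])
    all_t = np.concatenate([np.asarray(t) for t in fold_truths])
    _, pooled = roc_auc(all_s, all_t)
    per_fold = []
    for i, (s, t) in enumerate(zip(fold_scores, fold_truths)):
        try:
            per_fold.append(roc_auc(s, t)[1])
        except UndefinedAUCError:
            warnings.warn(f"fold {i} has a single-class truth; "
                          "skipped from mean AUC", DegenerateMetricWarning)
    if not per_fold:
        raise UndefinedAUCError("no fold had both classes")
    return pooled, float(np.mean(per_fold))


def _confusion(true_labels, pred_labels) -> np.ndarray:
    cm = np.zeros((2, 2), dtype=int)
    for t, p in zip(true_labels, pred_labels):
        cm[CLASS_ORDER.index(t), CLASS_ORDER.index(p)] += 1
    return cm


def _split_by_origin(aug_crops: list[CellCrop], val_fraction: float,
                     rng: np.random.Generator):
    """80/20 train/validation split of augmented crops at the origin level,
    stratified by class so both sides keep both classes."""
    by_origin: dict[str, list[CellCrop]] = {}
    for c in aug_crops:
        by_origin.setdefault(c.origin_id, []).append(c)
    origin_class = {o: crops[0].label for o, crops in by_origin.items()}
    val_origins: set[str] = set()
    for cls in CLASS_ORDER:
        origins = sorted(o for o, c in origin_class.items() if c == cls)
        origins = list(rng.permutation(origins))
        n_val = max(int(round(val_fraction * len(origins))), 1)
        val_origins.update(origins[:n_val])
    train = [c for c in aug_crops if c.origin_id not in val_origins]
    val = [c for c in aug_crops if c.origin_id in val_origins]
    return train, val


def run_cv(originals: list[CellCrop], plan: FoldPlan,
           aug_spec: AugmentSpec, train_config: TrainConfig,
           val_fraction: float = 0.2) -> EvalReport:
    """Run the full k-fold protocol and aggregate metrics.

    For each fold: augment the complement, split it 80/20 by origin, train,
    and predict on the fold's originals.  Origin-disjointness between
    (train u validation) and test is asserted for every fold; a violated
    plan raises :class:`LeakageError`.
    """
    by_id = {c.crop_id: c for c in originals}
    if set(plan.assignments) != set(by_id):
        raise ParameterError("fold plan does not cover exactly the originals")

    fold_results: list[FoldResult] = []
    all_scores, all_truths = [], []
    for f in range(plan.k):
        test_ids = plan.fold_ids(f)
        test = [by_id[i] for i in sorted(test_ids)]
        rest = [c for c in originals if c.crop_id not in test_ids]
        spec = replace(aug_spec, seed=aug_spec.seed + 1000 * (f + 1))
        augmented = augment(rest, spec)

        rng = np.random.default_rng(spec.seed + 1)
        train_crops, val_crops = _split_by_origin(augmented, val_fraction, rng)

        test_origins = {c.origin_id for c in test}
        used_origins = {c.origin_id for c in train_crops} | \
                       {c.origin_id for c in val_crops}
        shared = test_origins & used_origins
        if shared:
            raise LeakageError(
                f"fold {f}: {len(shared)} test origin(s) leaked into "
                f"training/validation, e.g. {sorted(shared)[:3]}")

        config = replace(train_config, seed=train_config.seed + f)
        network = build_model(config)
        trained = _train(network, train_crops, val_crops, config)
        probs, pred_labels = _predict(trained, test)

        truths = [c.label for c in test]
        scores = probs[:, CLASS_ORDER.index(CTC)]
        cm = _confusion(truths, pred_labels)
        acc = float(np.trace(cm) / cm.sum())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateMetricWarning)
            f1 = f_score(cm)
        try:
            _, fold_auc = roc_auc(scores, truths)
        except UndefinedAUCError:
            fold_auc = None
        tp, fp = cm[1, 1], cm[0, 1]
        fn = cm[1, 0]
        fold_results.append(FoldResult(
            confusion=cm, accuracy=acc,
            precision=float(tp / (tp + fp)) if tp + fp else 0.0,
            recall=float(tp / (tp + fn)) if tp + fn else 0.0,
            f_score=f1, auc=fold_auc, scores=scores,
            truths=np.array(truths), history=trained.history))
        all_scores.append(scores)
        all_truths.append(truths)

    pooled_cm = sum(fr.confusion for fr in fold_results)
    pooled_points, pooled_auc_v = roc_auc(
        np.concatenate(all_scores), np.concatenate(all_truths))
    _, mean_auc_v = pooled_and_mean_auc(all_scores, all_truths)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateMetricWarning)
        pooled_f1 = f_score(pooled_cm)

    # average learning curves over folds (truncated to the shortest run)
    mean_history: dict = {}
    keys = ("train_loss", "train_acc", "val_loss", "val_acc")
    n_ep = min(len(fr.history[k]) for fr in fold_results for k in keys)
    for k in keys:
        mean_history[k] = list(np.mean(
            [fr.history[k][:n_ep] for fr in fold_results], axis=0))

    return EvalReport(
        folds=fold_results, pooled_confusion=pooled_cm,
        pooled_accuracy=float(np.trace(pooled_cm) / pooled_cm.sum()),
        pooled_f_score=pooled_f1, pooled_roc=pooled_points,
        pooled_auc=pooled_auc_v, mean_auc=mean_auc_v,
        mean_history=mean_history)


def tsne_embed(crops: list[CellCrop], perplexity: float = 50.0,
               learning_rate: float = 100.0, seed: int = 0) -> np.ndarray:
    """2-D t-SNE of flattened normalized crop pixels (n x 2 coordinates)."""
    n = len(crops)
    if n < 3 * perplexity:
        raise ParameterError(
            f"t-SNE needs at least 3*perplexity={int(3 * perplexity)} points, "
            f"got {n}")
    X = np.stack([c.pixels.ravel() for c in crops])
    ts = TSNE(n_components=2, perplexity=perplexity,
              learning_rate=learning_rate, init="pca", random_state=seed)
    return ts.fit_transform(X)


def tsne_plot(crops: list[CellCrop], perplexity: float = 50.0,
              learning_rate: float = 100.0, seed: int = 0, out_path=None):
    """t-SNE embedding plus a class-colored scatter (saved if a path given)."""
    emb = tsne_embed(crops, perplexity, learning_rate, seed)
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(5, 5))
    colors = {WBC: "tab:green", CTC: "tab:red"}
    for cls in (WBC, CTC):
        m = np.array([c.label == cls for c in crops])
        if m.any():
            ax.scatter(emb[m, 0], emb[m, 1], s=8, alpha=0.7,
                       c=colors[cls], label=cls)
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    ax.legend()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return emb
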