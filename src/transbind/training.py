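"""Training loop, ranking metrics, paired comparison, and the zero-shot
cross-validation harness.

Loss is binary cross-entropy on logits; optimization is AdamW with cosine
annealing of the learning rate over the epoch budget; the retained
checkpoint is the one with the best validation macro-AUPR (average
precision), the metric of choice under the severe class imbalance of
genome-wide binding labels. Per-label AUROC/AUPR are macro-averaged over
labels that have both positives and negatives in the evaluation set;
degenerate labels are listed, not silently averaged in.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .model import PairwiseTransBind, TransBindModel, regularize_embedding
from .nn import AdamW, Tensor, cosine_lr, softplus

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "MetricTable",
    "ComparisonResult",
    "bce_with_logits",
    "train",
    "train_pairwise",
    "per_label_metrics",
    "paired_compare",
    "loto_folds",
    "zeroshot_evaluate",
]


@dataclass
class TrainConfig:
    lr: float = 3.28e-4
    weight_decay: float = 0.028
    max_epochs: int = 60
    batch_size: int = 256
    patience: int = 10  # early stop on validation macro-AUPR
    min_lr: float = 0.0
    seed: int = 0
    eval_every: int = 1  # epochs between validation passes

    def __post_init__(self):
        if self.lr < 0:
            raise ValueError("lr must be nonnegative")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class MetricTable:
    labels: list[str]
    auroc: np.ndarray  # per label; nan where skipped
    aupr: np.ndarray
    skipped: list[str]  # labels without both classes

    @property
    def macro_auroc(self) -> float:
        v = self.auroc[~np.isnan(self.auroc)]
        return float(v.mean()) if v.size else float("nan")

    @property
    def macro_aupr(self) -> float:
        v = self.aupr[~np.isnan(self.aupr)]
        return float(v.mean()) if v.size else float("nan")

    def to_tsv(self) -> str:
        lines = ["label\tauroc\taupr"]
        for i, name in enumerate(self.labels):
            lines.append(f"{name}\t{self.auroc[i]:.6f}\t{self.aupr[i]:.6f}")
        return "\n".join(lines)


@dataclass
class ComparisonResult:
    t_statistic: float
    p_value: float
    cohens_d: float
    n_pairs: int
    degenerate: bool = False


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy computed stably from logits:
    max(z,0) - z*y + log(1 + exp(-|z|))."""
    y = Tensor(np.asarray(targets, dtype=float))
    return (softplus(logits) - logits * y).mean()


def per_label_metrics(scores: np.ndarray, labels: np.ndarray,
                      label_names: list[str] | None = None) -> MetricTable:
    """Per-label AUROC (rank statistic, ties get half credit) and AUPR
    (average precision), with macro means over evaluable labels."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.ndim == 1:
        scores = scores[:, None]
        labels = labels[:, None]
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same shape")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    E = scores.shape[1]
    names = label_names or [f"label{i}" for i in range(E)]
    auroc = np.full(E, np.nan)
    aupr = np.full(E, np.nan)
    skipped = []
    for e in range(E):
        y = labels[:, e]
        if y.min() == y.max():
            skipped.append(names[e])
            continue
        auroc[e] = roc_auc_score(y, scores[:, e])
        aupr[e] = average_precision_score(y, scores[:, e])
    if len(skipped) == E:
        raise ValueError("every label lacks one of the two classes")
    return MetricTable(names, auroc, aupr, skipped)


def paired_compare(metrics_a: np.ndarray, metrics_b: np.ndarray) -> ComparisonResult:
    """Two-sided paired t-test on per-label differences plus paired
    Cohen's d = mean(diff) / sd(diff, ddof=1)."""
    a = np.asarray(metrics_a, dtype=float)
    b = np.asarray(metrics_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        return ComparisonResult(
            t_statistic=0.0 if diff.mean() == 0 else float("inf"),
            p_value=float("nan"), cohens_d=float("nan"),
            n_pairs=len(a), degenerate=True,
        )
    t, p = stats.ttest_rel(a, b)
    return ComparisonResult(float(t), float(p), float(diff.mean() / sd), len(a))


# ------------------------------------------------------------------ training


def _iterate_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i : i + batch_size]


def train(
    model: TransBindModel,
    data: dict,
    cfg: TrainConfig,
    log_path: str | None = None,
) -> dict:
    """Fit the multilabel model. `data` holds 'train'/'val' dicts with X
    (N, L, 4) and Y (N, E). Returns {'history': [...], 'best_state': ...,
    'best_epoch': int, 'best_val_aupr': float}; the model is left loaded
    with the best-validation weights (or final weights if no val set)."""
    Xtr = np.asarray(data["train"]["X"], dtype=float)
    Ytr = np.asarray(data["train"]["Y"], dtype=float)
    if len(Xtr) == 0:
        raise ValueError("empty training set")
    has_val = "val" in data and len(data["val"]["X"]) > 0
    opt = AdamW(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    droprng = np.random.default_rng(cfg.seed + 1)
    history = []
    best = {"epoch": -1, "val_aupr": -np.inf, "state": None}
    since_improve = 0
    for epoch in range(cfg.max_epochs):
        opt.lr = cosine_lr(cfg.lr, epoch, cfg.max_epochs, cfg.min_lr)
        losses = []
        for idx in _iterate_batches(len(Xtr), cfg.batch_size, rng):
            opt.zero_grad()
            logits = model(Xtr[idx], rng=droprng, training=True)
            loss = bce_with_logits(logits, Ytr[idx])
            loss.backward()
            opt.step()
            losses.append(loss.item())
        entry = {"epoch": epoch, "lr": opt.lr,
                 "train_loss": float(np.mean(losses))}
        if has_val and epoch % cfg.eval_every == 0:
            scores = model.predict(data["val"]["X"])
            mt = per_label_metrics(scores, data["val"]["Y"])
            entry["val_macro_aupr"] = mt.macro_aupr
            entry["val_macro_auroc"] = mt.macro_auroc
            if mt.macro_aupr > best["val_aupr"]:
                best = {"epoch": epoch, "val_aupr": mt.macro_aupr,
                        "state": model.state_dict()}
                since_improve = 0
            else:
                since_improve += 1
        history.append(entry)
        logger.debug("epoch %d: %s", epoch, entry)
        if has_val and since_improve > cfg.patience:
            break
    if best["state"] is not None:
        model.load_state_dict(best["state"])
    if log_path:
        with open(log_path, "w") as fh:
            for entry in history:
                fh.write(json.dumps(entry) + "\n")
    return {"history": history, "best_epoch": best["epoch"],
            "best_val_aupr": best["val_aupr"], "best_state": best["state"]}


def train_pairwise(
    model: PairwiseTransBind,
    pairs: dict,
    cfg: TrainConfig,
    log_path: str | None = None,
) -> dict:
    """Fit the pairwise model on (DNA window, TF embedding, 0/1) triples.

    `pairs` holds 'train'/'val' dicts with X (N, L, 4), E (N, d2), y (N,).
    Whole-embedding masking and Gaussian noise (per the model config) are
    applied during training only."""
    Xtr = np.asarray(pairs["train"]["X"], dtype=float)
    Etr = np.asarray(pairs["train"]["E"], dtype=float)
    ytr = np.asarray(pairs["train"]["y"], dtype=float)
    if len(Xtr) == 0:
        raise ValueError("empty training set")
    has_val = "val" in pairs and len(pairs["val"]["X"]) > 0
    opt = AdamW(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    droprng = np.random.default_rng(cfg.seed + 1)
    maskrng = np.random.default_rng(cfg.seed + 2)
    mcfg = model.cfg
    history = []
    best = {"epoch": -1, "val_aupr": -np.inf, "state": None}
    since_improve = 0
    for epoch in range(cfg.max_epochs):
        opt.lr = cosine_lr(cfg.lr, epoch, cfg.max_epochs, cfg.min_lr)
        losses = []
        for idx in _iterate_batches(len(Xtr), cfg.batch_size, rng):
            opt.zero_grad()
            emb = regularize_embedding(Etr[idx], mcfg.mask_prob,
                                       mcfg.noise_sigma, maskrng)
            logits = model(Xtr[idx], emb, rng=droprng, training=True)
            loss = bce_with_logits(logits, ytr[idx])
            loss.backward()
            opt.step()
            losses.append(loss.item())
        entry = {"epoch": epoch, "lr": opt.lr,
                 "train_loss": float(np.mean(losses))}
        if has_val and epoch % cfg.eval_every == 0:
            scores = model.predict(pairs["val"]["X"], pairs["val"]["E"])
            mt = per_label_metrics(scores, np.asarray(pairs["val"]["y"]))
            entry["val_macro_aupr"] = mt.macro_aupr
            if mt.macro_aupr > best["val_aupr"]:
                best = {"epoch": epoch, "val_aupr": mt.macro_aupr,
                        "state": model.state_dict()}
                since_improve = 0
            else:
                since_improve += 1
        history.append(entry)
        if has_val and since_improve > cfg.patience:
            break
    if best["state"] is not None:
        model.load_state_dict(best["state"])
    if log_path:
        with open(log_path, "w") as fh:
            for entry in history:
                fh.write(json.dumps(entry) + "\n")
    return {"history": history, "best_epoch": best["epoch"],
            "best_val_aupr": best["val_aupr"], "best_state": best["state"]}


# ------------------------------------------------------------- zero-shot CV


def loto_folds(tf_names: list[str], fold_size: int = 3, n_folds: int = 8,
               seed: int = 0) -> list[tuple[list[str], list[str]]]:
    """Leave-`fold_size`-out folds with disjoint held-out sets.

    Returns [(train_tfs, held_out_tfs), ...]; each of the first
    fold_size * n_folds TFs of a seeded shuffle is held out exactly once.
    """
    if fold_size * n_folds > len(tf_names):
        raise ValueError(
            f"cannot hold out {fold_size * n_folds} TFs from {len(tf_names)}"
        )
    rng = np.random.default_rng(seed)
    order = [tf_names[i] for i in rng.permutation(len(tf_names))]
    folds = []
    for f in range(n_folds):
        held = sorted(order[f * fold_size : (f + 1) * fold_size])
        train = sorted(set(tf_names) - set(held))
        assert not set(train) & set(held)
        folds.append((train, held))
    return folds


def zeroshot_evaluate(model: PairwiseTransBind, pairs_by_tf: dict) -> dict:
    """Score held-out TFs' pairs; per-TF AUROC/AUPR plus a macro summary.

    `pairs_by_tf`: {tf_name: {'X': (N,L,4), 'E': (N,d2), 'y': (N,)}}.
    TFs whose pairs lack positives (or negatives) are skipped with a warning.
    """
    per_tf = {}
    for tf, d in pairs_by_tf.items():
        y = np.asarray(d["y"])
        if y.min() == y.max():
            logger.warning("held-out TF %s has a single class; skipped", tf)
            continue
        scores = model.predict(d["X"], d["E"])
        mt = per_label_metrics(scores, y)
        per_tf[tf] = {"auroc": mt.macro_auroc, "aupr": mt.macro_aupr,
                      "n_pairs": int(len(y)), "n_pos": int(y.sum())}
    if not per_tf:
        raise ValueError("no evaluable held-out TFs")
    aurocs = np.array([v["auroc"] for v in per_tf.values()])
    auprs = np.array([v["aupr"] for v in per_tf.values()])
    return {
        "per_tf": per_tf,
        "macro_auroc": float(aurocs.mean()),
        "macro_auroc_sd": float(aurocs.std(ddof=1)) if len(aurocs) > 1 else 0.0,
        "macro_aupr": float(auprs.mean()),
        "macro_aupr_sd": float(auprs.std(ddof=1)) if len(auprs) > 1 else 0.0,
    }
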