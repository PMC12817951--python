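"""Three-stage training: contrastive pretraining, supervised warm-up, and
confidence-weighted consistency training with alternating freezes.

Stage 3 alternates, per epoch, (a) a pseudo-label refresh, (b) an
estimator phase (annotator frozen, estimator minimizes the weighted
consistency loss) and (c) an annotator phase (estimator frozen, annotator
minimizes supervised + lambda * consistency loss).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .augment import AugmentationConfig, strong_augment, weak_augment
from .contrastive import ContrastiveConfig, pretrain_stage1
from .data import ExpressionMatrix, LabeledSet, UnlabeledSet
from .model import (
    Adam,
    AnnotatorNetwork,
    ConfidenceEstimator,
    load_checkpoint,
    save_checkpoint,
    softmax,
)
from .pseudolabel import assign_pseudo_labels

__all__ = [
    "TrainingPlan",
    "TrainedModel",
    "supervised_loss",
    "consistency_loss",
    "run_stage2",
    "run_stage3",
    "fit",
    "predict",
]

_ABLATIONS = {"no_pretrain", "no_consistency", "no_confidence"}


@dataclass
class TrainingPlan:
    """Stage schedule, learning rates, loss weight and ablation switches."""

    stage_epochs: tuple[int, int, int] = (100, 200, 150)
    stage_lrs: tuple[float, float, float] = (5e-4, 1e-4, 5e-5)
    estimator_lr: float = 1e-4
    lam: float = 0.5
    batch_size: int = 128
    warmup_epochs_before_estimator: int = 0
    seed: int = 0
    ablation: frozenset = field(default_factory=frozenset)
    hidden_dims: tuple[int, int, int] = (100, 50, 25)
    estimator_hidden_dims: tuple[int, ...] = (64,)
    confidence_floor: float = 0.01
    # log-barrier weight keeping the estimator away from the trivial
    # conf == 0 minimizer of the weighted consistency loss; the stationary
    # confidence is min(1, confidence_reg / disagreement)
    confidence_reg: float = 0.5
    pseudo_refresh_every: int = 1
    kmeans_max_iter: int = 100
    kmeans_tol: float = 1e-6

    def __post_init__(self) -> None:
        self.ablation = frozenset(self.ablation)
        unknown = self.ablation - _ABLATIONS
        if unknown:
            raise ValueError(f"unknown ablation switches: {sorted(unknown)}")
        if any(e < 0 for e in self.stage_epochs):
            raise ValueError("stage epochs must be >= 0")
        if any(lr <= 0 for lr in self.stage_lrs) or self.estimator_lr <= 0:
            raise ValueError("learning rates must be positive")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be positive")


@dataclass
class TrainedModel:
    """A fitted annotator (plus optional confidence estimator) bound to the
    gene space and class names it was trained on."""

    net: AnnotatorNetwork
    est: ConfidenceEstimator | None
    gene_ids: list[str]
    class_names: list[str]
    log: list[dict] = field(default_factory=list)

    def save(self, path) -> None:
        save_checkpoint(path, self.net, self.est, self.gene_ids, self.class_names)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        net, est, gene_ids, class_names = load_checkpoint(path)
        return cls(net, est, gene_ids, class_names)


# ---------------------------------------------------------------------------
# losses


def supervised_loss(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean cross-entropy of predicted probabilities against hard labels."""
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if probs.ndim != 2 or len(labels) != probs.shape[0]:
        raise ValueError("probs rows must align with labels")
    if labels.min() < 0 or labels.max() >= probs.shape[1]:
        raise ValueError(
            f"label out of range [0, {probs.shape[1]}): "
            f"{int(labels.min())}..{int(labels.max())}"
        )
    picked = probs[np.arange(len(labels)), labels]
    return float(-np.mean(np.log(np.clip(picked, 1e-300, None))))


def consistency_loss(
    conf: np.ndarray,
    pseudo: np.ndarray,
    probs_weak: np.ndarray,
    probs_strong: np.ndarray,
) -> float:
    """Confidence-weighted cross-entropy of both augmented views against
    the hard pseudo-labels, averaged over cells."""
    conf = np.asarray(conf, dtype=np.float64)
    pseudo = np.asarray(pseudo, dtype=np.int64)
    probs_weak = np.asarray(probs_weak, dtype=np.float64)
    probs_strong = np.asarray(probs_strong, dtype=np.float64)
    n = len(pseudo)
    if not (len(conf) == n == probs_weak.shape[0] == probs_strong.shape[0]):
        raise ValueError("conf, pseudo and probability matrices must align")
    if np.any(conf < 0) or np.any(conf > 1):
        raise ValueError("confidences must lie in [0, 1]")
    rows = np.arange(n)
    ce_w = -np.log(np.clip(probs_weak[rows, pseudo], 1e-300, None))
    ce_s = -np.log(np.clip(probs_strong[rows, pseudo], 1e-300, None))
    return float(np.mean(conf * ce_w + conf * ce_s))


def _ce_grad(probs: np.ndarray, labels: np.ndarray, weight) -> np.ndarray:
    """d(mean weighted CE)/d(logits) = w * (p - onehot) / N."""
    g = probs.copy()
    g[np.arange(len(labels)), labels] -= 1.0
    return g * (np.asarray(weight, dtype=np.float64).reshape(-1, 1) / len(labels))


# ---------------------------------------------------------------------------
# stages


def run_stage2(
    net: AnnotatorNetwork,
    labeled: LabeledSet,
    plan: TrainingPlan,
    log: list | None = None,
) -> AnnotatorNetwork:
    """Supervised warm-up: Adam on the labeled cross-entropy."""
    x = labeled.matrix.values
    y = labeled.labels
    ns = len(y)
    batch_size = min(plan.batch_size, ns)
    rng = np.random.default_rng(np.random.SeedSequence([int(plan.seed), 2]))
    opt = Adam(net.parameters(), lr=plan.stage_lrs[1], owner=net)
    for epoch in range(plan.stage_epochs[1]):
        order = rng.permutation(ns)
        losses = []
        for start in range(0, ns, batch_size):
            idx = order[start : start + batch_size]
            logits, cache = net.forward_cached(x[idx])
            probs = softmax(logits)
            losses.append(supervised_loss(probs, y[idx]))
            opt.step(net.backward(_ce_grad(probs, y[idx], 1.0), cache))
        if log is not None:
            log.append(
                {"stage": 2, "epoch": epoch, "loss_supervised": float(np.mean(losses))}
            )
    return net


def _estimator_phase(net, est, xt, pseudo, aug_cfg, plan, opt_e, rng_aug, order):
    """One pass over unlabeled batches updating the (unfrozen) estimator
    while the annotator is frozen; returns (mean Lu, mean confidence)."""
    nt = len(order)
    bs = min(plan.batch_size, nt)
    losses, confs = [], []
    for start in range(0, nt, bs):
        idx = order[start : start + bs]
        xb = xt[idx]
        emb = net.embed(xb)
        logits, _ = net.forward(xb)
        xw = weak_augment(xb, aug_cfg, rng_aug)
        xs = strong_augment(xb, aug_cfg, rng_aug)
        pw = softmax(net.forward(xw)[0])
        ps = softmax(net.forward(xs)[0])
        rows = np.arange(len(idx))
        ce = -np.log(np.clip(pw[rows, pseudo[idx]], 1e-300, None)) - np.log(
            np.clip(ps[rows, pseudo[idx]], 1e-300, None)
        )
        conf, state = est.forward_cached(emb, logits)
        eff = np.clip(conf, plan.confidence_floor, None)
        beta = plan.confidence_reg
        losses.append(float(np.mean(eff * ce - beta * np.log(eff))))
        confs.append(float(np.mean(conf)))
        # floor gates the weighted term; the barrier gradient always flows
        grad_conf = (
            np.where(conf > plan.confidence_floor, ce, 0.0) - beta / eff
        ) / len(idx)
        opt_e.step(est.backward(grad_conf, state))
    return float(np.mean(losses)), float(np.mean(confs))


def run_stage3(
    net: AnnotatorNetwork,
    est: ConfidenceEstimator,
    labeled: LabeledSet,
    unlabeled: UnlabeledSet,
    plan: TrainingPlan,
    aug_cfg: AugmentationConfig,
    log: list | None = None,
) -> tuple[AnnotatorNetwork, ConfidenceEstimator]:
    """Consistency training with per-epoch pseudo-label refresh and
    alternating annotator/estimator freezes."""
    xs_, ys = labeled.matrix.values, labeled.labels
    xt = unlabeled.matrix.values
    ns, nt = len(ys), xt.shape[0]
    no_consistency = "no_consistency" in plan.ablation or nt == 0
    no_confidence = "no_confidence" in plan.ablation
    ss = np.random.SeedSequence([int(plan.seed), 3])
    rng_lab, rng_unlab, rng_aug = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )
    opt_phi = Adam(net.parameters(), lr=plan.stage_lrs[2], owner=net)
    opt_e = Adam(est.parameters(), lr=plan.estimator_lr, owner=est)
    bs = min(plan.batch_size, max(ns, 1))
    n_steps = max(1, -(-nt // min(plan.batch_size, max(nt, 1)))) if nt else 1
    pseudo = None
    for epoch in range(plan.stage_epochs[2]):
        record: dict = {"stage": 3, "epoch": epoch}
        if not no_consistency:
            if pseudo is None or epoch % max(1, plan.pseudo_refresh_every) == 0:
                state = assign_pseudo_labels(
                    net, labeled, unlabeled, plan.kmeans_max_iter, plan.kmeans_tol
                )
                pseudo = state.assignments
                record["kmeans_iterations"] = state.n_iterations
            # ---- estimator phase: annotator frozen
            if (
                not no_confidence
                and nt > 0
                and epoch >= plan.warmup_epochs_before_estimator
            ):
                net.freeze()
                lu, mean_conf = _estimator_phase(
                    net, est, xt, pseudo, aug_cfg, plan, opt_e,
                    rng_aug, rng_unlab.permutation(nt),
                )
                net.unfreeze()
                record["loss_estimator"] = lu
                record["mean_confidence"] = mean_conf
        # ---- annotator phase: estimator frozen
        est.freeze()
        sup_losses, con_losses = [], []
        unlab_order = rng_unlab.permutation(nt) if (nt and not no_consistency) else None
        for step in range(n_steps):
            lab_idx = rng_lab.choice(ns, size=min(bs, ns), replace=False)
            logits_l, cache_l = net.forward_cached(xs_[lab_idx])
            probs_l = softmax(logits_l)
            ls = supervised_loss(probs_l, ys[lab_idx])
            grads = net.backward(_ce_grad(probs_l, ys[lab_idx], 1.0), cache_l)
            sup_losses.append(ls)
            if not no_consistency:
                lo = step * min(plan.batch_size, nt)
                idx = unlab_order[lo : lo + min(plan.batch_size, nt)]
                if idx.size:
                    xb = xt[idx]
                    conf = (
                        np.ones(len(idx))
                        if no_confidence
                        else est.forward(net.embed(xb), net.forward(xb)[0])
                    )
                    xw = weak_augment(xb, aug_cfg, rng_aug)
                    xstr = strong_augment(xb, aug_cfg, rng_aug)
                    logits_w, cache_w = net.forward_cached(xw)
                    logits_s, cache_s = net.forward_cached(xstr)
                    pw, psg = softmax(logits_w), softmax(logits_s)
                    lu = consistency_loss(np.clip(conf, 0, 1), pseudo[idx], pw, psg)
                    con_losses.append(lu)
                    if plan.lam > 0:
                        w = plan.lam * conf
                        for acc, g in zip(
                            grads, net.backward(_ce_grad(pw, pseudo[idx], w), cache_w)
                        ):
                            acc += g
                        for acc, g in zip(
                            grads, net.backward(_ce_grad(psg, pseudo[idx], w), cache_s)
                        ):
                            acc += g
            opt_phi.step(grads)
        est.unfreeze()
        record["loss_supervised"] = float(np.mean(sup_losses))
        if con_losses:
            record["loss_consistency"] = float(np.mean(con_losses))
        total = record["loss_supervised"] + plan.lam * record.get("loss_consistency", 0.0)
        if not np.isfinite(total):
            raise FloatingPointError(
                f"stage-3 objective became non-finite at epoch {epoch}: {record}"
            )
        if log is not None:
            log.append(record)
    return net, est


def fit(
    labeled: LabeledSet,
    unlabeled: UnlabeledSet,
    plan: TrainingPlan | None = None,
    aug_cfg: AugmentationConfig | None = None,
    c_cfg: ContrastiveConfig | None = None,
) -> TrainedModel:
    """Full three-stage training; deterministic given ``plan.seed``."""
    plan = plan or TrainingPlan()
    aug_cfg = aug_cfg or AugmentationConfig()
    c_cfg = c_cfg or ContrastiveConfig(
        batch_size=plan.batch_size,
        epochs=plan.stage_epochs[0],
        learning_rate=plan.stage_lrs[0],
    )
    unlabeled.validate_against(labeled)
    d = labeled.matrix.n_genes
    c = labeled.n_classes
    net = AnnotatorNetwork(d, c, plan.hidden_dims, seed=plan.seed)
    est = ConfidenceEstimator(
        net.embed_dim, c, plan.estimator_hidden_dims, seed=plan.seed + 1
    )
    log: list[dict] = []
    if "no_pretrain" not in plan.ablation and plan.stage_epochs[0] > 0:
        if unlabeled.matrix.n_cells >= 2:
            pretrain_stage1(net, unlabeled, aug_cfg, c_cfg, plan.seed, log)
        else:
            warnings.warn("fewer than 2 unlabeled cells: skipping pretraining")
    run_stage2(net, labeled, plan, log)
    if plan.stage_epochs[2] > 0:
        run_stage3(net, est, labeled, unlabeled, plan, aug_cfg, log)
    return TrainedModel(net, est, list(labeled.matrix.gene_ids),
                        list(labeled.class_names), log)


def predict(
    model: TrainedModel, query: ExpressionMatrix
) -> tuple[list[str], np.ndarray]:
    """Class names + probabilities for a query matrix, aligned by gene id.

    Query genes are reordered to the training gene space; genes absent from
    the query are zero-filled with a warning. Ties in the argmax resolve to
    the lowest class index.
    """
    pos = {g: i for i, g in enumerate(query.gene_ids)}
    cols = [pos.get(g, -1) for g in model.gene_ids]
    n_missing = sum(1 for cint in cols if cint < 0)
    if n_missing == len(model.gene_ids):
        raise ValueError("query shares no genes with the training gene space")
    x = np.zeros((query.n_cells, len(model.gene_ids)))
    for j, cint in enumerate(cols):
        if cint >= 0:
            x[:, j] = query.values[:, cint]
    if n_missing:
        warnings.warn(
            f"{n_missing} training gene(s) missing from query; zero-filled"
        )
    elif query.gene_ids != model.gene_ids:
        warnings.warn("query gene order differs from training; reordered by id")
    _, probs = model.net.forward(x)
    codes = np.argmax(probs, axis=1)
    return [model.class_names[cint] for cint in codes], probs
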