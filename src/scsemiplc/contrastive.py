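"""Stage-1 pretraining: NT-Xent loss between weak and strong views.

The loss treats all 2N augmented samples as anchors. For anchor i with
partner j, with cosine similarity s and temperature tau:

    l_i = -log( exp(s_ij / tau) / sum_{k != i} exp(s_ik / tau) )

and the reported loss is the mean of l_i over the 2N anchors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .augment import AugmentationConfig, strong_augment, weak_augment
from .data import UnlabeledSet
from .model import AnnotatorNetwork, Adam

__all__ = ["ContrastiveConfig", "nt_xent_loss", "nt_xent_loss_and_grad", "pretrain_stage1"]


@dataclass
class ContrastiveConfig:
    temperature: float = 0.5
    batch_size: int = 128
    epochs: int = 100
    learning_rate: float = 5e-4
    # which network output serves as the contrastive embedding z:
    # "embedding" = phi_2 hidden output (default), "logits" = final layer.
    embedding_source: str = "embedding"

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")
        if self.embedding_source not in ("embedding", "logits"):
            raise ValueError("embedding_source must be 'embedding' or 'logits'")


def _normalize_rows(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    norms = np.linalg.norm(z, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("zero-norm embedding row: cosine similarity undefined")
    return z / norms[:, None], norms


def _pair_logits(z_weak: np.ndarray, z_strong: np.ndarray, temperature: float):
    z_weak = np.asarray(z_weak, dtype=np.float64)
    z_strong = np.asarray(z_strong, dtype=np.float64)
    if z_weak.shape != z_strong.shape:
        raise ValueError("view matrices must have identical shapes")
    n = z_weak.shape[0]
    z = np.vstack([z_weak, z_strong])
    u, norms = _normalize_rows(z)
    sim = u @ u.T
    logits = sim / temperature
    np.fill_diagonal(logits, -np.inf)  # the indicator 1(k != i)
    partner = np.concatenate([np.arange(n) + n, np.arange(n)])
    return u, norms, logits, partner


def nt_xent_loss(z_weak: np.ndarray, z_strong: np.ndarray, temperature: float) -> float:
    """Mean NT-Xent loss over all 2N anchors (both views anchor)."""
    _, _, logits, partner = _pair_logits(z_weak, z_strong, temperature)
    shift = logits.max(axis=1, keepdims=True)
    logZ = np.log(np.exp(logits - shift).sum(axis=1)) + shift[:, 0]
    m = logits.shape[0]
    return float(np.mean(logZ - logits[np.arange(m), partner]))


def nt_xent_loss_and_grad(
    z_weak: np.ndarray, z_strong: np.ndarray, temperature: float
) -> tuple[float, np.ndarray, np.ndarray]:
    """Loss plus its gradient w.r.t. both (unnormalized) view matrices."""
    u, norms, logits, partner = _pair_logits(z_weak, z_strong, temperature)
    m = logits.shape[0]
    shift = logits.max(axis=1, keepdims=True)
    expl = np.exp(logits - shift)
    probs = expl / expl.sum(axis=1, keepdims=True)  # diagonal is exactly 0
    loss = float(
        np.mean(np.log(expl.sum(axis=1)) + shift[:, 0] - logits[np.arange(m), partner])
    )
    # dL/ds_{ik} for k != i; pair term subtracts the one-hot partner
    g_sim = probs.copy()
    g_sim[np.arange(m), partner] -= 1.0
    g_sim /= m * temperature
    grad_u = (g_sim + g_sim.T) @ u
    # back through row normalization u = z / ||z||
    grad_z = (grad_u - (grad_u * u).sum(axis=1, keepdims=True) * u) / norms[:, None]
    n = m // 2
    return loss, grad_z[:n], grad_z[n:]


def _contrastive_views(net: AnnotatorNetwork, batch, aug_cfg, rng, source: str):
    xw = weak_augment(batch, aug_cfg, rng)
    xs = strong_augment(batch, aug_cfg, rng)
    n_layers = net.EMBED_LAYER if source == "embedding" else None
    zw, cw = net.forward_cached(xw, n_layers=n_layers)
    zs, cs = net.forward_cached(xs, n_layers=n_layers)
    return zw, cw, zs, cs


def pretrain_stage1(
    net: AnnotatorNetwork,
    unlabeled: UnlabeledSet,
    aug_cfg: AugmentationConfig,
    c_cfg: ContrastiveConfig,
    seed: int,
    log: list | None = None,
) -> AnnotatorNetwork:
    """Adam-train the annotator on the NT-Xent objective over shuffled
    batches of unlabeled cells; mutates and returns ``net``."""
    x = unlabeled.matrix.values
    nt = x.shape[0]
    if nt == 0:
        raise ValueError("unlabeled set is empty")
    batch_size = c_cfg.batch_size
    if batch_size > nt:
        warnings.warn(
            f"batch_size {batch_size} > {nt} unlabeled cells; reducing to {nt}"
        )
        batch_size = nt
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EED]))
    opt = Adam(net.parameters(), lr=c_cfg.learning_rate, owner=net)
    for epoch in range(c_cfg.epochs):
        order = rng.permutation(nt)
        losses = []
        for start in range(0, nt - 1, batch_size):
            idx = order[start : start + batch_size]
            if idx.size < 2:
                continue
            zw, cw, zs, cs = _contrastive_views(
                net, x[idx], aug_cfg, rng, c_cfg.embedding_source
            )
            # ReLU-dead cells (zero-norm embedding in either view) cannot
            # enter the cosine loss; exclude their gradients for this step
            live = (np.linalg.norm(zw, axis=1) > 1e-12) & (
                np.linalg.norm(zs, axis=1) > 1e-12
            )
            if live.sum() < 2:
                continue
            loss, gw_live, gs_live = nt_xent_loss_and_grad(
                zw[live], zs[live], c_cfg.temperature
            )
            gw = np.zeros_like(zw)
            gs = np.zeros_like(zs)
            gw[live] = gw_live
            gs[live] = gs_live
            grads = net.backward(gw, cw)
            for acc, g in zip(grads, net.backward(gs, cs)):
                acc += g
            opt.step(grads)
            losses.append(loss)
        if log is not None:
            log.append(
                {"stage": 1, "epoch": epoch, "loss_contrastive": float(np.mean(losses))}
            )
    return net
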