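"""Weak (Gaussian-noise) and strong (random-masking) views of expression batches.

Both operators share the same stochastic skeleton: each cell is selected
with probability ``apply_prob``, and within a selected cell a uniformly
random subset of ``floor(feature_fraction * D)`` gene positions is
perturbed. The weak view adds N(noise_mean, noise_sd^2) noise at those
positions; the strong view zeroes them. Entries outside the subset are
bit-identical to the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AugmentationConfig", "weak_augment", "strong_augment"]


@dataclass
class AugmentationConfig:
    apply_prob: float = 0.8
    feature_fraction: float = 0.5
    noise_mean: float = 0.0
    noise_sd: float = 0.5
    # per_entry=True replaces the per-cell gate + fixed-size subset with an
    # independent Bernoulli(apply_prob * feature_fraction) per entry.
    per_entry: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.apply_prob <= 1.0:
            raise ValueError("apply_prob must be in [0, 1]")
        if not 0.0 < self.feature_fraction <= 1.0:
            raise ValueError("feature_fraction must be in (0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def _perturbation_mask(
    shape: tuple[int, int], cfg: AugmentationConfig, rng: np.random.Generator
) -> np.ndarray:
    n, d = shape
    if cfg.per_entry:
        return rng.random(shape) < cfg.apply_prob * cfg.feature_fraction
    mask = np.zeros(shape, dtype=bool)
    k = int(np.floor(cfg.feature_fraction * d))
    if k == 0:
        return mask
    gate = rng.random(n) < cfg.apply_prob
    for i in np.flatnonzero(gate):
        mask[i, rng.choice(d, size=k, replace=False)] = True
    return mask


def weak_augment(
    batch: np.ndarray, cfg: AugmentationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Add Gaussian noise to a random gene subset of randomly gated cells."""
    batch = np.asarray(batch, dtype=np.float64)
    if not np.all(np.isfinite(batch)):
        raise ValueError("batch must be finite")
    mask = _perturbation_mask(batch.shape, cfg, rng)
    out = batch.copy()
    n_hit = int(mask.sum())
    if n_hit:
        out[mask] += rng.normal(cfg.noise_mean, cfg.noise_sd, size=n_hit)
    return out


def strong_augment(
    batch: np.ndarray, cfg: AugmentationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Zero out a random gene subset of randomly gated cells."""
    batch = np.asarray(batch, dtype=np.float64)
    if not np.all(np.isfinite(batch)):
        raise ValueError("batch must be finite")
    mask = _perturbation_mask(batch.shape, cfg, rng)
    out = batch.copy()
    out[mask] = 0.0
    return out
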