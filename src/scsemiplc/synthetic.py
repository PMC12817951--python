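"""Desk-scale synthetic scRNA-seq count generator with known cell types.

Counts follow a gamma-Poisson (negative-binomial) model around
type-specific mean profiles with marker-gene upshifts, per-cell lognormal
library-size factors and independent dropout zeroing, so the generated
matrices exercise the same filtering/normalization path as real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ExpressionMatrix, LabeledSet, UnlabeledSet
from .preprocess import PreprocessConfig, run_pipeline, split_by_label_fraction

__all__ = ["SyntheticSpec", "generate", "make_benchmark_fixture"]


@dataclass
class SyntheticSpec:
    n_cells: int = 2000
    n_genes: int = 500
    n_types: int = 5
    type_proportions: list[float] | None = None
    n_marker_genes_per_type: int = 20
    marker_log_fold_change: float = 2.0
    dispersion: float = 2.0  # NB shape; var = mu + mu^2 / dispersion
    dropout_rate: float = 0.3
    library_size_log_sd: float = 0.3
    mean_library_size: float = 2000.0
    seed: int = 0
    # pairs of type indices that share a marker block, the second member
    # shifted by only `near_duplicate_lfc_gap` in log space
    near_duplicate_pairs: list[tuple[int, int]] = field(default_factory=list)
    near_duplicate_lfc_gap: float = 0.5

    def __post_init__(self) -> None:
        if self.type_proportions is None:
            self.type_proportions = [1.0 / self.n_types] * self.n_types
        props = np.asarray(self.type_proportions, dtype=np.float64)
        if len(props) != self.n_types or np.any(props <= 0):
            raise ValueError("type_proportions must be positive, length n_types")
        if abs(props.sum() - 1.0) > 1e-8:
            raise ValueError("type_proportions must sum to 1")
        if self.n_types * self.n_marker_genes_per_type > self.n_genes:
            raise ValueError("marker blocks exceed the gene count")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must be a probability")
        if self.dispersion <= 0 or self.marker_log_fold_change <= 0:
            raise ValueError("dispersion and marker_log_fold_change must be positive")


def _type_means(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """C x G matrix of expected expression per type, normalized so each
    type's total equals mean_library_size."""
    base = rng.lognormal(mean=0.0, sigma=1.0, size=spec.n_genes)
    means = np.tile(base, (spec.n_types, 1))
    k = spec.n_marker_genes_per_type
    dup_second = {b: a for a, b in spec.near_duplicate_pairs}
    for t in range(spec.n_types):
        block = slice(t * k, (t + 1) * k)
        if t in dup_second:
            # near-duplicate: inherits the partner's full-strength marker
            # block and keeps only a weak block of its own, so the pair is
            # separated by a small angular offset rather than magnitude
            partner = slice(dup_second[t] * k, (dup_second[t] + 1) * k)
            means[t, partner] = means[t, partner] * np.exp(spec.marker_log_fold_change)
            means[t, block] = means[t, block] * np.exp(spec.near_duplicate_lfc_gap)
        else:
            means[t, block] = means[t, block] * np.exp(spec.marker_log_fold_change)
    means *= spec.mean_library_size / means.sum(axis=1, keepdims=True)
    return means


def generate(spec: SyntheticSpec) -> tuple[ExpressionMatrix, np.ndarray]:
    """Draw a counts matrix and its 0-based type labels; fully seeded."""
    rng = np.random.default_rng(spec.seed)
    means = _type_means(spec, rng)
    labels = rng.choice(spec.n_types, size=spec.n_cells, p=spec.type_proportions)
    lib = np.exp(rng.normal(0.0, spec.library_size_log_sd, size=spec.n_cells))
    mu = means[labels] * lib[:, None]
    shape = spec.dispersion
    lam = rng.gamma(shape, mu / shape)
    counts = rng.poisson(lam).astype(np.float64)
    if spec.dropout_rate > 0:
        counts[rng.random(counts.shape) < spec.dropout_rate] = 0.0
    cell_ids = [f"cell_{i:05d}" for i in range(spec.n_cells)]
    gene_ids = [f"gene_{j:04d}" for j in range(spec.n_genes)]
    return ExpressionMatrix(counts, cell_ids, gene_ids), labels.astype(np.int64)


def benchmark_spec(difficulty: str, seed: int) -> SyntheticSpec:
    if difficulty == "easy":
        return SyntheticSpec(
            n_cells=2000, n_genes=500, n_types=5,
            n_marker_genes_per_type=20, marker_log_fold_change=2.0,
            dispersion=10.0, dropout_rate=0.2, library_size_log_sd=0.2, seed=seed,
        )
    if difficulty == "hard":
        # two near-duplicate type pairs mimic hard-to-separate subtypes
        return SyntheticSpec(
            n_cells=2000, n_genes=500, n_types=8,
            n_marker_genes_per_type=25, marker_log_fold_change=2.0,
            near_duplicate_pairs=[(0, 1), (4, 5)], near_duplicate_lfc_gap=0.5,
            dispersion=50.0, dropout_rate=0.0, library_size_log_sd=0.1,
            mean_library_size=10000.0, seed=seed,
        )
    raise ValueError(f"unknown difficulty {difficulty!r}")


def make_benchmark_fixture(
    difficulty: str,
    seed: int,
    p: float = 0.1,
    preprocess_cfg: PreprocessConfig | None = None,
) -> tuple[LabeledSet, UnlabeledSet, np.ndarray]:
    """Generate + preprocess + stratified split; the standard test bed.

    Returns ``(labeled, unlabeled, held_out_truth)`` with truth as 0-based
    codes aligned to the unlabeled cells.
    """
    spec = benchmark_spec(difficulty, seed)
    matrix, labels = generate(spec)
    cfg = preprocess_cfg or PreprocessConfig(
        min_genes_per_cell=50, min_cells_per_gene=3, n_hvg=300
    )
    processed, kept = run_pipeline(matrix, cfg)
    kept_labels = labels[kept]
    class_names = [f"type_{t}" for t in range(spec.n_types)]
    return split_by_label_fraction(
        processed,
        [class_names[t] for t in kept_labels],
        p,
        seed,
        class_names,
    )
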