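import numpy as np
import pytest

from scsemiplc.data import ExpressionMatrix, LabeledSet, UnlabeledSet
from scsemiplc.preprocess import PreprocessConfig, run_pipeline, split_by_label_fraction
from scsemiplc.synthetic import SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def _toy_matrix(values) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        [f"c{i}" for i in range(values.shape[0])],
        [f"g{j}" for j in range(values.shape[1])],
    )


@pytest.fixture
def toy_matrix():
    return _toy_matrix


@pytest.fixture(scope="session")
def small_problem():
    """A small preprocessed semi-supervised problem (fast: ~400 cells)."""
    spec = SyntheticSpec(
        n_cells=400,
        n_genes=150,
        n_types=3,
        n_marker_genes_per_type=15,
        marker_log_fold_change=2.0,
        dispersion=10.0,
        dropout_rate=0.2,
        library_size_log_sd=0.2,
        seed=7,
    )
    matrix, labels = generate(spec)
    processed, kept = run_pipeline(
        matrix, PreprocessConfig(min_genes_per_cell=20, min_cells_per_gene=3, n_hvg=100)
    )
    names = [f"type_{t}" for t in range(3)]
    labeled, unlabeled, truth = split_by_label_fraction(
        processed, [names[t] for t in labels[kept]], 0.15, seed=7, class_names=names
    )
    return labeled, unlabeled, truth


@pytest.fixture(scope="session")
def trained_toy_model(small_problem):
    """A model trained enough on the small problem to be clearly better
    than chance; shared across tests to keep the suite fast."""
    from scsemiplc.train import TrainingPlan, fit

    labeled, unlabeled, _ = small_problem
    plan = TrainingPlan(
        stage_epochs=(5, 30, 5),
        stage_lrs=(1e-3, 1e-3, 2e-4),
        batch_size=64,
        seed=7,
    )
    return fit(labeled, unlabeled, plan)
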