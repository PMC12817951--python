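import itertools

import numpy as np
import pytest

from scsemiplc.data import ExpressionMatrix, LabeledSet, UnlabeledSet
from scsemiplc.model import AnnotatorNetwork
from scsemiplc.pseudolabel import (
    ClusterCenters,
    assign_pseudo_labels,
    cosine_distance,
    init_centers_from_labeled,
    spherical_kmeans,
)


def spherical_cloud(rng, directions, n_per, noise=0.05):
    """Unit-ish vectors concentrated around given directions."""
    points, labels = [], []
    for c, d in enumerate(directions):
        d = d / np.linalg.norm(d)
        for _ in range(n_per):
            points.append(d + rng.normal(0, noise, size=len(d)))
            labels.append(c)
    return np.array(points), np.array(labels)


class TestCosineDistance:
    def test_self_distance_zero(self, rng):
        a = rng.normal(size=5)
        assert cosine_distance(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_antipodal_is_one(self, rng):
        a = rng.normal(size=5)
        assert cosine_distance(a, -a) == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_is_half(self):
        assert cosine_distance(np.array([1.0, 0.0]), np.array([0.0, 3.0])) == 0.5

    def test_scale_invariance(self, rng):
        a, b = rng.normal(size=4), rng.normal(size=4)
        assert cosine_distance(a, b) == pytest.approx(cosine_distance(5 * a, 0.1 * b))

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero vector"):
            cosine_distance(np.zeros(3), np.ones(3))


class TestInitCenters:
    def _labeled(self, net, x, y, c):
        m = ExpressionMatrix(
            x, [f"c{i}" for i in range(len(x))], [f"g{j}" for j in range(x.shape[1])]
        )
        return LabeledSet(m, y, [f"t{i}" for i in range(c)])

    def test_single_cell_per_class(self, rng):
        net = AnnotatorNetwork(6, 2, hidden_dims=(8, 5, 4), seed=0)
        x = np.abs(rng.normal(size=(2, 6)))
        labeled = self._labeled(net, x, np.array([0, 1]), 2)
        centers = init_centers_from_labeled(net, labeled)
        emb = net.embed(x)
        for c in range(2):
            expected = emb[c] / np.linalg.norm(emb[c])
            np.testing.assert_allclose(centers.centers[c], expected, atol=1e-10)

    def test_duplicated_cell_direction_unchanged(self, rng):
        net = AnnotatorNetwork(6, 2, hidden_dims=(8, 5, 4), seed=0)
        row = np.abs(rng.normal(size=6))
        x1 = np.vstack([row, np.abs(rng.normal(size=6))])
        x2 = np.vstack([row, row, np.abs(rng.normal(size=6))])
        c1 = init_centers_from_labeled(net, self._labeled(net, x1, np.array([0, 1]), 2))
        c2 = init_centers_from_labeled(net, self._labeled(net, x2, np.array([0, 0, 1]), 2))
        np.testing.assert_allclose(c1.centers[0], c2.centers[0], atol=1e-10)

    def test_matches_normalize_sum_renormalize_oracle(self, rng):
        net = AnnotatorNetwork(10, 3, seed=1)
        x = np.abs(rng.normal(size=(12, 10)))
        y = np.repeat([0, 1, 2], 4)
        labeled = self._labeled(net, x, y, 3)
        centers = init_centers_from_labeled(net, labeled)
        emb = net.embed(x)
        for c in range(3):
            unit = emb[y == c] / np.linalg.norm(emb[y == c], axis=1, keepdims=True)
            expected = unit.sum(axis=0)
            expected /= np.linalg.norm(expected)
            np.testing.assert_allclose(centers.centers[c], expected, atol=1e-6)


class TestSphericalKMeans:
    def test_fixed_point(self, rng):
        directions = rng.normal(size=(3, 6))
        centers = ClusterCenters(
            directions / np.linalg.norm(directions, axis=1, keepdims=True)
        )
        state = spherical_kmeans(centers.centers.copy(), centers)
        assert state.converged
        assert state.n_iterations == 1
        np.testing.assert_array_equal(state.assignments, [0, 1, 2])

    def test_antipodal_recovery(self, rng):
        d = rng.normal(size=4)
        points, labels = spherical_cloud(rng, [d, -d], n_per=30, noise=0.05)
        init = ClusterCenters(np.array([d / np.linalg.norm(d), -d / np.linalg.norm(d)]))
        state = spherical_kmeans(points, init)
        np.testing.assert_array_equal(state.assignments, labels)

    def test_self_consistency_of_final_assignments(self, rng):
        points = rng.normal(size=(40, 5))
        init_dirs = rng.normal(size=(4, 5))
        init = ClusterCenters(init_dirs / np.linalg.norm(init_dirs, axis=1, keepdims=True))
        state = spherical_kmeans(points, init)
        unit = points / np.linalg.norm(points, axis=1, keepdims=True)
        reassign = np.argmax(unit @ state.centers.centers.T, axis=1)
        np.testing.assert_array_equal(state.assignments, reassign)

    def test_unit_norm_centers_and_monotone_objective(self, rng):
        points = rng.normal(size=(60, 8))
        init_dirs = rng.normal(size=(5, 8))
        init = ClusterCenters(init_dirs / np.linalg.norm(init_dirs, axis=1, keepdims=True))
        state = spherical_kmeans(points, init)
        np.testing.assert_allclose(
            np.linalg.norm(state.centers.centers, axis=1), 1.0, atol=1e-6
        )
        hist = state.objective_history
        assert all(b <= a + 1e-9 for a, b in zip(hist, hist[1:]))

    def test_tiny_instance_objective_sane(self, rng):
        """Final objective is locally optimal: no single-pass reassignment
        against exhaustively recomputed centers beats self-consistency."""
        points = rng.normal(size=(6, 3))
        init_dirs = rng.normal(size=(2, 3))
        init = ClusterCenters(init_dirs / np.linalg.norm(init_dirs, axis=1, keepdims=True))
        state = spherical_kmeans(points, init)
        unit = points / np.linalg.norm(points, axis=1, keepdims=True)
        final_obj = state.objective_history[-1]
        # exhaustive check: the converged objective cannot be worse than the
        # objective of its own assignment with recomputed centers
        for assign in itertools.product([0, 1], repeat=6):
            assign = np.array(assign)
            if not np.array_equal(assign, state.assignments):
                continue
            centers = state.centers.centers
            obj = 0.5 * (1 - (unit * centers[assign]).sum(axis=1)).sum()
            assert final_obj == pytest.approx(obj, abs=1e-9)

    def test_dimension_mismatch(self, rng):
        init = ClusterCenters(np.eye(3))
        with pytest.raises(ValueError, match="incompatible"):
            spherical_kmeans(rng.normal(size=(5, 4)), init)

    def test_vmf_like_label_recovery(self, rng):
        directions = rng.normal(size=(4, 12))
        points, labels = spherical_cloud(rng, directions, n_per=50, noise=0.02)
        unit_dirs = directions / np.linalg.norm(directions, axis=1, keepdims=True)
        state = spherical_kmeans(points, ClusterCenters(unit_dirs))
        assert (state.assignments == labels).mean() >= 0.99

    def test_zero_row_euclidean_fallback(self, rng):
        points = rng.normal(size=(10, 4))
        points[3] = 0.0
        init_dirs = rng.normal(size=(2, 4))
        init = ClusterCenters(init_dirs / np.linalg.norm(init_dirs, axis=1, keepdims=True))
        with pytest.warns(UserWarning, match="Euclidean"):
            state = spherical_kmeans(points, init)
        d2 = ((init.centers - 0.0) ** 2).sum(axis=1)
        assert state.assignments[3] in (0, 1)


class TestAssignPseudoLabels:
    def test_closed_loop_on_trained_model(self, small_problem, trained_toy_model):
        labeled, _, _ = small_problem
        state = assign_pseudo_labels(
            trained_toy_model.net, labeled, UnlabeledSet(labeled.matrix)
        )
        agreement = (state.assignments == labeled.labels).mean()
        assert agreement >= 0.9

    def test_single_cell(self, small_problem, trained_toy_model):
        labeled, unlabeled, _ = small_problem
        one = UnlabeledSet(unlabeled.matrix.subset_cells(np.array([0])))
        state = assign_pseudo_labels(trained_toy_model.net, labeled, one)
        assert state.assignments.shape == (1,)
        assert 0 <= state.assignments[0] < labeled.n_classes

    def test_row_permutation_equivariance(self, small_problem, trained_toy_model):
        labeled, unlabeled, _ = small_problem
        sub = unlabeled.matrix.subset_cells(np.arange(50))
        base = assign_pseudo_labels(trained_toy_model.net, labeled, UnlabeledSet(sub))
        perm = np.random.default_rng(0).permutation(50)
        permuted = assign_pseudo_labels(
            trained_toy_model.net, labeled, UnlabeledSet(sub.subset_cells(perm))
        )
        np.testing.assert_array_equal(base.assignments[perm], permuted.assignments)


class TestExportPseudoLabels:
    def test_tsv_roundtrip(self, tmp_path, rng):
        from scsemiplc.pseudolabel import PseudoLabelState, export_pseudo_labels

        centers = rng.normal(size=(2, 3))
        centers /= np.linalg.norm(centers, axis=1, keepdims=True)
        state = PseudoLabelState(
            assignments=np.array([0, 1, 1]),
            centers=ClusterCenters(centers),
            n_iterations=4,
            converged=True,
        )
        path = tmp_path / "pseudo.tsv"
        export_pseudo_labels(state, ["a", "b", "c"], ["x", "y"], path,
                             confidences=np.array([0.5, 0.25, 1.0]))
        lines = path.read_text().splitlines()
        assert lines[0].startswith("#") and "4 iteration" in lines[0]
        assert lines[1].split("\t") == ["cell_id", "pseudo_label", "confidence"]
        assert lines[2].split("\t")[:2] == ["a", "x"]
        assert float(lines[3].split("\t")[2]) == 0.25

    def test_misaligned_ids_rejected(self, rng):
        from scsemiplc.pseudolabel import PseudoLabelState, export_pseudo_labels

        centers = np.eye(2)
        state = PseudoLabelState(np.array([0]), ClusterCenters(centers), 1, True)
        with pytest.raises(ValueError, match="align"):
            export_pseudo_labels(state, ["a", "b"], ["x", "y"], "/dev/null")
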