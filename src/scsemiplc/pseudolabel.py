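"""Pseudo-label generation: class-center-seeded spherical K-means on
second-layer embeddings.

Because every initial center is the (renormalized) resultant of one
labeled class's normalized embeddings, cluster index c IS class c, so the
converged assignment vector can be used directly as pseudo-labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import LabeledSet, UnlabeledSet
from .model import AnnotatorNetwork

__all__ = [
    "ClusterCenters",
    "PseudoLabelState",
    "cosine_distance",
    "init_centers_from_labeled",
    "spherical_kmeans",
    "assign_pseudo_labels",
]


def cosine_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Angular distance (1 - cos) / 2 in [0, 1]; 0 iff parallel."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        raise ValueError("cosine distance undefined for a zero vector")
    return float(0.5 * (1.0 - float(a @ b) / (na * nb)))


@dataclass
class ClusterCenters:
    """C x d matrix of unit-norm class centers; row c is class c."""

    centers: np.ndarray

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=np.float64)
        if self.centers.ndim != 2:
            raise ValueError("centers must be a 2-D matrix")
        norms = np.linalg.norm(self.centers, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("every center row must have unit L2 norm")

    @property
    def n_classes(self) -> int:
        return self.centers.shape[0]


@dataclass
class PseudoLabelState:
    assignments: np.ndarray  # 0-based class codes, length Nt
    centers: ClusterCenters
    n_iterations: int
    converged: bool
    objective_history: list[float] = field(default_factory=list)


def _normalized_embeddings(emb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit rows plus a mask of rows that were (near-)zero and could not be
    normalized; those fall back to Euclidean assignment."""
    emb = np.asarray(emb, dtype=np.float64)
    norms = np.linalg.norm(emb, axis=1)
    dead = norms < 1e-12
    safe = np.where(dead, 1.0, norms)
    return emb / safe[:, None], dead


def init_centers_from_labeled(
    net: AnnotatorNetwork, labeled: LabeledSet
) -> ClusterCenters:
    """Per class: sum the L2-normalized phi_2 embeddings of its labeled
    cells, then renormalize the sum to unit length."""
    emb = net.embed(labeled.matrix.values)
    unit, dead = _normalized_embeddings(emb)
    if np.any(dead):
        warnings.warn(
            f"{int(dead.sum())} labeled cell(s) have zero-norm embeddings and "
            "are excluded from center initialization"
        )
    c = labeled.n_classes
    centers = np.zeros((c, emb.shape[1]))
    for cls in range(c):
        members = (labeled.labels == cls) & ~dead
        if not members.any():
            raise ValueError(
                f"class {labeled.class_names[cls]!r} has no labeled cells "
                "with usable embeddings"
            )
        resultant = unit[members].sum(axis=0)
        norm = np.linalg.norm(resultant)
        if norm < 1e-8:
            raise ValueError(
                f"class {labeled.class_names[cls]!r}: normalized embeddings "
                "cancel (antipodal degenerate center)"
            )
        centers[cls] = resultant / norm
    return ClusterCenters(centers)


def _assign(unit: np.ndarray, dead: np.ndarray, raw: np.ndarray, centers: np.ndarray):
    """Cosine arg min (== dot-product arg max on unit vectors); ties go to
    the lowest class index via argmax's first-hit rule."""
    sim = unit @ centers.T
    assign = np.argmax(sim, axis=1)
    if dead.any():
        d2 = ((raw[dead][:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        assign[dead] = np.argmin(d2, axis=1)
    return assign


def spherical_kmeans(
    embeddings: np.ndarray,
    init: ClusterCenters,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> PseudoLabelState:
    """Alternate cosine-distance assignment and normalized-mean center
    updates from the given class-seeded centers.

    Empty clusters keep their previous center so class identity is never
    lost. Convergence = unchanged assignments or max center movement
    (1 - dot) below ``tol``.
    """
    emb = np.asarray(embeddings, dtype=np.float64)
    if emb.ndim != 2 or emb.shape[1] != init.centers.shape[1]:
        raise ValueError(
            f"embedding dim {emb.shape} incompatible with centers "
            f"{init.centers.shape}"
        )
    unit, dead = _normalized_embeddings(emb)
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} zero-norm embedding row(s): falling back to "
            "Euclidean nearest-center assignment for them"
        )
    centers = init.centers.copy()
    c = centers.shape[0]
    assign = _assign(unit, dead, emb, centers)
    history: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        history.append(_objective(unit, dead, emb, centers, assign))
        new_centers = centers.copy()
        for cls in range(c):
            members = assign == cls
            if not members.any():
                continue  # empty cluster: retain previous center
            resultant = unit[members].sum(axis=0)
            norm = np.linalg.norm(resultant)
            if norm < 1e-12:
                continue
            new_centers[cls] = resultant / norm
        movement = float(np.max(1.0 - (new_centers * centers).sum(axis=1)))
        centers = new_centers
        new_assign = _assign(unit, dead, emb, centers)
        if np.array_equal(new_assign, assign) or movement < tol:
            assign = new_assign
            converged = True
            break
        assign = new_assign
    history.append(_objective(unit, dead, emb, centers, assign))
    return PseudoLabelState(
        assignments=assign,
        centers=ClusterCenters(centers),
        n_iterations=n_iter,
        converged=converged,
        objective_history=history,
    )


def _objective(unit, dead, raw, centers, assign) -> float:
    """Sum of cosine distances to assigned centers (dead rows excluded)."""
    live = ~dead
    dots = (unit[live] * centers[assign[live]]).sum(axis=1)
    return float(0.5 * (1.0 - dots).sum())


def export_pseudo_labels(
    state: PseudoLabelState,
    cell_ids: list[str],
    class_names: list[str],
    path,
    confidences: np.ndarray | None = None,
) -> None:
    """Write the pseudo-label table as TSV: cell_id, pseudo_label and
    (optionally) confidence, with the iteration count in a header comment."""
    if len(cell_ids) != len(state.assignments):
        raise ValueError("cell_ids must align with assignments")
    with open(path, "w") as fh:
        fh.write(
            f"# spherical K-means: {state.n_iterations} iteration(s), "
            f"converged={state.converged}\n"
        )
        fh.write("cell_id\tpseudo_label\tconfidence\n")
        for i, cid in enumerate(cell_ids):
            conf = "" if confidences is None else f"{confidences[i]:.6f}"
            fh.write(f"{cid}\t{class_names[state.assignments[i]]}\t{conf}\n")


def assign_pseudo_labels(
    net: AnnotatorNetwork,
    labeled: LabeledSet,
    unlabeled: UnlabeledSet,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> PseudoLabelState:
    """embed -> class-center init -> spherical K-means; the assignment
    vector doubles as the pseudo-label vector."""
    unlabeled.validate_against(labeled)
    init = init_centers_from_labeled(net, labeled)
    emb = net.embed(unlabeled.matrix.values)
    return spherical_kmeans(emb, init, max_iter=max_iter, tol=tol)
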