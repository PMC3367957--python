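"""Niche-overlap matrices, Ward clustering and non-metric MDS.

Pianka's overlap index between two resource-use vectors u, v is the cosine
similarity ``sum(u*v) / sqrt(sum(u^2) * sum(v^2))``: 1 when the vectors are
proportional (identical diets), 0 when their supports are disjoint.  The same
form applied to two prey's mortality-by-predator vectors measures how much of
their predator assemblage they share.  Dissimilarities ``D = 1 - overlap``
feed Ward's minimum-variance hierarchical clustering and a 2-D non-metric
multidimensional scaling (Kruskal stress-1, SMACOF with monotone regression).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.manifold import smacof

from .selectivity import SelectivityProfile

__all__ = [
    "pianka", "diet_overlap_matrix", "predation_pressure_overlap_matrix",
    "to_dissimilarity", "ward_cluster", "ClusterTree", "nmds",
    "OrdinationResult",
]


def pianka(u: np.ndarray, v: np.ndarray) -> float:
    """Pianka overlap of two non-negative resource-use vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors differ in length")
    if (u < 0).any() or (v < 0).any():
        raise ValueError("resource-use vectors must be non-negative")
    nu, nv = np.sqrt((u * u).sum()), np.sqrt((v * v).sum())
    if nu == 0 or nv == 0:
        raise ValueError("overlap undefined for an all-zero resource-use vector")
    return float((u * v).sum() / (nu * nv))


def _overlap_frame(vectors: pd.DataFrame) -> pd.DataFrame:
    labels = list(vectors.index)
    n = len(labels)
    out = np.eye(n)
    arr = vectors.to_numpy(dtype=float)
    for i in range(n):
        for j in range(i):
            out[i, j] = out[j, i] = pianka(arr[i], arr[j])
    return pd.DataFrame(out, index=labels, columns=labels)


def diet_overlap_matrix(profiles: list[SelectivityProfile]) -> pd.DataFrame:
    """Predator x predator Pianka overlaps of species-mean alpha vectors."""
    if not profiles:
        raise ValueError("no profiles given")
    prey_ids = profiles[0].prey_ids
    vectors = pd.DataFrame(
        [p.mean_alpha for p in profiles],
        index=[p.predator_stage_id for p in profiles],
        columns=list(prey_ids),
    )
    return _overlap_frame(vectors)


def predation_pressure_overlap_matrix(mortality: pd.DataFrame) -> pd.DataFrame:
    """Prey x prey Pianka overlaps of mortality-by-predator vectors.

    ``mortality`` is a prey x predator table of mean proportions consumed
    (see :func:`preysel.vulnerability.mortality_table`).
    """
    return _overlap_frame(mortality)


def to_dissimilarity(overlap: pd.DataFrame) -> pd.DataFrame:
    """``D = 1 - overlap`` with an exactly zero diagonal."""
    arr = overlap.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T):
        raise ValueError("overlap matrix is not symmetric")
    d = 1.0 - arr
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 1.0)
    return pd.DataFrame(d, index=overlap.index, columns=overlap.columns)


@dataclass(frozen=True)
class ClusterTree:
    """Agglomerative tree in scipy linkage form with leaf labels."""

    labels: tuple[str, ...]
    linkage: np.ndarray   # scipy (n-1) x 4 matrix; heights = merge criterion
    variant: str

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, k: int) -> dict[str, int]:
        """Cut into ``k`` groups; group ids renumbered in leaf order."""
        flat = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        remap: dict[int, int] = {}
        out = {}
        for label, g in zip(self.labels, flat):
            out[label] = remap.setdefault(int(g), len(remap) + 1)
        return out

    def groups(self, k: int) -> list[frozenset[str]]:
        cut = self.cut(k)
        ids = sorted(set(cut.values()))
        return [frozenset(l for l, g in cut.items() if g == gid) for gid in ids]

    def to_newick(self) -> str:
        """Newick string; branch lengths from merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height):
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return rec(tree, tree.dist) + ";"


def ward_cluster(dissimilarity: pd.DataFrame, variant: str = "ward.D") -> ClusterTree:
    """Ward's minimum-variance clustering of a dissimilarity matrix.

    ``variant="ward.D"`` (default) runs the classic Lance-Williams Ward
    update on the raw dissimilarities — the behaviour of R's original
    ``hclust(method="ward")`` — implemented as scipy Ward linkage on the
    element-wise square root with squared merge heights.  ``"ward.D2"``
    applies scipy Ward linkage directly (heights in dissimilarity units).
    Ties between equal-criterion merge candidates follow scipy's scan order
    over pair indices, which is deterministic for a fixed label order.
    """
    arr = dissimilarity.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T):
        raise ValueError("dissimilarity matrix is not symmetric")
    if arr.shape[0] < 2:
        raise ValueError("need at least two labels to cluster")
    y = squareform(arr, checks=False)
    if variant == "ward.D":
        z = hierarchy.linkage(np.sqrt(y), method="ward")
        z = z.copy()
        z[:, 2] = z[:, 2] ** 2
    elif variant == "ward.D2":
        z = hierarchy.linkage(y, method="ward")
    else:
        raise ValueError(f"unknown Ward variant {variant!r}")
    return ClusterTree(labels=tuple(dissimilarity.index), linkage=z, variant=variant)


@dataclass(frozen=True)
class OrdinationResult:
    labels: tuple[str, ...]
    coordinates: np.ndarray   # n x dims
    stress: float             # Kruskal stress-1 on the percent scale (x100)
    n_restarts: int
    seed: int
    restart_stresses: np.ndarray  # final stress-1 (x100) of every start

    def to_frame(self) -> pd.DataFrame:
        cols = [f"axis{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=list(self.labels), columns=cols)


def nmds(
    dissimilarity: pd.DataFrame,
    dims: int = 2,
    restarts: int = 20,
    seed: int = 0,
    max_iter: int = 500,
) -> OrdinationResult:
    """Non-metric MDS by SMACOF majorization with monotone regression.

    Runs ``restarts`` random starts (seeded; reproducible) and returns the
    configuration with the lowest final Kruskal stress-1, reported multiplied
    by 100 as conventional for ordination summaries.
    """
    arr = dissimilarity.to_numpy(dtype=float)
    n = arr.shape[0]
    if n < 3:
        raise ValueError("NMDS needs at least 3 labels")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    rng = np.random.default_rng(seed)
    best = None
    finals = []
    for _ in range(restarts):
        sub = int(rng.integers(0, 2**31 - 1))
        coords, stress = smacof(
            arr, metric=False, n_components=dims, n_init=1,
            random_state=sub, max_iter=max_iter, eps=1e-9,
            normalized_stress=True,
        )
        finals.append(stress)
        if best is None or stress < best[1]:
            best = (coords, stress)
    coords, stress = best
    return OrdinationResult(
        labels=tuple(dissimilarity.index),
        coordinates=coords,
        stress=float(stress) * 100.0,
        n_restarts=restarts,
        seed=seed,
        restart_stresses=np.asarray(finals) * 100.0,
    )
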