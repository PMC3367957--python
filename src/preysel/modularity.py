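"""Weighted bipartite modularity (Barber's Q) and module detection.

The experimental food web is a two-mode network: predator stages in rows,
prey types in columns, edge weights given by an interaction-strength measure
(species-mean Manly's alpha or mean prey mortality) scaled to integers.  For
a joint partition g of rows and columns,

    Q = (1/F) * sum_ij (A_ij - k_i * d_j / F) * [g(row i) == g(col j)]

with F the total weight, k_i row sums and d_j column sums.  Q is maximised by
simulated annealing over joint label assignments (move / merge / split
proposals) with restarts; an exhaustive enumerator over all joint partitions
provides the exact optimum for small webs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BipartiteWeb", "ModulePartition", "scale_weights", "bipartite_modularity_q",
    "find_modules", "exhaustive_modules",
]


@dataclass(frozen=True)
class BipartiteWeb:
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    weights: np.ndarray   # non-negative integers, rows x cols
    measure: str = "manly_alpha"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights)
        if w.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("weight matrix shape does not match labels")
        if (w < 0).any():
            raise ValueError("weights must be non-negative")

    @property
    def n_nodes(self) -> int:
        return len(self.row_labels) + len(self.col_labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.weights, index=list(self.row_labels), columns=list(self.col_labels)
        )


def scale_weights(
    raw: pd.DataFrame, factor: int = 100, measure: str = "manly_alpha"
) -> BipartiteWeb:
    """Scale a [0, 1] interaction matrix to integers (round half away handled
    by nearest-integer rounding); warns about all-zero rows/columns."""
    arr = raw.to_numpy(dtype=float)
    if (arr < 0).any() or (arr > 1).any():
        raise ValueError("raw interaction strengths must lie in [0, 1]")
    w = np.rint(arr * factor).astype(int)
    for i, label in enumerate(raw.index):
        if w[i, :].sum() == 0:
            warnings.warn(f"row {label!r} has no interactions after scaling", stacklevel=2)
    for j, label in enumerate(raw.columns):
        if w[:, j].sum() == 0:
            warnings.warn(f"column {label!r} has no interactions after scaling", stacklevel=2)
    return BipartiteWeb(
        row_labels=tuple(str(i) for i in raw.index),
        col_labels=tuple(str(c) for c in raw.columns),
        weights=w,
        measure=measure,
    )


def _canonical(labels: np.ndarray) -> tuple[int, ...]:
    """Relabel module ids by first occurrence (restricted-growth form)."""
    remap: dict[int, int] = {}
    return tuple(remap.setdefault(int(l), len(remap)) for l in labels)


@dataclass(frozen=True)
class ModulePartition:
    web: BipartiteWeb
    row_modules: tuple[int, ...]
    col_modules: tuple[int, ...]
    q: float
    seed: int | None = None
    restarts: int | None = None
    method: str = "annealing"

    @property
    def n_modules(self) -> int:
        return len(set(self.row_modules) | set(self.col_modules))

    def module_members(self) -> list[tuple[frozenset[str], frozenset[str]]]:
        """(predator set, prey set) per module, ordered by module id."""
        ids = sorted(set(self.row_modules) | set(self.col_modules))
        out = []
        for mid in ids:
            rows = frozenset(
                l for l, g in zip(self.web.row_labels, self.row_modules) if g == mid
            )
            cols = frozenset(
                l for l, g in zip(self.web.col_labels, self.col_modules) if g == mid
            )
            out.append((rows, cols))
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (l, "row", g) for l, g in zip(self.web.row_labels, self.row_modules)
        ] + [
            (l, "column", g) for l, g in zip(self.web.col_labels, self.col_modules)
        ]
        return pd.DataFrame(rows, columns=["label", "role", "module"])


def bipartite_modularity_q(
    web: BipartiteWeb, row_modules: np.ndarray, col_modules: np.ndarray
) -> float:
    """Barber modularity of a joint partition (vectorised null-model form)."""
    a = np.asarray(web.weights, dtype=float)
    f = a.sum()
    if f == 0:
        raise ValueError("web has no interactions")
    k = a.sum(axis=1)
    d = a.sum(axis=0)
    same = np.asarray(row_modules)[:, None] == np.asarray(col_modules)[None, :]
    return float(((a - np.outer(k, d) / f) * same).sum() / f)


def _anneal_once(web: BipartiteWeb, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    nr, nc = web.weights.shape
    n = nr + nc
    max_mod = n
    labels = rng.integers(0, max(2, min(nr, nc)), size=n)
    q = bipartite_modularity_q(web, labels[:nr], labels[nr:])
    best_labels, best_q = labels.copy(), q
    t = 0.05
    cooling = 0.95
    sweeps = 60
    for _ in range(sweeps):
        for _ in range(2 * n):
            move = rng.random()
            proposal = labels.copy()
            if move < 0.7:
                # move one node to an existing or fresh module
                i = int(rng.integers(0, n))
                proposal[i] = int(rng.integers(0, max_mod))
            elif move < 0.85:
                # merge two modules
                mods = np.unique(labels)
                if len(mods) < 2:
                    continue
                a, b = rng.choice(mods, size=2, replace=False)
                proposal[proposal == a] = b
            else:
                # split a module by a random bisection
                mods = np.unique(labels)
                src = int(rng.choice(mods))
                members = np.flatnonzero(labels == src)
                if len(members) < 2:
                    continue
                mask = rng.random(len(members)) < 0.5
                if mask.all() or not mask.any():
                    continue
                fresh = int(max(mods)) + 1 if int(max(mods)) + 1 < max_mod else src
                proposal[members[mask]] = fresh
            q_new = bipartite_modularity_q(web, proposal[:nr], proposal[nr:])
            if q_new >= q or rng.random() < np.exp((q_new - q) / t):
                labels, q = proposal, q_new
                if q > best_q:
                    best_labels, best_q = labels.copy(), q
        t *= cooling
    # greedy polish: single-node moves to first improvement until none remains
    improved = True
    labels, q = best_labels, best_q
    while improved:
        improved = False
        for i in range(n):
            current = labels[i]
            for target in range(max_mod):
                if target == current:
                    continue
                labels[i] = target
                q_new = bipartite_modularity_q(web, labels[:nr], labels[nr:])
                if q_new > q + 1e-12:
                    q = q_new
                    current = target
                    improved = True
                else:
                    labels[i] = current
    return labels, q


def find_modules(
    web: BipartiteWeb, restarts: int = 50, seed: int = 0
) -> ModulePartition:
    """Best-of-restarts simulated annealing maximisation of Barber's Q.

    Deterministic for a fixed seed.  Degenerate webs (a single row or a
    single column) collapse to the trivial one-module partition.
    """
    nr, nc = web.weights.shape
    if nr < 2 or nc < 2:
        labels = np.zeros(nr + nc, dtype=int)
        q = bipartite_modularity_q(web, labels[:nr], labels[nr:])
        return ModulePartition(
            web=web, row_modules=_canonical(labels[:nr]),
            col_modules=_canonical(labels[nr:]), q=q, seed=seed,
            restarts=restarts, method="trivial",
        )
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, float] | None = None
    for _ in range(restarts):
        labels, q = _anneal_once(web, rng)
        if best is None or q > best[1]:
            best = (labels, q)
    labels, q = best
    joint = _canonical(labels)
    return ModulePartition(
        web=web, row_modules=joint[:nr], col_modules=joint[nr:], q=q,
        seed=seed, restarts=restarts, method="annealing",
    )


def _set_partitions(n: int):
    """Restricted-growth enumeration of all partitions of range(n)."""
    labels = np.zeros(n, dtype=int)

    def rec(i: int, max_used: int):
        if i == n:
            yield labels.copy()
            return
        for l in range(max_used + 2):
            labels[i] = l
            yield from rec(i + 1, max(max_used, l))

    yield from rec(0, -1)


def exhaustive_modules(web: BipartiteWeb) -> ModulePartition:
    """Exact Q maximum by enumerating every joint partition (small webs only)."""
    nr, nc = web.weights.shape
    n = nr + nc
    if n > 12:
        raise ValueError("exhaustive enumeration is limited to 12 nodes")
    best_q = -np.inf
    best = None
    for labels in _set_partitions(n):
        q = bipartite_modularity_q(web, labels[:nr], labels[nr:])
        if q > best_q + 1e-15:
            best_q, best = q, labels
    joint = _canonical(best)
    return ModulePartition(
        web=web, row_modules=joint[:nr], col_modules=joint[nr:], q=float(best_q),
        method="exhaustive",
    )
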