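"""TM-only similarity matrix and average-linkage (UPGMA) tree.

The superfamily tree is built from pairwise TM percent similarity alone
(loops ignored): dissimilarity = 100 - similarity, clustered by UPGMA.
A node's height is the average dissimilarity at which its two clusters
merge; branch lengths are half-height differences, so the leaf-to-leaf path
length through the root of a two-leaf clade equals their dissimilarity.

The in-package UPGMA exists because determinism requires an explicit tie
rule (lexicographically smallest pair of cluster labels) and because a
greedy sequential variant — grow one cluster by repeatedly attaching the
outsider with the lowest average dissimilarity — is offered as an
alternative mode.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from gross.similarity import AlignmentEntry, SubstitutionMatrix, TMSpans, tm_similarity


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric percent-similarity matrix over named proteins."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        ids = tuple(self.ids)
        values = np.asarray(self.values, dtype=float)
        n = len(ids)
        if values.shape != (n, n):
            raise ValueError(f"matrix shape {values.shape} does not match {n} ids")
        if not np.allclose(values, values.T):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(values), 100.0):
            raise ValueError("diagonal must be 100")
        if values.min() < 0 or values.max() > 100 + 1e-9:
            raise ValueError("entries must lie in [0, 100]")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "values", values)

    def dissimilarity(self) -> np.ndarray:
        return 100.0 - self.values

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(ids=tuple(df.index.astype(str)), values=df.to_numpy(dtype=float))


def build_similarity_matrix(
    entries: Sequence[AlignmentEntry],
    matrix: SubstitutionMatrix | None = None,
    tm_spans: TMSpans | None = None,
) -> SimilarityMatrix:
    """All-pairs TM percent similarity over the seven helices."""
    if len(entries) < 2:
        raise ValueError("need at least 2 entries")
    matrix = matrix or SubstitutionMatrix.blosum62()
    n = len(entries)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            s = tm_similarity(entries[i], entries[j], tm_spans=tm_spans, matrix=matrix)
            values[i, j] = values[j, i] = s
    return SimilarityMatrix(ids=tuple(e.uniprot_ac for e in entries), values=values)


@dataclass
class _Cluster:
    label: str              # lexicographically smallest member id (tie rule)
    size: int
    height: float           # dissimilarity at which this cluster formed
    node: TreeNode


def _merge(a: _Cluster, b: _Cluster, height: float) -> _Cluster:
    """Join two clusters at the given dissimilarity; ultrametric branch lengths."""
    for child in (a, b):
        child.node.length = (height - child.height) / 2.0
    node = TreeNode(children=[a.node, b.node])
    return _Cluster(label=min(a.label, b.label), size=a.size + b.size, height=height, node=node)


def cluster_tree(m: SimilarityMatrix, method: str = "upgma") -> TreeNode:
    """Agglomerative tree on dissimilarity (100 - similarity).

    ``method='upgma'``: standard average linkage; at each step the pair with
    the smallest average dissimilarity merges, ties broken by the
    lexicographically smallest (label, label) pair.  ``method='greedy'``: a
    single cluster grows from the closest pair by repeatedly absorbing the
    non-member with the lowest average dissimilarity to the members —
    a sequential variant that yields a caterpillar topology.
    """
    if method not in ("upgma", "greedy"):
        raise ValueError(f"unknown method {method!r}")
    d = m.dissimilarity()
    clusters = [
        _Cluster(label=name, size=1, height=0.0, node=TreeNode(name=name))
        for name in m.ids
    ]
    if len(clusters) == 1:
        return clusters[0].node
    dist: dict[tuple[int, int], float] = {}
    next_id = len(clusters)
    active: dict[int, _Cluster] = dict(enumerate(clusters))
    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            dist[(i, j)] = float(d[i, j])

    def pair_key(i: int, j: int) -> tuple[float, str, str]:
        la, lb = sorted((active[i].label, active[j].label))
        return dist[(min(i, j), max(i, j))], la, lb

    def closest_pair() -> tuple[int, int]:
        keys = sorted(active)
        best = None
        best_key = None
        for a_i, i in enumerate(keys):
            for j in keys[a_i + 1 :]:
                k = pair_key(i, j)
                if best_key is None or k < best_key:
                    best_key, best = k, (i, j)
        assert best is not None
        return best

    if method == "greedy":
        i, j = closest_pair()
        current = _do_merge(active, dist, i, j, next_id)
        next_id += 1
        while len(active) > 1:
            # attach the outsider with the lowest average dissimilarity to the
            # growing cluster (ties by label)
            others = [k for k in active if k != current]
            best = min(
                others,
                key=lambda k: (dist[(min(k, current), max(k, current))], active[k].label),
            )
            current = _do_merge(active, dist, current, best, next_id)
            next_id += 1
        return active[current].node

    while len(active) > 1:
        i, j = closest_pair()
        _do_merge(active, dist, i, j, next_id)
        next_id += 1
    (root,) = active.values()
    return root.node


def _do_merge(active: dict[int, _Cluster], dist: dict[tuple[int, int], float], i: int, j: int, new_id: int) -> int:
    """Merge clusters i and j into new_id, updating average-linkage distances."""
    ca, cb = active[i], active[j]
    height = dist[(min(i, j), max(i, j))]
    merged = _merge(ca, cb, height)
    for k in list(active):
        if k in (i, j):
            continue
        dik = dist.pop((min(i, k), max(i, k)))
        djk = dist.pop((min(j, k), max(j, k)))
        dist[(min(new_id, k), max(new_id, k))] = (ca.size * dik + cb.size * djk) / (ca.size + cb.size)
    del dist[(min(i, j), max(i, j))]
    del active[i], active[j]
    active[new_id] = merged
    return new_id


def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Standard Newick with branch lengths from merge heights."""
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")
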