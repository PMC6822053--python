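"""Patristic distances averaged over a set of phylogenies.

A set of candidate trees (e.g. a posterior sample) is reduced to one
pairwise distance matrix by computing, per tree, the patristic distance
(sum of branch lengths on the path between two leaves) and averaging
elementwise across trees.  Averaging over trees can break tree
additivity (the mean matrix need not correspond to any single tree);
only per-tree matrices are guaranteed tree metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .data_io import TreeSet

__all__ = [
    "PhyloDistanceMatrix",
    "patristic_matrix",
    "average_patristic",
    "align_matrices",
]


@dataclass
class PhyloDistanceMatrix:
    """Mean pairwise patristic distances over a tree set."""

    g: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.g.to_numpy(float)
        if not np.allclose(vals, vals.T):
            raise ValueError("phylogenetic distance matrix is not symmetric")
        if (vals < -1e-12).any():
            raise ValueError("negative patristic distances")

    @property
    def species(self) -> list[str]:
        return list(self.g.index)


def patristic_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """Pairwise patristic distances for one tree, species sorted."""
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node and edge.length is None:
            raise ValueError("tree has a missing branch length")
    pdm = tree.phylogenetic_distance_matrix()
    # the taxon namespace may be shared across a tree set; use this
    # tree's own leaves
    taxa = sorted(
        (leaf.taxon for leaf in tree.leaf_node_iter()), key=lambda t: t.label
    )
    labels = [t.label for t in taxa]
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=labels, columns=labels)


def average_patristic(treeset: TreeSet) -> PhyloDistanceMatrix:
    """Elementwise arithmetic mean of per-tree patristic matrices."""
    total: pd.DataFrame | None = None
    for tree in treeset.trees:
        m = patristic_matrix(tree)
        if total is None:
            total = m
        else:
            if list(m.index) != list(total.index):
                m = m.loc[total.index, total.columns]
            total = total + m
    assert total is not None
    return PhyloDistanceMatrix(total / len(treeset))


def align_matrices(
    m1: pd.DataFrame, m2: pd.DataFrame, min_overlap: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Trim two square species matrices to their sorted shared species.

    Mirrors the trimming applied before comparing matrices built from
    sources covering different species sets.
    """
    shared = sorted(set(m1.index) & set(m2.index))
    if len(shared) < min_overlap:
        raise ValueError(
            f"matrices share only {len(shared)} species (need >= {min_overlap})"
        )
    return m1.loc[shared, shared], m2.loc[shared, shared]
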