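"""Response-guild allocation by hierarchical clustering of the dynamics
distance matrix.

Species are agglomerated on d = 1 - r and the dendrogram is cut either
at a height threshold or into a target number k of guilds; several cuts
("resolutions") can be reported side by side.  Guild labels are
consecutive positive integers numbered in dendrogram leaf order, so
coarser and finer cuts are visibly nested.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from .dynamics import DynamicsDistanceMatrix

__all__ = [
    "LinkageTree",
    "GuildAllocation",
    "build_linkage",
    "cut_dendrogram",
    "allocate_guilds",
    "guild_recovery_score",
]


@dataclass
class LinkageTree:
    """A hierarchical merge tree over species.

    ``linkage`` is the (n-1) x 4 agglomeration matrix (scipy convention);
    ``species`` are in the canonical order used to build it.
    """

    species: list[str]
    linkage: np.ndarray
    method: str

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        return [self.species[i] for i in hierarchy.leaves_list(self.linkage)]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "method": self.method,
                "species": self.species,
                "linkage": [
                    [int(a), int(b), float(h), int(n)]
                    for a, b, h, n in self.linkage
                ],
            },
            indent=1,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def to_newick(self) -> str:
        """Render the dendrogram as Newick, branch lengths = height gaps."""
        root = hierarchy.to_tree(self.linkage)

        def fmt(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                label = self.species[node.id].replace(" ", "_")
                return f"{label}:{length:.10g}"
            left = fmt(node.left, node.dist)
            right = fmt(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        return f"({fmt(root.left, root.dist)},{fmt(root.right, root.dist)});"


@dataclass
class GuildAllocation:
    """Guild labels per species at one or more dendrogram resolutions."""

    species: list[str]
    resolutions: list[tuple[str, pd.Series]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(index=pd.Index(self.species, name="species"))
        for name, labels in self.resolutions:
            out[name] = labels.reindex(self.species)
        return out


def build_linkage(
    ddm: DynamicsDistanceMatrix | pd.DataFrame, method: str = "complete"
) -> LinkageTree:
    """Agglomerate species on the dynamics distance matrix.

    Species are ordered canonically (sorted names) before clustering so
    that equal-height merges resolve identically across runs and input
    orderings.  The matrix must be complete: undefined pairs are an
    error, not silently imputed.
    """
    d = ddm.require_complete() if isinstance(ddm, DynamicsDistanceMatrix) else ddm
    order = sorted(d.index)
    d = d.loc[order, order]
    vals = d.to_numpy(float)
    if not np.isfinite(vals).all():
        raise ValueError("distance matrix contains non-finite entries")
    condensed = squareform(vals, checks=False)
    linkage = hierarchy.linkage(condensed, method=method)
    return LinkageTree(species=order, linkage=linkage, method=method)


def _relabel_by_leaf_order(
    tree: LinkageTree, raw_labels: np.ndarray
) -> pd.Series:
    """Renumber guilds 1..G in order of first appearance along the leaves."""
    labels = pd.Series(raw_labels, index=tree.species)
    mapping: dict[int, int] = {}
    for sp in tree.leaf_order:
        g = labels[sp]
        if g not in mapping:
            mapping[g] = len(mapping) + 1
    return labels.map(mapping).astype(int)


def cut_dendrogram(
    tree: LinkageTree,
    threshold: float | None = None,
    k: int | None = None,
) -> pd.Series:
    """Cut the dendrogram at a height ``threshold`` or into ``k`` guilds.

    Exactly one of the two must be given.  Returns integer labels
    (1..G) indexed by species; labels follow dendrogram leaf order, so
    cuts at decreasing heights give nested partitions with consistent
    numbering.
    """
    if (threshold is None) == (k is None):
        raise ValueError("give exactly one of threshold or k")
    n = len(tree.species)
    if threshold is not None:
        top = float(tree.heights.max()) if n > 1 else 0.0
        if threshold < 0 or threshold > top + 1e-12:
            raise ValueError(
                f"threshold {threshold} outside [0, {top:.6g}]"
            )
        raw = hierarchy.fcluster(tree.linkage, t=threshold, criterion="distance")
    else:
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}], got {k}")
        raw = hierarchy.fcluster(tree.linkage, t=k, criterion="maxclust")
    return _relabel_by_leaf_order(tree, raw)


def allocate_guilds(
    tree: LinkageTree,
    ks: list[int] | None = None,
    thresholds: list[float] | None = None,
) -> GuildAllocation:
    """Cut at several resolutions, coarsest first (mirrors a multi-column
    guild table with one column per resolution)."""
    alloc = GuildAllocation(species=tree.leaf_order)
    for k in sorted(ks or []):
        alloc.resolutions.append((f"k={k}", cut_dendrogram(tree, k=k)))
    for t in sorted(thresholds or [], reverse=True):
        alloc.resolutions.append((f"h={t:g}", cut_dendrogram(tree, threshold=t)))
    return alloc


def guild_recovery_score(
    labels: pd.Series, truth: pd.Series
) -> float:
    """Adjusted Rand index between an allocation and ground-truth guilds.

    1 iff the partitions are identical up to relabeling; approximately 0
    for random allocations.
    """
    common = labels.index.intersection(truth.index)
    if len(common) == 0:
        raise ValueError("no species shared between allocation and truth")
    return float(adjusted_rand_score(truth[common], labels[common]))
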