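"""Phylogenetic utilities: Newick I/O, cophenetic distances, Brownian-motion
covariance, and the mean-distance-to-novel covariate.

Distances are kept in the tree's native branch-length units; no rescaling is
applied (GLS under Brownian motion is invariant to a global scale factor).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "PhyloTree",
    "PhyloDistanceMatrix",
    "read_newick",
    "write_newick",
    "cophenetic_matrix",
    "mean_distance_to_set",
    "brownian_covariance",
    "study_tree",
]


@dataclass
class PhyloTree:
    """A rooted tree with branch lengths, thin wrapper over dendropy."""

    tree: dendropy.Tree

    @property
    def taxa(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def drop_taxa(self, labels: Iterable[str]) -> "PhyloTree":
        labels = set(labels)
        pruned = self.tree.clone(depth=1)
        keep = [t for t in pruned.taxon_namespace if t.label not in labels]
        pruned.retain_taxa(keep)
        return PhyloTree(pruned)

    def validate(self) -> None:
        labels = self.taxa
        if len(set(labels)) != len(labels):
            raise ValueError("tip labels are not unique")
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue
            if edge.length is None:
                raise ValueError(
                    f"missing branch length above {_node_label(edge.head_node)}"
                )
            if edge.length < 0:
                raise ValueError(
                    f"negative branch length above {_node_label(edge.head_node)}"
                )


def _node_label(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return "internal node"


def read_newick(source: str | Path) -> PhyloTree:
    """Parse a Newick tree from a path or a literal Newick string.

    Underscores in unquoted labels are read as spaces (Newick convention),
    so ``Ipomoea_batatas`` matches the species name "Ipomoea batatas".
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and not source.lstrip().startswith("(")
    ):
        text = Path(source).read_text()
    else:
        text = source
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed Newick: {exc}") from exc
    tree.is_rooted = True
    wrapped = PhyloTree(tree)
    wrapped.validate()
    return wrapped


def write_newick(tree: PhyloTree, path: str | Path | None = None) -> str:
    text = tree.tree.as_string(schema="newick", suppress_rooting=True)
    if path is not None:
        Path(path).write_text(text)
    return text


@dataclass
class PhyloDistanceMatrix:
    """Symmetric cophenetic (tip-to-tip path length) distance matrix."""

    taxa: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match taxa list")

    def distance(self, a: str, b: str) -> float:
        return float(self.values[self.taxa.index(a), self.taxa.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxa, columns=self.taxa)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PhyloDistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index), df.to_numpy())


def cophenetic_matrix(tree: PhyloTree) -> PhyloDistanceMatrix:
    """d(i, j) = sum of branch lengths on the unique path between tips."""
    tree.validate()
    pdm = tree.tree.phylogenetic_distance_matrix()
    taxa = sorted(pdm.taxon_iter(), key=lambda t: t.label)
    n = len(taxa)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            out[i, j] = out[j, i] = d
    return PhyloDistanceMatrix([t.label for t in taxa], out)


def mean_distance_to_set(
    matrix: PhyloDistanceMatrix, focal: str, reference_set: Sequence[str]
) -> float:
    """Arithmetic mean cophenetic distance from ``focal`` to a reference set.

    Used to quantify how closely each evolutionarily familiar plant is
    related to the group of novel plants.
    """
    if focal in reference_set:
        raise ValueError(f"focal taxon {focal!r} is inside the reference set")
    if not reference_set:
        raise ValueError("reference set is empty")
    return float(np.mean([matrix.distance(focal, r) for r in reference_set]))


def brownian_covariance(tree: PhyloTree) -> PhyloDistanceMatrix:
    """Brownian-motion trait covariance structure implied by the tree.

    V(i, j) is the root-to-MRCA path length shared by tips i and j;
    V(i, i) is the full root-to-tip length. Returned in the same container
    as the distance matrix (taxa + symmetric array).
    """
    tree.validate()
    t = tree.tree
    depths: dict[dendropy.Node, float] = {}
    for node in t.preorder_node_iter():
        if node is t.seed_node:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + node.edge.length
    leaves = sorted(t.leaf_node_iter(), key=lambda nd: nd.taxon.label)
    # root-ward ancestor sets for MRCA lookup
    ancestors = {
        leaf: [leaf] + [a for a in leaf.ancestor_iter()] for leaf in leaves
    }
    n = len(leaves)
    out = np.zeros((n, n))
    for i, li in enumerate(leaves):
        out[i, i] = depths[li]
        anc_i = set(ancestors[li])
        for j in range(i + 1, n):
            lj = leaves[j]
            mrca = next(a for a in ancestors[lj] if a in anc_i)
            out[i, j] = out[j, i] = depths[mrca]
    return PhyloDistanceMatrix([leaf.taxon.label for leaf in leaves], out)


def study_tree(drop_outgroup: bool = True) -> PhyloTree:
    """The packaged ten-plant study tree (synthetic reconstruction; see
    fixtures module). The out-group is dropped by default because it is not
    part of the analysis set."""
    from .fixtures import OUTGROUP, STUDY_TREE_NEWICK

    tree = read_newick(STUDY_TREE_NEWICK)
    if drop_outgroup:
        tree = tree.drop_taxa([OUTGROUP])
    return tree
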