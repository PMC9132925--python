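"""Phylogeny input, genus-level grafting, and the species correlation matrix.

The correlation matrix entry for tips i, j is the root-to-MRCA shared path
length divided by the geometric mean of the two root-to-tip depths — for an
ultrametric tree this is the Brownian-motion variance-covariance matrix
scaled to unit diagonal.  Near- but non-ultrametric trees are accepted and
normalized per pair; the deviation is reported rather than rejected.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "PhyloCorrelation",
    "GraftError",
    "read_newick",
    "graft_at_genus",
    "phylo_correlation",
]

logger = logging.getLogger(__name__)

#: jitter added to the diagonal when a strictly positive-definite matrix is needed
PSD_JITTER = 1e-8


class GraftError(ValueError):
    """No congener available to anchor a genus-level graft."""


@dataclass
class Phylogeny:
    """A rooted, branch-length-bearing tree with unique tip labels."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError(f"negative branch length {edge.length}")

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def depths(self) -> dict[str, float]:
        """Root-to-tip path length per tip label."""
        self.tree.calc_node_root_distances(return_leaf_distances_only=False)
        return {
            lf.taxon.label: float(lf.root_distance)
            for lf in self.tree.leaf_node_iter()
        }

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        d = np.array(list(self.depths().values()))
        if d.max() == 0:
            return True
        return bool((d.max() - d.min()) <= rel_tol * d.max())

    def missing_species(self, species_ids: list[str]) -> list[str]:
        """Species in a trait table that have no tip in the tree."""
        tips = set(self.tip_labels)
        missing = [s for s in species_ids if s not in tips]
        if missing:
            logger.warning("species absent from tree: %s", ", ".join(missing))
        return missing

    def write_newick(self, path: str | Path) -> None:
        self.tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_newick(path: str | Path) -> Phylogeny:
    """Parse a Newick file (quoted labels allowed, underscores preserved)."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty file")
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise ValueError(f"{path}: malformed Newick: {exc}") from exc
    return Phylogeny(tree)


def newick_from_string(newick: str) -> Phylogeny:
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise ValueError(f"malformed Newick: {exc}") from exc
    return Phylogeny(tree)


def _mrca(nodes: list[dendropy.Node]) -> dendropy.Node:
    """Most recent common ancestor via root-to-node path intersection
    (robust regardless of the tree's rooting state flags)."""
    paths = []
    for node in nodes:
        path = []
        while node is not None:
            path.append(node)
            node = node.parent_node
        paths.append(list(reversed(path)))
    mrca = paths[0][0]
    for level in range(min(len(p) for p in paths)):
        first = paths[0][level]
        if all(p[level] is first for p in paths):
            mrca = first
        else:
            break
    return mrca


def genus_of(species_id: str) -> str:
    """Token before the first underscore or space in a binomial identifier."""
    return re.split(r"[_\s]", species_id.strip(), maxsplit=1)[0]


def _node_depth(tree: dendropy.Tree, node: dendropy.Node) -> float:
    d = 0.0
    while node.parent_node is not None:
        d += node.edge.length or 0.0
        node = node.parent_node
    return d


def graft_at_genus(
    phylo: Phylogeny,
    species_id: str,
    genus_name: str | None = None,
) -> Phylogeny:
    """Attach a tip for ``species_id`` at its genus within the tree.

    With two or more congener tips present, the new tip hangs from their
    MRCA with pendant length chosen so its depth equals the congeners' mean
    depth.  With a single congener, that tip's subtending branch is split at
    its midpoint and the new tip gets a pendant equal to the half branch, so
    both tips end at the same depth.
    """
    genus = genus_name or genus_of(species_id)
    tree = phylo.tree.clone(depth=1)
    congeners = [
        lf for lf in tree.leaf_node_iter() if genus_of(lf.taxon.label) == genus
    ]
    if not congeners:
        raise GraftError(
            f"no congener of genus {genus!r} in tree; place {species_id!r} manually"
        )
    if any(lf.taxon.label == species_id for lf in congeners):
        raise ValueError(f"{species_id!r} already present in tree")

    taxon = dendropy.Taxon(label=species_id)
    tree.taxon_namespace.add_taxon(taxon)

    if len(congeners) == 1:
        leaf = congeners[0]
        parent = leaf.parent_node
        half = (leaf.edge.length or 0.0) / 2.0
        knee = dendropy.Node(edge_length=half)
        parent.remove_child(leaf)
        parent.add_child(knee)
        leaf.edge.length = half
        knee.add_child(leaf)
        knee.new_child(taxon=taxon, edge_length=half)
    else:
        mrca = _mrca(congeners)
        mean_depth = float(np.mean([_node_depth(tree, lf) for lf in congeners]))
        pendant = mean_depth - _node_depth(tree, mrca)
        mrca.new_child(taxon=taxon, edge_length=pendant)

    return Phylogeny(tree)


@dataclass
class PhyloCorrelation:
    """Unit-diagonal species correlation implied by shared ancestry."""

    species: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.species), len(self.species)):
            raise ValueError("matrix shape does not match species list")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-10):
            raise ValueError("correlation matrix diagonal is not 1")
        if np.linalg.eigvalsh(m).min() < -1e-8:
            raise ValueError("correlation matrix is not positive semi-definite")
        self.matrix = m

    def subset(self, species: list[str]) -> "PhyloCorrelation":
        idx = [self.species.index(s) for s in species]
        return PhyloCorrelation(list(species), self.matrix[np.ix_(idx, idx)])

    def cholesky(self, jitter: float = PSD_JITTER) -> np.ndarray:
        return np.linalg.cholesky(self.matrix + jitter * np.eye(len(self.species)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.species, columns=self.species)

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index_label="species_id")


def phylo_correlation(phylo: Phylogeny) -> PhyloCorrelation:
    """Correlation (i, j) = shared root-to-MRCA path / sqrt(depth_i * depth_j)."""
    tree = phylo.tree
    labels = phylo.tip_labels
    depths = phylo.depths()
    dvec = np.array([depths[l] for l in labels])
    if np.all(dvec == 0):
        raise ValueError("tree has zero depth everywhere; correlations undefined")
    if dvec.min() <= 0:
        raise ValueError("a tip has zero root-to-tip depth; correlations undefined")
    if not phylo.is_ultrametric(rel_tol=1e-6):
        logger.info(
            "tree is not ultrametric (depth range %.6g-%.6g); "
            "normalizing per pair by geometric-mean depths",
            dvec.min(),
            dvec.max(),
        )

    pdm = tree.phylogenetic_distance_matrix()
    taxa = {lf.taxon.label: lf.taxon for lf in tree.leaf_node_iter()}
    n = len(labels)
    corr = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            dist = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            shared = (dvec[i] + dvec[j] - dist) / 2.0
            corr[i, j] = corr[j, i] = shared / np.sqrt(dvec[i] * dvec[j])
    return PhyloCorrelation(labels, corr)
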