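"""Species-level phylogenetic correlation matrices and the Pagel-λ transform.

The correlation between species j and k is the shared evolutionary path
length t_jk — the root-to-MRCA distance on an ultrametric tree — divided by
total tree depth, so that every diagonal element is exactly 1. A sample of
trees (e.g. a pseudo-posterior sample) is pooled either by averaging the
per-tree correlation matrices elementwise (default) or by averaging MRCA
node heights across trees before normalizing.

Pagel's λ scales the off-diagonal elements: λ = 0 removes all phylogenetic
signal (identity matrix), λ = 1 leaves the Brownian-motion expectation
untouched. For a unit-diagonal matrix C this is the convex combination
λ·C + (1−λ)·I.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "PhyloCorrelation",
    "correlation_from_tree",
    "correlation_from_trees",
    "apply_lambda",
]

#: Maximum relative spread of tip depths tolerated before a tree is
#: rejected as non-ultrametric.
ULTRAMETRIC_RTOL = 1e-6


@dataclass(frozen=True)
class PhyloCorrelation:
    """An S×S phylogenetic correlation matrix with its species ordering.

    Invariants: symmetric, unit diagonal, off-diagonal in [0, 1],
    positive semidefinite.
    """

    species: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        s = len(self.species)
        if values.shape != (s, s):
            raise ValueError(
                f"matrix shape {values.shape} does not match {s} species"
            )
        if not np.allclose(values, values.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(values), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")

    @property
    def n_species(self) -> int:
        return len(self.species)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.species), columns=list(self.species)
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="species")

    @classmethod
    def from_csv(cls, path) -> "PhyloCorrelation":
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError("correlation CSV must have matching row/column species")
        return cls(tuple(df.columns), df.to_numpy(dtype=float))

    def reorder(self, species: list[str] | tuple[str, ...]) -> "PhyloCorrelation":
        """Return the matrix restricted/permuted to the given species order."""
        missing = [s for s in species if s not in self.species]
        if missing:
            raise ValueError(f"species not in correlation matrix: {missing}")
        idx = [self.species.index(s) for s in species]
        return PhyloCorrelation(tuple(species), self.values[np.ix_(idx, idx)])

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])


def _tip_depths(tree: dendropy.Tree) -> dict:
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    return {leaf.taxon.label: leaf.root_distance for leaf in tree.leaf_node_iter()}


def _check_ultrametric(depths: dict) -> float:
    d = np.array(list(depths.values()), dtype=float)
    depth = float(d.mean())
    if depth <= 0:
        raise ValueError("tree has zero depth")
    if (d.max() - d.min()) / depth > ULTRAMETRIC_RTOL:
        raise ValueError(
            "tree is not ultrametric: tip depths range "
            f"[{d.min():.6g}, {d.max():.6g}]"
        )
    return depth


def _shared_path_matrix(tree: dendropy.Tree) -> tuple[list[str], np.ndarray, float]:
    """Root-to-MRCA path lengths for all species pairs, plus tree depth."""
    depths = _tip_depths(tree)
    labels = sorted(depths)
    if len(set(labels)) != len(labels):
        raise ValueError("tree has duplicate leaf labels")
    depth = _check_ultrametric(depths)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    s = len(labels)
    shared = np.empty((s, s), dtype=float)
    for j, a in enumerate(labels):
        shared[j, j] = depths[a]
        for k in range(j + 1, s):
            b = labels[k]
            # ultrametric: root-to-MRCA depth = tip depth - patristic/2
            d_ab = pdm.patristic_distance(taxa[a], taxa[b])
            shared[j, k] = shared[k, j] = depths[a] - d_ab / 2.0
    return labels, shared, depth


def correlation_from_tree(tree: dendropy.Tree) -> PhyloCorrelation:
    """Correlation matrix of one ultrametric tree: t_jk / tree depth.

    Element (j, k) is the shared root-to-MRCA path length of species j and
    k divided by total tree depth; the diagonal is exactly 1. Raises
    ``ValueError`` on non-ultrametric trees or duplicate leaf labels.
    """
    labels, shared, depth = _shared_path_matrix(tree)
    corr = shared / depth
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, 0.0, 1.0)
    corr = (corr + corr.T) / 2.0
    return PhyloCorrelation(tuple(labels), corr)


def correlation_from_trees(
    trees, method: str = "mean_matrix"
) -> PhyloCorrelation:
    """Pool a tree sample into one correlation matrix.

    ``method="mean_matrix"`` (default) averages per-tree correlation
    matrices elementwise; ``method="mean_heights"`` averages MRCA node
    heights and tree depths first and normalizes the pooled heights. All
    trees must share the same leaf set.
    """
    trees = list(trees)
    if not trees:
        raise ValueError("empty tree sample")
    if method not in {"mean_matrix", "mean_heights"}:
        raise ValueError(f"unknown pooling method: {method!r}")

    ref_labels: list[str] | None = None
    acc: np.ndarray | None = None
    depth_acc = 0.0
    for tree in trees:
        if method == "mean_matrix":
            corr = correlation_from_tree(tree)
            labels, mat = list(corr.species), corr.values
        else:
            labels, mat, depth = _shared_path_matrix(tree)
            depth_acc += depth
        if ref_labels is None:
            ref_labels = labels
            acc = np.zeros_like(mat)
        elif labels != ref_labels:
            raise ValueError(
                "trees have inconsistent leaf sets: "
                f"{sorted(set(labels) ^ set(ref_labels))}"
            )
        acc += mat

    assert acc is not None and ref_labels is not None
    acc /= len(trees)
    if method == "mean_heights":
        acc /= depth_acc / len(trees)
    np.fill_diagonal(acc, 1.0)
    acc = np.clip((acc + acc.T) / 2.0, 0.0, 1.0)
    return PhyloCorrelation(tuple(ref_labels), acc)


def apply_lambda(correlation: PhyloCorrelation, lam: float) -> PhyloCorrelation:
    """Multiply off-diagonal elements by λ ∈ [0, 1].

    Equivalent to λ·C + (1−λ)·I for a unit-diagonal C, so the result is
    positive semidefinite whenever C is.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    out = lam * correlation.values + (1.0 - lam) * np.eye(correlation.n_species)
    return PhyloCorrelation(correlation.species, out)


def read_newick(path) -> list[dendropy.Tree]:
    """Read a Newick file, one tree per line, into a shared taxon namespace."""
    trees = dendropy.TreeList.get(path=str(path), schema="newick")
    return list(trees)


def write_newick(trees, path) -> None:
    """Write trees to a Newick file, one per line."""
    with open(path, "w") as fh:
        for tree in trees:
            fh.write(tree.as_string(schema="newick").strip() + "\n")


def trees_from_string(newick: str) -> list[dendropy.Tree]:
    return list(dendropy.TreeList.get(file=_io.StringIO(newick), schema="newick"))
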