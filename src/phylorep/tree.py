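"""Newick trees and patristic distances.

A phylogenetic tree with branch lengths induces a metric on its leaves: the
patristic distance between two leaves is the sum of branch lengths along the
unique path connecting them (units: expected substitutions per site on a
maximum-likelihood tree).  Everything downstream — threshold clustering,
representative subsampling, and phenotype association — is driven by this
metric, so this module owns the validated tree container and the dense
leaf-by-leaf distance matrix.

Parsing is delegated to :mod:`dendropy`; this module adds the validation
layer (unique leaf labels, non-negative branch lengths) and keeps labels
byte-exact so that tree leaves can be joined against screen-table keys.
"""

from __future__ import annotations

import difflib
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "NewickError",
    "TreeValidationError",
    "PhyloTree",
    "PatristicMatrix",
    "parse_newick",
    "read_newick",
    "patristic_matrix",
    "distances_from",
]


class NewickError(ValueError):
    """Raised when a Newick string cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a parsed tree violates the tree invariants."""


class PhyloTree:
    """A rooted (or basally multifurcating) tree with labeled leaves.

    Wraps a :class:`dendropy.Tree` and guarantees, after construction:

    * every leaf carries a unique, non-empty label;
    * every branch length is >= 0 (missing lengths default to 0 with a
      warning);
    * internal-node labels (bootstrap supports and the like) are preserved
      verbatim but never used in any computation.
    """

    def __init__(self, dtree: dendropy.Tree):
        self._tree = dtree
        self._validate()

    # -- construction ----------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        if not text or not text.strip():
            raise NewickError("empty Newick string")
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            msg = str(exc)
            if "Duplicate taxon labels" in msg:
                dup = msg.rsplit(":", 1)[-1].strip()
                raise TreeValidationError(f"duplicate leaf label: {dup!r}") from exc
            raise NewickError(f"malformed Newick: {msg}") from exc
        return cls(dtree)

    @classmethod
    def from_file(cls, path) -> "PhyloTree":
        with open(path, "r", encoding="utf-8") as handle:
            return cls.from_newick(handle.read())

    def _validate(self) -> None:
        seen: set[str] = set()
        n_missing = 0
        for node in self._tree.preorder_node_iter():
            if node.is_leaf():
                label = node.taxon.label if node.taxon is not None else None
                if not label:
                    raise TreeValidationError("leaf with empty label")
                if label in seen:
                    raise TreeValidationError(f"duplicate leaf label: {label!r}")
                seen.add(label)
            length = node.edge.length
            if length is None:
                # the root edge conventionally has no length; only count
                # missing lengths on non-root edges
                if node.parent_node is not None:
                    n_missing += 1
                node.edge.length = 0.0
            elif length < 0:
                raise TreeValidationError(
                    f"negative branch length {length} on edge above "
                    f"{label if node.is_leaf() else 'internal node'}"
                )
        if not seen:
            raise TreeValidationError("tree has no labeled leaves")
        if n_missing:
            warnings.warn(
                f"{n_missing} branch length(s) missing in Newick input; "
                "defaulting to 0",
                stacklevel=3,
            )
        self._leaves = [nd for nd in self._tree.leaf_node_iter()]
        self._labels = [nd.taxon.label for nd in self._leaves]

    # -- accessors -------------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def leaf_labels(self) -> list[str]:
        """Leaf labels in tree traversal order."""
        return list(self._labels)

    @property
    def n_leaves(self) -> int:
        return len(self._labels)

    def postorder_nodes(self):
        return self._tree.postorder_node_iter()

    @property
    def root(self):
        return self._tree.seed_node

    def diameter(self) -> float:
        """Maximum leaf-to-leaf patristic distance."""
        mat = patristic_matrix(self)
        return float(mat.values.max())

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".12g",
        ).strip()

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            handle.write(self.to_newick() + "\n")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PhyloTree(n_leaves={self.n_leaves})"


@dataclass
class PatristicMatrix:
    """Dense symmetric matrix of leaf-to-leaf path-length distances."""

    labels: list[str]
    values: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    @property
    def n(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            near = difflib.get_close_matches(label, self.labels, n=3)
            hint = f"; closest matches: {near}" if near else ""
            raise KeyError(f"leaf label {label!r} not in matrix{hint}") from None

    def distance(self, a: str, b: str) -> float:
        return float(self.values[self.index_of(a), self.index_of(b)])

    def submatrix(self, labels: Sequence[str]) -> "PatristicMatrix":
        idx = [self.index_of(lab) for lab in labels]
        return PatristicMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path, fmt: str = "square") -> None:
        """Write as TSV; ``fmt`` is ``square`` or ``long``."""
        if fmt == "square":
            self.to_frame().to_csv(path, sep="\t", index_label="leaf")
        elif fmt == "long":
            rows = []
            for i, a in enumerate(self.labels):
                for j, b in enumerate(self.labels):
                    if j > i:
                        rows.append((a, b, self.values[i, j]))
            pd.DataFrame(rows, columns=["leaf_a", "leaf_b", "distance"]).to_csv(
                path, sep="\t", index=False
            )
        else:
            raise ValueError(f"unknown matrix format {fmt!r} (use square/long)")


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a validated :class:`PhyloTree`."""
    return PhyloTree.from_newick(text)


def read_newick(path) -> PhyloTree:
    return PhyloTree.from_file(path)


def patristic_matrix(tree: PhyloTree) -> PatristicMatrix:
    """Compute all pairwise leaf path-length distances.

    Single postorder sweep: each node carries the distances from itself to
    the leaves below it; when children merge at a node, every cross-child
    leaf pair is completed with an outer sum.  O(n^2) time and memory.
    """
    labels = tree.leaf_labels
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    out = np.zeros((n, n), dtype=float)

    # per-node: (array of leaf indices, array of distances node->leaf)
    carry: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for node in tree.postorder_nodes():
        if node.is_leaf():
            carry[id(node)] = (
                np.array([index[node.taxon.label]], dtype=np.intp),
                np.zeros(1, dtype=float),
            )
            continue
        parts = []
        for child in node.child_nodes():
            idx, dist = carry.pop(id(child))
            parts.append((idx, dist + child.edge.length))
        for a in range(len(parts)):
            ia, da = parts[a]
            for b in range(a + 1, len(parts)):
                ib, db = parts[b]
                block = da[:, None] + db[None, :]
                out[np.ix_(ia, ib)] = block
                out[np.ix_(ib, ia)] = block.T
        carry[id(node)] = (
            np.concatenate([p[0] for p in parts]),
            np.concatenate([p[1] for p in parts]),
        )
    return PatristicMatrix(labels, out)


def distances_from(matrix: PatristicMatrix, focal: str) -> pd.Series:
    """Patristic distances from ``focal`` to every *other* leaf.

    The focal leaf's zero self-distance is dropped, so the vector has
    ``n_leaves - 1`` entries: distance distributions "from" a reference
    ortholog conventionally exclude the reference itself.
    """
    i = matrix.index_of(focal)
    row = pd.Series(matrix.values[i], index=matrix.labels, name=focal)
    return row.drop(focal)
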