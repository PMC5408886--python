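"""Protein distance matrices and UPGMA trees for receptor family grouping.

Distances are computed on aligned amino-acid sequences, either as the raw
proportion of mismatching columns (p-distance) or with the Poisson multiple-
hit correction ``-ln(1 - p)``.  Columns where either sequence has a gap are
excluded.  Trees are built with UPGMA (unweighted pair-group method with
arithmetic mean): the closest pair of clusters is merged iteratively, ties
broken towards the lexicographically smallest taxon-id pair, and the merge
node is placed at half the merge distance, which makes the output ultrametric
by construction.  The question these trees answer is qualitative -- do the
receptor families form coherent clades? -- so branch lengths matter less than
topology, and the simple distance models are adequate for it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import InputError, UndefinedDistanceError

GAP_CHARS = frozenset("-.")

#: Proportions above this are capped before the Poisson correction so the
#: corrected distance stays finite; capped pairs are flagged with a warning.
P_CAP = 0.95


def pairwise_distance(seq_a: str, seq_b: str, model: str = "poisson") -> float:
    """Distance between two aligned sequences under ``p_distance`` or
    ``poisson``.  Raises when no column is comparable."""
    if len(seq_a) != len(seq_b):
        raise InputError(
            f"aligned sequences differ in length ({len(seq_a)} vs {len(seq_b)})"
        )
    compared = mismatches = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a in GAP_CHARS or b in GAP_CHARS:
            continue
        compared += 1
        if a != b:
            mismatches += 1
    if compared == 0:
        raise UndefinedDistanceError("no gap-free columns shared by the pair")
    p = mismatches / compared
    if model == "p_distance":
        return p
    if model == "poisson":
        if p >= P_CAP:
            warnings.warn(
                f"p={p:.3f} capped at {P_CAP} before Poisson correction",
                stacklevel=2,
            )
            p = P_CAP
        return -math.log1p(-p)
    raise InputError(f"unknown distance model {model!r}")


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise InputError(f"matrix shape {self.d.shape} does not match {n} taxa")
        if not np.allclose(self.d, self.d.T):
            raise InputError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise InputError("distance matrix has nonzero diagonal")
        if not np.all(np.isfinite(self.d)) or np.any(self.d < 0):
            raise InputError("distances must be finite and nonnegative")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.taxa.index(pair[0]), self.taxa.index(pair[1])
        return float(self.d[i, j])


def distance_matrix(
    alignment: Mapping[str, str], model: str = "poisson"
) -> DistanceMatrix:
    """All-pairs distances over an ``{id: aligned sequence}`` mapping."""
    taxa = list(alignment)
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pairwise_distance(
                alignment[taxa[i]], alignment[taxa[j]], model
            )
    return DistanceMatrix(taxa, d)


@dataclass
class TreeNode:
    """A node of the rooted ultrametric tree; leaves have ``name`` set."""

    height: float
    name: Optional[str] = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> frozenset[str]:
        if self.is_leaf:
            return frozenset([self.name])
        out: frozenset[str] = frozenset()
        for c in self.children:
            out |= c.leaf_names()
        return out

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass
class Tree:
    root: TreeNode

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.root.walk() if n.is_leaf]

    def clades(self) -> list[frozenset[str]]:
        return [n.leaf_names() for n in self.root.walk()]


def upgma(dm: DistanceMatrix) -> Tree:
    """UPGMA clustering with deterministic tie-breaking.

    At each step the pair of clusters at minimal distance is merged; ties are
    resolved towards the pair whose (sorted) labels -- each cluster labelled
    by its lexicographically smallest member -- compare smallest.  The
    distance from the merged cluster to any other is the size-weighted mean
    of the member distances, i.e. the arithmetic mean over all cross pairs
    of original taxa.
    """
    n = len(dm.taxa)
    if n < 2:
        raise InputError("UPGMA needs at least two taxa")

    # active clusters: label -> (node, size); distances in a dict keyed by
    # frozenset pairs of labels.  Labels are the smallest member name.
    nodes: dict[str, TreeNode] = {
        t: TreeNode(height=0.0, name=t) for t in dm.taxa
    }
    sizes: dict[str, int] = {t: 1 for t in dm.taxa}
    dist: dict[frozenset[str], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((dm.taxa[i], dm.taxa[j]))] = float(dm.d[i, j])

    while len(nodes) > 1:
        best = min(
            dist.items(),
            key=lambda kv: (kv[1], tuple(sorted(kv[0]))),
        )
        pair, dmin = best
        a, b = sorted(pair)
        merged = TreeNode(height=dmin / 2.0, children=[nodes[a], nodes[b]])
        label = a  # min(a, b)
        na, nb = sizes[a], sizes[b]
        for other in list(nodes):
            if other in (a, b):
                continue
            da = dist.pop(frozenset((a, other)))
            db = dist.pop(frozenset((b, other)))
            dist[frozenset((label, other))] = (na * da + nb * db) / (na + nb)
        dist.pop(pair)
        del nodes[b]
        del sizes[b]
        nodes[label] = merged
        sizes[label] = na + nb

    return Tree(root=next(iter(nodes.values())))


def family_coherence(tree: Tree, family_map: Mapping[str, str]) -> dict[str, bool]:
    """For each family: is its member set exactly the leaf set of some clade?"""
    leaves = {leaf.name for leaf in tree.leaves()}
    missing = leaves - set(family_map)
    if missing:
        raise InputError(f"leaves without family assignment: {sorted(missing)}")
    members: dict[str, set[str]] = {}
    for taxon, fam in family_map.items():
        if taxon in leaves:
            members.setdefault(fam, set()).add(taxon)
    clades = set(tree.clades())
    return {fam: frozenset(m) in clades for fam, m in sorted(members.items())}


# ---------------------------------------------------------------------------
# Newick I/O (branch lengths = parent height - child height)

def to_newick(tree: Tree, precision: int = 9) -> str:
    def fmt(node: TreeNode, parent_height: float) -> str:
        bl = parent_height - node.height
        if node.is_leaf:
            return f"{node.name}:{bl:.{precision}f}"
        inner = ",".join(fmt(c, node.height) for c in node.children)
        return f"({inner}):{bl:.{precision}f}"

    root = tree.root
    if root.is_leaf:
        return f"{root.name}:0.0;"
    inner = ",".join(fmt(c, root.height) for c in root.children)
    return f"({inner});"


def write_newick(tree: Tree, path: str | Path) -> None:
    Path(path).write_text(to_newick(tree) + "\n")


def read_newick(path_or_string: str | Path) -> Tree:
    """Read a rooted tree (dendropy-backed); node heights are reconstructed
    from branch lengths assuming leaves sit at height zero."""
    import dendropy

    text = str(path_or_string)
    if "\n" not in text and Path(text).exists():
        text = Path(text).read_text()
    dt = dendropy.Tree.get(data=text, schema="newick")

    def convert(dnode) -> TreeNode:
        if dnode.is_leaf():
            return TreeNode(height=0.0, name=dnode.taxon.label.replace(" ", "_"))
        children = [convert(c) for c in dnode.child_nodes()]
        heights = [
            c.height + (dc.edge.length or 0.0)
            for c, dc in zip(children, dnode.child_nodes())
        ]
        return TreeNode(height=max(heights), children=children)

    return Tree(root=convert(dt.seed_node))


def write_distance_csv(dm: DistanceMatrix, path: str | Path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([""] + dm.taxa)
        for i, t in enumerate(dm.taxa):
            writer.writerow([t] + [f"{x:.9f}" for x in dm.d[i]])


def read_distance_csv(path: str | Path) -> DistanceMatrix:
    import csv

    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    taxa = rows[0][1:]
    d = np.array([[float(x) for x in row[1:]] for row in rows[1:]])
    return DistanceMatrix(taxa, d)
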