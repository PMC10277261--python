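"""Time-tree operations: Newick I/O, ultrametricity, MRCA-age matrices.

A time tree is a rooted tree whose branch lengths are in millions of
years; when ultrametric, all root-to-tip path lengths agree and equal the
crown age. The divergence time of a pair of tips is the age of their most
recent common ancestor — i.e. the tip depth minus the MRCA depth, which is
*half* the cophenetic (total path) distance. That convention makes the
crown age the maximum entry of the pairwise matrix.

Trees are carried as :mod:`dendropy` trees inside a thin :class:`TimeTree`
wrapper that enforces unique tip labels and nonnegative branch lengths.
"""

from __future__ import annotations

import dendropy
import numpy as np

from .divergence_data import DivergenceMatrix, normalize_name

__all__ = [
    "TimeTree",
    "TreeError",
    "parse_newick",
    "write_newick",
    "is_ultrametric",
    "divergence_from_tree",
    "tree_from_matrix",
    "crown_age",
    "ascii_preview",
]

#: Default ultrametricity tolerance (MY): max minus min root-to-tip depth.
#: The upstream resource prints times at 0.1-MY precision.
DEFAULT_ULTRAMETRIC_TOL = 0.01

#: Default tolerance for the three-point condition in reconstruction.
DEFAULT_THREE_POINT_TOL = 1e-6


class TreeError(ValueError):
    """Malformed tree or operation outside its domain."""


class TimeTree:
    """A rooted tree with branch lengths in MY and unique tip labels."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = self.tip_labels
        if len(labels) < 2:
            raise TreeError("a time tree needs at least 2 tips")
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise TreeError(f"duplicate tip labels: {sorted(dupes)}")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < -1e-12:
                raise TreeError(f"negative branch length {edge.length}")

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        return [
            normalize_name(leaf.taxon.label)
            for leaf in self._tree.leaf_node_iter()
        ]

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path length for every tip."""
        self._tree.calc_node_root_distances(return_leaf_distances_only=False)
        return {
            normalize_name(leaf.taxon.label): float(leaf.root_distance)
            for leaf in self._tree.leaf_node_iter()
        }

    def __eq__(self, other) -> bool:  # topology + branch-length identity
        if not isinstance(other, TimeTree):
            return NotImplemented
        return write_newick(self) == write_newick(other)


def parse_newick(text: str) -> TimeTree:
    """Parse a Newick string (branch lengths in MY) into a :class:`TimeTree`."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise TreeError(f"duplicate tip labels: {exc}") from exc
    except Exception as exc:  # dendropy reports the character position
        raise TreeError(f"malformed Newick: {exc}") from exc
    if tree.seed_node is None or len(tree.leaf_nodes()) < 2:
        raise TreeError("Newick string has fewer than 2 tips")
    return TimeTree(tree)


def write_newick(tree: TimeTree) -> str:
    """Serialize to Newick with branch lengths; spaces kept via underscores."""
    out = tree.dendropy_tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=False,
    ).strip()
    return out


def is_ultrametric(tree: TimeTree, tol: float = DEFAULT_ULTRAMETRIC_TOL) -> bool:
    """True iff all root-to-tip depths agree within ``tol`` MY."""
    depths = list(tree.tip_depths().values())
    return (max(depths) - min(depths)) <= tol


def _require_ultrametric(tree: TimeTree, tol: float) -> None:
    if not is_ultrametric(tree, tol):
        depths = list(tree.tip_depths().values())
        raise TreeError(
            f"tree is not ultrametric: root-to-tip spread "
            f"{max(depths) - min(depths):.6g} MY exceeds tolerance {tol}"
        )


def divergence_from_tree(
    tree: TimeTree, tol: float = DEFAULT_ULTRAMETRIC_TOL
) -> DivergenceMatrix:
    """Pairwise MRCA ages (MY) for all tips of an ultrametric tree.

    Entry (i, j) is the tip depth minus the depth of MRCA(i, j) —
    equivalently half the cophenetic path length between the tips.
    """
    _require_ultrametric(tree, tol)
    dtree = tree.dendropy_tree
    dtree.calc_node_root_distances(return_leaf_distances_only=False)
    labels = tree.tip_labels
    index = {l: i for i, l in enumerate(labels)}
    height = max(tree.tip_depths().values())
    n = len(labels)
    values = np.zeros((n, n), dtype=float)
    # Tips first meet at the shallowest internal node above both; walking in
    # postorder and joining child tip-sets assigns each pair its MRCA once.
    tipsets: dict = {}
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            tipsets[node] = [index[normalize_name(node.taxon.label)]]
            continue
        children = [tipsets.pop(c) for c in node.child_nodes()]
        age = height - float(node.root_distance)
        merged: list[int] = []
        for group in children:
            for i in merged:
                for j in group:
                    values[i, j] = values[j, i] = max(age, 0.0)
            merged.extend(group)
        tipsets[node] = merged
    return DivergenceMatrix(labels=labels, values=values)


def check_three_point(
    matrix: DivergenceMatrix, tol: float = DEFAULT_THREE_POINT_TOL
) -> tuple[bool, tuple | None, float]:
    """Check the ultrametric three-point condition on a matrix.

    For every triple, the two largest pairwise distances must agree.
    Returns (ok, worst_triple, worst_violation).
    """
    v = matrix.values
    n = matrix.n
    worst = 0.0
    worst_triple = None
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                d = sorted([v[i, j], v[i, k], v[j, k]])
                gap = d[2] - d[1]
                if gap > worst:
                    worst = gap
                    worst_triple = (
                        matrix.labels[i],
                        matrix.labels[j],
                        matrix.labels[k],
                    )
    return worst <= tol, worst_triple, worst


def tree_from_matrix(
    matrix: DivergenceMatrix, tol: float = DEFAULT_THREE_POINT_TOL
) -> TimeTree:
    """Reconstruct an ultrametric tree from an MRCA-age matrix by UPGMA.

    Average-linkage agglomeration; the height of each merge is the average
    divergence between the merged clusters, so node heights are MRCA ages
    and the reconstruction is exact on matrices satisfying the three-point
    condition. Ties are broken by merging the pair whose (lexicographically
    smallest member, then next) sorts first.
    """
    ok, triple, gap = check_three_point(matrix, tol)
    if not ok:
        raise TreeError(
            f"matrix violates the three-point condition: triple {triple} "
            f"has top-two distance gap {gap:.6g} (tol {tol})"
        )
    labels = matrix.labels
    taxa = dendropy.TaxonNamespace(labels)
    if len(labels) == 1:
        raise TreeError("cannot build a tree from a single label")

    # cluster: (member indices, representative sorted labels, node, height)
    clusters: list[dict] = []
    nodes: dict[int, dendropy.Node] = {}
    for i, label in enumerate(labels):
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        clusters.append(
            {"members": [i], "key": (label,), "node": node, "height": 0.0}
        )

    v = matrix.values

    def linkage(ca: dict, cb: dict) -> float:
        total = sum(v[i, j] for i in ca["members"] for j in cb["members"])
        return total / (len(ca["members"]) * len(cb["members"]))

    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = linkage(clusters[a], clusters[b])
                tie_key = tuple(
                    sorted(clusters[a]["key"] + clusters[b]["key"])
                )
                cand = (d, tie_key, a, b)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        d, _, a, b = best
        ca, cb = clusters[a], clusters[b]
        parent = dendropy.Node()
        for child in (ca, cb):
            child["node"].edge.length = d - child["height"]
            parent.add_child(child["node"])
        merged = {
            "members": ca["members"] + cb["members"],
            "key": tuple(sorted(ca["key"] + cb["key"])),
            "node": parent,
            "height": d,
        }
        clusters = [c for idx, c in enumerate(clusters) if idx not in (a, b)]
        clusters.append(merged)

    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = clusters[0]["node"]
    tree.is_rooted = True
    return TimeTree(tree)


def crown_age(tree: TimeTree, tol: float = DEFAULT_ULTRAMETRIC_TOL) -> float:
    """Crown age (MY): the root height of an ultrametric tree."""
    _require_ultrametric(tree, tol)
    return max(tree.tip_depths().values())


def ascii_preview(tree: TimeTree) -> str:
    """Deterministic ASCII rendering of the topology with tip labels."""
    return tree.dendropy_tree.as_ascii_plot(plot_metric="depth")
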