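"""Rooted-tree handling, phylogenetic covariance and Brownian-motion simulation.

The covariance convention is the standard comparative-methods one: for a
rooted tree with branch lengths in time units, ``C[i, j]`` is the length of
evolutionary history shared by tips *i* and *j*, i.e. the distance from the
root to their most recent common ancestor; the diagonal holds root-to-tip
path lengths.  Pagel's lambda rescales the off-diagonal entries only, so
``lambda = 0`` gives independent tips (the OLS limit) and ``lambda = 1`` the
full Brownian-motion covariance.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .errors import InvalidInputError, ParseError

__all__ = [
    "PhyloTree",
    "read_tree",
    "covariance",
    "simulate_bm",
    "simulate_bm_matrix",
    "normalize_label",
]

#: Relative tolerance (times tree depth) for the ultrametricity check.
ULTRAMETRIC_RTOL = 1e-6


def normalize_label(label: str) -> str:
    """Normalize a species label: strip and replace whitespace runs with '_'."""
    return "_".join(str(label).split())


@dataclass
class PhyloTree:
    """A rooted phylogenetic tree with named tips and branch lengths.

    Thin wrapper around a :class:`dendropy.Tree` that fixes a tip order,
    normalizes labels and records whether the tree is (numerically)
    ultrametric.  Branch lengths are non-negative; a missing length on the
    root edge is treated as zero.
    """

    tree: dendropy.Tree
    tip_labels: list[str] = field(default_factory=list)
    is_ultrametric: bool = True

    def __post_init__(self):
        if not self.tip_labels:
            self.tip_labels = [
                normalize_label(leaf.taxon.label) for leaf in self.tree.leaf_node_iter()
            ]
        if len(set(self.tip_labels)) != len(self.tip_labels):
            dups = sorted({t for t in self.tip_labels if self.tip_labels.count(t) > 1})
            raise ParseError(f"duplicate tip labels: {', '.join(dups)}")
        depths = np.array(list(self.tip_depths().values()))
        depth = depths.max() if len(depths) else 0.0
        self.is_ultrametric = bool(
            depth == 0 or np.ptp(depths) <= ULTRAMETRIC_RTOL * depth
        )
        if not self.is_ultrametric:
            warnings.warn(
                "tree is not ultrametric (tip-depth spread "
                f"{np.ptp(depths):.3g} exceeds tolerance); proceeding",
                stacklevel=3,
            )

    # -- basic accessors ---------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path length for every tip."""
        out = {}
        for leaf in self.tree.leaf_node_iter():
            d = 0.0
            node = leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            out[normalize_label(leaf.taxon.label)] = d
        return out

    @property
    def depth(self) -> float:
        return max(self.tip_depths().values())

    def clade_tipsets(self) -> dict[frozenset[str], "dendropy.Node"]:
        """Map each branch (as the set of tip labels below its child node)
        to that child node.  The root itself carries no branch and is not
        included."""
        out = {}
        for node in self.tree.postorder_node_iter():
            if node.parent_node is None:
                continue
            tips = frozenset(
                normalize_label(l.taxon.label) for l in node.leaf_iter()
            )
            out[tips] = node
        return out

    def path_to_tip(self, tip: str) -> list[frozenset[str]]:
        """Branches (child-clade tip sets) on the root-to-tip path, root first."""
        tip = normalize_label(tip)
        if tip not in self.tip_labels:
            raise InvalidInputError(f"tip {tip!r} not in tree")
        leaf = next(
            l
            for l in self.tree.leaf_node_iter()
            if normalize_label(l.taxon.label) == tip
        )
        path = []
        node = leaf
        while node.parent_node is not None:
            path.append(
                frozenset(normalize_label(l.taxon.label) for l in node.leaf_iter())
            )
            node = node.parent_node
        return path[::-1]

    # -- manipulation ------------------------------------------------------

    def prune_to(self, labels) -> "PhyloTree":
        """Return a new tree restricted to ``labels`` (normalized match).

        The root of the result is the most recent common ancestor of the
        retained tips, so root-to-tip depths are recomputed relative to that
        ancestor.
        """
        keep = {normalize_label(l) for l in labels}
        missing = keep - set(self.tip_labels)
        if missing:
            raise InvalidInputError(f"labels not in tree: {sorted(missing)}")
        clone = self.tree.clone(depth=1)
        taxa = [t for t in clone.taxon_namespace if normalize_label(t.label) in keep]
        clone.retain_taxa(taxa)
        # collapse a unifurcating root left behind by pruning
        seed = clone.seed_node
        while len(seed.child_nodes()) == 1:
            child = seed.child_nodes()[0]
            clone.seed_node = child
            child.parent_node = None
            child.edge.length = None
            seed = child
        clone.seed_node.edge.length = None
        return PhyloTree(clone)

    def to_newick(self) -> str:
        s = self.tree.as_string(schema="newick", suppress_rooting=True)
        return s.strip() + ("" if s.strip().endswith(";") else ";")


def read_tree(source: str) -> PhyloTree:
    """Parse a rooted Newick tree with branch lengths.

    ``source`` is Newick text (or a path-like already read by the caller).
    Raises :class:`ParseError` on malformed text, duplicate tip labels or
    missing branch lengths on non-root edges.
    """
    text = source.strip()
    if not text:
        raise ParseError("empty Newick input")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ParseError(f"malformed Newick: {exc}") from exc
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if node.edge.length is None:
            name = node.taxon.label if node.taxon else (node.label or "<internal>")
            raise ParseError(f"missing branch length on edge above {name!r}")
        if node.edge.length < 0:
            name = node.taxon.label if node.taxon else (node.label or "<internal>")
            raise ParseError(f"negative branch length above {name!r}")
    return PhyloTree(tree)


def covariance(tree: PhyloTree, lam: float = 1.0, tip_order=None) -> np.ndarray:
    """Shared-path-length matrix under Pagel's lambda.

    ``C(lambda) = lambda * C(1) + (1 - lambda) * diag(C(1))`` where
    ``C(1)[i, j]`` is the root-to-MRCA distance of tips *i*, *j*.
    """
    if not 0.0 <= lam <= 1.0:
        raise InvalidInputError(f"lambda must lie in [0, 1], got {lam}")
    order = list(tip_order) if tip_order is not None else tree.tip_labels
    idx = {t: i for i, t in enumerate(order)}
    n = len(order)
    C = np.zeros((n, n))
    depths = tree.tip_depths()
    for t, i in idx.items():
        C[i, i] = depths[t]
    # node depth from root, then fill cross-child pairs at each internal node
    node_depth = {}
    tipsets = {}
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            node_depth[node] = 0.0
        else:
            node_depth[node] = node_depth[node.parent_node] + (node.edge.length or 0.0)
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            lbl = normalize_label(node.taxon.label)
            tipsets[node] = [idx[lbl]] if lbl in idx else []
        else:
            kids = [tipsets[c] for c in node.child_nodes()]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for i in kids[a]:
                        for j in kids[b]:
                            C[i, j] = C[j, i] = node_depth[node]
            tipsets[node] = [i for k in kids for i in k]
    if lam != 1.0:
        d = np.diag(C).copy()
        C = lam * C
        np.fill_diagonal(C, d)
    return C


def simulate_bm_matrix(
    tree: PhyloTree,
    sigma2: float,
    root_state: float = 0.0,
    lam: float = 1.0,
    seed=None,
    n_rep: int = 1,
) -> np.ndarray:
    """Draw ``n_rep`` Brownian-motion tip vectors (rows) on ``tree``.

    Tip values are multivariate normal with mean ``root_state`` and
    covariance ``sigma2 * C(lambda)``.  ``seed`` may be an int or a
    :class:`numpy.random.Generator`.
    """
    if sigma2 <= 0:
        raise InvalidInputError("sigma2 must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    C = covariance(tree, lam)
    try:
        L = np.linalg.cholesky(sigma2 * C)
    except np.linalg.LinAlgError:
        # zero-length terminal branches can make C singular; jitter minimally
        eps = 1e-12 * max(sigma2 * tree.depth, 1.0)
        L = np.linalg.cholesky(sigma2 * C + eps * np.eye(len(C)))
    z = rng.standard_normal((n_rep, tree.n_tips))
    return root_state + z @ L.T


def simulate_bm(
    tree: PhyloTree,
    sigma2: float,
    root_state: float = 0.0,
    lam: float = 1.0,
    seed=None,
) -> dict[str, float]:
    """Single Brownian-motion replicate as a tip-label -> value map."""
    x = simulate_bm_matrix(tree, sigma2, root_state, lam, seed, n_rep=1)[0]
    return dict(zip(tree.tip_labels, x))
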