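"""Phylogeny handling and comparative primitives.

The dated, ultrametric species tree is an *input* to this pipeline (tree
inference and divergence dating are upstream).  This module wraps a compact
array-based tree representation around dendropy's Newick reader/writer and
provides the comparative primitives the downstream analyses need: pruning to
the taxa with shape data, Brownian-motion (BM) and Ornstein-Uhlenbeck (OU)
trait simulation, generalized-least-squares ancestral state estimation under
BM, and the node placements behind phylomorphospace and phenogram plots.

Nodes are integer ids: tips ``0..n_tips-1`` (in Newick reading order),
internal nodes following in postorder with the root last.  Every non-root
node identifies the edge above it; the stable *edge index* of that edge is
its postorder position, fixed at parse time so that shift configurations are
reproducible across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .errors import (BadParameter, EmptyIntersection, NonUltrametric,
                     ParseError, SingularCovariance)

logger = logging.getLogger(__name__)


class Phylogeny:
    """Rooted tree with named tips, edge lengths in time units (Myr), and a
    stable postorder edge indexing."""

    def __init__(self, parent: np.ndarray, edge_length: np.ndarray,
                 tip_labels: list[str]):
        self.parent = np.asarray(parent, dtype=int)
        self.edge_length = np.asarray(edge_length, dtype=float)
        self.tip_labels = list(tip_labels)
        self.n_tips = len(tip_labels)
        self.n_nodes = len(self.parent)
        if np.any(self.edge_length[self.parent >= 0] < 0):
            raise BadParameter("edge lengths must be non-negative")
        roots = np.nonzero(self.parent < 0)[0]
        if len(roots) != 1:
            raise BadParameter("tree must have exactly one root")
        self.root = int(roots[0])
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v in range(self.n_nodes):
            if v != self.root:
                self.children[self.parent[v]].append(v)
        self.postorder = self._postorder()
        # edge e <-> child node edge_nodes[e]; postorder enumeration
        self.edge_nodes = np.array([v for v in self.postorder if v != self.root])
        self.edge_index_of_node = {int(v): e
                                   for e, v in enumerate(self.edge_nodes)}
        self._depths: np.ndarray | None = None
        self._desc_tips: list[np.ndarray] | None = None
        self._mrca_depth: np.ndarray | None = None
        self._descent: np.ndarray | None = None

    # -- construction -----------------------------------------------------

    def _postorder(self) -> np.ndarray:
        order, stack = [], [(self.root, False)]
        while stack:
            v, done = stack.pop()
            if done:
                order.append(v)
            else:
                stack.append((v, True))
                for c in reversed(self.children[v]):
                    stack.append((c, False))
        return np.array(order, dtype=int)

    @property
    def n_edges(self) -> int:
        return self.n_nodes - 1

    # -- geometry ----------------------------------------------------------

    def node_depths(self) -> np.ndarray:
        """Distance from the root to every node."""
        if self._depths is None:
            d = np.zeros(self.n_nodes)
            for v in self.postorder[::-1]:  # preorder
                if v != self.root:
                    d[v] = d[self.parent[v]] + self.edge_length[v]
            self._depths = d
        return self._depths

    @property
    def height(self) -> float:
        return float(self.node_depths()[: self.n_tips].max())

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        tip_d = self.node_depths()[: self.n_tips]
        h = tip_d.max()
        return bool(h > 0 and np.all(np.abs(tip_d - h) <= rel_tol * h))

    def descendant_tips(self, node: int) -> np.ndarray:
        """Sorted tip ids descending from ``node`` (a tip descends from itself)."""
        if self._desc_tips is None:
            desc: list = [None] * self.n_nodes
            for v in self.postorder:
                if not self.children[v]:
                    desc[v] = np.array([v], dtype=int)
                else:
                    desc[v] = np.sort(np.concatenate(
                        [desc[c] for c in self.children[v]]))
            self._desc_tips = desc
        return self._desc_tips[node]

    def mrca_depth_matrix(self) -> np.ndarray:
        """(n_tips, n_tips) matrix of root-to-MRCA distances (shared times);
        the diagonal holds tip depths."""
        if self._mrca_depth is not None:
            return self._mrca_depth
        d = self.node_depths()
        m = np.zeros((self.n_tips, self.n_tips))
        np.fill_diagonal(m, d[: self.n_tips])
        for v in self.postorder:
            kids = self.children[v]
            for i in range(len(kids)):
                for j in range(i + 1, len(kids)):
                    ti = self.descendant_tips(kids[i])
                    tj = self.descendant_tips(kids[j])
                    m[np.ix_(ti, tj)] = d[v]
                    m[np.ix_(tj, ti)] = d[v]
        self._mrca_depth = m
        return m

    def descent_indicator(self) -> np.ndarray:
        """(n_tips, n_edges) 0/1 matrix: tip i descends from edge e."""
        if self._descent is None:
            D = np.zeros((self.n_tips, self.n_edges))
            for e, v in enumerate(self.edge_nodes):
                D[self.descendant_tips(v), e] = 1.0
            self._descent = D
        return self._descent

    def patristic_distance_matrix(self) -> pd.DataFrame:
        d = self.node_depths()[: self.n_tips]
        shared = self.mrca_depth_matrix()
        mat = d[:, None] + d[None, :] - 2.0 * shared
        np.fill_diagonal(mat, 0.0)
        return pd.DataFrame(mat, index=self.tip_labels, columns=self.tip_labels)

    def node_tip_shared_time(self) -> np.ndarray:
        """(n_nodes, n_tips) root-to-MRCA distance between every node and
        every tip (the BM covariance pattern between node and tip states)."""
        d = self.node_depths()
        out = np.zeros((self.n_nodes, self.n_tips))
        is_desc = np.zeros((self.n_nodes, self.n_tips), dtype=bool)
        for v in self.postorder:
            is_desc[v, self.descendant_tips(v)] = True
        for v in range(self.n_nodes):
            # climb from v; the MRCA with tip j is the first ancestor holding j
            out[v, is_desc[v]] = d[v]
            u, remaining = v, ~is_desc[v]
            while remaining.any() and u != self.root:
                u = self.parent[u]
                newly = remaining & is_desc[u]
                out[v, newly] = d[u]
                remaining &= ~newly
        return out

    # -- serialization ------------------------------------------------------

    def to_newick(self) -> str:
        def fmt(v: int) -> str:
            if not self.children[v]:
                s = self.tip_labels[v]
            else:
                s = "(" + ",".join(fmt(c) for c in self.children[v]) + ")"
            if v != self.root:
                s += f":{self.edge_length[v]:.12g}"
            return s
        return fmt(self.root) + ";"

    def __repr__(self) -> str:
        return (f"Phylogeny(n_tips={self.n_tips}, height={self.height:.4g}, "
                f"ultrametric={self.is_ultrametric()})")


def _from_dendropy(dtree: dendropy.Tree) -> Phylogeny:
    leaves = [nd for nd in dtree.leaf_node_iter()]
    internals = [nd for nd in dtree.postorder_node_iter() if not nd.is_leaf()]
    ids = {id(nd): i for i, nd in enumerate(leaves)}
    for nd in internals:
        ids[id(nd)] = len(ids)
    n = len(ids)
    parent = np.full(n, -1, dtype=int)
    length = np.zeros(n)
    for nd in dtree.preorder_node_iter():
        i = ids[id(nd)]
        if nd.parent_node is not None:
            parent[i] = ids[id(nd.parent_node)]
            length[i] = nd.edge.length if nd.edge.length is not None else 0.0
    labels = [lf.taxon.label if lf.taxon is not None else (lf.label or "")
              for lf in leaves]
    return Phylogeny(parent, length, labels)


def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string (with branch lengths) into a :class:`Phylogeny`."""
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  preserve_underscores=True)
    except Exception as exc:  # dendropy raises several error classes
        raise ParseError(f"malformed Newick: {exc}") from exc
    if dtree.seed_node is None or not list(dtree.leaf_node_iter()):
        raise ParseError("Newick input contains no tips")
    return _from_dendropy(dtree)


def write_newick(tree: Phylogeny) -> str:
    return tree.to_newick()


def prune_to_taxa(tree: Phylogeny, keep) -> Phylogeny:
    """Prune to the tip set ``keep``; unary internal nodes are suppressed with
    their edge lengths summed, preserving all retained patristic distances."""
    keep = set(keep)
    present = [t for t in tree.tip_labels if t in keep]
    if not present:
        raise EmptyIntersection("no requested taxa are present in the tree")
    if len(present) == len(tree.tip_labels):
        return tree
    dtree = dendropy.Tree.get(data=tree.to_newick(), schema="newick",
                              preserve_underscores=True)
    taxa = [t for t in dtree.taxon_namespace if t.label in keep]
    sub = dtree.extract_tree_with_taxa(taxa=taxa,
                                       suppress_unifurcations=True)
    return _from_dendropy(sub)


def default_genus(label: str) -> str:
    return label.replace(" ", "_").split("_")[0]


def cull_to_genus(tree: Phylogeny, genus_of=default_genus) -> Phylogeny:
    """Retain one tip per genus: the lexicographically smallest label
    (deterministic; intrageneric sequences are near-identical so the choice
    is inconsequential)."""
    chosen: dict[str, str] = {}
    for label in sorted(tree.tip_labels):
        chosen.setdefault(genus_of(label), label)
    dropped = set(tree.tip_labels) - set(chosen.values())
    if dropped:
        logger.info("genus culling drops %d tips: %s", len(dropped),
                    sorted(dropped))
    return prune_to_taxa(tree, chosen.values())


# ---------------------------------------------------------------------------
# Trait simulation
# ---------------------------------------------------------------------------

def simulate_bm(tree: Phylogeny, sigma2: float, root_state: float = 0.0,
                seed=None, n_cols: int = 1, prefix: str = "bm") -> pd.DataFrame:
    """Brownian motion: each edge adds an independent Gaussian increment with
    variance ``sigma2 * edge_length``.  Returns a tips x ``n_cols`` table."""
    if sigma2 < 0:
        raise BadParameter("sigma2 must be non-negative")
    rng = np.random.default_rng(seed)
    x = np.zeros((tree.n_nodes, n_cols))
    x[tree.root] = root_state
    for v in tree.postorder[::-1]:
        if v == tree.root:
            continue
        sd = np.sqrt(sigma2 * tree.edge_length[v])
        x[v] = x[tree.parent[v]] + sd * rng.standard_normal(n_cols)
    return pd.DataFrame(x[: tree.n_tips], index=tree.tip_labels,
                        columns=[f"{prefix}{j + 1}" for j in range(n_cols)])


def edge_regimes(tree: Phylogeny, shift_edges) -> np.ndarray:
    """Regime id per node: 0 before any shift; shift ``k`` (on edge
    ``shift_edges[k]``) switches the regime at the start of that edge for the
    whole subtree below, the nearest ancestral shift winning."""
    shift_edges = list(shift_edges)
    regime = np.zeros(tree.n_nodes, dtype=int)
    for v in tree.postorder[::-1]:  # preorder
        if v == tree.root:
            continue
        e = tree.edge_index_of_node[v]
        regime[v] = (shift_edges.index(e) + 1 if e in shift_edges
                     else regime[tree.parent[v]])
    return regime


def simulate_ou(tree: Phylogeny, alpha: float, sigma2: float,
                theta_by_regime=(0.0,), shift_edges=(), seed=None,
                root_state: float | None = None, n_cols: int = 1,
                prefix: str = "ou") -> pd.DataFrame:
    """Ornstein-Uhlenbeck simulation with optional optimum shifts.

    Along an edge of length ``l`` under regime optimum ``theta``::

        X_child | X_parent ~ Normal(theta + (X_parent - theta) e^{-alpha l},
                                    sigma2 (1 - e^{-2 alpha l}) / (2 alpha))

    ``alpha = 0`` falls back to Brownian motion.  The optimum switches at the
    start of each shift edge.  The root starts at the base optimum unless
    ``root_state`` is given.
    """
    if alpha < 0 or sigma2 < 0:
        raise BadParameter("rates must be non-negative")
    theta = np.asarray(theta_by_regime, dtype=float)
    regime = edge_regimes(tree, shift_edges)
    if regime.max() >= len(theta):
        raise BadParameter("theta_by_regime must cover base + one optimum "
                           "per shift edge")
    rng = np.random.default_rng(seed)
    x = np.zeros((tree.n_nodes, n_cols))
    x[tree.root] = theta[0] if root_state is None else root_state
    for v in tree.postorder[::-1]:
        if v == tree.root:
            continue
        ell = tree.edge_length[v]
        th = theta[regime[v]]
        if alpha == 0:
            mean, var = x[tree.parent[v]], sigma2 * ell
        else:
            w = np.exp(-alpha * ell)
            mean = th + (x[tree.parent[v]] - th) * w
            var = sigma2 * (1.0 - w ** 2) / (2.0 * alpha)
        x[v] = mean + np.sqrt(var) * rng.standard_normal(n_cols)
    return pd.DataFrame(x[: tree.n_tips], index=tree.tip_labels,
                        columns=[f"{prefix}{j + 1}" for j in range(n_cols)])


# ---------------------------------------------------------------------------
# Ancestral states and tree projections
# ---------------------------------------------------------------------------

def _tip_values(tree: Phylogeny, trait) -> np.ndarray:
    if isinstance(trait, pd.Series):
        missing = set(tree.tip_labels) - set(trait.index)
        if missing:
            raise BadParameter(f"trait missing for tips: {sorted(missing)}")
        return trait.reindex(tree.tip_labels).to_numpy(dtype=float)
    arr = np.asarray(trait, dtype=float)
    if arr.shape != (tree.n_tips,):
        raise BadParameter("trait must give one value per tip")
    return arr


def ancestral_states_bm(tree: Phylogeny, trait) -> np.ndarray:
    """Maximum-likelihood (GLS) states under Brownian motion at every node.

    With tip covariance V (shared times) the root estimate is
    ``(1' V^-1 1)^-1 1' V^-1 y``; internal nodes take the conditional mean
    given the tips, which coincides with the joint-ML states.  Returns an
    array over all node ids (tips carry their observations).
    """
    y = _tip_values(tree, trait)
    V = tree.mrca_depth_matrix()
    try:
        Vinv_y = np.linalg.solve(V, y)
        Vinv_1 = np.linalg.solve(V, np.ones_like(y))
    except np.linalg.LinAlgError as exc:
        raise SingularCovariance("BM tip covariance is singular "
                                 "(zero-length pathological tree)") from exc
    root_hat = float(Vinv_y.sum() / Vinv_1.sum())
    resid_w = np.linalg.solve(V, y - root_hat)
    C = tree.node_tip_shared_time()  # (n_nodes, n_tips)
    states = root_hat + C @ resid_w
    states[: tree.n_tips] = y  # tips are observed exactly
    return states


@dataclass
class NodePlacement:
    """Per-node 2-D coordinates plus the parent-child edge list for drawing
    a tree inside a trait space."""

    coords: np.ndarray          # (n_nodes, 2)
    edges: list[tuple[int, int]]
    tip_labels: list[str]
    columns: tuple[str, str]

    def frame(self) -> pd.DataFrame:
        n = len(self.coords)
        names = list(self.tip_labels) + [f"node{i}" for i in
                                         range(len(self.tip_labels), n)]
        df = pd.DataFrame(self.coords, columns=list(self.columns))
        df.insert(0, "node", names)
        df["is_tip"] = [i < len(self.tip_labels) for i in range(n)]
        return df


def _edge_list(tree: Phylogeny) -> list[tuple[int, int]]:
    return [(int(tree.parent[v]), int(v)) for v in range(tree.n_nodes)
            if v != tree.root]


def phylomorphospace(tree: Phylogeny, trait1, trait2,
                     names: tuple[str, str] = ("trait1", "trait2"),
                     ) -> NodePlacement:
    """Tree projected into a 2-D trait space: tips at observed values,
    internal nodes at BM ancestral estimates."""
    s1 = ancestral_states_bm(tree, trait1)
    s2 = ancestral_states_bm(tree, trait2)
    return NodePlacement(np.column_stack([s1, s2]), _edge_list(tree),
                         tree.tip_labels, names)


def phenogram(tree: Phylogeny, trait, name: str = "trait") -> NodePlacement:
    """Traitgram: x = node age (distance from root), y = observed (tips) or
    BM-estimated (internal) trait value."""
    states = ancestral_states_bm(tree, trait)
    return NodePlacement(np.column_stack([tree.node_depths(), states]),
                         _edge_list(tree), tree.tip_labels, ("age", name))


def require_ultrametric(tree: Phylogeny, rel_tol: float = 1e-6) -> None:
    if not tree.is_ultrametric(rel_tol):
        raise NonUltrametric("this operation requires an ultrametric tree")


# ---------------------------------------------------------------------------
# Trait table I/O
# ---------------------------------------------------------------------------

def read_trait_table(path) -> pd.DataFrame:
    """Trait CSV with a ``tip_label`` column; remaining columns are traits."""
    df = pd.read_csv(path)
    if "tip_label" not in df.columns:
        raise BadParameter("trait CSV needs a tip_label column")
    return df.set_index("tip_label")


def write_trait_table(traits: pd.DataFrame, path) -> None:
    traits.rename_axis("tip_label").to_csv(path)
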