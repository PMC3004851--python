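"""Phylogenetic beta diversity (UniFrac) and principal coordinates.

UniFrac measures the fraction of phylogenetic branch length unique to
one of two communities.  The unweighted variant uses tip presence/
absence only (community membership); the weighted variant sums branch
lengths multiplied by the difference in relative read abundance
descending through each branch (community structure), optionally
normalised to [0, 1].

Root handling: the branch above the lowest common ancestor (LCA) of
all tips observed in a pair is excluded from both numerator and
denominator, so two communities occupying disjoint clades score exactly
1 under the unweighted metric.  The normalised weighted denominator
``D = sum_j d_j (a_j + b_j)`` likewise measures tip depths ``d_j`` from
that LCA.

Taxa present in the count table but absent from the tree are a hard
error: dropping them silently would change distances invisibly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix, TreeNode

from .io import CountTable

__all__ = [
    "TreeIndex",
    "unifrac_unweighted",
    "unifrac_weighted",
    "distance_matrix",
    "pcoa",
    "OrdinationResult",
]


class TreeIndex:
    """Flat edge representation of a rooted tree over a taxon set.

    ``edge_tips`` is a boolean matrix (n_edges × n_taxa): edge e is on
    the root-ward path of taxon t.  Edge order is postorder; each edge
    is identified with its child node.
    """

    def __init__(self, tree: TreeNode, taxa: list[str]):
        taxon_pos = {t: i for i, t in enumerate(taxa)}
        tree_tips = {t.name for t in tree.tips()}
        missing = set(taxa) - tree_tips
        if missing:
            raise KeyError(
                f"taxa in table but absent from tree: {sorted(missing)[:5]}"
            )
        extra = tree_tips - set(taxa)
        if extra:
            from .io import prune_tree

            tree = prune_tree(tree, set(taxa))
        nodes = [n for n in tree.postorder(include_self=False)]
        self.n_taxa = len(taxa)
        self.n_edges = len(nodes)
        self.lengths = np.array([float(n.length or 0.0) for n in nodes])
        self.edge_tips = np.zeros((self.n_edges, self.n_taxa), dtype=bool)
        edge_index = {id(n): i for i, n in enumerate(nodes)}
        below: dict[int, np.ndarray] = {}
        for i, node in enumerate(nodes):
            if node.is_tip():
                mask = np.zeros(self.n_taxa, dtype=bool)
                mask[taxon_pos[node.name]] = True
            else:
                mask = np.zeros(self.n_taxa, dtype=bool)
                for child in node.children:
                    mask |= below[id(child)]
            below[id(node)] = mask
            self.edge_tips[i] = mask
        # depth of each edge's child node measured from the root
        self.node_depths = np.zeros(self.n_edges)
        depth_of: dict[int, float] = {id(tree): 0.0}
        for node in tree.preorder(include_self=False):
            d = depth_of[id(node.parent)] + float(node.length or 0.0)
            depth_of[id(node)] = d
            self.node_depths[edge_index[id(node)]] = d
        # root-to-tip depth per taxon
        self.tip_depths = np.zeros(self.n_taxa)
        for node in tree.tips():
            self.tip_depths[taxon_pos[node.name]] = depth_of[id(node)]
        # parent edge index (-1 if parent is root) for LCA chains
        self.parent_edge = np.full(self.n_edges, -1, dtype=np.int64)
        for i, node in enumerate(nodes):
            if node.parent is not None and id(node.parent) in edge_index:
                self.parent_edge[i] = edge_index[id(node.parent)]

    # -- per-sample summaries ----------------------------------------------

    def edge_counts(self, counts: np.ndarray) -> np.ndarray:
        """Counts descending through each edge: (n_edges, n_samples)."""
        return self.edge_tips @ counts.T

    def lca_edge(self, present: np.ndarray) -> int:
        """Edge whose child node is the LCA of the present tips, or -1
        if that LCA is the root."""
        n_present = int(present.sum())
        if n_present == 0:
            return -1
        containing = np.flatnonzero(
            (self.edge_tips @ present.astype(np.int64)) == n_present
        )
        if containing.size == 0:
            return -1
        # deepest containing edge = the LCA's own edge
        return int(containing[np.argmax(self.node_depths[containing])])

    def _lca_chain(self, edge: int) -> list[int]:
        chain = []
        while edge >= 0:
            chain.append(edge)
            edge = int(self.parent_edge[edge])
        return chain


def _pair_vectors(table: CountTable, pair) -> tuple[np.ndarray, np.ndarray]:
    i, j = pair
    for s in (i, j):
        if s not in table.counts.index:
            raise KeyError(f"sample {s!r} not in count table")
    a = table.counts.loc[i].to_numpy(dtype=float)
    b = table.counts.loc[j].to_numpy(dtype=float)
    if a.sum() == 0 and b.sum() == 0:
        raise ValueError(f"both samples {i!r}, {j!r} are empty")
    return a, b


def unifrac_unweighted(
    table: CountTable, tree: TreeNode, pair, index: TreeIndex | None = None
) -> float:
    """Unweighted UniFrac for one sample pair: unique / observed branch
    length, excluding branches above the pair's LCA.  In [0, 1]."""
    if index is None:
        index = TreeIndex(tree, table.taxon_ids)
    a, b = _pair_vectors(table, pair)
    return _unweighted_from_vectors(index, a > 0, b > 0)


def _unweighted_from_vectors(
    index: TreeIndex, pres_a: np.ndarray, pres_b: np.ndarray
) -> float:
    ea = index.edge_tips @ pres_a.astype(np.int64)  # present tips under edge
    eb = index.edge_tips @ pres_b.astype(np.int64)
    on_a = ea > 0
    on_b = eb > 0
    full = (ea == pres_a.sum()) & (eb == pres_b.sum())
    union = (on_a | on_b) & ~full
    unique = (on_a ^ on_b) & ~full
    denom = float(index.lengths[union].sum())
    if denom == 0.0:
        return 0.0
    return float(index.lengths[unique].sum()) / denom


def unifrac_weighted(
    table: CountTable,
    tree: TreeNode,
    pair,
    normalized: bool = True,
    index: TreeIndex | None = None,
) -> float:
    """Weighted UniFrac for one sample pair.

    Raw: ``W = sum_b l_b |A_b/A_T - B_b/B_T|``.  Normalised (default)
    divides by ``D = sum_j d_j (A_j/A_T + B_j/B_T)`` with tip depths
    ``d_j`` measured from the pair's LCA, giving a value in [0, 1].
    """
    if index is None:
        index = TreeIndex(tree, table.taxon_ids)
    a, b = _pair_vectors(table, pair)
    ra = a / a.sum() if a.sum() else a
    rb = b / b.sum() if b.sum() else b
    ea = index.edge_tips @ ra
    eb = index.edge_tips @ rb
    w = float((index.lengths * np.abs(ea - eb)).sum())
    if not normalized:
        return w
    if w == 0.0:
        return 0.0
    lca = index.lca_edge((a + b) > 0)
    lca_depth = index.node_depths[lca] if lca >= 0 else 0.0
    d = index.tip_depths - lca_depth
    denom = float((d * (ra + rb)).sum())
    return w / denom if denom > 0 else 0.0


def distance_matrix(
    table: CountTable,
    tree: TreeNode,
    metric: str = "unweighted",
    normalized: bool = True,
) -> DistanceMatrix:
    """All-pairs UniFrac distance matrix (vectorised over edges)."""
    if metric not in {"unweighted", "weighted"}:
        raise ValueError(f"metric must be 'unweighted' or 'weighted', got {metric!r}")
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    totals = table.counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("empty samples present; drop them before computing distances")
    index = TreeIndex(tree, table.taxon_ids)
    counts = table.counts.to_numpy(dtype=float)
    n = counts.shape[0]
    l = index.lengths
    if metric == "unweighted":
        pres = counts > 0
        ep = index.edge_tips.astype(float) @ pres.T.astype(float)  # edges × samples
        on = ep > 0
        n_pres = pres.sum(axis=1)
        fullc = (ep == n_pres[None, :])  # edge contains all present tips of sample
        wl = l[:, None]
        on_len = (wl * on).sum(axis=0)  # L_i
        and_len = (wl * on).T @ on  # Σ l on_i on_j
        full_len = (wl * fullc).T @ fullc  # Σ l full_i full_j (root chain to pair LCA)
        union = on_len[:, None] + on_len[None, :] - and_len
        uniq = union - and_len
        denom = union - full_len
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(denom > 0, uniq / denom, 0.0)
    else:
        rel = counts / counts.sum(axis=1, keepdims=True)
        e = index.edge_tips.astype(float) @ rel.T  # edges × samples
        # pairwise weighted L1 over edges
        d = squareform(
            _pairwise_weighted_l1(e, l), checks=False
        )
        if normalized:
            lca_depths = _pair_lca_depths(index, counts)
            s = index.tip_depths @ rel.T  # Σ_t depth_t a_ti per sample
            denom = s[:, None] + s[None, :] - 2.0 * lca_depths
            with np.errstate(invalid="ignore", divide="ignore"):
                d = np.where((d > 0) & (denom > 0), d / np.where(denom > 0, denom, 1.0), 0.0)
    d = np.asarray(d, dtype=float)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    d[d < 0] = 0.0
    return DistanceMatrix(d, ids=table.sample_ids)


def _pairwise_weighted_l1(e: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Condensed pairwise sum_k w_k |x_ik - x_jk| over columns of e."""
    from scipy.spatial.distance import pdist

    return pdist(e.T, metric="minkowski", p=1, w=weights)


def _pair_lca_depths(index: TreeIndex, counts: np.ndarray) -> np.ndarray:
    """Matrix of LCA depths for the union of present tips of each pair."""
    n = counts.shape[0]
    chains = []
    for i in range(n):
        chains.append(index._lca_chain(index.lca_edge(counts[i] > 0)))
    chain_sets = [set(c) for c in chains]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            # pair LCA = deepest edge on both samples' root chains
            common = chain_sets[i] & chain_sets[j]
            if common:
                depth = max(index.node_depths[e] for e in common)
                out[i, j] = out[j, i] = depth
    return out


# ---------------------------------------------------------------------------
# principal coordinates analysis


@dataclass
class OrdinationResult:
    """PCoA embedding: sample coordinates on axes ordered by decreasing
    eigenvalue; proportions explained computed over positive eigenvalues
    only (negative eigenvalues are reported but carry no coordinates)."""

    sample_ids: list[str]
    coordinates: np.ndarray  # samples × retained axes
    eigenvalues: np.ndarray  # all eigenvalues, decreasing
    proportion_explained: np.ndarray  # per retained (positive) axis


def pcoa(dm: DistanceMatrix, eps: float = 1e-10) -> OrdinationResult:
    """Classical metric MDS: Gower double-centering of −½ d², symmetric
    eigendecomposition, axes scaled by sqrt(eigenvalue).

    Axis signs are fixed deterministically (largest-magnitude loading
    positive); ties in eigenvalues are ordered stably.
    """
    d = np.asarray(dm.data, dtype=float)
    if d.shape[0] < 3:
        raise ValueError("PCoA needs at least 3 samples")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    a = -0.5 * d**2
    centerer = np.eye(n) - np.ones((n, n)) / n
    b = centerer @ a @ centerer
    b = (b + b.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(-eigvals, kind="stable")
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = eps * max(1.0, float(np.abs(eigvals).max(initial=0.0)))
    positive = eigvals > tol
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    # deterministic signs: largest-magnitude loading on each axis positive
    for k in range(coords.shape[1]):
        col = coords[:, k]
        pivot = int(np.argmax(np.abs(col)))
        if col[pivot] < 0:
            coords[:, k] = -col
    pos_sum = eigvals[positive].sum()
    proportion = (
        eigvals[positive] / pos_sum if pos_sum > 0 else np.zeros(int(positive.sum()))
    )
    return OrdinationResult(
        sample_ids=list(dm.ids),
        coordinates=coords,
        eigenvalues=eigvals,
        proportion_explained=proportion,
    )
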