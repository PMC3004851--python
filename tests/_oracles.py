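"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's edge-matrix machinery: every
branch is classified by recursively collected descendant tip sets, so
agreement with the vectorised implementation is a genuine dual-route
check.
"""

from __future__ import annotations

import numpy as np
from skbio import TreeNode


def _descendant_tips(node: TreeNode) -> frozenset:
    if node.is_tip():
        return frozenset([node.name])
    out = frozenset()
    for child in node.children:
        out |= _descendant_tips(child)
    return out


def _depths_from_root(tree: TreeNode) -> dict[str, float]:
    depths = {}

    def walk(node, acc):
        if node.is_tip():
            depths[node.name] = acc
        for child in node.children:
            walk(child, acc + float(child.length or 0.0))

    walk(tree, 0.0)
    return depths


def _lca_node(tree: TreeNode, present: set) -> TreeNode:
    node = tree
    while True:
        containing = [
            c for c in node.children if present <= _descendant_tips(c)
        ]
        if not containing:
            return node
        node = containing[0]


def _node_depth(tree: TreeNode, target: TreeNode) -> float:
    def walk(node, acc):
        if node is target:
            return acc
        for child in node.children:
            r = walk(child, acc + float(child.length or 0.0))
            if r is not None:
                return r
        return None

    return walk(tree, 0.0) or 0.0


def brute_unifrac_unweighted(tree: TreeNode, abund_a: dict, abund_b: dict) -> float:
    pres_a = {t for t, c in abund_a.items() if c > 0}
    pres_b = {t for t, c in abund_b.items() if c > 0}
    union = pres_a | pres_b
    unique = shared = 0.0
    for node in tree.traverse(include_self=False):
        tips = _descendant_tips(node)
        if tips >= union:  # at or above the pair LCA: excluded
            continue
        in_a = bool(tips & pres_a)
        in_b = bool(tips & pres_b)
        if not (in_a or in_b):
            continue
        l = float(node.length or 0.0)
        if in_a and in_b:
            shared += l
        else:
            unique += l
    total = unique + shared
    return unique / total if total > 0 else 0.0


def brute_unifrac_weighted(
    tree: TreeNode, abund_a: dict, abund_b: dict, normalized: bool
) -> float:
    tot_a = sum(abund_a.values())
    tot_b = sum(abund_b.values())
    w = 0.0
    for node in tree.traverse(include_self=False):
        tips = _descendant_tips(node)
        pa = sum(abund_a.get(t, 0) for t in tips) / tot_a
        pb = sum(abund_b.get(t, 0) for t in tips) / tot_b
        w += float(node.length or 0.0) * abs(pa - pb)
    if not normalized:
        return w
    if w == 0.0:
        return 0.0
    present = {t for t in set(abund_a) | set(abund_b) if abund_a.get(t, 0) + abund_b.get(t, 0) > 0}
    lca = _lca_node(tree, present)
    lca_depth = _node_depth(tree, lca)
    depths = _depths_from_root(tree)
    denom = sum(
        (depths[t] - lca_depth)
        * (abund_a.get(t, 0) / tot_a + abund_b.get(t, 0) / tot_b)
        for t in depths
    )
    return w / denom if denom > 0 else 0.0


def random_tree(n_tips: int, rng: np.random.Generator) -> TreeNode:
    """Random bifurcating tree with uniform(0.1, 2) branch lengths,
    built by joining subtrees in random order (independent of the
    package's Yule generator)."""
    nodes = []
    for i in range(n_tips):
        tip = TreeNode(name=f"t{i}")
        tip.length = float(rng.uniform(0.1, 2.0))
        nodes.append(tip)
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(children=[a, b])
        parent.length = float(rng.uniform(0.1, 2.0))
        nodes.append(parent)
    root = TreeNode(children=nodes)
    root.length = None
    return root


def classical_anova_f(values: np.ndarray, labels: np.ndarray) -> float:
    """One-way ANOVA F on 1-D data, textbook sums of squares."""
    groups = [values[labels == g] for g in np.unique(labels)]
    k = len(groups)
    n = values.size
    grand = values.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    return (ss_between / (k - 1)) / (ss_within / (n - k))
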