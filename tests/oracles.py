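"""Independent reference implementations used only to cross-check the package.

Everything here is deliberately coded from first principles along different
algorithmic routes than the library (set enumeration instead of edge-matrix
algebra, numerically differenced Newton-Raphson instead of IRLS, permutation
averaging instead of weighted subset sums).
"""

import itertools

import numpy as np
import dendropy


# ---------------------------------------------------------------------------
# tree metrics by exhaustive root-path enumeration
# ---------------------------------------------------------------------------

def _root_path_edges(tree: dendropy.Tree, tip_label: str):
    """Edges (as node ids) on the path from a tip to the root."""
    leaf = next(lf for lf in tree.leaf_node_iter() if lf.taxon.label == tip_label)
    path = set()
    nd = leaf
    while nd is not None:
        path.add(id(nd))
        nd = nd.parent_node
    return path


def _edge_table(tree: dendropy.Tree):
    return {id(nd): (nd.edge.length or 0.0) for nd in tree.preorder_node_iter()}


def pd_oracle(tree: dendropy.Tree, species) -> float:
    """Faith's PD as the union of per-tip root paths."""
    lengths = _edge_table(tree)
    edges = set()
    for sp in species:
        edges |= _root_path_edges(tree, sp)
    return sum(lengths[e] for e in edges)


def partition_oracle(tree: dendropy.Tree, set_x, set_y):
    """(A, B, C) branch-length partition by explicit edge-set operations."""
    lengths = _edge_table(tree)
    ex = set()
    for sp in set_x:
        ex |= _root_path_edges(tree, sp)
    ey = set()
    for sp in set_y:
        ey |= _root_path_edges(tree, sp)
    a = sum(lengths[e] for e in ex & ey)
    b = sum(lengths[e] for e in ex - ey)
    c = sum(lengths[e] for e in ey - ex)
    return a, b, c


def simpson_oracle(a: float, b: float, c: float) -> float:
    m = min(b, c)
    return 0.0 if a + m == 0 else m / (a + m)


def random_tree(rng: np.random.Generator, n_tips: int) -> dendropy.Tree:
    """Random rooted binary tree with exponential branch lengths."""
    labels = [f"t{i}" for i in range(n_tips)]
    nodes = [f"{lab}:{rng.exponential(1.0):.6f}" for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{rng.exponential(1.0):.6f}"
        nodes[i] = merged
        del nodes[j]
    newick = nodes[0].rsplit(":", 1)[0] + ";"
    return dendropy.Tree.get(data=newick, schema="newick")


# ---------------------------------------------------------------------------
# cloglog likelihood by numerically differenced Newton-Raphson
# ---------------------------------------------------------------------------

def cloglog_loglik(beta, X, y):
    eta = np.clip(X @ beta, -30, 3.5)
    mu = np.clip(1.0 - np.exp(-np.exp(eta)), 1e-12, 1 - 1e-12)
    return float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


def newton_raphson_cloglog(X, y, beta0=None, max_iter=200):
    """ML fit via Newton-Raphson on numerically differenced derivatives."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    p = X.shape[1]
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, float).copy()
    h = 1e-6

    def grad(b):
        g = np.empty(p)
        for j in range(p):
            e = np.zeros(p)
            e[j] = h
            g[j] = (cloglog_loglik(b + e, X, y) - cloglog_loglik(b - e, X, y)) / (2 * h)
        return g

    for _ in range(max_iter):
        g = grad(beta)
        H = np.empty((p, p))
        for j in range(p):
            e = np.zeros(p)
            e[j] = h
            H[:, j] = (grad(beta + e) - grad(beta - e)) / (2 * h)
        step = np.linalg.solve(H, g)
        new = beta - step
        # damp if the likelihood decreases
        while cloglog_loglik(new, X, y) < cloglog_loglik(beta, X, y) - 1e-9:
            step *= 0.5
            new = beta - step
        if np.max(np.abs(new - beta)) < 1e-10:
            beta = new
            break
        beta = new
    return beta


# ---------------------------------------------------------------------------
# importance shares by permutation (Shapley) averaging
# ---------------------------------------------------------------------------

def shapley_oracle(r2_by_subset: dict, group_names):
    """Average marginal R2 gain over all orderings of the groups."""
    k = len(group_names)
    total = {g: 0.0 for g in group_names}
    perms = list(itertools.permutations(range(k)))
    for perm in perms:
        seen = frozenset()
        for gi in perm:
            gained = r2_by_subset[seen | {gi}] - r2_by_subset[seen]
            total[group_names[gi]] += gained
            seen = seen | {gi}
    return {g: v / len(perms) for g, v in total.items()}
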