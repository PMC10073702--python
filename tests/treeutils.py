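"""Test-side tree oracles: random tree generation, additive distance
matrices, leaf-distance read-back, and a two-clade supermatrix builder.
Independent of the package's phylo implementation wherever possible."""

from __future__ import annotations

import numpy as np

from sigbin.phylo import MarkerAlignment, TreeNode, concatenate

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_tree(rng, n_leaves):
    """Random unrooted binary tree as (parent array, branch lengths);
    nodes 0..n_leaves-1 are leaves, roots have parent -1."""
    parent = [-1] * n_leaves
    lengths = [0.0] * n_leaves
    r = n_leaves
    parent += [-1]
    lengths += [0.0]
    for i in range(3):
        parent[i] = r
    edges = [0, 1, 2]
    for leaf in range(3, n_leaves):
        e = edges[int(rng.integers(len(edges)))]
        new_internal = len(parent)
        parent.append(parent[e])
        lengths.append(rng.uniform(0.05, 0.5))
        parent[e] = new_internal
        parent[leaf] = new_internal
        edges.append(leaf)
        edges.append(new_internal)
    for i in range(len(lengths)):
        if parent[i] != -1:
            lengths[i] = rng.uniform(0.05, 0.5)
    return parent, lengths


def tree_distance_matrix(parent, lengths, n_leaves):
    """Path-length (additive) matrix of a parent-array tree."""
    D = np.zeros((n_leaves, n_leaves))
    for i in range(n_leaves):
        full_i = {}
        node, acc = i, 0.0
        while node != -1:
            full_i[node] = acc
            acc += lengths[node]
            node = parent[node]
        for j in range(i + 1, n_leaves):
            node, acc = j, 0.0
            while node not in full_i:
                acc += lengths[node]
                node = parent[node]
            D[i, j] = D[j, i] = acc + full_i[node]
    return D


def leaf_dist_from_tree_node(tree: TreeNode):
    """Read pairwise leaf distances back off a TreeNode."""
    names = sorted(tree.leaf_names())
    idx = {n: i for i, n in enumerate(names)}
    D = np.zeros((len(names), len(names)))

    def walk(node, acc):
        if node.is_leaf:
            return {node.name: acc}
        out = {}
        for c in node.children:
            out.update(walk(c, acc + c.length))
        return out

    def collect(node):
        subtrees = [walk(c, c.length) for c in node.children]
        for a in range(len(subtrees)):
            for b in range(a + 1, len(subtrees)):
                for la, da in subtrees[a].items():
                    for lb, db in subtrees[b].items():
                        D[idx[la], idx[lb]] = D[idx[lb], idx[la]] = da + db
        for c in node.children:
            if not c.is_leaf:
                collect(c)

    collect(tree)
    return names, D


def two_clade_supermatrix(n_per_clade=5, n_diag=50, n_noise=150, seed=0):
    """Supermatrix with two clean clades separated by diagnostic columns."""
    rng = np.random.default_rng(seed)
    genomes = [f"A{i}" for i in range(n_per_clade)] + [
        f"B{i}" for i in range(n_per_clade)
    ]
    cols = []
    for _ in range(n_diag):
        ra, rb = rng.choice(list(AA), size=2, replace=False)
        cols.append([ra] * n_per_clade + [rb] * n_per_clade)
    for _ in range(n_noise):
        base = rng.choice(list(AA))
        col = [base] * (2 * n_per_clade)
        col[int(rng.integers(2 * n_per_clade))] = rng.choice(list(AA))
        cols.append(col)
    mat = np.array(cols).T
    rows = {g: "".join(mat[i]) for i, g in enumerate(genomes)}
    return concatenate([MarkerAlignment(marker_id="m", rows=rows)], genomes)
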