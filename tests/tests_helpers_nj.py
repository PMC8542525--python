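"""Shared oracle helpers: random additive trees and path-length distances,
independent of any neighbor-joining implementation."""

import io

import numpy as np


def tree_distances(newick_str, names):
    """Leaf-to-leaf path-length distances of a newick tree."""
    from skbio import TreeNode
    tree = TreeNode.read(io.StringIO(newick_str))
    n = len(names)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = tree.find(names[i]).distance(tree.find(names[j]))
            D[i, j] = D[j, i] = d
    return D


def random_additive_tree(n_taxa, rng):
    """Random binary topology with uniform(0.5, 2) branch lengths.

    Returns (newick, leaf names, additive distance matrix); distances come
    from path summation on the generating tree.
    """
    names = [f"T{i}" for i in range(n_taxa)]
    subtrees = {nm: nm for nm in names}
    active = list(names)
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        la, lb = rng.uniform(0.5, 2.0, size=2).round(3)
        merged = f"({subtrees[a]}:{la},{subtrees[b]}:{lb})"
        new = f"N{len(subtrees)}"
        subtrees[new] = merged
        active = [x for x in active if x not in (a, b)] + [new]
    nwk = subtrees[active[0]] + ";"
    return nwk, names, tree_distances(nwk, names)
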