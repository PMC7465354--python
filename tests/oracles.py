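"""Independent oracles used by the test suite.

These deliberately avoid the code paths they validate: the Fisher oracle
enumerates the hypergeometric support with exact rational arithmetic, and the
tree helpers compute leaf-to-leaf path distances directly on a constructed
topology.
"""

from fractions import Fraction
from math import comb

import numpy as np

from sdrscan.phylo_divergence import Clade, PhyloTree


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by full enumeration at fixed margins,
    summing (exactly, as rationals) every table whose probability does not
    exceed the observed table's."""
    r1 = a + b
    c1 = a + c
    n = a + b + c + d
    denom = comb(n, r1)

    def pmf(x: int) -> Fraction:
        return Fraction(comb(c1, x) * comb(n - c1, r1 - x), denom)

    lo = max(0, r1 - (n - c1))
    hi = min(r1, c1)
    p_obs = pmf(a)
    return float(sum(p for x in range(lo, hi + 1) if (p := pmf(x)) <= p_obs))


def random_additive_tree(n_taxa: int, rng: np.random.Generator) -> PhyloTree:
    """Random unrooted binary topology (trifurcating root) with branch
    lengths in [0.5, 5)."""
    labels = [f"T{i}" for i in range(n_taxa)]

    def build(leaves: list[str]) -> Clade:
        if len(leaves) == 1:
            return Clade(name=leaves[0], branch_length=float(rng.uniform(0.5, 5)))
        cut = int(rng.integers(1, len(leaves)))
        node = Clade(
            branch_length=float(rng.uniform(0.5, 5)),
            children=[build(leaves[:cut]), build(leaves[cut:])],
        )
        return node

    order = [labels[i] for i in rng.permutation(n_taxa)]
    cut1 = int(rng.integers(1, n_taxa - 1))
    cut2 = int(rng.integers(cut1 + 1, n_taxa))
    root = Clade(
        children=[build(order[:cut1]), build(order[cut1:cut2]), build(order[cut2:])]
    )
    return PhyloTree(root=root)


def tree_distances(tree: PhyloTree) -> tuple[list[str], np.ndarray]:
    """Leaf-to-leaf path-length matrix by traversal (the additive metric)."""
    edges: dict[int, list[tuple[int, float]]] = {}
    leaf_of: dict[int, str] = {}
    counter = [0]

    def walk(clade, parent_id):
        my_id = counter[0]
        counter[0] += 1
        edges.setdefault(my_id, [])
        if parent_id is not None:
            w = clade.branch_length or 0.0
            edges[my_id].append((parent_id, w))
            edges[parent_id].append((my_id, w))
        if clade.is_leaf:
            leaf_of[my_id] = clade.name
        for child in clade.children:
            walk(child, my_id)

    walk(tree.root, None)
    labels = sorted(leaf_of.values())
    index = {lab: i for i, lab in enumerate(labels)}
    dist = np.zeros((len(labels), len(labels)))
    for src, lab in leaf_of.items():
        seen = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in edges[u]:
                if v not in seen:
                    seen[v] = seen[u] + w
                    stack.append(v)
        for dst, lab2 in leaf_of.items():
            dist[index[lab], index[lab2]] = seen[dst]
    return labels, dist
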