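"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's PhyloIndex machinery: every branch is
enumerated and classified by explicit tip-descendant set membership.
"""

from __future__ import annotations

import random

import dendropy


def edge_table(tree: dendropy.Tree):
    """(length, frozenset of tip labels below) for every branch with a length."""
    out = []
    for node in tree.postorder_node_iter():
        length = node.edge.length
        if node is tree.seed_node and length is None:
            continue
        tips = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        out.append((float(length or 0.0), tips))
    return out


def brute_branch_overlap(tree, flora_a, flora_b):
    """A, B, C by exhaustive per-branch classification."""
    fa, fb = set(flora_a), set(flora_b)
    A = B = C = 0.0
    for length, tips in edge_table(tree):
        in_a = bool(tips & fa)
        in_b = bool(tips & fb)
        if in_a and in_b:
            A += length
        elif in_a:
            B += length
        elif in_b:
            C += length
    return A, B, C


def brute_simpson_phylo(tree, flora_a, flora_b):
    A, B, C = brute_branch_overlap(tree, flora_a, flora_b)
    m = min(B, C)
    return 1.0 - m / (A + m)


def brute_faith_pd(tree, flora):
    flora = set(flora)
    total = 0.0
    for length, tips in edge_table(tree):
        if tips & flora:
            total += length
    return total


def brute_simpson_tax(flora_a, flora_b):
    fa, fb = set(flora_a), set(flora_b)
    a = len(fa & fb)
    b, c = len(fa - fb), len(fb - fa)
    m = min(b, c)
    return 1.0 - m / (a + m) if (a + m) else 1.0


def brute_sorensen_tax(flora_a, flora_b):
    fa, fb = set(flora_a), set(flora_b)
    a = len(fa & fb)
    return 2 * a / (2 * a + len(fa - fb) + len(fb - fa))


def random_tree(seed: int, n_tips: int) -> dendropy.Tree:
    """Random birth-death tree with labelled tips t1..tn."""
    from dendropy.simulate import treesim

    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=random.Random(seed),
    )
    for k, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"t{k + 1}"
    return tree
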