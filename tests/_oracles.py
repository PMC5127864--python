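"""Independent oracles used by the test suite.

These deliberately avoid the package's dynamic-programming code paths:
the Wagner oracle enumerates every ancestral state assignment, and the
Fitch oracle is the classic set-intersection pass for symmetric binary
parsimony.
"""

from itertools import product
from typing import Dict, Tuple

import dendropy


def brute_force_wagner(
    tree: dendropy.Tree,
    leaf_states: Dict[str, int],
    gain_penalty: float,
    cmax: int,
    loss_penalty: float = 1.0,
) -> Tuple[float, Dict[int, set]]:
    """Exhaustive minimum over all internal-node state assignments.

    Returns (min cost, {root states achieving it}). Only usable for tiny
    trees (the state space is (cmax+1)^n_internal).
    """
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    root = tree.seed_node
    best = float("inf")
    best_roots: set = set()
    for combo in product(range(cmax + 1), repeat=len(internal)):
        states = {id(n): s for n, s in zip(internal, combo)}
        for leaf in tree.leaf_node_iter():
            label = leaf.taxon.label if leaf.taxon else leaf.label
            states[id(leaf)] = leaf_states[label]
        cost = 0.0
        for node in tree.preorder_node_iter():
            if node is root:
                continue
            a = states[id(node.parent_node)]
            b = states[id(node)]
            cost += gain_penalty * max(b - a, 0) + loss_penalty * max(a - b, 0)
        if cost < best - 1e-12:
            best = cost
            best_roots = {states[id(root)]}
        elif abs(cost - best) <= 1e-12:
            best_roots.add(states[id(root)])
    return best, best_roots


def fitch_length(tree: dendropy.Tree, leaf_states: Dict[str, int]) -> int:
    """Minimum number of state changes under symmetric (Fitch) parsimony,
    computed by the bottom-up set pass on a rooted tree."""
    changes = 0
    sets: Dict[int, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label if node.taxon else node.label
            sets[id(node)] = frozenset({leaf_states[label]})
            continue
        child_sets = [sets[id(c)] for c in node.child_nodes()]
        inter = frozenset.intersection(*child_sets)
        if inter:
            sets[id(node)] = inter
        else:
            sets[id(node)] = frozenset.union(*child_sets)
            changes += len(child_sets) - 1  # binary trees: one change per union
    return changes
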