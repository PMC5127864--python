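"""Wagner-parsimony reconstruction of gene gain and loss on a guide tree.

Given a rooted guide tree and a taxa x families copy-count matrix, each
family is reconstructed independently by a Sankoff dynamic program over
integer states 0..Cmax with the asymmetric branch cost

    c(a -> b) = g * max(b - a, 0) + max(a - b, 0)

where ``g`` is the gain penalty (cost per copy gained) and each copy lost
costs 1. A high gain penalty (e.g. g = 5) makes independent acquisitions
expensive and so favors large ancestors with subsequent genome reduction;
g = 1 treats gains and losses symmetrically and favors small ancestors
with lineage-specific expansion. Presence/absence data is the Cmax = 1
special case.

Ties are resolved deterministically toward the smaller state (biasing
against unobservable ancestral genes); families whose optimum is not
unique are flagged so downstream summaries can report the ambiguity.
The DP minimum is verified against exhaustive enumeration over all
ancestral state assignments in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "WagnerParams",
    "GainLossReconstruction",
    "wagner_reconstruct",
    "summarize_events",
    "map_family_origins",
]

_BIG = 1e18


@dataclass(frozen=True)
class WagnerParams:
    """Wagner parsimony penalties: ``gain_penalty`` per copy gained, a
    fixed cost of 1 per copy lost, over states 0..``max_count`` (default:
    the largest observed leaf count, at least 1)."""

    gain_penalty: float = 1.0
    loss_penalty: float = 1.0
    max_count: Optional[int] = None

    def __post_init__(self) -> None:
        if self.gain_penalty <= 0:
            raise ValueError("gain_penalty must be > 0")
        if self.loss_penalty <= 0:
            raise ValueError("loss_penalty must be > 0")
        if self.max_count is not None and self.max_count < 1:
            raise ValueError("max_count must be >= 1")


@dataclass
class GainLossReconstruction:
    """Ancestral copy counts, per-branch event totals, and total cost.

    ``counts``: node-label x family matrix of reconstructed copy counts
    (leaves carry their observed counts). ``branch_events``: per non-root
    node, total gains and losses on the branch above it, summed over
    families. ``tied_families``: families with more than one equally
    parsimonious reconstruction under the tie-break.
    """

    tree: dendropy.Tree
    counts: pd.DataFrame
    branch_events: pd.DataFrame
    total_cost: float
    params: WagnerParams
    tied_families: List[str]

    def node_sizes(self) -> pd.Series:
        """Number of families with count >= 1 at each node."""
        return (self.counts >= 1).sum(axis=1)

    @property
    def root_label(self) -> str:
        return self.tree.seed_node.label


def _ensure_labels(tree: dendropy.Tree) -> None:
    existing = {n.label for n in tree.preorder_node_iter() if n.label}
    k = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            if node.label is None and node.taxon is not None:
                node.label = node.taxon.label
        elif not node.label:
            k += 1
            while f"N{k:03d}" in existing:
                k += 1
            node.label = f"N{k:03d}"
            existing.add(node.label)


def wagner_reconstruct(
    tree: dendropy.Tree,
    matrix: pd.DataFrame,
    params: WagnerParams = WagnerParams(),
) -> GainLossReconstruction:
    """Most parsimonious ancestral copy counts for every family.

    The tree must be rooted and its leaf labels must equal the matrix
    rows exactly. Per family the Sankoff DP computes, bottom-up, the
    minimal subtree cost of each ancestral state; the root takes the
    cheapest state and the backtrace picks, at every node, the smallest
    child state achieving the parent's optimum.
    """
    _ensure_labels(tree)
    leaf_labels = sorted(
        (lf.taxon.label if lf.taxon else lf.label) for lf in tree.leaf_node_iter()
    )
    matrix_taxa = sorted(str(t) for t in matrix.index)
    if leaf_labels != matrix_taxa:
        only_tree = sorted(set(leaf_labels) - set(matrix_taxa))
        only_matrix = sorted(set(matrix_taxa) - set(leaf_labels))
        raise ValueError(
            f"tree/matrix taxa mismatch: only in tree {only_tree}, "
            f"only in matrix {only_matrix}"
        )
    observed = matrix.to_numpy()
    if (observed < 0).any():
        raise ValueError("negative counts in matrix")
    cmax = params.max_count
    if cmax is None:
        cmax = max(1, int(observed.max()))
    if int(observed.max()) > cmax:
        raise ValueError(
            f"observed count {int(observed.max())} exceeds max_count {cmax}"
        )
    n_states = cmax + 1
    families = [str(c) for c in matrix.columns]
    n_fam = len(families)
    g = params.gain_penalty
    lo = params.loss_penalty

    states = np.arange(n_states)
    # cost_matrix[a, b] = cost of a parent in state a having a child in state b
    diff = states[None, :] - states[:, None]
    cost_matrix = g * np.maximum(diff, 0) + lo * np.maximum(-diff, 0)

    node_cost: Dict[str, np.ndarray] = {}
    children: Dict[str, List[str]] = {}
    ties = np.zeros(n_fam, dtype=bool)

    for node in tree.postorder_node_iter():
        label = node.label
        if node.is_leaf():
            obs = matrix.loc[label].to_numpy() if n_fam else np.zeros(0, dtype=int)
            cost = np.full((n_fam, n_states), _BIG)
            cost[np.arange(n_fam), obs.astype(int)] = 0.0
            node_cost[label] = cost
        else:
            kids = [c.label for c in node.child_nodes()]
            children[label] = kids
            total = np.zeros((n_fam, n_states))
            for kid in kids:
                # msg[f, a] = min_b cost_matrix[a, b] + node_cost[kid][f, b]
                combined = node_cost[kid][:, None, :] + cost_matrix[None, :, :]
                total += combined.min(axis=2)
            node_cost[label] = total

    root = tree.seed_node.label
    root_cost = node_cost[root]
    root_state = root_cost.argmin(axis=1)  # argmin -> smallest state on tie
    total_cost = float(root_cost[np.arange(n_fam), root_state].sum()) if n_fam else 0.0
    near = np.isclose(root_cost, root_cost.min(axis=1, keepdims=True))
    ties |= near.sum(axis=1) > 1

    assigned: Dict[str, np.ndarray] = {root: root_state}
    for node in tree.preorder_node_iter():
        label = node.label
        if node.is_leaf() or label not in children:
            continue
        parent_state = assigned[label]
        for kid in children[label]:
            combined = (
                node_cost[kid] + cost_matrix[parent_state, :]
            )  # (n_fam, n_states)
            kid_state = combined.argmin(axis=1)
            near_k = np.isclose(combined, combined.min(axis=1, keepdims=True))
            ties |= near_k.sum(axis=1) > 1
            assigned[kid] = kid_state

    node_order = [n.label for n in tree.preorder_node_iter()]
    counts = pd.DataFrame(
        {label: assigned[label] for label in node_order},
        index=families,
    ).T.astype(int)
    counts.index.name = "node"

    rows = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = assigned[node.parent_node.label]
        child = assigned[node.label]
        gains = int(np.maximum(child - parent, 0).sum())
        losses = int(np.maximum(parent - child, 0).sum())
        rows.append({"branch_child": node.label, "gains": gains, "losses": losses})
    branch_events = pd.DataFrame(rows).set_index("branch_child") if rows else (
        pd.DataFrame(columns=["gains", "losses"])
    )

    # conservation sanity: the event totals must price out to the DP optimum
    event_cost = g * branch_events["gains"].sum() + lo * branch_events["losses"].sum()
    if n_fam and not np.isclose(event_cost, total_cost):
        raise AssertionError(
            f"backtraced event cost {event_cost} != DP minimum {total_cost}"
        )

    return GainLossReconstruction(
        tree=tree,
        counts=counts,
        branch_events=branch_events,
        total_cost=total_cost,
        params=params,
        tied_families=[f for f, t in zip(families, ties) if t],
    )


def summarize_events(
    reconstruction: GainLossReconstruction,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Per-branch (gains, losses) table and per-node family-content sizes
    (number of families with count >= 1)."""
    sizes = reconstruction.node_sizes()
    sizes.name = "n_families"
    return reconstruction.branch_events.copy(), sizes


def map_family_origins(
    reconstruction: GainLossReconstruction,
    families_of_interest: Optional[Iterable[str]] = None,
) -> Dict[str, Dict[str, object]]:
    """Where each family emerged and where it was lost.

    Origins are the root-most nodes with count >= 1 whose parent (if any)
    has count 0 — the root itself if the family is ancestral. Losses are
    the branches on which the count drops to 0. Families reconstructed as
    absent everywhere are annotated 'never present'.
    """
    counts = reconstruction.counts
    fams = (
        [str(f) for f in families_of_interest]
        if families_of_interest is not None
        else list(counts.columns)
    )
    nodes = {n.label: n for n in reconstruction.tree.preorder_node_iter()}
    root = reconstruction.root_label
    out: Dict[str, Dict[str, object]] = {}
    for fam in fams:
        if fam not in counts.columns:
            raise KeyError(f"family {fam!r} not in reconstruction")
        col = counts[fam]
        origins: List[str] = []
        losses: List[str] = []
        for label, node in nodes.items():
            present = col[label] >= 1
            if label == root:
                if present:
                    origins.append(label)
                continue
            parent_present = col[node.parent_node.label] >= 1
            if present and not parent_present:
                origins.append(label)
            if parent_present and not present:
                losses.append(label)
        status = "never present" if not origins else "reconstructed"
        out[fam] = {
            "origins": sorted(origins),
            "losses": sorted(losses),
            "status": status,
            "tied": fam in reconstruction.tied_families,
        }
    return out
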