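"""Gain/loss parsimony of miRNA families on a dated species tree.

Each family's presence/absence pattern across extant species is explained
by gain and loss events on tree branches.  Two reconstruction modes:

* ``dollo`` (default): each family originates exactly once, on the branch
  above the most recent common ancestor of all species carrying it;
  absences below that node are explained by a minimal set of loss
  branches.  Single origin is the standard assumption for miRNA families,
  whose hairpins are unlikely to arise twice identically.
* ``wagner``: unweighted (gain cost = loss cost = 1) minimum-change
  reconstruction by dynamic programming (Sankoff); root-state ties resolve
  toward absence, favouring later gains.

Branch lengths are taken as given, in million years; per-branch gain rates
are gains / branch length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .io import FamilyPresenceMatrix, PhyloTree, ValidationError

ROOT_BRANCH = "ROOT"


def _node_label(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return node.label


def label_internal_nodes(tree: dendropy.Tree) -> None:
    """Give deterministic labels N1, N2, ... (preorder) to unlabeled
    internal nodes so branches can be keyed by their child node."""
    i = 0
    for node in tree.preorder_node_iter():
        if node.taxon is None and not node.label:
            i += 1
            node.label = f"N{i}"


@dataclass
class EventSummary:
    branches: pd.DataFrame
    """One row per branch keyed by child node: columns parent, child,
    length_my, gains, losses, gain_rate, is_terminal.  The root's own edge
    appears with parent = "ROOT"."""
    ancestral_counts: dict[str, int]
    """node label -> number of families reconstructed as present."""
    per_family_gain_branch: dict[str, str] = field(default_factory=dict)
    """family -> child-node key of the branch carrying its (first) gain."""
    per_family_states: dict[str, dict[str, int]] = field(default_factory=dict)
    mode: str = "dollo"
    total_gains: int = 0
    total_losses: int = 0


def _check_inputs(tree: PhyloTree, presence: FamilyPresenceMatrix) -> None:
    leaves = set(tree.leaf_names())
    species = set(presence.species)
    if leaves != species:
        raise ValidationError(
            f"tree leaves and matrix species differ: only-tree={sorted(leaves - species)}, "
            f"only-matrix={sorted(species - leaves)}"
        )
    empty = [f for f in presence.families if presence.matrix.loc[f].sum() == 0]
    if empty:
        raise ValidationError(f"families present in no species: {empty}")


def infer_events(tree: PhyloTree, presence: FamilyPresenceMatrix,
                 mode: str = "dollo") -> EventSummary:
    """Reconstruct per-branch family gains and losses by parsimony."""
    if mode not in ("dollo", "wagner"):
        raise ValueError(f"unknown mode {mode!r}")
    _check_inputs(tree, presence)
    t = tree.tree
    label_internal_nodes(t)

    states_all: dict[str, dict[str, int]] = {}
    for fam in presence.families:
        leaf_states = {sp: int(presence.matrix.loc[fam, sp]) for sp in presence.species}
        if mode == "dollo":
            states_all[fam] = _dollo_states(t, leaf_states)
        else:
            states_all[fam] = _wagner_states(t, leaf_states)
    return _summarize(t, states_all, mode)


def _dollo_states(t: dendropy.Tree, leaf_states: dict[str, int]) -> dict[str, int]:
    """Present iff the node lies in the subtree of the MRCA of presence
    leaves and its own subtree still contains a presence leaf."""
    present_leaves = {sp for sp, s in leaf_states.items() if s == 1}
    # has_present[node] = subtree contains a present leaf (postorder)
    has_present: dict[dendropy.Node, bool] = {}
    for node in t.postorder_node_iter():
        if node.is_leaf():
            has_present[node] = node.taxon.label in present_leaves
        else:
            has_present[node] = any(has_present[c] for c in node.child_nodes())
    # MRCA of present leaves: deepest node whose subtree covers them all
    covers: dict[dendropy.Node, set] = {}
    for node in t.postorder_node_iter():
        if node.is_leaf():
            covers[node] = {node.taxon.label} & present_leaves
        else:
            covers[node] = set().union(*(covers[c] for c in node.child_nodes()))
    mrca = None
    for node in t.postorder_node_iter():
        if covers[node] == present_leaves:
            mrca = node
            break
    states: dict[str, int] = {}
    inside: set[dendropy.Node] = set()
    if mrca is not None:
        stack = [mrca]
        while stack:
            n = stack.pop()
            inside.add(n)
            stack.extend(n.child_nodes())
    for node in t.preorder_node_iter():
        states[_node_label(node)] = int(node in inside and has_present[node])
    return states


def _wagner_states(t: dendropy.Tree, leaf_states: dict[str, int]) -> dict[str, int]:
    """Sankoff DP with unit gain/loss costs; ties resolve toward absence."""
    cost: dict[dendropy.Node, np.ndarray] = {}
    for node in t.postorder_node_iter():
        if node.is_leaf():
            s = leaf_states[node.taxon.label]
            cost[node] = np.array([0.0 if s == 0 else np.inf,
                                   0.0 if s == 1 else np.inf])
        else:
            c = np.zeros(2)
            for child in node.child_nodes():
                cc = cost[child]
                # transition cost = 1 for a state change on the child branch
                c += np.array([min(cc[0], cc[1] + 1), min(cc[1], cc[0] + 1)])
            cost[node] = c
    states: dict[str, int] = {}
    assign: dict[dendropy.Node, int] = {}
    root = t.seed_node
    assign[root] = 0 if cost[root][0] <= cost[root][1] else 1
    for node in t.preorder_node_iter():
        if node is not root:
            ps = assign[node.parent_node]
            c0 = cost[node][0] + (ps != 0)
            c1 = cost[node][1] + (ps != 1)
            assign[node] = 0 if c0 <= c1 else 1
        states[_node_label(node)] = assign[node]
    return states


def _summarize(t: dendropy.Tree, states_all: dict[str, dict[str, int]],
               mode: str) -> EventSummary:
    rows = []
    gain_branch: dict[str, str] = {}
    root = t.seed_node
    branch_nodes = list(t.preorder_node_iter())
    for node in branch_nodes:
        child = _node_label(node)
        parent = ROOT_BRANCH if node is root else _node_label(node.parent_node)
        length = node.edge.length if node.edge.length is not None else 0.0
        gains = losses = 0
        for fam, states in states_all.items():
            parent_state = 0 if node is root else states[parent]
            s = states[child]
            if s > parent_state:
                gains += 1
                gain_branch.setdefault(fam, child)  # first gain in preorder
            elif s < parent_state:
                losses += 1
        rate = gains / length if length > 0 else np.nan
        rows.append({
            "parent": parent, "child": child, "length_my": float(length),
            "gains": gains, "losses": losses, "gain_rate": rate,
            "is_terminal": node.is_leaf(),
        })
    branches = pd.DataFrame(rows).set_index("child", drop=False)
    ancestral = {
        _node_label(n): sum(states[_node_label(n)] for states in states_all.values())
        for n in branch_nodes
    }
    return EventSummary(
        branches=branches,
        ancestral_counts=ancestral,
        per_family_gain_branch=gain_branch,
        per_family_states=states_all,
        mode=mode,
        total_gains=int(branches["gains"].sum()),
        total_losses=int(branches["losses"].sum()),
    )


@dataclass
class GainRateSummary:
    branches: pd.DataFrame
    mean_terminal_net_gain_rate: float
    mean_interior_net_gain_rate: float
    n_zero_length_skipped: int


def gain_rates(events: EventSummary) -> GainRateSummary:
    """Per-branch gain rates (families/MY) and the terminal-vs-interior
    comparison of net gain rates ((gains - losses) / length)."""
    df = events.branches.copy()
    rated = df[df["length_my"] > 0].copy()
    skipped = len(df) - len(rated)
    rated["net_gain_rate"] = (rated["gains"] - rated["losses"]) / rated["length_my"]
    term = rated[rated["is_terminal"]]["net_gain_rate"]
    inter = rated[~rated["is_terminal"]]["net_gain_rate"]
    return GainRateSummary(
        branches=rated,
        mean_terminal_net_gain_rate=float(term.mean()) if len(term) else np.nan,
        mean_interior_net_gain_rate=float(inter.mean()) if len(inter) else np.nan,
        n_zero_length_skipped=skipped,
    )


def write_events_tsv(events: EventSummary, path) -> None:
    events.branches.to_csv(path, sep="\t", index=False)


def annotated_newick(tree: PhyloTree, events: EventSummary) -> str:
    """Newick string with +gains/-losses appended to node labels."""
    # re-parse into a fresh taxon namespace so relabelling cannot touch
    # the caller's tree
    t = dendropy.Tree.get(
        data=tree.tree.as_string(schema="newick"),
        schema="newick", preserve_underscores=True)
    label_internal_nodes(t)
    for node in t.preorder_node_iter():
        key = _node_label(node)
        if key in events.branches.index:
            row = events.branches.loc[key]
            tag = f"+{int(row['gains'])}/-{int(row['losses'])}"
            if node.taxon is not None:
                node.taxon.label = f"{node.taxon.label}_{tag}"
            else:
                node.label = f"{key}_{tag}"
    return t.as_string(schema="newick").strip()
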