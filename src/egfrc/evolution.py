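"""Parsimony reconstruction of pathway-component evolution on a species tree.

Two complementary reconstructions:

* **Dollo parsimony** for presence/absence characters: a character is gained
  exactly once (at the most recent common ancestor of all taxa possessing
  it) and may be lost any number of times; losses are placed on the root
  edges of maximal absent subtrees, which minimizes the loss count.
* **Sankoff parsimony** for copy-number characters: dynamic programming over
  states ``0..max_count`` with a linear cost ``|parent - child|`` (one
  duplication and one loss cost the same; the cost function is pluggable).
  Ties are broken toward the smaller ancestral count, a deliberately
  conservative convention.

Both handle polytomies natively. Gains, losses and copy-number expansions are
enumerated per edge and merged into a scenario report with the reconstructed
root complements.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import dendropy
import pandas as pd

from .classify import ComplementMatrix
from .records import ContractViolationError

BINARY_CHARACTERS = ("EGFR_PRESENT", "EGF_TYPE_PRESENT", "NRG_TYPE_PRESENT")
COUNT_CHARACTERS = ("EGFR_COUNT", "EGF_TYPE_COUNT", "NRG_TYPE_COUNT")


class NoGainError(ValueError):
    """Raised when a presence/absence character is absent from every taxon."""


@dataclass
class CharacterMatrix:
    """Taxa x character table; PRESENT == (COUNT >= 1) by construction."""

    df: pd.DataFrame

    @property
    def taxa(self) -> list:
        return list(self.df.index)


@dataclass
class DolloReconstruction:
    character: str
    gain_node: dendropy.Node
    loss_edges: list  # child nodes whose root edge carries a loss
    node_states: dict  # node -> 0/1

    @property
    def n_losses(self) -> int:
        return len(self.loss_edges)


@dataclass
class SankoffReconstruction:
    character: str
    node_counts: dict  # node -> int
    total_cost: float
    events: list  # (child_node, delta) with delta != 0


def matrix_from_complements(m: ComplementMatrix) -> CharacterMatrix:
    """Derive binary and count characters from a complement matrix."""
    df = m.df
    counts = pd.DataFrame(
        {
            "EGFR_COUNT": df["egfr_count"].astype(int),
            "EGF_TYPE_COUNT": df["egf_like_count"].astype(int),
            "NRG_TYPE_COUNT": df["nrg_like_count"].astype(int),
        },
        index=df.index,
    )
    if (counts < 0).any().any():
        raise ContractViolationError("complement counts must be non-negative")
    for present, count in zip(BINARY_CHARACTERS, COUNT_CHARACTERS):
        counts[present] = (counts[count] >= 1).astype(int)
    return CharacterMatrix(counts[list(BINARY_CHARACTERS) + list(COUNT_CHARACTERS)])


def node_name(node: dendropy.Node) -> str:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    if node.label:
        return node.label
    return f"node_{id(node)}"


def _tip_values(tree: dendropy.Tree, char: Mapping) -> dict:
    values = {}
    for leaf in tree.leaf_node_iter():
        label = node_name(leaf)
        if label not in char:
            raise ContractViolationError(f"tree tip {label!r} missing from character data")
        values[leaf] = int(char[label])
    return values


def dollo_reconstruct(tree: dendropy.Tree, char: Mapping, character: str = "") -> DolloReconstruction:
    """Single-gain, minimal-loss reconstruction of a binary character.

    The gain is placed at the MRCA of all present taxa (for a single present
    taxon, on that tip's edge); within the gain clade a node is present iff
    its subtree contains a present taxon, and a loss is charged to the root
    edge of every maximal absent subtree.
    """
    if isinstance(char, pd.Series):
        char = char.to_dict()
    tips = _tip_values(tree, char)
    present_leaves = [leaf for leaf, v in tips.items() if v == 1]
    if not present_leaves:
        raise NoGainError(f"character {character or '<unnamed>'} is absent from all taxa")
    if len(present_leaves) == 1:
        gain = present_leaves[0]
    else:
        gain = tree.mrca(taxa=[l.taxon for l in present_leaves])

    # bottom-up: does the subtree under each node contain a present taxon?
    has_present = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            has_present[node] = tips[node] == 1
        else:
            has_present[node] = any(has_present[c] for c in node.child_nodes())

    in_gain_clade = set(gain.preorder_iter())
    node_states = {}
    for node in tree.preorder_node_iter():
        node_states[node] = int(node in in_gain_clade and has_present[node])

    loss_edges = [
        node
        for node in tree.preorder_node_iter()
        if node is not gain
        and node.parent_node is not None
        and node_states.get(node.parent_node) == 1
        and node_states[node] == 0
    ]
    return DolloReconstruction(
        character=character, gain_node=gain, loss_edges=loss_edges, node_states=node_states
    )


def sankoff_counts(
    tree: dendropy.Tree,
    counts: Mapping,
    max_count: int | None = None,
    cost: Callable[[int, int], float] | None = None,
    character: str = "",
) -> SankoffReconstruction:
    """Minimum-cost copy-number assignment by Sankoff dynamic programming.

    ``cost(parent_state, child_state)`` defaults to ``abs(parent - child)``.
    ``max_count`` defaults to the maximum tip count. Ties are broken toward
    the smaller count at every node.
    """
    if isinstance(counts, pd.Series):
        counts = counts.to_dict()
    tips = _tip_values(tree, counts)
    if max_count is None:
        max_count = max(tips.values())
    for leaf, v in tips.items():
        if v > max_count:
            raise ContractViolationError(
                f"tip count {v} of {node_name(leaf)!r} exceeds max_count {max_count}"
            )
    if cost is None:
        cost = lambda a, b: abs(a - b)
    states = range(max_count + 1)

    table: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            table[node] = [0.0 if s == tips[node] else float("inf") for s in states]
        else:
            row = []
            for s in states:
                total = 0.0
                for child in node.child_nodes():
                    total += min(table[child][t] + cost(s, t) for t in states)
                row.append(total)
            table[node] = row

    root = tree.seed_node
    root_costs = table[root]
    best = min(root_costs)
    node_counts = {root: min(s for s in states if root_costs[s] == best)}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        p = node_counts[node.parent_node]
        child_costs = [table[node][t] + cost(p, t) for t in states]
        cbest = min(child_costs)
        node_counts[node] = min(t for t in states if child_costs[t] == cbest)

    events = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        delta = node_counts[node] - node_counts[node.parent_node]
        if delta != 0:
            events.append((node, delta))
    return SankoffReconstruction(
        character=character, node_counts=node_counts, total_cost=best, events=events
    )


def detect_expansions(recon: SankoffReconstruction):
    """Copy-number increases not explained by de novo gain.

    Returns ``(child_node, from_count, to_count)`` for every edge where the
    count rises from an already-nonzero ancestral value.
    """
    out = []
    for node, delta in recon.events:
        parent = recon.node_counts[node.parent_node]
        child = recon.node_counts[node]
        if child > parent >= 1:
            out.append((node, parent, child))
    return out


def scenario_report(tree: dendropy.Tree, matrix: CharacterMatrix):
    """Merged gain/loss/expansion table plus reconstructed root complements.

    Returns ``(events_df, root_complement)`` where ``root_complement`` maps
    the labelled root ('Metazoa') and 'Bilateria' nodes -- when present in the
    tree -- to their reconstructed copy numbers for each component class.
    """
    rows = []
    sankoffs = {}
    for present, count in zip(BINARY_CHARACTERS, COUNT_CHARACTERS):
        char_short = count.replace("_COUNT", "")
        try:
            dollo = dollo_reconstruct(tree, matrix.df[present], character=present)
        except NoGainError:
            dollo = None
        if dollo is not None:
            rows.append(
                {
                    "character": char_short,
                    "event": "gain",
                    "node": node_name(dollo.gain_node),
                    "from_count": 0,
                    "to_count": 1,
                }
            )
            for node in dollo.loss_edges:
                rows.append(
                    {
                        "character": char_short,
                        "event": "loss",
                        "node": node_name(node),
                        "from_count": 1,
                        "to_count": 0,
                    }
                )
        sank = sankoff_counts(tree, matrix.df[count], character=count)
        sankoffs[char_short] = sank
        for node, frm, to in detect_expansions(sank):
            rows.append(
                {
                    "character": char_short,
                    "event": "expansion",
                    "node": node_name(node),
                    "from_count": frm,
                    "to_count": to,
                }
            )
    events = pd.DataFrame(
        rows, columns=["character", "event", "node", "from_count", "to_count"]
    )
    events = events.sort_values(["character", "event", "node"]).reset_index(drop=True)

    labelled = {}
    for node in tree.preorder_node_iter():
        name = node_name(node)
        labelled.setdefault(name, node)
    root_complement = {}
    for name in ("Metazoa", "Bilateria"):
        target = labelled.get(name)
        if name == "Metazoa" and target is None:
            target = tree.seed_node
        if target is None:
            continue
        root_complement[name] = {
            char: sank.node_counts[target] for char, sank in sankoffs.items()
        }
    return events, root_complement
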