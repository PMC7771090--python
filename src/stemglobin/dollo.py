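"""Dollo-parsimony gain/loss reconstruction of gene clades on a species tree.

Each clade (character) is assumed to have been gained exactly once -- the
Dollo assumption, appropriate for gene families whose members are
recognisably homologous -- and lost any number of times.  The gain is placed
on the branch *above* the MRCA of all species carrying the clade; losses are
the defining edges of the maximal subtrees under that MRCA containing no
carrier.  This is the minimum-loss single-gain reconstruction, and replaying
gain-then-losses always regenerates the input presence flags (checked on
every call).

Edges are named by their child node, so a loss on the vertebrate stem is
reported as the edge above the internal node for vertebrates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import dendropy
import pandas as pd

from .species import SpeciesTree


class DolloError(ValueError):
    pass


NEVER_GAINED = "never-gained"


@dataclass
class DolloEvents:
    """Reconstruction for one clade: one gain edge and a set of loss edges."""

    clade: str
    gain_edge: Optional[str]  # child-node label; None when never gained
    loss_edges: List[str] = field(default_factory=list)

    @property
    def n_losses(self) -> int:
        return len(self.loss_edges)


def dollo_reconstruct(
    tree: SpeciesTree, presence: Dict[str, bool], clade: str = "clade"
) -> DolloEvents:
    """Minimum-loss single-gain reconstruction of one presence/absence map.

    ``presence`` maps every species of the tree to a flag.  Raises on species
    mismatches; returns the never-gained sentinel when all flags are false.
    """
    species = set(tree.species())
    unknown = set(presence) - species
    if unknown:
        raise DolloError(f"species not in tree: {sorted(unknown)}")
    missing = species - set(presence)
    if missing:
        raise DolloError(f"presence flags missing for: {sorted(missing)}")
    present = {sp for sp, flag in presence.items() if flag}
    if not present:
        return DolloEvents(clade=clade, gain_edge=None)

    mrca = _mrca(tree, present)
    events = DolloEvents(clade=clade, gain_edge=mrca.label)
    # losses: maximal subtrees under the MRCA with no present species
    stack = list(mrca.child_nodes())
    while stack:
        node = stack.pop()
        leaves = tree.leaves_under(node)
        if leaves & present:
            stack.extend(node.child_nodes())
        else:
            events.loss_edges.append(node.label)
    events.loss_edges.sort()
    _check_replay(tree, events, presence)
    return events


def _mrca(tree: SpeciesTree, present: set) -> dendropy.Node:
    if len(present) == 1:
        (only,) = present
        for leaf in tree.tree.leaf_node_iter():
            if leaf.label == only:
                return leaf
        raise DolloError(f"species {only!r} not found")
    node = tree.root
    while True:
        carriers = [
            c for c in node.child_nodes() if tree.leaves_under(c) & present
        ]
        if len(carriers) == 1 and present <= tree.leaves_under(carriers[0]):
            node = carriers[0]
        else:
            return node


def replay(tree: SpeciesTree, events: DolloEvents) -> Dict[str, bool]:
    """Apply gain then losses; return the implied presence flags."""
    if events.gain_edge is None:
        return {sp: False for sp in tree.species()}
    gained = tree.leaves_under(tree.node(events.gain_edge))
    lost = set()
    for edge in events.loss_edges:
        lost |= tree.leaves_under(tree.node(edge))
    return {sp: (sp in gained and sp not in lost) for sp in tree.species()}


def _check_replay(tree: SpeciesTree, events: DolloEvents, presence: Dict[str, bool]) -> None:
    implied = replay(tree, events)
    if implied != {sp: bool(f) for sp, f in presence.items()}:
        raise DolloError(
            f"internal error: reconstruction for {events.clade!r} does not "
            "replay to the input presence flags"
        )


def presence_history(
    tree: SpeciesTree, presence: Dict[str, bool], clade: str = "clade"
) -> DolloEvents:
    """The presence-level event history under a root origin: the clade is
    treated as present at the root and every branch where presence switches
    off (parent subtree has carriers on another path, child subtree has none)
    is a loss.  This is the truth-side counterpart of ``dollo_reconstruct``
    for simulations whose lineages all start at the species-tree root."""
    present = {sp for sp, flag in presence.items() if flag}
    if not present:
        return DolloEvents(clade=clade, gain_edge=None)
    events = DolloEvents(clade=clade, gain_edge=tree.root.label)
    stack = list(tree.root.child_nodes())
    while stack:
        node = stack.pop()
        leaves = tree.leaves_under(node)
        if leaves & present:
            stack.extend(node.child_nodes())
        else:
            events.loss_edges.append(node.label)
    events.loss_edges.sort()
    return events


def event_table(
    tree: SpeciesTree, matrix: pd.DataFrame
) -> tuple:
    """Reconstruct every clade of a presence matrix (clades x species counts).

    Returns (events_df, summary) where the summary lists species retaining
    every gained clade and species carrying none at all.
    """
    species = tree.species()
    missing = set(matrix.columns) - set(species)
    if missing:
        raise DolloError(f"matrix species absent from tree: {sorted(missing)}")
    absent_cols = set(species) - set(matrix.columns)
    if absent_cols:
        raise DolloError(f"matrix lacks species: {sorted(absent_cols)}")
    rows = []
    events: Dict[str, DolloEvents] = {}
    for clade in matrix.index:
        flags = {sp: bool(matrix.loc[clade, sp] > 0) for sp in species}
        ev = dollo_reconstruct(tree, flags, clade=str(clade))
        events[str(clade)] = ev
        rows.append(
            (
                clade,
                ev.gain_edge if ev.gain_edge is not None else NEVER_GAINED,
                ";".join(ev.loss_edges),
                ev.n_losses,
            )
        )
    df = pd.DataFrame(rows, columns=["clade", "gain_edge", "loss_edges", "n_losses"])
    gained = [c for c in matrix.index if events[str(c)].gain_edge is not None]
    full_complement = [
        sp for sp in species if all(matrix.loc[c, sp] > 0 for c in gained)
    ] if gained else []
    no_genes = [sp for sp in species if (matrix[sp] <= 0).all()]
    summary = {
        "species_with_full_complement": full_complement,
        "species_without_genes": no_genes,
        "total_gains": len(gained),
        "total_losses": int(df["n_losses"].sum()),
    }
    return df, summary
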