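"""Lineage trees and division events.

A :class:`LineageTree` is the founder-rooted binary tree of one tracked
clone: cells with birth/end times, parent links, timed division events and
terminal fate calls (progenitor P or neuron N).  Trees are produced by the
synthetic generator and by the tracking-XML importer, and consumed by the
lineage statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

PROGENITOR = "P"
NEURON = "N"
UNASSIGNED = "unassigned"

PP = "PP"
PN = "PN"
NN = "NN"
MODES = (PP, PN, NN)


@dataclass
class CellNode:
    """One tracked cell: alive from ``birth`` until ``end`` (division or end
    of observation)."""

    cell_id: str
    parent: Optional[str] = None
    birth: float = 0.0
    end: float = float("inf")
    fate: str = PROGENITOR  # fate while alive; leaves keep terminal fate
    children: tuple[str, ...] = ()


@dataclass
class DivisionEvent:
    mother: str
    daughters: tuple[str, str]
    time: float
    mode: str = UNASSIGNED  # ground-truth or inferred PP/PN/NN


@dataclass
class LineageTree:
    """Founder-rooted tree of one clone."""

    root: str
    nodes: dict[str, CellNode] = field(default_factory=dict)
    divisions: list[DivisionEvent] = field(default_factory=list)
    clone_id: str = ""
    condition: str = "control"
    meta: dict = field(default_factory=dict)

    def add_root(self, cell_id: str, birth: float) -> CellNode:
        node = CellNode(cell_id=cell_id, birth=birth)
        self.nodes[cell_id] = node
        self.root = cell_id
        return node

    def add_division(
        self, mother: str, time: float, daughter_ids: tuple[str, str],
        daughter_fates: tuple[str, str], mode: str = UNASSIGNED,
    ) -> DivisionEvent:
        mnode = self.nodes[mother]
        if mnode.children:
            raise ValueError(f"cell {mother} already divided")
        if time < mnode.birth:
            raise ValueError("division before birth")
        mnode.end = time
        mnode.children = daughter_ids
        for did, f in zip(daughter_ids, daughter_fates):
            self.nodes[did] = CellNode(cell_id=did, parent=mother, birth=time, fate=f)
        event = DivisionEvent(mother=mother, daughters=daughter_ids, time=time, mode=mode)
        self.divisions.append(event)
        return event

    def cells_alive_at(self, t: float) -> list[CellNode]:
        return [n for n in self.nodes.values() if n.birth <= t < n.end]

    def leaves(self) -> list[CellNode]:
        return [n for n in self.nodes.values() if not n.children]

    def divisions_in(self, t0: float, tf: float) -> list[DivisionEvent]:
        return [d for d in self.divisions if t0 <= d.time <= tf]

    def n_cells_at(self, t: float) -> int:
        return len(self.cells_alive_at(t))

    def iter_nodes(self) -> Iterator[CellNode]:
        return iter(self.nodes.values())

    def validate(self) -> None:
        """Structural invariants: one root, binary divisions, acyclic,
        non-decreasing division times along every root-to-leaf path."""
        seen = set()
        stack = [(self.root, self.nodes[self.root].birth)]
        while stack:
            cid, t = stack.pop()
            if cid in seen:
                raise ValueError(f"cycle through {cid}")
            seen.add(cid)
            node = self.nodes[cid]
            if node.children and len(node.children) != 2:
                raise ValueError(f"non-binary division at {cid}")
            if node.birth < t - 1e-9:
                raise ValueError(f"time decreases at {cid}")
            for child in node.children:
                stack.append((child, node.end))
        if seen != set(self.nodes):
            raise ValueError("unreachable cells in tree")
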