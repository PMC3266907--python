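"""Rooted ultrametric trees and their branching-event schedule.

The species-delimitation model operates on a rooted, ultrametric gene tree
(all tips equidistant from the root, branch lengths in substitutions/site).
This module parses and validates such trees from newick, resolves polytomies
into zero-length binary splits, and derives the schedule of branching events
(event depths, inter-event intervals, lineage counts) that the likelihood
machinery consumes.

Depths are measured back from the tips: a tip has depth 0 and the root has
the largest depth. This matches the convention in which the delimitation
threshold is reported as a genetic distance from the branch tips.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO
import dendropy
import numpy as np

__all__ = [
    "UltrametricTree",
    "BranchingSchedule",
    "TreeError",
    "UltrametricityError",
    "parse_newick",
    "write_newick",
    "branching_schedule",
]

#: relative tolerance (fraction of tree depth) for root-to-tip equality
DEFAULT_ULTRA_TOL = 1e-6

#: depths closer than this (absolute, substitutions/site) are one event
EVENT_MERGE_TOL = 1e-10


class TreeError(ValueError):
    """Malformed or invalid tree input."""


class UltrametricityError(TreeError):
    """Root-to-tip path lengths differ beyond tolerance."""


@dataclass
class UltrametricTree:
    """Rooted binary ultrametric tree stored as flat parallel arrays.

    Attributes
    ----------
    parent : int array, parent index per node (-1 for the root)
    children : list of child-index lists (empty for tips)
    length : float array, branch length to parent (0.0 for the root)
    label : tip label or ``None`` for internal nodes
    depth : float array, distance from the node down to any descendant tip
    root : index of the root node
    tips : indices of tip nodes, in input (newick) order
    """

    parent: np.ndarray
    children: list
    length: np.ndarray
    label: list
    depth: np.ndarray
    root: int
    tips: list

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root_depth(self) -> float:
        return float(self.depth[self.root])

    @property
    def tip_labels(self) -> list:
        return [self.label[i] for i in self.tips]

    def internal_nodes(self) -> list:
        return [i for i in range(self.n_nodes) if self.children[i]]

    def preorder(self) -> list:
        """Node indices root-first; children visited in stored order."""
        order, stack = [], [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(reversed(self.children[v]))
        return order

    def subtree_tips(self, node: int) -> list:
        """Tip indices below ``node`` (inclusive if node is a tip)."""
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if not self.children[v]:
                out.append(v)
            else:
                stack.extend(reversed(self.children[v]))
        return out

    def validate(self, ultra_tol: float = DEFAULT_ULTRA_TOL) -> None:
        if np.any(self.length[np.arange(self.n_nodes) != self.root] < 0):
            raise TreeError("negative branch length")
        # reachability: preorder must visit every node exactly once
        order = self.preorder()
        if sorted(order) != list(range(self.n_nodes)):
            raise TreeError("tree is not a single rooted component")
        rootdist = self._root_distances()
        tipdist = rootdist[self.tips]
        depth0 = float(np.mean(tipdist))
        if depth0 > 0 and np.max(np.abs(tipdist - depth0)) > ultra_tol * depth0:
            raise UltrametricityError(
                "root-to-tip path lengths differ by "
                f"{np.max(np.abs(tipdist - depth0)):.3g} "
                f"(tolerance {ultra_tol * depth0:.3g})"
            )

    def _root_distances(self) -> np.ndarray:
        dist = np.zeros(self.n_nodes)
        for v in self.preorder():
            if v != self.root:
                dist[v] = dist[self.parent[v]] + self.length[v]
        return dist


@dataclass
class BranchingSchedule:
    """Event depths and inter-event intervals of an ultrametric tree.

    ``event_depths`` are the distinct internal-node depths, root first
    (descending).  Interval ``i`` runs from ``event_depths[i]`` down to the
    next event (or to the tips), carries ``counts[i]`` lineages, lasts
    ``durations[i]``, and ``ends_in_event[i]`` says whether a branching event
    terminates it at its shallow end.  The root event opens the process and
    the shallowest interval ends at the present without an event.
    """

    event_depths: np.ndarray  # distinct depths, descending; root first
    multiplicity: np.ndarray  # lineages added at each event (>=1)
    durations: np.ndarray
    counts: np.ndarray  # lineages during each interval
    ends_in_event: np.ndarray  # bool per interval

    @property
    def n_events(self) -> int:
        return len(self.event_depths)

    @property
    def root_depth(self) -> float:
        return float(self.event_depths[0])


def _resolve_polytomies(tree: dendropy.Tree) -> None:
    """Binarize in place: ladderize extra children onto zero-length nodes.

    Children are taken in input order; the first two are joined first, then
    each remaining child is attached one level up, all on zero-length
    branches, so depths are unchanged.
    """
    for nd in list(tree.preorder_node_iter()):
        while len(nd._child_nodes) > 2:
            kids = list(nd._child_nodes)
            a, b = kids[0], kids[1]
            joint = dendropy.Node()
            joint.edge.length = 0.0
            nd.remove_child(a)
            nd.remove_child(b)
            joint.add_child(a)
            joint.add_child(b)
            nd._child_nodes.insert(0, joint)
            joint._parent_node = nd
            joint.edge.head_node = joint
            joint.edge.tail_node = nd


def parse_newick(
    text: str,
    ultra_tol: float = DEFAULT_ULTRA_TOL,
    force_ultrametric: bool = False,
) -> UltrametricTree:
    """Parse a rooted newick string into a validated :class:`UltrametricTree`.

    Branch lengths are required on all non-root edges.  Input whose
    root-to-tip distances differ by more than ``ultra_tol`` (relative to tree
    depth) is rejected unless ``force_ultrametric`` is set, in which case
    node depths are taken as (mean root-to-tip distance) − (root distance)
    and tips are pinned to depth 0.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"newick parse error: {exc}") from exc
    if dtree.seed_node is None or not dtree.seed_node._child_nodes:
        raise TreeError("tree has no branching structure")
    _resolve_polytomies(dtree)

    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    n = len(nodes)
    parent = np.full(n, -1, dtype=int)
    length = np.zeros(n)
    children: list = [[] for _ in range(n)]
    label: list = [None] * n
    tips = []
    for i, nd in enumerate(nodes):
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            if nd.edge.length is None:
                raise TreeError("branch length missing on a non-root edge")
            length[i] = float(nd.edge.length)
        children[i] = [index[id(c)] for c in nd._child_nodes]
        if not nd._child_nodes:
            tips.append(i)
            label[i] = nd.taxon.label if nd.taxon is not None else None

    tree = UltrametricTree(
        parent=parent,
        children=children,
        length=length,
        label=label,
        depth=np.zeros(n),
        root=0,
        tips=tips,
    )
    if np.any(length[1:] < 0):
        raise TreeError("negative branch length")
    rootdist = tree._root_distances()
    depth0 = float(np.mean(rootdist[tips]))
    if not force_ultrametric:
        tree.depth = depth0 - rootdist
        tree.depth[tips] = 0.0
        tree.validate(ultra_tol=ultra_tol)
    else:
        tree.depth = depth0 - rootdist
        tree.depth[tips] = 0.0
        tree.depth = np.maximum(tree.depth, 0.0)
    return tree


def write_newick(tree: UltrametricTree, precision: int = 12) -> str:
    """Serialize back to newick; round-trips topology, labels and depths."""

    def fmt(x: float) -> str:
        return f"{x:.{precision}g}"

    def quote(lab: str) -> str:
        if lab and all(c not in lab for c in " ()[]:;,'\t\n"):
            return lab
        return "'" + (lab or "").replace("'", "''") + "'"

    out = StringIO()

    def rec(v: int) -> None:
        if tree.children[v]:
            out.write("(")
            for j, c in enumerate(tree.children[v]):
                if j:
                    out.write(",")
                rec(c)
            out.write(")")
        else:
            out.write(quote(tree.label[v] or ""))
        if v != tree.root:
            out.write(":" + fmt(float(tree.length[v])))

    rec(tree.root)
    out.write(";")
    return out.getvalue()


def branching_schedule(
    tree: UltrametricTree, merge_tol: float = EVENT_MERGE_TOL
) -> BranchingSchedule:
    """Derive the event/interval schedule from a validated tree.

    Events are the distinct internal-node depths in descending order;
    near-simultaneous events (depth difference < ``merge_tol``) are merged
    into one multi-lineage increment and the zero-length interval between
    them is skipped.
    """
    if tree.n_tips < 2:
        raise TreeError("schedule requires at least 2 tips")
    internal = tree.internal_nodes()
    depths = np.sort(tree.depth[internal])[::-1]
    # merge near-simultaneous events
    event_depths, multiplicity = [], []
    for d in depths:
        if event_depths and event_depths[-1] - d < merge_tol:
            multiplicity[-1] += 1
        else:
            event_depths.append(float(d))
            multiplicity.append(1)
    event_depths = np.asarray(event_depths)
    multiplicity = np.asarray(multiplicity)

    counts = 1 + np.cumsum(multiplicity)  # lineages after each event
    lower = np.concatenate([event_depths[1:], [0.0]])
    durations = event_depths - lower
    ends_in_event = np.concatenate(
        [np.ones(len(event_depths) - 1, dtype=bool), [False]]
    )
    sched = BranchingSchedule(
        event_depths=event_depths,
        multiplicity=multiplicity,
        durations=durations,
        counts=counts,
        ends_in_event=ends_in_event,
    )
    total = float(np.sum(durations))
    if abs(total - tree.root_depth) > DEFAULT_ULTRA_TOL * max(tree.root_depth, 1e-300):
        raise TreeError("interval durations do not sum to root depth")
    return sched
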