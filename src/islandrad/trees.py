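"""Time-calibrated trees, regime paintings, trait tables, and clade partitions.

The tree model is deliberately minimal: rooted, strictly bifurcating,
ultrametric trees with branch lengths in Myr, the substrate every likelihood
in this package assumes.  Node ages are measured backward from the present
(tips at age 0), so Newick branch lengths are durations.

Plain Newick (and the trees block of NEXUS files) is read and written through
dendropy; the simmap-annotated Newick dialect used for stochastic character
maps (``taxon:{state,duration:state,duration}``, segments ordered
rootward-to-tipward) has no Python reader, so it is parsed here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "TreeError",
    "NewickParseError",
    "UltrametricityError",
    "Node",
    "TimeTree",
    "RegimePaintedTree",
    "TraitTable",
    "CladePartition",
    "parse_newick",
    "write_newick",
    "parse_simmap_newick",
    "write_simmap_newick",
    "cophenetic_matrix",
    "prune_tips",
    "clade_tips",
]

#: relative (to tree height) tolerance for declaring a tree ultrametric
ULTRAMETRIC_RTOL = 1e-6


class TreeError(ValueError):
    """Invalid tree structure or incompatible inputs."""


class NewickParseError(TreeError):
    """Malformed Newick text; carries an approximate character offset."""

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (near character {offset})"
        super().__init__(message)


class UltrametricityError(TreeError):
    """Tip ages deviate from 0 beyond tolerance; names the worst tip."""


class Node:
    """A tree node.  ``length`` is the branch to the parent (None at root)."""

    __slots__ = ("label", "length", "children", "parent", "depth", "index", "segments")

    def __init__(self, label=None, length=None):
        self.label = label
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.depth = 0.0  # time from root (forward)
        self.index = -1  # postorder index, assigned by TimeTree
        self.segments = None  # regime painting of the parent branch, or None

    def add_child(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class TimeTree:
    """Rooted, bifurcating, ultrametric tree with branch lengths in Myr.

    Node indices are postorder (tips first within each subtree); ``tip_labels``
    lists tips in postorder, and all matrices returned by this module follow
    that order.
    """

    def __init__(self, root: Node, validate: bool = True):
        self.root = root
        self._index()
        if validate:
            self.validate()

    # -- structure bookkeeping -------------------------------------------------

    def _index(self) -> None:
        self.postorder: list[Node] = []
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                self.postorder.append(node)
                continue
            stack.append((node, True))
            for child in reversed(node.children):
                stack.append((child, False))
        for i, node in enumerate(self.postorder):
            node.index = i
        self.root.depth = 0.0
        for node in self.preorder:
            for child in node.children:
                child.depth = node.depth + (child.length or 0.0)
        self.tips: list[Node] = [n for n in self.postorder if n.is_leaf]
        self.tip_labels: list[str] = [t.label for t in self.tips]
        self.height: float = max((t.depth for t in self.tips), default=0.0)

    @property
    def preorder(self) -> list[Node]:
        return list(reversed(self.postorder))

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def age(self, node: Node) -> float:
        """Node age in Myr before present (tips ~ 0)."""
        return self.height - node.depth

    def node_ages(self) -> dict[Node, float]:
        return {n: self.age(n) for n in self.postorder}

    def internal_node_ages(self) -> np.ndarray:
        """Ages of internal nodes, root (crown) first, rest descending."""
        ages = sorted((self.age(n) for n in self.postorder if not n.is_leaf), reverse=True)
        return np.asarray(ages)

    def crown_age(self) -> float:
        return self.height

    # -- validation ------------------------------------------------------------

    def validate(self) -> None:
        labels = self.tip_labels
        if len(labels) < 2:
            raise TreeError("tree must have at least 2 tips")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate tip labels: {dupes}")
        if any(l is None for l in labels):
            raise TreeError("all tips must be labelled")
        for node in self.postorder:
            if node is not self.root:
                if node.length is None or not (node.length > 0.0):
                    raise TreeError(
                        f"non-positive or missing branch length above "
                        f"{node.label or 'internal node'!r}"
                    )
            if node.children and len(node.children) != 2:
                raise TreeError(
                    f"polytomy or unifurcation at node with {len(node.children)} "
                    "children; strictly bifurcating trees required"
                )
        # reference depth is the median so the deviant tip, not the
        # majority, is the one named in the error
        ref = float(np.median([t.depth for t in self.tips]))
        tol = ULTRAMETRIC_RTOL * max(ref, self.height, 1e-300)
        worst = max(self.tips, key=lambda t: abs(t.depth - ref))
        if abs(worst.depth - ref) > tol:
            raise UltrametricityError(
                f"tree is not ultrametric: tip {worst.label!r} sits at age "
                f"{ref - worst.depth:.6g} Myr (tolerance {tol:.3g})"
            )
        n_internal = sum(1 for n in self.postorder if n.children)
        if n_internal != self.n_tips - 1:
            raise TreeError("bifurcating tree must have n-1 internal nodes")

    # -- queries ---------------------------------------------------------------

    def tip(self, label: str) -> Node:
        for t in self.tips:
            if t.label == label:
                return t
        raise TreeError(f"tip {label!r} not in tree")

    def mrca(self, labels) -> Node:
        target = set(labels)
        missing = target - set(self.tip_labels)
        if missing:
            raise TreeError(f"tips not in tree: {sorted(missing)}")
        # smallest postorder node whose tip set covers the target
        tipsets: dict[Node, set] = {}
        for node in self.postorder:
            if node.is_leaf:
                tipsets[node] = {node.label}
            else:
                tipsets[node] = set().union(*(tipsets[c] for c in node.children))
            if target <= tipsets[node]:
                return node
        return self.root

    def subtree_tip_labels(self, node: Node) -> list[str]:
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n.label)
            else:
                stack.extend(n.children)
        return sorted(out)

    def copy(self) -> "TimeTree":
        def dup(node: Node) -> Node:
            out = Node(node.label, node.length)
            out.segments = list(node.segments) if node.segments else None
            for c in node.children:
                out.add_child(dup(c))
            return out

        return TimeTree(dup(self.root), validate=False)

    def __repr__(self) -> str:
        return f"<TimeTree {self.n_tips} tips, height {self.height:.4g} Myr>"


# -- plain Newick I/O ------------------------------------------------------------


def _from_dendropy(dtree: dendropy.Tree) -> Node:
    def build(dnode) -> Node:
        node = Node(
            label=(dnode.taxon.label if dnode.taxon is not None else dnode.label),
            length=dnode.edge.length,
        )
        for dchild in dnode.child_nodes():
            node.add_child(build(dchild))
        return node

    return build(dtree.seed_node)


def parse_newick(text: str, schema: str = "newick") -> TimeTree:
    """Parse a rooted Newick (or NEXUS trees block) string into a TimeTree."""
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema=schema,
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        offset = getattr(exc, "column", None)
        raise NewickParseError(f"could not parse {schema}: {exc}", offset) from exc
    return TimeTree(_from_dendropy(dtree))


def write_newick(tree: TimeTree, precision: int = 12) -> str:
    parts = []

    def emit(node: Node) -> str:
        if node.is_leaf:
            core = node.label
        else:
            core = "(" + ",".join(emit(c) for c in node.children) + ")"
        if node.parent is not None:
            core += f":{node.length:.{precision}g}"
        return core

    parts.append(emit(tree.root))
    return "".join(parts) + ";"


# -- simmap-annotated Newick -----------------------------------------------------

_SIMMAP_RE = re.compile(r"\{([^{}]*)\}")


@dataclass
class RegimePaintedTree:
    """A TimeTree whose branches carry ordered (state, duration) segments.

    Segments run rootward-to-tipward along each branch; adjacent segments in
    the same state are merged on construction, so paintings have a canonical
    form.  ``node_state`` of a node is the state of the last (tipward) segment
    of its parent branch; the root carries an explicit ``root_state``.
    """

    tree: TimeTree
    root_state: str

    def __post_init__(self):
        self._canonicalize()
        self.validate()

    def _canonicalize(self) -> None:
        for node in self.tree.postorder:
            if node is self.tree.root:
                continue
            merged: list[tuple[str, float]] = []
            for state, dur in node.segments:
                if merged and merged[-1][0] == state:
                    merged[-1] = (state, merged[-1][1] + dur)
                else:
                    merged.append((str(state), float(dur)))
            node.segments = merged

    def validate(self) -> None:
        for node in self.tree.postorder:
            if node is self.tree.root:
                continue
            if not node.segments:
                raise TreeError(f"branch above {node.label!r} has no painting")
            total = sum(d for _, d in node.segments)
            if abs(total - node.length) > 1e-6 * max(self.tree.height, 1.0):
                raise TreeError(
                    f"segment durations ({total:.6g}) do not sum to branch length "
                    f"({node.length:.6g}) above {node.label or 'internal node'!r}"
                )
            if any(d <= 0 for _, d in node.segments):
                raise TreeError("segment durations must be positive")
            # rescale tiny float drift so invariants hold exactly downstream
            scale = node.length / total
            node.segments = [(s, d * scale) for s, d in node.segments]

    def node_state(self, node: Node) -> str:
        if node is self.tree.root:
            return self.root_state
        return node.segments[-1][0]

    def states(self) -> list[str]:
        seen = {self.root_state}
        for node in self.tree.postorder:
            if node.segments:
                seen.update(s for s, _ in node.segments)
        return sorted(seen)

    def state_times(self) -> dict[str, float]:
        """Total branch time spent in each state, summed over the tree."""
        out: dict[str, float] = {}
        for node in self.tree.postorder:
            if node is self.tree.root:
                continue
            for state, dur in node.segments:
                out[state] = out.get(state, 0.0) + dur
        return out

    def n_changes(self) -> dict[tuple[str, str], int]:
        """Counts of state changes by (from, to) direction over all branches."""
        counts: dict[tuple[str, str], int] = {}
        for node in self.tree.postorder:
            if node is self.tree.root:
                continue
            prev = self.node_state(node.parent)
            for state, _ in node.segments:
                if state != prev:
                    counts[(prev, state)] = counts.get((prev, state), 0) + 1
                prev = state
        return counts

    def strip(self) -> TimeTree:
        """The underlying TimeTree, painting removed (fresh copy)."""
        return self.tree.copy()

    def copy(self) -> "RegimePaintedTree":
        return parse_simmap_newick(write_simmap_newick(self))


def parse_simmap_newick(text: str, states: list[str] | None = None) -> RegimePaintedTree:
    """Parse simmap-annotated Newick: branch lengths replaced by
    ``{state,dur:state,dur:...}`` listing segments rootward-to-tipward."""
    segment_lists: list[list[tuple[str, float]]] = []

    def swap(match: re.Match) -> str:
        body = match.group(1)
        segs = []
        for chunk in body.split(":"):
            try:
                state, dur = chunk.split(",")
                segs.append((state.strip(), float(dur)))
            except ValueError as exc:
                raise NewickParseError(
                    f"bad simmap segment {chunk!r}", match.start()
                ) from exc
        segment_lists.append(segs)
        total = sum(d for _, d in segs)
        return f"{total:.12g}"

    plain = _SIMMAP_RE.sub(swap, text)
    if not segment_lists:
        raise NewickParseError("no simmap annotations found in input")
    tree = TimeTree(_from_dendropy(
        dendropy.Tree.get(data=plain, schema="newick",
                          suppress_internal_node_taxa=True,
                          preserve_underscores=True)))
    # annotation k in string order belongs to the k-th non-root node in
    # postorder with left-to-right children (the order ':' tokens appear)
    nonroot = [n for n in tree.postorder if n is not tree.root]
    if len(segment_lists) != len(nonroot):
        raise TreeError(
            f"found {len(segment_lists)} simmap annotations for "
            f"{len(nonroot)} branches; every branch must be annotated"
        )
    for node, segs in zip(nonroot, segment_lists):
        node.segments = list(segs)
    if states is not None:
        declared = set(states)
        seen = {s for segs in segment_lists for s, _ in segs}
        unknown = seen - declared
        if unknown:
            raise TreeError(
                f"unknown state symbol(s) {sorted(unknown)}; declared states: "
                f"{sorted(declared)}"
            )
    root_state = tree.root.children[0].segments[0][0]
    return RegimePaintedTree(tree, root_state=root_state)


def write_simmap_newick(painted: RegimePaintedTree, precision: int = 12) -> str:
    def emit(node: Node) -> str:
        if node.is_leaf:
            core = node.label
        else:
            core = "(" + ",".join(emit(c) for c in node.children) + ")"
        if node.parent is not None:
            body = ":".join(f"{s},{d:.{precision}g}" for s, d in node.segments)
            core += ":{" + body + "}"
        return core

    return emit(painted.tree.root) + ";"


# -- distances and clade utilities -----------------------------------------------


def cophenetic_matrix(tree: TimeTree) -> pd.DataFrame:
    """Patristic (path-length) distances between all tips, in Myr.

    On an ultrametric tree this equals twice the age of the MRCA of each pair;
    the implementation sums exact path lengths so it also matches a
    path-walking computation to machine precision.
    """
    n = tree.n_tips
    labels = tree.tip_labels
    pos = {t: i for i, t in enumerate(labels)}
    D = np.zeros((n, n))
    tipsets: dict[Node, list[tuple[int, float]]] = {}
    for node in tree.postorder:
        if node.is_leaf:
            tipsets[node] = [(pos[node.label], node.depth)]
            continue
        groups = [tipsets.pop(c) for c in node.children]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                for i, di in groups[a]:
                    for j, dj in groups[b]:
                        d = (di - node.depth) + (dj - node.depth)
                        D[i, j] = D[j, i] = d
        tipsets[node] = [x for g in groups for x in g]
    return pd.DataFrame(D, index=labels, columns=labels)


def clade_tips(tree: TimeTree, mrca_of: tuple[str, str]) -> set[str]:
    """All tips descending from the MRCA of two tip labels (monophyletic by
    construction)."""
    node = tree.mrca(list(mrca_of))
    return set(tree.subtree_tip_labels(node))


def _prune_node_copy(node: Node, keep: set[str]) -> Node | None:
    """Deep-copy subtree keeping only `keep` tips; returns None if empty.
    Degree-2 nodes are suppressed, concatenating lengths and paintings."""
    if node.is_leaf:
        if node.label not in keep:
            return None
        out = Node(node.label, node.length)
        out.segments = list(node.segments) if node.segments else None
        return out
    kids = [c for c in (_prune_node_copy(c, keep) for c in node.children) if c is not None]
    if not kids:
        return None
    if len(kids) == 1:
        child = kids[0]
        if node.length is not None:
            child.length = (child.length or 0.0) + node.length
            if node.segments is not None:
                # parent branch is rootward of the child's branch
                child.segments = list(node.segments) + (child.segments or [])
        return child
    out = Node(node.label, node.length)
    out.segments = list(node.segments) if node.segments else None
    for k in kids:
        out.add_child(k)
    return out


def prune_tips(tree_or_painted, keep) -> "TimeTree | RegimePaintedTree":
    """Restrict to `keep` tips, suppressing degree-2 nodes.

    Pairwise distances among kept tips are unchanged; on painted trees the
    paintings of merged branches are concatenated, preserving per-state
    occupancy times along retained root-to-tip paths.
    """
    painted = isinstance(tree_or_painted, RegimePaintedTree)
    tree = tree_or_painted.tree if painted else tree_or_painted
    keep = set(keep)
    missing = keep - set(tree.tip_labels)
    if missing:
        raise TreeError(f"tips not in tree: {sorted(missing)}")
    if len(keep) < 2:
        raise TreeError("must keep at least 2 tips")
    root = _prune_node_copy(tree.root, keep)
    # pruning can leave a chain above the new root: drop its pendant length
    root.length = None
    if painted:
        root_state = tree_or_painted.root_state
        rootward = root.segments  # painting of collapsed branches above new root
        if rootward:
            root_state = rootward[-1][0]
        root.segments = None
        return RegimePaintedTree(TimeTree(root), root_state=root_state)
    root.segments = None
    return TimeTree(root)


# -- trait table -----------------------------------------------------------------

TRAIT_COLUMNS = ["taxon", "height_loge_cm", "life_history", "occupancy", "clade"]


@dataclass
class TraitTable:
    """Per-tip trait records.

    Columns: ``taxon``; ``height_loge_cm`` — mean plant height, log_e(cm);
    ``life_history`` — herbaceous/annual vs woody/perennial; ``occupancy`` —
    island vs nonisland; ``clade`` — partition label.  Missing values are
    empty strings / NaN.
    """

    data: pd.DataFrame
    life_history_states: tuple[str, str] = ("herbaceous", "woody")
    occupancy_states: tuple[str, str] = ("nonisland", "island")

    def __post_init__(self):
        missing = [c for c in TRAIT_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"trait table missing columns: {missing}")
        self.data = self.data[TRAIT_COLUMNS].copy()
        if self.data["taxon"].duplicated().any():
            raise ValueError("duplicate taxa in trait table")
        heights = self.data["height_loge_cm"].dropna()
        if not np.isfinite(heights.to_numpy(dtype=float)).all():
            raise ValueError("non-finite heights in trait table")
        for col, allowed in (
            ("life_history", self.life_history_states),
            ("occupancy", self.occupancy_states),
        ):
            vals = set(self.data[col].dropna()) - {""}
            bad = vals - set(allowed)
            if bad:
                raise ValueError(f"{col} has states {sorted(bad)}; allowed {allowed}")

    def validate_against(self, tree: TimeTree) -> None:
        table_taxa = set(self.data["taxon"])
        tree_taxa = set(tree.tip_labels)
        if table_taxa != tree_taxa:
            raise ValueError(
                f"trait table/tree mismatch: {sorted(tree_taxa - table_taxa)[:5]} "
                f"missing from table, {sorted(table_taxa - tree_taxa)[:5]} extra"
            )

    def heights(self, tree: TimeTree) -> np.ndarray:
        """Heights ordered to match ``tree.tip_labels``."""
        self.validate_against(tree)
        ser = self.data.set_index("taxon")["height_loge_cm"]
        return ser.loc[tree.tip_labels].to_numpy(dtype=float)

    def states(self, column: str, tree: TimeTree) -> dict[str, str | None]:
        self.validate_against(tree)
        ser = self.data.set_index("taxon")[column]
        out = {}
        for t in tree.tip_labels:
            v = ser.loc[t]
            out[t] = None if (pd.isna(v) or v == "") else str(v)
        return out

    def to_csv(self, path_or_buf, sep: str = ",") -> None:
        self.data.to_csv(path_or_buf, sep=sep, index=False)

    @classmethod
    def from_csv(cls, path_or_buf, sep: str | None = None, **kw) -> "TraitTable":
        if sep is None:
            if isinstance(path_or_buf, str) and path_or_buf.endswith((".tsv", ".txt")):
                sep = "\t"
            else:
                sep = ","
        return cls(pd.read_csv(path_or_buf, sep=sep, **kw))


# -- clade partition -------------------------------------------------------------

BACKGROUND = "background"


@dataclass
class CladePartition:
    """Named, disjoint tip sets covering the tree, with sampling fractions.

    Every named set except the complement set ``background`` must be
    monophyletic on the tree it is validated against.  ``rho`` maps each set
    to the fraction of the clade's true species richness sampled in the tree.
    """

    sets: dict[str, set]
    rho: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.sets = {k: set(v) for k, v in self.sets.items()}
        for name in self.sets:
            self.rho.setdefault(name, 1.0)
        for name, r in self.rho.items():
            if not (0.0 < r <= 1.0):
                raise ValueError(f"sampling fraction for {name!r} must be in (0,1], got {r}")
        all_tips = [t for s in self.sets.values() for t in s]
        if len(all_tips) != len(set(all_tips)):
            raise ValueError("partition sets are not disjoint")

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def focal_clades(self) -> list[str]:
        return [n for n in self.sets if n != BACKGROUND]

    def set_of(self, tip: str) -> str:
        for name, s in self.sets.items():
            if tip in s:
                return name
        raise KeyError(tip)

    def validate_against(self, tree: TimeTree) -> None:
        union = set().union(*self.sets.values())
        tree_tips = set(tree.tip_labels)
        if union != tree_tips:
            raise TreeError(
                f"partition does not cover the tree: missing "
                f"{sorted(tree_tips - union)[:5]}, extra {sorted(union - tree_tips)[:5]}"
            )
        for name in self.focal_clades():
            members = self.sets[name]
            if len(members) < 2:
                continue
            mrca = tree.mrca(members)
            if set(tree.subtree_tip_labels(mrca)) != members:
                raise TreeError(f"clade {name!r} is not monophyletic on the tree")
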