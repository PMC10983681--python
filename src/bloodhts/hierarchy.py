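"""Strict balanced hierarchies of monthly count series.

A hierarchy is a tree of node labels: one root (the grand total), interior
nodes (here, donor gender) and bottom nodes (gender x ABO blood group).
Every upper series is, by definition, the sum of its bottom-level
descendants; the 0/1 *summing matrix* S encodes that map, so that the full
node vector is recovered from the bottom block as ``y = S @ y_bottom``.

Only strict, balanced trees are supported: every non-root node has exactly
one parent and every bottom node sits at the same depth. Grouped or crossed
structures are rejected.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import MalformedHierarchyError, UnbalancedTreeError, LabelError

__all__ = [
    "HierarchySpec",
    "SummingMatrix",
    "HierarchicalSeries",
    "CoherenceReport",
    "build_summing_matrix",
    "aggregate",
    "check_coherence",
    "gender_abo_hierarchy",
]


@dataclass(frozen=True)
class HierarchySpec:
    """Node tree declaration.

    Nodes are ordered root first, then level by level, left to right within
    a level — the column/row order used by every matrix and CSV the package
    produces.
    """

    nodes: tuple[str, ...]
    parent_of: Mapping[str, str]  # child -> parent; root absent
    level_of: Mapping[str, int]  # root = 0

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise MalformedHierarchyError("duplicate node labels")
        roots = [n for n in self.nodes if n not in self.parent_of]
        if len(roots) != 1:
            raise MalformedHierarchyError(
                f"expected exactly one root, found {len(roots)}: {roots}"
            )
        for child, parent in self.parent_of.items():
            if child not in self.nodes or parent not in self.nodes:
                raise MalformedHierarchyError(
                    f"edge {parent!r} -> {child!r} references unknown node"
                )
        # walk each node to the root; a cycle or detached component shows up
        # as a walk longer than the node count
        root = roots[0]
        for node in self.nodes:
            seen, cur = 0, node
            while cur != root:
                cur = self.parent_of.get(cur)
                seen += 1
                if cur is None or seen > len(self.nodes):
                    raise MalformedHierarchyError(f"node {node!r} not connected to root")
        depths = {n: self._depth(n, root) for n in self.nodes}
        if dict(self.level_of) != depths:
            raise MalformedHierarchyError("level_of inconsistent with parent_of")
        leaf_levels = {depths[n] for n in self.bottom_nodes}
        if len(leaf_levels) != 1:
            raise UnbalancedTreeError(
                f"bottom nodes sit at several levels: {sorted(leaf_levels)}"
            )

    def _depth(self, node: str, root: str) -> int:
        d, cur = 0, node
        while cur != root:
            cur = self.parent_of[cur]
            d += 1
        return d

    @classmethod
    def from_children(cls, children: Mapping[str, Sequence[str]]) -> "HierarchySpec":
        """Build a spec from a parent -> children mapping.

        Node order is breadth-first: root, then each level left to right in
        declaration order.
        """
        all_children = [c for kids in children.values() for c in kids]
        if len(set(all_children)) != len(all_children):
            raise MalformedHierarchyError("a node is declared under several parents")
        roots = [p for p in children if p not in set(all_children)]
        if len(roots) != 1:
            raise MalformedHierarchyError(
                f"expected exactly one root, found {len(roots)}: {roots}"
            )
        parent_of: dict[str, str] = {}
        level_of: dict[str, int] = {roots[0]: 0}
        order: list[str] = [roots[0]]
        frontier = [roots[0]]
        while frontier:
            nxt: list[str] = []
            for parent in frontier:
                for child in children.get(parent, ()):  # leaves have no entry
                    if child in parent_of or child == roots[0]:
                        raise MalformedHierarchyError(f"node {child!r} revisited (cycle?)")
                    parent_of[child] = parent
                    level_of[child] = level_of[parent] + 1
                    order.append(child)
                    nxt.append(child)
            frontier = nxt
        return cls(tuple(order), parent_of, level_of)

    @property
    def root(self) -> str:
        return self.nodes[0]

    @property
    def n_levels(self) -> int:
        return max(self.level_of.values()) + 1

    @property
    def bottom_nodes(self) -> tuple[str, ...]:
        parents = set(self.parent_of.values())
        return tuple(n for n in self.nodes if n not in parents)

    @property
    def upper_nodes(self) -> tuple[str, ...]:
        bottom = set(self.bottom_nodes)
        return tuple(n for n in self.nodes if n not in bottom)

    def children_of(self, node: str) -> tuple[str, ...]:
        return tuple(c for c in self.nodes if self.parent_of.get(c) == node)

    def ancestors_of(self, node: str) -> tuple[str, ...]:
        """Chain from the node's parent up to the root (inclusive)."""
        chain = []
        cur = node
        while cur in self.parent_of:
            cur = self.parent_of[cur]
            chain.append(cur)
        return tuple(chain)

    def descendant_leaves(self, node: str) -> tuple[str, ...]:
        bottom = set(self.bottom_nodes)
        if node in bottom:
            return (node,)
        out = []
        for leaf in self.bottom_nodes:
            if node == leaf or node in self.ancestors_of(leaf):
                out.append(leaf)
        return tuple(out)


@dataclass(frozen=True)
class SummingMatrix:
    """0/1 aggregation matrix: full node vector = entries @ bottom vector."""

    entries: np.ndarray  # (n_nodes, n_bottom)
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, index=list(self.row_labels),
                            columns=list(self.col_labels))

    @property
    def n_bottom(self) -> int:
        return self.entries.shape[1]


def build_summing_matrix(spec: HierarchySpec) -> SummingMatrix:
    """Construct the summing matrix S of a strict balanced hierarchy.

    Rows follow the hierarchy's node order (root, interior levels, then a bottom
    identity block); columns follow the bottom-node order. ``S[r, c] == 1``
    iff bottom node ``c`` equals node ``r`` or descends from it, so every
    column sums to the number of levels.
    """
    bottom = spec.bottom_nodes
    col_index = {n: j for j, n in enumerate(bottom)}
    S = np.zeros((len(spec.nodes), len(bottom)), dtype=float)
    for i, node in enumerate(spec.nodes):
        for leaf in spec.descendant_leaves(node):
            S[i, col_index[leaf]] = 1.0
    return SummingMatrix(S, tuple(spec.nodes), bottom)


@dataclass(frozen=True)
class HierarchicalSeries:
    """Time-aligned observed counts for every node of a hierarchy.

    ``data`` is a (periods x nodes) frame with a monthly ``PeriodIndex`` and
    one column per node, in hierarchy order. The container itself does not
    force coherence; :func:`check_coherence` reports on it.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if not isinstance(self.data.index, pd.PeriodIndex) or self.data.index.freqstr not in ("M",):
            raise ValueError("HierarchicalSeries requires a monthly PeriodIndex")
        if len(self.data) < 1:
            raise ValueError("at least one period required")
        if self.data.isna().any().any():
            raise ValueError("missing cells are not allowed")
        if not self.data.index.is_monotonic_increasing:
            raise ValueError("periods must be increasing")

    @property
    def start_period(self) -> pd.Period:
        return self.data.index[0]

    @property
    def end_period(self) -> pd.Period:
        return self.data.index[-1]

    @property
    def node_labels(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def __len__(self) -> int:
        return len(self.data)

    def node(self, label: str) -> pd.Series:
        if label not in self.data.columns:
            raise LabelError(f"unknown node {label!r}")
        return self.data[label]

    def split(self, holdout: int) -> tuple["HierarchicalSeries", "HierarchicalSeries"]:
        """Split into (history, holdout) with the last `holdout` months held out."""
        if not 0 < holdout < len(self.data):
            raise ValueError(f"holdout must be in (0, {len(self.data)})")
        return (HierarchicalSeries(self.data.iloc[:-holdout]),
                HierarchicalSeries(self.data.iloc[-holdout:]))

    def window(self, start: pd.Period, end: pd.Period) -> "HierarchicalSeries":
        return HierarchicalSeries(self.data.loc[start:end])


def _monthly_index(start, n: int) -> pd.PeriodIndex:
    return pd.period_range(pd.Period(start, freq="M"), periods=n, freq="M")


def aggregate(bottom_values, summing: SummingMatrix, start="2007-01") -> HierarchicalSeries:
    """Build the full coherent series from bottom-level values (y = S @ y_b).

    ``bottom_values`` is a (periods x bottom-nodes) array or DataFrame; a
    DataFrame with a monthly PeriodIndex keeps its own index, otherwise a
    monthly index starting at ``start`` is attached.
    """
    if isinstance(bottom_values, pd.DataFrame):
        idx = bottom_values.index
        if not isinstance(idx, pd.PeriodIndex):
            idx = _monthly_index(start, len(bottom_values))
        vals = bottom_values.to_numpy(dtype=float)
        if tuple(bottom_values.columns) != summing.col_labels:
            raise LabelError("bottom columns do not match the summing matrix")
    else:
        vals = np.atleast_2d(np.asarray(bottom_values, dtype=float))
        idx = _monthly_index(start, vals.shape[0])
    if vals.shape[1] != summing.n_bottom:
        raise ValueError(
            f"expected {summing.n_bottom} bottom columns, got {vals.shape[1]}"
        )
    full = vals @ summing.entries.T
    frame = pd.DataFrame(full, index=idx, columns=list(summing.row_labels))
    return HierarchicalSeries(frame)


@dataclass(frozen=True)
class CoherenceReport:
    """Maximum absolute aggregation violation per upper node."""

    violations: pd.Series  # indexed by upper-node label
    tol: float

    @property
    def max_violation(self) -> float:
        return float(self.violations.max()) if len(self.violations) else 0.0

    @property
    def passed(self) -> bool:
        return bool((self.violations <= self.tol).all())


def check_coherence(series: HierarchicalSeries, summing: SummingMatrix,
                    tol: float = 1e-6) -> CoherenceReport:
    """Compare each upper node with the sum of its bottom descendants.

    Report-only: never raises on incoherent data.
    """
    if tol < 0:
        raise ValueError("tol must be non-negative")
    if tuple(series.node_labels) != summing.row_labels:
        raise LabelError("series columns do not match the summing matrix rows")
    bottom_set = set(summing.col_labels)
    vals = series.data
    bottoms = vals[list(summing.col_labels)].to_numpy()
    implied = bottoms @ summing.entries.T
    diff = np.abs(vals.to_numpy() - implied)
    upper = [n for n in summing.row_labels if n not in bottom_set]
    idx = [list(summing.row_labels).index(n) for n in upper]
    viol = pd.Series(diff[:, idx].max(axis=0), index=upper, dtype=float)
    return CoherenceReport(viol, tol)


def gender_abo_hierarchy() -> HierarchySpec:
    """The 11-node donation hierarchy: Total -> gender -> ABO group.

    Bottom order (A_M, B_M, AB_M, O_M, A_F, B_F, AB_F, O_F) matches the
    column order of the canonical 11x8 summing matrix.
    """
    return HierarchySpec.from_children({
        "Total": ["M", "F"],
        "M": ["A_M", "B_M", "AB_M", "O_M"],
        "F": ["A_F", "B_F", "AB_F", "O_F"],
    })
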