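"""Reading, validating and decomposing ultrametric chronograms.

A chronogram is a rooted tree whose branch lengths are in units of absolute
time (here millions of years, Myr).  Every temporal diversification statistic
in this package consumes only the *branching times* of the chronogram: the
ages, measured backwards from the present (present = 0), at which the
reconstructed lineage count increases.  This module provides the newick I/O,
the ultrametricity check, outgroup pruning, and the extraction of branching
times and lineage counts.

Tree parsing, writing and pruning are delegated to :mod:`dendropy`; the
temporal decomposition is implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "Chronogram",
    "BranchingTimes",
    "ChronogramError",
    "UltrametricityReport",
    "read_newick",
    "write_newick",
    "validate_ultrametric",
    "prune_taxa",
    "branching_times",
    "lineages_at",
]


class ChronogramError(ValueError):
    """Raised for malformed, non-ultrametric or otherwise unusable trees."""


@dataclass(frozen=True)
class UltrametricityReport:
    is_ultrametric: bool
    max_deviation: float
    tol: float


@dataclass(frozen=True)
class BranchingTimes:
    """Node ages of an ultrametric chronogram, Myr before present.

    ``ages`` is sorted non-increasing; ``ages[0]`` is the crown age and the
    vector has ``n - 1`` entries for an ``n``-tip binary tree.  This is the
    sufficient statistic for every temporal diversification likelihood.
    """

    ages: np.ndarray
    n: int

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        object.__setattr__(self, "ages", ages)
        if ages.ndim != 1:
            raise ChronogramError("ages must be a 1-D vector")
        if self.n < 2:
            raise ChronogramError("a chronogram has at least 2 tips")
        if len(ages) != self.n - 1:
            raise ChronogramError(
                f"expected {self.n - 1} branching times for n={self.n}, got {len(ages)}"
            )
        if np.any(ages <= 0):
            raise ChronogramError("branching times must be strictly positive")
        if np.any(np.diff(ages) > 0):
            raise ChronogramError("branching times must be sorted non-increasing")

    @property
    def crown_age(self) -> float:
        return float(self.ages[0])

    @property
    def total_lineage_time(self) -> float:
        """Total reconstructed lineage time A = 2*x2 + sum_{i>=3} x_i."""
        return float(2.0 * self.ages[0] + self.ages[1:].sum())


class Chronogram:
    """A rooted tree with absolute-time branch lengths (thin dendropy wrapper)."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        tips = self.tip_labels
        if len(tips) < 2:
            raise ChronogramError("a chronogram needs at least 2 tips")
        if len(set(tips)) != len(tips):
            dupes = sorted({t for t in tips if tips.count(t) > 1})
            raise ChronogramError(f"duplicate tip labels: {dupes}")
        for nd in tree.preorder_node_iter():
            if nd.parent_node is not None and nd.edge.length is None:
                raise ChronogramError(
                    f"missing branch length on edge above {_node_repr(nd)}"
                )
            if nd.parent_node is not None and nd.edge.length < 0:
                raise ChronogramError(
                    f"negative branch length on edge above {_node_repr(nd)}"
                )

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    def node_depths(self) -> dict[dendropy.Node, float]:
        """Distance of each node from the root (root edge ignored)."""
        depths: dict[dendropy.Node, float] = {}
        for nd in self._tree.preorder_node_iter():
            if nd.parent_node is None:
                depths[nd] = 0.0
            else:
                depths[nd] = depths[nd.parent_node] + nd.edge.length
        return depths

    def height(self) -> float:
        """Mean root-to-tip distance (the crown age for an ultrametric tree)."""
        depths = self.node_depths()
        tip_depths = [depths[lf] for lf in self._tree.leaf_node_iter()]
        return float(np.mean(tip_depths))

    def is_binary(self) -> bool:
        return all(
            len(nd.child_nodes()) == 2
            for nd in self._tree.preorder_internal_node_iter()
        )

    def clone(self) -> "Chronogram":
        return Chronogram(self._tree.clone(depth=1))

    def __repr__(self) -> str:  # pragma: no cover
        return f"Chronogram(n_tips={self.n_tips}, height={self.height():.4g})"


def _node_repr(nd: dendropy.Node) -> str:
    if nd.taxon is not None:
        return f"tip {nd.taxon.label!r}"
    return "an internal node"


def read_newick(text: str) -> Chronogram:
    """Parse a single newick tree with mandatory branch lengths.

    Raises :class:`ChronogramError` on malformed newick, a missing branch
    length on any non-root edge, or duplicate tip labels.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ChronogramError(f"malformed newick: {exc}") from exc
    return Chronogram(tree)


def write_newick(tree: Chronogram) -> str:
    """Serialize to a single-line newick string, lossless to 1e-9 Myr."""
    out = tree.tree.as_string(
        schema="newick",
        suppress_rooting=True,
        preserve_spaces=True,  # quote labels containing spaces
        real_value_format_specifier=".12g",
    )
    return out.strip() + ("" if out.strip().endswith(";") else ";")


def validate_ultrametric(tree: Chronogram, tol: float | None = None) -> UltrametricityReport:
    """Check that all root-to-tip distances agree within ``tol`` Myr.

    ``max_deviation`` is the largest absolute deviation of a tip depth from
    the mean tip depth.  Default tolerance is ``1e-6`` times the tree height.
    """
    depths = tree.node_depths()
    tip_depths = np.array([depths[lf] for lf in tree.tree.leaf_node_iter()])
    mean_depth = tip_depths.mean()
    max_dev = float(np.abs(tip_depths - mean_depth).max())
    if tol is None:
        tol = 1e-6 * max(mean_depth, 1e-300)
    return UltrametricityReport(is_ultrametric=max_dev <= tol, max_deviation=max_dev, tol=tol)


def prune_taxa(tree: Chronogram, labels) -> Chronogram:
    """Remove the listed tips (e.g. outgroups); depths of survivors unchanged.

    Unary nodes created by pruning are suppressed with their branch lengths
    summed, so remaining root-to-tip distances are preserved exactly.
    """
    labels = set(labels)
    if not labels:
        return tree.clone()
    present = set(tree.tip_labels)
    unknown = sorted(labels - present)
    if unknown:
        raise ChronogramError(f"cannot prune unknown tip labels: {unknown}")
    survivors = present - labels
    if len(survivors) < 2:
        raise ChronogramError(
            f"pruning would leave {len(survivors)} tip(s); at least 2 required"
        )
    t = tree.tree.clone(depth=1)
    taxa = [tx for tx in t.taxon_namespace if tx.label in labels]
    t.prune_taxa(taxa, suppress_unifurcations=True)
    return Chronogram(t)


def branching_times(
    tree: Chronogram,
    tol: float | None = None,
    resolve_polytomies: bool = False,
) -> BranchingTimes:
    """Extract node ages (Myr before present), sorted descending.

    The tree must be ultrametric within ``tol``.  Polytomies are rejected by
    default because all downstream likelihoods assume binary trees; with
    ``resolve_polytomies=True`` they are resolved into zero-length ladders
    (arbitrary order), which places the duplicated ages at the polytomy age.
    """
    report = validate_ultrametric(tree, tol)
    if not report.is_ultrametric:
        raise ChronogramError(
            f"tree is not ultrametric: max tip-depth deviation {report.max_deviation:.3g}"
            f" exceeds tolerance {report.tol:.3g}"
        )
    work = tree
    if not tree.is_binary():
        if not resolve_polytomies:
            raise ChronogramError(
                "tree contains polytomies; pass resolve_polytomies=True to "
                "resolve them into zero-length binary ladders"
            )
        t = tree.tree.clone(depth=1)
        t.resolve_polytomies(limit=2, update_bipartitions=False)
        for nd in t.preorder_node_iter():
            if nd.parent_node is not None and nd.edge.length is None:
                nd.edge.length = 0.0
        work = Chronogram(t)

    depths = work.node_depths()
    height = work.height()
    ages = [
        height - depths[nd]
        for nd in work.tree.preorder_internal_node_iter()
    ]
    ages = np.sort(np.asarray(ages, dtype=float))[::-1]
    # guard tiny negative ages from rounding at near-present nodes
    ages = np.maximum(ages, np.finfo(float).tiny)
    return BranchingTimes(ages=ages, n=work.n_tips)


def lineages_at(bt: BranchingTimes, tau: float) -> int:
    """Number of reconstructed lineages extant at age ``tau`` before present.

    Counts on the younger side of events: exactly at a branching age the
    split has happened, so exactly at the crown age the count is 2 (the stem
    lineage is never counted); above the crown age it is 1; at tau = 0 it is
    the tip count n.  This matches the LTT curve pointwise.
    """
    if tau < 0:
        raise ChronogramError("tau must be non-negative")
    if tau > bt.crown_age:
        return 1
    return int(1 + np.sum(bt.ages >= tau))
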