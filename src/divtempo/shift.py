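"""Topology-only per-branch diversification-shift test.

Under the equal-rates-Markov (ERM) null, every extant lineage is equally
likely to split next, so a clade of ``n`` tips splits into ordered daughter
sizes ``(l, n-l)`` with probability ``1/(n-1)`` for every ``l``.  A
diversification-rate shift on one branch makes that branch's clade grow
faster (or slower) than its sister; this module scores each internal branch
with a two-rate likelihood ratio built from a biased Yule urn:

* :func:`urn_split_prob` - probability that a growth process started at one
  "focal" and one "sister" lineage, in which the next tip joins the focal
  side with probability ``beta*i / (beta*i + j)`` from state ``(i, j)``, ends
  at ``(m, o)`` tips.  ``beta`` is the rate ratio; ``beta = 1`` recovers the
  ERM closed form.
* :func:`delta1_branch` - the per-branch statistic
  ``2 * [sup_beta ln P(m, o | beta) - ln P(m, o | 1)]`` (>= 0).
* :func:`delta1_scan` / :func:`delta1_pvalues` - whole-tree scan with a
  family-wise Monte Carlo p-value: the observed per-branch statistic is
  compared against the distribution of the *maximum* statistic over all
  branches of ERM trees of the same size.

This is a transparent reconstruction of the published Delta-1 machinery
(topology-only, per-node, ERM null); the exact published algebra may differ
in how the three-way partition at the parent is conditioned, so absolute
p-values should be interpreted with that caveat.  The statistic ignores
branch lengths entirely.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize

from .chronogram import Chronogram, ChronogramError

__all__ = [
    "NodePartition",
    "NodeShiftResult",
    "urn_split_prob",
    "log_urn_split_prob",
    "delta1_branch",
    "delta1_scan",
    "delta1_pvalues",
]

DEFAULT_BETA_BOUNDS = (1e-3, 1e3)


@dataclass(frozen=True)
class NodePartition:
    node_id: str
    l: int
    r: int
    o: int

    @property
    def m(self) -> int:
        return self.l + self.r


@dataclass(frozen=True)
class NodeShiftResult:
    node_id: str
    m: int
    o: int
    delta1: float
    beta_hat: float
    p_mc: float | None = None
    flagged: bool | None = None


def log_urn_split_prob(a: int, b: int, beta: float) -> float:
    """log probability that the biased urn started at (1, 1) ends at (a, b).

    Dynamic programming over anti-diagonals of the (focal, sister) lattice;
    each growth step adds one tip, joining the focal side with probability
    ``beta*i / (beta*i + j)`` from state ``(i, j)``.  Computed with running
    rescaling so extreme ``beta`` cannot underflow.
    """
    if a < 1 or b < 1:
        raise ValueError("tip counts must be >= 1")
    if beta <= 0:
        raise ValueError("beta must be > 0")
    n = a + b
    if n == 2:
        return 0.0
    # diag[k] = P(state (i, j)) with i = i_min + k; i + j = current total
    diag = np.array([1.0])
    i_min = 1
    log_scale = 0.0
    for s in range(2, n):  # total tips before the step: s -> s + 1
        i_vals = np.arange(i_min, i_min + len(diag))
        j_vals = s - i_vals
        p_left = beta * i_vals / (beta * i_vals + j_vals)
        new = np.zeros(len(diag) + 1)
        new[1:] += diag * p_left           # focal side grows: i -> i+1
        new[:-1] += diag * (1.0 - p_left)  # sister side grows: j -> j+1
        diag = new  # states now span i = i_min .. i_min + len(diag) - 1
        # prune states that can no longer reach (a, b)
        i_new = np.arange(i_min, i_min + len(diag))
        keep = (i_new <= a) & ((s + 1) - i_new <= b)
        diag = diag[keep]
        i_min = int(i_new[keep][0])
        peak = diag.max()
        if peak < 1e-250:
            diag = diag / peak
            log_scale += np.log(peak)
    # final totals = n; the surviving states include (a, b)
    i_vals = np.arange(i_min, i_min + len(diag))
    idx = int(np.where(i_vals == a)[0][0])
    p = diag[idx]
    if p <= 0:
        return -np.inf
    return float(np.log(p) + log_scale)


def urn_split_prob(a: int, b: int, beta: float) -> float:
    """Probability the biased urn ends at (a, b); at beta = 1 this equals the
    ERM closed form 1/(a+b-1)."""
    return float(np.exp(log_urn_split_prob(a, b, beta)))


@functools.lru_cache(maxsize=100_000)
def _delta1_cached(m: int, o: int, lo: float, hi: float) -> tuple:
    log_erm = -np.log(m + o - 1.0)

    def neg(log_beta):
        return -log_urn_split_prob(m, o, float(np.exp(log_beta)))

    grid = np.linspace(np.log(lo), np.log(hi), 33)
    vals = np.array([neg(lb) for lb in grid])
    i = int(np.argmin(vals))
    g_lo = grid[max(i - 1, 0)]
    g_hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(neg, bounds=(g_lo, g_hi), method="bounded",
                                   options={"xatol": 1e-8})
    if res.fun <= vals[i]:
        best_lp, beta_hat = -float(res.fun), float(np.exp(res.x))
    else:
        best_lp, beta_hat = -float(vals[i]), float(np.exp(grid[i]))
    delta1 = max(2.0 * (best_lp - log_erm), 0.0)
    if delta1 == 0.0:
        beta_hat = 1.0
    return delta1, beta_hat


def delta1_branch(m: int, o: int, beta_bounds=DEFAULT_BETA_BOUNDS) -> tuple:
    """(delta1, beta_hat) for a clade of ``m`` tips with an ``o``-tip sister.

    delta1 = 2 * [sup_beta ln P(m, o | beta) - ln P(m, o | 1)], located by a
    log-grid scan plus bounded refinement; always >= 0.
    """
    if m < 1 or o < 1:
        raise ValueError("clade and sister sizes must be >= 1")
    lo, hi = beta_bounds
    if not 0 < lo < hi:
        raise ValueError("invalid beta bounds")
    return _delta1_cached(int(m), int(o), float(lo), float(hi))


def delta1_scan(tree: Chronogram, beta_bounds=DEFAULT_BETA_BOUNDS) -> list:
    """delta1 for every internal branch with a sister (root excluded).

    Branch lengths play no role; only the (clade size, sister size)
    partition at each internal node enters.
    """
    if not tree.is_binary():
        raise ChronogramError("the shift scan requires a binary tree")
    if tree.n_tips < 4:
        raise ChronogramError("the shift scan needs at least 4 tips")
    t = tree.tree
    n_leaves: dict = {}
    for nd in t.postorder_node_iter():
        if nd.is_leaf():
            n_leaves[nd] = 1
        else:
            n_leaves[nd] = sum(n_leaves[ch] for ch in nd.child_nodes())
    results = []
    idx = 0
    for nd in t.preorder_internal_node_iter():
        if nd.parent_node is None:
            continue
        idx += 1
        sibs = [ch for ch in nd.parent_node.child_nodes() if ch is not nd]
        o = sum(n_leaves[s] for s in sibs)
        m = n_leaves[nd]
        d1, bh = delta1_branch(m, o, beta_bounds)
        label = nd.label or f"node{idx}"
        results.append(NodeShiftResult(node_id=label, m=m, o=o,
                                       delta1=d1, beta_hat=bh))
    return results


def _erm_partitions(n: int, rng: np.random.Generator) -> list:
    """(m, o) partitions of the internal non-root branches of one ERM tree.

    The tree is grown by uniform leaf splitting (the ERM / Yule topology
    law), tracked with parent pointers only.
    """
    parent = [-1, 0, 0]
    is_leaf = [False, True, True]
    leaves = [1, 2]
    while len(leaves) < n:
        k = int(rng.integers(len(leaves)))
        nd = leaves[k]
        c1, c2 = len(parent), len(parent) + 1
        parent.extend([nd, nd])
        is_leaf[nd] = False
        is_leaf.extend([True, True])
        leaves[k] = c1
        leaves.append(c2)
    counts = np.zeros(len(parent), dtype=int)
    for v in range(len(parent) - 1, 0, -1):
        if is_leaf[v]:
            counts[v] = 1
        counts[parent[v]] += counts[v]
    counts[0] = n
    out = []
    for v in range(1, len(parent)):
        if is_leaf[v]:
            continue
        m = int(counts[v])
        o = int(counts[parent[v]] - counts[v])
        out.append((m, o))
    return out


def delta1_pvalues(
    scan_results: list,
    n: int,
    reps: int,
    seed,
    alpha: float = 0.05,
    beta_bounds=DEFAULT_BETA_BOUNDS,
) -> list:
    """Attach family-wise Monte Carlo p-values to a whole-tree scan.

    ``reps`` ERM topologies of ``n`` tips are simulated; for each, the
    maximum delta1 across internal branches is recorded.  Each observed
    branch gets ``p = (1 + #{max_sim >= delta1}) / (reps + 1)``, a
    max-statistic correction over the whole-tree scan.
    """
    if reps < 100:
        raise ValueError("use at least 100 Monte Carlo replicates")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sim_max = np.empty(reps)
    for r in range(reps):
        parts = _erm_partitions(n, rng)
        sim_max[r] = max(
            (delta1_branch(m, o, beta_bounds)[0] for m, o in parts), default=0.0
        )
    out = []
    for res in scan_results:
        p = float((1 + np.sum(sim_max >= res.delta1)) / (reps + 1))
        out.append(replace(res, p_mc=p, flagged=p <= alpha))
    return out
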