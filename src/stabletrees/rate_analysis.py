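"""Per-branch evolutionary rate multipliers and rate-through-time curves.

The posterior distribution of squared per-edge trait increments defines
a variance-like raw rate for each branch, ``r_e = median[(dx_e)^2] /
t_e``.  Dividing by the tree-wide median gives a unit-free fold-change
relative to the input chronogram ("x times the original branch
length"): the tree-wide median multiplier is 1 by construction, and the
multipliers are invariant to shifting all log-masses by a constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phylo_io import TimeTree
from .sampler import PosteriorDraws

__all__ = ["RateProfile", "branch_rate_multipliers", "max_rate_branch", "rate_scaled_tree"]


@dataclass
class RateProfile:
    """Per-edge rate multipliers and a time-binned mean-multiplier curve.

    Edges are identified by their child node index (``edge_child``).
    ``time_curve`` is (bin midpoint in Myr before present, mean
    multiplier weighted by branch-bin overlap).
    """

    edge_child: np.ndarray
    edge_multiplier: np.ndarray
    raw_rate: np.ndarray
    reference_rate: float  # tree-wide median raw rate, (log10 kg)^2 / Myr
    bin_mid: np.ndarray
    time_curve: np.ndarray


def branch_rate_multipliers(draws: PosteriorDraws, tree: TimeTree,
                            n_bins: int = 20) -> RateProfile:
    """Posterior branch-rate multipliers relative to the input chronogram.

    ``draws`` must come from a fit on ``tree`` (edge sets are checked).
    The time curve averages edge multipliers within ``n_bins``
    equal-width age bins from the root to the present, weighting each
    edge by its overlap with the bin.
    """
    if draws.tree.n_nodes != tree.n_nodes or \
            not np.array_equal(draws.tree.edge_child, tree.edge_child) or \
            not np.array_equal(draws.tree.parent, tree.parent):
        raise ValueError("draws were not produced on this tree (edge sets differ)")
    inc = draws.edge_increments()
    t = tree.duration[tree.edge_child]
    raw = np.median(inc ** 2, axis=0) / t
    ref = float(np.median(raw))
    mult = raw / ref

    edges_hi = tree.node_age[tree.parent[tree.edge_child]]  # older end
    edges_lo = tree.node_age[tree.edge_child]
    bins = np.linspace(tree.root_age, 0.0, n_bins + 1)
    mids = 0.5 * (bins[:-1] + bins[1:])
    curve = np.full(n_bins, np.nan)
    for b in range(n_bins):
        hi, lo = bins[b], bins[b + 1]
        ov = np.minimum(edges_hi, hi) - np.maximum(edges_lo, lo)
        ov = np.maximum(ov, 0.0)
        w = ov.sum()
        if w > 0:
            curve[b] = float((mult * ov).sum() / w)
    return RateProfile(
        edge_child=tree.edge_child.copy(), edge_multiplier=mult, raw_rate=raw,
        reference_rate=ref, bin_mid=mids, time_curve=curve,
    )


def max_rate_branch(profile: RateProfile, tree: TimeTree):
    """The branch with the largest rate multiplier.

    Returns ``(child node index, multiplier, descendant tip labels)``;
    exact ties are broken toward the longer branch.
    """
    m = profile.edge_multiplier
    t = tree.duration[profile.edge_child]
    top = m == m.max()
    cand = np.flatnonzero(top)
    e = int(cand[np.argmax(t[cand])])
    child = int(profile.edge_child[e])
    return child, float(m[e]), tree.clade_tips(child)


def rate_scaled_tree(profile: RateProfile, tree: TimeTree) -> TimeTree:
    """Copy of the tree with branch lengths ``multiplier * duration``
    (the usual rate-scaled tree for plotting)."""
    out = tree.copy()
    dur = out.duration.copy()
    for e, child in enumerate(profile.edge_child):
        dur[child] = profile.edge_multiplier[e] * tree.duration[child]
    return TimeTree(out.parent, dur, out.labels)
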