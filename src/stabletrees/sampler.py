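"""MCMC over (alpha, c, internal-node states) for the stable trait model.

Metropolis-within-Gibbs with the run protocol used for this kind of
analysis: several independent chains, a fixed burn-in fraction,
convergence judged by the Gelman-Rubin potential scale reduction factor
(PSRF) on the scalar parameters.

Moves per iteration
-------------------
* a random-walk update of every internal node value, performed as two
  vectorized Metropolis sweeps over the depth-parity classes of the
  tree (nodes of equal depth parity are never adjacent, so simultaneous
  acceptance decisions are exact single-site updates);
* a reflected random walk on alpha over a fine lattice (step 0.0025) on
  (ALPHA_MIN, 2], skipped when ``alpha_fixed`` is set — each lattice
  value reuses a cached high-accuracy density table;
* a random walk on log c, with a wide uniform prior on log c;
* every 10th iteration, a subtree shift: all internal values below a
  random node move together.

Priors: alpha uniform on its lattice, log c uniform on (-14, 7), node
states flat.  Proposal widths adapt during burn-in only, so detailed
balance holds for every retained draw.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .phylo_io import TimeTree, TraitTable
from .stable import (
    ALPHA_MIN,
    AugmentedState,
    _get_table,
    contrasts_rate_estimate,
)

__all__ = ["ChainConfig", "PosteriorDraws", "run_mcmc", "psrf", "initialize_state"]

ALPHA_STEP = 0.0025
#: Lattice of admissible alpha values for the free-alpha sampler.
ALPHA_GRID = np.round(np.arange(ALPHA_MIN + ALPHA_STEP, 2.0 + 1e-9, ALPHA_STEP), 4)

_LOG_C_LO, _LOG_C_HI = -14.0, 7.0


@dataclass
class ChainConfig:
    """Run protocol for :func:`run_mcmc`.

    Defaults follow the full-scale protocol (4 runs of 2,000,000
    iterations, 10% burn-in, PSRF target 1.01); synthetic-scale
    analyses pass much smaller ``iterations``.
    """

    iterations: int = 2_000_000
    runs: int = 4
    thin: int | None = None
    burnin_frac: float = 0.10
    psrf_target: float = 1.01
    alpha_fixed: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.iterations <= 0:
            raise ValueError("iterations must be positive")
        if not (0 <= self.burnin_frac < 1):
            raise ValueError("burnin_frac must lie in [0, 1)")
        if self.psrf_target <= 1:
            raise ValueError("psrf_target must exceed 1")
        if self.runs < 1:
            raise ValueError("need at least one run")
        if self.alpha_fixed is not None and not (ALPHA_MIN < self.alpha_fixed <= 2.0):
            raise ValueError(f"alpha_fixed must lie in ({ALPHA_MIN}, 2]")


def initialize_state(tree: TimeTree, traits: TraitTable) -> AugmentedState:
    """Midpoint initialization of internal-node values.

    Post-order pass sets each internal node to the mean of its
    children; a pre-order smoothing pass then averages each non-root
    internal node with its parent.
    """
    wv = traits.working_values
    x = np.zeros(tree.n_nodes)
    for v in tree.postorder:
        if tree.is_tip[v]:
            x[v] = wv[tree.labels[v]]
        else:
            x[v] = np.mean([x[c] for c in tree.children[v]])
    for v in tree.preorder:
        if v != tree.root and not tree.is_tip[v]:
            x[v] = 0.5 * (x[v] + x[tree.parent[v]])
    values = {}
    for v in range(tree.n_nodes):
        if not tree.is_tip[v]:
            values[tree.labels[v] if tree.labels[v] is not None else int(v)] = float(x[v])
    return AugmentedState(values)


def psrf(chains) -> float:
    """Gelman-Rubin potential scale reduction factor.

    sqrt([(n-1)/n * W + B/n] / W) from the between- and within-run
    variances of ``chains`` (one row per run).  Returns +inf with a
    warning when the within-run variance is zero (degenerate chains).
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("psrf needs at least two runs")
    if arr.shape[1] < 10:
        raise ValueError("psrf needs at least 10 draws per run")
    n = arr.shape[1]
    w = arr.var(axis=1, ddof=1).mean()
    if not (w > 0):
        warnings.warn("zero within-run variance; PSRF undefined (+inf)")
        return math.inf
    b_over_n = arr.mean(axis=1).var(ddof=1)
    if b_over_n == 0.0:
        warnings.warn("zero between-run variance; runs look like duplicates")
    return math.sqrt(((n - 1) / n * w + b_over_n) / w)


# ----------------------------------------------------------------------
class _Machine:
    """Precomputed structure for fast likelihood bookkeeping."""

    def __init__(self, tree: TimeTree, traits: TraitTable):
        traits.bind(tree)
        self.tree = tree
        self.n = tree.n_nodes
        self.root = tree.root
        self.edge_child = tree.edge_child  # edge id == position in this array
        self.edge_parent = tree.parent[self.edge_child]
        self.t = tree.duration[self.edge_child]
        if np.any(self.t <= 0):
            raise ValueError("non-positive branch duration; collapse degenerate edges first")
        self.log_t = np.log(self.t)
        self.mean_log_t = float(self.log_t.mean())
        self.n_edges = len(self.edge_child)
        self.internal = np.array([v for v in range(self.n) if not tree.is_tip[v]])

        wv = traits.working_values
        self.x_obs = np.zeros(self.n)
        for i in np.flatnonzero(tree.is_tip):
            self.x_obs[i] = wv[tree.labels[i]]

        depth_int = np.zeros(self.n, dtype=int)
        for v in tree.preorder:
            if v != self.root:
                depth_int[v] = depth_int[tree.parent[v]] + 1

        edge_of_child = {int(c): e for e, c in enumerate(self.edge_child)}
        self.classes = []
        for parity in (0, 1):
            nodes = np.array([v for v in self.internal if depth_int[v] % 2 == parity])
            if len(nodes) == 0:
                continue
            pos = {int(v): i for i, v in enumerate(nodes)}
            edges, owner, sign = [], [], []
            for e in range(self.n_edges):
                ch, pa = int(self.edge_child[e]), int(self.edge_parent[e])
                if ch in pos:
                    edges.append(e); owner.append(pos[ch]); sign.append(1.0)
                elif pa in pos:
                    edges.append(e); owner.append(pos[pa]); sign.append(-1.0)
            self.classes.append(dict(
                nodes=nodes,
                edges=np.array(edges), owner=np.array(owner),
                sign=np.array(sign),
            ))

        # subtree-shift bookkeeping: internal descendants and boundary edges
        self.sub_internal, self.sub_edges, self.sub_sign = [], [], []
        for v in self.internal:
            members, stack = [], [int(v)]
            while stack:
                u = stack.pop()
                members.append(u)
                stack.extend(c for c in tree.children[u] if not tree.is_tip[c])
            mset = set(members)
            edges, sign = [], []
            if v != self.root:
                edges.append(edge_of_child[int(v)]); sign.append(1.0)
            for u in members:
                for c in tree.children[u]:
                    if tree.is_tip[c]:
                        edges.append(edge_of_child[int(c)]); sign.append(-1.0)
            self.sub_internal.append(np.array(members))
            self.sub_edges.append(np.array(edges))
            self.sub_sign.append(np.array(sign))

    def edge_logpdf(self, dx, alpha, log_c):
        """Per-edge stable log-density of increments dx under (alpha, c)."""
        log_s = log_c + self.log_t / alpha
        s = np.exp(log_s)
        return _get_table(alpha).logpdf(dx / s) - log_s


def _run_single_chain(mach: _Machine, config: ChainConfig, rng: np.random.Generator,
                      n_keep: int, thin: int, burnin: int):
    tree = mach.tree
    free_alpha = config.alpha_fixed is None
    if free_alpha:
        j = int(np.argmin(np.abs(ALPHA_GRID - 1.5)))
        alpha = float(ALPHA_GRID[j])
        jmax = len(ALPHA_GRID) - 1
    else:
        alpha = float(config.alpha_fixed)

    # midpoint initialization (inline form of initialize_state)
    x = mach.x_obs.copy()
    for v in tree.postorder:
        if not tree.is_tip[v]:
            x[v] = np.mean([x[c] for c in tree.children[v]])
    for v in tree.preorder:
        if v != tree.root and not tree.is_tip[v]:
            x[v] = 0.5 * (x[v] + x[tree.parent[v]])

    sigma2_hat = max(mach.sigma2_hat, 1e-12)
    log_c = 0.5 * math.log(sigma2_hat / 2.0)
    log_c = float(np.clip(log_c, _LOG_C_LO + 1.0, _LOG_C_HI - 1.0))

    dx = x[mach.edge_child] - x[mach.edge_parent]
    edge_lp = mach.edge_logpdf(dx, alpha, log_c)
    if not np.all(np.isfinite(edge_lp)):
        bad = mach.edge_child[~np.isfinite(edge_lp)][:5]
        raise FloatingPointError(
            f"non-finite likelihood at initialization (edges above nodes {bad.tolist()}); "
            "check trait values and branch durations"
        )

    widths = np.full(mach.n, 0.5)
    w_alpha, w_c, w_shift = 20.0, 0.3, 0.3
    n_int = len(mach.internal)

    keep_alpha = np.empty(n_keep)
    keep_c = np.empty(n_keep)
    keep_root = np.empty(n_keep)
    keep_ll = np.empty(n_keep)
    keep_nodes = np.empty((n_keep, n_int))
    kept = 0

    acc_nodes = np.zeros(mach.n)
    try_nodes = np.zeros(mach.n)
    acc_a = try_a = acc_c = try_c = acc_s = try_s = 0.0
    batch = 0

    for it in range(config.iterations):
        # --- node sweeps over depth-parity classes
        for cls in mach.classes:
            nodes, edges, owner, sign = cls["nodes"], cls["edges"], cls["owner"], cls["sign"]
            eps = rng.standard_normal(len(nodes)) * widths[nodes]
            dx_new = dx[edges] + sign * eps[owner]
            log_s = log_c + mach.log_t[edges] / alpha
            lp_new = _get_table(alpha).logpdf(dx_new / np.exp(log_s)) - log_s
            delta = np.bincount(owner, weights=lp_new - edge_lp[edges], minlength=len(nodes))
            acc = np.log(rng.random(len(nodes))) < delta
            if acc.any():
                x[nodes[acc]] += eps[acc]
                m = acc[owner]
                dx[edges[m]] = dx_new[m]
                edge_lp[edges[m]] = lp_new[m]
            if it < burnin:
                acc_nodes[nodes] += acc
                try_nodes[nodes] += 1

        # --- alpha move (lattice random walk, reflected), with log-c
        # compensation along the likelihood ridge: log c shifts so the
        # mean per-edge log-scale is preserved (translation in log c,
        # unit Jacobian, symmetric step -> valid Metropolis proposal)
        if free_alpha:
            step = int(round(rng.standard_normal() * w_alpha))
            try_a += 1
            if step != 0:
                jp = (j + step) % (2 * jmax) if jmax > 0 else 0
                jp = jp if jp <= jmax else 2 * jmax - jp
                if jp != j:
                    alpha_p = float(ALPHA_GRID[jp])
                    lc_p = log_c + mach.mean_log_t * (1.0 / alpha - 1.0 / alpha_p)
                    if _LOG_C_LO < lc_p < _LOG_C_HI:
                        lp_p = mach.edge_logpdf(dx, alpha_p, lc_p)
                        if math.log(rng.random()) < lp_p.sum() - edge_lp.sum():
                            j, alpha, log_c, edge_lp = jp, alpha_p, lc_p, lp_p
                            acc_a += 1

        # --- c move (random walk on log c, uniform prior on log c)
        lc_p = log_c + rng.standard_normal() * w_c
        try_c += 1
        if _LOG_C_LO < lc_p < _LOG_C_HI:
            lp_p = mach.edge_logpdf(dx, alpha, lc_p)
            if math.log(rng.random()) < lp_p.sum() - edge_lp.sum():
                log_c, edge_lp = lc_p, lp_p
                acc_c += 1

        # --- subtree shift
        if it % 10 == 9:
            vi = int(rng.integers(n_int))
            delta_s = rng.standard_normal() * w_shift
            be, bs = mach.sub_edges[vi], mach.sub_sign[vi]
            try_s += 1
            if len(be):
                dx_new = dx[be] + bs * delta_s
                log_s = log_c + mach.log_t[be] / alpha
                lp_new = _get_table(alpha).logpdf(dx_new / np.exp(log_s)) - log_s
                if math.log(rng.random()) < lp_new.sum() - edge_lp[be].sum():
                    x[mach.sub_internal[vi]] += delta_s
                    dx[be] = dx_new
                    edge_lp[be] = lp_new
                    acc_s += 1

        # --- adaptation (burn-in only), and drift control
        if it < burnin and (it + 1) % 50 == 0:
            batch += 1
            g = min(0.5, 2.0 / math.sqrt(batch))
            with np.errstate(divide="ignore", invalid="ignore"):
                rate = np.where(try_nodes > 0, acc_nodes / np.maximum(try_nodes, 1), 0.44)
            widths *= np.exp(g * (rate - 0.44))
            widths = np.clip(widths, 1e-4, 50.0)
            if free_alpha and try_a:
                w_alpha = float(np.clip(w_alpha * math.exp(g * (acc_a / try_a - 0.35)), 0.5, len(ALPHA_GRID)))
            if try_c:
                w_c = float(np.clip(w_c * math.exp(g * (acc_c / try_c - 0.44)), 1e-3, 10.0))
            if try_s:
                w_shift = float(np.clip(w_shift * math.exp(g * (acc_s / try_s - 0.25)), 1e-3, 10.0))
            acc_nodes[:] = 0; try_nodes[:] = 0
            acc_a = try_a = acc_c = try_c = acc_s = try_s = 0.0
        if (it + 1) % 10000 == 0:
            dx = x[mach.edge_child] - x[mach.edge_parent]
            edge_lp = mach.edge_logpdf(dx, alpha, log_c)

        # --- record
        if it >= burnin and (it - burnin) % thin == 0 and kept < n_keep:
            keep_alpha[kept] = alpha
            keep_c[kept] = math.exp(log_c)
            keep_root[kept] = x[mach.root]
            keep_ll[kept] = edge_lp.sum()
            keep_nodes[kept] = x[mach.internal]
            kept += 1

    return dict(alpha=keep_alpha[:kept], c=keep_c[:kept], root=keep_root[:kept],
                loglik=keep_ll[:kept], nodes=keep_nodes[:kept])


@dataclass
class PosteriorDraws:
    """Post-burn-in MCMC draws, partitioned by run.

    ``nodes`` has shape (runs, draws, n_internal) in the order of
    ``internal_nodes`` (node indices into the tree).  ``psrf`` maps
    scalar-parameter names to their Gelman-Rubin statistics.
    """

    tree: TimeTree
    internal_nodes: np.ndarray
    alpha: np.ndarray
    c: np.ndarray
    root: np.ndarray
    loglik: np.ndarray
    nodes: np.ndarray
    config: ChainConfig
    tip_values: dict
    psrf: dict = field(default_factory=dict)
    converged: bool = False

    @property
    def n_draws(self) -> int:
        return self.alpha.shape[0] * self.alpha.shape[1]

    def combined(self, name: str) -> np.ndarray:
        return getattr(self, name).reshape(-1)

    def node_draws(self, node: int) -> np.ndarray:
        pos = int(np.flatnonzero(self.internal_nodes == node)[0])
        return self.nodes.reshape(-1, self.nodes.shape[-1])[:, pos]

    def edge_increments(self) -> np.ndarray:
        """(total draws, n_edges) array of per-edge increments x_child - x_parent."""
        tree = self.tree
        flat = self.nodes.reshape(-1, self.nodes.shape[-1])
        x = np.empty((flat.shape[0], tree.n_nodes))
        for k, v in enumerate(self.internal_nodes):
            x[:, v] = flat[:, k]
        for i in np.flatnonzero(tree.is_tip):
            x[:, i] = self.tip_values[tree.labels[i]]
        return x[:, tree.edge_child] - x[:, tree.parent[tree.edge_child]]

    def _summary(self, draws: np.ndarray, back_transform: bool):
        med = float(np.median(draws))
        lo, hi = np.quantile(draws, [0.025, 0.975])
        if back_transform:
            return {"median_kg": 10.0 ** med, "ci95_kg": (10.0 ** float(lo), 10.0 ** float(hi))}
        return {"median": med, "ci95": (float(lo), float(hi))}

    def root_summary(self, kg: bool = True) -> dict:
        """Posterior median and 95% quantile interval of the root state.

        Quantiles are taken on the log10 scale and back-transformed, so
        the kg-scale interval is scale-consistent.
        """
        return self._summary(self.combined("root"), kg)

    def node_summary(self, node: int, kg: bool = True) -> dict:
        return self._summary(self.node_draws(node), kg)

    def alpha_summary(self) -> dict:
        return self._summary(self.combined("alpha"), False)

    @property
    def map_estimate(self) -> dict:
        """Highest-posterior draw (flat priors: the max-likelihood draw)."""
        ll = self.combined("loglik")
        i = int(np.argmax(ll))
        flat = self.nodes.reshape(-1, self.nodes.shape[-1])
        return {
            "alpha": float(self.combined("alpha")[i]),
            "c": float(self.combined("c")[i]),
            "root_state": float(self.combined("root")[i]),
            "node_values": {int(v): float(flat[i, k]) for k, v in enumerate(self.internal_nodes)},
            "loglik": float(ll[i]),
        }


def run_mcmc(tree: TimeTree, traits: TraitTable, config: ChainConfig) -> PosteriorDraws:
    """Sample the posterior of (alpha, c, node states) given tree and traits.

    Runs ``config.runs`` independent chains (seeds derived
    deterministically from ``config.seed``), discards the burn-in
    fraction, thins to at most ~1000 draws per run by default, and
    reports PSRF over runs for alpha (if free), c, the root state and
    the log-likelihood.  Identical inputs and seed give identical
    draws.
    """
    mach = _Machine(tree, traits)
    mach.sigma2_hat = contrasts_rate_estimate(tree, traits)
    burnin = int(config.burnin_frac * config.iterations)
    post = config.iterations - burnin
    thin = config.thin if config.thin is not None else max(1, post // 1000)
    n_keep = (post + thin - 1) // thin

    seeds = np.random.SeedSequence(config.seed).spawn(config.runs)
    runs = [
        _run_single_chain(mach, config, np.random.default_rng(s), n_keep, thin, burnin)
        for s in seeds
    ]
    nmin = min(len(r["alpha"]) for r in runs)
    out = PosteriorDraws(
        tree=tree,
        internal_nodes=mach.internal,
        alpha=np.stack([r["alpha"][:nmin] for r in runs]),
        c=np.stack([r["c"][:nmin] for r in runs]),
        root=np.stack([r["root"][:nmin] for r in runs]),
        loglik=np.stack([r["loglik"][:nmin] for r in runs]),
        nodes=np.stack([r["nodes"][:nmin] for r in runs]),
        config=config,
        tip_values=dict(traits.working_values),
    )
    if config.runs >= 2 and nmin >= 10:
        names = ["c", "root", "loglik"] + (["alpha"] if config.alpha_fixed is None else [])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out.psrf = {nm: psrf(getattr(out, nm)) for nm in names}
        out.converged = all(v < config.psrf_target for v in out.psrf.values())
        if not out.converged:
            warnings.warn(
                f"PSRF target {config.psrf_target} not reached: "
                + ", ".join(f"{k}={v:.4f}" for k, v in out.psrf.items())
            )
    return out
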