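# Methods

## Model

Body mass is analyzed on the log10-kg scale. On a rooted
time-calibrated phylogeny (branch lengths in Myr; fossil tips may end
above the present), the trait evolves along each branch by an
independent, symmetric, mean-zero increment from an alpha-stable law.
The model is parameterized by

* **alpha** — the stability index, in (1.05, 2]. At alpha = 2 the
  increments are Gaussian and the model is exactly Brownian motion
  (BM); as alpha decreases, the increment law keeps a Gaussian-like
  core but gains power-law tails, so occasional branch-sized bursts
  coexist with gradual change.
* **c** — the dispersion per Myr^(1/alpha), on the log10-kg scale.
* **x_root** — the trait value at the root, plus one latent value per
  internal node (data augmentation).

The density convention is fixed by the characteristic function
`E[exp(ikX)] = exp(-(scale*|k|)^alpha)`, so alpha = 2 gives variance
`2*scale^2` (the BM rate is `sigma2 = 2 c^2`) and alpha = 1 is Cauchy.
Stability closure forces the branch scale to aggregate as
`scale(t) = c * t^(1/alpha)`; this is the only scaling consistent with
subdividing a branch. The joint likelihood of tip data and node states
is the product of per-edge increment densities; at alpha = 2,
marginalizing the node states analytically (Felsenstein pruning)
recovers the Gaussian phylogenetic likelihood, which the test suite
verifies by quadrature on small trees.

Because the mean of the stable law is undefined at alpha <= 1 (and the
ancestral-state problem degenerates), the sampler's support is bounded
below at ALPHA_MIN = 1.05; the density utilities still accept
alpha = 1 for testing against the Cauchy closed form.

## Numerical density

No closed form exists for 1 < alpha < 2, so the density is computed by
inverting the characteristic function:
`f(z) = (1/pi) * Int_0^inf cos(zk) exp(-k^alpha) dk` at standard scale.
Per alpha, the integral is evaluated on a 600-point grid in
asinh(z) over [0, 32] by composite 10-point Gauss–Legendre panels
(the k-space oscillatory kernel is alpha-free and cached once), with
the substitution k = v^3 on [0, 1] to tame the non-smoothness of
k^alpha at zero. Beyond |z| = 30 an 8-term asymptotic power-law series
takes over. Log-densities are interpolated cubically on the uniform
asinh grid. Verified relative accuracy is better than 1e-8 for
|z| <= 50 against adaptive oscillatory quadrature and
scipy.stats.levy_stable (used only as a cross-check, never in the
likelihood path).

## Sampler

Metropolis-within-Gibbs over (alpha, c, node states):

* **Node states** — random-walk updates of every internal node per
  iteration, executed as two vectorized sweeps over the depth-parity
  classes of the tree. Nodes at even and odd depth are never adjacent,
  so simultaneous accept/reject decisions within one class are exact
  single-site Metropolis updates. Per-node proposal widths adapt
  toward 44% acceptance during burn-in only.
* **alpha** — a reflected random walk on a lattice of step 0.0025 over
  (1.05, 2]. The discretization means each visited alpha reuses a
  cached high-accuracy density table; the induced granularity (0.0025)
  is far below the posterior spread of alpha on any realistic dataset.
  Each alpha proposal carries a deterministic log-c compensation that
  preserves the mean per-edge log-scale (a translation with unit
  Jacobian, so the kernel stays valid): alpha and c are strongly
  ridge-correlated, and the compensated move cuts the autocorrelation
  time of the pair by an order of magnitude on 150-tip problems.
  In BM mode alpha is fixed at 2 and this move is skipped.
* **c** — a Gaussian random walk on log c.
* **Subtree shifts** — every 10th iteration, all internal values below
  a random node move together, which decorrelates deep nodes.

Priors: alpha uniform on its lattice, log c uniform on (-14, 7), node
states flat. Proposal-width adaptation freezes at the end of burn-in,
so every retained draw comes from a fixed, detailed-balanced kernel.
The full protocol defaults to 4 independent runs of 2,000,000
iterations with 10% burn-in; convergence is reported as the
Gelman–Rubin potential scale reduction factor (PSRF) of alpha, c, the
root state and the log-likelihood across runs, with target 1.01.
Initialization is a two-pass midpoint recursion (post-order child
means, pre-order parent smoothing), alpha = 1.5, and c from the
independent-contrasts moment estimate.

Correctness is tested three ways: seeded determinism; BM-mode root
posterior mean vs the GLS phylogenetic mean; and agreement of the
posterior mean and spread with a brute-force two-dimensional grid
posterior on a 5-tip star.

## Model comparison

Model fit is summarized by a Bayesian predictive information
criterion, operationalized as `BPIC = Dbar + 2 pD` where
`Dbar = -2 E_post[log L]` and `pD = Dbar - D(theta_hat)` with
`theta_hat` the posterior mean of (alpha, c, node states); the
`Dbar + pD` (DIC) variant is selectable. The comparison statistic is
`delta = BPIC(BM) - BPIC(stable)`; positive values favor the
heavy-tailed model, and an exact tie goes to BM (fewer free
parameters). Because only a plug-in bias estimate is available, delta
magnitudes are comparable across variants only to rough accuracy; the
sign and ordering are the robust outputs.

## Branch rates

For each edge, the raw rate is the posterior median of the squared
increment divided by the branch duration,
`r_e = median[(dx_e)^2] / t_e`, a variance-like quantity matching BM
dimensional analysis. Multipliers `m_e = r_e / median_e(r_e)` are
normalized by the tree-wide median, so the median multiplier is 1 by
construction and values read as "x times the original branch length".
Multipliers are invariant to shifting all log-masses by a constant.
A rate-through-time curve averages multipliers in 20 equal-width age
bins, weighting each edge by its overlap with the bin; the
duration-weighted curve mean equals the duration-weighted mean
multiplier. The maximum-rate branch is the argmax edge, ties broken
toward the longer branch. Whether squared or absolute increments, and
median or mean normalization, best matches other implementations is
not determinable from published descriptions; the argmax branch and
the order of magnitude of the top multipliers are the stable outputs.

## Fossil and outgroup experiments

* **Fossil contrast** — the same model is fitted to the fossil-bearing
  tree and to the tree with all fossil tips pruned (tips with age
  > 1e-3 Myr; degree-2 nodes are suppressed with durations summed, and
  a root left with one child keeps its stem so extant root-to-tip
  distances are conserved exactly). The contrast reports the ratio of
  root medians, the ratio of 95%-interval widths on the log scale, and
  whether the maximum-rate branch selects the same extant clade.
* **Pseudo-outgroup grafting** — prior knowledge of the ancestral mass
  is encoded by a grafted outgroup tip: a new root whose children are
  the focal root (stem 4.99 Myr) and a pendant tip of 0.01 Myr
  carrying the prescribed mass, i.e. 5 Myr total separation. Published
  descriptions of this construction are ambiguous about whether 5 Myr
  is the stem or the total separation, so both readings are selectable
  (`sep_is_stem`); the default satisfies both printed numbers.
  The sweep refits the model for outgroup masses
  {0.1, 0.5, 1, 5, 10, 20} kg and reports the *focal* root's
  posterior, not the grafted root's.

Root summaries are posterior medians with 2.5%/97.5% quantile
intervals computed on the log10 scale and back-transformed to kg
(never means of kg values, which would be scale-inconsistent); highest
-posterior-density intervals are not implemented.

## Synthetic data

The generator emulates a mid-sized mammalian clade with fossils:

* **Trees** — constant-rate birth–death (defaults birth 0.065/Myr,
  death 0.03/Myr), grown forward from two lineages and stopped at the
  birth event that first reaches `n_extant` standing species, so
  extant tips have age 0 and the root age is a sum of exponential
  waiting times (closed-form mean under pure birth, used as the test
  oracle). Extinct lineages are uniformly subsampled as dated fossil
  tips to reach the requested fossil fraction; the rest are pruned.
  Defaults give root ages of roughly 80–130 Myr for 77 extant tips.
* **Traits** — exact stable increments (Chambers–Mallows–Stuck) from a
  root of 0.1 kg (log10 = -1) with alpha = 1.77 and c = 0.06 per
  Myr^(1/alpha), spanning 4+ orders of magnitude of mass across the
  tips. An optional rate shift multiplies dispersion-squared by
  `shift_fold` on the stem of a selected (or automatically chosen,
  moderate-sized) clade.
* **The reference scenario** (`afrotheria_like_scenario`) has 77
  extant + 20 fossil tips and a 100-fold dispersion-squared shift on
  one stem. It is *conditioned* on the shift being expressed: the stem
  deviate is positive and at least 1.5 log10 units, and the stem's
  realized squared-increment rate is the largest in the tree. Under
  heavy tails an unconditioned shifted branch would carry the largest
  realized rate only ~40% of the time (background branches draw large
  jumps too), so recovery experiments would measure the luck of the
  draw; the conditioning pins the scenario to the phenomenon it
  emulates — a conspicuous, dominant burst producing a large-bodied
  clade — making recovery rates a statement about the inference.

What the generator does not emulate: fossilized-birth–death sampling
(fossils are uniform over extinct lineages), measurement error in
masses, topological or dating uncertainty in the input tree, and
non-stable forms of rate variation. Passing recovery tests therefore
show that the estimator works when its model and tree are correct, not
that real chronograms and mass compilations satisfy those conditions.

## Problem sizes and runtime choices

Tests and the acceptance script run the protocol at reduced scale,
chosen so posterior medians and interval coverage are stable on
synthetic data of this size: typically 2 runs of 12,000 iterations
(10% burn-in, ~1000 retained draws per run) for 97-tip datasets, and
30,000 iterations for the 150-tip stability-index coverage study,
where the (alpha, c) pair mixes more slowly. PSRF values on these runs
are typically below 1.03 but not always below the full-protocol target
of 1.01; convergence flags are reported, not suppressed. Degenerate
inputs are handled by construction: internal edges shorter than 1e-8
Myr are collapsed into polytomies at read time (pendant edges exempt,
so fossils attached by very short edges survive), non-positive
durations are rejected, and increment drift in the sampler's cached
state is eliminated by periodic exact recomputation.

## Known limitations

* The likelihood targets the augmented joint (states + parameters);
  no marginal-likelihood or Bayes-factor machinery is provided.
* BPIC bias correction is plug-in (DIC-style); magnitudes of delta
  BPIC are approximate whenever the posterior is far from Gaussian.
* Skewed stable laws, Ornstein–Uhlenbeck attraction and trend models
  are out of scope.
* The sampler's alpha lattice bounds inference away from alpha <= 1.05
  by design; data genuinely favoring alpha near 1 will pile up at the
  boundary.
* Frequentist coverage of the 90% credible interval for alpha is
  about 80% (not 90%) in the 150-tip synthetic regime — a finite-n
  effect compounded by the hard alpha <= 2 boundary; the misses are
  dataset-level, not sampler artifacts (intervals are unchanged by
  longer chains at PSRF ~ 1.00).
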