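# stabletrees

Bayesian ancestral state reconstruction on time-calibrated phylogenies
under heavy-tailed trait evolution.

## The problem

Reconstructing ancestral body mass from a phylogeny and present-day
(plus fossil) masses is notoriously model-sensitive. The standard
Brownian-motion (BM) model assumes gradual Gaussian change at a single
rate, so a clade that got large in one burst — elephants among
otherwise shrew-sized relatives — drags the inferred ancestor upward.
`stabletrees` implements the heavy-tailed alternative: trait increments
on each branch follow a symmetric, mean-zero **alpha-stable** law,

    E[exp(ik X_e)] = exp(-(c * t_e^(1/alpha) * |k|)^alpha),

where `t_e` is the branch duration (Myr), `c` the dispersion, and
`alpha` in (1, 2] the stability index. At `alpha = 2` this is exactly
BM with rate `sigma2 = 2 c^2`; at `alpha < 2` rare branch-sized jumps
coexist with gradual change, so a single burst no longer inflates the
root estimate. Masses are analyzed as log10 kg.

The package provides, for rooted chronograms with or without fossil
tips (Newick/NEXUS + a species,mass_kg table):

* exact/numeric stable densities and BM (pruning) likelihoods;
* an MCMC sampler for the joint posterior of `(alpha, c, ancestral
  states)`, with multi-run Gelman-Rubin (PSRF) convergence reporting
  and a BM-constrained mode (`alpha` fixed to 2);
* model comparison by BPIC (`Dbar + 2 pD`); `delta = BPIC(BM) -
  BPIC(stable) > 0` favors the heavy-tailed model;
* per-branch evolutionary **rate multipliers** relative to the input
  chronogram ("x times the original branch length") and
  rate-through-time curves;
* fossil-inclusion contrasts and **pseudo-outgroup grafting** (a dated
  tip of prescribed mass near the root, encoding prior knowledge of
  ancestral size) with a mass-sweep sensitivity analysis;
* a synthetic-data generator (birth-death chronograms with fossil
  tips, exact stable increments, planted rate shifts) with full truth
  records, so every stage is testable without external data.

## Worked example

`examples/02_model_comparison.py` simulates a 97-tip fossil-bearing
clade whose log-mass evolved heavy-tailed (`alpha = 1.77`) from a
0.1 kg root with one stem branch at 100x the background
dispersion-squared, then fits both models:

```
true root 0.10 kg, true alpha 1.77
stable: root 0.081 kg (0.024 - 0.335), Dbar -32.7, pD 110.7, BPIC 188.8
    bm: root 0.087 kg (0.015 - 0.548), Dbar 81.0, pD 96.3, BPIC 273.6
delta BPIC = 84.8 -> best model: stable
```

The stable fit recovers the small ancestor with the truth inside the
95% interval, and the positive delta BPIC selects the heavy-tailed
model. `examples/03_branch_rates.py` then locates the planted burst:

```
planted shift stem: node 32 (29 descendant tips)
max-rate branch:    node 32 (29 descendant tips), 296.5x the original branch length
recovered: True
tree-wide median multiplier (by construction): 1.0
```

and `examples/04_fossils_and_outgroups.py` shows the fossil-removal
contrast (intervals widen when fossils are dropped) and the
pseudo-outgroup sweep (a matched 0.1 kg outgroup tightens the root
interval to 0.053-0.321 kg without biasing it; even a 20 kg outgroup
leaves the estimate small). Each example prints what its numbers mean;
all run from a fresh checkout with no external inputs.

A thin CLI mirrors the library (`stabletrees fit / compare / rates /
simulate / pipeline`); see `stabletrees --help`.

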