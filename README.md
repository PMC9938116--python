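# mefkit

Maximum-entropy analysis of community assembly: what do functional traits,
and what does the surrounding regional species pool, tell us about who is
locally abundant?

`mefkit` implements the CATS-style (Community Assembly via Trait Selection)
maximum-entropy model for plot-level relative abundances, together with the
information decomposition, selection inference and spatial-scaling analyses
built on top of it.  It is written for community ecologists working with
plot-by-taxon count tables (e.g. forest inventories), a taxon-by-trait
table, and plot coordinates/habitat labels.  Because large inventory
networks are typically available only on request, the package ships a
first-class synthetic-community generator with known ground truth, so every
stage of the pipeline is testable end to end.

## The model

For a plot with observed relative abundances `o_i` over S genera, the
predicted distribution is the one minimizing the Kullback–Leibler
divergence from a prior `q` subject to community-weighted-mean (CWM) trait
constraints:

    p_i = q_i · exp(Σ_j λ_j t_ij) / Z(λ),     Σ_i p_i t_ij = T̄_j,

where `t_ij` is the value of trait j for genus i, `T̄_j = Σ_i t_ij o_i` is
the plot's CWM, and the Lagrange multipliers `λ_j` are found on the convex
dual (damped Newton with log-sum-exp stabilization; traits standardized
internally, multipliers reported in raw-trait units).  Each multiplier is a
selection gradient: `∂p_i/∂t_ij = λ_j p_i (1 − p_i)`.

Goodness of fit is the Kullback–Leibler R²,
`R²_KL = 1 − D_KL(o‖p) / D_KL(o‖u)` with `u` uniform.  Four models are
fitted per plot — permuted constraints × {uniform, metacommunity} prior and
observed constraints × {uniform, metacommunity} prior — and their R² values
decompose the information in the observed abundances into **pure trait**,
**pure metacommunity**, **joint**, **bias** (what any CWM-shaped constraint
set explains by construction) and **unexplained** fractions that sum to
one.  Growing the regional pool in concentric distance rings and refitting
measures how far the metacommunity's influence reaches; the decline is
summarized by an asymptotic exponential decay
`y(t) = y_f + (y_0 − y_f)·exp(−exp(log α)·t)`.

Missing trait values are filled by chained-equation predictive mean
matching (PMM) with optional delta adjustment for sensitivity analysis.

## Worked example

Generate a community under strong selection on one trait *and* limited
migration, then decompose the information and test the multipliers:

```python
import warnings
from dataclasses import replace
from mefkit import (scenario_presets, generate_scenario, decompose_dataset,
                    collect_lambdas, anova_by_trait)

config = replace(scenario_presets()["filtering_limited"], seed=42)
dataset, truth = generate_scenario(config)
table, fits = decompose_dataset(dataset, n_perm=10, seed=42, keep_fits=True)

print(table[["pure_trait", "pure_metacommunity", "joint", "bias",
             "unexplained"]].mean().round(3))
lambdas = collect_lambdas({p: f.trait_fit for p, f in fits.items()},
                          dataset.metadata)
print(anova_by_trait(lambdas)[["F", "p_raw", "p_holm", "mean_lambda"]].round(3))
```

prints

```
pure_trait            0.000
pure_metacommunity    0.057
joint                 0.425
bias                  0.510
unexplained           0.008
               F  p_raw  p_holm  mean_lambda
trait
trait_c1  58.094  0.000   0.000        4.006
trait_c2  29.220  0.000   0.000       -0.518
trait_c3   0.593  0.557   1.000       -0.117
trait_b1   1.902  0.161   0.482        1.058
trait_b2   0.353  0.704   1.000       -1.498
```

Reading this: the hybrid model leaves almost nothing unexplained (0.008),
but hardly any information is *uniquely* attributable to traits — under
limited migration the regional pool already carries the selection signature,
so trait and metacommunity information are almost entirely shared (joint +
bias).  The multiplier ANOVA still identifies the truly selected trait:
`trait_c1` (the one with nonzero selection strength in the scenario's
ground truth) has the largest F across forest types and a strongly positive
mean λ, while λ for the neutral traits is indistinguishable between types
after Holm correction.

The same analyses are available from the shell:

```bash
mefkit simulate --preset filtering_limited --seed 42 --out data/
mefkit decompose --abundance data/abundance.csv --traits data/traits.csv \
    --metadata data/metadata.csv --n-perm 50 --seed 1 --out results/
mefkit radius --abundance data/abundance.csv --traits data/traits.csv \
    --metadata data/metadata.csv --step-km 50 --n-perm 2 --seed 1 --out results/
mefkit run --config config.yaml        # full pipeline with manifests
```

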