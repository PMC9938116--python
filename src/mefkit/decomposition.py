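"""Four-step model comparison and decomposition of explained information.

For each plot four maximum-entropy models are fitted:

1. uniform prior, randomly permuted trait constraints (model bias);
2. uniform prior, observed CWM constraints (trait model);
3. metacommunity prior, permuted constraints (metacommunity model);
4. metacommunity prior, observed constraints (hybrid model).

Goodness of fit is the Kullback-Leibler R-squared

    R2_KL = 1 - D_KL(o || p) / D_KL(o || u),

with ``o`` the observed, ``p`` the predicted and ``u`` the uniform relative
abundances on the analysis support.  All four models share the uniform
reference ``u`` so their R2 values are directly comparable and the
partition below is coherent.  The explained information is decomposed into

    bias                = R2(permuted, uniform prior)
    pure trait          = R2(hybrid) - R2(metacommunity)
    pure metacommunity  = R2(hybrid) - R2(trait)
    joint               = R2(trait) + R2(metacommunity) - R2(hybrid) - bias
    unexplained         = 1 - R2(hybrid)

which sums to one by construction.  Components may come out (slightly)
negative; they are reported raw, truncation being a presentation choice.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import AlignedDataset, PlotMetadata
from .maxent import (ConstraintSpec, InfeasibleConstraints, MaxEntFit, Prior,
                     kl_divergence, permute_traits, solve_maxent)
from .traits import cwm, relative_abundances

logger = logging.getLogger("mefkit")

__all__ = [
    "ModelFitSet",
    "Decomposition",
    "r2_kl",
    "build_metacommunity_prior",
    "constraint_matrix",
    "four_step",
    "decompose",
    "decompose_dataset",
    "rarefy_bootstrap",
    "summarize_by_forest_type",
    "COMPONENTS",
]

#: Canonical component order of the information partition.
COMPONENTS = ("pure_trait", "pure_metacommunity", "joint", "bias", "unexplained")

#: Default pseudocount, as a fraction of total prior mass, for genera
#: observed in the focal plot but absent from the regional pool.
DEFAULT_EPSILON = 1e-6


def r2_kl(observed, predicted, reference=None) -> float:
    """Kullback-Leibler R2 of a prediction against a reference distribution.

    ``1 - D_KL(o||p) / D_KL(o||u)`` with the ``0 * log(0/x) = 0``
    convention.  Returns NaN (flagged undefined) when the observed
    distribution equals the reference, i.e. the denominator vanishes.
    """
    o = np.asarray(observed, float)
    p = np.asarray(predicted, float)
    u = (np.full_like(o, 1.0 / len(o)) if reference is None
         else np.asarray(reference, float))
    d_ref = kl_divergence(o, u)
    if d_ref <= 0.0:
        return float("nan")
    return 1.0 - kl_divergence(o, p) / d_ref


@dataclass
class ModelFitSet:
    """Per-plot R2_KL of the four models (permutation arms averaged)."""

    plot_id: str
    r2_bias_uniform: float
    r2_trait: float
    r2_meta: float
    r2_hybrid: float
    n_permutations: int
    trait_fit: MaxEntFit | None = None
    hybrid_fit: MaxEntFit | None = None
    degenerate: bool = False


@dataclass
class Decomposition:
    """Information partition for one plot (raw fractions, may be negative)."""

    plot_id: str
    pure_trait: float
    pure_metacommunity: float
    joint: float
    bias: float
    unexplained: float

    def as_series(self) -> pd.Series:
        return pd.Series({c: getattr(self, c) for c in COMPONENTS},
                         name=self.plot_id)


def build_metacommunity_prior(abund, plot_set, focal: str,
                              epsilon: float = DEFAULT_EPSILON,
                              exclude_focal: bool = False) -> Prior:
    """Prior from summed counts over a plot set, pseudocounting focal genera.

    ``q_i`` is proportional to the summed count of genus i over
    ``plot_set`` (optionally excluding the focal plot itself); genera
    observed in the focal plot but absent from that pool receive a
    pseudocount ``epsilon`` (fraction of total mass) so the focal plot's
    support is always covered and divergences stay finite.
    """
    counts = abund.counts
    plot_set = [p for p in plot_set if not (exclude_focal and p == focal)]
    if not plot_set:
        raise ValueError("empty plot set for metacommunity prior")
    pooled = counts.loc[plot_set].sum(axis=0).astype(float)
    total = pooled.sum()
    if total <= 0:
        raise ValueError("metacommunity pool has zero total count")
    q = pooled / total
    focal_obs = counts.loc[focal] > 0
    needs_mass = focal_obs & (q <= 0)
    if needs_mass.any():
        q = q.copy()
        q[needs_mass] = epsilon
        q = q / q.sum()
    return Prior(q)


def constraint_matrix(dataset: AlignedDataset, constrained_traits=None) -> pd.DataFrame:
    """Trait matrix used as maxent constraints, complete over all genera.

    Genera carrying counts but no trait data (``prior_only_genera``) enter
    with the column mean — a selection-neutral value that leaves their
    predicted abundance governed by the prior alone.
    """
    values = dataset.traits.values
    if constrained_traits is not None:
        values = values[list(constrained_traits)]
    if values.isna().any().any():
        filled = values.fillna(values.mean())
        n = int(values.isna().sum().sum())
        logger.info("filled %d missing constraint cells with trait means "
                    "(prior-only genera)", n)
        values = filled
    return values


def four_step(dataset: AlignedDataset, plot_id: str,
              meta_prior: Prior, constrained_traits=None,
              n_perm: int = 50, seed=None, tol: float = 1e-8,
              keep_fits: bool = True) -> ModelFitSet:
    """Fit the four models for one plot and average the permutation arms.

    Each permutation shuffles whole trait vectors among genera and
    recomputes the CWM targets from the shuffled assignment, i.e. the
    genus-trait combinations are randomized while the community stays
    fixed.  Under neutral assembly the permuted and observed constraint
    sets are then exchangeable, so the permutation arms measure exactly the
    self-information any CWM constraint set extracts from the plot's own
    composition (the model bias).  The same ``n_perm`` permutations (drawn
    from ``seed``) are reused in the uniform-prior and metacommunity-prior
    arms, reducing the Monte-Carlo noise of their difference.
    """
    rng = np.random.default_rng(seed)
    ra = relative_abundances(dataset.abundance)
    o = ra.loc[plot_id]
    traits_m = constraint_matrix(dataset, constrained_traits)
    targets = pd.Series(o.to_numpy() @ traits_m.to_numpy(), index=traits_m.columns)
    spec = ConstraintSpec(traits=traits_m, targets=targets)
    uniform = Prior.uniform(dataset.genus_ids)
    u = np.full(len(o), 1.0 / len(o))

    degenerate = (o > 0).sum() <= 1
    d_ref = kl_divergence(o.to_numpy(), u)
    if degenerate or d_ref <= 0:
        # single-genus or uniform plot: all models trivially exact/undefined
        val = 1.0 if degenerate else float("nan")
        return ModelFitSet(plot_id=plot_id, r2_bias_uniform=val, r2_trait=val,
                           r2_meta=val, r2_hybrid=val, n_permutations=n_perm,
                           degenerate=True)

    def fit_r2(prior: Prior, s: ConstraintSpec) -> tuple[float, MaxEntFit]:
        fit = solve_maxent(prior, s, tol=tol)
        return r2_kl(o.to_numpy(), fit.p.to_numpy(), u), fit

    r2_t, trait_fit = fit_r2(uniform, spec)
    r2_h, hybrid_fit = fit_r2(meta_prior, spec)

    bias_vals, meta_vals = [], []
    for _ in range(n_perm):
        shuffled = permute_traits(spec, rng).traits
        perm_targets = pd.Series(o.to_numpy() @ shuffled.to_numpy(),
                                 index=shuffled.columns)
        perm_spec = ConstraintSpec(traits=shuffled, targets=perm_targets)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                bias_vals.append(fit_r2(uniform, perm_spec)[0])
                meta_vals.append(fit_r2(meta_prior, perm_spec)[0])
        except InfeasibleConstraints:
            logger.warning("plot %s: infeasible permutation dropped", plot_id)
    if not bias_vals:
        raise RuntimeError(f"plot {plot_id}: no feasible trait permutation")

    return ModelFitSet(
        plot_id=plot_id,
        r2_bias_uniform=float(np.mean(bias_vals)),
        r2_trait=float(r2_t),
        r2_meta=float(np.mean(meta_vals)),
        r2_hybrid=float(r2_h),
        n_permutations=len(bias_vals),
        trait_fit=trait_fit if keep_fits else None,
        hybrid_fit=hybrid_fit if keep_fits else None,
    )


def decompose(fits: ModelFitSet) -> Decomposition:
    """Partition explained information into the five additive components."""
    bias = fits.r2_bias_uniform
    pure_trait = fits.r2_hybrid - fits.r2_meta
    pure_meta = fits.r2_hybrid - fits.r2_trait
    joint = fits.r2_trait + fits.r2_meta - fits.r2_hybrid - bias
    unexplained = 1.0 - fits.r2_hybrid
    return Decomposition(
        plot_id=fits.plot_id,
        pure_trait=pure_trait,
        pure_metacommunity=pure_meta,
        joint=joint,
        bias=bias,
        unexplained=unexplained,
    )


def decompose_dataset(dataset: AlignedDataset, constrained_traits=None,
                      n_perm: int = 50, seed=None,
                      prior_scope: str = "all", radius_km: float | None = None,
                      exclude_focal: bool = False,
                      epsilon: float = DEFAULT_EPSILON,
                      keep_fits: bool = False,
                      ) -> tuple[pd.DataFrame, dict[str, ModelFitSet]]:
    """Run the four-step model and decomposition for every plot.

    ``prior_scope`` selects which plots feed each focal plot's
    metacommunity prior: ``"all"`` (whole dataset), ``"forest-type"``
    (plots sharing the focal plot's label) or ``"radius"`` (plots within
    ``radius_km`` great-circle km; see :mod:`mefkit.scaling`).

    Returns a plots x components DataFrame (plus the four R2 columns) and
    the per-plot :class:`ModelFitSet`.
    """
    from .scaling import haversine_km  # local import to avoid cycle

    meta = dataset.metadata.table
    root = np.random.SeedSequence(seed)
    plot_seeds = root.spawn(len(dataset.plot_ids))
    rows, fitsets = [], {}
    for k, plot in enumerate(dataset.plot_ids):
        if prior_scope == "all":
            pool = list(dataset.plot_ids)
        elif prior_scope == "forest-type":
            ft = meta.loc[plot, "forest_type"]
            pool = meta.index[meta["forest_type"] == ft].tolist()
        elif prior_scope == "radius":
            if radius_km is None:
                raise ValueError("radius_km required for prior_scope='radius'")
            d = haversine_km(meta.loc[plot, "latitude"], meta.loc[plot, "longitude"],
                             meta["latitude"].to_numpy(), meta["longitude"].to_numpy())
            pool = meta.index[d <= radius_km].tolist()
        else:
            raise ValueError(f"unknown prior scope {prior_scope!r}")
        prior = build_metacommunity_prior(dataset.abundance, pool, plot,
                                          epsilon=epsilon,
                                          exclude_focal=exclude_focal)
        fits = four_step(dataset, plot, prior, constrained_traits,
                         n_perm=n_perm, seed=plot_seeds[k],
                         keep_fits=keep_fits)
        fitsets[plot] = fits
        dec = decompose(fits)
        rows.append({"plot_id": plot, **{c: getattr(dec, c) for c in COMPONENTS},
                     "r2_bias_uniform": fits.r2_bias_uniform,
                     "r2_trait": fits.r2_trait, "r2_meta": fits.r2_meta,
                     "r2_hybrid": fits.r2_hybrid,
                     "degenerate": fits.degenerate})
    table = pd.DataFrame(rows).set_index("plot_id")
    return table, fitsets


def rarefy_bootstrap(decompositions: pd.DataFrame, metadata: PlotMetadata,
                     n_plots: int = 28, reps: int = 25, seed=None,
                     group_col: str = "forest_type") -> pd.DataFrame:
    """Rarefy groups to a common plot count and bootstrap the group means.

    Each repetition samples ``n_plots`` plots per group *without*
    replacement and recomputes group means of every component, removing
    sample-size artefacts from between-group comparisons.
    """
    rng = np.random.default_rng(seed)
    groups = metadata.table.loc[decompositions.index, group_col]
    sizes = groups.value_counts()
    too_small = sizes.index[sizes < n_plots].tolist()
    if too_small:
        raise ValueError(f"groups smaller than n_plots={n_plots}: {too_small}")
    rows = []
    for rep in range(reps):
        for g, size in sizes.items():
            members = decompositions.index[groups == g]
            take = rng.choice(len(members), size=n_plots, replace=False)
            sub = decompositions.loc[members[np.sort(take)], list(COMPONENTS)]
            rows.append({"rep": rep, group_col: g, **sub.mean().to_dict()})
    return pd.DataFrame(rows)


def summarize_by_forest_type(decompositions: pd.DataFrame,
                             metadata: PlotMetadata) -> pd.DataFrame:
    """Mean/median/quartiles of each component per forest type."""
    groups = metadata.table.loc[decompositions.index, "forest_type"]
    out = []
    for g, sub in decompositions.groupby(groups):
        for comp in COMPONENTS:
            col = sub[comp]
            out.append({
                "forest_type": g, "component": comp,
                "n_plots": len(col),
                "mean": col.mean(), "median": col.median(),
                "q25": col.quantile(0.25), "q75": col.quantile(0.75),
            })
    frame = pd.DataFrame(out)
    frame["component"] = pd.Categorical(frame["component"], categories=COMPONENTS,
                                        ordered=True)
    return frame.sort_values(["forest_type", "component"]).reset_index(drop=True)
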