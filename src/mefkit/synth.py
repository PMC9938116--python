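"""Synthetic metacommunities with known assembly ground truth.

The generator emulates the structure of a large tropical-forest inventory —
a skewed regional abundance distribution over genera, genus-level trait
vectors (continuous and binary), and spatially located plots in discrete
habitat types — and assembles local communities under two independently
tunable forces:

* **trait selection**: per-plot multinomial sampling weights are tilted by
  ``exp(beta_j * z_ij * e_jk)``, with ``z`` the standardized trait value and
  ``e_jk`` a smooth spatial environment field (mean 1), so ``beta_j > 0``
  imposes region-wide directional selection whose local strength varies in
  space and with habitat;
* **dispersal limitation**: the effective local pool is the mixture
  ``m * q_star + (1 - m) * neighbourhood``, where the neighbourhood
  composition is a Gaussian-kernel average of the realized compositions of
  surrounding plots.  ``m = 1`` is the infinite-migration limit; small
  ``m`` lets sampling drift propagate between neighbours, producing the
  spatially clustered compositions that distance-decay analyses measure.

Four named presets cover the crossed scenarios of neutral vs deterministic
dynamics under infinite vs limited migration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import AbundanceTable, PlotMetadata, TraitTable, align_dataset

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "generate_metacommunity",
    "generate_traits",
    "assemble_local_communities",
    "generate_scenario",
    "scenario_presets",
]

# Reference point for converting the simulation grid (km) to coordinates:
# central Amazonia, where one degree is ~111 km.
_BASE_LAT = -5.0
_BASE_LON = -65.0
_KM_PER_DEG = 111.32


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic assembly scenario.

    Defaults describe a desk-scale regional system: 100 genera, 50 one-ha
    plots of 500 stems on a 500 km square, three continuous and two binary
    traits, a lognormal rank-abundance distribution (sdlog 1.5, a typical
    skew for tropical tree communities) and an environment field with a
    150 km correlation length binned into three forest types.
    """

    name: str = "custom"
    n_genera: int = 100
    n_plots: int = 50
    individuals_per_plot: int = 500
    n_continuous_traits: int = 3
    n_binary_traits: int = 2
    metacommunity: str = "lognormal"     # or "logseries"
    lognormal_sdlog: float = 1.5
    logseries_theta: float = 0.995
    trait_correlation: float = 0.3
    binary_prob: float = 0.3
    missing_fraction: float = 0.0
    selection_strengths: tuple[float, ...] = ()   # beta_j, one per trait
    migration: float = 1.0                        # m in (0, 1]
    grid_km: float = 500.0
    env_length_km: float = 150.0
    env_sd: float = 0.5
    kernel_km: float = 250.0
    n_mixing_sweeps: int = 5
    landscape_drift_sigma: float = 1.0
    drift_length_km: float = 1000.0
    n_forest_types: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genera, self.n_plots, self.individuals_per_plot) <= 0:
            raise ValueError("S, K and J must be positive")
        if not (0.0 < self.migration <= 1.0):
            raise ValueError("migration m must lie in (0, 1]")
        n_traits = self.n_continuous_traits + self.n_binary_traits
        beta = self.selection_strengths or (0.0,) * n_traits
        if len(beta) != n_traits:
            raise ValueError(f"need {n_traits} selection strengths, got {len(beta)}")
        if not np.all(np.isfinite(beta)):
            raise ValueError("selection strengths must be finite")
        object.__setattr__(self, "selection_strengths", tuple(float(b) for b in beta))

    @property
    def n_traits(self) -> int:
        return self.n_continuous_traits + self.n_binary_traits

    @property
    def trait_ids(self) -> list[str]:
        return ([f"trait_c{i + 1}" for i in range(self.n_continuous_traits)]
                + [f"trait_b{i + 1}" for i in range(self.n_binary_traits)])


@dataclass
class GroundTruth:
    """True generative quantities, for recovery tests."""

    q_star: pd.Series
    traits: pd.DataFrame
    beta: pd.Series
    migration: float
    environment: pd.DataFrame | None = None      # plots x traits loadings
    effective_priors: pd.DataFrame | None = None  # plots x genera q_eff

    def to_dict(self) -> dict:
        return {
            "migration": self.migration,
            "beta": {k: float(v) for k, v in self.beta.items()},
            "q_star": {k: float(v) for k, v in self.q_star.items()},
        }


def _streams(config: ScenarioConfig) -> dict[str, np.random.Generator]:
    """Named independent RNG streams derived from the one root seed."""
    root = np.random.SeedSequence(config.seed)
    names = ("metacommunity", "traits", "layout", "environment", "assembly")
    return {n: np.random.default_rng(s) for n, s in zip(names, root.spawn(len(names)))}


def generate_metacommunity(config: ScenarioConfig,
                           rng: np.random.Generator) -> pd.Series:
    """Regional relative abundances q*, sorted descending over genus ids."""
    S = config.n_genera
    if config.metacommunity == "lognormal":
        raw = rng.lognormal(mean=0.0, sigma=config.lognormal_sdlog, size=S)
    elif config.metacommunity == "logseries":
        raw = stats.logser.rvs(config.logseries_theta, size=S,
                               random_state=rng).astype(float)
    else:
        raise ValueError(f"unknown metacommunity family {config.metacommunity!r}")
    raw = np.sort(raw)[::-1]
    ids = [f"G{i + 1:04d}" for i in range(S)]
    return pd.Series(raw / raw.sum(), index=ids, name="q_star")


def generate_traits(config: ScenarioConfig, rng: np.random.Generator,
                    genus_ids=None) -> tuple[TraitTable, pd.DataFrame]:
    """Genus trait table (optionally MCAR-masked) plus the complete truth.

    Continuous traits are equicorrelated multivariate normal (unit scale);
    binary traits are independent Bernoulli mapped onto the {1, 2} coding.
    """
    S = config.n_genera
    ids = list(genus_ids) if genus_ids is not None else [f"G{i + 1:04d}"
                                                         for i in range(S)]
    nc, nb = config.n_continuous_traits, config.n_binary_traits
    cols = {}
    if nc:
        r = config.trait_correlation
        cov = np.full((nc, nc), r)
        np.fill_diagonal(cov, 1.0)
        cont = rng.multivariate_normal(np.zeros(nc), cov, size=S,
                                       method="cholesky")
        for j in range(nc):
            cols[f"trait_c{j + 1}"] = cont[:, j]
    for j in range(nb):
        cols[f"trait_b{j + 1}"] = np.where(
            rng.random(S) < config.binary_prob, 2.0, 1.0)
    truth = pd.DataFrame(cols, index=ids)

    values = truth.copy()
    if config.missing_fraction > 0:
        mask = rng.random(values.shape) < config.missing_fraction
        # never blank a whole genus: chained equations need one anchor value
        full_rows = mask.all(axis=1)
        if full_rows.any():
            mask[full_rows, 0] = False
        values = values.mask(mask)
    kinds = pd.Series({c: ("binary" if c.startswith("trait_b") else "continuous")
                       for c in truth.columns})
    return TraitTable(values, kinds=kinds), truth


def _grid_coordinates(config: ScenarioConfig,
                      rng: np.random.Generator) -> np.ndarray:
    """Plot positions (km) uniform over the square study region."""
    return rng.random((config.n_plots, 2)) * config.grid_km


def _environment_field(xy: np.ndarray, config: ScenarioConfig,
                       rng: np.random.Generator) -> np.ndarray:
    """Smooth per-trait environment loadings e_jk, mean 1, sd ``env_sd``.

    Gaussian process over plot locations with squared-exponential
    covariance (length scale ``env_length_km``).  The unit mean makes
    selection directional region-wide; ``env_sd`` sets the amplitude of the
    smooth spatial modulation around it, kept below the mean so that a
    deterministic-selection scenario reliably realizes the direction its
    ground truth declares while local strength still varies with habitat.
    """
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
    cov = np.exp(-0.5 * d2 / config.env_length_km ** 2)
    cov[np.diag_indices_from(cov)] += 1e-8
    L = np.linalg.cholesky(cov)
    z = rng.standard_normal((xy.shape[0], config.n_traits))
    return 1.0 + config.env_sd * (L @ z)


def _forest_types(env: np.ndarray, config: ScenarioConfig) -> np.ndarray:
    """Quantile-bin the leading environment axis into habitat labels."""
    lead = env[:, 0] if env.shape[1] else np.zeros(env.shape[0])
    qs = np.quantile(lead, np.linspace(0, 1, config.n_forest_types + 1)[1:-1])
    bins = np.searchsorted(qs, lead)
    return np.array([f"FT{b + 1}" for b in bins])


def assemble_local_communities(
        config: ScenarioConfig, q_star: pd.Series, traits_true: pd.DataFrame,
        rng: np.random.Generator,
) -> tuple[AbundanceTable, PlotMetadata, GroundTruth]:
    """Draw local communities under trait selection and dispersal limitation.

    Sampling weights are ``w_ik \\propto q_eff_ik * exp(sum_j beta_j z_ij
    e_jk)`` with ``q_eff = m q* + (1 - m) * neighbourhood``.  Plots are
    assembled in randomized order; the neighbourhood of a plot is the
    Gaussian-kernel (scale ``kernel_km``) average of the realized relative
    abundances of already-assembled plots, and a second full sweep re-draws
    every plot against the completed landscape so all neighbourhoods are
    well defined.  ``beta = 0`` with ``m = 1`` reduces to i.i.d. multinomial
    sampling from q*.
    """
    S, K, J = config.n_genera, config.n_plots, config.individuals_per_plot
    beta = np.asarray(config.selection_strengths, float)
    m = config.migration

    xy = _grid_coordinates(config, rng)
    env = _environment_field(xy, config, rng)
    ft = _forest_types(env, config)

    # standardized trait scores for the selection kernel
    T = traits_true.loc[q_star.index].to_numpy(float)
    sd = T.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (T - T.mean(axis=0)) / sd

    tilt = np.exp(np.clip(Z @ (beta[None, :] * env).T, -30, 30))  # S x K
    q = q_star.to_numpy()

    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
    kern = np.exp(-0.5 * d2 / config.kernel_km ** 2)
    np.fill_diagonal(kern, 0.0)

    # Deep-time landscape drift: under limited migration the forest matrix
    # surrounding the plots has itself drifted away from the global pool.
    # q_land(x) ~ q* log-normally tilted by a per-genus spatial Gaussian
    # process (length scale drift_length_km, sd landscape_drift_sigma *
    # (1 - m)), so local pools are largely shared across the window while
    # similarity still decays with distance.  The finite plot-to-plot mixture below cannot generate this
    # drift on its own: resampling among ~K plots of J stems averages the
    # noise away almost completely.
    if m < 1.0 and config.landscape_drift_sigma > 0:
        cov = np.exp(-0.5 * d2 / config.drift_length_km ** 2)
        cov[np.diag_indices_from(cov)] += 1e-8
        Lg = np.linalg.cholesky(cov)
        G = Lg @ rng.standard_normal((K, S))
        q_land = q[None, :] * np.exp(config.landscape_drift_sigma * (1.0 - m) * G)
        q_land /= q_land.sum(axis=1, keepdims=True)
    else:
        q_land = np.tile(q, (K, 1))

    comps = np.tile(q, (K, 1))          # realized relative abundances, K x S
    assembled = np.zeros(K, dtype=bool)
    counts = np.zeros((K, S), dtype=np.int64)
    q_eff_final = np.tile(q, (K, 1))

    n_sweeps = 1 if m >= 1.0 else max(2, config.n_mixing_sweeps)
    order = rng.permutation(K)
    for sweep in range(n_sweeps):
        for k in order:
            if m >= 1.0:
                q_eff = q
            else:
                # first sweep: only already-assembled neighbours are defined
                wk = kern[k] * assembled if sweep == 0 else kern[k]
                if wk.sum() > 0:
                    nb = wk @ comps / wk.sum()
                    local = 0.5 * q_land[k] + 0.5 * nb
                else:
                    local = q_land[k]
                q_eff = m * q + (1.0 - m) * local
            w = q_eff * tilt[:, k]
            w = w / w.sum()
            counts[k] = rng.multinomial(J, w)
            comps[k] = counts[k] / J
            assembled[k] = True
            if sweep == n_sweeps - 1:
                q_eff_final[k] = q_eff

    plot_ids = [f"P{k + 1:03d}" for k in range(K)]
    abund = AbundanceTable(pd.DataFrame(counts, index=plot_ids,
                                        columns=q_star.index))
    lat = _BASE_LAT + xy[:, 1] / _KM_PER_DEG
    lon = _BASE_LON + xy[:, 0] / (_KM_PER_DEG * np.cos(np.radians(_BASE_LAT)))
    meta = PlotMetadata(pd.DataFrame({
        "latitude": lat, "longitude": lon, "forest_type": ft,
        "area_ha": np.ones(K),
    }, index=pd.Index(plot_ids, name="plot_id")))
    truth = GroundTruth(
        q_star=q_star,
        traits=traits_true,
        beta=pd.Series(beta, index=traits_true.columns),
        migration=m,
        environment=pd.DataFrame(env, index=plot_ids,
                                 columns=traits_true.columns),
        effective_priors=pd.DataFrame(q_eff_final, index=plot_ids,
                                      columns=q_star.index),
    )
    return abund, meta, truth


def generate_scenario(config: ScenarioConfig):
    """Generate one full dataset (aligned) plus its ground truth."""
    streams = _streams(config)
    q_star = generate_metacommunity(config, streams["metacommunity"])
    trait_table, truth_traits = generate_traits(config, streams["traits"],
                                                genus_ids=q_star.index)
    abund, meta, truth = assemble_local_communities(
        config, q_star, truth_traits, streams["assembly"])
    dataset = align_dataset(abund, trait_table, meta)
    return dataset, truth


def scenario_presets() -> dict[str, ScenarioConfig]:
    """The four canonical assembly scenarios (names are stable API).

    ``filtering`` presets select strongly on the first continuous trait
    (beta = 1.5); ``limited`` presets use migration m = 0.2 so four fifths
    of each local pool comes from the spatial neighbourhood.
    """
    base = dict(n_genera=100, n_plots=50, individuals_per_plot=500,
                n_continuous_traits=3, n_binary_traits=2, seed=0)
    beta_sel = (1.5, 0.0, 0.0, 0.0, 0.0)
    return {
        "neutral_infinite": ScenarioConfig(name="neutral_infinite",
                                           migration=1.0, **base),
        "neutral_limited": ScenarioConfig(name="neutral_limited",
                                          migration=0.2, **base),
        "filtering_infinite": ScenarioConfig(name="filtering_infinite",
                                             migration=1.0,
                                             selection_strengths=beta_sel,
                                             **base),
        "filtering_limited": ScenarioConfig(name="filtering_limited",
                                            migration=0.2,
                                            selection_strengths=beta_sel,
                                            **base),
    }
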