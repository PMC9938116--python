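"""Direction and strength of trait selection from Lagrange multipliers.

Each converged maximum-entropy fit yields one multiplier per constrained
trait and plot.  A positive multiplier means genera with larger trait
values are predicted to be more abundant in that plot (positive selection),
a negative one the opposite; magnitudes are in inverse raw-trait units and
are therefore only comparable *within* a trait, never across traits.
Consequently each trait is analysed separately: a one-way ANOVA of its
multipliers across forest types tests for environment-dependent selection,
and the multiplier-versus-CWM association checks that stronger selection
accompanies larger community-weighted trait values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_io import PlotMetadata
from .maxent import MaxEntFit

__all__ = ["LambdaTable", "collect_lambdas", "anova_by_trait",
           "lambda_cwm_association"]


@dataclass
class LambdaTable:
    """Plots x traits multipliers with forest-type labels (converged fits only)."""

    values: pd.DataFrame          # plots x traits
    forest_type: pd.Series        # per plot
    n_dropped: int = 0            # non-converged fits excluded


def collect_lambdas(fits: dict[str, MaxEntFit],
                    metadata: PlotMetadata) -> LambdaTable:
    """Assemble multipliers across plots, dropping non-converged fits."""
    rows, kept = {}, []
    n_dropped = 0
    for plot, fit in fits.items():
        if fit is None or not fit.converged:
            n_dropped += 1
            continue
        rows[plot] = fit.lambda_
        kept.append(plot)
    if not rows:
        raise ValueError("no converged fits to collect multipliers from")
    if n_dropped:
        warnings.warn(f"excluded {n_dropped} non-converged fits from the "
                      "multiplier table", stacklevel=2)
    values = pd.DataFrame(rows).T.loc[kept]
    ft = metadata.table.loc[values.index, "forest_type"]
    return LambdaTable(values=values, forest_type=ft, n_dropped=n_dropped)


def anova_by_trait(lambdas: LambdaTable, min_group_size: int = 2) -> pd.DataFrame:
    """One-way ANOVA of each trait's multipliers across forest types.

    Types with fewer than ``min_group_size`` plots are dropped with a
    warning.  The F statistic is computed per trait (never pooling traits,
    whose multipliers are on incommensurable scales); raw p-values are
    reported alongside a Holm adjustment across the traits tested.  Zero
    within-group variance with non-zero between-group variance yields an
    infinite F (flagged via ``p_raw = 0``); all-identical multipliers give
    F = 0, p = 1.
    """
    sizes = lambdas.forest_type.value_counts()
    small = sizes.index[sizes < min_group_size].tolist()
    if small:
        warnings.warn(f"dropping forest types with < {min_group_size} plots: "
                      f"{small}", stacklevel=2)
    keep_types = [t for t in sizes.index if t not in small]
    if len(keep_types) < 2:
        raise ValueError("need at least two forest types with enough plots")
    mask = lambdas.forest_type.isin(keep_types)
    vals = lambdas.values.loc[mask]
    ft = lambdas.forest_type.loc[mask]

    rows = []
    for trait in vals.columns:
        groups = [vals.loc[ft == t, trait].to_numpy() for t in sorted(keep_types)]
        k = len(groups)
        n = sum(len(g) for g in groups)
        grand = np.concatenate(groups).mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        df1, df2 = k - 1, n - k
        if ss_between <= 0 and ss_within <= 0:
            F, p = 0.0, 1.0
        elif ss_within <= 0:
            F, p = float("inf"), 0.0
        else:
            F = (ss_between / df1) / (ss_within / df2)
            p = float(stats.f.sf(F, df1, df2))
        rows.append({
            "trait": trait, "F": float(F), "df_between": df1, "df_within": df2,
            "p_raw": p,
            **{f"mean_lambda[{t}]": float(vals.loc[ft == t, trait].mean())
               for t in sorted(keep_types)},
            "mean_lambda": float(vals[trait].mean()),
            "sign": int(np.sign(vals[trait].mean())),
        })
    out = pd.DataFrame(rows).set_index("trait")
    out["p_holm"] = multipletests(out["p_raw"].to_numpy(), method="holm")[1]
    return out


def lambda_cwm_association(lambdas: LambdaTable,
                           cwms: pd.DataFrame) -> pd.DataFrame:
    """Pearson/Spearman association of multipliers with CWM values per trait.

    A positive correlation means plots under stronger positive selection on
    a trait also carry larger community-weighted values of it.  Returns one
    row per trait overall plus one per forest type; constant columns or
    single plots yield NaN (flagged missing).
    """
    shared = lambdas.values.index.intersection(cwms.index)
    vals = lambdas.values.loc[shared]
    cw = cwms.loc[shared]
    ft = lambdas.forest_type.loc[shared]

    def _assoc(x: np.ndarray, y: np.ndarray) -> dict:
        if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
            return {"pearson_r": np.nan, "spearman_rho": np.nan, "slope": np.nan,
                    "n": len(x)}
        pear = stats.pearsonr(x, y)[0]
        rho = stats.spearmanr(x, y)[0]
        slope = np.polyfit(x, y, 1)[0]
        return {"pearson_r": float(pear), "spearman_rho": float(rho),
                "slope": float(slope), "n": len(x)}

    rows = []
    for trait in vals.columns.intersection(cw.columns):
        x = cw[trait].to_numpy(float)
        y = vals[trait].to_numpy(float)
        rows.append({"trait": trait, "forest_type": "ALL", **_assoc(x, y)})
        for t in sorted(ft.unique()):
            m = (ft == t).to_numpy()
            rows.append({"trait": trait, "forest_type": t,
                         **_assoc(x[m], y[m])})
    return pd.DataFrame(rows)
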