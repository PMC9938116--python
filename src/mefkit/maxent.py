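"""Constrained maximum-entropy prediction of relative abundances.

Given a prior distribution ``q`` over genera and community-weighted-mean
(CWM) constraints, the predicted local relative abundance vector is the
distribution ``p`` that minimizes the Kullback-Leibler divergence
``KL(p || q)`` subject to matching the trait constraints
``sum_i p_i t_ij = c_j``.  When the prior is uniform this is the classic
maximum-entropy solution.  The optimum has Gibbs form

    p_i = q_i exp(sum_j lambda_j t_ij) / Z(lambda)

restricted to the prior's support, where the Lagrange multipliers
``lambda_j`` are found by minimizing the smooth convex dual

    f(lambda) = log Z(lambda) - sum_j lambda_j c_j.

The multiplier ``lambda_j`` measures direction and strength of selection on
trait ``j``: the derivative of a genus's predicted abundance with respect
to its trait value, holding the multipliers fixed, is
``lambda_j p_i (1 - p_i)``.

Traits are standardized internally (prior-weighted z-scores) for
conditioning; multipliers are reported back-transformed to raw trait units.
The dual is solved with a damped Newton iteration (the Hessian is the
prior-tilted trait covariance, symmetric PSD) with log-sum-exp
stabilization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp, rel_entr

__all__ = [
    "Prior",
    "ConstraintSpec",
    "MaxEntFit",
    "FeasibilityReport",
    "InfeasibleConstraints",
    "solve_maxent",
    "sensitivity",
    "permute_traits",
    "check_feasibility",
    "kl_divergence",
]

#: Multiplier magnitude cap for targets at (or within eps of) the hull boundary.
LAMBDA_CAP = 1e3
#: Relative margin below which a target is flagged near-boundary.
BOUNDARY_EPS = 1e-9


class InfeasibleConstraints(ValueError):
    """A CWM target lies outside the trait hull over the prior's support."""


@dataclass
class Prior:
    """A reference distribution over genera (simplex vector, labelled)."""

    q: pd.Series

    def __post_init__(self) -> None:
        q = pd.Series(self.q, dtype=float)
        if (q < 0).any():
            raise ValueError("prior has negative mass")
        total = q.sum()
        if not np.isclose(total, 1.0, atol=1e-12, rtol=1e-9):
            raise ValueError(f"prior mass sums to {total}, not 1")
        if not (q > 0).any():
            raise ValueError("prior support is empty")
        self.q = q / total

    @classmethod
    def uniform(cls, genus_ids) -> "Prior":
        ids = pd.Index(genus_ids)
        return cls(pd.Series(1.0 / len(ids), index=ids))

    @classmethod
    def from_counts(cls, counts: pd.Series) -> "Prior":
        counts = pd.Series(counts, dtype=float)
        return cls(counts / counts.sum())

    @property
    def support(self) -> pd.Index:
        return self.q.index[self.q > 0]


@dataclass
class ConstraintSpec:
    """Trait matrix (genera x traits) plus one CWM target per trait."""

    traits: pd.DataFrame
    targets: pd.Series

    def __post_init__(self) -> None:
        self.traits = self.traits.astype(float)
        self.targets = pd.Series(self.targets, dtype=float).reindex(self.traits.columns)
        if self.targets.isna().any():
            missing = self.targets.index[self.targets.isna()].tolist()
            raise ValueError(f"no target for traits {missing}")
        if self.traits.isna().any().any():
            raise ValueError("constraint trait matrix must be complete (impute first)")

    @property
    def trait_ids(self) -> pd.Index:
        return self.traits.columns


@dataclass
class MaxEntFit:
    """Solution of one constrained maximum-entropy problem."""

    p: pd.Series
    lambda_: pd.Series
    log_partition: float
    converged: bool
    n_iterations: int
    constraint_residuals: pd.Series
    dropped_traits: tuple[str, ...] = ()
    near_boundary: bool = False


@dataclass
class FeasibilityReport:
    lower_margin: pd.Series   # c_j - min_i t_ij over support
    upper_margin: pd.Series   # max_i t_ij - c_j over support
    feasible: bool
    near_boundary_traits: tuple[str, ...] = ()


def kl_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """KL(p || q) in nats with the 0*log(0/x) = 0 convention."""
    return float(rel_entr(np.asarray(p, float), np.asarray(q, float)).sum())


def check_feasibility(prior: Prior, spec: ConstraintSpec,
                      eps: float = BOUNDARY_EPS) -> FeasibilityReport:
    """Report per-trait margins of the targets inside the support trait hull."""
    sup = prior.support
    t = spec.traits.loc[sup]
    lo = spec.targets - t.min(axis=0)
    hi = t.max(axis=0) - spec.targets
    span = (t.max(axis=0) - t.min(axis=0)).replace(0.0, 1.0)
    near = tuple(spec.trait_ids[((lo / span) < eps) | ((hi / span) < eps)])
    return FeasibilityReport(
        lower_margin=lo, upper_margin=hi,
        feasible=bool((lo >= 0).all() and (hi >= 0).all()),
        near_boundary_traits=near,
    )


def permute_traits(spec: ConstraintSpec, rng: np.random.Generator) -> ConstraintSpec:
    """Shuffle whole trait rows uniformly among genera; targets unchanged."""
    perm = rng.permutation(len(spec.traits))
    permuted = pd.DataFrame(spec.traits.to_numpy()[perm],
                            index=spec.traits.index, columns=spec.traits.columns)
    return ConstraintSpec(traits=permuted, targets=spec.targets.copy())


def sensitivity(p, lambda_, i, j) -> float:
    """d p_i / d t_ij at fixed multipliers: lambda_j * p_i * (1 - p_i).

    ``i`` and ``j`` are labels when ``p`` / ``lambda_`` are labelled Series,
    otherwise positional indices.
    """
    if isinstance(p, pd.Series) and i in p.index:
        pi = float(p.loc[i])
    else:
        pi = float(np.asarray(p, float)[i])
    if isinstance(lambda_, pd.Series) and j in lambda_.index:
        lj = float(lambda_.loc[j])
    else:
        lj = float(np.asarray(lambda_, float)[j])
    return lj * pi * (1.0 - pi)


def _solve_dual(logq: np.ndarray, T: np.ndarray, c: np.ndarray,
                tol: float, max_iter: int, lam_cap: float) -> tuple:
    """Damped Newton on f(lam) = logsumexp(logq + T lam) - lam.c (standardized)."""
    n, J = T.shape
    lam = np.zeros(J)

    def state(lam):
        a = logq + T @ lam
        logz = logsumexp(a)
        p = np.exp(a - logz)
        grad = T.T @ p - c
        return logz, p, grad

    logz, p, grad = state(lam)
    f = logz - lam @ c
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) <= tol:
            converged = True
            break
        Tc = T - (p @ T)  # centered columns under current p
        H = Tc.T @ (Tc * p[:, None])
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(J), -grad)
        except np.linalg.LinAlgError:
            step = -grad
        # backtracking line search on the convex dual; near the optimum f
        # changes fall below float precision, so non-increase (within noise)
        # is accepted to let the final Newton polish through
        alpha = 1.0
        for _ in range(60):
            lam_new = np.clip(lam + alpha * step, -lam_cap, lam_cap)
            logz_new = logsumexp(logq + T @ lam_new)
            f_new = logz_new - lam_new @ c
            if f_new <= f + 1e-12 * max(1.0, abs(f)):
                break
            alpha *= 0.5
        else:
            break  # no acceptable step (cap active or numerically flat)
        if np.array_equal(lam_new, lam):
            break
        lam = lam_new
        logz, p, grad = state(lam)
        f = logz - lam @ c
    else:
        it = max_iter
    if not converged:
        converged = bool(np.max(np.abs(grad)) <= tol)
    return lam, p, logz, grad, converged, it


def solve_maxent(prior: Prior, spec: ConstraintSpec, tol: float = 1e-8,
                 max_iter: int = 200) -> MaxEntFit:
    """Solve the CWM-constrained minimum-divergence problem for one plot.

    Parameters
    ----------
    prior
        Reference distribution (uniform or metacommunity relative
        abundances).  Genera with zero prior mass get predicted abundance
        exactly zero.
    spec
        Complete trait matrix and CWM targets.  The trait matrix must cover
        every genus in the prior's index.
    tol
        Tolerance on the constraint residuals in standardized trait units.
    max_iter
        Newton iteration cap; if reached, the fit is returned with
        ``converged=False`` and a warning.

    Raises
    ------
    InfeasibleConstraints
        If a target lies strictly outside the trait hull over the support.
    """
    q = prior.q.reindex(spec.traits.index)
    if q.isna().any():
        raise ValueError("prior and trait matrix indices do not match")
    sup_mask = (q > 0).to_numpy()
    sup_ids = q.index[sup_mask]

    rep = check_feasibility(prior, spec)
    if not rep.feasible:
        bad = [t for t in spec.trait_ids
               if rep.lower_margin[t] < 0 or rep.upper_margin[t] < 0]
        raise InfeasibleConstraints(
            f"targets outside support trait hull for traits {bad}")
    near_boundary = bool(rep.near_boundary_traits)

    T_raw = spec.traits.loc[sup_ids].to_numpy()
    c_raw = spec.targets.to_numpy(dtype=float)
    qs = q.to_numpy()[sup_mask]
    qs = qs / qs.sum()

    # prior-weighted standardization over the support
    mu = qs @ T_raw
    var = qs @ (T_raw - mu) ** 2
    sd = np.sqrt(var)
    keep = sd > 1e-12 * np.maximum(1.0, np.abs(mu))
    dropped = tuple(spec.trait_ids[~keep])
    if dropped:
        warnings.warn(f"dropping degenerate (constant over support) traits "
                      f"{list(dropped)}; their multipliers are reported as 0",
                      stacklevel=2)

    lam_full = np.zeros(len(spec.trait_ids))
    if keep.any():
        Ts = (T_raw[:, keep] - mu[keep]) / sd[keep]
        cs = (c_raw[keep] - mu[keep]) / sd[keep]
        lam_s, p_sup, logz, grad, converged, n_iter = _solve_dual(
            np.log(qs), Ts, cs, tol=tol, max_iter=max_iter, lam_cap=LAMBDA_CAP)
        lam_full[keep] = lam_s / sd[keep]
    else:
        p_sup, logz, grad = qs, 0.0, np.zeros(0)
        converged, n_iter = True, 0

    if not converged and not near_boundary:
        warnings.warn(f"maxent solver did not reach tolerance {tol} in "
                      f"{n_iter} iterations (max residual "
                      f"{np.max(np.abs(grad)):.2e})", stacklevel=2)
    if near_boundary and not converged:
        converged = False  # boundary targets: capped lambda, explicit flag

    p = pd.Series(0.0, index=spec.traits.index)
    p.loc[sup_ids] = p_sup / p_sup.sum()
    residuals = pd.Series(
        np.abs(spec.traits.to_numpy().T @ p.to_numpy() - c_raw),
        index=spec.trait_ids)
    return MaxEntFit(
        p=p,
        lambda_=pd.Series(lam_full, index=spec.trait_ids),
        log_partition=float(logz),
        converged=bool(converged),
        n_iterations=int(n_iter),
        constraint_residuals=residuals,
        dropped_traits=dropped,
        near_boundary=near_boundary,
    )
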