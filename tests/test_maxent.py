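import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import rel_entr

from mefkit.maxent import (ConstraintSpec, InfeasibleConstraints, Prior,
                           check_feasibility, kl_divergence, permute_traits,
                           sensitivity, solve_maxent)


def _spec(T, c, genus_ids=None, trait_ids=None):
    T = np.atleast_2d(np.asarray(T, float))
    genus_ids = genus_ids or [f"g{i}" for i in range(T.shape[0])]
    trait_ids = trait_ids or [f"t{j}" for j in range(T.shape[1])]
    return ConstraintSpec(pd.DataFrame(T, index=genus_ids, columns=trait_ids),
                          pd.Series(np.atleast_1d(c), index=trait_ids))


def primal_oracle(q, T, c, x0):
    """Generic constrained convex optimization of KL(p||q) via SLSQP."""
    cons = [{"type": "eq", "fun": lambda p: p.sum() - 1.0}]
    for j in range(T.shape[1]):
        cons.append({"type": "eq",
                     "fun": (lambda j: lambda p: p @ T[:, j] - c[j])(j)})
    res = minimize(lambda p: rel_entr(p, q).sum(), x0, method="SLSQP",
                   constraints=cons, bounds=[(1e-12, 1.0)] * len(q),
                   options={"maxiter": 500, "ftol": 1e-14})
    assert res.success
    return res.x


class TestSolveMaxent:
    def test_two_genus_analytic(self):
        fit = solve_maxent(Prior.uniform(["g0", "g1"]), _spec([[0.0], [1.0]], 0.7))
        assert np.allclose(fit.p.to_numpy(), [0.3, 0.7], atol=1e-10)
        assert fit.lambda_.iloc[0] == pytest.approx(np.log(7 / 3), abs=1e-8)
        assert fit.converged

    def test_prior_mean_targets_give_zero_lambda(self, rng):
        S = 8
        q = rng.dirichlet(np.ones(S))
        T = rng.normal(size=(S, 3))
        fit = solve_maxent(Prior(pd.Series(q, index=[f"g{i}" for i in range(S)])),
                           _spec(T, q @ T))
        assert np.max(np.abs(fit.lambda_.to_numpy())) <= 1e-8
        assert np.allclose(fit.p.to_numpy(), q, atol=1e-10)

    def test_matches_primal_oracle_on_random_instances(self):
        g = np.random.default_rng(2024)
        worst = 0.0
        for _ in range(40):
            S = int(g.integers(4, 7))
            J = int(g.integers(1, min(4, S - 1)))  # keep the oracle determined
            q = g.dirichlet(np.ones(S))
            T = g.normal(size=(S, J))
            r = g.dirichlet(np.ones(S))
            fit = solve_maxent(Prior(pd.Series(q, index=[f"g{i}" for i in range(S)])),
                               _spec(T, r @ T))
            oracle = primal_oracle(q, T, r @ T, r)
            worst = max(worst, float(np.max(np.abs(fit.p.to_numpy() - oracle))))
        assert worst <= 1e-6

    def test_simplex_and_support_invariants(self, rng):
        q = np.array([0.5, 0.5, 0.0, 0.0])
        T = rng.normal(size=(4, 2))
        c = np.array([0.3, 0.7]) @ T[:2]
        fit = solve_maxent(Prior(pd.Series(q, index=list("abcd"))),
                           _spec(T, c, genus_ids=list("abcd")))
        assert fit.p.sum() == pytest.approx(1.0, abs=1e-12)
        assert (fit.p[["c", "d"]] == 0).all()
        assert (fit.p[["a", "b"]] > 0).all()

    def test_kl_optimality_against_random_feasible(self, rng):
        S = 5
        q = rng.dirichlet(np.ones(S))
        prior = Prior(pd.Series(q, index=[f"g{i}" for i in range(S)]))
        T = rng.normal(size=(S, 2))
        for _ in range(200):
            r = rng.dirichlet(np.ones(S))
            fit = solve_maxent(prior, _spec(T, r @ T))
            assert (kl_divergence(fit.p.to_numpy(), q)
                    <= kl_divergence(r, q) + 1e-9)

    def test_affine_trait_rescaling_invariance(self, rng):
        S = 6
        q = rng.dirichlet(np.ones(S))
        T = rng.normal(size=(S, 2))
        r = rng.dirichlet(np.ones(S))
        prior = Prior(pd.Series(q, index=[f"g{i}" for i in range(S)]))
        base = solve_maxent(prior, _spec(T, r @ T))
        a, b = 3.5, -2.0
        scaled = solve_maxent(prior, _spec(a * T + b, r @ (a * T + b)))
        assert np.allclose(base.p.to_numpy(), scaled.p.to_numpy(), atol=1e-8)
        assert np.allclose(base.lambda_.to_numpy(),
                           a * scaled.lambda_.to_numpy(), atol=1e-6)

    def test_constant_trait_dropped_leaves_p_unchanged(self, rng):
        S = 5
        q = rng.dirichlet(np.ones(S))
        prior = Prior(pd.Series(q, index=[f"g{i}" for i in range(S)]))
        T = rng.normal(size=(S, 1))
        r = rng.dirichlet(np.ones(S))
        base = solve_maxent(prior, _spec(T, r @ T))
        T2 = np.column_stack([T, np.full(S, 7.0)])
        with pytest.warns(UserWarning, match="degenerate"):
            extended = solve_maxent(prior, _spec(T2, np.append(r @ T, 7.0)))
        assert np.allclose(base.p.to_numpy(), extended.p.to_numpy(), atol=1e-10)
        assert extended.lambda_.iloc[1] == 0.0
        assert extended.dropped_traits == ("t1",)

    def test_uniform_prior_no_constraints_gives_uniform(self):
        prior = Prior.uniform(list("abcd"))
        spec = ConstraintSpec(pd.DataFrame(index=list("abcd")), pd.Series(dtype=float))
        fit = solve_maxent(prior, spec)
        assert np.allclose(fit.p.to_numpy(), 0.25, atol=1e-12)

    def test_infeasible_target_raises_before_iteration(self):
        with pytest.raises(InfeasibleConstraints):
            solve_maxent(Prior.uniform(["g0", "g1"]), _spec([[0.0], [1.0]], 1.5))


class TestSensitivity:
    def test_zero_lambda_gives_zero(self):
        p = pd.Series([0.4, 0.6], index=["a", "b"])
        lam = pd.Series([0.0], index=["t"])
        assert sensitivity(p, lam, "a", "t") == 0.0

    def test_degenerate_support_gives_zero(self):
        p = pd.Series([1.0], index=["a"])
        lam = pd.Series([2.3], index=["t"])
        assert sensitivity(p, lam, "a", "t") == 0.0

    def test_matches_finite_difference(self):
        g = np.random.default_rng(7)
        rel_errs = []
        for _ in range(30):
            S, J = g.integers(3, 7), g.integers(1, 4)
            q = g.dirichlet(np.ones(S))
            T = g.normal(size=(S, J))
            r = g.dirichlet(np.ones(S))
            fit = solve_maxent(
                Prior(pd.Series(q, index=[f"g{i}" for i in range(S)])),
                _spec(T, r @ T))
            lam = fit.lambda_.to_numpy()
            i, j = g.integers(S), g.integers(J)
            if abs(lam[j]) < 1e-6:
                continue
            h = 1e-6

            def p_of(tij):
                T2 = T.copy()
                T2[i, j] = tij
                a = np.log(q) + T2 @ lam
                p = np.exp(a - a.max())
                return (p / p.sum())[i]

            fd = (p_of(T[i, j] + h) - p_of(T[i, j] - h)) / (2 * h)
            analytic = sensitivity(fit.p.to_numpy(), lam, int(i), int(j))
            if abs(fd) > 1e-12:
                rel_errs.append(abs(analytic - fd) / abs(fd))
        assert rel_errs and max(rel_errs) < 1e-4


class TestPermuteTraits:
    def test_single_genus_identity(self):
        spec = _spec([[1.0, 2.0]], [1.0, 2.0])
        out = permute_traits(spec, np.random.default_rng(0))
        pd.testing.assert_frame_equal(out.traits, spec.traits)

    def test_fixed_seed_reproducible(self, rng):
        spec = _spec(np.arange(8.0).reshape(4, 2), [1.0, 2.0])
        a = permute_traits(spec, np.random.default_rng(5))
        b = permute_traits(spec, np.random.default_rng(5))
        pd.testing.assert_frame_equal(a.traits, b.traits)

    def test_targets_unchanged_and_rows_preserved(self, rng):
        spec = _spec(rng.normal(size=(6, 3)), [0.0, 0.0, 0.0])
        out = permute_traits(spec, rng)
        pd.testing.assert_series_equal(out.targets, spec.targets)
        # whole rows move together: sorted row tuples identical
        rows_in = sorted(map(tuple, spec.traits.to_numpy().round(12)))
        rows_out = sorted(map(tuple, out.traits.to_numpy().round(12)))
        assert rows_in == rows_out

    def test_uniform_over_orderings(self):
        g = np.random.default_rng(99)
        spec = _spec(np.arange(4.0).reshape(4, 1), [0.0])
        n = 10_000
        seen = {}
        for _ in range(n):
            key = tuple(permute_traits(spec, g).traits["t0"])
            seen[key] = seen.get(key, 0) + 1
        assert len(seen) == 24
        p = 1 / 24
        se = np.sqrt(p * (1 - p) / n)
        for count in seen.values():
            assert abs(count / n - p) <= 3 * se + 1e-12


class TestFeasibility:
    def test_target_at_support_maximum_near_boundary_but_feasible(self):
        rep = check_feasibility(Prior.uniform(["g0", "g1"]), _spec([[0.0], [1.0]], 1.0))
        assert rep.feasible
        assert "t0" in rep.near_boundary_traits

    def test_target_above_maximum_infeasible(self):
        rep = check_feasibility(Prior.uniform(["g0", "g1"]), _spec([[0.0], [1.0]], 1.1))
        assert not rep.feasible

    def test_random_convex_combination_always_feasible(self, rng):
        for _ in range(50):
            S = rng.integers(2, 8)
            T = rng.normal(size=(S, 2))
            r = rng.dirichlet(np.ones(S))
            rep = check_feasibility(
                Prior.uniform([f"g{i}" for i in range(S)]), _spec(T, r @ T))
            assert rep.feasible
            assert (rep.lower_margin >= -1e-12).all()
            assert (rep.upper_margin >= -1e-12).all()
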