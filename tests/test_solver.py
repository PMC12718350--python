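"""Generalized Sinkhorn solver: bimarginal building block, multistage
program, proximal annealing, constraint residuals."""

import numpy as np
import pytest

from msot import (
    CostSet,
    InvalidInputError,
    MsotConfig,
    NumericalInstabilityError,
    StagePlans,
    StatePartition,
    constraint_residuals,
    proximal_solve,
    sinkhorn_bimarginal,
    solve_msot_entropic,
)

from oracles import lp_flow_oracle, random_geometric_instance


class TestSinkhornBimarginal:
    def test_one_by_one(self):
        plan = sinkhorn_bimarginal(np.array([[3.0]]), [1.0], [1.0], epsilon=0.1)
        np.testing.assert_allclose(plan, [[1.0]], atol=1e-9)

    def test_small_epsilon_recovers_permutation(self):
        C = np.array([[0.0, 1.0], [1.0, 0.0]])
        plan = sinkhorn_bimarginal(C, [0.5, 0.5], [0.5, 0.5], epsilon=1e-3)
        np.testing.assert_allclose(plan, 0.5 * np.eye(2), atol=1e-6)
        assert float(np.sum(plan * C)) == pytest.approx(0.0, abs=1e-6)

    def test_symmetric_problem_symmetric_plan(self, rng):
        C = rng.random((3, 3))
        C = C + C.T
        mu = np.array([0.2, 0.5, 0.3])
        plan = sinkhorn_bimarginal(C, mu, mu, epsilon=0.1)
        np.testing.assert_allclose(plan, plan.T, atol=1e-8)

    def test_marginals_enforced(self, rng):
        C = rng.random((4, 3))
        mu1 = np.array([1.0, 2.0, 0.5, 0.5])
        mu2 = np.array([2.0, 1.0, 1.0])
        plan = sinkhorn_bimarginal(C, mu1, mu2, epsilon=0.2, tau=1e-10)
        np.testing.assert_allclose(plan.sum(axis=1), mu1, atol=1e-7)
        np.testing.assert_allclose(plan.sum(axis=0), mu2, atol=1e-7)

    def test_unbalanced_masses_rejected(self):
        with pytest.raises(InvalidInputError):
            sinkhorn_bimarginal(np.ones((2, 2)), [1.0, 1.0], [1.0, 2.0], epsilon=0.1)

    def test_kernel_underflow_reported(self):
        with pytest.raises(NumericalInstabilityError):
            sinkhorn_bimarginal(np.array([[1e5, 1e5]]), [1.0], [0.5, 0.5], epsilon=1e-2)


def _chain():
    """Initial at 0.0, intermediate at 0.5, terminal at 1.0 (1D)."""
    part = StatePartition(X0=[0], X=[1], XF=[2], fate_of={2: "A"})
    costs = CostSet(
        C_0X=np.array([[0.25]]), C_0F=np.array([[1.0]]),
        C_XX=np.array([[0.0]]), C_XF=np.array([[0.25]]),
    )
    return costs, part


class TestMultistage:
    def test_chain_routes_through_midpoint(self):
        costs, part = _chain()
        cfg = MsotConfig(T=3, epsilon_start=0.05, prox_iters=20, tol_tau=1e-6)
        plans, report = proximal_solve(costs, part, cfg)
        assert report.converged
        # two half steps (0.25 each) beat the direct move of cost 1.0
        assert report.transport_cost == pytest.approx(0.5, abs=5e-3)
        assert report.transport_cost == pytest.approx(
            lp_flow_oracle(costs, part, 3), abs=5e-3
        )

    def test_single_pair_no_intermediates(self):
        part = StatePartition(X0=[0], X=[], XF=[1], fate_of={1: "A"})
        costs = CostSet(
            C_0X=np.zeros((1, 0)), C_0F=np.array([[0.7]]),
            C_XX=np.zeros((0, 0)), C_XF=np.zeros((0, 1)),
        )
        cfg = MsotConfig(T=2, epsilon_start=0.01, prox_iters=5, tol_tau=1e-8)
        plans, report = proximal_solve(costs, part, cfg)
        # exactly one unit moves: extra mass only adds cost
        assert plans.Mhat[0][0, 0] == pytest.approx(1.0, abs=1e-4)
        assert report.transport_cost == pytest.approx(0.7, abs=1e-3)

    def test_no_intermediates_reduces_to_inequality_bimarginal(self, rng):
        """With X empty the multistage machinery must coincide with plain
        entropic bimarginal transport under >= 1 marginal bounds."""
        n0, nF, eps = 2, 3, 0.05
        C = rng.random((n0, nF)) * 2
        part = StatePartition(
            X0=np.arange(n0), X=[], XF=np.arange(n0, n0 + nF),
            fate_of={int(j): "A" for j in range(n0, n0 + nF)},
        )
        costs = CostSet(
            C_0X=np.zeros((n0, 0)), C_0F=C, C_XX=np.zeros((0, 0)), C_XF=np.zeros((0, nF))
        )
        cfg = MsotConfig(T=3, epsilon_start=eps, prox_iters=1, tol_tau=1e-9)
        plans, _ = solve_msot_entropic(costs, part, cfg)
        # independent scaling loop for the inequality-marginal problem
        K = np.exp(-C / eps)
        u, v = np.ones(n0), np.ones(nF)
        for _ in range(100_000):
            u_new = np.maximum(1.0, 1.0 / (K @ v))
            v_new = np.maximum(1.0, 1.0 / (K.T @ u_new))
            if max(np.abs(np.log(v_new / v)).max(), np.abs(np.log(u_new / u)).max()) < 1e-13:
                u, v = u_new, v_new
                break
            u, v = u_new, v_new
        np.testing.assert_allclose(plans.Mhat[0], u[:, None] * K * v[None, :], atol=1e-6)

    def test_prox_one_round_equals_single_shot(self, rng):
        costs, part = random_geometric_instance(rng, 2, 3, 2)
        cfg = MsotConfig(T=3, epsilon_start=0.05, prox_iters=1, tol_tau=1e-6)
        p1, _ = proximal_solve(costs, part, cfg)
        p2, _ = solve_msot_entropic(costs, part, cfg)
        for a, b in zip(p1.Mtilde + p1.Mhat, p2.Mtilde + p2.Mhat):
            np.testing.assert_array_equal(a, b)

    def test_annealing_approaches_small_epsilon_solution(self):
        costs, part = _chain()
        annealed, _ = proximal_solve(
            costs, part, MsotConfig(T=3, epsilon_start=0.05, prox_iters=10, tol_tau=1e-7)
        )
        direct, _ = solve_msot_entropic(
            costs, part, MsotConfig(T=3, epsilon_start=0.005, prox_iters=1, tol_tau=1e-7)
        )
        assert annealed.transport_cost(costs) == pytest.approx(
            direct.transport_cost(costs), abs=1e-2
        )

    def test_cost_nonincreasing_over_prox_rounds(self, rng):
        costs, part = random_geometric_instance(rng, 2, 4, 2)
        prior = None
        prev_cost = np.inf
        for _ in range(6):
            cfg = MsotConfig(T=4, epsilon_start=0.05, prox_iters=1, tol_tau=1e-6)
            prior, rep = solve_msot_entropic(costs, part, cfg, prior=prior)
            assert rep.transport_cost <= prev_cost + 1e-6
            prev_cost = rep.transport_cost

    def test_deterministic_bitwise(self, rng, fast_config):
        costs, part = random_geometric_instance(rng, 2, 3, 2)
        p1, _ = proximal_solve(costs, part, fast_config)
        p2, _ = proximal_solve(costs, part, fast_config)
        for a, b in zip(p1.Mtilde + p1.Mhat, p2.Mtilde + p2.Mhat):
            np.testing.assert_array_equal(a, b)

    def test_log_domain_matches_linear(self, rng):
        costs, part = random_geometric_instance(rng, 2, 4, 2)
        lin, _ = proximal_solve(
            costs, part, MsotConfig(T=4, epsilon_start=0.05, prox_iters=3, tol_tau=1e-6)
        )
        log, _ = proximal_solve(
            costs, part,
            MsotConfig(T=4, epsilon_start=0.05, prox_iters=3, tol_tau=1e-6, log_domain=True),
        )
        for a, b in zip(lin.Mtilde + lin.Mhat, log.Mtilde + log.Mhat):
            np.testing.assert_allclose(a, b, atol=1e-10)

    def test_entropic_oracle_trust_constr(self):
        """On a tiny instance the entropic solution must agree with a
        generic convex solver minimizing the identical objective."""
        from scipy.optimize import LinearConstraint, minimize

        rng = np.random.default_rng(11)
        costs, part = random_geometric_instance(rng, 1, 2, 1)
        T, eps = 3, 0.2
        cfg = MsotConfig(T=T, epsilon_start=eps, prox_iters=1, tol_tau=1e-9)
        plans, rep = solve_msot_entropic(costs, part, cfg)

        # variables: Mt0 (1x2), Mt1 (2x2), Mh0 (1x1), Mh1 (2x1), Mh2 (2x1)
        shapes = [(1, 2), (2, 2), (1, 1), (2, 1), (2, 1)]
        cost_vecs = [costs.C_0X, costs.C_XX, costs.C_0F, costs.C_XF, costs.C_XF]
        sizes = [r * c for r, c in shapes]
        offs = np.concatenate([[0], np.cumsum(sizes)])
        cvec = np.concatenate([np.asarray(M).ravel() for M in cost_vecs])

        def unpack(x):
            return [x[offs[i]: offs[i + 1]].reshape(shapes[i]) for i in range(5)]

        def obj(x):
            ent = np.sum(x * (np.log(np.maximum(x, 1e-300)) - 1.0))
            return float(cvec @ x + eps * ent)

        A_rows, lb, ub = [], [], []

        def row(block, fill):
            v = [np.zeros(s) for s in shapes]
            v[block] = fill
            return np.concatenate([w.ravel() for w in v])

        # coupling t=1: col sums of Mt0 = row sums of Mt1 + Mh1
        for j in range(2):
            e = np.zeros((1, 2)); e[0, j] = 1
            r1 = np.zeros((2, 2)); r1[j, :] = -1
            r2 = np.zeros((2, 1)); r2[j, 0] = -1
            A_rows.append(row(0, e) + row(1, r1) + row(3, r2)); lb.append(0.0); ub.append(0.0)
        # coupling t=2: col sums of Mt1 = row sums of Mh2
        for j in range(2):
            e = np.zeros((2, 2)); e[:, j] = 1
            r2 = np.zeros((2, 1)); r2[j, 0] = -1
            A_rows.append(row(1, e) + row(4, r2)); lb.append(0.0); ub.append(0.0)
        # initial emission >= 1
        A_rows.append(row(0, np.ones((1, 2))) + row(2, np.ones((1, 1))))
        lb.append(1.0); ub.append(np.inf)
        # throughput >= 1 per intermediate
        for j in range(2):
            r1 = np.zeros((2, 2)); r1[j, :] = 1
            r2 = np.zeros((2, 1)); r2[j, 0] = 1
            A_rows.append(row(1, r1) + row(3, r2) + row(4, r2)); lb.append(1.0); ub.append(np.inf)
        # terminal reception >= 1
        A_rows.append(row(2, np.ones((1, 1))) + row(3, np.ones((2, 1))) + row(4, np.ones((2, 1))))
        lb.append(1.0); ub.append(np.inf)

        x0 = np.full(offs[-1], 0.5)
        res = minimize(
            obj, x0, method="trust-constr",
            constraints=LinearConstraint(np.array(A_rows), lb, ub),
            bounds=[(1e-12, None)] * offs[-1],
            options={"maxiter": 3000, "gtol": 1e-10, "xtol": 1e-12},
        )
        assert res.success
        assert rep.transport_cost + eps * float(
            np.sum(np.concatenate([M.ravel() for M in plans.Mtilde + plans.Mhat])
                   * (np.log(np.maximum(np.concatenate(
                       [M.ravel() for M in plans.Mtilde + plans.Mhat]), 1e-300)) - 1.0))
        ) == pytest.approx(res.fun, abs=2e-3)


class TestConstraintResiduals:
    def test_converged_plans_within_tolerance(self, rng, fast_config):
        costs, part = random_geometric_instance(rng, 2, 4, 2)
        plans, rep = proximal_solve(costs, part, fast_config)
        assert rep.converged
        assert max(constraint_residuals(plans, part).values()) <= fast_config.tol_tau

    def test_hand_built_coupling_violation(self):
        part = StatePartition(X0=[0], X=[1], XF=[2], fate_of={2: "A"})
        # intermediate receives 1 at stage 1 but sends only 0.5 on
        plans = StagePlans(
            Mtilde=[np.array([[1.0]]), np.array([[0.0]])],
            Mhat=[np.array([[0.0]]), np.array([[0.5]]), np.array([[0.0]])],
        )
        res = constraint_residuals(plans, part)
        assert res["coupling"] == pytest.approx(0.5)

    def test_forward_simulated_flows_feasible(self, rng):
        """Flows built by pushing mass forward stage by stage satisfy the
        coupling exactly and the residual report must say so."""
        n0, n, nF, T = 2, 3, 2, 4
        part = StatePartition(
            X0=np.arange(n0), X=np.arange(n0, n0 + n), XF=np.arange(n0 + n, n0 + n + nF),
            fate_of={int(j): "A" for j in range(n0 + n, n0 + n + nF)},
        )
        # stage 0: each initial cell splits mass 3 among X and XF
        Mt = [rng.random((n0, n)) + 0.5]
        Mh = [rng.random((n0, nF)) + 0.5]
        arriving = Mt[0].sum(axis=0)
        for t in range(1, T):
            if t < T - 1:
                frac = rng.uniform(0.2, 0.8, size=n)
                cont = rng.random((n, n)) + 0.1
                cont *= (arriving * frac / cont.sum(axis=1))[:, None]
                exit_ = rng.random((n, nF)) + 0.1
                exit_ *= (arriving * (1 - frac) / exit_.sum(axis=1))[:, None]
                Mt.append(cont)
                Mh.append(exit_)
                arriving = cont.sum(axis=0)
            else:
                exit_ = rng.random((n, nF)) + 0.1
                exit_ *= (arriving / exit_.sum(axis=1))[:, None]
                Mh.append(exit_)
        res = constraint_residuals(StagePlans(Mt, Mh), part)
        assert res["coupling"] == pytest.approx(0.0, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        part = StatePartition(X0=[0], X=[], XF=[1], fate_of={1: "A"})
        plans = StagePlans(Mtilde=[np.zeros((2, 0))], Mhat=[np.ones((2, 2))])
        with pytest.raises(InvalidInputError):
            constraint_residuals(plans, part)


class TestMassConservation:
    def test_emitted_equals_exited(self, rng, fast_config):
        """All mass leaving X0 eventually exits to XF (stage coupling), and
        total throughput is at least max(n0, nF) up to tolerance."""
        costs, part = random_geometric_instance(rng, 3, 5, 2)
        plans, rep = proximal_solve(costs, part, fast_config)
        emitted = plans.mu_tilde(0).sum() + plans.mu_hat(0).sum()
        exited = sum(plans.nu_hat(t).sum() for t in range(plans.T))
        # equality holds up to the accumulated stage-coupling tolerance
        assert exited == pytest.approx(emitted, abs=fast_config.tol_tau * part.n * plans.T)
        tol = fast_config.tol_tau * (part.n0 + part.nF)
        assert exited >= max(part.n0, part.nF) - tol
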