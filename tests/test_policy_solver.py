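"""Dynamic-programming solver: brute-force oracle on a tiny decision
problem, lattice invariants at the best-fit profile, lookup semantics, and
the archive format."""

from __future__ import annotations

import numpy as np
import pytest

from attnddm.policy_solver import (
    Action,
    GridSpec,
    GridTooSmallError,
    OutOfHorizonError,
    PolicySolution,
    boundary_contours,
    delta_transition_variance,
    expected_continuation_value,
    policy_lookup,
    solve_policy,
)
from attnddm.task_model import ModelParams, posterior_moments


# ---------------------------------------------------------------- oracle --
def oracle_solve(params: ModelParams, grid: GridSpec):
    """Exhaustive recursive enumeration of the tiny decision problem,
    written independently of the production sweep (plain recursion with
    memoization, explicit kernel built from the Normal density)."""
    deltas = grid.delta_axis
    nd = deltas.size
    step = grid.delta_step
    nt = grid.n_t_steps
    memo: dict = {}

    def expectation(values_next, delta_idx, var):
        if var == 0:
            return values_next[delta_idx]
        sd = np.sqrt(var)
        half = int(np.ceil(4.0 * sd / step))
        total_w = 0.0
        total = 0.0
        for m in range(-half, half + 1):
            w = np.exp(-0.5 * (m * step / sd) ** 2)
            j = delta_idx + m
            if 0 <= j < nd:
                v = values_next[j]
            else:  # outside the lattice an immediate choice is optimal
                v = abs(deltas[delta_idx] + m * step) / 2.0
            total += w * v
            total_w += w
        return total / total_w

    def value(k, i1, i2, y):
        key = (k, i1, i2, y)
        if key in memo:
            return memo[key]
        d = deltas[k]
        if i1 + i2 == nt:
            res = (abs(d) / 2.0, Action.CHOOSE_1 if d <= 0 else Action.CHOOSE_2)
            memo[key] = res
            return res
        choose1, choose2 = -d / 2.0, d / 2.0

        def acc(yy):
            t1, t2 = i1 * grid.dt_grid, i2 * grid.dt_grid
            var = delta_transition_variance(t1, t2, yy, params, grid.dt_grid)
            j1, j2 = (i1 + 1, i2) if yy == 1 else (i1, i2 + 1)
            nxt = np.array([value(kk, j1, j2, yy)[0] for kk in range(nd)])
            return -params.c * grid.dt_grid + expectation(nxt, k, var)

        a_self = acc(y)
        a_other = acc(3 - y)
        switch = -params.c_s + max(choose1, choose2, a_other)
        candidates = [
            (choose1, Action.CHOOSE_1),
            (choose2, Action.CHOOSE_2),
            (a_self, Action.ACCUMULATE),
            (switch, Action.SWITCH),
        ]
        best = max(range(4), key=lambda i: (candidates[i][0], -i))
        memo[key] = (candidates[best][0], candidates[best][1])
        return memo[key]

    return value


# ---------------------------------------------------------------- tests --
class TestDeltaTransitionVariance:
    def test_hand_computed_example(self):
        p = ModelParams(sigma_x2=1.0, sigma_z2=1.0, kappa=0.2, dt_sim=0.05)
        var = delta_transition_variance(0.0, 0.0, 1, p, 0.05)
        assert var == pytest.approx((1 - 1 / 1.04) + (1 - 1 / 1.01), abs=1e-9)

    def test_matches_simulated_posterior_mean_spread(self):
        """Cross-check against 1e5 simulated one-step posterior-mean updates
        with values drawn from the current belief."""
        p = ModelParams(sigma_x2=1.0, sigma_z2=1.0, kappa=0.2, dt_sim=0.05)
        rng = np.random.default_rng(2)
        n, dt = 100_000, 0.05
        z1 = rng.normal(0, np.sqrt(p.sigma_z2), size=n)
        z2 = rng.normal(0, np.sqrt(p.sigma_z2), size=n)
        dx1 = rng.normal(z1 * dt, np.sqrt(p.sigma_x2 * dt / (1 - p.kappa)))
        dx2 = rng.normal(z2 * dt, np.sqrt(p.sigma_x2 * dt / p.kappa))
        w = p.unattended_weight
        m1, m2, _, _ = posterior_moments(dx1, w * dx2, dt, 0.0, p)
        delta = m2 - m1
        expected = delta_transition_variance(0.0, 0.0, 1, p, dt)
        assert np.var(delta) == pytest.approx(expected, rel=0.03)
        assert abs(np.mean(delta)) < 4 * np.std(delta) / np.sqrt(n)

    def test_limit_and_symmetry(self):
        p = ModelParams()
        assert delta_transition_variance(1.0, 0.5, 1, p, 1e-7) < 1e-5
        p5 = ModelParams(kappa=0.5)
        v1 = delta_transition_variance(0.8, 0.3, 1, p5, 0.05)
        v2 = delta_transition_variance(0.8, 0.3, 2, p5, 0.05)
        assert v1 == pytest.approx(v2)


class TestExpectedContinuationValue:
    deltas = np.arange(-41, 42) * 0.05

    def test_zero_variance_interpolates(self):
        slice_ = np.sin(self.deltas)
        v = expected_continuation_value(slice_, self.deltas, 0.123, 0.0)
        assert v == pytest.approx(np.interp(0.123, self.deltas, slice_))

    def test_linear_slice_is_exact(self):
        """Linearity of the expectation, for kernels that stay on-lattice
        (beyond the edge the padding follows the choose value, not the
        slice's own extension)."""
        slice_ = 3.0 * self.deltas + 0.5
        for var in (0.005, 0.02, 0.05):
            v = expected_continuation_value(slice_, self.deltas, 0.4, var)
            assert v == pytest.approx(3.0 * 0.4 + 0.5, rel=1e-6)

    def test_choose_value_slice_is_exact_across_the_edge(self):
        """The padding continues |Delta|/2 linearly, so for the choose-value
        slice the expectation far from the kink is exact even when the
        kernel overhangs the lattice edge."""
        slice_ = np.abs(self.deltas) / 2.0
        v = expected_continuation_value(slice_, self.deltas, 1.9, 0.04)
        assert v == pytest.approx(1.9 / 2.0, rel=1e-6)

    def test_quadratic_slice_second_moment(self):
        # E[D'^2] = delta^2 + var; 4-SD truncation + renormalization leaves
        # a relative error of order 1e-3 of the variance
        deltas = np.arange(-201, 202) * 0.05
        slice_ = deltas**2
        for var in (0.05, 0.5):
            v = expected_continuation_value(slice_, deltas, 0.3, var)
            assert v == pytest.approx(0.3**2 + var, abs=2e-3 * var + 1e-9)

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            expected_continuation_value(self.deltas, self.deltas, 0.0, -1.0)


class TestSolverOracle:
    def test_toy_mdp_matches_exhaustive_enumeration(self):
        """Two-step horizon, 5-point Delta lattice, 20 random parameter
        draws: the sweep must agree exactly with plain recursion."""
        rng = np.random.default_rng(42)
        for draw in range(20):
            params = ModelParams(
                sigma_x2=float(rng.uniform(0.5, 20)),
                sigma_z2=float(rng.uniform(0.5, 20)),
                kappa=float(rng.uniform(0.05, 0.95)),
                c=float(rng.uniform(0.0, 1.0)),
                c_s=float(rng.uniform(0.0, 0.2)),
                dt_sim=0.05,
                dt_grid=0.05,
                t_max=0.1,
                delta_step=1.0,
                delta_max=2.0,
            )
            grid = GridSpec.from_params(params)
            try:
                sol = solve_policy(params, grid)
            except GridTooSmallError:
                continue  # draw puts the boundary off this tiny lattice
            oracle = oracle_solve(params, grid)
            for k in range(5):
                for i1 in range(3):
                    for i2 in range(3 - i1):
                        for y in (1, 2):
                            v, a = oracle(k, i1, i2, y)
                            assert sol.value[y - 1, i1, i2, k] == pytest.approx(v, abs=1e-10), (
                                draw, k, i1, i2, y)
                            assert sol.policy[y - 1, i1, i2, k] == a, (draw, k, i1, i2, y)


class TestPolicyInvariants:
    def test_terminal_slice_is_choices_only(self, bestfit_policy):
        g = bestfit_policy.grid
        nt = g.n_t_steps
        for i1 in (0, nt // 2, nt):
            labels = bestfit_policy.policy[0, i1, nt - i1]
            assert set(np.unique(labels)) <= {int(Action.CHOOSE_1), int(Action.CHOOSE_2)}
            deltas = g.delta_axis
            assert np.all(labels[deltas > 0] == Action.CHOOSE_2)
            assert np.all(labels[deltas <= 0] == Action.CHOOSE_1)

    def test_mirror_symmetry(self, bestfit_policy):
        """Attending item 2 at (Delta, t1, t2) mirrors attending item 1 at
        (-Delta, t2, t1) with the choose labels swapped."""
        pol = bestfit_policy.policy
        swapped = pol[1, :, :, ::-1].swapaxes(0, 1).copy()
        m = swapped == Action.CHOOSE_1
        swapped[swapped == Action.CHOOSE_2] = Action.CHOOSE_1
        swapped[m] = Action.CHOOSE_2
        # the Delta = 0 column is an exact choose-1/choose-2 tie, resolved by
        # the fixed tie-break rule, which is itself not mirror-symmetric
        k0 = np.argmin(np.abs(bestfit_policy.grid.delta_axis))
        mismatch = pol[0] != swapped
        mismatch[:, :, k0] = False
        assert not mismatch.any()

    def test_switch_nested_in_other_accumulate(self, bestfit_policy):
        pol = bestfit_policy.policy
        for yi in (0, 1):
            sw = pol[yi] == Action.SWITCH
            assert sw.any()
            assert np.all(pol[1 - yi][sw] == Action.ACCUMULATE)

    def test_collapsing_delta_extent(self, bestfit_policy):
        """Max |Delta| still labeled ACCUMULATE (union over (t1,t2) at fixed
        total time) never grows with total time."""
        g = bestfit_policy.grid
        deltas = np.abs(g.delta_axis)
        nt = g.n_t_steps
        extents = []
        for total in range(nt):
            best = 0.0
            for i1 in range(total + 1):
                labels = bestfit_policy.policy[0, i1, total - i1]
                acc = labels == Action.ACCUMULATE
                if acc.any():
                    best = max(best, deltas[acc].max())
            extents.append(best)
        assert np.all(np.diff(extents) <= 1e-12)

    def test_no_switch_region_at_kappa_half(self, bestfit_params):
        """With equally informative items, switching buys nothing and costs
        c_s, so it is never optimal."""
        params = bestfit_params.with_(kappa=0.5, dt_grid=0.1, dt_sim=0.1, t_max=3.0,
                                      delta_step=0.1)
        sol = solve_policy(params)
        assert not (sol.policy == Action.SWITCH).any()

    def test_parameter_monotonicity(self, coarse_params):
        """More expensive or noisier evidence shrinks the accumulate region;
        a higher switch cost shrinks the switch region."""
        def accumulate_extent(sol):
            labels = sol.policy[0, 0, 0]
            acc = (labels == Action.ACCUMULATE) | (labels == Action.SWITCH)
            return np.abs(sol.grid.delta_axis[acc]).max()

        base = solve_policy(coarse_params)
        assert accumulate_extent(solve_policy(coarse_params.with_(c=coarse_params.c * 2))) <= accumulate_extent(base)
        assert accumulate_extent(solve_policy(coarse_params.with_(sigma_x2=coarse_params.sigma_x2 * 2))) <= accumulate_extent(base)
        n_switch_base = int((base.policy == Action.SWITCH).sum())
        more_cs = solve_policy(coarse_params.with_(c_s=coarse_params.c_s * 10))
        assert int((more_cs.policy == Action.SWITCH).sum()) <= n_switch_base

    def test_grid_too_small_raises(self, bestfit_params):
        with pytest.raises(GridTooSmallError):
            solve_policy(bestfit_params.with_(delta_max=1.0))


class TestPolicyLookup:
    def test_on_lattice_point_returns_its_label(self, bestfit_policy):
        g = bestfit_policy.grid
        a = policy_lookup(bestfit_policy, 0.0, 0.0, 0.0, 1)
        k0 = np.argmin(np.abs(g.delta_axis))
        assert a == Action(int(bestfit_policy.policy[0, 0, 0, k0]))
        assert a == Action.ACCUMULATE  # origin lies inside the accumulate region

    def test_deep_choose_region(self, bestfit_policy):
        assert policy_lookup(bestfit_policy, 9.5, 0.0, 0.0, 1) == Action.CHOOSE_2
        assert policy_lookup(bestfit_policy, -9.5, 0.0, 0.0, 1) == Action.CHOOSE_1

    def test_mirrored_lookup(self, bestfit_policy):
        rng = np.random.default_rng(0)
        swap = {Action.CHOOSE_1: Action.CHOOSE_2, Action.CHOOSE_2: Action.CHOOSE_1}
        for _ in range(200):
            d = float(rng.uniform(-9, 9))
            t1 = float(rng.uniform(0, 3))
            t2 = float(rng.uniform(0, 3))
            a = policy_lookup(bestfit_policy, d, t1, t2, 1)
            b = policy_lookup(bestfit_policy, -d, t2, t1, 2)
            assert b == swap.get(a, a)

    def test_out_of_horizon(self, bestfit_policy):
        with pytest.raises(OutOfHorizonError):
            policy_lookup(bestfit_policy, 0.0, 4.0, 3.0, 1)


class TestArchive:
    def test_round_trip_and_refusals(self, tmp_path, coarse_params):
        sol = solve_policy(coarse_params)
        path = tmp_path / "policy.npz"
        sol.save(path)
        loaded = PolicySolution.load(path, expected_params=coarse_params)
        assert np.array_equal(loaded.policy, sol.policy)
        assert np.allclose(loaded.value, sol.value, equal_nan=True)
        assert loaded.grid == sol.grid
        with pytest.raises(ValueError, match="different model parameters"):
            PolicySolution.load(path, expected_params=coarse_params.with_(c=0.5))

    def test_corruption_detected(self, tmp_path, coarse_params):
        sol = solve_policy(coarse_params)
        path = tmp_path / "policy.npz"
        sol.save(path)
        import json as _json
        with np.load(path) as data:
            meta = _json.loads(bytes(data["meta"]).decode())
            value, policy = data["value"], data["policy"]
        policy = policy.copy()
        policy[0, 0, 0, 0] = Action.CHOOSE_2
        np.savez_compressed(
            path, value=value, policy=policy,
            meta=np.frombuffer(_json.dumps(meta).encode(), dtype=np.uint8),
        )
        with pytest.raises(ValueError, match="hash mismatch"):
            PolicySolution.load(path)


class TestBoundaryExport:
    def test_contours_bracket_the_actions(self, coarse_params):
        sol = solve_policy(coarse_params)
        table = boundary_contours(sol)
        assert {"y", "t1", "t2", "delta_boundary", "action_below", "action_above"} <= set(table.columns)
        assert len(table) > 0
        assert (table["action_below"] != table["action_above"]).all()
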