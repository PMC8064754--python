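"""Optimal policy by backward induction on the reduced state space.

The full value function over both posterior means decomposes into the
martingale mean-sum (unaffected by any action) plus a *reduced* value that
depends only on the posterior-mean difference ``Delta = mean2 - mean1``.  In
reduced coordinates choosing item 1 is worth ``-Delta/2``, choosing item 2
``+Delta/2``, accumulating for ``dt`` costs ``c*dt`` plus the expected reduced
value after a Gaussian ``Delta`` transition, and switching attention costs
``c_s`` and swaps the attended item.  Backward induction runs from the horizon
``t_max`` (where a choice is forced and the terminal reduced value is
``|Delta|/2``) down to ``t = 0`` over the lattice ``(Delta, t1, t2, y)``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from enum import IntEnum

import numpy as np

from .task_model import ModelParams

__all__ = [
    "Action",
    "GridSpec",
    "PolicySolution",
    "GridTooSmallError",
    "OutOfHorizonError",
    "delta_transition_variance",
    "expected_continuation_value",
    "solve_policy",
    "policy_lookup",
    "boundary_contours",
]

_KERNEL_SDS = 4.0  # Gaussian transition kernel truncated at +/- 4 SD


class Action(IntEnum):
    """Optimal-action labels; the integer order is the tie-break order."""

    CHOOSE_1 = 0
    CHOOSE_2 = 1
    ACCUMULATE = 2
    SWITCH = 3


class GridTooSmallError(ValueError):
    """The accumulate region touches the Delta lattice edge."""


class OutOfHorizonError(ValueError):
    """Lookup at t1 + t2 beyond the solver horizon."""


@dataclass(frozen=True)
class GridSpec:
    """Discretization of the reduced state space.

    Time lattice ``{0, dt_grid, ..., t_max}`` (endpoints inclusive) with
    ``(t1, t2)`` restricted to ``t1 + t2 <= t_max``; Delta lattice
    ``{-delta_max, ..., +delta_max}`` in steps of ``delta_step``.
    """

    dt_grid: float = 0.05
    t_max: float = 6.0
    delta_step: float = 0.05
    delta_max: float = 10.0

    @classmethod
    def from_params(cls, params: ModelParams) -> "GridSpec":
        return cls(
            dt_grid=params.dt_grid,
            t_max=params.t_max,
            delta_step=params.delta_step,
            delta_max=params.delta_max,
        )

    @property
    def n_t_steps(self) -> int:
        """Number of dt_grid steps from 0 to t_max (lattice has one more point)."""
        return round(self.t_max / self.dt_grid)

    @property
    def t_axis(self) -> np.ndarray:
        return np.arange(self.n_t_steps + 1) * self.dt_grid

    @property
    def delta_axis(self) -> np.ndarray:
        n = round(self.delta_max / self.delta_step)
        return np.arange(-n, n + 1) * self.delta_step


def _posterior_variances(t1, t2, params: ModelParams):
    k = params.kappa
    prior_prec = params.sigma_x2 / params.sigma_z2
    v1 = params.sigma_x2 / (prior_prec + (1.0 - k) * t1 + k * t2)
    v2 = params.sigma_x2 / (prior_prec + (1.0 - k) * t2 + k * t1)
    return v1, v2


def delta_transition_variance(
    t1: float, t2: float, y: int, params: ModelParams, dt: float
) -> float:
    """Variance of the one-step ``Delta`` increment while attending ``y``.

    The posterior mean of each item is a martingale, so the predictive
    variance of its one-step change equals the drop in posterior variance
    over that step; the two items' evidence streams are independent, hence
    the ``Delta`` increment variance is the sum of both drops.  The increment
    has mean zero.
    """
    if y not in (1, 2):
        raise ValueError(f"attended item y must be 1 or 2, got {y}")
    if t1 < 0 or t2 < 0 or dt <= 0:
        raise ValueError("require t1, t2 >= 0 and dt > 0")
    v1, v2 = _posterior_variances(t1, t2, params)
    t1n, t2n = (t1 + dt, t2) if y == 1 else (t1, t2 + dt)
    v1n, v2n = _posterior_variances(t1n, t2n, params)
    return (v1 - v1n) + (v2 - v2n)


def _gaussian_kernel(variance: float, step: float) -> np.ndarray:
    """Discrete Gaussian kernel on the Delta lattice, truncated and renormalized."""
    if variance < 0:
        raise ValueError(f"variance must be >= 0, got {variance}")
    sd = np.sqrt(variance)
    half = int(np.ceil(_KERNEL_SDS * sd / step))
    if half == 0:
        return np.ones(1)
    offsets = np.arange(-half, half + 1) * step
    w = np.exp(-0.5 * (offsets / sd) ** 2)
    return w / w.sum()


def _pad_choose(value_slice: np.ndarray, deltas: np.ndarray, half: int) -> np.ndarray:
    """Extend a value slice beyond the lattice edge by the choose value |Delta|/2."""
    if half == 0:
        return value_slice
    step = deltas[1] - deltas[0]
    left = (np.abs(deltas[0] - step * np.arange(half, 0, -1))) / 2.0
    right = (np.abs(deltas[-1] + step * np.arange(1, half + 1))) / 2.0
    return np.concatenate([left, value_slice, right])


def _expected_slice(value_slice: np.ndarray, deltas: np.ndarray, variance: float) -> np.ndarray:
    """E[V(Delta')] for every lattice Delta, with Delta' ~ N(Delta, variance)."""
    step = deltas[1] - deltas[0]
    kernel = _gaussian_kernel(variance, step)
    half = (len(kernel) - 1) // 2
    padded = _pad_choose(value_slice, deltas, half)
    return np.convolve(padded, kernel, mode="valid")


def expected_continuation_value(
    value_slice: np.ndarray,
    deltas: np.ndarray,
    delta: float,
    variance: float,
) -> float:
    """Expected reduced value ``E[V(Delta')]`` with ``Delta' ~ N(delta, variance)``.

    Computed by discrete Gaussian-kernel convolution truncated at
    +/- 4 SD and renormalized; off-lattice ``delta`` is handled by linear
    interpolation, and beyond the lattice edge the slice is extrapolated by
    the choose value ``|Delta|/2``.
    """
    expected = _expected_slice(np.asarray(value_slice, dtype=float), deltas, variance)
    return float(np.interp(delta, deltas, expected))


@dataclass
class PolicySolution:
    """Solved value and policy grids for both attention states.

    ``value[y-1, i1, i2, k]`` is the reduced value and
    ``policy[y-1, i1, i2, k]`` the :class:`Action` label at
    ``t1 = i1*dt_grid, t2 = i2*dt_grid, Delta = delta_axis[k]``; lattice
    points with ``t1 + t2 > t_max`` are unused (value NaN, policy -1).
    """

    params: ModelParams
    grid: GridSpec
    value: np.ndarray
    policy: np.ndarray

    SOLVER_VERSION = "1.0"

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.value).tobytes())
        h.update(np.ascontiguousarray(self.policy).tobytes())
        return h.hexdigest()

    def save(self, path) -> None:
        """Write a single .npz archive with JSON metadata and dense arrays."""
        meta = {
            "solver_version": self.SOLVER_VERSION,
            "params": asdict(self.params),
            "grid": asdict(self.grid),
            "content_hash": self.content_hash(),
        }
        np.savez_compressed(
            path,
            value=self.value,
            policy=self.policy,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        )

    @classmethod
    def load(cls, path, expected_params: ModelParams | None = None) -> "PolicySolution":
        """Load an archive; refuses corrupted arrays or mismatched parameters."""
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            value = data["value"]
            policy = data["policy"]
        if meta.get("solver_version") != cls.SOLVER_VERSION:
            raise ValueError(
                f"solver version mismatch: archive {meta.get('solver_version')!r}, "
                f"loader {cls.SOLVER_VERSION!r}"
            )
        params = ModelParams(**meta["params"])
        grid = GridSpec(**meta["grid"])
        sol = cls(params=params, grid=grid, value=value, policy=policy)
        if sol.content_hash() != meta["content_hash"]:
            raise ValueError("policy archive content hash mismatch (corrupted file)")
        if expected_params is not None and params != expected_params:
            raise ValueError("policy archive was solved for different model parameters")
        return sol


def solve_policy(
    params: ModelParams, grid: GridSpec | None = None
) -> PolicySolution:
    """Backward induction over the ``(Delta, t1, t2, y)`` lattice.

    At each lattice point the four action values are
    ``choose 1: -Delta/2``, ``choose 2: +Delta/2``,
    ``accumulate: -c*dt + E[V]`` at the attended time advanced by one grid
    step, and ``switch: -c_s +`` the best non-switch action under the other
    attention state at the same ``(Delta, t1, t2)`` (an immediate switch-back
    costs ``2*c_s`` and returns to the same state, hence never optimal, which
    breaks the within-slice mutual recursion between the two attention
    states).  Total time sweeps from ``t_max`` downward; ties are broken in
    the fixed order choose 1 > choose 2 > accumulate > switch.

    Raises
    ------
    GridTooSmallError
        If the accumulate (or switch) region touches the Delta lattice edge
        anywhere, i.e. ``delta_max`` does not contain the decision boundary.
    """
    if grid is None:
        grid = GridSpec.from_params(params)
    deltas = grid.delta_axis
    nd = deltas.size
    nt = grid.n_t_steps
    dtg = grid.dt_grid

    value = np.full((2, nt + 1, nt + 1, nd), np.nan)
    policy = np.full((2, nt + 1, nt + 1, nd), -1, dtype=np.int8)

    choose1 = -deltas / 2.0
    choose2 = +deltas / 2.0
    terminal_value = np.abs(deltas) / 2.0
    terminal_policy = np.where(
        deltas > 0, np.int8(Action.CHOOSE_2), np.int8(Action.CHOOSE_1)
    )

    # terminal slice t1 + t2 = t_max: a decision is forced
    for i1 in range(nt + 1):
        i2 = nt - i1
        for yi in (0, 1):
            value[yi, i1, i2] = terminal_value
            policy[yi, i1, i2] = terminal_policy

    for total in range(nt - 1, -1, -1):
        for i1 in range(total + 1):
            i2 = total - i1
            t1, t2 = i1 * dtg, i2 * dtg
            acc = np.empty((2, nd))
            for yi, y in ((0, 1), (1, 2)):
                nxt = value[yi, i1 + 1, i2] if y == 1 else value[yi, i1, i2 + 1]
                var = delta_transition_variance(t1, t2, y, params, dtg)
                acc[yi] = -params.c * dtg + _expected_slice(nxt, deltas, var)
            for yi in (0, 1):
                other = 1 - yi
                switch = -params.c_s + np.maximum(
                    np.maximum(choose1, choose2), acc[other]
                )
                stacked = np.stack([choose1, choose2, acc[yi], switch])
                policy[yi, i1, i2] = np.argmax(stacked, axis=0).astype(np.int8)
                value[yi, i1, i2] = np.max(stacked, axis=0)

    sol = PolicySolution(params=params, grid=grid, value=value, policy=policy)
    _check_boundary_contained(sol)
    return sol


def _check_boundary_contained(sol: PolicySolution) -> None:
    edge = sol.policy[:, :, :, [0, -1]]
    bad = (edge == Action.ACCUMULATE) | (edge == Action.SWITCH)
    if bad.any():
        raise GridTooSmallError(
            "accumulate region touches the Delta lattice edge; "
            "enlarge delta_max (and re-solve) so the decision boundary is contained"
        )


def _nearest_index(x, step: float):
    """Nearest lattice index with half-way ties toward the smaller index."""
    return np.ceil(np.asarray(x) / step - 0.5).astype(int)


def policy_lookup(
    sol: PolicySolution, delta: float, t1: float, t2: float, y: int
) -> Action:
    """Action at the nearest lattice point to ``(delta, t1, t2)`` for
    attention state ``y``; ``delta`` is clamped to the lattice."""
    if y not in (1, 2):
        raise ValueError(f"attended item y must be 1 or 2, got {y}")
    g = sol.grid
    if t1 + t2 > g.t_max + 1e-9:
        raise OutOfHorizonError(
            f"t1 + t2 = {t1 + t2:.4f} exceeds the horizon t_max = {g.t_max}; "
            "the caller must force a choice"
        )
    nt = g.n_t_steps
    i1 = int(np.clip(_nearest_index(t1, g.dt_grid), 0, nt))
    i2 = int(np.clip(_nearest_index(t2, g.dt_grid), 0, nt - i1))
    nd = sol.value.shape[-1]
    k = int(np.clip(_nearest_index(delta + g.delta_max, g.delta_step), 0, nd - 1))
    return Action(int(sol.policy[y - 1, i1, i2, k]))


def boundary_contours(sol: PolicySolution):
    """Boundary contours as tidy records for Fig-2-style plotting.

    For every attention state and ``(t1, t2)`` lattice point, scans the Delta
    axis for changes of the optimal action and records the midpoint of each
    change as one row ``(y, t1, t2, delta_boundary, action_below,
    action_above)``.  Returns a pandas DataFrame.
    """
    import pandas as pd

    g = sol.grid
    deltas = g.delta_axis
    rows = []
    nt = g.n_t_steps
    for yi in (0, 1):
        for i1 in range(nt + 1):
            for i2 in range(nt + 1 - i1):
                labels = sol.policy[yi, i1, i2]
                change = np.nonzero(np.diff(labels) != 0)[0]
                for k in change:
                    rows.append(
                        {
                            "y": yi + 1,
                            "t1": i1 * g.dt_grid,
                            "t2": i2 * g.dt_grid,
                            "delta_boundary": (deltas[k] + deltas[k + 1]) / 2.0,
                            "action_below": Action(int(labels[k])).name,
                            "action_above": Action(int(labels[k + 1])).name,
                        }
                    )
    return pd.DataFrame(rows)
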