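"""Attentional drift diffusion model (aDDM) baseline with matched
signal-to-noise evidence.

The aDDM is a one-dimensional accumulator with fixed (non-collapsing)
boundaries and *exogenous* fixations: while fixating item 1 it drifts by
``(z1 - theta*z2)*dt``, while fixating item 2 by ``(theta*z1 - z2)*dt``,
with additive Gaussian noise, and commits to item 1 (2) when the upper
(lower) boundary is crossed.  Fixation durations are drawn from an external
source and alternate between items; the model cannot end a fixation early.

For a fair reward comparison against the optimal policy, the aDDM's
discounting and noise are chosen so its momentary evidence carries the same
per-item Fisher information as the optimal model's: with accumulator noise
variance ``sigma_a2 = sigma_x2/(1-kappa)`` per second and discounting
``theta = sqrt(kappa/(1-kappa))``, one accumulator increment provides
information ``(1-kappa)/sigma_x2`` about the fixated item's value and
``kappa/sigma_x2`` about the unfixated one — exactly the optimal model's
attended/unattended information rates, for any ``kappa``.  (A raw
unit-weight difference of the two evidence streams would instead let the
unattended stream's ``sigma_x2/kappa`` variance swamp the accumulator at
small ``kappa`` — a property of bad pooling, not of the evidence.)  What
remains different, and is what the comparison isolates, is the aDDM's flat
boundaries and exogenous fixations.

Net-reward accounting is identical to the optimal model's
(``z_chosen - c*rt - c_s*n_switches``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .task_model import ModelParams
from .trial_simulator import TrialDesign, TrialRecord, Fixation

__all__ = [
    "ADDMParams",
    "EmpiricalFixationSource",
    "LogNormalFixationSource",
    "match_snr_params",
    "simulate_addm_trial",
    "simulate_addm_cohort",
    "addm_boundary_sweep",
]

_HARD_CAP_S = 20.0  # runaway-trial cap; forces a choice by accumulator sign


@dataclass
class EmpiricalFixationSource:
    """Resamples completed fixation durations from a simulated cohort,
    first fixations separately from later ones (mirroring the original
    aDDM's use of empirical fixation distributions)."""

    first: np.ndarray
    later: np.ndarray

    @classmethod
    def from_cohort(cls, trials: pd.DataFrame, fixations: pd.DataFrame) -> "EmpiricalFixationSource":
        """Pool completed (non-final) fixations of an optimal-model cohort."""
        n_fix = trials.set_index(["participant_id", "trial_id"])["n_switches"] + 1
        f = fixations.merge(
            n_fix.rename("n_fix"),
            left_on=["participant_id", "trial_id"],
            right_index=True,
        )
        completed = f[f["fixation_index"] < f["n_fix"]]
        first = completed.loc[completed["fixation_index"] == 1, "duration"].to_numpy()
        later = completed.loc[completed["fixation_index"] > 1, "duration"].to_numpy()
        if first.size == 0 or later.size == 0:
            raise ValueError("cohort has no completed first/later fixations to resample")
        return cls(first=first, later=later)

    def draw(self, n: int, first: bool, rng: np.random.Generator) -> np.ndarray:
        pool = self.first if first else self.later
        return rng.choice(pool, size=n, replace=True)


@dataclass
class LogNormalFixationSource:
    """Parametric fallback: log-normal fixation durations per index class."""

    first_median: float = 0.5
    later_median: float = 0.8
    sigma_log: float = 0.5

    def draw(self, n: int, first: bool, rng: np.random.Generator) -> np.ndarray:
        med = self.first_median if first else self.later_median
        return np.exp(rng.normal(np.log(med), self.sigma_log, size=n))


@dataclass
class ADDMParams:
    """aDDM configuration.

    ``theta`` discounts the unattended item's contribution; ``sigma_a2`` is
    the accumulator noise variance per second; ``boundary`` the threshold
    half-height.  ``charge_switch_cost`` keeps accounting parity with the
    optimal model by charging ``c_s`` per fixation alternation.
    """

    theta: float
    sigma_a2: float
    boundary: float
    dt_sim: float
    fixation_source: object
    charge_switch_cost: bool = True

    def __post_init__(self) -> None:
        if self.boundary <= 0:
            raise ValueError("boundary must be > 0")
        if self.sigma_a2 <= 0:
            raise ValueError("sigma_a2 must be > 0")
        # theta <= 1 in the classic aDDM; SNR-matching at kappa > 1/2 can
        # exceed 1 (the unfixated item then carries more information)
        if self.theta < 0:
            raise ValueError("theta must be non-negative")


def match_snr_params(
    params: ModelParams,
    fixation_source: object | None = None,
    boundary_in_sd: float = 1.0,
) -> ADDMParams:
    """aDDM parameters whose momentary evidence matches the optimal model's
    per-item signal-to-noise ratios.

    ``theta = sqrt(kappa/(1-kappa))`` and per-second accumulator variance
    ``sigma_a2 = sigma_x2/(1-kappa)``, the unique pair for which one
    accumulator increment carries Fisher information ``(1-kappa)/sigma_x2``
    about the fixated and ``kappa/sigma_x2`` about the unfixated item's
    value (see module docstring).  The boundary defaults to
    ``boundary_in_sd`` per-second accumulator SDs and is meant to be swept
    (:func:`addm_boundary_sweep`).
    """
    theta = float(np.sqrt(params.kappa / (1.0 - params.kappa)))
    sigma_a2 = params.sigma_x2 / (1.0 - params.kappa)
    if fixation_source is None:
        fixation_source = LogNormalFixationSource()
    return ADDMParams(
        theta=theta,
        sigma_a2=sigma_a2,
        boundary=boundary_in_sd * np.sqrt(sigma_a2),
        dt_sim=params.dt_sim,
        fixation_source=fixation_source,
    )


def _simulate_addm_batch(
    z: np.ndarray,
    addm: ADDMParams,
    params: ModelParams,
    rng: np.random.Generator,
):
    """Vectorized aDDM simulation; returns result arrays + fixation events."""
    n = z.shape[0]
    dt = addm.dt_sim
    sd_step = np.sqrt(addm.sigma_a2 * dt)
    theta = addm.theta
    B = addm.boundary

    A = np.zeros(n)
    y = rng.integers(1, 3, size=n)
    first_fixated = y.copy()
    remaining = np.asarray(addm.fixation_source.draw(n, True, rng), dtype=float)
    fix_start = np.zeros(n)
    n1 = np.zeros(n)
    n2 = np.zeros(n)
    n_switch = np.zeros(n, dtype=np.int64)
    choice = np.zeros(n, dtype=np.int64)
    rt = np.full(n, np.nan)
    final_A = np.zeros(n)
    active = np.ones(n, dtype=bool)
    events: list[tuple[int, int, float]] = []

    def end_fixations(idx, t):
        for i in idx:
            events.append((int(i), int(y[i]), float(t - fix_start[i])))

    n_steps = round(_HARD_CAP_S / dt)
    for step in range(1, n_steps + 1):
        idx = np.nonzero(active)[0]
        if idx.size == 0:
            break
        t = step * dt
        att1 = y[idx] == 1
        drift = np.where(att1, z[idx, 0] - theta * z[idx, 1], theta * z[idx, 0] - z[idx, 1])
        A[idx] += drift * dt + sd_step * rng.standard_normal(idx.size)
        n1[idx] += np.where(att1, dt, 0.0)
        n2[idx] += np.where(att1, 0.0, dt)

        hit = np.abs(A[idx]) >= B
        if hit.any():
            h = idx[hit]
            choice[h] = np.where(A[h] > 0, 1, 2)
            # exact tie A == B == -B impossible for B > 0
            rt[h] = t
            final_A[h] = A[h]
            active[h] = False
            end_fixations(h, t)

        idx = np.nonzero(active)[0]
        if idx.size:
            remaining[idx] -= dt
            done = remaining[idx] <= 1e-12
            if done.any():
                d = idx[done]
                end_fixations(d, t)
                y[d] = 3 - y[d]
                n_switch[d] += 1
                fix_start[d] = t
                remaining[d] = addm.fixation_source.draw(d.size, False, rng)

    # runaway trials: forced choice by accumulator sign (tie -> item 1)
    idx = np.nonzero(active)[0]
    if idx.size:
        warnings.warn(f"{idx.size} aDDM trials hit the {_HARD_CAP_S:.0f}s cap; forced by sign")
        choice[idx] = np.where(A[idx] > 0, 1, 2)
        rt[idx] = _HARD_CAP_S
        final_A[idx] = A[idx]
        end_fixations(idx, _HARD_CAP_S)

    z_chosen = np.where(choice == 1, z[:, 0], z[:, 1])
    switch_cost = params.c_s * n_switch if addm.charge_switch_cost else 0.0
    return {
        "z1": z[:, 0],
        "z2": z[:, 1],
        "choice": choice,
        "rt": rt,
        "n_switches": n_switch,
        "t1_total": n1,
        "t2_total": n2,
        "first_fixated": first_fixated,
        "last_fixated": y,
        "final_delta": final_A,  # accumulator state, the aDDM's decision variable
        "net_reward": z_chosen - params.c * rt - switch_cost,
    }, events


def simulate_addm_trial(
    z1: float,
    z2: float,
    addm: ADDMParams,
    params: ModelParams,
    rng: np.random.Generator,
) -> TrialRecord:
    """Simulate a single aDDM trial (see module docstring)."""
    res, events = _simulate_addm_batch(np.array([[z1, z2]], float), addm, params, rng)
    fixations = [Fixation(item=it, duration=d) for _, it, d in events]
    return TrialRecord(
        z1=z1,
        z2=z2,
        choice=int(res["choice"][0]),
        rt=float(res["rt"][0]),
        fixations=fixations,
        n_switches=int(res["n_switches"][0]),
        t1_total=float(res["t1_total"][0]),
        t2_total=float(res["t2_total"][0]),
        first_fixated=int(res["first_fixated"][0]),
        last_fixated=int(res["last_fixated"][0]),
        final_delta=float(res["final_delta"][0]),
        net_reward=float(res["net_reward"][0]),
    )


def simulate_addm_cohort(
    design: TrialDesign,
    addm: ADDMParams,
    params: ModelParams,
    master_seed: int,
) -> pd.DataFrame:
    """Simulate an aDDM cohort; same seeding/shuffling scheme as the optimal
    model's cohort simulator.  Returns a trials DataFrame."""
    streams = np.random.SeedSequence(master_seed).spawn(design.participants)
    frames = []
    for pid, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        order = rng.permutation(design.n_trials)
        res, _ = _simulate_addm_batch(design.pairs[order], addm, params, rng)
        tf = pd.DataFrame(res)
        tf.insert(0, "trial_id", np.arange(design.n_trials))
        tf.insert(0, "participant_id", pid)
        frames.append(tf)
    return pd.concat(frames, ignore_index=True)


def addm_boundary_sweep(
    heights: list[float],
    design: TrialDesign,
    addm: ADDMParams,
    params: ModelParams,
    seed: int,
) -> pd.DataFrame:
    """Mean net reward of the aDDM cohort at each boundary height.

    Returns one row per height with the across-participant mean and SEM of
    per-participant mean net rewards, flagging the argmax; warns when the
    best height sits at an endpoint of the sweep (the sweep should then be
    extended).
    """
    heights = list(heights)
    if any(h <= 0 for h in heights):
        raise ValueError("boundary heights must be positive")
    if sorted(heights) != heights:
        raise ValueError("boundary heights must be increasing")
    rows = []
    for h in heights:
        trials = simulate_addm_cohort(design, replace(addm, boundary=h), params, seed)
        per = trials.groupby("participant_id")["net_reward"].mean()
        rows.append(
            {"height": h, "mean_reward": per.mean(), "sem": per.sem(), "n_participants": len(per)}
        )
    table = pd.DataFrame(rows)
    best = int(table["mean_reward"].idxmax())
    table["is_best"] = False
    table.loc[best, "is_best"] = True
    if len(heights) > 1 and best in (0, len(heights) - 1):
        warnings.warn(
            f"reward-maximizing boundary {heights[best]:.3g} is an endpoint of the sweep; "
            "consider widening the height range"
        )
    return table
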