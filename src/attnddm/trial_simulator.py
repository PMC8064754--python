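"""Free-response trial simulation under the solved optimal policy.

Each trial steps the generative model at ``dt_sim`` (default 0.01 s) and
updates the Bayesian belief every step, but consults the policy only at the
solver's decision epochs (multiples of ``dt_grid``): the Bellman recursion's
"accumulate" action commits to one full grid step of evidence, so checking
the absorbing boundaries more often than the policy assumes would terminate
fixations systematically earlier than the optimal policy intends.  Attention
switches are endogenous: they occur exactly when the state enters the
policy's switch region at an epoch, are instantaneous in time, and are
charged the switch cost.  A trial ends when the state enters a choose
region, or at the horizon ``t_max`` where the larger posterior mean is
chosen (tie -> item 1).

The net reward of a trial is ``z_chosen - c*rt - c_s*n_switches`` — the same
accounting used for the aDDM baseline, so model comparisons are like for
like.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .policy_solver import Action, PolicySolution, _nearest_index
from .task_model import ModelParams, posterior_moments

__all__ = [
    "TrialDesign",
    "Fixation",
    "TrialRecord",
    "generate_trial_design",
    "simulate_trial",
    "simulate_cohort",
    "TRIALS_COLUMNS",
    "FIXATIONS_COLUMNS",
    "save_cohort",
    "load_cohort",
]

TRIALS_COLUMNS = [
    "participant_id",
    "trial_id",
    "z1",
    "z2",
    "choice",
    "rt",
    "n_switches",
    "t1_total",
    "t2_total",
    "first_fixated",
    "last_fixated",
    "final_delta",
    "net_reward",
]

FIXATIONS_COLUMNS = ["participant_id", "trial_id", "fixation_index", "item", "duration"]


@dataclass(frozen=True)
class TrialDesign:
    """All ordered value pairs over an integer range, repeated ``reps`` times
    per participant (order is shuffled per participant at simulation time)."""

    pairs: np.ndarray  # (n_trials, 2) float
    participants: int
    reps: int

    @property
    def n_trials(self) -> int:
        return self.pairs.shape[0]


@dataclass(frozen=True)
class Fixation:
    item: int
    duration: float


@dataclass
class TrialRecord:
    """One simulated (or observed) trial."""

    z1: float
    z2: float
    choice: int
    rt: float
    fixations: list[Fixation] = field(default_factory=list)
    n_switches: int = 0
    t1_total: float = 0.0
    t2_total: float = 0.0
    first_fixated: int = 1
    last_fixated: int = 1
    final_delta: float = 0.0
    net_reward: float = 0.0


def generate_trial_design(
    value_min: int, value_max: int, reps: int, participants: int
) -> TrialDesign:
    """All ordered pairs ``(v_i, v_j)`` over the integer range, each repeated
    ``reps`` times.  The published task uses values 0-7 with 20 repetitions,
    i.e. 8*8*20 = 1280 trials per participant."""
    if value_max < value_min:
        raise ValueError("value_max must be >= value_min")
    if reps < 1 or participants < 1:
        raise ValueError("reps and participants must be >= 1")
    values = np.arange(value_min, value_max + 1, dtype=float)
    pairs = np.array([(v1, v2) for v1 in values for v2 in values])
    pairs = np.tile(pairs, (reps, 1))
    return TrialDesign(pairs=pairs, participants=participants, reps=reps)


def _simulate_batch(
    z: np.ndarray,
    sol: PolicySolution,
    params: ModelParams,
    rng: np.random.Generator,
    record_fixations: bool = True,
):
    """Vectorized free-response simulation of a batch of trials.

    Returns a dict of per-trial result arrays plus a fixation event list of
    ``(trial_index, item, duration)`` in fixation order.
    """
    n = z.shape[0]
    dt = params.dt_sim
    g = sol.grid
    nt = g.n_t_steps
    nd = sol.policy.shape[-1]
    k_c = params.unattended_weight
    sd_att = np.sqrt(params.sigma_x2 * dt / (1.0 - params.kappa))
    sd_un = np.sqrt(params.sigma_x2 * dt / params.kappa)

    X1 = np.zeros(n)
    X2 = np.zeros(n)
    n1 = np.zeros(n, dtype=np.int64)  # attention steps on item 1 (dt units)
    n2 = np.zeros(n, dtype=np.int64)
    y = rng.integers(1, 3, size=n)  # initial attention uniform at random
    first_fixated = y.copy()
    fix_start = np.zeros(n)
    n_switch = np.zeros(n, dtype=np.int64)
    choice = np.zeros(n, dtype=np.int64)
    rt = np.full(n, np.nan)
    final_delta = np.full(n, np.nan)
    active = np.ones(n, dtype=bool)
    fixation_events: list[tuple[int, int, float]] = []

    def end_fixations(idx, t):
        if record_fixations and idx.size:
            dur = t - fix_start[idx]
            for i, d in zip(idx, dur):
                fixation_events.append((int(i), int(y[i]), float(d)))

    def finish(idx, t, chosen):
        choice[idx] = chosen
        rt[idx] = t
        active[idx] = False
        end_fixations(idx, t)

    stride = max(1, round(g.dt_grid / dt))  # sim steps per decision epoch
    n_steps_max = round(g.t_max / dt)
    for step in range(n_steps_max + 1):
        if not active.any():
            break
        t = step * dt
        idx = np.nonzero(active)[0]
        m1, m2, _, _ = posterior_moments(
            X1[idx], X2[idx], n1[idx] * dt, n2[idx] * dt, params
        )
        delta = m2 - m1
        final_delta[idx] = delta

        if step == n_steps_max:  # horizon: force the larger posterior mean
            finish(idx, t, np.where(m2 > m1, 2, 1))
            break

        if step % stride == 0:  # decision epoch
            i1 = np.clip(_nearest_index(n1[idx] * dt, g.dt_grid), 0, nt)
            i2 = np.clip(_nearest_index(n2[idx] * dt, g.dt_grid), 0, nt - i1)
            kk = np.clip(_nearest_index(delta + g.delta_max, g.delta_step), 0, nd - 1)
            act = sol.policy[y[idx] - 1, i1, i2, kk]

            ch = (act == Action.CHOOSE_1) | (act == Action.CHOOSE_2)
            if ch.any():
                finish(idx[ch], t, np.where(act[ch] == Action.CHOOSE_2, 2, 1))

            sw = act == Action.SWITCH
            if sw.any():
                sidx = idx[sw]
                end_fixations(sidx, t)
                y[sidx] = 3 - y[sidx]
                n_switch[sidx] += 1
                fix_start[sidx] = t
                # re-lookup without advancing time; the switch region under one
                # attention state must lie in the other's accumulate region
                act2 = sol.policy[y[sidx] - 1, i1[sw], i2[sw], kk[sw]]
                if (act2 == Action.SWITCH).any():
                    raise RuntimeError(
                        "policy demanded an immediate switch-back; the solved grid "
                        "violates the switch-in-accumulate nesting invariant"
                    )
                ch2 = (act2 == Action.CHOOSE_1) | (act2 == Action.CHOOSE_2)
                if ch2.any():
                    finish(sidx[ch2], t, np.where(act2[ch2] == Action.CHOOSE_2, 2, 1))

        # accumulate one dt of evidence for the trials still running
        run = np.nonzero(active)[0]
        if run.size == 0:
            continue
        att1 = y[run] == 1
        sd1 = np.where(att1, sd_att, sd_un)
        sd2 = np.where(att1, sd_un, sd_att)
        dx1 = z[run, 0] * dt + sd1 * rng.standard_normal(run.size)
        dx2 = z[run, 1] * dt + sd2 * rng.standard_normal(run.size)
        X1[run] += np.where(att1, dx1, k_c * dx1)
        X2[run] += np.where(att1, k_c * dx2, dx2)
        n1[run] += att1
        n2[run] += ~att1

    z_chosen = np.where(choice == 1, z[:, 0], z[:, 1])
    return {
        "z1": z[:, 0],
        "z2": z[:, 1],
        "choice": choice,
        "rt": rt,
        "n_switches": n_switch,
        "t1_total": n1 * dt,
        "t2_total": n2 * dt,
        "first_fixated": first_fixated,
        "last_fixated": y,
        "final_delta": final_delta,
        "net_reward": z_chosen - params.c * rt - params.c_s * n_switch,
    }, fixation_events


def simulate_trial(
    z1: float,
    z2: float,
    sol: PolicySolution,
    params: ModelParams,
    rng: np.random.Generator,
) -> TrialRecord:
    """Simulate a single free-response trial; see the module docstring."""
    res, events = _simulate_batch(np.array([[z1, z2]], dtype=float), sol, params, rng)
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


def simulate_cohort(
    design: TrialDesign,
    sol: PolicySolution,
    params: ModelParams,
    master_seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate every participant in the design.

    Per-participant RNG streams are spawned deterministically from
    ``master_seed`` (identical inputs reproduce identical outputs
    bit-for-bit), and each participant sees the design's trials in their own
    shuffled order.

    Returns
    -------
    (trials, fixations) : tuple of DataFrame
        ``trials`` has one row per trial (:data:`TRIALS_COLUMNS`);
        ``fixations`` is long format (:data:`FIXATIONS_COLUMNS`), fixation
        index 1-based in presentation order.
    """
    streams = np.random.SeedSequence(master_seed).spawn(design.participants)
    trial_frames = []
    fix_frames = []
    for pid, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        order = rng.permutation(design.n_trials)
        z = design.pairs[order]
        res, events = _simulate_batch(z, sol, params, rng)
        tf = pd.DataFrame(res)
        tf.insert(0, "trial_id", np.arange(design.n_trials))
        tf.insert(0, "participant_id", pid)
        trial_frames.append(tf)
        if events:
            ev = pd.DataFrame(events, columns=["trial_id", "item", "duration"])
            ev["fixation_index"] = ev.groupby("trial_id").cumcount() + 1
            ev.insert(0, "participant_id", pid)
            fix_frames.append(ev[FIXATIONS_COLUMNS])
    trials = pd.concat(trial_frames, ignore_index=True)[TRIALS_COLUMNS]
    fixations = pd.concat(fix_frames, ignore_index=True)
    return trials, fixations


def save_cohort(trials: pd.DataFrame, fixations: pd.DataFrame, outdir) -> None:
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    trials.to_csv(out / "trials.csv", index=False)
    fixations.to_csv(out / "fixations.csv", index=False)


def load_cohort(outdir) -> tuple[pd.DataFrame, pd.DataFrame]:
    from pathlib import Path

    out = Path(outdir)
    trials = pd.read_csv(out / "trials.csv")
    fixations = pd.read_csv(out / "fixations.csv")
    missing = set(TRIALS_COLUMNS) - set(trials.columns)
    if missing:
        raise ValueError(f"trials.csv missing required columns: {sorted(missing)}")
    missing = set(FIXATIONS_COLUMNS) - set(fixations.columns)
    if missing:
        raise ValueError(f"fixations.csv missing required columns: {sorted(missing)}")
    return trials, fixations
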