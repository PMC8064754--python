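"""Orchestration: configuration, the kappa sweep, the reduced-scale random
parameter search, and the end-to-end pipeline that regenerates the
model-side behavioral statistics."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as bh
from .addm import EmpiricalFixationSource, addm_boundary_sweep, match_snr_params, simulate_addm_cohort
from .policy_solver import GridSpec, GridTooSmallError, PolicySolution, solve_policy
from .task_model import ModelParams
from .trial_simulator import TrialDesign, generate_trial_design, save_cohort, simulate_cohort

log = logging.getLogger("attnddm")

__all__ = [
    "DesignSpec",
    "ExperimentConfig",
    "run_kappa_sweep",
    "random_parameter_search",
    "summary_curves",
    "curve_discrepancy",
    "reproduce_paper_stats",
]

#: Published model-side statistics, attached to pipeline output as reference
#: fields only (never substituted for computed values).
PUBLISHED_REFERENCE = {
    "psychometric_t": 105.7,
    "rt_vs_difficulty_t": -11.1,
    "switches_vs_difficulty_t": -8.10,
    "choice_bias_t": 5.32,
    "bias_vs_rt_t": -32.0,
    "bias_vs_value_sum_t": 11.4,
    "optimal_vs_addm_t": 3.01,
    "kappa_peak_t": -8.51,
}


@dataclass(frozen=True)
class DesignSpec:
    value_min: int = 0
    value_max: int = 7
    reps: int = 20
    participants: int = 39

    def build(self) -> TrialDesign:
        return generate_trial_design(self.value_min, self.value_max, self.reps, self.participants)


@dataclass
class ExperimentConfig:
    """Everything a run needs; round-trips losslessly through JSON/YAML."""

    model: ModelParams = field(default_factory=ModelParams)
    design: DesignSpec = field(default_factory=DesignSpec)
    seed: int = 0
    kappa_list: list[float] = field(default_factory=lambda: [round(0.1 * k, 1) for k in range(1, 10)])
    kappa_reps: int = 10
    addm_n_heights: int = 16
    addm_height_range_sd: tuple[float, float] = (0.25, 4.0)
    addm_sweep_reps: int = 5
    search_n_iter: int = 50
    outdir: str = "results"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["addm_height_range_sd"] = list(d["addm_height_range_sd"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "model" in d:
            d["model"] = ModelParams(**d["model"])
        if "design" in d:
            d["design"] = DesignSpec(**d["design"])
        if "addm_height_range_sd" in d:
            d["addm_height_range_sd"] = tuple(d["addm_height_range_sd"])
        return cls(**d)

    @classmethod
    def load(cls, path) -> "ExperimentConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls.from_dict(data)

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix in (".yml", ".yaml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))


def _write_run_metadata(outdir: Path, config: ExperimentConfig, seed: int, extra: dict) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    config.save(outdir / "resolved_config.json")
    meta = {"seed": seed, **extra}
    (outdir / "run_metadata.json").write_text(json.dumps(meta, indent=2))


def run_kappa_sweep(
    config: ExperimentConfig,
    seed: int | None = None,
    outdir: str | Path | None = None,
):
    """Per-participant mean net reward at each kappa, plus the peak test.

    For each kappa the policy is re-solved (all other parameters fixed at
    the config profile) and a cohort is simulated with ``kappa_reps``
    repetitions per value pair.  Returns ``(rewards, summary)`` where
    ``rewards`` has one row per (participant, kappa) and ``summary`` is the
    :func:`attnddm.behavior.kappa_peak_test` result (None with < 3 levels).
    """
    for k in config.kappa_list:
        if not 0.0 < k < 1.0:
            raise ValueError(f"kappa={k} rejected: must lie strictly inside (0, 1)")
    design = DesignSpec(
        config.design.value_min,
        config.design.value_max,
        config.kappa_reps,
        config.design.participants,
    ).build()
    seed = config.seed if seed is None else seed
    rows = []
    for i, k in enumerate(config.kappa_list):
        t0 = time.perf_counter()
        params = config.model.with_(kappa=k)
        sol = solve_policy(params)
        trials, _ = simulate_cohort(design, sol, params, master_seed=seed + 1000 * (i + 1))
        per = trials.groupby("participant_id")["net_reward"].mean()
        rows.extend(
            {"participant_id": pid, "kappa": k, "mean_reward": r} for pid, r in per.items()
        )
        log.info("kappa=%.2f solved+simulated in %.1fs", k, time.perf_counter() - t0)
    rewards = pd.DataFrame(rows)
    summary = None
    if len(config.kappa_list) >= 3:
        summary = bh.kappa_peak_test(rewards)
    if outdir is not None:
        outdir = Path(outdir)
        _write_run_metadata(outdir, config, seed, {"rows": len(rewards)})
        rewards.to_csv(outdir / "kappa_rewards.csv", index=False)
    return rewards, summary


def summary_curves(trials: pd.DataFrame, fixations: pd.DataFrame) -> dict[str, np.ndarray]:
    """Behavioral summary curves used as the parameter-search objective:
    psychometric (P(choose 1) per value difference), mean RT and mean switch
    count per absolute value difference, and mean duration of fixations
    1-3."""
    diff = (trials["z1"] - trials["z2"]).astype(int)
    adiff = diff.abs()
    psycho = (trials["choice"] == 1).groupby(diff).mean()
    rt = trials.groupby(adiff)["rt"].mean()
    sw = trials.groupby(adiff)["n_switches"].mean()
    fx = fixations[fixations["fixation_index"] <= 3].groupby("fixation_index")["duration"].mean()
    return {
        "psychometric": psycho.to_numpy(),
        "rt_by_difficulty": rt.to_numpy(),
        "switches_by_difficulty": sw.to_numpy(),
        "fixation_order": fx.reindex([1, 2, 3]).to_numpy(),
    }


def curve_discrepancy(a: dict[str, np.ndarray], b: dict[str, np.ndarray]) -> float:
    """Equal-weight normalized RMSE across the four summary curves.

    Non-negative; zero only when the curves are identical.  Each curve's
    RMSE is normalized by the target curve's standard deviation (or its
    absolute mean when constant) so curves on different scales contribute
    comparably.
    """
    total = 0.0
    for key, target in b.items():
        x = np.asarray(a[key], float)
        t = np.asarray(target, float)
        if x.shape != t.shape:
            raise ValueError(f"curve {key!r} shapes differ: {x.shape} vs {t.shape}")
        mask = np.isfinite(x) & np.isfinite(t)
        rmse = np.sqrt(np.mean((x[mask] - t[mask]) ** 2))
        scale = np.std(t[mask])
        if scale == 0:
            scale = max(abs(np.mean(t[mask])), 1.0)
        total += rmse / scale
    return total / len(b)


def random_parameter_search(
    ranges: dict[str, tuple[float, float]],
    n_iter: int,
    target: dict[str, np.ndarray],
    seed: int,
    base: ModelParams | None = None,
    design: DesignSpec | None = None,
) -> pd.DataFrame:
    """Random search for parameters whose simulated behavior matches target
    summary curves.

    ``ranges`` maps parameter names (any of sigma_x2, sigma_z2, c, c_s,
    kappa) to (low, high); variances and costs are sampled log-uniformly,
    kappa uniformly.  Each draw solves the policy, simulates a reduced
    cohort, and scores :func:`curve_discrepancy` against ``target``;
    infeasible draws (boundary not contained in the lattice) score ``inf``.
    Deterministic given ``seed``; returns the table sorted by score.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    base = base or ModelParams()
    design = design or DesignSpec(reps=2, participants=3)
    built = design.build()
    rng = np.random.default_rng(seed)
    log_uniform = {"sigma_x2", "sigma_z2", "c", "c_s"}
    rows = []
    for it in range(n_iter):
        draw = {}
        for name, (lo, hi) in ranges.items():
            if name in log_uniform:
                draw[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            else:
                draw[name] = float(rng.uniform(lo, hi))
        params = base.with_(**draw)
        try:
            sol = solve_policy(params)
            trials, fix = simulate_cohort(built, sol, params, master_seed=seed + it)
            score = curve_discrepancy(summary_curves(trials, fix), target)
        except GridTooSmallError:
            log.warning("iteration %d infeasible (boundary not contained): %s", it, draw)
            score = np.inf
        rows.append({"iteration": it, **draw, "score": score})
    table = pd.DataFrame(rows).sort_values("score", kind="stable").reset_index(drop=True)
    return table


def reproduce_paper_stats(
    config: ExperimentConfig | None = None,
    seed: int | None = None,
    outdir: str | Path | None = None,
    n_fixation_bins: int = 6,
    n_value_sum_bins: int = 5,
) -> dict:
    """End-to-end pipeline: solve the policy at the config profile, simulate
    the cohort, run the full analysis suite, and return the statistics
    table (with the published values attached as reference fields)."""
    config = config or ExperimentConfig()
    seed = config.seed if seed is None else seed
    t0 = time.perf_counter()
    sol = solve_policy(config.model)
    log.info("policy solved in %.1fs", time.perf_counter() - t0)
    design = config.design.build()
    t0 = time.perf_counter()
    trials, fixations = simulate_cohort(design, sol, config.model, master_seed=seed)
    log.info(
        "simulated %d trials x %d participants in %.1fs",
        design.n_trials,
        design.participants,
        time.perf_counter() - t0,
    )

    diff = trials["z1"] - trials["z2"]
    pid = trials["participant_id"]
    results = {
        "psychometric": bh.slope_ttest(diff, (trials["choice"] == 1).astype(float), pid),
        "rt_vs_difficulty": bh.slope_ttest(diff.abs(), trials["rt"], pid),
        "switches_vs_difficulty": bh.slope_ttest(diff.abs(), trials["n_switches"], pid),
        "switch_rate_vs_difficulty": bh.slope_ttest(
            diff.abs(), trials["n_switches"] / trials["rt"].clip(lower=config.model.dt_sim), pid
        ),
        "choice_bias": bh.choice_bias_coefficient(trials, adjust_for_value=True),
        "choice_bias_unadjusted": bh.choice_bias_coefficient(trials),
    }
    trials = trials.assign(
        n_fixations=trials["n_switches"] + 1, value_sum=trials["z1"] + trials["z2"]
    )
    try:
        rt_bins = bh.bin_by_quantile(trials, "n_fixations", n_fixation_bins)
        results["bias_vs_rt"] = bh.bias_by_bin(trials, rt_bins, "rt")["trend"]
        vs_bins = bh.bin_by_quantile(trials, "value_sum", n_value_sum_bins)
        results["bias_vs_value_sum"] = bh.bias_by_bin(trials, vs_bins, "value_sum")["trend"]
    except ValueError as err:  # too few trials per (participant, bin) cell
        log.warning("binned bias analyses skipped: %s", err)

    out = {
        name: (summary.to_dict() if summary is not None else None)
        for name, summary in results.items()
    }
    out["fixation_order"] = bh.fixation_order_stats(fixations).reset_index().to_dict("records")
    out["p_choose_last_fixated"] = float((trials["choice"] == trials["last_fixated"]).mean())
    out["published_reference"] = PUBLISHED_REFERENCE
    out["n_trials"] = int(len(trials))
    out["policy_hash"] = sol.content_hash()
    out["seed"] = seed

    if outdir is not None:
        outdir = Path(outdir)
        _write_run_metadata(
            outdir, config, seed, {"rows": len(trials), "policy_hash": sol.content_hash()}
        )
        save_cohort(trials[[c for c in trials.columns if not c.startswith("_")]], fixations, outdir)
        (outdir / "results.json").write_text(json.dumps(out, indent=2))
    return out


def run_addm_comparison(
    config: ExperimentConfig,
    seed: int | None = None,
) -> dict:
    """Optimal-policy vs SNR-matched aDDM reward comparison.

    Simulates the optimal cohort, builds the empirical fixation source from
    it, sweeps aDDM boundary heights on a reduced design, then compares
    per-participant mean net rewards at the best height on the full design
    (equal-variance independent-samples t-test, df = 2N - 2).
    """
    from dataclasses import replace as _replace

    seed = config.seed if seed is None else seed
    sol = solve_policy(config.model)
    design = config.design.build()
    trials, fixations = simulate_cohort(design, sol, config.model, master_seed=seed)
    source = EmpiricalFixationSource.from_cohort(trials, fixations)
    addm = match_snr_params(config.model, fixation_source=source)
    sd = float(np.sqrt(addm.sigma_a2))
    lo, hi = config.addm_height_range_sd
    heights = list(np.linspace(lo * sd, hi * sd, config.addm_n_heights))
    sweep_design = DesignSpec(
        config.design.value_min,
        config.design.value_max,
        config.addm_sweep_reps,
        config.design.participants,
    ).build()
    table = addm_boundary_sweep(heights, sweep_design, addm, config.model, seed=seed + 1)
    best_h = float(table.loc[table["is_best"], "height"].iloc[0])
    addm_trials = simulate_addm_cohort(
        design, _replace(addm, boundary=best_h), config.model, master_seed=seed + 2
    )
    comparison = bh.compare_mean_rewards(
        trials.groupby("participant_id")["net_reward"].mean(),
        addm_trials.groupby("participant_id")["net_reward"].mean(),
    )
    return {
        "sweep": table,
        "best_height": best_h,
        "comparison": comparison,
        "optimal_mean_reward": float(trials["net_reward"].mean()),
        "addm_mean_reward": float(addm_trials["net_reward"].mean()),
    }
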