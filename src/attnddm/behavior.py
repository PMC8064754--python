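"""Behavioral statistics: per-participant regressions with across-participant
one-sample t-tests, the fixation-driven choice-bias coefficient, binned bias
analyses, fixation-order statistics, and model performance comparisons.

All tests are two-sided.  Per-participant slopes come from OLS (linear
outcomes) or maximum-likelihood logistic regression (binary choice); the
group-level statistic is a one-sample t-test of the slopes against zero with
``df = participants - 1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RegressionSummary",
    "slope_ttest",
    "choice_bias_coefficient",
    "normalized_choice_prob",
    "bin_by_quantile",
    "bias_by_bin",
    "fixation_order_stats",
    "kappa_peak_test",
    "compare_mean_rewards",
]


@dataclass
class RegressionSummary:
    """Per-participant coefficients plus the across-participant t-test."""

    coefficients: np.ndarray
    t_stat: float
    p_value: float
    df: int
    n_excluded: int = 0
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "coefficients": np.asarray(self.coefficients).tolist(),
            "t": self.t_stat,
            "p": self.p_value,
            "df": self.df,
            "n_excluded": self.n_excluded,
            "flags": list(self.flags),
        }


def _one_sample_t(coefs: np.ndarray) -> tuple[float, float, list[str]]:
    """t-test of coefficients against 0; constant coefficients get a signed
    infinity sentinel instead of a 0/0."""
    coefs = np.asarray(coefs, dtype=float)
    if coefs.size < 2:
        raise ValueError("need at least 2 participants for a group t-test")
    if np.ptp(coefs) == 0:
        m = coefs[0]
        if m == 0:
            return 0.0, 1.0, ["zero-variance coefficients, all zero"]
        return float(np.sign(m) * np.inf), 0.0, ["zero-variance coefficients"]
    t, p = stats.ttest_1samp(coefs, 0.0)
    return float(t), float(p), []


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(beta[1])


def slope_ttest(x, y, participant) -> RegressionSummary:
    """OLS slope of ``y`` on ``x`` within each participant, then a one-sample
    t-test of the slopes across participants.

    Participants with constant ``x`` are excluded with a warning; if all are
    excluded this is an error.
    """
    df_in = pd.DataFrame(
        {"x": np.asarray(x, float), "y": np.asarray(y, float), "p": np.asarray(participant)}
    )
    slopes = []
    n_excluded = 0
    for pid, grp in df_in.groupby("p"):
        if len(grp) < 3 or np.ptp(grp["x"].to_numpy()) == 0:
            warnings.warn(f"participant {pid!r} excluded: constant predictor or <3 trials")
            n_excluded += 1
            continue
        slopes.append(_ols_slope(grp["x"], grp["y"]))
    if not slopes:
        raise ValueError("all participants excluded (constant predictor everywhere)")
    slopes = np.array(slopes)
    t, p, flags = _one_sample_t(slopes)
    return RegressionSummary(slopes, t, p, df=len(slopes) - 1, n_excluded=n_excluded, flags=flags)


def _logistic_slope(x, y01: np.ndarray, ridge: float = 1e-4, tol: float = 1e-8):
    """ML logistic slope of a binary outcome on a predictor (intercept
    included; ``x`` may carry extra covariate columns — the reported slope is
    always the first predictor's).  Falls back to a small-ridge Newton fit on
    separation or non-convergence; returns (slope, used_ridge)."""
    x = np.asarray(x, float)
    if x.ndim == 1:
        x = x[:, None]
    X = np.column_stack([np.ones(len(x)), x])
    y01 = np.asarray(y01, float)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y01, X).fit(disp=0, maxiter=200, tol=tol)
        if res.mle_retvals.get("converged", False) and np.all(np.abs(res.params) < 1e4):
            return float(res.params[1]), False
    except Exception:
        pass
    # ridge-penalized Newton (penalty on all coefficients)
    k = X.shape[1]
    beta = np.zeros(k)
    for _ in range(200):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        H = X.T @ (X * w[:, None]) + ridge * np.eye(k)
        g = X.T @ (y01 - p) - ridge * beta
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return float(beta[1]), True


def choice_bias_coefficient(
    trials: pd.DataFrame,
    participant_col: str = "participant_id",
    adjust_for_value: bool = False,
) -> RegressionSummary:
    """Fixation-driven choice bias.

    Per participant: logistic regression of the item-1 choice indicator on
    the fixation-time difference ``t1_total - t2_total`` (with intercept);
    then a one-sample t-test of the slopes across participants.  The
    resulting t statistic is the *choice bias coefficient*.

    With ``adjust_for_value=True`` the value difference ``z1 - z2`` enters as
    a covariate, isolating the fixation effect from the value effect — the
    logistic counterpart of plotting choice probabilities normalized per
    value-difference level.  With endogenous fixations the unadjusted slope
    confounds the two (dwelling long on an item often means its evidence was
    unconvincing), so the adjusted form is what the simulated-cohort bias
    analyses use.
    """
    slopes = []
    flags = []
    for pid, grp in trials.groupby(participant_col):
        dx = (grp["t1_total"] - grp["t2_total"]).to_numpy()
        if adjust_for_value:
            dx = np.column_stack([dx, (grp["z1"] - grp["z2"]).to_numpy()])
        y01 = (grp["choice"] == 1).to_numpy()
        slope, ridged = _logistic_slope(dx, y01)
        if ridged:
            flags.append(f"participant {pid}: ridge fallback (separation)")
        slopes.append(slope)
    slopes = np.array(slopes)
    t, p, tflags = _one_sample_t(slopes)
    return RegressionSummary(slopes, t, p, df=len(slopes) - 1, flags=flags + tflags)


def normalized_choice_prob(trials: pd.DataFrame, diff_col: str | None = None) -> pd.Series:
    """Centered choice indicator: ``1[choice==1]`` minus the cohort mean
    P(choose 1) at the trial's value-difference level.  Centered values
    average to zero within every level."""
    if diff_col is None:
        diff = trials["z1"] - trials["z2"]
    else:
        diff = trials[diff_col]
    ind = (trials["choice"] == 1).astype(float)
    return ind - ind.groupby(diff).transform("mean")


def bin_by_quantile(trials: pd.DataFrame, key: str, n_bins: int) -> pd.Series:
    """Equal-count bins of a continuous column, or value bins for integer
    keys (e.g. fixation counts).  Returns integer labels aligned to trials."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    col = trials[key]
    if pd.api.types.is_integer_dtype(col) and col.nunique() <= n_bins:
        codes, _ = pd.factorize(col, sort=True)
        return pd.Series(codes, index=trials.index, name=f"{key}_bin")
    # rank-based to give ties a stable, order-independent resolution
    ranks = col.rank(method="first")
    labels = pd.qcut(ranks, q=n_bins, labels=False)
    return pd.Series(labels, index=trials.index, name=f"{key}_bin")


def bias_by_bin(
    trials: pd.DataFrame,
    bin_labels: pd.Series,
    x_col: str,
    participant_col: str = "participant_id",
    min_trials: int = 10,
    method: str = "normalized_linear",
) -> dict:
    """Choice-bias coefficient within each bin, and its trend across bins.

    Per participant and bin: a bias slope of choice on fixation-time
    difference — by default the linear slope of the value-difference-
    normalized choice indicator (``method="normalized_linear"``; robust
    inside bins where fixation time and choice are near-deterministically
    linked), or ``method="logistic"`` for the plain logistic slope.
    ``per_bin`` reports the across-participant t-test within each bin (the
    bin's choice-bias coefficient); ``trend`` regresses each participant's
    per-bin slopes on their per-bin mean of ``x_col`` and t-tests those
    regression slopes across participants.  Bins with fewer than
    ``min_trials`` trials for a participant are dropped for that
    participant.
    """
    if method not in ("normalized_linear", "logistic"):
        raise ValueError(f"unknown method {method!r}")
    d = trials.copy()
    d["_bin"] = np.asarray(bin_labels)
    d["_nc"] = normalized_choice_prob(d)
    rows = []
    for (pid, b), grp in d.groupby([participant_col, "_bin"]):
        if len(grp) < min_trials:
            continue
        dx = (grp["t1_total"] - grp["t2_total"]).to_numpy()
        y01 = (grp["choice"] == 1).to_numpy()
        if np.ptp(dx) == 0 or y01.all() or (~y01).all():
            continue
        if method == "logistic":
            slope, _ = _logistic_slope(dx, y01)
        else:
            slope = _ols_slope(dx, grp["_nc"].to_numpy())
        rows.append({"participant": pid, "bin": b, "coef": slope, "x": grp[x_col].mean()})
    per = pd.DataFrame(rows)
    if per.empty:
        raise ValueError("no (participant, bin) cell had enough usable trials")

    per_bin = {}
    for b, grp in per.groupby("bin"):
        if len(grp) < 2:
            continue
        t, p, flags = _one_sample_t(grp["coef"].to_numpy())
        per_bin[b] = RegressionSummary(
            grp["coef"].to_numpy(), t, p, df=len(grp) - 1, flags=flags
        )

    trend_slopes = []
    for pid, grp in per.groupby("participant"):
        if len(grp) < 3 or np.ptp(grp["x"].to_numpy()) == 0:
            continue
        trend_slopes.append(_ols_slope(grp["x"], grp["coef"]))
    trend = None
    if len(trend_slopes) >= 2:
        trend_slopes = np.array(trend_slopes)
        t, p, flags = _one_sample_t(trend_slopes)
        trend = RegressionSummary(trend_slopes, t, p, df=len(trend_slopes) - 1, flags=flags)
    return {"per_participant_bin": per, "per_bin": per_bin, "trend": trend}


def fixation_order_stats(
    fixations: pd.DataFrame,
    participant_col: str = "participant_id",
    max_index: int = 3,
) -> pd.DataFrame:
    """Mean fixation duration per fixation index (1st, 2nd, 3rd, ...).

    Per-participant means first (trials lacking an index are excluded for
    that index), then the cohort mean and SEM across participants.
    """
    f = fixations[fixations["fixation_index"] <= max_index]
    per = f.groupby([participant_col, "fixation_index"])["duration"].mean().reset_index()
    out = per.groupby("fixation_index")["duration"].agg(["mean", "sem", "count"])
    out.columns = ["mean_duration", "sem", "n_participants"]
    return out


def kappa_peak_test(rewards: pd.DataFrame, participant_col: str = "participant_id") -> RegressionSummary:
    """Test for a performance peak at kappa = 0.5.

    Input: one row per (participant, kappa) with column ``mean_reward``.
    Per participant, OLS of mean reward on ``|kappa - 0.5|``; a negative
    group-level slope indicates the peak.
    """
    kappas = rewards["kappa"].unique()
    if kappas.size < 3:
        raise ValueError("need at least 3 kappa levels")
    if not ((kappas < 0.5).any() and (kappas > 0.5).any()):
        raise ValueError("kappa levels must span both sides of 0.5")
    x_all = np.abs(rewards["kappa"] - 0.5)
    slopes = [
        _ols_slope(np.abs(grp["kappa"] - 0.5), grp["mean_reward"])
        for _, grp in rewards.assign(_x=x_all).groupby(participant_col)
    ]
    slopes = np.array(slopes)
    t, p, flags = _one_sample_t(slopes)
    return RegressionSummary(slopes, t, p, df=len(slopes) - 1, flags=flags)


def compare_mean_rewards(rewards_a, rewards_b) -> RegressionSummary:
    """Equal-variance independent-samples t-test on per-participant mean net
    rewards of two simulated cohorts; ``df = nA + nB - 2``."""
    a = np.asarray(rewards_a, dtype=float)
    b = np.asarray(rewards_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 participants per cohort")
    df = a.size + b.size - 2
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        diff = a[0] - b[0]
        if diff == 0:
            return RegressionSummary(np.concatenate([a, b]), 0.0, 1.0, df)
        return RegressionSummary(
            np.concatenate([a, b]),
            float(np.sign(diff) * np.inf),
            0.0,
            df,
            flags=["zero-variance cohorts"],
        )
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return RegressionSummary(np.concatenate([a, b]), float(t), float(p), df)
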