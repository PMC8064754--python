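"""Generative model of attention-modulated momentary evidence and the
closed-form Bayesian posterior over item values.

Two items carry latent values ``z1, z2`` drawn from a Normal prior
``N(z_bar, sigma_z2)``.  In every time step of length ``dt`` the decision
maker observes a noisy sample of each value (the *momentary evidence*).
Attention acts as an information bottleneck: a fixed total Fisher-information
rate ``1/sigma_x2`` is split between the items, fraction ``1 - kappa`` to the
attended and ``kappa`` to the unattended item, realised as attention-dependent
evidence variances ``sigma_x2*dt/(1-kappa)`` and ``sigma_x2*dt/kappa``.

The posterior over each item's value given the whole evidence stream is
Gaussian with sufficient statistics ``(X1, X2, t1, t2)``, where ``X_j`` is the
accumulated evidence for item ``j`` with unattended samples down-weighted by
``kappa/(1-kappa)`` and ``t_j`` is the total time item ``j`` was attended.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ModelParams",
    "BeliefState",
    "PosteriorBelief",
    "sample_momentary_evidence",
    "update_belief",
    "posterior_belief",
    "information_rates",
]


def _is_multiple(a: float, b: float, tol: float = 1e-9) -> bool:
    """True if ``a`` is a positive integer multiple of ``b``."""
    if a <= 0 or b <= 0:
        return False
    r = a / b
    return abs(r - round(r)) < tol


@dataclass(frozen=True)
class ModelParams:
    """Generative and cost constants plus discretization settings.

    Parameters
    ----------
    sigma_x2 : float
        Evidence variance scale (value-units^2 * s).  ``1/sigma_x2`` is the
        total Fisher-information rate shared between the two items.
    sigma_z2 : float
        Prior variance over item values (value-units^2).
    z_bar : float
        Prior mean (value-units).  A zero-mean prior is what produces the
        fixation-driven choice bias, so 0 is the default.
    kappa : float
        Fraction of the information rate allocated to the *unattended* item,
        in (0, 1).  ``kappa = 0.5`` recovers the attention-free model.
    c : float
        Cost of accumulating evidence (reward-units per second).
    c_s : float
        Cost of one attention switch (reward-units).
    dt_sim : float
        Simulation time step (s).
    dt_grid : float
        Solver time step (s); must be >= ``dt_sim``.
    t_max : float
        Solver horizon (s); a decision is forced at ``t1 + t2 = t_max``.
    delta_step, delta_max : float
        Spacing and half-width of the posterior-mean-difference lattice.

    Defaults are the parameter profile that best mimics human behavior
    (``c_s=0.0065, c=0.23, sigma_x2=27, sigma_z2=18, kappa=0.004``) and the
    published discretization (0.05 s grid steps to 6 s, Delta step 0.05).
    """

    sigma_x2: float = 27.0
    sigma_z2: float = 18.0
    z_bar: float = 0.0
    kappa: float = 0.004
    c: float = 0.23
    c_s: float = 0.0065
    dt_sim: float = 0.01
    dt_grid: float = 0.05
    t_max: float = 6.0
    delta_step: float = 0.05
    delta_max: float = 10.0

    def __post_init__(self) -> None:
        if self.sigma_x2 <= 0:
            raise ValueError(f"sigma_x2 must be > 0, got {self.sigma_x2}")
        if self.sigma_z2 <= 0:
            raise ValueError(f"sigma_z2 must be > 0, got {self.sigma_z2}")
        if not 0.0 < self.kappa < 1.0:
            raise ValueError(f"kappa must lie in (0, 1), got {self.kappa}")
        if self.c < 0 or self.c_s < 0:
            raise ValueError("costs c and c_s must be non-negative")
        if not 0.0 < self.dt_sim <= self.dt_grid:
            raise ValueError("require 0 < dt_sim <= dt_grid")
        if not _is_multiple(self.t_max, self.dt_grid):
            raise ValueError("t_max must be a positive multiple of dt_grid")
        if not _is_multiple(self.delta_max, self.delta_step):
            raise ValueError("delta_max must be a positive multiple of delta_step")

    @property
    def unattended_weight(self) -> float:
        """Down-weight ``kappa/(1-kappa)`` applied to unattended evidence."""
        return self.kappa / (1.0 - self.kappa)

    def with_(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


@dataclass
class BeliefState:
    """Sufficient statistics of the running decision.

    ``X1, X2`` are the attention-weighted accumulated evidence streams,
    ``t1, t2`` the cumulative attention times, and ``y`` the currently
    attended item (1 or 2).
    """

    X1: float = 0.0
    X2: float = 0.0
    t1: float = 0.0
    t2: float = 0.0
    y: int = 1

    def __post_init__(self) -> None:
        if self.y not in (1, 2):
            raise ValueError(f"attended item y must be 1 or 2, got {self.y}")
        if self.t1 < 0 or self.t2 < 0:
            raise ValueError("attention times must be non-negative")


@dataclass(frozen=True)
class PosteriorBelief:
    """Gaussian posterior over both item values.

    ``delta`` is the decision-relevant coordinate ``mean2 - mean1``.
    """

    mean1: float
    mean2: float
    var1: float
    var2: float
    delta: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "delta", self.mean2 - self.mean1)


def sample_momentary_evidence(
    z1: float,
    z2: float,
    y: int,
    params: ModelParams,
    dt: float,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Draw one step of momentary evidence for both items.

    The attended item ``j = y`` yields ``dx_j ~ N(z_j*dt, sigma_x2*dt/(1-kappa))``
    and the unattended item ``k = 3-y`` yields
    ``dx_k ~ N(z_k*dt, sigma_x2*dt/kappa)``; draws are independent across items
    and steps.  The unattended item is degraded, never silenced.

    Returns
    -------
    (dx1, dx2) : tuple of float
        Evidence increments for items 1 and 2.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if y not in (1, 2):
        raise ValueError(f"attended item y must be 1 or 2, got {y}")
    var_att = params.sigma_x2 * dt / (1.0 - params.kappa)
    var_un = params.sigma_x2 * dt / params.kappa
    var1, var2 = (var_att, var_un) if y == 1 else (var_un, var_att)
    dx1 = rng.normal(z1 * dt, np.sqrt(var1))
    dx2 = rng.normal(z2 * dt, np.sqrt(var2))
    return dx1, dx2


def update_belief(
    state: BeliefState,
    dx1: float,
    dx2: float,
    dt: float,
    params: ModelParams,
) -> BeliefState:
    """Fold one step of momentary evidence into the sufficient statistics.

    The attended item's ``X`` gains its increment at weight 1, the unattended
    item's at weight ``kappa/(1-kappa)``, and the attended item's attention
    time gains ``dt``.  Additive: consecutive updates commute with a single
    update of the summed weighted increments.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    w = params.unattended_weight
    if state.y == 1:
        return BeliefState(
            X1=state.X1 + dx1,
            X2=state.X2 + w * dx2,
            t1=state.t1 + dt,
            t2=state.t2,
            y=state.y,
        )
    return BeliefState(
        X1=state.X1 + w * dx1,
        X2=state.X2 + dx2,
        t1=state.t1,
        t2=state.t2 + dt,
        y=state.y,
    )


def posterior_belief(state: BeliefState, params: ModelParams) -> PosteriorBelief:
    """Closed-form Gaussian posterior over both item values.

    For item 1::

        mean1 = (sigma_x2/sigma_z2 * z_bar + (1-kappa)*X1) / D1
        var1  = sigma_x2 / D1
        D1    = sigma_x2/sigma_z2 + (1-kappa)*t1 + kappa*t2

    and symmetrically for item 2 with the roles of ``t1``/``t2`` exchanged.
    At ``t1 = t2 = 0`` the prior is recovered exactly.
    """
    k = params.kappa
    prior_prec = params.sigma_x2 / params.sigma_z2
    d1 = prior_prec + (1.0 - k) * state.t1 + k * state.t2
    d2 = prior_prec + (1.0 - k) * state.t2 + k * state.t1
    mean1 = (prior_prec * params.z_bar + (1.0 - k) * state.X1) / d1
    mean2 = (prior_prec * params.z_bar + (1.0 - k) * state.X2) / d2
    return PosteriorBelief(
        mean1=mean1,
        mean2=mean2,
        var1=params.sigma_x2 / d1,
        var2=params.sigma_x2 / d2,
    )


def posterior_moments(
    X1, X2, t1, t2, params: ModelParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized posterior means and variances (array-in, array-out).

    Same formulas as :func:`posterior_belief`; used by the trial simulator
    where thousands of beliefs are updated per step.
    """
    k = params.kappa
    prior_prec = params.sigma_x2 / params.sigma_z2
    d1 = prior_prec + (1.0 - k) * np.asarray(t1) + k * np.asarray(t2)
    d2 = prior_prec + (1.0 - k) * np.asarray(t2) + k * np.asarray(t1)
    mean1 = (prior_prec * params.z_bar + (1.0 - k) * np.asarray(X1)) / d1
    mean2 = (prior_prec * params.z_bar + (1.0 - k) * np.asarray(X2)) / d2
    return mean1, mean2, params.sigma_x2 / d1, params.sigma_x2 / d2


def information_rates(params: ModelParams) -> tuple[float, float]:
    """Fisher-information rates (per second) about the attended and
    unattended item's value: ``(1-kappa)/sigma_x2`` and ``kappa/sigma_x2``.

    Their sum is the fixed total rate ``1/sigma_x2`` for any ``kappa``.
    """
    return (1.0 - params.kappa) / params.sigma_x2, params.kappa / params.sigma_x2
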