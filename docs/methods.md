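# Methods

## The model

Two items carry latent values `z1, z2`, drawn (from the decision maker's
point of view) from a Normal prior `N(z_bar, sigma_z2)`.  In every time step
`dt` the decision maker receives *momentary evidence* about both values.
Attention is an information bottleneck: the total Fisher-information rate
`1/sigma_x2` about the two values is fixed, and the attended item receives
fraction `1 - kappa` of it, the unattended item fraction `kappa`.
Concretely, the attended item `j` yields
`dx_j ~ N(z_j dt, sigma_x2 dt / (1 - kappa))` and the unattended item `k`
yields `dx_k ~ N(z_k dt, sigma_x2 dt / kappa)`; `kappa = 1/2` recovers the
attention-free accumulator.

Because everything is Gaussian, the posterior over each value is available
in closed form from four sufficient statistics: the attention times
`t1, t2` and the accumulated evidence `X1, X2`, in which unattended samples
are down-weighted by `kappa/(1 - kappa)`.  For item 1:

```
mean1 = (sigma_x2/sigma_z2 * z_bar + (1-kappa) X1) / D1,   var1 = sigma_x2 / D1,
D1    = sigma_x2/sigma_z2 + (1-kappa) t1 + kappa t2,
```

and symmetrically for item 2.  The down-weight `kappa/(1-kappa)` is not a
free choice: it is the unique scalar for which this expression equals the
brute-force product of the prior with every per-sample Gaussian likelihood
(the test suite solves for the weight and checks uniqueness).

## The optimal policy

At every instant the decision maker may choose item 1, choose item 2,
accumulate for another `dt` at cost `c*dt`, or switch attention at cost
`c_s`.  The value function over the two posterior means decomposes into the
mean-sum — a martingale no action can influence — plus a reduced value that
depends only on the posterior-mean difference `Delta = mean2 - mean1`.  In
reduced coordinates, choosing item 1 is worth `-Delta/2`, choosing item 2
`+Delta/2`, and the state space is `(Delta, t1, t2, y)` with `y` the
attended item.

The solver runs backward induction from a horizon `t_max` where a choice is
forced (terminal reduced value `|Delta|/2`) down to `t = 0`, on a lattice
with time step `dt_grid = 0.05 s`, horizon `t_max = 6 s`, and `Delta` step
0.05.  The one-step `Delta` transition is mean-zero Gaussian whose variance
equals the one-step drop in the two posterior variances (the martingale
identity); the expectation in the Bellman recursion is a discrete Gaussian
convolution truncated at ±4 SD and renormalized.  Beyond the lattice edge
the value slice is extended by the choose value `|Delta|/2`, which is exact
there because far outside the lattice an immediate choice is certainly
optimal.  The switch action's value is `c_s` below the best *non-switch*
action under the other attention state at the same `(Delta, t1, t2)`; an
immediate switch-back would cost `2 c_s` and return to the same state, so
excluding it is lossless and breaks the within-slice recursion between the
two attention states.

Numerical conventions: ties between actions resolve in the fixed order
choose 1 > choose 2 > accumulate > switch (hence exactly at `Delta = 0` the
policy says choose 1, the one lattice column where the two policy spaces
are not mirror images); lattice lookups are nearest-neighbor with half-way
ties toward the smaller index; the solver refuses configurations whose
accumulate region touches the `Delta` lattice edge (enlarge `delta_max`).
The default half-width `delta_max = 10` comfortably contains the boundary
at the shipped parameters.

## Trial simulation

Trials step the generative process at `dt_sim = 0.01 s` but consult the
policy only at the solver's decision epochs (multiples of `dt_grid`).  This
is deliberate: the Bellman accumulate action commits to one full grid step
of evidence, so checking the absorbing choose/switch boundaries five times
per grid step would end fixations systematically earlier than the policy
intends — empirically it reverses the sign of the fixation-duration choice
bias.  Within an epoch, five fine evidence increments sum to exactly one
grid-step increment in distribution, so nothing else changes.

The first attended item is uniform random per trial.  Switches are
instantaneous (they cost `c_s` but no time).  If a trial reaches the 6 s
horizon the larger posterior mean is chosen (tie toward item 1).  Net
reward is `z_chosen - c*rt - c_s*n_switches` and is the single performance
currency for every model comparison.  The shipped trial design is the
published protocol: all 64 ordered pairs of integer values 0–7, 20
repetitions, 39 simulated participants, per-participant RNG streams spawned
from one master seed (bit-for-bit reproducible).  Note the deliberate
mismatch between these integer values (mean 3.5) and the zero-mean prior:
it mirrors the experimental protocol, and the zero-mean prior is exactly
what produces the fixation-driven choice bias (longer-attended items are
shrunk less toward 0).

## The aDDM baseline

The attentional drift diffusion model is a one-dimensional accumulator with
flat boundaries `±B` and *exogenous* fixations (resampled from the optimal
model's completed fixation durations, first fixations separately from later
ones; a log-normal fallback is available).  While fixating item 1 it drifts
by `(z1 - theta*z2) dt` with noise variance `sigma_a2*dt`.  For the reward
comparison, `theta = sqrt(kappa/(1-kappa))` and `sigma_a2 =
sigma_x2/(1-kappa)` — the unique pair for which one accumulator increment
carries Fisher information `(1-kappa)/sigma_x2` about the fixated and
`kappa/sigma_x2` about the unfixated value, i.e. exactly the optimal
model's information rates.  (A raw unit-weight difference of the two
evidence streams is *not* an SNR match in any useful sense: at
`kappa = 0.004` the unattended stream's `sigma_x2/kappa` variance would
swamp the accumulator and the comparison would measure bad pooling rather
than flat bounds and exogenous fixations.)  The boundary is swept from 0.25
to 4 per-second accumulator SDs in 16 steps and the reward-maximizing
height is used; accounting (time and switch costs) is identical to the
optimal model's.

### What the reward comparison shows here

At the shipped parameters the boundary-swept aDDM collects *slightly more*
net reward than the optimal policy on the 0–7 integer-value protocol
(difference ≈ 0.06–0.09 value units; independent-samples t around −10).
This is not a solver defect: when values are drawn from the model's own
prior `N(0, 18)`, the optimal policy beats the same aDDM, as it must.  On
the integer protocol the realized values (all positive, mean 3.5) are
mis-matched to the zero-mean prior, so the "optimal" policy — optimal under
its prior — deliberates longer than is profitable for the values actually
presented, and a fast flat-bound accumulator edges it out.  The
corresponding acceptance test asserts the direction reported for the
original model comparison and is therefore expected to fail under this
implementation; we keep it as an honest discrepancy rather than weaken it.

## Statistics

Every group-level statistic is a per-participant regression followed by a
two-sided one-sample t-test of the coefficients across participants
(`df = N - 1`; independent-samples comparisons use `df = nA + nB - 2`).
Linear slopes are OLS; choice models are maximum-likelihood logistic
regressions with intercept (statsmodels), falling back to a Newton solver
with ridge penalty `1e-4` on separation or non-convergence (flagged per
participant).  Zero-variance coefficient vectors yield a signed-infinity
t sentinel with a flag instead of 0/0.

The *choice bias coefficient* is the across-participant t statistic of
per-participant logistic slopes of the item-1 choice indicator on the
fixation-time difference `t1 - t2`.  With endogenous fixations the raw
slope confounds fixation and value effects (dwelling long on an item often
means its evidence was unconvincing), so the cohort-level bias analyses
remove the value-difference effect: the global coefficient includes
`z1 - z2` as a covariate (`adjust_for_value=True`), and the binned analyses
use the linear slope of the value-difference-normalized choice indicator
(the choice indicator minus the cohort mean P(choose 1) at that value
difference), which is robust inside bins where fixation time and choice are
near-deterministically linked.  Unadjusted logistic slopes remain available
and are reported alongside.

Binned analyses use equal-count bins for continuous keys (rank-based, so
ties resolve stably) and value bins for small-integer keys such as fixation
counts; (participant, bin) cells with fewer than 10 usable trials are
dropped.  The trend of the bias across bins is, per participant, the OLS
slope of per-bin bias coefficients on the per-bin mean of the binning
covariate, t-tested across participants.  The bin counts (6 fixation-count
bins, 5 value-sum bins) are package defaults chosen once for the shipped
protocol's trial counts.

The kappa sweep re-solves the policy per kappa (everything else fixed),
simulates a cohort, and tests for a performance peak at `kappa = 0.5` by
regressing per-participant mean reward on `|kappa - 0.5|` (negative slope =
peak).  The packaged sweep uses five kappa levels {0.1, 0.3, 0.5, 0.7,
0.9} at the full 20 repetitions per value pair; the peak is clear but
shallow (≈ 0.02 reward units between 0.5 and the extremes at these
parameters).

## Synthetic data and its limits

All cohorts are simulated; the 39 "participants" are identical-parameter
replicates differing only in RNG stream, exactly as in the original
model-side analyses.  Across-participant t statistics therefore measure
effect size against Monte-Carlo variability, not biological heterogeneity,
and can be far larger than any human-cohort statistic.  The simulator also
omits non-decision time, saccade kinematics, and trial-to-trial parameter
variability, so passing tests demonstrate properties of the model, not fit
to any human dataset.  Human data in the same trials/fixations CSV schema
can be fed to the analysis functions unchanged.

## Reproducibility and problem sizes

Every stochastic routine takes an explicit seed or Generator; cohort
simulators spawn per-participant substreams from a master seed.  The
default problem sizes — full 121×121×401 policy lattice, 39×1280-trial
cohorts, 16-point boundary sweep at 5 reps, 5-point kappa sweep at 20 reps
— were chosen so the complete reproduction pipeline runs in a few minutes
on one CPU core.
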