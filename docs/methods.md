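# Methods

This note records the modelling assumptions, parameter choices, numerical
methods and known limitations behind `p53loop`, in the order the analysis
runs.

## Linear continuous model

The loop is modelled as two coupled first-order systems — Mdm2 produced in
proportion to p53 and degraded at p_y; p53 suppressed by Mdm2 and degraded
at p_z — with ATM held constant (it is inactive under normal conditions and
enters only as a constant input).  The model deliberately omits basal p53
production: a constant source shifts the equilibrium but not the transfer
function, and the disturbance-rejection analysis lives entirely in the
frequency domain.  A consequence is that the open-loop p53 step response
under a fixed Mdm2 level is a *downward* deviation; `step_response_p53`
reports the deviation magnitude and documents the sign convention.

All rates default to h⁻¹ (the operating point p_yz = p_zy = 0.8 h⁻¹,
p_y = p_z = 2.0 h⁻¹ corresponds to ~20-minute protein half-lives).  Some
published illustrations of second-order responses use min⁻¹ values; the
package never converts units silently — `convert_rate` makes the
conversion explicit, and metric values are unit-consistent as long as all
five rates share a unit (ζ and %OS are dimensionless; e_ss is too).

Percent overshoot is defined as 0 for ζ ≥ 1: the underdamped closed form
applies only below critical damping, and overdamped responses do not
overshoot.  `zeta_minimizing_pz` returns None when p_y² < 2·p_yz·p_zy (no
positive interior minimum) and 0.0 on the boundary.  Trade-off sweeps
default to 50 evenly spaced points on 0.5–3.0 h⁻¹, the range over which
the published trade-off curves are drawn; grids are configurable.

Second-order step responses are evaluated with `scipy.signal.lti` rather
than a hand-coded formula, and a test closes the loop by checking the
empirical peak of the trajectory against the closed-form %OS to 0.5%
relative for ζ ∈ {0.1,…,0.9}.

## Discrete-time model and pole-ensemble robustness

The per-step weights w_y, w_z encode stability (1−w is the per-step
degradation fraction — note the sign convention is opposite to p_y, p_z).
Weights in [0, 1) give the nominal stable regime; values outside it are
accepted with a warning rather than rejected, because Monte-Carlo samples
and estimated schedules legitimately stray outside.

The z→s correspondence z = e^{sT} gives ζ = −ln r/√(ln²r + θ²) and
ω_n = √(ln²r + θ²)/T for a pole with modulus r and angle θ.  ζ is
independent of T; a positive real pole inside the unit circle maps to
ζ = 1, a pole on the circle to ζ = 0, and negative real poles take θ = π
(they never arise from the identified distributions but the mapping is
total).  Poles at z = 0 and z = 1 have no damping equivalent and raise.

Monte-Carlo sampling draws the four weights as independent Gaussians with
the identified means ± SDs (w_y 0.8737±0.0830, w_z 0.3627±0.0825,
w_zy 0.2662±0.0343, w_yz 0.1656±0.1169), truncated by rejection to [0, 1)
for the stability weights and to ≥ 0 for the couplings.  Mean ± SD is the
only published description of the estimated range, and independent
truncated Gaussians are the minimal distribution consistent with it.  The
default ensemble size is 100 draws, matching the published pole maps, and
every draw flows from one seeded `numpy` generator so ensembles are
exactly reproducible.

Condition scaling multiplies the w_yz mean by the measured 3.67-fold
suppression difference (transcriptional), optionally also dividing the
w_z mean by the same fold (post-translational); SDs are never scaled.
Note 0.1656 × 3.67 = 0.6078 and 0.3627 / 3.67 = 0.0988, whereas the
published scaled means are printed as 0.6708 and 0.0998; the package
computes the arithmetic faithfully and accepts the printed values as
explicit overrides (`w_yz_mean_override`, `w_z_mean_override`) for exact
reproduction of the published ensembles.

## NLMS weight tracking

The two difference equations are regressions: Mdm2 on
[z(i−1), −x(i−1), y(i−1)] and p53 on [−y(i−1), z(i−1)].  The regressors
carry the model's minus signs so the tracked weights land directly on the
positive scale of the identified values.  ATM is unmeasured; its channel
defaults to a constant 1 and w_xy absorbs the scale.

Defaults: μ = 0.5 (mid-range of the NLMS stability interval (0, 2]),
ε = 1e−6, zero initial weights, burn-in 10% of the track.  Fluorescence
units are arbitrary, so channels are min–max normalised before filtering
by default; normalisation changes the absolute weight scale, so recovery
tests disable it and work on raw model-scale series.

Identifiability caveat: NLMS recovery requires persistently exciting
regressors.  The recovery oracles therefore generate from a marginally
stable schedule (|poles| = 1, sustained oscillation) over 1000 frames,
where constant weights are recovered to better than 1e−3.  At the study's
own scale — 285 frames of a decaying oscillation — the three-weight Mdm2
regression recovers only to ~5e−3: an excitation limit of short series,
not a filter defect.  With 5% relative measurement noise, post-burn-in
means stay within 3 tracked SDs of truth, and shuffling the series
destroys recovery (the guard against vacuously passing oracles).

## Synthetic data generator

The generator emulates the shape of the study's input: two positive,
noisy, oscillatory channels, 285 frames at 0.11 hr.  It iterates the
difference equations under a known schedule, affinely maps each channel
onto [10, 1000] arbitrary units (positive, non-zero background, mimicking
nuclear fluorescence quantification), adds independent Gaussian noise
scaled to the channel amplitude, and clips at zero.  Noise is added after
the affine map so that the map is exactly invertible on noise-free data;
`invert_scaling` uses the recorded per-channel (scale, offset) metadata.
Gaussian (not Poisson) noise reflects fluorescence readout and is the
generator's choice, not a measured property.  The default schedule places
the poles at modulus 0.995 (period ≈ 2.3 hr) so the channels ring visibly
across the whole window.

What passing tests show — and don't: recovery results demonstrate the
tracker works when the data really follow the discrete model with additive
Gaussian noise.  Real single-cell data add model mismatch, photobleaching
trends, segmentation error and non-stationary weights; the dynamic range
and noise statistics of the original movie are not published, so the
generator's scales are documented placeholders.

## Nonlinear mechanistic model

Four species (mdm2 mRNA, Mdm2, p53 mRNA, p53) with Hill activation
(n = 2, K1 = 10) of mdm2 transcription and Michaelis–Menten Mdm2-mediated
p53 degradation (rate γ, K2 = 100); all β's = 1, α1 = α3 = 1,
α2 = α4 = 0.01 (arbitrary units).  Integration uses LSODA with
rtol 1e−8/atol 1e−10.  Steady states are found by bracketed 1-D
root-solving on the p53 balance (the mRNA equilibria are linear and the
net removal is strictly increasing in p53, so the root is unique) — far
cheaper and more precise than integrating to convergence, and valid for
any delay since delay does not move equilibria.

The disturbance protocol starts at the exact pre-step equilibrium,
multiplies a p53 production rate by 1 + step (default +1%), and
integrates to the new equilibrium over a horizon of 10× the slowest
first-order timescale (plus 20τ when delayed), verifying settlement to
1e−6 relative.  The step lands on β3 (p53 transcription) by default; β4
(translation) is a config option — the two give near-identical metrics
because p53 mRNA equilibrates fast — and the choice between them is
genuinely open in the protocol's description.  Metrics follow the
simulation definitions: ss error |SS_old−SS_new|/SS_old and overshoot
(peak−SS_new)/SS_new, both *fractions* (the simulation overshoot
definition carries no factor of 100, unlike the linear-model %OS).

Delay integration uses the method of steps: each interval of length τ is
integrated with RK45 (max step τ/10) against the previous interval's dense
solution, with the delayed mRNA arguments on both translation terms.
At τ = 0 the code path reduces to the plain ODE solver, and a small-τ
continuity test pins the two paths together.

Two findings of this implementation worth flagging:

* On the default parameter set, the γ sweep's ss error decreases
  monotonically across 10⁻²–10² as expected, but the overshoot's
  rise-then-fall turnover sits near γ ≈ 10³ — outside that window, where
  %OS is still rising.  The unimodality of %OS in γ is therefore asserted
  over 10⁻²–10⁵, a grid that brackets the computed peak.
* Delay-induced sustained oscillation at this parameter set requires
  τ ≈ 200 time units: the 100-unit Mdm2 lifetime dominates the loop's
  phase lag, so the Hopf threshold is large.  Tests contrast τ = 100
  (damped) with τ = 250 (sustained limit cycle).

Oscillation detection operates on the tail half of a trajectory: sustained
means tail peak-to-peak amplitude above 1% of the tail mean, at least
three peaks, and successive peak heights not decaying by more than 5%;
the period estimate is the mean peak spacing.

## Stochastic simulation

The network is eight reaction channels whose summed drift reproduces the
ODE right-hand sides exactly at every state (a tested identity).  Hill and
MM expressions are used directly as propensities on copy numbers — no
expansion into elementary binding steps — mirroring the deterministic
model in the macroscopic limit, which is standard for toolbox-style kinetic
models.  The simulator is the exact direct-method SSA; species are counts,
with a volume factor Ω (default 1) scaling zeroth-order productions and
the K constants.  Noise magnitudes depend on Ω, so only trends, not
absolute noise values, are comparable across parameterisations.

The noise-vs-γ analysis holds the deterministic p53 mean at a target by
compensating α₄ in closed form from the steady-state balance.  At target
mean 50 the compensation is feasible for γ below ≈ 0.031 (beyond that the
Mdm2-mediated flux alone exceeds production and α₄ would have to be
negative); the default 5-point grid (0.002–0.028) spans that feasible
range.  Runs start at the rounded deterministic equilibrium, burn in for
150 time units, and pool 8 samples per run spaced ~64 time units apart
from each of the (default 60–200) runs; spacing on the order of the p53
relaxation time keeps residual autocorrelation from biasing the pooled
variance materially, and the monotone noise trend is insensitive to it.
The published stochastic model's volume, run count and exact reaction list
are not in the main text, so the increasing variance/mean trend — which
this implementation reproduces robustly — is the reproduction surface.

## Problem sizes and determinism

Default analysis sizes are desk-scale by design: 100-draw pole ensembles,
50-point sweep grids, 285-frame series (1000 frames for recovery oracles),
60-run SSA ensembles on 5-point γ grids.  Every stochastic component
(Monte-Carlo sampling, noise injection, SSA) accepts either a seed or a
`numpy` Generator and is bit-reproducible under a fixed seed; the
adaptive-filter and ODE paths are deterministic outright.

## Known limitations

* The linear analysis is first-order by construction; its metrics describe
  the loop only near the operating point.
* The discrete weight distribution treats the four weights as independent;
  any correlation structure in the underlying estimates is unpublished and
  therefore not modelled.
* The DDE integrator is method-of-steps with per-interval RK45 — accurate
  for the smooth histories used here, but not a general-purpose stiff DDE
  solver.
* The SSA uses pure-Python propensity evaluation; it is comfortable at the
  default copy-number scale (~10²) but not tuned for Ω ≫ 1.
* The generator emulates data *shape*, not biology: no photobleaching,
  segmentation noise, or cell-cycle trends.
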