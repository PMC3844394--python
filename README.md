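# p53loop

Control-theoretic analysis of disturbance rejection in the p53–Mdm2
negative feedback loop.

The tumour suppressor p53 is held at a low, steady level under normal
conditions by a negative feedback loop: p53 transcriptionally activates the
E3 ubiquitin ligase Mdm2, and Mdm2 targets p53 for degradation.  Notably
the repressive arm is *post-translational* (protein degradation) rather
than transcriptional, even though continuously producing and destroying
p53 wastes energy.  This package implements the quantitative argument for
why: treating the loop as a feedback control system, post-translational
suppression modulates both the feedback gain and the p53 degradation rate,
and thereby achieves a better trade-off between steady-state error and
transient overshoot than a transcriptional mechanism, which can only
modulate the gain.  It is written for systems biologists and control
engineers who want to reproduce, perturb, or extend that analysis.

## The models

**Linear continuous model** (`p53loop.linear_continuous`).  With x = ATM
(constant), y = Mdm2, z = p53 and all rates positive (h⁻¹):

    dy/dt =  p_zy·z − p_xy·x − p_y·y
    dz/dt = −p_yz·y − p_z·z

The closed loop from x to z is second order,
G(s) = p_xy·p_yz / (s² + (p_y+p_z)·s + (p_y·p_z + p_yz·p_zy)), with

* steady-state error to a unit step disturbance
  e_ss = p_zy·p_y / (p_y·p_z + p_yz·p_zy),
* natural frequency ω_n = √(p_y·p_z + p_yz·p_zy),
* damping ratio ζ = (p_y+p_z) / 2ω_n,
* percent overshoot %OS = 100·exp(−ζπ/√(1−ζ²)) for ζ < 1,

and ζ is minimised at p_z\* = p_y − 2·p_yz·p_zy/p_y.  Above p_z\* (where
the published operating point p_yz = p_zy = 0.8, p_y = p_z = 2.0 h⁻¹ sits),
raising p53 turnover reduces error *and* overshoot simultaneously.

**Discrete-time model and robustness** (`p53loop.discrete_robustness`).
The sampled counterpart (sampling period T = 0.11 hr) with stability
weights w_y, w_z and coupling weights w_zy, w_yz has characteristic
polynomial z² − (w_y+w_z)z + (w_y·w_z + w_yz·w_zy).  Monte-Carlo sampling
of the weight distribution identified from single-cell data maps parameter
uncertainty into a pole ensemble; the z→s correspondence
ζ = −ln r / √(ln²r + θ²) turns each pole into an equivalent damping ratio.
Scaling w_yz by the measured 3.67-fold suppression difference emulates
transcriptional repression; also dividing w_z by the same fold emulates
post-translational repression, which keeps the ensemble far better damped.

**NLMS weight tracking** (`p53loop.nlms_estimation`).  The two difference
equations are linear regressions in the weights, so a normalized
least-mean-squares adaptive filter tracks them frame by frame from a
two-channel p53/Mdm2 fluorescence series.  `p53loop.synthetic_data`
generates such series from the discrete model with known (optionally
time-varying) weights so recovery can be verified against exact truth.

**Nonlinear mechanistic model** (`p53loop.nonlinear_mechanistic`).  Four
species (both mRNAs and proteins) with Hill activation of mdm2
transcription by p53 and Michaelis–Menten Mdm2-mediated p53 degradation
(rate γ), optional transcription→translation delay τ, a +1% production
step protocol measuring ss error |SS_old−SS_new|/SS_old and overshoot
fraction (peak−SS_new)/SS_new, and delay-induced sustained-oscillation
detection.

**Stochastic simulation** (`p53loop.stochastic_sim`).  An exact Gillespie
(direct-method) simulation of the same network; sweeping γ while
compensating the basal degradation rate α₄ to hold the mean p53 level
fixed shows the price of the feedback: the stationary noise
(variance/mean) of p53 rises with γ.

## Worked example

```python
import p53loop as pl

s = pl.second_order_summary(pl.OPERATING_POINT)
print(f"ss error {s.ss_error:.4f}  zeta {s.zeta:.4f}  %OS {s.percent_os:.4f}")

damage = pl.monte_carlo_poles(pl.DNA_DAMAGE_DISTRIBUTION, 100, seed=1)
trans = pl.monte_carlo_poles(
    pl.scale_condition(pl.DNA_DAMAGE_DISTRIBUTION, 3.67, "transcriptional"),
    100, seed=1)
post = pl.monte_carlo_poles(
    pl.scale_condition(pl.DNA_DAMAGE_DISTRIBUTION, 3.67, "post_translational"),
    100, seed=1)
print(f"median zeta: damage {damage.median_zeta:.3f}  "
      f"transcriptional {trans.median_zeta:.3f}  post {post.median_zeta:.3f}")
```

prints

```
ss error 0.3448  zeta 0.9285  %OS 0.0388
median zeta: damage 1.000  transcriptional 0.645  post 0.958
```

At the operating point the loop keeps about a third of a unit step
disturbance (e_ss ≈ 0.34) while overshooting by under 0.04% — nearly
critically damped.  The pole ensembles show the central claim: a 3.67-fold
transcriptional strengthening of the feedback drops the median damping
ratio to 0.65 (more overshoot-prone), whereas the post-translational
version of the same strengthening keeps it at 0.96.

The same analyses are scriptable from the shell:

```bash
p53loop linear --out out/            # metrics JSON + trade-off CSVs
p53loop poles --seed 1 --out out/    # pole ensembles for all three conditions
p53loop synth --seed 5 --out out/    # synthetic fluorescence-like series
p53loop track --out out/             # NLMS weight tracks and summaries
p53loop mech --out out/              # gamma sweep of the mechanistic model
p53loop ssa --seed 1 --out out/      # stochastic noise-vs-gamma table
p53loop all --seed 1 --out out/      # the full narrative
```

## Layout

- `src/p53loop/` — the library (modules listed above plus `cli`).
- `tests/` — pytest suite; all fixtures are generated programmatically.
- `docs/methods.md` — modelling assumptions, parameter choices, numerical
  methods and known limitations.
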