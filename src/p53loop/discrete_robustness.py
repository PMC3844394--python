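"""Discrete-time model of the p53-Mdm2 loop and pole-ensemble robustness analysis.

The sampled-data counterpart of the continuous loop is the difference system ::

    x(i) = x(i-1)
    y(i) = w_zy * z(i-1) - w_xy * x(i-1) + w_y * y(i-1)
    z(i) = -w_yz * y(i-1) + w_z * z(i-1)

where the per-step weights w_y and w_z encode *stability* (1 - w is the
per-step degradation fraction, the opposite sign convention to the
continuous rates p_y, p_z).  The closed loop has characteristic polynomial
``z^2 - (w_y + w_z) z + (w_y w_z + w_yz w_zy)``; the positions of its two
poles in the z-plane determine stability and, through the standard
z-to-s correspondence, an equivalent damping ratio.

The robustness analysis Monte-Carlo samples the weight distribution
estimated from single-cell data, maps every sampled parameter set to its
pole pair, and summarises the damping-ratio ensemble.  Scaling the
distribution emulates the two suppression mechanisms: a transcriptional
mechanism scales only the Mdm2->p53 gain w_yz, while a post-translational
mechanism additionally destabilises p53 (divides w_z) by the same fold.
"""

from __future__ import annotations

import cmath
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "DEFAULT_SAMPLING_PERIOD_HR",
    "SUPPRESSION_FOLD",
    "DiscreteParams",
    "ParamDistribution",
    "PoleRecord",
    "DNA_DAMAGE_DISTRIBUTION",
    "simulate_discrete",
    "dt_steady_state_error",
    "dt_closed_loop_coeffs",
    "char_poles",
    "pole_to_damping",
    "monte_carlo_poles",
    "MonteCarloResult",
    "scale_condition",
    "euler_discretize",
]

#: Sampling period of the single-cell fluorescence time series (hours).
DEFAULT_SAMPLING_PERIOD_HR = 0.11

#: Measured fold-increase of Mdm2-mediated p53 suppression in normal vs
#: DNA-damage conditions (western blots of total and ubiquitinated p53).
SUPPRESSION_FOLD = 3.67


@dataclass(frozen=True)
class DiscreteParams:
    """Per-step weights of the difference-equation loop plus sampling period."""

    w_xy: float
    w_zy: float
    w_yz: float
    w_y: float
    w_z: float
    T: float = DEFAULT_SAMPLING_PERIOD_HR

    def __post_init__(self) -> None:
        if not self.T > 0:
            raise ValueError(f"sampling period T must be positive, got {self.T!r}")
        if self.w_zy < 0 or self.w_yz < 0:
            raise ValueError("coupling weights w_zy, w_yz must be non-negative")
        for name in ("w_y", "w_z"):
            value = getattr(self, name)
            if not (0.0 <= value < 1.0):
                warnings.warn(
                    f"{name}={value!r} lies outside the nominal stable range [0, 1)",
                    stacklevel=3,
                )

    def replace(self, **changes: float) -> "DiscreteParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class ParamDistribution:
    """Independent mean +/- SD description of the four sampled weights.

    w_xy is not part of the characteristic polynomial, so it is not sampled;
    it only scales the transfer-function numerator.
    """

    w_y_mean: float
    w_y_sd: float
    w_z_mean: float
    w_z_sd: float
    w_zy_mean: float
    w_zy_sd: float
    w_yz_mean: float
    w_yz_sd: float
    T: float = DEFAULT_SAMPLING_PERIOD_HR

    def __post_init__(self) -> None:
        for name in ("w_y_sd", "w_z_sd", "w_zy_sd", "w_yz_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def replace(self, **changes: float) -> "ParamDistribution":
        return replace(self, **changes)


#: Weight distribution identified by NLMS tracking of the single-cell data
#: under DNA damage (feedback weakened): w_y 0.8737+/-0.0830,
#: w_z 0.3627+/-0.0825, w_zy 0.2662+/-0.0343, w_yz 0.1656+/-0.1169.
DNA_DAMAGE_DISTRIBUTION = ParamDistribution(
    w_y_mean=0.8737, w_y_sd=0.0830,
    w_z_mean=0.3627, w_z_sd=0.0825,
    w_zy_mean=0.2662, w_zy_sd=0.0343,
    w_yz_mean=0.1656, w_yz_sd=0.1169,
)


@dataclass(frozen=True)
class PoleRecord:
    """One closed-loop pole with its z-plane and damping-equivalent coordinates."""

    pole: complex
    magnitude: float
    angle: float  # radians in (-pi, pi]
    zeta: float
    omega_n: float  # rad/hr, uses the sampling period


def simulate_discrete(
    params: DiscreteParams,
    initial: tuple[float, float, float] = (1.0, 0.0, 0.0),
    n_steps: int = 100,
    disturbance: np.ndarray | float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Iterate the difference equations for ``n_steps`` updates.

    ``disturbance``, if given, is an additive term on the p53 update (a
    scalar applies from step 1 onward; an array gives the per-step value),
    mirroring a disturbance injected at the p53 node of the block diagram.

    Returns the (x, y, z) sequences, each of length ``n_steps + 1``
    including the initial state.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if disturbance is None:
        d = np.zeros(n_steps)
    elif np.isscalar(disturbance):
        d = np.full(n_steps, float(disturbance))
    else:
        d = np.asarray(disturbance, dtype=float)
        if d.shape != (n_steps,):
            raise ValueError("disturbance array must have length n_steps")
    x = np.empty(n_steps + 1)
    y = np.empty(n_steps + 1)
    z = np.empty(n_steps + 1)
    x[0], y[0], z[0] = initial
    for i in range(1, n_steps + 1):
        x[i] = x[i - 1]
        y[i] = params.w_zy * z[i - 1] - params.w_xy * x[i - 1] + params.w_y * y[i - 1]
        z[i] = -params.w_yz * y[i - 1] + params.w_z * z[i - 1] + d[i - 1]
    return x, y, z


def dt_steady_state_error(params: DiscreteParams) -> float:
    """Final-value-theorem error of the discrete loop to a unit step disturbance.

    ``w_zy (1 - w_y) / [(1 - w_y)(1 - w_z) + w_yz w_zy]`` — decreased by a
    stronger Mdm2->p53 gain (w_yz up) or by destabilising p53 (w_z down),
    the discrete mirror of the continuous-time result.
    """
    denominator = (1.0 - params.w_y) * (1.0 - params.w_z) + params.w_yz * params.w_zy
    if denominator == 0.0:
        raise ZeroDivisionError("steady-state error undefined: zero denominator")
    return params.w_zy * (1.0 - params.w_y) / denominator


def dt_closed_loop_coeffs(params: DiscreteParams) -> tuple[float, float, float]:
    """Coefficients (gain, b, c) of G(z) = gain / (z^2 - b z + c)."""
    gain = params.w_xy * params.w_yz
    b = params.w_y + params.w_z
    c = params.w_y * params.w_z + params.w_yz * params.w_zy
    return gain, b, c


def pole_to_damping(pole: complex, T: float = DEFAULT_SAMPLING_PERIOD_HR) -> tuple[float, float]:
    """Map a z-plane pole to an equivalent (zeta, omega_n) via z = exp(sT).

    With r = |pole| and theta = arg(pole):
    ``zeta = -ln r / sqrt(ln^2 r + theta^2)`` and
    ``omega_n = sqrt(ln^2 r + theta^2) / T``.  zeta is independent of T and
    lies in [0, 1] for poles inside the closed unit disk; a positive real
    pole in (0, 1) maps to zeta = 1 and a pole on the unit circle to
    zeta = 0.  Negative real poles take theta = pi.  A pole at the origin
    (or exactly at z = 1, where both ln r and theta vanish) has no damping
    equivalent and raises.
    """
    r = abs(pole)
    if r == 0.0:
        raise ValueError("pole at the origin has no damping-ratio equivalent")
    log_r = math.log(r)
    theta = cmath.phase(pole)
    norm = math.hypot(log_r, theta)
    if norm == 0.0:
        raise ValueError("pole at z=1 (integrator) has no damping-ratio equivalent")
    zeta = -log_r / norm
    return zeta, norm / T


def _pole_record(pole: complex, T: float) -> PoleRecord:
    zeta, omega_n = pole_to_damping(pole, T)
    return PoleRecord(
        pole=pole, magnitude=abs(pole), angle=cmath.phase(pole), zeta=zeta, omega_n=omega_n
    )


def char_poles(params: DiscreteParams) -> tuple[PoleRecord, PoleRecord]:
    """The two roots of z^2 - (w_y + w_z) z + (w_y w_z + w_yz w_zy).

    A negative discriminant gives a complex-conjugate pair (oscillatory
    sampled dynamics); otherwise the poles are real.
    """
    _, b, c = dt_closed_loop_coeffs(params)
    disc = b * b - 4.0 * c
    if disc >= 0:
        root = math.sqrt(disc)
        poles = ((b + root) / 2.0 + 0.0j, (b - root) / 2.0 + 0.0j)
    else:
        root = math.sqrt(-disc)
        poles = (complex(b / 2.0, root / 2.0), complex(b / 2.0, -root / 2.0))
    return _pole_record(poles[0], params.T), _pole_record(poles[1], params.T)


@dataclass(frozen=True)
class MonteCarloResult:
    """Pole ensemble and damping summary from Monte-Carlo weight sampling."""

    samples: np.ndarray  # (n, 4) sampled (w_y, w_z, w_zy, w_yz)
    poles: np.ndarray  # (n, 2) complex pole pairs
    zetas: np.ndarray  # (n, 2) damping ratios per pole
    summary: dict = field(repr=False)

    @property
    def median_zeta(self) -> float:
        return self.summary["median"]


def _sample_truncated(
    rng: np.random.Generator, mean: float, sd: float, low: float, high: float, size: int
) -> np.ndarray:
    """Rejection-sample N(mean, sd) truncated to [low, high)."""
    if sd == 0.0:
        if not (low <= mean < high):
            raise ValueError(f"degenerate sample {mean} outside [{low}, {high})")
        return np.full(size, mean)
    out = np.empty(size)
    remaining = np.arange(size)
    while remaining.size:
        draws = rng.normal(mean, sd, remaining.size)
        ok = (draws >= low) & (draws < high)
        out[remaining[ok]] = draws[ok]
        remaining = remaining[~ok]
    return out


def monte_carlo_poles(
    dist: ParamDistribution,
    n_samples: int = 100,
    seed: int | np.random.Generator | None = None,
    w_xy: float = 1.0,
) -> MonteCarloResult:
    """Sample the weight distribution and map every draw to its pole pair.

    Weights are drawn as independent Gaussians with the distribution's
    mean +/- SD, truncated to the physically admissible ranges: [0, 1) for
    the stability weights w_y and w_z, and [0, inf) for the coupling gains
    w_zy and w_yz.  Each draw's two characteristic poles are converted to
    damping ratios, and the summary reports the median and quartiles of the
    pooled zeta ensemble.  Fully reproducible under a fixed seed.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    w_y = _sample_truncated(rng, dist.w_y_mean, dist.w_y_sd, 0.0, 1.0, n_samples)
    w_z = _sample_truncated(rng, dist.w_z_mean, dist.w_z_sd, 0.0, 1.0, n_samples)
    w_zy = _sample_truncated(rng, dist.w_zy_mean, dist.w_zy_sd, 0.0, math.inf, n_samples)
    w_yz = _sample_truncated(rng, dist.w_yz_mean, dist.w_yz_sd, 0.0, math.inf, n_samples)
    samples = np.column_stack([w_y, w_z, w_zy, w_yz])
    poles = np.empty((n_samples, 2), dtype=complex)
    zetas = np.empty((n_samples, 2))
    for i in range(n_samples):
        params = DiscreteParams(
            w_xy=w_xy, w_zy=w_zy[i], w_yz=w_yz[i], w_y=w_y[i], w_z=w_z[i], T=dist.T
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sampled w outside [0,1) is expected noise
            rec0, rec1 = char_poles(params)
        poles[i] = rec0.pole, rec1.pole
        zetas[i] = rec0.zeta, rec1.zeta
    pooled = zetas.ravel()
    summary = {
        "median": float(np.median(pooled)),
        "q25": float(np.quantile(pooled, 0.25)),
        "q75": float(np.quantile(pooled, 0.75)),
        "mean": float(np.mean(pooled)),
        "n_samples": n_samples,
    }
    return MonteCarloResult(samples=samples, poles=poles, zetas=zetas, summary=summary)


def scale_condition(
    dist: ParamDistribution,
    fold: float = SUPPRESSION_FOLD,
    mode: Literal["transcriptional", "post_translational"] = "transcriptional",
    w_yz_mean_override: float | None = None,
    w_z_mean_override: float | None = None,
) -> ParamDistribution:
    """Rescale the DNA-damage distribution to emulate normal-condition suppression.

    ``transcriptional`` multiplies only the w_yz mean by ``fold`` (stronger
    Mdm2->p53 repression); ``post_translational`` additionally divides the
    w_z mean by ``fold`` (p53 destabilised in equal measure).  SDs are left
    untouched in both modes.  The ``*_override`` arguments substitute
    explicit scaled means — e.g. published rounded values — in place of the
    computed ones.
    """
    if fold <= 0:
        raise ValueError("fold must be positive")
    if mode not in ("transcriptional", "post_translational"):
        raise ValueError("mode must be 'transcriptional' or 'post_translational'")
    w_yz_mean = dist.w_yz_mean * fold if w_yz_mean_override is None else w_yz_mean_override
    changes: dict[str, float] = {"w_yz_mean": w_yz_mean}
    if mode == "post_translational":
        changes["w_z_mean"] = (
            dist.w_z_mean / fold if w_z_mean_override is None else w_z_mean_override
        )
    return dist.replace(**changes)


def euler_discretize(
    p_zy: float, p_yz: float, p_y: float, p_z: float, T: float, w_xy: float = 1.0
) -> DiscreteParams:
    """Forward-Euler map from continuous rates to per-step weights.

    ``w = 1 - p*T`` for the stability weights and ``w = p*T`` for the
    couplings; under this substitution the discrete steady-state error
    equals the continuous one exactly, for any T.
    """
    return DiscreteParams(
        w_xy=w_xy,
        w_zy=p_zy * T,
        w_yz=p_yz * T,
        w_y=1.0 - p_y * T,
        w_z=1.0 - p_z * T,
        T=T,
    )
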