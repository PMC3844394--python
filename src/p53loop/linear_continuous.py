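"""Closed-form analysis of the continuous linear p53-Mdm2 feedback model.

The model is a three-variable linear ODE system in which ATM (``x``) is held
constant, Mdm2 (``y``) is produced in proportion to p53 and degraded at rate
``p_y``, and p53 (``z``) is suppressed by Mdm2 and degraded at rate ``p_z``::

    dx/dt = 0
    dy/dt = p_zy * z - p_xy * x - p_y * y
    dz/dt = -p_yz * y - p_z * z

Closing the loop from the ATM input to the p53 output yields a second-order
transfer function whose steady-state disturbance error, natural frequency,
damping ratio and percent overshoot all have closed forms in the five rates.
Those closed forms, and the trade-off sweeps built on them, are what this
module implements.

All rates are expressed in h^-1 by default.  Rates given per minute (some
published parameter sets use min^-1) must be converted explicitly with
:func:`convert_rate`; no function here performs silent unit conversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy import signal

__all__ = [
    "ContinuousParams",
    "SecondOrderSummary",
    "TradeoffCurve",
    "OPERATING_POINT",
    "convert_rate",
    "closed_loop_coeffs",
    "steady_state_error",
    "natural_frequency",
    "damping_ratio",
    "percent_overshoot",
    "second_order_summary",
    "zeta_minimizing_pz",
    "step_response_p53",
    "second_order_step_response",
    "tradeoff_sweep",
]

_MINUTES_PER_HOUR = 60.0


def convert_rate(value: float, from_unit: str, to_unit: str = "per_hour") -> float:
    """Convert a first-order rate between ``per_hour`` and ``per_minute``.

    Conversion is always explicit: passing a min^-1 literature value into a
    ContinuousParams field without routing it through this helper is a user
    error, not something the library guesses at.
    """
    units = {"per_hour": 1.0, "per_minute": _MINUTES_PER_HOUR}
    try:
        return value * units[from_unit] / units[to_unit]
    except KeyError as exc:
        raise ValueError(f"unknown rate unit {exc.args[0]!r}") from None


@dataclass(frozen=True)
class ContinuousParams:
    """The five strictly positive rates of the linear feedback loop (h^-1).

    Attributes
    ----------
    p_xy : ATM -> Mdm2 suppression gain.
    p_zy : p53 -> Mdm2 transcriptional activation gain.
    p_yz : Mdm2 -> p53 suppression gain.
    p_y  : Mdm2 degradation rate.
    p_z  : p53 degradation rate.
    """

    p_xy: float
    p_zy: float
    p_yz: float
    p_y: float
    p_z: float

    def __post_init__(self) -> None:
        for name in ("p_xy", "p_zy", "p_yz", "p_y", "p_z"):
            value = getattr(self, name)
            if not (value > 0 and math.isfinite(value)):
                raise ValueError(f"{name} must be strictly positive and finite, got {value!r}")

    def replace(self, **changes: float) -> "ContinuousParams":
        return replace(self, **changes)


#: Published operating point of the loop under normal conditions
#: (p_yz = p_zy = 0.8 h^-1, p_y = p_z = 2.0 h^-1; protein half-lives ~20 min).
OPERATING_POINT = ContinuousParams(p_xy=1.0, p_zy=0.8, p_yz=0.8, p_y=2.0, p_z=2.0)


@dataclass(frozen=True)
class SecondOrderSummary:
    """Second-order metrics of the closed loop at one parameter set."""

    omega_n: float  # natural frequency, h^-1
    zeta: float  # damping ratio, dimensionless
    percent_os: float  # percent overshoot, % of final value
    ss_error: float  # steady-state error to a unit step disturbance


@dataclass(frozen=True)
class TradeoffCurve:
    """Steady-state-error vs percent-overshoot pairs along a parameter sweep."""

    swept_parameter: Literal["p_yz", "p_z"]
    values: np.ndarray
    points: np.ndarray  # shape (n, 2): columns (ss_error, percent_os)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        points = np.asarray(self.points, dtype=float)
        if values.ndim != 1 or np.any(np.diff(values) <= 0):
            raise ValueError("sweep grid must be 1-D and strictly increasing")
        if points.shape != (values.size, 2):
            raise ValueError("points must be (n, 2) matching the grid length")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "points", points)

    @property
    def ss_error(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def percent_os(self) -> np.ndarray:
        return self.points[:, 1]


def closed_loop_coeffs(params: ContinuousParams) -> tuple[float, float, float]:
    """Coefficients (gain, b, c) of the closed loop G(s) = gain / (s^2 + b s + c).

    gain = p_xy * p_yz, b = p_y + p_z, c = p_y * p_z + p_yz * p_zy.
    """
    gain = params.p_xy * params.p_yz
    b = params.p_y + params.p_z
    c = params.p_y * params.p_z + params.p_yz * params.p_zy
    return gain, b, c


def steady_state_error(params: ContinuousParams) -> float:
    """Asymptotic error caused by a unit step disturbance on p53.

    By the final value theorem the error signal settles at
    ``p_zy * p_y / (p_y * p_z + p_yz * p_zy)``: strengthening the Mdm2
    suppression of p53 (p_yz) or destabilising p53 (p_z) both shrink it.
    """
    return params.p_zy * params.p_y / (params.p_y * params.p_z + params.p_yz * params.p_zy)


def natural_frequency(params: ContinuousParams) -> float:
    """omega_n = sqrt(p_y * p_z + p_yz * p_zy), in h^-1."""
    return math.sqrt(params.p_y * params.p_z + params.p_yz * params.p_zy)


def damping_ratio(params: ContinuousParams) -> float:
    """zeta = (p_y + p_z) / (2 * omega_n); below 1 the loop overshoots."""
    return (params.p_y + params.p_z) / (2.0 * natural_frequency(params))


def percent_overshoot(zeta: float) -> float:
    """Percent overshoot of the second-order unit step response.

    For an underdamped loop (0 <= zeta < 1) this is
    ``100 * exp(-zeta * pi / sqrt(1 - zeta^2))``; at zeta = 0 the response
    is a sustained oscillation peaking at twice the final value (100%
    overshoot), and for zeta >= 1 there is no overshoot at all, so 0 is
    returned there by definition.
    """
    if not math.isfinite(zeta) or zeta < 0:
        raise ValueError(f"damping ratio must be finite and >= 0, got {zeta!r}")
    if zeta >= 1.0:
        return 0.0
    return 100.0 * math.exp(-zeta * math.pi / math.sqrt(1.0 - zeta * zeta))


def second_order_summary(params: ContinuousParams) -> SecondOrderSummary:
    """All four closed-form metrics of the loop at one parameter set."""
    zeta = damping_ratio(params)
    return SecondOrderSummary(
        omega_n=natural_frequency(params),
        zeta=zeta,
        percent_os=percent_overshoot(zeta),
        ss_error=steady_state_error(params),
    )


def zeta_minimizing_pz(params: ContinuousParams) -> float | None:
    """p53 degradation rate at which the damping ratio is minimal.

    Setting d(zeta)/d(p_z) = 0 gives ``p_z* = p_y - 2 p_yz p_zy / p_y``,
    a positive interior minimum only when ``p_y^2 > 2 p_yz p_zy``.  Below
    the returned value zeta falls with p_z; above it zeta rises, which is
    the regime where increasing p53 turnover improves both the steady-state
    error and the overshoot.  Returns ``None`` when no positive interior
    minimum exists (the boundary case ``p_y^2 == 2 p_yz p_zy`` returns 0.0,
    the minimum sitting at the origin of the admissible range).
    """
    pz_star = params.p_y - 2.0 * params.p_yz * params.p_zy / params.p_y
    if pz_star < 0.0:
        return None
    return pz_star


def step_response_p53(
    params: ContinuousParams, Y: float, times: Sequence[float]
) -> tuple[np.ndarray, float]:
    """Magnitude of the p53 step response under a constant Mdm2 level ``Y``.

    With y(t) held at Y, the p53 equation integrates to
    ``z(t) = -(p_yz * Y / p_z) * (1 - exp(-p_z * t))``: the deviation is
    downward because the model carries no basal p53 production, so this
    function reports the deviation magnitude ``|z(t)|``.  The response time
    (time for z to reach half its steady amplitude) is ``ln 2 / p_z`` and is
    independent of p_yz, while the steady amplitude ``p_yz * Y / p_z``
    depends on both rates.

    Returns (|z| trajectory, response time in hours).
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("time grid must be non-empty")
    if np.any(t < 0) or np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be non-negative and strictly increasing")
    if Y < 0:
        raise ValueError("Mdm2 level Y must be non-negative")
    amplitude = params.p_yz * Y / params.p_z
    trajectory = amplitude * (1.0 - np.exp(-params.p_z * t))
    response_time = math.log(2.0) / params.p_z
    return trajectory, response_time


def second_order_step_response(
    omega_n: float, zeta: float, times: Sequence[float]
) -> np.ndarray:
    """Unit step response of the canonical loop omega_n^2 / (s^2 + 2 zeta omega_n s + omega_n^2).

    Normalised so the final value is 1; covers the underdamped, critically
    damped and overdamped regimes (and the undamped zeta = 0 case, which
    oscillates forever between 0 and 2).
    """
    t = np.asarray(times, dtype=float)
    if not omega_n > 0:
        raise ValueError("omega_n must be strictly positive")
    if zeta < 0:
        raise ValueError("zeta must be >= 0")
    system = signal.lti([omega_n**2], [1.0, 2.0 * zeta * omega_n, omega_n**2])
    _, response = signal.step(system, T=t)
    return np.asarray(response)


def tradeoff_sweep(
    params: ContinuousParams,
    which: Literal["p_yz", "p_z"],
    grid: Sequence[float] | None = None,
) -> TradeoffCurve:
    """Sweep one rate and record the (ss_error, %OS) trade-off curve.

    Sweeping p_yz trades the two off against each other (error falls, %OS
    rises); sweeping p_z improves the error monotonically while %OS rises
    then falls, turning over at :func:`zeta_minimizing_pz`.  The default
    grid is 50 evenly spaced points over 0.5-3.0 h^-1.
    """
    if which not in ("p_yz", "p_z"):
        raise ValueError("which must be 'p_yz' or 'p_z'")
    values = np.linspace(0.5, 3.0, 50) if grid is None else np.asarray(grid, dtype=float)
    if values.ndim != 1 or values.size == 0 or np.any(values <= 0):
        raise ValueError("grid must be 1-D and strictly positive")
    if values.size > 1 and np.any(np.diff(values) <= 0):
        raise ValueError("grid must be strictly increasing")
    points = np.empty((values.size, 2))
    for i, value in enumerate(values):
        p = params.replace(**{which: float(value)})
        points[i, 0] = steady_state_error(p)
        points[i, 1] = percent_overshoot(damping_ratio(p))
    return TradeoffCurve(swept_parameter=which, values=values, points=points)
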