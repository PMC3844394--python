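"""Nonlinear mechanistic model of the p53-Mdm2 loop with optional delay.

Four species — mdm2 mRNA, Mdm2 protein, p53 mRNA, p53 protein — with
cooperative (Hill) transcriptional activation of mdm2 by p53 and
Michaelis-Menten Mdm2-mediated p53 ubiquitination/degradation::

    d[mdm2_mRNA]/dt = beta1 * P^n / (K1^n + P^n) - alpha1 * [mdm2_mRNA]
    d[Mdm2]/dt      = beta2 * [mdm2_mRNA]        - alpha2 * [Mdm2]
    d[p53_mRNA]/dt  = beta3                      - alpha3 * [p53_mRNA]
    d[P53]/dt       = beta4 * [p53_mRNA] - alpha4 * [P53]
                      - gamma * [P53] / (K2 + [P53]) * [Mdm2]

A transcription->translation delay tau shifts the mRNA arguments of both
translation terms to ``t - tau``; the delayed system is integrated by the
method of steps.  The disturbance protocol applies a small multiplicative
step (default +1%) to p53 production after the system has equilibrated and
reads off the steady-state error ``|SS_old - SS_new| / SS_old`` and the
overshoot fraction ``(peak - SS_new) / SS_new`` (a fraction of the new
steady level, not x100).

Time and concentration are in the arbitrary units of the published
parameter set (all betas 1, alpha1 = alpha3 = 1, alpha2 = alpha4 = 0.01,
n = 2, K1 = 10, K2 = 100), exposed here as :data:`MECH_DEFAULTS`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq
from scipy.signal import find_peaks

__all__ = [
    "MechParams",
    "MECH_DEFAULTS",
    "DisturbanceMetrics",
    "Trajectory",
    "IntegrationError",
    "mech_rhs",
    "steady_state",
    "simulate_mech",
    "simulate_mech_delay",
    "disturbance_response",
    "gamma_sweep",
    "detect_sustained_oscillation",
]

SPECIES = ("mdm2_mrna", "mdm2", "p53_mrna", "p53")


class IntegrationError(RuntimeError):
    """Raised when the ODE/DDE solver fails or a steady state is not reached."""


@dataclass(frozen=True)
class MechParams:
    """Rates and constants of the mechanistic model (arbitrary units)."""

    beta1: float = 1.0  # mdm2 transcription (max Hill rate)
    beta2: float = 1.0  # Mdm2 translation
    beta3: float = 1.0  # p53 transcription (constitutive)
    beta4: float = 1.0  # p53 translation
    alpha1: float = 1.0  # mdm2 mRNA degradation
    alpha2: float = 0.01  # Mdm2 protein degradation
    alpha3: float = 1.0  # p53 mRNA degradation
    alpha4: float = 0.01  # p53 basal protein degradation
    n: float = 2.0  # Hill coefficient
    K1: float = 10.0  # Hill dissociation constant
    K2: float = 100.0  # MM saturation constant
    gamma: float = 1.0  # Mdm2-mediated p53 ubiquitination rate
    tau: float = 0.0  # transcription -> translation delay

    def __post_init__(self) -> None:
        positive = (
            "beta1", "beta2", "beta3", "beta4",
            "alpha1", "alpha2", "alpha3", "alpha4", "K1", "K2",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.n < 1:
            raise ValueError("Hill coefficient n must be >= 1")
        if self.tau < 0:
            raise ValueError("delay tau must be >= 0")

    def replace(self, **changes: float) -> "MechParams":
        return replace(self, **changes)


#: Published parameter set used for the disturbance and delay simulations.
MECH_DEFAULTS = MechParams()


@dataclass(frozen=True)
class Trajectory:
    """Time grid plus a (len(t), 4) state array in SPECIES order."""

    t: np.ndarray
    y: np.ndarray

    def species(self, name: str) -> np.ndarray:
        return self.y[:, SPECIES.index(name)]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.y, columns=list(SPECIES))
        frame.insert(0, "time", self.t)
        return frame


@dataclass(frozen=True)
class DisturbanceMetrics:
    """Steady-state and transient response to a production step on p53."""

    ss_old: float
    ss_new: float
    overshoot_level: float
    ss_error: float  # |ss_old - ss_new| / ss_old
    percent_os: float  # (overshoot_level - ss_new) / ss_new, a fraction


def _hill(p53: float, params: MechParams) -> float:
    pn = p53**params.n
    return params.beta1 * pn / (params.K1**params.n + pn)


def mech_rhs(t: float, state: np.ndarray, params: MechParams) -> np.ndarray:
    """Right-hand side of the four ODEs (tau = 0 form)."""
    m_rna, mdm2, p_rna, p53 = state
    p53 = max(p53, 0.0)  # guards the Hill/MM terms against solver undershoot
    return np.array([
        _hill(p53, params) - params.alpha1 * m_rna,
        params.beta2 * m_rna - params.alpha2 * mdm2,
        params.beta3 - params.alpha3 * p_rna,
        params.beta4 * p_rna
        - params.alpha4 * p53
        - params.gamma * p53 / (params.K2 + p53) * mdm2,
    ])


def steady_state(params: MechParams) -> np.ndarray:
    """Equilibrium of the mechanistic model, found by 1-D root bracketing.

    The mRNA equilibria are linear (``p53_mRNA* = beta3/alpha3``;
    ``mdm2_mRNA*`` follows from the Hill term), leaving a single scalar
    balance in the p53 level that is strictly decreasing in net removal, so
    the root is unique and bracketed by (0, beta4*beta3/(alpha3*alpha4)].
    Delay does not shift the equilibrium, so this holds for any tau.
    """
    p_rna = params.beta3 / params.alpha3
    production = params.beta4 * p_rna

    def balance(p53: float) -> float:
        mdm2 = params.beta2 * _hill(p53, params) / (params.alpha1 * params.alpha2)
        return production - params.alpha4 * p53 - params.gamma * p53 / (params.K2 + p53) * mdm2

    upper = production / params.alpha4
    p53_ss = brentq(balance, 1e-12, upper, xtol=1e-12, rtol=1e-14)
    m_rna = _hill(p53_ss, params) / params.alpha1
    return np.array([m_rna, params.beta2 * m_rna / params.alpha2, p_rna, p53_ss])


def simulate_mech(
    params: MechParams,
    initial: Sequence[float],
    t_end: float,
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the tau = 0 model with a stiff-capable adaptive solver."""
    y0 = np.asarray(initial, dtype=float)
    if y0.shape != (4,) or np.any(y0 < 0):
        raise ValueError("initial state must be four non-negative values")
    sol = solve_ivp(
        mech_rhs, (0.0, t_end), y0, args=(params,), method="LSODA",
        t_eval=t_eval, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"ODE integration failed: {sol.message}")
    return Trajectory(t=sol.t, y=np.clip(sol.y.T, 0.0, None))


def simulate_mech_delay(
    params: MechParams,
    history: Sequence[float] | Callable[[float], np.ndarray],
    t_end: float,
    n_points: int = 2000,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the delayed model by the method of steps.

    ``history`` is either a constant state on [-tau, 0] or a callable
    returning the full state for t <= 0.  Each interval of length tau is
    integrated with the previous interval's dense solution supplying the
    delayed mRNA arguments; the solver step is capped at tau/10 so the
    history lookups never skip over structure.  At tau = 0 this reduces
    exactly to :func:`simulate_mech`.
    """
    if params.tau == 0.0:
        t_eval = np.linspace(0.0, t_end, n_points)
        if callable(history):
            y0 = np.asarray(history(0.0), dtype=float)
        else:
            y0 = np.asarray(history, dtype=float)
        return simulate_mech(params, y0, t_end, t_eval=t_eval, rtol=rtol, atol=atol)

    tau = params.tau
    if callable(history):
        hist_fn = history
    else:
        const = np.asarray(history, dtype=float)
        if const.shape != (4,):
            raise ValueError("constant history must be a state of four values")
        hist_fn = lambda t: const  # noqa: E731

    segments: list = []  # (t_start, t_stop, dense OdeSolution)

    def delayed_state(t: float) -> np.ndarray:
        if t <= 0.0:
            return np.asarray(hist_fn(t), dtype=float)
        for t0, t1, dense in reversed(segments):
            if t0 - 1e-12 <= t <= t1 + 1e-12:
                return dense(min(max(t, t0), t1))
        raise IntegrationError(f"no history available at t={t}")

    def rhs(t: float, state: np.ndarray) -> np.ndarray:
        m_rna, mdm2, p_rna, p53 = state
        p53 = max(p53, 0.0)
        lagged = delayed_state(t - tau)
        m_rna_lag, p_rna_lag = max(lagged[0], 0.0), max(lagged[2], 0.0)
        return np.array([
            _hill(p53, params) - params.alpha1 * m_rna,
            params.beta2 * m_rna_lag - params.alpha2 * mdm2,
            params.beta3 - params.alpha3 * p_rna,
            params.beta4 * p_rna_lag
            - params.alpha4 * p53
            - params.gamma * p53 / (params.K2 + p53) * mdm2,
        ])

    y0 = np.asarray(hist_fn(0.0), dtype=float)
    t_now = 0.0
    state = y0
    while t_now < t_end:
        t_next = min(t_now + tau, t_end)
        sol = solve_ivp(
            rhs, (t_now, t_next), state, method="RK45", dense_output=True,
            max_step=tau / 10.0, rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise IntegrationError(f"DDE integration failed at t={t_now}: {sol.message}")
        segments.append((t_now, t_next, sol.sol))
        state = sol.y[:, -1]
        t_now = t_next

    t_grid = np.linspace(0.0, t_end, n_points)
    y_grid = np.empty((t_grid.size, 4))
    y_grid[0] = y0
    seg_idx = 0
    for k, t in enumerate(t_grid):
        if k == 0:
            continue
        while t > segments[seg_idx][1] + 1e-12:
            seg_idx += 1
        t0, t1, dense = segments[seg_idx]
        y_grid[k] = dense(min(max(t, t0), t1))
    return Trajectory(t=t_grid, y=np.clip(y_grid, 0.0, None))


def _settle_time(params: MechParams) -> float:
    """Integration horizon covering ~10x the slowest first-order timescale."""
    slowest = 1.0 / min(params.alpha1, params.alpha2, params.alpha3, params.alpha4)
    return 10.0 * slowest + 20.0 * params.tau


def disturbance_response(
    params: MechParams,
    step: float = 0.01,
    step_target: str = "beta3",
    t_end: float | None = None,
    n_points: int = 4000,
    settle_rtol: float = 1e-6,
) -> DisturbanceMetrics:
    """Apply a relative production step at equilibrium and measure the response.

    The system is placed at its pre-step equilibrium (the protocol's burn-in
    taken to convergence), the chosen p53 production rate (``beta3`` by
    default, ``beta4`` as the alternative) is multiplied by ``1 + step``,
    and the trajectory is integrated to the new equilibrium.  The overshoot
    level is the extreme p53 value in the direction of the step.  Both
    metrics are fractions per the simulation definitions: steady-state
    error ``|SS_old - SS_new|/SS_old`` and %OS ``(peak - SS_new)/SS_new``.
    """
    if step_target not in ("beta3", "beta4"):
        raise ValueError("step_target must be 'beta3' or 'beta4'")
    ss0 = steady_state(params)
    ss_old = ss0[3]
    if step == 0.0:
        return DisturbanceMetrics(ss_old, ss_old, ss_old, 0.0, 0.0)

    stepped = params.replace(**{step_target: getattr(params, step_target) * (1.0 + step)})
    ss1 = steady_state(stepped)
    ss_new = ss1[3]
    horizon = _settle_time(stepped) if t_end is None else t_end
    if stepped.tau > 0:
        traj = simulate_mech_delay(stepped, ss0, horizon, n_points=n_points)
    else:
        traj = simulate_mech(
            stepped, ss0, horizon, t_eval=np.linspace(0.0, horizon, n_points)
        )
    p53 = traj.species("p53")
    if abs(p53[-1] - ss_new) > settle_rtol * max(ss_new, 1.0):
        raise IntegrationError(
            f"trajectory did not settle: final p53 {p53[-1]:.6g} vs equilibrium {ss_new:.6g}"
        )
    peak = p53.max() if step > 0 else p53.min()
    overshoot = max((peak - ss_new) / ss_new, 0.0) if step > 0 else max((ss_new - peak) / ss_new, 0.0)
    return DisturbanceMetrics(
        ss_old=ss_old,
        ss_new=ss_new,
        overshoot_level=peak,
        ss_error=abs(ss_old - ss_new) / ss_old,
        percent_os=overshoot,
    )


def gamma_sweep(
    params: MechParams,
    gamma_grid: Sequence[float] | None = None,
    step: float = 0.01,
    step_target: str = "beta3",
    tau: float | None = None,
) -> pd.DataFrame:
    """Disturbance metrics along a gamma grid (default log-spaced 1e-2..1e2).

    Returns a DataFrame with columns (gamma, ss_error, percent_os) and two
    attrs flags: ``monotone_error`` (ss_error strictly decreasing along the
    grid) and ``unimodal_os`` (percent_os rises then falls with a single
    interior turning point).
    """
    grid = (
        np.logspace(-2, 2, 25) if gamma_grid is None else np.asarray(gamma_grid, dtype=float)
    )
    if grid.ndim != 1 or np.any(grid <= 0):
        raise ValueError("gamma grid must be 1-D and strictly positive")
    if grid.size > 1 and np.any(np.diff(grid) <= 0):
        raise ValueError("gamma grid must be strictly increasing")
    rows = []
    for gamma in grid:
        p = params.replace(gamma=float(gamma))
        if tau is not None:
            p = p.replace(tau=tau)
        metrics = disturbance_response(p, step=step, step_target=step_target)
        rows.append((float(gamma), metrics.ss_error, metrics.percent_os))
    table = pd.DataFrame(rows, columns=["gamma", "ss_error", "percent_os"])
    err = table["ss_error"].to_numpy()
    os_ = table["percent_os"].to_numpy()
    table.attrs["monotone_error"] = bool(np.all(np.diff(err) < 0)) if err.size > 1 else True
    rises = np.diff(os_) > 0
    table.attrs["unimodal_os"] = (
        bool(np.sum(np.diff(rises.astype(int)) == -1) == 1) if os_.size > 2 else True
    )
    return table


def detect_sustained_oscillation(
    trajectory: Trajectory,
    species: str = "p53",
    tail_fraction: float = 0.5,
    rel_amplitude_tol: float = 0.01,
    decay_tol: float = 0.05,
) -> tuple[bool, dict]:
    """Decide whether the tail of a trajectory oscillates without decaying.

    Sustained means: the tail-window peak-to-peak amplitude exceeds
    ``rel_amplitude_tol`` times the tail mean, and the amplitudes of
    successive maxima do not shrink (ratio >= 1 - decay_tol).  Returns the
    flag plus amplitude/period estimates (period from mean peak spacing).
    """
    if not 0.0 < tail_fraction <= 1.0:
        raise ValueError("tail_fraction must lie in (0, 1]")
    values = trajectory.species(species)
    t = trajectory.t
    if values.size < 16:
        raise ValueError("trajectory too short for oscillation analysis")
    start = int(values.size * (1.0 - tail_fraction))
    tail = values[start:]
    tail_t = t[start:]
    amplitude = float(tail.max() - tail.min())
    level = float(np.mean(tail))
    info = {"amplitude": amplitude, "period": math.nan, "n_peaks": 0}
    if level <= 0 or amplitude < rel_amplitude_tol * max(level, 1e-12):
        return False, info
    peaks, props = find_peaks(tail, prominence=0.25 * amplitude)
    info["n_peaks"] = int(peaks.size)
    if peaks.size < 3:
        return False, info
    info["period"] = float(np.mean(np.diff(tail_t[peaks])))
    heights = tail[peaks] - tail.min()
    ratios = heights[1:] / heights[:-1]
    sustained = bool(np.all(ratios >= 1.0 - decay_tol))
    return sustained, info
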