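"""Exact stochastic simulation of the mechanistic p53-Mdm2 reaction network.

The four deterministic rate equations are recast as eight reaction channels
whose macroscopic rate equations reproduce them exactly: Hill-propensity
mdm2 transcription, zeroth-order p53 transcription, two translations, four
linear degradations, and a Michaelis-Menten propensity for Mdm2-mediated
p53 removal.  The Hill and MM expressions are used directly as propensities
on copy numbers (no expansion into elementary binding steps), mirroring the
deterministic model in the macroscopic limit.

Species are interpreted as molecule counts; a volume factor ``omega`` maps
the concentration-scale parameters to counts (production rates and the
constants K1, K2 scale with omega, first-order rates do not).  Noise
magnitudes depend on omega.

The headline analysis sweeps gamma while holding the deterministic p53
mean constant by compensating the basal degradation rate alpha4, and
reports the Fano-factor-style noise statistic variance/mean — which grows
with gamma: routing p53 turnover through fluctuating Mdm2 buys disturbance
rejection at the price of amplified intrinsic noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .nonlinear_mechanistic import MechParams, steady_state

__all__ = [
    "ReactionSystem",
    "EnsembleStats",
    "build_reaction_system",
    "gillespie_run",
    "ensemble_steady_stats",
    "compensate_alpha4",
    "noise_vs_gamma",
]

SPECIES = ("mdm2_mrna", "mdm2", "p53_mrna", "p53")


@dataclass(frozen=True)
class ReactionSystem:
    """Named species with stoichiometry vectors and propensity callables."""

    species: tuple
    stoichiometry: np.ndarray  # (n_reactions, n_species) integer changes
    propensities: tuple  # callables state -> rate >= 0
    labels: tuple

    def propensity_vector(self, state: np.ndarray) -> np.ndarray:
        return np.array([a(state) for a in self.propensities])


@dataclass(frozen=True)
class EnsembleStats:
    """Moments of the stationary p53 copy-number ensemble."""

    mean: float
    variance: float
    sd: float
    noise: float  # variance / mean
    n_samples: int


def build_reaction_system(params: MechParams, omega: float = 1.0) -> ReactionSystem:
    """Eight reaction channels whose mean-field limit is the ODE model.

    With volume factor omega, concentration x maps to count N = omega * x:
    zeroth-order productions scale by omega and the K constants become
    omega * K, leaving all first-order channels untouched.
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    K1n = (omega * params.K1) ** params.n
    K2 = omega * params.K2

    def hill(state: np.ndarray) -> float:
        pn = float(state[3]) ** params.n
        return omega * params.beta1 * pn / (K1n + pn) if pn > 0 else 0.0

    def mm(state: np.ndarray) -> float:
        p53 = float(state[3])
        return params.gamma * p53 / (K2 + p53) * float(state[1]) if p53 > 0 else 0.0

    propensities: tuple[Callable[[np.ndarray], float], ...] = (
        hill,                                                  # -> mdm2_mrna
        lambda s: params.alpha1 * float(s[0]),                 # mdm2_mrna ->
        lambda s: params.beta2 * float(s[0]),                  # -> mdm2
        lambda s: params.alpha2 * float(s[1]),                 # mdm2 ->
        lambda s: omega * params.beta3,                        # -> p53_mrna
        lambda s: params.alpha3 * float(s[2]),                 # p53_mrna ->
        lambda s: params.beta4 * float(s[2]),                  # -> p53
        lambda s: params.alpha4 * float(s[3]) + mm(s),         # p53 -> (basal + MM)
    )
    stoich = np.array([
        [1, 0, 0, 0],
        [-1, 0, 0, 0],
        [0, 1, 0, 0],
        [0, -1, 0, 0],
        [0, 0, 1, 0],
        [0, 0, -1, 0],
        [0, 0, 0, 1],
        [0, 0, 0, -1],
    ])
    labels = (
        "mdm2 transcription (Hill)", "mdm2 mRNA decay", "Mdm2 translation",
        "Mdm2 decay", "p53 transcription", "p53 mRNA decay",
        "p53 translation", "p53 removal (basal + MM)",
    )
    return ReactionSystem(
        species=SPECIES, stoichiometry=stoich, propensities=propensities, labels=labels
    )


def drift(system: ReactionSystem, state: np.ndarray) -> np.ndarray:
    """Summed stoichiometry-weighted propensities — the mean-field RHS."""
    return system.stoichiometry.T @ system.propensity_vector(np.asarray(state, dtype=float))


def gillespie_run(
    system: ReactionSystem,
    initial: Sequence[int],
    t_end: float,
    seed: int | np.random.Generator | None = None,
    sample_times: Sequence[float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Direct-method SSA sample path.

    Returns event times and states; if ``sample_times`` is given, the
    piecewise-constant path is instead sampled on that grid (memory-frugal
    for long runs).  When every propensity vanishes the state is absorbing
    and the trajectory stays flat to t_end.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    state = np.asarray(initial, dtype=np.int64).copy()
    if state.shape != (len(system.species),) or np.any(state < 0):
        raise ValueError("initial counts must be non-negative, one per species")
    stoich = system.stoichiometry
    t = 0.0
    if sample_times is not None:
        grid = np.asarray(sample_times, dtype=float)
        out = np.empty((grid.size, state.size), dtype=np.int64)
        next_idx = 0
    else:
        times_list = [0.0]
        states_list = [state.copy()]

    while t < t_end:
        a = system.propensity_vector(state)
        total = a.sum()
        if total <= 0.0:  # absorbing state: flat to the horizon
            t_next = t_end
        else:
            t_next = t + rng.exponential(1.0 / total)
        if sample_times is not None:
            while next_idx < grid.size and grid[next_idx] < min(t_next, t_end) + 1e-15:
                out[next_idx] = state
                next_idx += 1
        if t_next >= t_end or total <= 0.0:
            t = t_end
            break
        t = t_next
        reaction = int(np.searchsorted(np.cumsum(a), rng.random() * total, side="right"))
        reaction = min(reaction, a.size - 1)  # guard float roundoff at the top edge
        state += stoich[reaction]
        if sample_times is None:
            times_list.append(t)
            states_list.append(state.copy())

    if sample_times is not None:
        while next_idx < grid.size:
            out[next_idx] = state
            next_idx += 1
        return grid, out
    return np.array(times_list), np.array(states_list)


def ensemble_steady_stats(
    system: ReactionSystem,
    initial: Sequence[int],
    n_runs: int = 200,
    t_end: float = 600.0,
    burn_in: float = 150.0,
    seed: int | np.random.Generator | None = None,
    n_samples_per_run: int = 8,
) -> EnsembleStats:
    """Stationary p53 moments pooled over independent SSA runs.

    Each run is sampled at ``n_samples_per_run`` times evenly spaced between
    burn_in and t_end; samples within a run are spaced by several p53
    correlation times under the default horizon, and pooling across runs
    removes any residual within-run dependence from the mean estimate.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    if burn_in >= t_end:
        raise ValueError("burn_in must be < t_end")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sample_times = np.linspace(burn_in, t_end, n_samples_per_run)
    samples = []
    for _ in range(n_runs):
        _, states = gillespie_run(system, initial, t_end, seed=rng, sample_times=sample_times)
        samples.append(states[:, 3])
    pooled = np.concatenate(samples).astype(float)
    mean = float(pooled.mean())
    variance = float(pooled.var(ddof=1))
    return EnsembleStats(
        mean=mean,
        variance=variance,
        sd=math.sqrt(variance),
        noise=variance / mean if mean > 0 else math.inf,
        n_samples=pooled.size,
    )


def compensate_alpha4(params: MechParams, gamma: float, target_p53: float) -> float:
    """Basal degradation rate that pins the deterministic p53 mean at a target.

    At equilibrium ``p53_mRNA* = beta3/alpha3`` and Mdm2* follows from the
    Hill term at the target p53, so the p53 balance solves in closed form::

        alpha4 = [beta4 beta3/alpha3 - gamma * p/(K2+p) * Mdm2*(p)] / p

    Raising gamma shifts removal onto the Mdm2-mediated channel, so the
    compensating alpha4 falls; past the flux the channel can absorb there is
    no positive alpha4 and the target is infeasible.
    """
    if target_p53 <= 0:
        raise ValueError("target p53 level must be positive")
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    p = target_p53
    production = params.beta4 * params.beta3 / params.alpha3
    pn = p**params.n
    mdm2_eq = (
        params.beta2 * params.beta1 * pn / (params.K1**params.n + pn)
        / (params.alpha1 * params.alpha2)
    )
    alpha4 = (production - gamma * p / (params.K2 + p) * mdm2_eq) / p
    if alpha4 <= 0:
        raise ValueError(
            f"no positive alpha4 holds p53 at {target_p53} with gamma={gamma}: "
            "the Mdm2-mediated flux already exceeds production"
        )
    return alpha4


def noise_vs_gamma(
    params: MechParams,
    gamma_grid: Sequence[float],
    target_p53: float,
    n_runs: int = 200,
    t_end: float = 600.0,
    burn_in: float = 150.0,
    seed: int | None = None,
    omega: float = 1.0,
) -> pd.DataFrame:
    """Stationary p53 noise along a gamma grid with the mean held constant.

    Per grid point: compensate alpha4 so the deterministic fixed point stays
    at ``target_p53``, build the reaction system, start each SSA run at the
    (rounded) deterministic equilibrium, and pool stationary samples.
    Returns columns (gamma, alpha4, mean, variance, noise).
    """
    grid = np.asarray(gamma_grid, dtype=float)
    if grid.ndim != 1 or np.any(grid <= 0) or (grid.size > 1 and np.any(np.diff(grid) <= 0)):
        raise ValueError("gamma grid must be 1-D, positive and strictly increasing")
    rng = np.random.default_rng(seed)
    rows = []
    for gamma in grid:
        alpha4 = compensate_alpha4(params, float(gamma), target_p53)
        p = params.replace(gamma=float(gamma), alpha4=alpha4)
        system = build_reaction_system(p, omega=omega)
        initial = np.rint(omega * steady_state(p)).astype(np.int64)
        stats = ensemble_steady_stats(
            system, initial, n_runs=n_runs, t_end=t_end, burn_in=burn_in, seed=rng
        )
        rows.append((float(gamma), alpha4, stats.mean, stats.variance, stats.noise))
    return pd.DataFrame(rows, columns=["gamma", "alpha4", "mean", "variance", "noise"])
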