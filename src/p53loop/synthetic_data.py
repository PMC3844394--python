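"""Synthetic two-channel p53/Mdm2 fluorescence-like time series.

The study's parameter-tracking input is a fluorescence quantification of a
single-cell movie: two positive, noisy, oscillatory channels of 285 frames
sampled every 0.11 hr.  That data set is not publicly downloadable, so this
module emulates it from the discrete-time model itself: iterate the
difference equations under a known (possibly time-varying) weight
schedule, map each channel affinely onto a positive fluorescence-like
range, and add Gaussian measurement noise.  Because the generating
schedule is returned alongside the data, parameter-recovery tests can
check the NLMS tracker against exact ground truth — something the real
movie could never provide.

The affine channel mapping is recorded in the output's ``channel_scaling``
metadata (per channel: (scale, offset) with stored = scale * raw + offset)
so tests can invert it back to the raw model scale; note the
difference-equation weights are not invariant under this map, so recovery
tests must track on the inverted (raw) series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .discrete_robustness import DEFAULT_SAMPLING_PERIOD_HR, DiscreteParams, char_poles
from .nlms_estimation import TimeSeries

__all__ = [
    "GeneratorSpec",
    "DEFAULT_WEIGHTS",
    "generate_timeseries",
    "generate_step_disturbance_series",
    "invert_scaling",
]

#: Default generating weights: an underdamped regime with poles close to the
#: unit circle (|p| ~ 0.995, period ~ 21 frames ~ 2.3 hr) so the channels
#: ring visibly across the full 285-frame window, as the single-cell movie
#: does during DNA damage.
DEFAULT_WEIGHTS = {
    "w_xy": 0.05,
    "w_zy": 0.296,
    "w_yz": 0.296,
    "w_y": 0.95,
    "w_z": 0.95,
}

#: Fluorescence-like output range (arbitrary units, positive background).
FLUOR_RANGE = (10.0, 1000.0)


@dataclass(frozen=True)
class GeneratorSpec:
    """What to generate: weight schedule, length, sampling, noise, seed.

    ``schedule`` maps each weight name to a scalar (constant in time) or an
    array of per-step values of length ``n_frames - 1``.  ``noise_sd`` is
    the measurement-noise SD relative to each channel's amplitude (its
    max - min after scaling).  The defaults mirror the study's data shape:
    285 frames at 0.11 hr.
    """

    schedule: dict = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    n_frames: int = 285
    T: float = DEFAULT_SAMPLING_PERIOD_HR
    noise_sd: float = 0.0
    seed: int | None = None
    initial: tuple[float, float, float] = (1.0, 0.5, 1.5)
    fluor_range: tuple[float, float] = FLUOR_RANGE

    def __post_init__(self) -> None:
        if self.n_frames < 3:
            raise ValueError("n_frames must be >= 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.T > 0:
            raise ValueError("sampling period must be positive")
        missing = set(DEFAULT_WEIGHTS) - set(self.schedule)
        if missing:
            raise ValueError(f"schedule is missing weights: {sorted(missing)}")

    def weight_at(self, name: str, step: int) -> float:
        value = self.schedule[name]
        if np.isscalar(value):
            return float(value)
        return float(np.asarray(value, dtype=float)[step])

    def schedule_arrays(self) -> dict:
        """The full per-step schedule as arrays of length n_frames - 1."""
        n = self.n_frames - 1
        out = {}
        for name, value in self.schedule.items():
            if np.isscalar(value):
                out[name] = np.full(n, float(value))
            else:
                arr = np.asarray(value, dtype=float)
                if arr.shape != (n,):
                    raise ValueError(
                        f"schedule for {name} must be scalar or length {n}, got {arr.shape}"
                    )
                out[name] = arr
        return out


def _affine_to_range(raw: np.ndarray, lo: float, hi: float) -> tuple[np.ndarray, float, float]:
    rmin, rmax = raw.min(), raw.max()
    if rmax == rmin:
        scale = 1.0
        offset = (lo + hi) / 2.0 - rmin
    else:
        scale = (hi - lo) / (rmax - rmin)
        offset = lo - rmin * scale
    return raw * scale + offset, scale, offset


def _iterate(spec: GeneratorSpec, disturbance: np.ndarray | None = None):
    n = spec.n_frames
    x = np.empty(n)
    y = np.empty(n)
    z = np.empty(n)
    x[0], y[0], z[0] = spec.initial
    unstable = False
    for i in range(1, n):
        k = i - 1
        w_zy, w_xy = spec.weight_at("w_zy", k), spec.weight_at("w_xy", k)
        w_yz = spec.weight_at("w_yz", k)
        w_y, w_z = spec.weight_at("w_y", k), spec.weight_at("w_z", k)
        x[i] = x[i - 1]
        y[i] = w_zy * z[i - 1] - w_xy * x[i - 1] + w_y * y[i - 1]
        z[i] = -w_yz * y[i - 1] + w_z * z[i - 1]
        if disturbance is not None:
            z[i] += disturbance[k]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # schedules may roam outside [0, 1)
            params = DiscreteParams(w_xy=w_xy, w_zy=w_zy, w_yz=w_yz, w_y=w_y, w_z=w_z, T=spec.T)
        if max(rec.magnitude for rec in char_poles(params)) > 1.05:
            unstable = True
    return x, y, z, unstable


def _package(
    spec: GeneratorSpec, x: np.ndarray, y: np.ndarray, z: np.ndarray, unstable: bool
) -> tuple[TimeSeries, dict]:
    lo, hi = spec.fluor_range
    rng = np.random.default_rng(spec.seed)
    p53_scaled, s_z, o_z = _affine_to_range(z, lo, hi)
    mdm2_scaled, s_y, o_y = _affine_to_range(y, lo, hi)
    if spec.noise_sd > 0:
        p53_scaled = p53_scaled + rng.normal(0.0, spec.noise_sd * (hi - lo), z.size)
        mdm2_scaled = mdm2_scaled + rng.normal(0.0, spec.noise_sd * (hi - lo), y.size)
    p53_scaled = np.clip(p53_scaled, 0.0, None)
    mdm2_scaled = np.clip(mdm2_scaled, 0.0, None)
    scaling = {"p53": (s_z, o_z), "mdm2": (s_y, o_y)}
    ts = TimeSeries(
        sampling_period=spec.T,
        p53=p53_scaled,
        mdm2=mdm2_scaled,
        atm=x.copy(),
        channel_scaling=scaling,
    )
    truth = {
        "schedule": spec.schedule_arrays(),
        "scaling": scaling,
        "seed": spec.seed,
        "unstable": unstable,
        "raw": {"x": x, "y": y, "z": z},
    }
    return ts, truth


def generate_timeseries(spec: GeneratorSpec) -> tuple[TimeSeries, dict]:
    """Generate a fluorescence-like series plus its exact generating truth.

    Returns (TimeSeries, truth) where truth holds the per-step weight
    schedule, the per-channel affine scaling, the raw model sequences, and
    an ``unstable`` flag set when the scheduled weights put a pole beyond
    magnitude 1.05 (the dynamics then diverge and the channels saturate the
    affine map — usable, but flagged).
    """
    x, y, z, unstable = _iterate(spec)
    return _package(spec, x, y, z, unstable)


def generate_step_disturbance_series(
    spec: GeneratorSpec, step_index: int, magnitude: float
) -> tuple[TimeSeries, dict]:
    """Series with a sustained additive disturbance on the p53 update.

    From ``step_index`` onward the p53 update gains ``+magnitude`` per
    step.  For stable weights the induced plateau offset in the raw error
    signal ``w_zy * z`` equals the discrete final-value-theorem error times
    the magnitude; the truth dict carries that prediction
    (``predicted_error_offset``) and the raw p53 offset
    (``predicted_z_offset``) for oracle checks.
    """
    n_steps = spec.n_frames - 1
    if not 0 <= step_index < n_steps:
        raise ValueError(f"step_index must lie in [0, {n_steps})")
    disturbance = np.zeros(n_steps)
    disturbance[step_index:] = magnitude
    x, y, z, unstable = _iterate(spec, disturbance=disturbance)
    ts, truth = _package(spec, x, y, z, unstable)
    sched = truth["schedule"]
    w_y, w_z = sched["w_y"][-1], sched["w_z"][-1]
    w_zy, w_yz = sched["w_zy"][-1], sched["w_yz"][-1]
    denom = (1.0 - w_y) * (1.0 - w_z) + w_yz * w_zy
    z_offset = magnitude * (1.0 - w_y) / denom if denom != 0 else np.inf
    truth["step_index"] = step_index
    truth["magnitude"] = magnitude
    truth["predicted_z_offset"] = z_offset
    truth["predicted_error_offset"] = w_zy * z_offset
    return ts, truth


def invert_scaling(ts: TimeSeries) -> TimeSeries:
    """Undo the recorded affine fluorescence mapping, returning raw-scale data.

    Only valid for generator output whose ``channel_scaling`` metadata is
    intact (noise, if any, is carried through the inverse map).
    """
    if not ts.channel_scaling:
        raise ValueError("time series carries no channel_scaling metadata")
    s_p, o_p = ts.channel_scaling["p53"]
    s_m, o_m = ts.channel_scaling["mdm2"]
    return TimeSeries(
        sampling_period=ts.sampling_period,
        p53=(ts.p53 - o_p) / s_p,
        mdm2=(ts.mdm2 - o_m) / s_m,
        atm=ts.atm,
        channel_scaling={},
    )
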