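"""NLMS tracking of the time-varying discrete-model weights from p53/Mdm2 series.

The discrete loop's two update equations are linear regressions in the
per-step weights, so a normalized least-mean-squares (NLMS) adaptive filter
can track those weights frame by frame from a two-channel fluorescence
time series:

* the Mdm2 filter predicts ``y(i)`` from the regressor
  ``[z(i-1), -x(i-1), y(i-1)]`` with weights ``[w_zy, w_xy, w_y]``;
* the p53 filter predicts ``z(i)`` from ``[-y(i-1), z(i-1)]`` with weights
  ``[w_yz, w_z]``.

The regressors carry the model's negative signs so the tracked weights come
out directly on the (positive) scale of the difference-equation parameters.
ATM is unmeasured and assumed constant; its channel defaults to 1, with
w_xy absorbing the scale.  Because fluorescence units are arbitrary, each
channel is min-max normalised to [0, 1] before filtering by default — this
changes the absolute weight scale, so recovery tests against a known
generator disable it and work on the raw model scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeries",
    "FilterConfig",
    "ParamTrack",
    "nlms_step",
    "track_parameters",
    "summarize_track",
    "read_timeseries_csv",
    "write_timeseries_csv",
]

MDM2_WEIGHT_NAMES = ("w_zy", "w_xy", "w_y")
P53_WEIGHT_NAMES = ("w_yz", "w_z")
WEIGHT_NAMES = MDM2_WEIGHT_NAMES + P53_WEIGHT_NAMES


@dataclass(frozen=True)
class TimeSeries:
    """Uniformly sampled two-channel (p53, Mdm2) trajectory.

    ``atm`` is optional; when absent a constant channel of 1 is assumed.
    ``channel_scaling`` records any affine map ``raw -> stored`` applied by a
    generator (per channel: (scale, offset)), so tests can invert it.
    """

    sampling_period: float  # hours
    p53: np.ndarray
    mdm2: np.ndarray
    atm: np.ndarray | None = None
    channel_scaling: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        p53 = np.asarray(self.p53, dtype=float)
        mdm2 = np.asarray(self.mdm2, dtype=float)
        if p53.ndim != 1 or mdm2.ndim != 1 or p53.size != mdm2.size:
            raise ValueError("p53 and mdm2 must be 1-D arrays of equal length")
        if p53.size < 3:
            raise ValueError("time series must contain at least 3 samples")
        if not self.sampling_period > 0:
            raise ValueError("sampling period must be positive")
        object.__setattr__(self, "p53", p53)
        object.__setattr__(self, "mdm2", mdm2)
        if self.atm is not None:
            atm = np.asarray(self.atm, dtype=float)
            if atm.shape != p53.shape:
                raise ValueError("atm channel must match p53/mdm2 length")
            object.__setattr__(self, "atm", atm)

    def __len__(self) -> int:
        return self.p53.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) * self.sampling_period


@dataclass(frozen=True)
class FilterConfig:
    """NLMS hyper-parameters.

    mu is the adaptation step size (stable for 0 < mu <= 2), eps regularises
    the energy normalisation, and burn_in steps are excluded from summaries
    (None means 10% of the series).  Initial weights default to zero.
    """

    mu: float = 0.5
    eps: float = 1e-6
    initial_weights: dict | None = None
    burn_in: int | None = None
    normalize: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.mu <= 2.0):
            raise ValueError(f"mu must lie in (0, 2], got {self.mu!r}")
        if not self.eps > 0:
            raise ValueError("eps must be positive")
        if self.burn_in is not None and self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")


@dataclass(frozen=True)
class ParamTrack:
    """Per-step NLMS weight estimates and their post-burn-in summaries."""

    tracks: dict  # weight name -> np.ndarray of per-step estimates
    errors_mdm2: np.ndarray
    errors_p53: np.ndarray
    burn_in: int
    summary: dict  # weight name -> (mean, sd)

    def __len__(self) -> int:
        return next(iter(self.tracks.values())).size


def nlms_step(
    weights: np.ndarray, regressor: np.ndarray, target: float, config: FilterConfig
) -> tuple[np.ndarray, float]:
    """One NLMS update: a-priori error then energy-normalised gradient step.

    ``e = d - w.u``; ``w <- w + mu * e * u / (eps + ||u||^2)``.  A zero
    regressor leaves the weights untouched (the error is then the raw
    target).  Returns the updated weights and the a-priori error.
    """
    w = np.asarray(weights, dtype=float)
    u = np.asarray(regressor, dtype=float)
    if w.shape != u.shape:
        raise ValueError(f"weights {w.shape} and regressor {u.shape} differ in shape")
    e = float(target - w @ u)
    w_new = w + config.mu * e * u / (config.eps + u @ u)
    return w_new, e


def _normalize(channel: np.ndarray) -> np.ndarray:
    lo, hi = channel.min(), channel.max()
    if hi == lo:
        return np.zeros_like(channel)
    return (channel - lo) / (hi - lo)


def track_parameters(ts: TimeSeries, config: FilterConfig | None = None) -> ParamTrack:
    """Run the two parallel NLMS filters over a series and summarise the weights.

    Track length is ``len(ts) - 1`` (one estimate per predicted frame);
    summaries are the arithmetic mean and sample SD of each weight over the
    post-burn-in estimates.
    """
    config = config or FilterConfig()
    n = len(ts)
    p53 = _normalize(ts.p53) if config.normalize else ts.p53.astype(float)
    mdm2 = _normalize(ts.mdm2) if config.normalize else ts.mdm2.astype(float)
    if ts.atm is None:
        atm = np.ones(n)
    else:
        atm = _normalize(ts.atm) if config.normalize else ts.atm.astype(float)

    init = config.initial_weights or {}
    w_m = np.array([init.get(k, 0.0) for k in MDM2_WEIGHT_NAMES])
    w_p = np.array([init.get(k, 0.0) for k in P53_WEIGHT_NAMES])

    n_track = n - 1
    tracks = {name: np.empty(n_track) for name in WEIGHT_NAMES}
    err_m = np.empty(n_track)
    err_p = np.empty(n_track)
    for i in range(1, n):
        u_m = np.array([p53[i - 1], -atm[i - 1], mdm2[i - 1]])
        w_m, err_m[i - 1] = nlms_step(w_m, u_m, mdm2[i], config)
        u_p = np.array([-mdm2[i - 1], p53[i - 1]])
        w_p, err_p[i - 1] = nlms_step(w_p, u_p, p53[i], config)
        for name, value in zip(MDM2_WEIGHT_NAMES, w_m):
            tracks[name][i - 1] = value
        for name, value in zip(P53_WEIGHT_NAMES, w_p):
            tracks[name][i - 1] = value

    burn_in = config.burn_in if config.burn_in is not None else n_track // 10
    track = ParamTrack(
        tracks=tracks, errors_mdm2=err_m, errors_p53=err_p, burn_in=burn_in, summary={}
    )
    object.__setattr__(track, "summary", summarize_track(track))
    return track


def summarize_track(track: ParamTrack, burn_in: int | None = None) -> dict:
    """Per-weight (mean, sample SD) over the post-burn-in estimates."""
    burn_in = track.burn_in if burn_in is None else burn_in
    n = len(track)
    if burn_in >= n:
        raise ValueError(f"burn_in {burn_in} consumes the whole track of length {n}")
    out = {}
    for name, values in track.tracks.items():
        tail = values[burn_in:]
        sd = float(np.std(tail, ddof=1)) if tail.size > 1 else 0.0
        out[name] = (float(np.mean(tail)), sd)
    return out


def read_timeseries_csv(path: str | Path, sampling_period: float | None = None) -> TimeSeries:
    """Read a `time_hr, p53, mdm2[, atm]` CSV into a TimeSeries.

    The sampling period is inferred from the time column unless given
    explicitly; the time grid must be uniform.
    """
    frame = pd.read_csv(path)
    required = {"time_hr", "p53", "mdm2"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"CSV is missing required columns: {sorted(missing)}")
    times = frame["time_hr"].to_numpy(dtype=float)
    steps = np.diff(times)
    if sampling_period is None:
        if steps.size == 0 or not np.allclose(steps, steps[0], rtol=1e-6):
            raise ValueError("time column is not uniformly sampled")
        sampling_period = float(steps[0])
    atm = frame["atm"].to_numpy(dtype=float) if "atm" in frame.columns else None
    return TimeSeries(
        sampling_period=sampling_period,
        p53=frame["p53"].to_numpy(dtype=float),
        mdm2=frame["mdm2"].to_numpy(dtype=float),
        atm=atm,
    )


def write_timeseries_csv(ts: TimeSeries, path: str | Path) -> None:
    """Write a TimeSeries as a `time_hr, p53, mdm2[, atm]` CSV."""
    data = {"time_hr": ts.times, "p53": ts.p53, "mdm2": ts.mdm2}
    if ts.atm is not None:
        data["atm"] = ts.atm
    pd.DataFrame(data).to_csv(path, index=False)
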