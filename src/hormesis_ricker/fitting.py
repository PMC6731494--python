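"""Least-squares estimation from field pest counts and dose-response data.

Field series (dated counts with spray flags) are modelled as one impulsive
Ricker generation per inter-observation interval: the per-generation growth
rate is ``r_i = rbar * shape(t_i + tau) * (t_{i+1} - t_i)`` where ``shape``
is a seasonal host-plant curve (here, cotton squares versus days into the
season), ``tau`` a phase shift between host and pest, and a spray flagged at
``t_i`` applies survival ``p`` at the start of that interval.  Unknowns
``(p, K, rbar, tau)`` are estimated by bounded least squares on the counts
with scrambled quasi-random multistarts (the SSE surface is multimodal,
especially in ``tau``).

Dose-response datasets (dose, response) are modelled through the exponential
survival law ``p = exp(-rho * dose)`` feeding the impulsive Ricker map from
``N = K``, with ``K`` pinned by the zero-dose datum; unknowns are
``(r, theta, rho)``.
"""

from __future__ import annotations

import datetime as _dt
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import least_squares
from scipy.stats import qmc

from .core import ModelParams, hrm_step, ricker_step

__all__ = [
    "ObservationSeries",
    "SeasonalGrowth",
    "DoseResponseParams",
    "FitResult",
    "default_squares_shape",
    "seasonal_rate",
    "simulate_field",
    "fit_field",
    "predict_dose_response",
    "fit_dose_response",
]


@dataclass
class ObservationSeries:
    """Dated pest counts with spray events for one field plot.

    A spray flag on a date means the pesticide acted at the start of the
    interval that begins at that date (applied right after the triggering
    observation).  Counts are per-100-plants rates and stay real-valued.
    """

    plot_id: str
    dates: list
    counts: np.ndarray
    sprayed: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.dates = list(self.dates)
        self.counts = np.asarray(self.counts, dtype=float)
        self.sprayed = np.asarray(self.sprayed, dtype=bool)
        if not (len(self.dates) == len(self.counts) == len(self.sprayed)):
            raise ValueError("dates, counts and sprayed must have equal length")
        if any(b <= a for a, b in zip(self.dates, self.dates[1:])):
            raise ValueError("observation dates must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        # field data can carry spray flags that precede any threshold
        # exceedance (operational decisions); warn rather than reject
        exceeded = False
        for c, s in zip(self.counts, self.sprayed):
            exceeded = exceeded or (c > self.threshold)
            if s and not exceeded:
                warnings.warn(
                    f"plot {self.plot_id!r}: spray flagged before any count "
                    f"exceeded the action threshold {self.threshold}",
                    stacklevel=2,
                )
                break

    def __len__(self) -> int:
        return len(self.dates)

    def days_from(self, origin) -> np.ndarray:
        return np.array([(d - origin).days for d in self.dates], dtype=float)

    def window(self, start_date) -> "ObservationSeries":
        """Sub-series from ``start_date`` onward."""
        i0 = next((i for i, d in enumerate(self.dates) if d >= start_date), None)
        if i0 is None:
            raise ValueError("start_date is after the last observation")
        return ObservationSeries(
            plot_id=self.plot_id,
            dates=self.dates[i0:],
            counts=self.counts[i0:],
            sprayed=self.sprayed[i0:],
            threshold=self.threshold,
        )


@dataclass
class SeasonalGrowth:
    """Time-varying growth rate ``r(t) = rbar * shape(t + tau)``.

    ``shape`` is a smooth non-negative seasonal curve (host-plant squares
    versus days into the season); ``tau`` (days) is the phase difference
    between the host curve and the pest, and ``rbar`` (per day per shape
    unit) sets the overall scale.
    """

    rbar: float
    tau: float
    shape: object  # callable day -> value

    def rate(self, t: float) -> float:
        return max(self.rbar * float(self.shape(t + self.tau)), 0.0)

    @classmethod
    def from_knots(cls, days, values, rbar: float, tau: float) -> "SeasonalGrowth":
        """Cubic-spline shape through (day, value) knots, clamped outside."""
        days = np.asarray(days, dtype=float)
        values = np.asarray(values, dtype=float)
        if np.any(values < 0):
            raise ValueError("shape knot values must be non-negative")
        cs = CubicSpline(days, values)
        lo, hi = days[0], days[-1]

        def shape(t):
            return max(float(cs(min(max(t, lo), hi))), 0.0)

        return cls(rbar=rbar, tau=tau, shape=shape)


def default_squares_shape():
    """Synthetic stand-in for the seasonal cotton-squares curve.

    A smooth unimodal bump (Gaussian in days since the season start, peak
    value 120 at day 40, width 25 days) standing in for a host-plant squares
    curve; real squares data supplied as (day, value) knots via
    :meth:`SeasonalGrowth.from_knots` replace it.
    """

    def shape(s: float) -> float:
        z = (s - 40.0) / 25.0
        return 120.0 * math.exp(-0.5 * z * z)

    return shape


@dataclass(frozen=True)
class DoseResponseParams:
    """Parameters of the dose-response fit: map (r, theta, K) plus the
    dose-mortality coefficient rho in ``p = exp(-rho * dose)``."""

    r: float
    theta: float
    rho: float
    K: float

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ValueError(f"rho must be >= 0, got {self.rho}")
        ModelParams(r=self.r, p=1.0, theta=self.theta, K=self.K)  # validate

    def survival(self, dose: float) -> float:
        return math.exp(-self.rho * float(dose))


@dataclass
class FitResult:
    """Outcome of a multistart bounded least-squares fit."""

    estimates: dict
    sse: float
    n_starts: int
    n_converged: int
    converged: bool
    start_sses: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "estimates": {k: float(v) for k, v in self.estimates.items()},
            "sse": float(self.sse),
            "n_starts": int(self.n_starts),
            "n_converged": int(self.n_converged),
            "converged": bool(self.converged),
        }


def seasonal_rate(t: float, growth: SeasonalGrowth) -> float:
    """Instantaneous growth rate ``rbar * shape(t + tau)`` (per day, >= 0)."""
    return growth.rate(t)


def simulate_field(
    series_template: ObservationSeries,
    p: float,
    K: float,
    growth: SeasonalGrowth,
    N0: float | None = None,
    start_date=None,
    spray_theta: float = 0.0,
) -> tuple[list, np.ndarray]:
    """Predicted counts at each observation date of a field template.

    One impulsive Ricker generation is run per inter-observation interval
    ``[t_i, t_{i+1}]`` with duration-scaled growth rate
    ``r_i = rate(t_i) * (t_{i+1} - t_i)``; a spray flagged at ``t_i``
    applies survival ``p`` at fraction ``spray_theta`` of that interval.
    Returns ``(dates, predicted)`` from ``start_date`` (default: the first
    observation) with ``N0`` defaulting to the observed count there.
    """
    obs = series_template if start_date is None else series_template.window(start_date)
    if len(obs) < 2:
        raise ValueError("need at least two observation dates to simulate")
    t = obs.days_from(obs.dates[0])
    if np.any(np.diff(t) <= 0):
        raise ValueError("zero-length observation interval")
    N = float(obs.counts[0] if N0 is None else N0)
    pred = np.empty(len(obs))
    pred[0] = N
    for i in range(len(obs) - 1):
        r_i = growth.rate(t[i]) * (t[i + 1] - t[i])
        if obs.sprayed[i]:
            N = hrm_step(N, ModelParams(r=r_i, p=p, theta=spray_theta, K=K))
        else:
            N = ricker_step(N, r_i, K)
        pred[i + 1] = N
    return obs.dates, pred


def _multistart_ls(residual_fn, bounds_lo, bounds_hi, starts, seed):
    """Bounded least squares from scrambled-Sobol starting points."""
    lo = np.asarray(bounds_lo, dtype=float)
    hi = np.asarray(bounds_hi, dtype=float)
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
        raise ValueError("bounds must be finite")
    sampler = qmc.Sobol(d=len(lo), scramble=True, seed=seed)
    x0s = qmc.scale(sampler.random(starts), lo, hi)
    best = None
    sses = np.full(starts, np.inf)
    n_conv = 0
    for i, x0 in enumerate(x0s):
        try:
            res = least_squares(residual_fn, x0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        sses[i] = float(np.sum(res.fun**2))
        if res.success:
            n_conv += 1
        if best is None or sses[i] < best[0]:
            best = (sses[i], res.x, res.success)
    if best is None:
        raise RuntimeError(
            f"all {starts} optimization starts failed; check bounds and data"
        )
    return best, sses, n_conv


def fit_field(
    obs: ObservationSeries,
    growth_shape,
    bounds: dict | None = None,
    starts: int = 32,
    seed: int = 0,
    start_date=None,
    spray_theta: float = 0.0,
) -> FitResult:
    """Estimate ``(p, K, rbar, tau)`` from a field series by least squares.

    ``growth_shape`` is the seasonal shape callable (day -> value).  SSE is
    computed on counts at the observation dates from ``start_date`` onward;
    the initial population is pinned to the observed count at the start.
    """
    work = obs if start_date is None else obs.window(start_date)
    if len(work) < 5:
        raise ValueError("need at least 5 observations to fit")
    cmax = float(max(work.counts.max(), 1.0))
    default_bounds = {
        "p": (1e-3, 1.0),
        "K": (0.5 * cmax, 10.0 * cmax),
        "rbar": (0.0, 0.05),
        "tau": (0.0, 60.0),
    }
    if bounds:
        default_bounds.update(bounds)
    names = ["p", "K", "rbar", "tau"]
    lo = [default_bounds[k][0] for k in names]
    hi = [default_bounds[k][1] for k in names]

    shape = growth_shape

    def residuals(x):
        p, K, rbar, tau = x
        growth = SeasonalGrowth(rbar=rbar, tau=tau, shape=shape)
        try:
            _, pred = simulate_field(work, p=p, K=K, growth=growth,
                                     spray_theta=spray_theta)
        except (OverflowError, ValueError):
            return np.full(len(work), 1e6)
        pred = np.where(np.isfinite(pred), pred, 1e9)
        return np.clip(pred, 0, 1e9) - work.counts

    (sse, x, ok), sses, n_conv = _multistart_ls(residuals, lo, hi, starts, seed)
    return FitResult(
        estimates=dict(zip(names, x)),
        sse=sse,
        n_starts=starts,
        n_converged=n_conv,
        converged=bool(n_conv > 0),
        start_sses=sses,
    )


def predict_dose_response(
    doses,
    params: DoseResponseParams,
    horizon: int = 1,
) -> np.ndarray:
    """Model response at each dose: ``horizon`` impulsive generations from K.

    Each generation applies the pulse with survival ``exp(-rho * dose)`` at
    timing ``theta``.  At dose 0 the response is exactly K for any horizon.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1 generation")
    out = np.empty(len(doses))
    for i, d in enumerate(doses):
        p = min(params.survival(d), 1.0)
        mp = ModelParams(r=params.r, p=max(p, 1e-300), theta=params.theta,
                         K=params.K)
        N = params.K
        for _ in range(horizon):
            N = hrm_step(N, mp)
        out[i] = N
    return out


def fit_dose_response(
    doses,
    responses,
    bounds: dict | None = None,
    starts: int = 32,
    seed: int = 0,
    horizon: int = 1,
) -> FitResult:
    """Estimate ``(r, theta, rho)`` from a dose-response dataset.

    The carrying capacity K is pinned by the zero-dose datum (mean of the
    zero-dose responses), which must be present.  Note the identifiability
    caveat: a single-generation design started at K constrains only ``rho``
    and the product ``r * (1 - theta)``; separating ``r`` from ``theta``
    needs ``horizon >= 2`` (or an independently known theta).
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if len(doses) != len(responses):
        raise ValueError("doses and responses must have equal length")
    if len(np.unique(doses)) < 4:
        raise ValueError("need at least 4 distinct dose levels")
    zero = doses == 0.0
    if not zero.any():
        raise ValueError("a zero-dose datum is required to pin K")
    K = float(responses[zero].mean())
    if K <= 0:
        raise ValueError("zero-dose response must be positive")

    dmax = float(doses.max())
    default_bounds = {
        "r": (1e-3, 8.0),
        "theta": (0.0, 1.0),
        "rho": (1e-6, 20.0 / dmax),
    }
    if bounds:
        default_bounds.update(bounds)
    names = ["r", "theta", "rho"]
    lo = [default_bounds[k][0] for k in names]
    hi = [default_bounds[k][1] for k in names]

    def residuals(x):
        r, theta, rho = x
        try:
            pred = predict_dose_response(
                doses, DoseResponseParams(r=r, theta=theta, rho=rho, K=K),
                horizon=horizon)
        except (OverflowError, ValueError):
            return np.full(len(doses), 1e6)
        pred = np.where(np.isfinite(pred), pred, 1e9)
        return pred - responses

    (sse, x, ok), sses, n_conv = _multistart_ls(residuals, lo, hi, starts, seed)
    est = dict(zip(names, x))
    est["K"] = K
    return FitResult(
        estimates=est,
        sse=sse,
        n_starts=starts,
        n_converged=n_conv,
        converged=bool(n_conv > 0),
        start_sses=sses,
    )
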