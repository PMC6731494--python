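"""Dose and dose-timing response curves and hormesis classification.

A hormetic (biphasic) dose response is low-dose stimulation followed by
high-dose inhibition: the long-run population level first rises above the
unperturbed baseline as the kill fraction q grows, then falls below it.
Curves here follow the map's attractor across a parameter grid either by
continuation (warm-starting each point from the previous attractor, which is
faithful to hysteresis in bistable windows) or from a cold start at K.
Non-equilibrium attractors (periodic/chaotic) are summarized by their time
average over the recorded post-transient orbit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ModelParams, PulseSchedule
from .equilibria import GenerationMap

__all__ = [
    "ResponseCurve",
    "BiphasicSummary",
    "attractor_level",
    "dose_response_curve",
    "timing_response_curve",
    "characterize_biphasic",
    "cumulative_effect_comparison",
]

#: divergence guard, in units of K
DIVERGENCE_FACTOR = 50.0
#: relative tolerance deciding hormetic stimulation/inhibition vs baseline
HORMESIS_TOL = 1e-3


@dataclass
class ResponseCurve:
    """Attractor level versus a swept control parameter (q or theta)."""

    control: str
    grid: np.ndarray
    levels: np.ndarray
    baseline: float
    invalid: np.ndarray       # divergence flags
    jumps: np.ndarray         # catastrophic-shift markers
    family: str = "hrm"
    meta: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "control_value": self.grid,
            "level": self.levels,
            "jump_flag": self.jumps.astype(int),
            "invalid_flag": self.invalid.astype(int),
        })


@dataclass(frozen=True)
class BiphasicSummary:
    """Verdict and geometry of a (possibly) hormetic response curve."""

    is_hormetic: bool
    baseline: float
    hormetic_zone: tuple | None = None
    q_max: float | None = None
    max_response: float | None = None
    inhibition_threshold: float | None = None
    indeterminate: bool = False

    def to_dict(self) -> dict:
        return {
            "is_hormetic": self.is_hormetic,
            "baseline": self.baseline,
            "hormetic_zone": self.hormetic_zone,
            "q_max": self.q_max,
            "max_response": self.max_response,
            "inhibition_threshold": self.inhibition_threshold,
            "indeterminate": self.indeterminate,
        }


def attractor_level(
    gm: GenerationMap,
    N0: float,
    transient: int = 500,
    record: int = 200,
) -> tuple[float, float, bool]:
    """Time-averaged attractor level reached from ``N0``.

    Returns ``(level, final_state, diverged)``.  The level is the mean over
    ``record`` post-transient iterates; an orbit exceeding 50 K is flagged
    as diverged.
    """
    cap = DIVERGENCE_FACTOR * gm.K
    N = float(N0)
    for _ in range(transient):
        N = gm(N)
        if not math.isfinite(N) or N > cap:
            return math.nan, N, True
    s = 0.0
    for _ in range(record):
        N = gm(N)
        if not math.isfinite(N) or N > cap:
            return math.nan, N, True
        s += N
    return s / record, N, False


def _mark_jumps(levels: np.ndarray) -> np.ndarray:
    """Flag grid steps where the level change dwarfs the local trend (5x)."""
    jumps = np.zeros(len(levels), dtype=bool)
    d = np.abs(np.diff(levels))
    if len(d) < 3:
        return jumps
    for i in range(len(d)):
        neigh = np.concatenate([d[max(0, i - 3):i], d[i + 1:i + 4]])
        neigh = neigh[np.isfinite(neigh)]
        if not len(neigh):
            continue
        trend = max(np.median(neigh), 1e-12)
        if np.isfinite(d[i]) and d[i] > 5.0 * trend:
            jumps[i + 1] = True
    return jumps


def _map_for(base, r, K, family, control, value):
    """Build the generation map at one grid value of the swept control."""
    if isinstance(base, PulseSchedule):
        if control == "q":
            sched = base.with_survival(1.0 - value)
        else:
            raise ValueError("theta sweeps need a ModelParams base")
        return GenerationMap.schedule(r, K, sched)
    d = base.to_dict()
    if control == "q":
        d["p"] = 1.0 - value
    else:
        d["theta"] = value
    params = ModelParams(**d)
    if family == "hrm":
        return GenerationMap.hrm(params)
    if family == "ebhm":
        return GenerationMap.ebhm(params)
    raise ValueError(f"unknown map family {family!r}")


def _sweep_curve(base, grid, control, mode, family, r, K,
                 transient, record) -> ResponseCurve:
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError(f"{control} grid must be strictly ascending")
    if control == "q" and (grid[0] < 0 or grid[-1] >= 1):
        raise ValueError("q grid must lie in [0, 1)")
    if control == "theta" and (grid[0] < 0 or grid[-1] > 1):
        raise ValueError("theta grid must lie in [0, 1]")
    if mode not in ("continuation", "cold"):
        raise ValueError(f"mode must be 'continuation' or 'cold', got {mode!r}")

    if isinstance(base, ModelParams):
        r, K = base.r, base.K
    if r is None or K is None:
        raise ValueError("schedule sweeps need explicit r and K")

    levels = np.empty(len(grid))
    invalid = np.zeros(len(grid), dtype=bool)
    state = K
    for i, v in enumerate(grid):
        gm = _map_for(base, r, K, family, control, v)
        N0 = state if mode == "continuation" else K
        level, final, diverged = attractor_level(gm, N0, transient, record)
        levels[i] = level
        invalid[i] = diverged
        if not diverged:
            state = final

    # baseline: zero dose, same timing/schedule shape
    if control == "q" and grid[0] == 0.0 and not invalid[0]:
        baseline = levels[0]
    else:
        gm0 = _map_for(base, r, K, family, "q", 0.0) \
            if control == "q" or isinstance(base, PulseSchedule) \
            else _map_for(ModelParams(r=r, p=1.0, theta=base.theta, K=K),
                          r, K, family, "theta", base.theta)
        baseline, _, _ = attractor_level(gm0, K, transient, record)

    return ResponseCurve(
        control=control, grid=grid, levels=levels, baseline=baseline,
        invalid=invalid, jumps=_mark_jumps(levels), family=family,
        meta={"mode": mode, "r": r, "K": K,
              "transient": transient, "record": record},
    )


def dose_response_curve(
    base,
    q_grid,
    mode: str = "continuation",
    family: str = "hrm",
    r: float | None = None,
    K: float | None = None,
    transient: int = 500,
    record: int = 200,
) -> ResponseCurve:
    """Attractor level versus kill fraction q.

    ``base`` is a :class:`ModelParams` (single pulse at its ``theta``) or a
    :class:`PulseSchedule` template (pass ``r`` and ``K`` explicitly; all
    pulse survivals are set to ``1 - q`` at each grid point).  In
    ``continuation`` mode each grid point starts from the previous point's
    final state; in ``cold`` mode every point starts from K.
    """
    return _sweep_curve(base, q_grid, "q", mode, family, r, K,
                        transient, record)


def timing_response_curve(
    base: ModelParams,
    theta_grid,
    mode: str = "continuation",
    family: str = "hrm",
    transient: int = 500,
    record: int = 200,
) -> ResponseCurve:
    """Attractor level versus pulse timing theta at fixed dose q."""
    return _sweep_curve(base, theta_grid, "theta", mode, family,
                        None, None, transient, record)


def _interp_crossing(x0, y0, x1, y1, target):
    if y1 == y0:
        return x1
    return x0 + (target - y0) * (x1 - x0) / (y1 - y0)


def characterize_biphasic(curve: ResponseCurve,
                          tol: float = HORMESIS_TOL) -> BiphasicSummary:
    """Classify a response curve as hormetic (biphasic) or not.

    Hormetic means the level exceeds baseline*(1+tol) somewhere and falls
    below baseline*(1-tol) at a larger control value.  Zone endpoints and
    the inhibition threshold are linearly interpolated between grid points.
    Invalid (diverged) cells inside the candidate zone give an
    indeterminate verdict.
    """
    if len(curve.grid) < 20:
        raise ValueError("biphasic classification needs >= 20 grid points")
    if curve.control == "q" and curve.grid[0] != 0.0:
        raise ValueError("q curve must include q = 0")

    b = curve.baseline
    g, lv = curve.grid, curve.levels
    above = lv > b * (1.0 + tol)
    if not above.any():
        return BiphasicSummary(is_hormetic=False, baseline=b)
    i_first = int(np.argmax(above))
    later_below = (lv < b * (1.0 - tol)) & (np.arange(len(g)) > i_first)
    if not later_below.any():
        return BiphasicSummary(is_hormetic=False, baseline=b)

    # candidate zone: contiguous run of above-baseline points from i_first
    i_end = i_first
    while i_end + 1 < len(g) and lv[i_end + 1] > b:
        i_end += 1
    if curve.invalid[i_first:i_end + 1].any():
        return BiphasicSummary(is_hormetic=False, baseline=b,
                               indeterminate=True)

    zone_lo = g[i_first] if i_first == 0 else _interp_crossing(
        g[i_first - 1], lv[i_first - 1], g[i_first], lv[i_first], b)
    zone_hi = g[i_end] if i_end + 1 == len(g) else _interp_crossing(
        g[i_end], lv[i_end], g[i_end + 1], lv[i_end + 1], b)

    seg = slice(i_first, i_end + 1)
    i_peak = i_first + int(np.argmax(lv[seg]))

    thresh = None
    for j in range(i_end + 1, len(g)):
        if lv[j] < b * (1.0 - tol):
            thresh = _interp_crossing(g[j - 1], lv[j - 1], g[j], lv[j], b)
            break

    return BiphasicSummary(
        is_hormetic=True,
        baseline=b,
        hormetic_zone=(float(zone_lo), float(zone_hi)),
        q_max=float(g[i_peak]),
        max_response=float(lv[i_peak]),
        inhibition_threshold=None if thresh is None else float(thresh),
    )


def cumulative_effect_comparison(
    r: float,
    K: float,
    schedules,
    q_grid,
    mode: str = "continuation",
    transient: int = 500,
    record: int = 200,
) -> dict:
    """Compare dose-response curves across multi-pulse schedules.

    ``schedules`` is a list of :class:`PulseSchedule` templates (typically
    k = 1, 2, 3 pulses); at every q all survivals are set to ``1 - q``
    (same per-pulse dose).  Returns the per-schedule curves and summaries
    plus cross-k comparison metrics: initial slope of the rise, hormetic-zone
    width, maximum response and inhibition threshold.
    """
    results = []
    for sched in schedules:
        curve = dose_response_curve(sched, q_grid, mode=mode, r=r, K=K,
                                    transient=transient, record=record)
        summary = characterize_biphasic(curve)
        results.append((curve, summary))

    comparison = []
    for sched, (curve, summary) in zip(schedules, results):
        g, lv = curve.grid, curve.levels
        i1 = 1 if len(g) > 1 else 0
        slope = (lv[i1] - lv[0]) / (g[i1] - g[0]) if i1 else math.nan
        zone = summary.hormetic_zone
        comparison.append({
            "k": sched.k,
            "initial_slope": float(slope),
            "zone_width": None if zone is None else zone[1] - zone[0],
            "max_response": summary.max_response,
            "inhibition_threshold": summary.inhibition_threshold,
        })
    return {"results": results, "comparison": comparison}
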