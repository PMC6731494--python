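"""One-generation maps: the impulsive (hormesis) Ricker map and relatives.

The model describes a discrete-generation population whose within-generation
growth follows Ricker-style density regulation, interrupted by an impulsive
kill event (pesticide pulse) at a fraction ``theta`` of the generation.  A
fraction ``p`` of the population survives the pulse; the kill fraction
``q = 1 - p`` plays the role of the dose.  The per-capita growth rate within
each segment is held at ``r * (1 - M/K)`` where ``M`` is the population just
after the most recent pulse (or the generation start), so a pulse *refreshes*
density regulation — the mechanism behind hormetic (paradoxical) effects.

The closed-form one-pulse map is

    f(N) = p N exp[ r (1 - (N/K) (theta + (1-theta) p e^{r theta (1-N/K)})) ]

which reduces to ``p N e^{r(1 - pN/K)}`` at ``theta = 0`` (kill before any
growth) and ``p N e^{r(1 - N/K)}`` at ``theta = 1`` (kill after full growth).
A Beverton–Holt analogue built on exact logistic growth between pulses is
provided as a no-hormesis control model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelParams",
    "PulseSchedule",
    "TrajectoryState",
    "hrm_step",
    "special_case_step",
    "multi_pulse_step",
    "within_generation_trajectory",
    "ebhm_step",
    "ricker_step",
]


@dataclass(frozen=True)
class ModelParams:
    """Parameters of one generation with a single kill pulse.

    Parameters
    ----------
    r : float
        Intrinsic per-generation growth rate, >= 0.
    p : float
        Survival fraction of the pulse, in (0, 1].  The dose is ``q = 1 - p``.
    theta : float
        Pulse timing as a fraction of the generation, in [0, 1].
    K : float
        Carrying capacity (population units), > 0.
    """

    r: float
    p: float
    theta: float
    K: float = 1.0

    def __post_init__(self) -> None:
        if not (self.r >= 0):
            raise ValueError(f"growth rate r must be >= 0, got {self.r}")
        if not (0 < self.p <= 1):
            raise ValueError(f"survival p must be in (0, 1], got {self.p}")
        if not (0 <= self.theta <= 1):
            raise ValueError(f"pulse timing theta must be in [0, 1], got {self.theta}")
        if not (self.K > 0):
            raise ValueError(f"carrying capacity K must be > 0, got {self.K}")

    @property
    def q(self) -> float:
        """Kill fraction (dose) of the pulse, ``1 - p``."""
        return 1.0 - self.p

    @classmethod
    def from_dose(cls, r: float, q: float, theta: float, K: float = 1.0) -> "ModelParams":
        """Construct from the dose ``q`` instead of the survival ``p``."""
        return cls(r=r, p=1.0 - q, theta=theta, K=K)

    def to_dict(self) -> dict:
        return {"r": self.r, "p": self.p, "theta": self.theta, "K": self.K}


@dataclass(frozen=True)
class PulseSchedule:
    """Ordered within-generation kill events ``(theta_i, p_i)``.

    ``events`` must have strictly increasing timings in (0, 1].  An empty
    schedule is an unperturbed Ricker generation.  A one-event schedule is
    equivalent to :class:`ModelParams` with the same ``(theta, p)``.
    """

    events: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ev = tuple((float(t), float(p)) for t, p in self.events)
        object.__setattr__(self, "events", ev)
        last = 0.0
        for i, (t, p) in enumerate(ev):
            if not (0 <= t <= 1):
                raise ValueError(f"pulse timing theta_{i+1}={t} outside [0, 1]")
            if i > 0 and t <= last:
                raise ValueError("pulse timings must be strictly increasing")
            if not (0 < p <= 1):
                raise ValueError(f"pulse survival p_{i+1}={p} outside (0, 1]")
            last = t

    @property
    def k(self) -> int:
        return len(self.events)

    @classmethod
    def single(cls, theta: float, p: float) -> "PulseSchedule":
        return cls(events=((theta, p),))

    @classmethod
    def equal_doses(cls, timings, p: float) -> "PulseSchedule":
        """Equal per-pulse survival ``p`` applied at each timing."""
        return cls(events=tuple((t, p) for t in timings))

    def with_survival(self, p: float) -> "PulseSchedule":
        """Same timings, all survivals replaced by ``p``."""
        return PulseSchedule.equal_doses([t for t, _ in self.events], p)


@dataclass(frozen=True)
class TrajectoryState:
    """Population at a point within a generation."""

    generation: int
    t: float
    N: float


def _check_population(N: float) -> float:
    N = float(N)
    if not (N >= 0):
        raise ValueError(f"population must be >= 0, got {N}")
    return N


def ricker_step(N: float, r: float, K: float = 1.0) -> float:
    """Classic Ricker map ``N e^{r(1 - N/K)}``."""
    N = _check_population(N)
    return N * math.exp(r * (1.0 - N / K))


def hrm_step(N: float, params: ModelParams) -> float:
    """One generation of the impulsive Ricker map (closed form).

    Evaluates ``p N exp[r(1 - (N/K)(theta + (1-theta) p e^{r theta (1-N/K)}))]``.
    Returns 0 iff ``N == 0``.

    A pulse with survival exactly 1 is no event: the within-generation
    density-regulation refresh at ``theta`` accompanies an actual kill, so
    ``p = 1`` yields the classic Ricker step for any ``theta``.
    """
    N = _check_population(N)
    r, p, th, K = params.r, params.p, params.theta, params.K
    if p == 1.0:
        return N * math.exp(r * (1.0 - N / K))
    if th == 0.0:  # kill before any growth (printed boundary form)
        return p * N * math.exp(r * (1.0 - p * N / K))
    if th == 1.0:  # kill after full growth
        return p * N * math.exp(r * (1.0 - N / K))
    u = N / K
    inner = th + (1.0 - th) * p * math.exp(r * th * (1.0 - u))
    return p * N * math.exp(r * (1.0 - u * inner))


def special_case_step(N: float, params: ModelParams, which: str) -> float:
    """The two boundary-timing maps, evaluated directly.

    ``which='start'``: kill at the beginning of the generation,
    ``p N e^{r(1 - pN/K)}``.  ``which='end'``: kill at the end,
    ``p N e^{r(1 - N/K)}``.  Kept on an independent code path from
    :func:`hrm_step` so the two can be cross-checked.
    """
    N = _check_population(N)
    r, p, K = params.r, params.p, params.K
    if which == "start":
        return p * N * math.exp(r * (1.0 - p * N / K))
    if which == "end":
        return p * N * math.exp(r * (1.0 - N / K))
    raise ValueError(f"which must be 'start' or 'end', got {which!r}")


def multi_pulse_step(N: float, r: float, K: float, schedule: PulseSchedule) -> float:
    """One generation with ``k`` ordered kill pulses.

    Between pulses the per-capita rate is held at ``r (1 - M_i/K)`` where
    ``M_i`` is the level just after pulse ``i``:

        M_0 = N;  M_i = p_i M_{i-1} exp[r (1 - M_{i-1}/K) (theta_i - theta_{i-1})]

    and the return value is ``M_k exp[r (1 - M_k/K) (1 - theta_k)]``.
    For ``k = 1`` this is algebraically identical to :func:`hrm_step`.
    Pulses with survival exactly 1 are no events (no kill, no refresh), so
    an all-``p_i = 1`` schedule is a plain Ricker generation.
    """
    N = _check_population(N)
    M = N
    t_prev = 0.0
    for theta_i, p_i in schedule.events:
        if p_i == 1.0:
            continue
        M = p_i * M * math.exp(r * (1.0 - M / K) * (theta_i - t_prev))
        t_prev = theta_i
    return M * math.exp(r * (1.0 - M / K) * (1.0 - t_prev))


def within_generation_trajectory(
    N: float,
    r: float,
    K: float,
    schedule: PulseSchedule,
    t_grid,
    generation: int = 0,
) -> list[TrajectoryState]:
    """Population along a time grid inside one generation.

    Piecewise exponential segments ``N(t) = M_i e^{r(1 - M_i/K)(t - theta_i)}``
    between pulses, with multiplicative drops by ``p_i`` at each pulse time.
    At a grid point equal to a pulse time the *post*-pulse value is reported.
    The value at ``t = 1`` equals :func:`multi_pulse_step` exactly.
    """
    N = _check_population(N)
    t_grid = [float(t) for t in t_grid]
    if any(t2 < t1 for t1, t2 in zip(t_grid, t_grid[1:])):
        raise ValueError("t_grid must be sorted ascending")
    if t_grid and (t_grid[0] < 0 or t_grid[-1] > 1):
        raise ValueError("t_grid must lie within [0, 1]")

    out: list[TrajectoryState] = []
    M = N
    t_seg = 0.0  # start of current segment
    events = [(t, p) for t, p in schedule.events if p != 1.0]  # p=1: no event
    j = 0  # next pulse index
    for t in t_grid:
        # advance through any pulses at or before t
        while j < len(events) and events[j][0] <= t:
            theta_j, p_j = events[j]
            M = p_j * M * math.exp(r * (1.0 - M / K) * (theta_j - t_seg))
            t_seg = theta_j
            j += 1
        val = M * math.exp(r * (1.0 - M / K) * (t - t_seg))
        out.append(TrajectoryState(generation=generation, t=t, N=val))
    return out


def _logistic(N0: float, r: float, K: float, t: float) -> float:
    """Exact logistic solution at time t from N0."""
    if N0 == 0.0:
        return 0.0
    e = math.exp(r * t)
    return K * N0 * e / (K + N0 * (e - 1.0))


def ebhm_step(N: float, params: ModelParams) -> float:
    """Beverton–Holt analogue: exact logistic growth with one kill pulse.

    Logistic growth (compensatory, no overshoot) runs to ``t = theta``, the
    population is multiplied by ``p``, and growth resumes to ``t = 1``.
    Because logistic regulation is memoryless in density, this map cannot
    produce hormetic effects — it serves as the control model.
    """
    N = _check_population(N)
    r, p, th, K = params.r, params.p, params.theta, params.K
    M = _logistic(N, r, K, th)
    M *= p
    return _logistic(M, r, K, 1.0 - th)


def iterate_map(
    step,
    N0: float,
    n: int,
    transient: int = 0,
):
    """Iterate a one-argument map ``step(N) -> N'``; return the recorded orbit.

    Discards ``transient`` iterations, then records ``n`` values (the value
    *after* each recorded step).
    """
    N = float(N0)
    for _ in range(transient):
        N = step(N)
    out = np.empty(n)
    for i in range(n):
        N = step(N)
        out[i] = N
    return out
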