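"""Parameter sweeps: branch tracking, bifurcation events, region atlases.

One-dimensional sweeps follow equilibrium branches by nearest-neighbour
continuation, flagging saddle-node events where the branch count changes and
flip events where a multiplier crosses -1 (both refined by bisection in the
swept parameter).  Two-dimensional sweeps classify every cell of a parameter
plane by its equilibrium structure and by the signs of the equilibrium
sensitivities dN*/dq or dN*/dtheta, reproducing the colour-legend vocabulary
of hormetic/paradoxical-effect (HPE) atlases:

- ``green``   unique stable equilibrium with dN*/dc > 0
- ``magenta`` bistable, dN1*/dc > 0 and dN3*/dc > 0
- ``cyan``    bistable, dN1*/dc > 0 and dN3*/dc < 0
- ``red``     dN1*/dc > 0 with N3* unstable
- ``blue``    dN3*/dc > 0 with N1* unstable
- ``white`` / ``grey`` no positive equilibrium / unique unstable
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ModelParams
from .equilibria import EquilibriumSet, GenerationMap, find_equilibria

__all__ = [
    "BifurcationEvent",
    "BifurcationGrid",
    "sweep_1d",
    "sweep_2d",
    "equilibrium_sensitivity",
    "set_param",
]

#: nearest-neighbour continuation jump tolerance, in units of K
BRANCH_JUMP_TOL = 0.2

_PARAM_NAMES = ("r", "p", "q", "theta", "K")


def set_param(base: ModelParams, name: str, value: float) -> ModelParams:
    """Return a copy of ``base`` with one named parameter replaced.

    ``q`` is accepted as an alias for ``1 - p``.
    """
    if name not in _PARAM_NAMES:
        raise ValueError(f"unknown parameter {name!r}; expected one of {_PARAM_NAMES}")
    d = base.to_dict()
    if name == "q":
        d["p"] = 1.0 - value
    else:
        d[name] = value
    return ModelParams(**d)


@dataclass(frozen=True)
class BifurcationEvent:
    """A located bifurcation along a 1-D sweep."""

    kind: str          # "saddle-node" | "flip"
    param: str
    value: float
    branch: str | None = None


@dataclass
class BifurcationGrid:
    """Result of a 1-D or 2-D parameter sweep."""

    vary: tuple
    grids: tuple
    base: ModelParams
    equilibrium_sets: list = field(default_factory=list)   # 1-D: per grid point
    events: list = field(default_factory=list)             # 1-D only
    region_codes: np.ndarray | None = None                 # 2-D: (n, m) strings
    sensitivity_wrt: str | None = None

    @property
    def ndim(self) -> int:
        return len(self.vary)

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: one row per grid point per equilibrium branch."""
        rows = []
        if self.ndim == 1:
            name = self.vary[0]
            for v, eqs in zip(self.grids[0], self.equilibrium_sets):
                if len(eqs) == 0:
                    rows.append({name: v, "branch_label": None, "N_star": np.nan,
                                 "multiplier": np.nan, "stable": None})
                for e in eqs:
                    rows.append({name: v, **e.to_dict()})
        else:
            n1, n2 = self.vary
            g1, g2 = self.grids
            for i, v1 in enumerate(g1):
                for j, v2 in enumerate(g2):
                    rows.append({n1: v1, n2: v2,
                                 "region_code": self.region_codes[i, j]})
        return pd.DataFrame(rows)


def _match_branch(prev_levels, level, K):
    """Index of the previous-branch level nearest to ``level`` (or None)."""
    if not prev_levels:
        return None
    d = [abs(x - level) for x in prev_levels]
    i = int(np.argmin(d))
    return i if d[i] <= BRANCH_JUMP_TOL * K else None


def sweep_1d(
    base: ModelParams,
    vary: str,
    lo: float,
    hi: float,
    n: int = 201,
    search_max: float = 3.0,
    refine_tol: float = 1e-6,
) -> BifurcationGrid:
    """Sweep one parameter, tracking equilibria, stability and events.

    Saddle-node events are flagged (and bisected to ``refine_tol``) wherever
    the positive-equilibrium count changes between adjacent grid points;
    flip events wherever a continued branch's multiplier crosses -1.
    """
    if n < 10:
        raise ValueError("sweep needs at least 10 grid points")
    grid = np.linspace(lo, hi, n)

    def solve(v: float) -> EquilibriumSet:
        return find_equilibria(set_param(base, vary, v), search_max=search_max)

    sets = [solve(v) for v in grid]
    events: list[BifurcationEvent] = []
    K = base.K

    for i in range(n - 1):
        a, b = sets[i], sets[i + 1]
        if len(a) != len(b):
            v = _bisect_count_change(solve, grid[i], grid[i + 1], len(a), refine_tol)
            events.append(BifurcationEvent("saddle-node", vary, v))
        # flip: multiplier of a continued branch crosses -1
        prev_levels = a.levels
        for eq in b:
            j = _match_branch(prev_levels, eq.N_star, K)
            if j is None:
                continue
            m0, m1 = a[j].multiplier, eq.multiplier
            s0, s1 = np.sign(m0 + 1.0), np.sign(m1 + 1.0)
            if s0 * s1 < 0 or (s1 == 0 and s0 != 0):
                v = _bisect_flip(solve, grid[i], grid[i + 1], a[j].N_star,
                                 eq.N_star, K, refine_tol)
                events.append(
                    BifurcationEvent("flip", vary, v, branch=eq.branch_label)
                )
    return BifurcationGrid(vary=(vary,), grids=(grid,), base=base,
                           equilibrium_sets=sets, events=events)


def _bisect_count_change(solve, a, b, count_a, tol):
    while b - a > tol:
        m = 0.5 * (a + b)
        if len(solve(m)) == count_a:
            a = m
        else:
            b = m
    return 0.5 * (a + b)


def _bisect_flip(solve, a, b, level_a, level_b, K, tol):
    def mult_at(v, level_guess):
        eqs = solve(v)
        j = _match_branch(eqs.levels, level_guess, K)
        return None if j is None else eqs[j]

    while b - a > tol:
        m = 0.5 * (a + b)
        guess = 0.5 * (level_a + level_b)
        eq = mult_at(m, guess)
        if eq is None:
            break
        if eq.multiplier + 1.0 > 0:
            a, level_a = m, eq.N_star
        else:
            b, level_b = m, eq.N_star
    return 0.5 * (a + b)


def equilibrium_sensitivity(
    params: ModelParams,
    branch: str,
    wrt: str,
    h: float = 1e-6,
    search_max: float = 3.0,
) -> float:
    """dN*/dc for c in {q, theta} by implicit differentiation at a branch.

    Uses ``dN*/dc = -(df/dc) / (df/dN - 1)`` at the fixed point, with a
    central (boundary-aware one-sided) finite difference for df/dc and the
    analytic map derivative for df/dN.  Raises at a tangency (df/dN ~ 1),
    where the sensitivity is undefined.
    """
    if wrt not in ("q", "theta"):
        raise ValueError(f"wrt must be 'q' or 'theta', got {wrt!r}")
    eqs = find_equilibria(params, search_max=search_max)
    eq = eqs.by_label(branch)
    if eq is None:
        raise ValueError(f"branch {branch!r} does not exist at these parameters")
    N = eq.N_star
    gm = GenerationMap.hrm(params)
    fN = gm.derivative(N)
    if abs(fN - 1.0) < 1e-8:
        raise ArithmeticError(
            "equilibrium sensitivity undefined at a tangency (df/dN = 1)"
        )

    c0 = params.q if wrt == "q" else params.theta
    c_hi_lim = 1.0 - 1e-12 if wrt == "q" else 1.0
    lo_c = max(c0 - h, 0.0)
    hi_c = min(c0 + h, c_hi_lim)

    def f_at(c: float) -> float:
        return GenerationMap.hrm(set_param(params, wrt, c))(N)

    dfdc = (f_at(hi_c) - f_at(lo_c)) / (hi_c - lo_c)
    return -dfdc / (fN - 1.0)


def sensitivity_sign(value: float, zero_tol: float = 1e-9) -> str:
    if abs(value) < zero_tol:
        return "0"
    return "+" if value > 0 else "-"


def _cell_code(params: ModelParams, wrt: str, search_max: float) -> str:
    eqs = find_equilibria(params, search_max=search_max)
    n = len(eqs)
    if n == 0:
        return "white"

    def sens(label):
        try:
            return equilibrium_sensitivity(params, label, wrt,
                                           search_max=search_max)
        except (ArithmeticError, ValueError):
            return np.nan

    if n == 1:
        if not eqs[0].stable:
            return "grey"
        s = sens("N1")
        return "green" if np.isfinite(s) and s > 0 else "other"
    if n == 3:
        e1, e2, e3 = eqs[0], eqs[1], eqs[2]
        s1, s3 = sens("N1"), sens("N3")
        if e1.stable and e3.stable:
            if np.isfinite(s1) and s1 > 0:
                if np.isfinite(s3) and s3 > 0:
                    return "magenta"
                if np.isfinite(s3) and s3 < 0:
                    return "cyan"
        if e1.stable and not e3.stable and np.isfinite(s1) and s1 > 0:
            return "red"
        if e3.stable and not e1.stable and np.isfinite(s3) and s3 > 0:
            return "blue"
    return "other"


def sweep_2d(
    base: ModelParams,
    vary: tuple,
    ranges: tuple,
    shape: tuple = (201, 201),
    wrt: str = "q",
    search_max: float = 3.0,
) -> BifurcationGrid:
    """Classify a 2-D parameter plane into HPE region codes.

    ``vary`` names two distinct parameters, ``ranges`` their (lo, hi) pairs,
    ``shape`` the grid resolution, and ``wrt`` the control parameter whose
    equilibrium sensitivity signs enter the colour code.
    """
    name1, name2 = vary
    if name1 == name2:
        raise ValueError("the two swept parameters must be distinct")
    (lo1, hi1), (lo2, hi2) = ranges
    n, m = shape
    g1 = np.linspace(lo1, hi1, n)
    g2 = np.linspace(lo2, hi2, m)
    codes = np.empty((n, m), dtype=object)
    for i, v1 in enumerate(g1):
        p1 = set_param(base, name1, v1)
        for j, v2 in enumerate(g2):
            codes[i, j] = _cell_code(set_param(p1, name2, v2), wrt, search_max)
    return BifurcationGrid(vary=(name1, name2), grids=(g1, g2), base=base,
                           region_codes=codes, sensitivity_wrt=wrt)
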