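"""Synthetic data generators and the packaged field-count fixture.

Generators emulate the three data shapes the fitting machinery consumes:
noisy model trajectories, threshold-triggered field spray campaigns, and
model-generated dose-response datasets.  Observation noise is applied to
the recorded values only — the underlying dynamics stay deterministic — and
is multiplicative lognormal by default (counts are non-negative with
roughly constant coefficient of variation); an additive-Gaussian option
suits dose-response measurements.  All randomness flows through a seeded
``numpy.random.Generator`` (PCG64), so identical seeds reproduce identical
datasets bit for bit.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .core import ModelParams, PulseSchedule
from .equilibria import GenerationMap, as_map
from .fitting import (
    DoseResponseParams,
    ObservationSeries,
    SeasonalGrowth,
    predict_dose_response,
)

__all__ = [
    "NoiseSpec",
    "generate_trajectory",
    "generate_field_campaign",
    "generate_hormetic_dataset",
    "load_table1_fixture",
    "FIXTURE_THRESHOLDS",
]

#: action thresholds (infested heads / 100 plants) of fixture plots South 1-7
FIXTURE_THRESHOLDS = (1, 2, 5, 10, 20, 40, 60)

_FIXTURE_NAME = "mirid_field_counts_2012.csv"


@dataclass(frozen=True)
class NoiseSpec:
    """Observation-noise model: kind, coefficient of variation, seed."""

    kind: str = "multiplicative-lognormal"
    cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("multiplicative-lognormal", "additive-gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Noisy copies of ``values``, mean-unbiased; cv=0 returns them as-is."""
        values = np.asarray(values, dtype=float)
        if self.cv == 0.0:
            return values.copy()
        if self.kind == "multiplicative-lognormal":
            s2 = math.log1p(self.cv**2)
            factors = rng.lognormal(mean=-s2 / 2.0, sigma=math.sqrt(s2),
                                    size=values.shape)
            return values * factors
        noise = rng.normal(0.0, self.cv * np.abs(values), size=values.shape)
        return values + noise


def generate_trajectory(
    model,
    N0: float,
    n_generations: int,
    noise: NoiseSpec = NoiseSpec(),
) -> pd.DataFrame:
    """Iterate a generation map and attach observation noise.

    ``model`` is a :class:`ModelParams`, a :class:`GenerationMap`, or a
    ``(r, K, PulseSchedule)`` tuple.  Returns a frame with columns
    ``generation`` (0..n), ``true_N`` and ``observed_N``.
    """
    if n_generations < 1:
        raise ValueError("need at least one generation")
    if isinstance(model, tuple) and len(model) == 3 \
            and isinstance(model[2], PulseSchedule):
        gm = GenerationMap.schedule(*model)
    else:
        gm = as_map(model)
    true = np.empty(n_generations + 1)
    true[0] = float(N0)
    for i in range(n_generations):
        true[i + 1] = gm(true[i])
    observed = noise.apply(true, noise.rng())
    return pd.DataFrame({
        "generation": np.arange(n_generations + 1),
        "true_N": true,
        "observed_N": observed,
    })


def generate_field_campaign(
    dates,
    threshold: float,
    p: float,
    K: float,
    growth: SeasonalGrowth,
    N0: float,
    noise: NoiseSpec = NoiseSpec(),
    spray_theta: float = 0.0,
    plot_id: str = "synthetic",
) -> ObservationSeries:
    """Simulate a threshold-triggered spray campaign over a date template.

    The population advances one impulsive Ricker generation per interval
    (duration-scaled rate from ``growth``); whenever the *observed* (noisy)
    count at a date exceeds ``threshold`` a spray is flagged for that date,
    i.e. the kill acts at fraction ``spray_theta`` of the following
    interval — mirroring "spray right after the triggering observation".
    """
    from .core import hrm_step, ricker_step  # local to avoid cycle at import

    dates = list(dates)
    if any(b <= a for a, b in zip(dates, dates[1:])):
        raise ValueError("template dates must be strictly increasing")
    t = np.array([(d - dates[0]).days for d in dates], dtype=float)
    rng = noise.rng()

    n = len(dates)
    true = np.empty(n)
    observed = np.empty(n)
    sprayed = np.zeros(n, dtype=bool)
    N = float(N0)
    for i in range(n):
        true[i] = N
        observed[i] = float(noise.apply(np.array([N]), rng)[0])
        sprayed[i] = observed[i] > threshold
        if i + 1 < n:
            r_i = growth.rate(t[i]) * (t[i + 1] - t[i])
            if sprayed[i]:
                N = hrm_step(N, ModelParams(r=r_i, p=p, theta=spray_theta, K=K))
            else:
                N = ricker_step(N, r_i, K)
    return ObservationSeries(
        plot_id=plot_id,
        dates=dates,
        counts=observed,
        sprayed=sprayed,
        threshold=threshold,
    )


def generate_hormetic_dataset(
    r: float,
    theta: float,
    rho: float,
    K: float,
    dose_grid,
    noise: NoiseSpec = NoiseSpec(kind="additive-gaussian", cv=0.0),
    horizon: int = 1,
) -> pd.DataFrame:
    """Model-generated dose-response dataset (columns ``dose, response``).

    The dose grid must include 0 (the datum that pins K for refitting).
    """
    dose_grid = np.asarray(dose_grid, dtype=float)
    if not np.any(dose_grid == 0.0):
        raise ValueError("dose grid must include dose 0")
    params = DoseResponseParams(r=r, theta=theta, rho=rho, K=K)
    clean = predict_dose_response(dose_grid, params, horizon=horizon)
    responses = noise.apply(clean, noise.rng())
    return pd.DataFrame({"dose": dose_grid, "response": responses})


def load_table1_fixture() -> list:
    """The packaged 2012 cotton mirid field campaign (plots South 1-7).

    Seven series of 21 dated counts of infested cotton heads per 100
    plants (28 May - 5 Sep 2012), with spray-application flags and the
    plot action thresholds 1, 2, 5, 10, 20, 40, 60 heads/100 plants.
    """
    import warnings

    with resources.files("hormesis_ricker.data").joinpath(_FIXTURE_NAME).open() as f:
        df = pd.read_csv(f)
    out = []
    for i, pid in enumerate(sorted(df["plot_id"].unique())):
        sub = df[df["plot_id"] == pid].sort_values("date")
        dates = [_dt.date.fromisoformat(d) for d in sub["date"]]
        with warnings.catch_warnings():
            # printed spray flags do not all respect the nominal thresholds
            warnings.simplefilter("ignore")
            out.append(ObservationSeries(
                plot_id=pid,
                dates=dates,
                counts=sub["count"].to_numpy(dtype=float),
                sprayed=sub["sprayed"].to_numpy(dtype=bool),
                threshold=float(sub["threshold"].iloc[0]),
            ))
    return out


def fixture_bytes() -> bytes:
    """Raw bytes of the packaged fixture CSV (for checksum pinning)."""
    return resources.files("hormesis_ricker.data").joinpath(_FIXTURE_NAME).read_bytes()
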