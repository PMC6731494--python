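"""CSV/JSON input-output with provenance headers.

Observation CSVs are long format with columns ``plot_id, date, count,
sprayed, threshold`` (ISO 8601 dates, "." decimal, UTF-8, header row).
Dose-response CSVs have columns ``dose, response``.  Artifacts written by
the CLI carry a provenance header (comment lines) recording the package
version, the seed and a hash of the generating configuration, so every
artifact is regenerable from its own header.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json

import numpy as np
import pandas as pd

from .fitting import ObservationSeries

__all__ = [
    "read_observations",
    "write_observations",
    "read_dose_response",
    "write_dose_response",
    "write_table",
    "write_report",
    "config_hash",
]

_OBS_COLUMNS = ["plot_id", "date", "count", "sprayed", "threshold"]


class ParseError(ValueError):
    """Malformed input file; message names the offending line/column."""


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _provenance_lines(config: dict | None, seed=None) -> list:
    from . import __version__

    lines = [f"# hormesis-ricker v{__version__}"]
    if config is not None:
        lines.append(f"# config_hash: {config_hash(config)}")
        lines.append(f"# config: {json.dumps(config, sort_keys=True, default=str)}")
    if seed is not None:
        lines.append(f"# seed: {seed}")
    return lines


def read_observations(path) -> list:
    """Read one or more observation series from a long-format CSV."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _OBS_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    series = []
    for pid in df["plot_id"].unique():
        sub = df[df["plot_id"] == pid]
        dates = []
        for idx, d in zip(sub.index, sub["date"]):
            try:
                dates.append(_dt.date.fromisoformat(str(d)))
            except ValueError:
                raise ParseError(
                    f"{path}: line {idx + 2}: invalid ISO date {d!r}") from None
        counts = sub["count"].to_numpy(dtype=float)
        bad = np.flatnonzero(counts < 0)
        if len(bad):
            raise ParseError(
                f"{path}: line {sub.index[bad[0]] + 2}: negative count")
        order = np.argsort([d.toordinal() for d in dates])
        series.append(ObservationSeries(
            plot_id=str(pid),
            dates=[dates[i] for i in order],
            counts=counts[order],
            sprayed=sub["sprayed"].to_numpy(dtype=bool)[order],
            threshold=float(sub["threshold"].iloc[0]),
        ))
    return series


def write_observations(series_list, path, config: dict | None = None,
                       seed=None) -> None:
    """Write observation series in the canonical long CSV form."""
    rows = []
    for s in series_list:
        for d, c, sp in zip(s.dates, s.counts, s.sprayed):
            rows.append({"plot_id": s.plot_id, "date": d.isoformat(),
                         "count": c, "sprayed": int(sp),
                         "threshold": s.threshold})
    df = pd.DataFrame(rows, columns=_OBS_COLUMNS)
    with open(path, "w") as f:
        for line in _provenance_lines(config, seed):
            f.write(line + "\n")
        df.to_csv(f, index=False)


def read_dose_response(path):
    """Read a dose-response CSV; returns ``(doses, responses)`` arrays."""
    df = pd.read_csv(path, comment="#")
    for col in ("dose", "response"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    return df["dose"].to_numpy(dtype=float), df["response"].to_numpy(dtype=float)


def write_dose_response(doses, responses, path, config: dict | None = None,
                        seed=None) -> None:
    df = pd.DataFrame({"dose": doses, "response": responses})
    with open(path, "w") as f:
        for line in _provenance_lines(config, seed):
            f.write(line + "\n")
        df.to_csv(f, index=False)


def write_table(df: pd.DataFrame, path, config: dict | None = None,
                seed=None) -> None:
    """Write any tabular artifact (sweeps, curves) with a provenance header."""
    with open(path, "w") as f:
        for line in _provenance_lines(config, seed):
            f.write(line + "\n")
        df.to_csv(f, index=False)


def write_report(report: dict, path, config: dict | None = None,
                 seed=None) -> None:
    """Write a nested JSON report with embedded provenance."""
    from . import __version__

    payload = {"version": __version__}
    if config is not None:
        payload["config"] = config
        payload["config_hash"] = config_hash(config)
    if seed is not None:
        payload["seed"] = seed
    payload.update(report)

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (_dt.date, _dt.datetime)):
            return o.isoformat()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as f:
        json.dump(payload, f, indent=2, default=default, sort_keys=False)
        f.write("\n")
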