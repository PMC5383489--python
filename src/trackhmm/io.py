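"""CSV input/output and run-metadata sidecars.

Telemetry vendors ship CSV, so CSV is the sole track format: one row per
position with an animal id, a timestamp (ISO-8601 or epoch seconds), and
longitude/latitude in degrees.  All numeric output is written with 6
significant digits so written files are byte-stable across runs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import MovementHMMResults, StateSequence
from .preprocess import Track
from .transforms import PARAM_NAMES, natural_estimates

__all__ = ["TrackFormatError", "read_track_csv", "write_results", "write_track_csv", "fmt"]


class TrackFormatError(ValueError):
    """A track CSV violates the expected schema; names row/column."""


def fmt(x: float) -> str:
    """Stable 6-significant-digit formatting; empty string for NaN."""
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return ""
    return f"{x:.6g}"


def _parse_times(col: pd.Series, time_column: str) -> np.ndarray:
    """Timestamps as float seconds; accepts epoch numbers or ISO-8601."""
    numeric = pd.to_numeric(col, errors="coerce")
    if numeric.notna().all():
        return numeric.to_numpy(dtype=float)
    parsed = pd.to_datetime(col, errors="coerce", utc=True, format="ISO8601")
    bad = parsed.isna() & numeric.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise TrackFormatError(
            f"unparseable timestamp in column {time_column!r}, row {row}: "
            f"{col.iloc[row]!r}"
        )
    out = np.empty(len(col), dtype=float)
    ok_dt = parsed.notna().to_numpy()
    out[ok_dt] = parsed[ok_dt].astype("int64").to_numpy(dtype=float) / 1e9
    use_num = numeric.notna().to_numpy()
    out[use_num] = numeric.to_numpy(dtype=float)[use_num]
    return out


def read_track_csv(
    path,
    id_column: str = "id",
    time_column: str = "datetime",
    lon_column: str = "lon",
    lat_column: str = "lat",
) -> dict[str, pd.DataFrame]:
    """Read a track CSV into time-sorted per-animal records.

    Returns
    -------
    dict mapping animal id to a DataFrame with columns ``time`` (float
    seconds), ``lon`` and ``lat``, sorted by time.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in (id_column, time_column, lon_column, lat_column):
        if col not in df.columns:
            raise TrackFormatError(f"{path.name}: missing required column {col!r}")
    times = _parse_times(df[time_column], time_column)
    out: dict[str, pd.DataFrame] = {}
    for col in (lon_column, lat_column):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise TrackFormatError(
                f"non-numeric coordinate in column {col!r}, row {row}: "
                f"{df[col].iloc[row]!r}"
            )
    work = pd.DataFrame(
        {
            "animal": df[id_column].astype(str),
            "time": times,
            "lon": pd.to_numeric(df[lon_column]).to_numpy(dtype=float),
            "lat": pd.to_numeric(df[lat_column]).to_numpy(dtype=float),
        }
    )
    for animal, grp in work.groupby("animal", sort=True):
        g = grp.sort_values("time", kind="mergesort").reset_index(drop=True)
        out[animal] = g[["time", "lon", "lat"]]
    return out


def write_track_csv(track: Track, path, states: np.ndarray | None = None) -> None:
    """Write a track (optionally with per-position states) as CSV."""
    cols = {
        "id": [track.animal_id] * len(track),
        "datetime": [fmt(t) for t in track.times],
        "lon": [fmt(v) for v in track.lon],
        "lat": [fmt(v) for v in track.lat],
    }
    if states is not None:
        cols["state"] = list(np.asarray(states, dtype=int))
    pd.DataFrame(cols).to_csv(path, index=False)


def write_results(
    fit: MovementHMMResults,
    states: StateSequence,
    track: Track,
    out_prefix,
    seed: int | None = None,
    options: dict | None = None,
) -> dict[str, Path]:
    """Write fit results to ``<prefix>_params.csv``, ``<prefix>_states.csv``
    and a ``<prefix>_meta.yaml`` sidecar.

    The parameters CSV has one row per model parameter with estimate and
    95% interval endpoints; interval cells are left empty (not zero) when
    standard errors are unavailable.  The states CSV carries one row per
    track position with the state mapped per the displacement-to-position
    convention.
    """
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    est = natural_estimates(fit.params)
    ci = fit.conf_int()
    params_path = prefix.with_name(prefix.name + "_params.csv")
    pd.DataFrame(
        {
            "parameter": list(PARAM_NAMES),
            "estimate": [fmt(v) for v in est],
            "lower": [fmt(v) for v in ci["lower"]],
            "upper": [fmt(v) for v in ci["upper"]],
        }
    ).to_csv(params_path, index=False)

    pos_states = states.to_position_states(len(track))
    states_path = prefix.with_name(prefix.name + "_states.csv")
    pd.DataFrame(
        {
            "time": [fmt(t) for t in track.times],
            "lon": [fmt(v) for v in track.lon],
            "lat": [fmt(v) for v in track.lat],
            "state": pos_states,
        }
    ).to_csv(states_path, index=False)

    from . import __version__

    meta = {
        "version": __version__,
        "animal_id": track.animal_id,
        "n_positions": int(len(track)),
        "time_step_s": float(track.dt),
        "loglik": float(fit.llf),
        "converged": bool(fit.converged),
        "n_restarts_used": int(fit.n_restarts_used),
        "initial_distribution": fit.model.delta_mode,
        "seed": seed,
        "options": options or {},
    }
    meta_path = prefix.with_name(prefix.name + "_meta.yaml")
    with open(meta_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)

    return {"params": params_path, "states": states_path, "meta": meta_path}
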