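"""Track container, time-regularization, and first differences.

The model assumes positions on a regular time grid with negligible
measurement error.  Raw telemetry is rarely regular, so the standard
preprocessing step is linear interpolation of each coordinate axis onto a
fixed time step (e.g. 6 h for a seal GPS track, 15 min for an acoustic
fish track), after which the model operates on the first differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Track", "interpolate_track", "first_differences"]


@dataclass(frozen=True)
class Track:
    """A regular-time-step planar track for one animal.

    Parameters
    ----------
    animal_id : str
        Label for the animal/deployment.
    times : ndarray of float
        Timestamps in seconds (e.g. POSIX epoch), strictly increasing and
        equally spaced.
    lon, lat : ndarray of float
        Positions in degrees, one per timestamp.
    """

    animal_id: str
    times: np.ndarray
    lon: np.ndarray
    lat: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        lon = np.asarray(self.lon, dtype=float)
        lat = np.asarray(self.lat, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "lon", lon)
        object.__setattr__(self, "lat", lat)
        n = times.shape[0]
        if not (lon.shape == lat.shape == (n,)):
            raise ValueError("times, lon and lat must have equal length")
        if n < 4:
            raise ValueError("a track needs at least 4 positions")
        if not (np.all(np.isfinite(times)) and np.all(np.isfinite(lon)) and np.all(np.isfinite(lat))):
            raise ValueError("track fields must be finite")
        steps = np.diff(times)
        if np.any(steps <= 0):
            raise ValueError("times must be strictly increasing")
        dt = steps[0]
        if np.any(np.abs(steps - dt) > 1e-6 * max(dt, 1.0)):
            raise ValueError("times must be equally spaced")

    def __len__(self) -> int:
        return self.times.shape[0]

    @property
    def dt(self) -> float:
        """The (constant) time step in seconds."""
        return float(self.times[1] - self.times[0])


def interpolate_track(
    raw_times,
    raw_lon,
    raw_lat,
    step: float,
    start: float | None = None,
    animal_id: str = "track",
    gap_warn_factor: float = 10.0,
) -> Track:
    """Linearly interpolate an irregular track onto a regular time grid.

    Each axis is interpolated independently and piecewise-linearly in time.
    The grid runs from ``start`` (default: the first raw timestamp) in
    increments of ``step`` up to the last raw timestamp; no extrapolation
    is performed.

    Parameters
    ----------
    raw_times : array-like of float
        Observation times in seconds, strictly increasing.
    raw_lon, raw_lat : array-like of float
        Observed positions in degrees.
    step : float
        Grid spacing in seconds, > 0.
    start : float, optional
        Grid origin; must lie within the raw time range.
    animal_id : str
        Label carried onto the output track.
    gap_warn_factor : float
        Emit a warning when a raw-data gap exceeds this multiple of
        ``step`` (interpolation still proceeds through the gap).

    Returns
    -------
    Track
    """
    t = np.asarray(raw_times, dtype=float)
    x = np.asarray(raw_lon, dtype=float)
    y = np.asarray(raw_lat, dtype=float)
    if t.ndim != 1 or t.shape[0] < 2:
        raise ValueError("need at least 2 raw observations")
    if x.shape != t.shape or y.shape != t.shape:
        raise ValueError("raw_times, raw_lon and raw_lat must have equal length")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("raw inputs must be finite")
    if np.any(np.diff(t) <= 0):
        raise ValueError("raw_times must be strictly increasing without duplicates")
    if not step > 0:
        raise ValueError("step must be positive")
    if start is None:
        start = float(t[0])
    if start < t[0] or start > t[-1]:
        raise ValueError("start must lie within the raw time range")

    n_grid = int(np.floor((t[-1] - start) / step)) + 1
    if n_grid < 4:
        raise ValueError(
            f"grid of {n_grid} points is too short to model; use a smaller step"
        )
    grid = start + step * np.arange(n_grid)

    gaps = np.diff(t)
    if np.any(gaps > gap_warn_factor * step):
        worst = float(gaps.max())
        warnings.warn(
            f"track {animal_id!r}: raw data gap of {worst:.0f} s exceeds "
            f"{gap_warn_factor:g}x the {step:.0f} s step; interpolating through it",
            stacklevel=2,
        )

    lon = np.interp(grid, t, x)
    lat = np.interp(grid, t, y)
    return Track(animal_id=animal_id, times=grid, lon=lon, lat=lat)


def first_differences(track: Track) -> np.ndarray:
    """First differences of the track positions.

    Returns
    -------
    ndarray, shape (n - 1, 2)
        ``d[t] = (lon[t+1] - lon[t], lat[t+1] - lat[t])`` in degrees.
    """
    return np.column_stack((np.diff(track.lon), np.diff(track.lat)))
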