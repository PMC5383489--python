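"""State-conditional step density of the switching correlated random walk.

Each displacement is an attenuated, rotated copy of the previous
displacement plus independent Gaussian noise on the two axes:

    d_t | b  ~  N2( gamma_b * T(theta_b) * d_{t-1}, diag(sigma_lon^2, sigma_lat^2) )

These functions evaluate that density; the HMM machinery lives in
:mod:`trackhmm.model`.
"""

from __future__ import annotations

import math

import numpy as np

from .params import BehaviorState, MovementParams

__all__ = ["rotation_matrix", "step_log_density", "emission_log_probs", "LOG_FLOOR"]

#: emission log-densities below this are floored so a single outlying step
#: cannot drive the forward recursion to -inf (exp(-745) is the smallest
#: positive normal double).
LOG_FLOOR = -745.0

_LOG_2PI = math.log(2.0 * math.pi)


def rotation_matrix(theta: float) -> np.ndarray:
    """Planar rotation matrix T(theta) = [[cos, -sin], [sin, cos]].

    Parameters
    ----------
    theta : float
        Rotation angle in radians; must be finite.
    """
    if not math.isfinite(theta):
        raise ValueError(f"theta must be finite, got {theta!r}")
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s], [s, c]], dtype=float)


def step_log_density(
    d_t,
    d_prev,
    state: BehaviorState,
    sigma_lon: float,
    sigma_lat: float,
) -> float:
    """Log-density (nats) of one displacement given the previous one.

    Evaluates the bivariate normal with mean ``gamma * T(theta) * d_prev``
    and diagonal covariance ``diag(sigma_lon^2, sigma_lat^2)`` at ``d_t``.

    Parameters
    ----------
    d_t, d_prev : array-like, shape (2,)
        Current and previous displacement (delta-lon, delta-lat), degrees.
    state : BehaviorState
        The behavioral state governing the step.
    sigma_lon, sigma_lat : float
        Per-axis process noise standard deviations, degrees, > 0.
    """
    if not (sigma_lon > 0.0 and sigma_lat > 0.0):
        raise ValueError("sigma_lon and sigma_lat must be positive")
    d_t = np.asarray(d_t, dtype=float)
    d_prev = np.asarray(d_prev, dtype=float)
    if not (np.all(np.isfinite(d_t)) and np.all(np.isfinite(d_prev))):
        raise ValueError("displacement vectors must be finite")
    mean = state.gamma * (rotation_matrix(state.theta) @ d_prev)
    zx = (d_t[0] - mean[0]) / sigma_lon
    zy = (d_t[1] - mean[1]) / sigma_lat
    return (
        -_LOG_2PI
        - math.log(sigma_lon)
        - math.log(sigma_lat)
        - 0.5 * (zx * zx + zy * zy)
    )


def emission_log_probs(diffs: np.ndarray, params: MovementParams) -> np.ndarray:
    """Per-step, per-state emission log-densities for an HMM evaluation.

    With ``m`` displacements, each conditional factor needs the previous
    displacement, so factors exist for steps ``1 .. m-1`` (the first
    displacement is conditioned on as fixed data).

    Parameters
    ----------
    diffs : ndarray, shape (m, 2)
        First differences of the track positions.
    params : MovementParams

    Returns
    -------
    ndarray, shape (m - 1, 2)
        ``out[i, k]`` is the log-density of ``diffs[i + 1]`` given
        ``diffs[i]`` under state ``k + 1``, floored at :data:`LOG_FLOOR`.
    """
    diffs = np.asarray(diffs, dtype=float)
    if diffs.ndim != 2 or diffs.shape[1] != 2 or diffs.shape[0] < 2:
        raise ValueError("diffs must have shape (m, 2) with m >= 2")
    prev = diffs[:-1]
    cur = diffs[1:]
    const = -_LOG_2PI - math.log(params.sigma_lon) - math.log(params.sigma_lat)
    out = np.empty((diffs.shape[0] - 1, 2), dtype=float)
    for k, st in enumerate((params.state1, params.state2)):
        c, s = math.cos(st.theta), math.sin(st.theta)
        mx = st.gamma * (c * prev[:, 0] - s * prev[:, 1])
        my = st.gamma * (s * prev[:, 0] + c * prev[:, 1])
        zx = (cur[:, 0] - mx) / params.sigma_lon
        zy = (cur[:, 1] - my) / params.sigma_lat
        out[:, k] = const - 0.5 * (zx * zx + zy * zy)
    np.maximum(out, LOG_FLOOR, out=out)
    return out
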