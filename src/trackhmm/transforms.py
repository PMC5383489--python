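"""Bijective map between natural parameters and an unconstrained working scale.

Optimization runs on the working scale so every candidate point is a valid
parameter set: autocorrelations and switching probabilities go through a
logit, noise standard deviations through a log, turning angles are left
unconstrained.  Standard errors computed on the working scale are pushed
back through the map by the delta method.

Working vector layout (length 8, or 9 when the initial state distribution
is estimated):

    [theta1, theta2, logit(gamma1), logit(gamma2),
     log(sigma_lon), log(sigma_lat), logit(a11), logit(a21), (logit(delta1))]
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import expit, logit

from .params import MovementParams

__all__ = [
    "PARAM_NAMES",
    "to_working",
    "from_working",
    "natural_estimates",
    "delta_method_se",
    "working_ci_to_natural",
]

PARAM_NAMES = (
    "theta1",
    "theta2",
    "gamma1",
    "gamma2",
    "sigma_lon",
    "sigma_lat",
    "a11",
    "a21",
)


def to_working(params: MovementParams, estimate_delta: bool = False) -> np.ndarray:
    """Map a valid parameter set to the unconstrained working vector."""
    vals = (
        params.state1.gamma,
        params.state2.gamma,
        params.a11,
        params.a21,
    )
    if any(v <= 0.0 or v >= 1.0 for v in vals):
        raise ValueError("probabilities/autocorrelations on the boundary are not mappable")
    w = [
        params.state1.theta,
        params.state2.theta,
        logit(params.state1.gamma),
        logit(params.state2.gamma),
        math.log(params.sigma_lon),
        math.log(params.sigma_lat),
        logit(params.a11),
        logit(params.a21),
    ]
    if estimate_delta:
        d1 = params.initial_distribution()[0]
        if d1 <= 0.0 or d1 >= 1.0:
            raise ValueError("delta on the boundary is not mappable")
        w.append(logit(d1))
    w = np.asarray(w, dtype=float)
    if not np.all(np.isfinite(w)):
        raise ValueError("working parameters must be finite")
    return w


def from_working(w: np.ndarray, delta_mode: str = "stationary") -> MovementParams:
    """Inverse of :func:`to_working`.

    ``delta_mode`` is one of ``"stationary"`` (delta tied to the transition
    matrix; vector length 8), ``"uniform"`` (fixed (1/2, 1/2); length 8) or
    ``"estimate"`` (free; length 9).
    """
    w = np.asarray(w, dtype=float)
    expected = 9 if delta_mode == "estimate" else 8
    if w.shape != (expected,):
        raise ValueError(f"working vector must have shape ({expected},)")
    if delta_mode == "stationary":
        delta = None
    elif delta_mode == "uniform":
        delta = (0.5, 0.5)
    elif delta_mode == "estimate":
        d1 = float(expit(w[8]))
        delta = (d1, 1.0 - d1)
    else:
        raise ValueError(f"unknown delta_mode {delta_mode!r}")
    return MovementParams.from_arrays(
        theta=(float(w[0]), float(w[1])),
        gamma=(float(expit(w[2])), float(expit(w[3]))),
        sigma_lon=float(math.exp(w[4])),
        sigma_lat=float(math.exp(w[5])),
        a11=float(expit(w[6])),
        a21=float(expit(w[7])),
        delta=delta,
    )


def natural_estimates(params: MovementParams) -> np.ndarray:
    """The 8 reported parameters on the natural scale, in PARAM_NAMES order."""
    return np.array(
        [
            params.state1.theta,
            params.state2.theta,
            params.state1.gamma,
            params.state2.gamma,
            params.sigma_lon,
            params.sigma_lat,
            params.a11,
            params.a21,
        ],
        dtype=float,
    )


def _jacobian_diag(w: np.ndarray) -> np.ndarray:
    """d(natural)/d(working) for the first 8 coordinates (the map is
    coordinate-wise, so the Jacobian is diagonal)."""
    g1, g2 = expit(w[2]), expit(w[3])
    a11, a21 = expit(w[6]), expit(w[7])
    return np.array(
        [
            1.0,
            1.0,
            g1 * (1.0 - g1),
            g2 * (1.0 - g2),
            math.exp(w[4]),
            math.exp(w[5]),
            a11 * (1.0 - a11),
            a21 * (1.0 - a21),
        ],
        dtype=float,
    )


def delta_method_se(w: np.ndarray, se_working: np.ndarray) -> np.ndarray:
    """Natural-scale standard errors for the 8 reported parameters."""
    return _jacobian_diag(w) * np.asarray(se_working[:8], dtype=float)


def working_ci_to_natural(w: np.ndarray, se_working: np.ndarray, z: float) -> tuple[np.ndarray, np.ndarray]:
    """Wald intervals built on the working scale, mapped coordinate-wise.

    Because logit and log are monotone, the transformed endpoints bracket
    the natural estimate and respect the parameter domains ((0,1) for
    probabilities, (0, inf) for sigmas).  Turning-angle intervals are plain
    Wald intervals on the same (unwrapped) branch as the estimate.
    """
    w = np.asarray(w, dtype=float)[:8]
    se = np.asarray(se_working, dtype=float)[:8]
    lo_w, hi_w = w - z * se, w + z * se
    transforms = [
        lambda x: x,
        lambda x: x,
        expit,
        expit,
        np.exp,
        np.exp,
        expit,
        expit,
    ]
    lo = np.array([f(v) for f, v in zip(transforms, lo_w)], dtype=float)
    hi = np.array([f(v) for f, v in zip(transforms, hi_w)], dtype=float)
    return lo, hi
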