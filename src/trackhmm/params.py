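"""Parameter containers for the two-state switching correlated random walk.

The movement process operates on first differences of positions,
``d_t = x_t - x_{t-1}`` (degrees longitude/latitude).  Conditional on the
behavioral state *b* governing a step,

    d_t | b  ~  N2( gamma_b * T(theta_b) * d_{t-1},  Sigma ),

where ``T`` is a planar rotation, ``gamma_b`` in (0, 1) is the persistence
(autocorrelation) of speed and heading, and ``Sigma = diag(sigma_lon^2,
sigma_lat^2)`` — the cross-axis correlation is fixed at zero, so the
covariance is carried as two standard deviations and never materialised
as a matrix.

State switching follows a two-state Markov chain with row-stochastic
transition matrix ``A = [[a11, 1-a11], [a21, 1-a21]]``.  By convention
state 1 is the directed ("transiting") state and state 2 the tortuous
("foraging") state; after fitting, labels are anchored by requiring
``gamma1 > gamma2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = ["BehaviorState", "MovementParams", "wrap_angle"]


def wrap_angle(theta: float) -> float:
    """Wrap an angle in radians to the interval (-pi, pi]."""
    w = math.remainder(theta, 2.0 * math.pi)
    # math.remainder returns [-pi, pi]; move -pi to +pi for a half-open interval
    if w <= -math.pi:
        w = math.pi
    return w


@dataclass(frozen=True)
class BehaviorState:
    """Movement parameters of one behavioral state.

    Parameters
    ----------
    gamma : float
        Autocorrelation of the step process, in (0, 1).  High values mean
        persistent speed and heading (directed travel).
    theta : float
        Mean turning angle in radians (any real; reported wrapped to
        (-pi, pi] where a convention is needed).  Near 0 for directed
        travel, near pi for course reversals.
    """

    gamma: float
    theta: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.gamma) and 0.0 < self.gamma < 1.0):
            raise ValueError(f"gamma must lie in (0, 1), got {self.gamma!r}")
        if not math.isfinite(self.theta):
            raise ValueError(f"theta must be finite, got {self.theta!r}")


@dataclass(frozen=True)
class MovementParams:
    """Full parameter set of the two-state switching random walk.

    Parameters
    ----------
    state1, state2 : BehaviorState
        Per-state (gamma, theta).  The canonical labeling has
        ``state1.gamma > state2.gamma`` (state 1 = directed); construction
        does not enforce it — see :meth:`is_canonical` / :meth:`canonical`.
    sigma_lon, sigma_lat : float
        Process noise standard deviations per axis, degrees, > 0.
    a11 : float
        P(stay in state 1), in (0, 1).
    a21 : float
        P(switch state 2 -> state 1), in (0, 1).
    delta : tuple of float, optional
        Initial state distribution.  ``None`` (default) means the
        stationary distribution of the transition matrix.
    """

    state1: BehaviorState
    state2: BehaviorState
    sigma_lon: float
    sigma_lat: float
    a11: float
    a21: float
    delta: tuple[float, float] | None = None

    #: cross-axis correlation of the process noise; structurally zero.
    rho = 0.0

    def __post_init__(self) -> None:
        for name in ("sigma_lon", "sigma_lat"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0.0):
                raise ValueError(f"{name} must be positive and finite, got {v!r}")
        for name in ("a11", "a21"):
            v = getattr(self, name)
            if not (math.isfinite(v) and 0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v!r}")
        if self.delta is not None:
            d = np.asarray(self.delta, dtype=float)
            if d.shape != (2,) or np.any(d < 0) or abs(d.sum() - 1.0) > 1e-8:
                raise ValueError(
                    "delta must be a length-2 nonnegative vector summing to 1"
                )

    @classmethod
    def from_arrays(
        cls,
        theta: tuple[float, float],
        gamma: tuple[float, float],
        sigma_lon: float,
        sigma_lat: float,
        a11: float,
        a21: float,
        delta: tuple[float, float] | None = None,
    ) -> "MovementParams":
        return cls(
            state1=BehaviorState(gamma=gamma[0], theta=theta[0]),
            state2=BehaviorState(gamma=gamma[1], theta=theta[1]),
            sigma_lon=sigma_lon,
            sigma_lat=sigma_lat,
            a11=a11,
            a21=a21,
            delta=delta,
        )

    @property
    def transition_matrix(self) -> np.ndarray:
        """Row-stochastic 2x2 transition matrix A."""
        return np.array(
            [[self.a11, 1.0 - self.a11], [self.a21, 1.0 - self.a21]], dtype=float
        )

    @property
    def stationary_delta(self) -> np.ndarray:
        """Stationary distribution of A, solving delta' A = delta'."""
        p1 = self.a21 / (1.0 - self.a11 + self.a21)
        return np.array([p1, 1.0 - p1], dtype=float)

    def initial_distribution(self) -> np.ndarray:
        """The initial state distribution actually in force."""
        if self.delta is None:
            return self.stationary_delta
        return np.asarray(self.delta, dtype=float)

    @property
    def is_canonical(self) -> bool:
        """True when state 1 carries the larger autocorrelation."""
        return self.state1.gamma > self.state2.gamma

    def canonical(self) -> "MovementParams":
        """Return an equivalent parameter set with the labeling anchored.

        If ``state1.gamma <= state2.gamma`` the two states are swapped;
        the transition probabilities and initial distribution are permuted
        accordingly (``a11' = 1 - a21``, ``a21' = 1 - a11``), which leaves
        the law of the process unchanged.
        """
        if self.is_canonical:
            return self
        delta = None if self.delta is None else (self.delta[1], self.delta[0])
        return replace(
            self,
            state1=self.state2,
            state2=self.state1,
            a11=1.0 - self.a21,
            a21=1.0 - self.a11,
            delta=delta,
        )

    def swapped(self) -> "MovementParams":
        """Exchange the two state labels unconditionally."""
        delta = None if self.delta is None else (self.delta[1], self.delta[0])
        return replace(
            self,
            state1=self.state2,
            state2=self.state1,
            a11=1.0 - self.a21,
            a21=1.0 - self.a11,
            delta=delta,
        )
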