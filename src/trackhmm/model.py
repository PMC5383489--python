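"""Two-state hidden Markov movement model: likelihood, decoding, fitting.

The model (:class:`MovementHMM`) is built from the first differences of a
regular-time-step track.  Conditional on a latent two-state Markov chain,
each displacement is a rotated, attenuated copy of the previous one plus
Gaussian noise (see :mod:`trackhmm.core`).  The marginal likelihood

    delta' P(d_2) A P(d_3) A ... P(d_m) 1

is evaluated by a scaled forward recursion (``P`` is the diagonal matrix
of state-conditional step densities, ``A`` the transition matrix, ``delta``
the initial state distribution).  Because each conditional factor needs
the previous displacement, the first displacement is treated as fixed
data: with ``n`` positions there are ``n - 1`` displacements and ``n - 2``
likelihood factors, and ``delta`` applies to the state of the first
evaluated factor.

``fit`` maximizes the likelihood on an unconstrained working scale
(:mod:`trackhmm.transforms`) and returns a results object carrying
natural-scale estimates, delta-method standard errors, Wald confidence
intervals and a ``summary()`` table; ``decode`` runs the Viterbi algorithm
for the jointly most probable state path (global decoding).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm
from statsmodels.tools.numdiff import approx_hess1

from .core import emission_log_probs
from .params import MovementParams, BehaviorState
from .preprocess import Track, first_differences
from .transforms import (
    PARAM_NAMES,
    delta_method_se,
    from_working,
    natural_estimates,
    to_working,
    working_ci_to_natural,
)

__all__ = [
    "StateSequence",
    "LikelihoodResult",
    "MovementHMM",
    "MovementHMMResults",
    "FitError",
]


class FitError(RuntimeError):
    """Raised when the optimizer fails on every attempted start.

    Carries the best parameters found so far in ``best_params``.
    """

    def __init__(self, message: str, best_params: MovementParams | None = None):
        super().__init__(message)
        self.best_params = best_params


@dataclass(frozen=True)
class StateSequence:
    """A sequence of behavioral-state labels aligned to displacements.

    Parameters
    ----------
    states : ndarray of int
        Labels in {1, 2}; ``states[i]`` governs displacement
        ``diffs[first_diff_index + i]``.
    first_diff_index : int
        Index (into the 0-based displacement array) of the first governed
        displacement.  Simulated truth covers every displacement
        (``first_diff_index = 0``); decoded sequences start at the second
        displacement (``first_diff_index = 1``) because the first carries
        no evaluable likelihood factor.
    """

    states: np.ndarray
    first_diff_index: int = 0

    def __post_init__(self) -> None:
        s = np.asarray(self.states, dtype=int)
        object.__setattr__(self, "states", s)
        if s.ndim != 1 or s.size == 0:
            raise ValueError("states must be a non-empty 1-d sequence")
        if not np.all((s == 1) | (s == 2)):
            raise ValueError("state labels must be 1 or 2")
        if self.first_diff_index < 0:
            raise ValueError("first_diff_index must be non-negative")

    def __len__(self) -> int:
        return self.states.shape[0]

    def to_position_states(self, n_positions: int) -> np.ndarray:
        """Map displacement-aligned states onto the track positions.

        The state of a displacement is attached to the position that
        terminates it; leading positions with no governed displacement
        inherit the first available state, so every position gets a label
        (convenient for plotting and export).
        """
        first_pos = self.first_diff_index + 1
        if first_pos + len(self) > n_positions:
            raise ValueError("state sequence does not fit the track length")
        out = np.empty(n_positions, dtype=int)
        out[: first_pos + 1] = self.states[0]
        out[first_pos : first_pos + len(self)] = self.states
        out[first_pos + len(self) :] = self.states[-1]
        return out


@dataclass(frozen=True)
class LikelihoodResult:
    """Log-likelihood with optional per-step log normalization constants."""

    loglik: float
    per_step_log_factors: np.ndarray | None = None


def _log(x: float) -> float:
    return math.log(x) if x > 0.0 else -math.inf


def _forward(loge: np.ndarray, a11: float, a21: float, delta: np.ndarray,
             return_factors: bool = False):
    """Scaled forward recursion over precomputed emission log-densities."""
    e1 = loge[:, 0].tolist()
    e2 = loge[:, 1].tolist()
    m = len(e1)
    l1 = _log(float(delta[0])) + e1[0]
    l2 = _log(float(delta[1])) + e2[0]
    hi = max(l1, l2)
    step_ll = hi + math.log(math.exp(l1 - hi) + math.exp(l2 - hi))
    ll = step_ll
    p1 = math.exp(l1 - step_ll)
    p2 = math.exp(l2 - step_ll)
    factors = [step_ll] if return_factors else None
    a12 = 1.0 - a11
    a22 = 1.0 - a21
    for i in range(1, m):
        q1 = p1 * a11 + p2 * a21
        q2 = p1 * a12 + p2 * a22
        l1 = math.log(q1) + e1[i]
        l2 = math.log(q2) + e2[i]
        hi = l1 if l1 >= l2 else l2
        step_ll = hi + math.log(math.exp(l1 - hi) + math.exp(l2 - hi))
        ll += step_ll
        p1 = math.exp(l1 - step_ll)
        p2 = math.exp(l2 - step_ll)
        if return_factors:
            factors.append(step_ll)
    if return_factors:
        return ll, np.asarray(factors)
    return ll


def _viterbi(loge: np.ndarray, a11: float, a21: float, delta: np.ndarray) -> np.ndarray:
    """Most probable state path; exact ties resolved toward state 1."""
    e1 = loge[:, 0].tolist()
    e2 = loge[:, 1].tolist()
    m = len(e1)
    la11, la12 = _log(a11), _log(1.0 - a11)
    la21, la22 = _log(a21), _log(1.0 - a21)
    v1 = _log(float(delta[0])) + e1[0]
    v2 = _log(float(delta[1])) + e2[0]
    back = np.empty((m - 1, 2), dtype=np.int8) if m > 1 else np.empty((0, 2), dtype=np.int8)
    for i in range(1, m):
        c11, c21 = v1 + la11, v2 + la21
        if c11 >= c21:
            nv1, b1 = c11 + e1[i], 0
        else:
            nv1, b1 = c21 + e1[i], 1
        c12, c22 = v1 + la12, v2 + la22
        if c12 >= c22:
            nv2, b2 = c12 + e2[i], 0
        else:
            nv2, b2 = c22 + e2[i], 1
        back[i - 1, 0] = b1
        back[i - 1, 1] = b2
        v1, v2 = nv1, nv2
    path = np.empty(m, dtype=int)
    path[-1] = 0 if v1 >= v2 else 1
    for i in range(m - 2, -1, -1):
        path[i] = back[i, path[i + 1]]
    return path + 1


class MovementHMM:
    """Hidden Markov switching random walk built from track displacements.

    Parameters
    ----------
    diffs : ndarray, shape (m, 2)
        First differences (delta-lon, delta-lat) of a regular-time-step
        track, degrees.  At least 2 displacements are required (one
        evaluable likelihood factor).
    delta_mode : {"stationary", "uniform", "estimate"}
        How the initial state distribution is handled: tied to the
        stationary distribution of the transition matrix (default), fixed
        at (1/2, 1/2), or estimated as a free parameter.

    See also
    --------
    MovementHMM.from_track : build directly from a :class:`Track`.
    """

    def __init__(self, diffs: np.ndarray, delta_mode: str = "stationary"):
        diffs = np.asarray(diffs, dtype=float)
        if diffs.ndim != 2 or diffs.shape[1] != 2:
            raise ValueError("diffs must have shape (m, 2)")
        if diffs.shape[0] < 2:
            raise ValueError(
                "need at least 2 displacements for one likelihood factor"
            )
        if not np.all(np.isfinite(diffs)):
            raise ValueError("displacements must be finite")
        if delta_mode not in ("stationary", "uniform", "estimate"):
            raise ValueError(f"unknown delta_mode {delta_mode!r}")
        self.diffs = diffs
        self.delta_mode = delta_mode

    @classmethod
    def from_track(cls, track: Track, delta_mode: str = "stationary") -> "MovementHMM":
        return cls(first_differences(track), delta_mode=delta_mode)

    @property
    def nobs(self) -> int:
        """Number of evaluated likelihood factors (displacements minus one)."""
        return self.diffs.shape[0] - 1

    # ------------------------------------------------------------------ #
    # likelihood and decoding
    # ------------------------------------------------------------------ #

    def _delta_for(self, params: MovementParams) -> np.ndarray:
        if self.delta_mode == "uniform" and params.delta is None:
            return np.array([0.5, 0.5])
        return params.initial_distribution()

    def loglike(self, params: MovementParams) -> float:
        """Log-likelihood (nats) of the displacements under ``params``."""
        loge = emission_log_probs(self.diffs, params)
        return _forward(loge, params.a11, params.a21, self._delta_for(params))

    def likelihood_result(self, params: MovementParams) -> LikelihoodResult:
        """Log-likelihood plus the per-step log normalization constants."""
        loge = emission_log_probs(self.diffs, params)
        ll, factors = _forward(
            loge, params.a11, params.a21, self._delta_for(params), return_factors=True
        )
        return LikelihoodResult(loglik=ll, per_step_log_factors=factors)

    def decode(self, params: MovementParams) -> StateSequence:
        """Viterbi decoding: the jointly most probable state sequence.

        Returns one state per evaluated likelihood factor, i.e. the
        sequence is aligned to displacements ``1 .. m-1`` (0-based).
        """
        loge = emission_log_probs(self.diffs, params)
        path = _viterbi(loge, params.a11, params.a21, self._delta_for(params))
        return StateSequence(states=path, first_diff_index=1)

    # ------------------------------------------------------------------ #
    # fitting
    # ------------------------------------------------------------------ #

    def _default_start(self) -> MovementParams:
        sd_lon = float(np.std(self.diffs[:, 0], ddof=1))
        sd_lat = float(np.std(self.diffs[:, 1], ddof=1))
        return MovementParams.from_arrays(
            theta=(0.0, math.pi),
            gamma=(0.7, 0.2),
            sigma_lon=max(sd_lon, 1e-8),
            sigma_lat=max(sd_lat, 1e-8),
            a11=0.8,
            a21=0.2,
            delta=(0.5, 0.5) if self.delta_mode == "estimate" else None,
        )

    def _nll(self, w: np.ndarray) -> float:
        try:
            params = from_working(w, self.delta_mode)
        except (ValueError, OverflowError):
            return 1e12
        ll = self.loglike(params)
        if not math.isfinite(ll):
            return 1e12
        return -ll

    @staticmethod
    def _swap_working(w: np.ndarray) -> np.ndarray:
        """Exchange state labels on the working scale (law-preserving)."""
        out = w.copy()
        out[0], out[1] = w[1], w[0]          # theta
        out[2], out[3] = w[3], w[2]          # logit gamma
        out[6], out[7] = -w[7], -w[6]        # logit a11' = logit(1 - a21)
        if w.shape[0] == 9:
            out[8] = -w[8]                   # logit delta1' = logit(1 - delta1)
        return out

    def fit(
        self,
        start: MovementParams | None = None,
        restarts: int = 4,
        seed: int = 0,
        min_diffs: int = 20,
        maxiter: int = 1000,
        ftol: float = 1e-10,
        gtol: float = 1e-5,
    ) -> "MovementHMMResults":
        """Maximum-likelihood fit on the unconstrained working scale.

        Parameters
        ----------
        start : MovementParams, optional
            Starting values; defaults to theta = (0, pi), gamma = (0.7,
            0.2), per-axis empirical standard deviations of the
            displacements for the sigmas, and (a11, a21) = (0.8, 0.2).
        restarts : int
            Maximum number of additional randomized starts attempted when
            the optimizer reports non-convergence.
        seed : int
            Seed for the randomized restarts.
        min_diffs : int
            Minimum number of displacements deemed sufficient for
            estimation (below this a ValueError is raised).
        maxiter, ftol, gtol
            L-BFGS-B settings: iteration cap, relative log-likelihood
            change tolerance, and projected-gradient sup-norm tolerance.

        Returns
        -------
        MovementHMMResults

        Raises
        ------
        FitError
            If every start fails to converge; the best parameters found
            are attached to the exception.
        """
        if self.diffs.shape[0] < min_diffs:
            raise ValueError(
                f"need at least {min_diffs} displacements to fit reliably "
                f"(got {self.diffs.shape[0]}); lower min_diffs to override"
            )
        start_params = start if start is not None else self._default_start()
        w0 = to_working(start_params, estimate_delta=(self.delta_mode == "estimate"))

        rng = np.random.default_rng(seed)
        scale = np.full(w0.shape, 0.5)
        scale[4:6] = 0.3  # log-sigma perturbations kept modest

        best = None
        tried_lls: list[float] = []
        n_restarts_used = 0
        for attempt in range(restarts + 1):
            w_start = w0 if attempt == 0 else w0 + rng.normal(0.0, scale)
            res = minimize(
                self._nll,
                w_start,
                method="L-BFGS-B",
                options={"maxiter": maxiter, "ftol": ftol, "gtol": gtol},
            )
            tried_lls.append(-self._nll(w_start))
            if best is None or res.fun < best.fun:
                best = res
            if attempt > 0:
                n_restarts_used += 1
            if res.success:
                best = res if res.fun <= best.fun else best
                break

        converged = bool(best.success)
        if not converged:
            raise FitError(
                f"optimizer failed to converge after {n_restarts_used + 1} starts: "
                f"{best.message}",
                best_params=from_working(best.x, self.delta_mode).canonical(),
            )

        w_hat = np.asarray(best.x, dtype=float)
        params_hat = from_working(w_hat, self.delta_mode)
        if not params_hat.is_canonical:
            w_hat = self._swap_working(w_hat)
            params_hat = from_working(w_hat, self.delta_mode)

        llf = -float(best.fun)

        # curvature-based uncertainty on the working scale
        se_working = np.full(w_hat.shape, np.nan)
        cov_working = None
        hessian_ok = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                hess = approx_hess1(w_hat, self._nll)
                cov = np.linalg.inv(hess)
                diag = np.diag(cov)
                if np.all(np.isfinite(diag)) and np.all(diag > 0):
                    cov_working = cov
                    se_working = np.sqrt(diag)
                    hessian_ok = True
            except np.linalg.LinAlgError:
                pass
        if not hessian_ok:
            warnings.warn(
                "Hessian not invertible at the optimum; standard errors unavailable",
                stacklevel=2,
            )

        return MovementHMMResults(
            model=self,
            params=params_hat,
            working_params=w_hat,
            llf=llf,
            converged=converged,
            n_iter=int(best.nit),
            n_restarts_used=n_restarts_used,
            se_working=se_working,
            cov_working=cov_working,
            hessian_ok=hessian_ok,
            start_loglikes=tuple(tried_lls),
        )


@dataclass(frozen=True)
class MovementHMMResults:
    """Results of a maximum-likelihood :class:`MovementHMM` fit.

    Attributes
    ----------
    params : MovementParams
        Estimates on the natural scale, labels anchored so state 1 has the
        larger autocorrelation.
    llf : float
        Maximized log-likelihood (nats).
    se_working, cov_working
        Standard errors / covariance on the working scale from the inverse
        negative Hessian of the log-likelihood; NaN / None when the
        Hessian was not invertible (``hessian_ok`` False).
    """

    model: MovementHMM
    params: MovementParams
    working_params: np.ndarray
    llf: float
    converged: bool
    n_iter: int
    n_restarts_used: int
    se_working: np.ndarray
    cov_working: np.ndarray | None
    hessian_ok: bool
    start_loglikes: tuple = ()

    param_names = PARAM_NAMES

    @property
    def estimates(self) -> pd.Series:
        """Natural-scale estimates of the 8 reported parameters."""
        return pd.Series(natural_estimates(self.params), index=PARAM_NAMES)

    @property
    def bse(self) -> pd.Series:
        """Delta-method standard errors on the natural scale."""
        return pd.Series(
            delta_method_se(self.working_params, self.se_working), index=PARAM_NAMES
        )

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Wald confidence intervals mapped from the working scale.

        Probability and sigma intervals respect their domains by
        construction; turning-angle intervals are reported on the same
        (unwrapped) branch as the estimate.
        """
        z = float(norm.ppf(1.0 - alpha / 2.0))
        lo, hi = working_ci_to_natural(self.working_params, self.se_working, z)
        return pd.DataFrame({"lower": lo, "upper": hi}, index=PARAM_NAMES)

    def decode(self) -> StateSequence:
        """Viterbi state sequence at the fitted parameters."""
        return self.model.decode(self.params)

    def summary(self, alpha: float = 0.05) -> str:
        """Plain-text summary table of estimates, SEs and intervals."""
        ci = self.conf_int(alpha)
        tab = pd.DataFrame(
            {
                "estimate": self.estimates,
                "std err": self.bse,
                f"[{alpha / 2:.3f}": ci["lower"],
                f"{1 - alpha / 2:.3f}]": ci["upper"],
            }
        )
        lines = [
            "Two-state switching random walk (ML fit)",
            "=" * 56,
            f"n factors: {self.model.nobs}    log-likelihood: {self.llf:.4f}",
            f"converged: {self.converged}    iterations: {self.n_iter}"
            f"    restarts: {self.n_restarts_used}",
            f"initial distribution: {self.model.delta_mode}",
            "-" * 56,
            tab.to_string(float_format=lambda v: f"{v: .6g}"),
            "=" * 56,
        ]
        return "\n".join(lines)
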