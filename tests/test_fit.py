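"""Maximum-likelihood fitting: oracles, invariances, uncertainty."""

import math
import warnings

import numpy as np
import pytest

from trackhmm import (
    MovementHMM,
    MovementParams,
    simulate_track,
)
from trackhmm.study import default_study_params


@pytest.fixture(scope="module")
def seal_like_fit():
    """One moderate-length simulated track and its ML fit, shared across
    the uncertainty-related tests."""
    params = default_study_params()
    sim = simulate_track(params, n_positions=600, seed=42)
    res = MovementHMM(sim.diffs).fit(seed=42)
    return params, sim, res


def test_single_state_fit_matches_least_squares_oracle():
    """With the chain effectively pinned in state 1, the step process is a
    vector AR(1): d_t = gamma R(theta) d_{t-1} + eps.  Writing a =
    gamma cos(theta), b = gamma sin(theta), the mean is linear in (a, b),
    so ordinary least squares provides an independent estimator to
    cross-check the HMM maximum likelihood fit."""
    truth = MovementParams.from_arrays(
        theta=(0.4, math.pi), gamma=(0.8, 0.05), sigma_lon=0.07, sigma_lat=0.05,
        a11=1 - 1e-9, a21=0.5, delta=(1.0, 0.0),
    )
    sim = simulate_track(truth, n_positions=5000, seed=3)
    d = sim.diffs
    prev, cur = d[:-1], d[1:]
    A = np.zeros((2 * len(prev), 2))
    y = np.empty(2 * len(prev))
    A[0::2, 0], A[0::2, 1], y[0::2] = prev[:, 0], -prev[:, 1], cur[:, 0]
    A[1::2, 0], A[1::2, 1], y[1::2] = prev[:, 1], prev[:, 0], cur[:, 1]
    (a, b), *_ = np.linalg.lstsq(A, y, rcond=None)
    g_ls, th_ls = math.hypot(a, b), math.atan2(b, a)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # gamma2 unidentified -> flat Hessian
        res = MovementHMM(d).fit(seed=3)
    assert res.converged
    assert res.params.state1.gamma == pytest.approx(g_ls, abs=0.02)
    assert res.params.state1.theta == pytest.approx(th_ls, abs=0.02)
    resid = y - A @ np.array([a, b])
    assert res.params.sigma_lon == pytest.approx(np.std(resid[0::2]), rel=0.05)
    assert res.params.sigma_lat == pytest.approx(np.std(resid[1::2]), rel=0.05)


def test_loglik_at_estimate_dominates_truth_and_starts(seal_like_fit):
    params, sim, res = seal_like_fit
    model = MovementHMM(sim.diffs)
    assert res.llf >= model.loglike(params) - 1e-6
    for start_ll in res.start_loglikes:
        assert res.llf >= start_ll - 1e-6


def test_multistart_reaches_same_optimum():
    """Dispersed starting values reach the same log-likelihood in at
    least 4 of 5 attempts (flat/multimodal cases are tolerated once)."""
    params = default_study_params()
    sim = simulate_track(params, n_positions=400, seed=5)
    model = MovementHMM(sim.diffs)
    starts = [
        None,
        MovementParams.from_arrays((0.5, 2.0), (0.6, 0.3), 0.1, 0.1, 0.7, 0.3),
        MovementParams.from_arrays((-0.5, -2.0), (0.9, 0.1), 0.05, 0.05, 0.9, 0.1),
        MovementParams.from_arrays((0.0, 3.0), (0.75, 0.15), 0.08, 0.06, 0.85, 0.25),
        MovementParams.from_arrays((0.2, -3.0), (0.5, 0.4), 0.2, 0.2, 0.6, 0.4),
    ]
    lls = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in starts:
            lls.append(model.fit(start=s, seed=5).llf)
    best = max(lls)
    assert sum(abs(ll - best) < 1e-4 for ll in lls) >= 4


def test_labels_anchored_even_from_flipped_start():
    params = default_study_params()
    sim = simulate_track(params, n_positions=500, seed=9)
    flipped = MovementParams.from_arrays(
        theta=(math.pi, 0.0), gamma=(0.1, 0.75), sigma_lon=0.07, sigma_lat=0.05,
        a11=0.2, a21=0.8,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = MovementHMM(sim.diffs).fit(start=flipped, seed=9)
    assert res.params.is_canonical
    assert res.params.state1.gamma > res.params.state2.gamma


def test_confidence_intervals_bracket_estimates_and_respect_domains(seal_like_fit):
    _, _, res = seal_like_fit
    assert res.hessian_ok
    est = res.estimates
    ci = res.conf_int()
    for name in res.param_names:
        assert ci.loc[name, "lower"] <= est[name] <= ci.loc[name, "upper"]
    for name in ("gamma1", "gamma2", "a11", "a21"):
        assert 0.0 < ci.loc[name, "lower"] < ci.loc[name, "upper"] < 1.0
    for name in ("sigma_lon", "sigma_lat"):
        assert ci.loc[name, "lower"] > 0.0
    assert np.all(res.bse[list(res.param_names)].to_numpy() > 0)


def test_estimates_near_truth_on_one_track(seal_like_fit):
    """Single-track sanity: each estimate within 4 standard errors of the
    generating value (a loose Wald-coverage check, not a study)."""
    params, _, res = seal_like_fit
    from trackhmm.transforms import natural_estimates

    truth = natural_estimates(params)
    est = res.estimates.to_numpy()
    se = res.bse.to_numpy()
    for t, e, s in zip(truth, est, se):
        assert abs(e - t) < 4 * s + 1e-9


def test_summary_mentions_key_fields(seal_like_fit):
    _, _, res = seal_like_fit
    text = res.summary()
    for token in ("log-likelihood", "gamma1", "sigma_lon", "converged: True"):
        assert token in text


def test_short_series_rejected(rng):
    diffs = rng.normal(size=(10, 2))
    with pytest.raises(ValueError, match="at least 20"):
        MovementHMM(diffs).fit()
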