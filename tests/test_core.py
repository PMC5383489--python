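"""Rotation matrix and state-conditional step density."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from trackhmm import BehaviorState, MovementParams, rotation_matrix, step_log_density
from trackhmm.core import emission_log_probs

from conftest import random_params


@pytest.mark.parametrize(
    "theta, expected",
    [
        (0.0, np.eye(2)),
        (math.pi, np.array([[-1.0, 0.0], [0.0, -1.0]])),
        (math.pi / 2, np.array([[0.0, -1.0], [1.0, 0.0]])),
    ],
)
def test_rotation_matrix_special_angles(theta, expected):
    np.testing.assert_allclose(rotation_matrix(theta), expected, atol=1e-12)


@settings(derandomize=True, max_examples=50)
@given(st.floats(-10.0, 10.0))
def test_rotation_matrix_is_orthogonal_with_unit_determinant(theta):
    R = rotation_matrix(theta)
    np.testing.assert_allclose(R @ R.T, np.eye(2), atol=1e-12)
    assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)
    # rotating back undoes the rotation
    np.testing.assert_allclose(R @ rotation_matrix(-theta), np.eye(2), atol=1e-12)


@pytest.mark.parametrize("bad", [math.nan, math.inf, -math.inf])
def test_rotation_matrix_rejects_nonfinite(bad):
    with pytest.raises(ValueError):
        rotation_matrix(bad)


def test_step_log_density_standard_normal_at_origin():
    # zero previous displacement => mean 0 regardless of gamma/theta
    st1 = BehaviorState(gamma=0.5, theta=1.3)
    got = step_log_density((0.0, 0.0), (0.0, 0.0), st1, 1.0, 1.0)
    assert got == pytest.approx(math.log(1.0 / (2.0 * math.pi)), abs=1e-12)
    # vanishing persistence: mean ~ 0 even for nonzero previous step
    st2 = BehaviorState(gamma=1e-12, theta=0.7)
    got = step_log_density((0.0, 0.0), (3.0, -2.0), st2, 1.0, 1.0)
    assert got == pytest.approx(math.log(1.0 / (2.0 * math.pi)), abs=1e-6)


def test_step_log_density_maximum_at_zero_residual():
    # gamma ~ 1, theta = 0, d_t = d_prev: density at its mode
    stt = BehaviorState(gamma=1.0 - 1e-12, theta=0.0)
    sl, sa = 0.07, 0.05
    got = step_log_density((0.1, -0.2), (0.1, -0.2), stt, sl, sa)
    assert got == pytest.approx(math.log(1.0 / (2.0 * math.pi * sl * sa)), abs=1e-6)


def test_step_log_density_rejects_bad_sigma():
    stt = BehaviorState(gamma=0.5, theta=0.0)
    with pytest.raises(ValueError):
        step_log_density((0, 0), (0, 0), stt, -1.0, 1.0)
    with pytest.raises(ValueError):
        step_log_density((0, 0), (0, 0), stt, 1.0, 0.0)


def test_step_log_density_matches_product_of_univariate_normals(rng):
    """Independent oracle: with a diagonal covariance the bivariate density
    factorizes into two univariate normal pdfs around the rotated mean."""
    for _ in range(50):
        stt = BehaviorState(
            gamma=rng.uniform(0.05, 0.95), theta=rng.uniform(-6, 6)
        )
        sl, sa = rng.uniform(0.05, 2.0, size=2)
        d_prev = rng.normal(size=2)
        d_t = rng.normal(size=2)
        c, s = math.cos(stt.theta), math.sin(stt.theta)
        mx = stt.gamma * (c * d_prev[0] - s * d_prev[1])
        my = stt.gamma * (s * d_prev[0] + c * d_prev[1])
        expected = norm.logpdf(d_t[0], mx, sl) + norm.logpdf(d_t[1], my, sa)
        got = step_log_density(d_t, d_prev, stt, sl, sa)
        assert got == pytest.approx(expected, abs=1e-10)


def test_step_log_density_axis_swap_symmetry(rng):
    """With equal sigmas, swapping lon/lat roles and negating theta (which
    transposes the rotation) leaves the density unchanged."""
    for _ in range(25):
        g = rng.uniform(0.05, 0.95)
        th = rng.uniform(-3, 3)
        sig = rng.uniform(0.1, 1.0)
        d_prev = rng.normal(size=2)
        d_t = rng.normal(size=2)
        a = step_log_density(d_t, d_prev, BehaviorState(g, th), sig, sig)
        b = step_log_density(
            d_t[::-1], d_prev[::-1], BehaviorState(g, -th), sig, sig
        )
        assert a == pytest.approx(b, abs=1e-10)


def test_step_density_integrates_to_one():
    stt = BehaviorState(gamma=0.6, theta=0.9)
    sl, sa = 0.8, 1.1
    d_prev = np.array([0.4, -0.3])
    # truncated grid out to ~6 sigma around the mean
    mean = stt.gamma * (rotation_matrix(stt.theta) @ d_prev)
    gx = np.linspace(mean[0] - 6 * sl, mean[0] + 6 * sl, 401)
    gy = np.linspace(mean[1] - 6 * sa, mean[1] + 6 * sa, 401)
    X, Y = np.meshgrid(gx, gy, indexing="ij")
    logp = np.array(
        [
            [step_log_density((x, y), d_prev, stt, sl, sa) for y in gy]
            for x in gx
        ]
    )
    integral = np.trapezoid(np.trapezoid(np.exp(logp), gy, axis=1), gx)
    assert integral == pytest.approx(1.0, abs=1e-3)


def test_emission_log_probs_agrees_with_scalar_density(rng):
    diffs = rng.normal(scale=0.1, size=(20, 2))
    params = random_params(rng)
    loge = emission_log_probs(diffs, params)
    assert loge.shape == (19, 2)
    for i in range(19):
        for k, stt in enumerate((params.state1, params.state2)):
            expected = step_log_density(
                diffs[i + 1], diffs[i], stt, params.sigma_lon, params.sigma_lat
            )
            assert loge[i, k] == pytest.approx(expected, abs=1e-12)


def test_emission_log_probs_floor():
    params = MovementParams.from_arrays(
        theta=(0.0, 0.0), gamma=(0.8, 0.1), sigma_lon=1e-4, sigma_lat=1e-4,
        a11=0.5, a21=0.5,
    )
    diffs = np.array([[0.0, 0.0], [50.0, 50.0]])
    loge = emission_log_probs(diffs, params)
    assert np.all(np.isfinite(loge))
    assert np.all(loge >= -745.0)
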