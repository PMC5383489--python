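"""Shared fixtures and independent oracles for the test suite.

The brute-force HMM oracles below enumerate every latent state sequence
explicitly; they share no code with the forward/Viterbi implementations
they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from scipy.special import logsumexp

from trackhmm import MovementParams
from trackhmm.core import step_log_density


def random_params(rng: np.random.Generator, ordered: bool = False) -> MovementParams:
    """A random valid parameter set; labeling unordered unless asked."""
    g = rng.uniform(0.05, 0.95, size=2)
    if ordered:
        g = np.sort(g)[::-1]
    return MovementParams.from_arrays(
        theta=tuple(rng.uniform(-math.pi, math.pi, size=2)),
        gamma=tuple(g),
        sigma_lon=float(rng.uniform(0.02, 0.5)),
        sigma_lat=float(rng.uniform(0.02, 0.5)),
        a11=float(rng.uniform(0.1, 0.9)),
        a21=float(rng.uniform(0.1, 0.9)),
    )


def seq_log_prob(diffs: np.ndarray, params: MovementParams, seq: tuple[int, ...]) -> float:
    """Joint log-probability of one latent state sequence and the data.

    ``seq`` holds 0-based state indices, one per likelihood factor
    (factor i governs displacement i+1, conditioning on displacement i).
    """
    delta = params.initial_distribution()
    A = params.transition_matrix
    states = (params.state1, params.state2)
    lp = math.log(delta[seq[0]])
    for k in range(1, len(seq)):
        lp += math.log(A[seq[k - 1], seq[k]])
    for i, s in enumerate(seq):
        # the likelihood definition floors emission log-densities at -745
        lp += max(
            step_log_density(
                diffs[i + 1], diffs[i], states[s], params.sigma_lon, params.sigma_lat
            ),
            -745.0,
        )
    return lp


def brute_force_loglik(diffs: np.ndarray, params: MovementParams) -> float:
    """Marginal log-likelihood by summation over all state sequences."""
    m = diffs.shape[0] - 1
    lps = [
        seq_log_prob(diffs, params, seq)
        for seq in itertools.product((0, 1), repeat=m)
    ]
    return float(logsumexp(lps))


def brute_force_viterbi(diffs: np.ndarray, params: MovementParams):
    """(best log-prob, all argmax sequences as 1/2 labels)."""
    m = diffs.shape[0] - 1
    best = -math.inf
    argmax = []
    for seq in itertools.product((0, 1), repeat=m):
        lp = seq_log_prob(diffs, params, seq)
        if lp > best + 1e-12:
            best, argmax = lp, [seq]
        elif abs(lp - best) <= 1e-12:
            argmax.append(seq)
    return best, [np.asarray(s) + 1 for s in argmax]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
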