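"""Shared fixtures and independent brute-force oracles.

The oracles below recompute likelihoods and posteriors with explicit Python
loops straight from the model definitions (DINA: 1-s for full masters else g;
G-DINA: reduced-class lookup), independently of the vectorized implementation
they are used to check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from cdmtau import QMatrix, builtin_qmatrix


def all_profiles(K):
    """Canonical profile order, re-derived by binary counting."""
    return [np.array(p, dtype=int) for p in itertools.product((0, 1), repeat=K)]


def oracle_success_prob(params, q_entries, j, alpha):
    """Success probability of item j under profile alpha, by direct definition."""
    req = [k for k in range(len(alpha)) if q_entries[j][k] == 1]
    if hasattr(params, "guess"):  # DINA
        masters_all = all(alpha[k] == 1 for k in req)
        return 1.0 - params.slip[j] if masters_all else params.guess[j]
    # G-DINA: reduced-profile lookup, first required attribute most significant
    idx = 0
    for k in req:
        idx = 2 * idx + int(alpha[k])
    return float(params.tables[j][idx])


def oracle_likelihood(x_i, alpha, params, q_entries):
    lik = 1.0
    for j, xij in enumerate(x_i):
        p = oracle_success_prob(params, q_entries, j, alpha)
        lik *= p if xij == 1 else 1.0 - p
    return lik


def oracle_posterior(x, params, pi, q_entries, K):
    """Bayes rule by full 2**K enumeration, person by person."""
    profiles = all_profiles(K)
    out = np.empty((len(x), len(profiles)))
    for i, x_i in enumerate(x):
        joint = np.array(
            [
                oracle_likelihood(x_i, alpha, params, q_entries) * pi[l]
                for l, alpha in enumerate(profiles)
            ]
        )
        out[i] = joint / joint.sum()
    return out


def oracle_marginal_loglik(x, params, pi, q_entries, K):
    profiles = all_profiles(K)
    total = 0.0
    for x_i in x:
        total += np.log(
            sum(
                oracle_likelihood(x_i, alpha, params, q_entries) * pi[l]
                for l, alpha in enumerate(profiles)
            )
        )
    return total


@pytest.fixture(scope="session")
def q15() -> QMatrix:
    return builtin_qmatrix(15)


@pytest.fixture(scope="session")
def q30() -> QMatrix:
    return builtin_qmatrix(30)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
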