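"""Marginal maximum likelihood estimation of DINA / G-DINA by EM.

The latent classes are the ``2**K`` attribute profiles; marginalizing the
conditional response likelihood over them gives the observed-data likelihood

    lik(X) = prod_i sum_l lik(x_i | alpha_l, delta) * P(alpha_l).

The E-step computes posterior class memberships and from them the expected
number of respondents and of correct responses in each reduced latent group
of each item; the M-step has a closed form in both parameterizations — each
item success probability is an expected proportion correct, and pi is the
mean posterior.  Item probabilities are clamped to ``[1e-4, 1 - 1e-4]``
during estimation; latent groups with vanishing expected mass (< 1e-8) keep
the previous iterate's value, which keeps the update defined on sparse data.

Initialization is deterministic: DINA starts at g = s = 0.2; G-DINA
reduced-class probabilities start linearly spaced in the number of mastered
required attributes from 0.2 to 0.8; pi starts uniform.  Iteration stops when
the largest absolute change over all item probabilities and pi entries drops
below ``tol_param``, or the log-likelihood improves by less than
``tol_loglik``, or after ``max_iter`` cycles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .model import loglik_matrix, posterior
from .params import ItemParamsDINA, ItemParamsGDINA, LatentDist
from .qmatrix import QMatrix

__all__ = [
    "EstimationError",
    "FitResult",
    "marginal_loglik",
    "e_step",
    "m_step_dina",
    "m_step_gdina",
    "initial_params",
    "fit_em",
]

logger = logging.getLogger(__name__)

#: Bounds for item success probabilities during estimation.
PROB_BOUNDS = (1e-4, 1.0 - 1e-4)
#: Expected-mass floor below which a latent group keeps its previous value.
MASS_FLOOR = 1e-8


class EstimationError(RuntimeError):
    """Raised when an EM fit cannot proceed (non-finite likelihood)."""


@dataclass
class FitResult:
    """Converged (or stopped) EM state for one dataset."""

    params: ItemParamsDINA | ItemParamsGDINA
    pi: LatentDist
    loglik: float
    n_iter: int
    converged: bool
    posteriors: np.ndarray  # (N, L) at the returned parameter values
    loglik_path: np.ndarray = field(default_factory=lambda: np.empty(0))
    model: str = ""


def marginal_loglik(
    x: np.ndarray,
    params: ItemParamsDINA | ItemParamsGDINA,
    pi: LatentDist,
    q: QMatrix,
) -> float:
    """Observed-data log-likelihood ``sum_i log sum_l lik(x_i|alpha_l) pi_l``."""
    ll = loglik_matrix(x, params, q)
    with np.errstate(divide="ignore"):
        return float(logsumexp(ll + np.log(pi.pi), axis=1).sum())


def e_step(
    x: np.ndarray,
    params: ItemParamsDINA | ItemParamsGDINA,
    pi: LatentDist,
    q: QMatrix,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Posterior memberships and expected counts.

    Returns
    -------
    post : ``(N, L)`` posterior profile probabilities.
    class_mass : ``(L,)`` expected respondents per class (sums to N).
    correct : ``(L, J)`` expected correct responses per class and item.
    """
    x = np.asarray(x, dtype=float)
    post = posterior(x, params, pi, q)
    class_mass = post.sum(axis=0)
    correct = post.T @ x
    return post, class_mass, correct


def _grouped(
    q: QMatrix, j: int, class_mass: np.ndarray, correct: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Expected respondents and corrects per reduced latent group of item j."""
    idx = q.reduced_index[j]
    size = 2 ** int(q.kstar[j])
    mass = np.bincount(idx, weights=class_mass, minlength=size)
    hits = np.bincount(idx, weights=correct[:, j], minlength=size)
    return mass, hits


def m_step_dina(
    class_mass: np.ndarray,
    correct: np.ndarray,
    q: QMatrix,
    prev: ItemParamsDINA,
) -> ItemParamsDINA:
    """Closed-form update: g from non-masters, 1 - s from full masters."""
    eta = q.full_mastery  # (J, L)
    mass1 = eta @ class_mass
    mass0 = class_mass.sum() - mass1
    hits1 = np.einsum("jl,lj->j", eta, correct)
    hits0 = correct.sum(axis=0) - hits1
    lo, hi = PROB_BOUNDS
    guess = prev.guess.copy()
    slip = prev.slip.copy()
    ok0 = mass0 > MASS_FLOOR
    ok1 = mass1 > MASS_FLOOR
    guess[ok0] = np.clip(hits0[ok0] / mass0[ok0], lo, hi)
    slip[ok1] = np.clip(1.0 - hits1[ok1] / mass1[ok1], lo, hi)
    return ItemParamsDINA(guess, slip)


def m_step_gdina(
    class_mass: np.ndarray,
    correct: np.ndarray,
    q: QMatrix,
    prev: ItemParamsGDINA,
) -> ItemParamsGDINA:
    """Closed-form update: one expected proportion per reduced latent group."""
    lo, hi = PROB_BOUNDS
    tables = []
    for j in range(q.J):
        mass, hits = _grouped(q, j, class_mass, correct)
        t = prev.tables[j].copy()
        ok = mass > MASS_FLOOR
        t[ok] = np.clip(hits[ok] / mass[ok], lo, hi)
        tables.append(t)
    return ItemParamsGDINA(tables)


def initial_params(q: QMatrix, model: str) -> ItemParamsDINA | ItemParamsGDINA:
    """Deterministic starting values (see module docstring)."""
    model = model.lower()
    if model == "dina":
        return ItemParamsDINA(np.full(q.J, 0.2), np.full(q.J, 0.2))
    if model == "gdina":
        tables = []
        for j in range(q.J):
            kstar = int(q.kstar[j])
            ones = np.array(
                [bin(c).count("1") for c in range(2**kstar)], dtype=float
            )
            tables.append(0.2 + 0.6 * ones / kstar)
        return ItemParamsGDINA(tables)
    raise ValueError(f"unknown model {model!r}; expected 'dina' or 'gdina'")


def fit_em(
    x: np.ndarray,
    q: QMatrix,
    model: str = "dina",
    *,
    max_iter: int = 1000,
    tol_param: float = 1e-4,
    tol_loglik: float = 1e-7,
) -> FitResult:
    """Fit DINA or G-DINA by EM and return the full estimation state."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != q.J:
        raise ValueError(
            f"response matrix shape {x.shape} does not match Q-matrix with J={q.J}"
        )
    model = model.lower()
    m_step = m_step_dina if model == "dina" else m_step_gdina
    params = initial_params(q, model)
    pi = LatentDist.uniform(q.K)

    loglik_path: list[float] = []
    prev_loglik = -np.inf
    converged = False
    n_iter = 0
    post = np.empty((x.shape[0], 2**q.K))
    for n_iter in range(1, max_iter + 1):
        ll = loglik_matrix(x, params, q)
        with np.errstate(divide="ignore"):
            a = ll + np.log(pi.pi)
        m = a.max(axis=1, keepdims=True)
        w = np.exp(a - m)
        totals = w.sum(axis=1, keepdims=True)
        loglik = float((m[:, 0] + np.log(totals[:, 0])).sum())
        if not np.isfinite(loglik):
            raise EstimationError(f"non-finite log-likelihood at iteration {n_iter}")
        loglik_path.append(loglik)
        post = w / totals

        class_mass = post.sum(axis=0)
        correct = post.T @ x
        new_params = m_step(class_mass, correct, q, params)
        new_pi = LatentDist(class_mass / class_mass.sum())

        param_delta = max(
            float(np.abs(new_params.flat() - params.flat()).max()),
            float(np.abs(new_pi.pi - pi.pi).max()),
        )
        loglik_delta = loglik - prev_loglik
        params, pi, prev_loglik = new_params, new_pi, loglik
        if param_delta < tol_param or abs(loglik_delta) < tol_loglik:
            converged = True
            break

    final_loglik = marginal_loglik(x, params, q=q, pi=pi)
    loglik_path.append(final_loglik)
    post = posterior(x, params, pi, q)
    logger.debug(
        "EM %s: %d iteration(s), loglik %.4f, converged=%s",
        model,
        n_iter,
        final_loglik,
        converged,
    )
    return FitResult(
        params=params,
        pi=pi,
        loglik=final_loglik,
        n_iter=n_iter,
        converged=converged,
        posteriors=post,
        loglik_path=np.asarray(loglik_path),
        model=model,
    )
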