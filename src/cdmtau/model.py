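"""Item response functions, likelihoods, posteriors and EAP classification.

The DINA item response function gives success probability ``1 - s_j`` to
respondents mastering every attribute the item requires and ``g_j`` to
everyone else.  The saturated G-DINA function assigns a free success
probability to each reduced attribute profile of the item.

Under conditional independence of items given the profile, the likelihood of
a response vector is the product over items of ``P^x (1-P)^(1-x)``; it is
evaluated in the log domain with probabilities clamped to
``[1e-10, 1 - 1e-10]`` so that boundary parameter estimates never produce
NaNs.  Posterior profile probabilities combine the likelihood with the
estimated latent-class distribution pi used as an empirical-Bayes prior.

EAP classification thresholds each attribute's marginal posterior mastery
probability at 0.5; a tie at exactly 0.5 classifies as mastery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .params import ItemParamsDINA, ItemParamsGDINA, LatentDist
from .profiles import reduce_profile
from .qmatrix import QMatrix

__all__ = [
    "PROB_CLAMP",
    "Classification",
    "irf_dina",
    "irf_gdina",
    "response_likelihood",
    "loglik_matrix",
    "posterior",
    "marginal_mastery",
    "eap_classify",
]

logger = logging.getLogger(__name__)

#: Clamp applied to item success probabilities inside likelihood evaluation only.
PROB_CLAMP = 1e-10


@dataclass
class Classification:
    """EAP attribute classifications and the mastery probabilities behind them."""

    alpha_hat: np.ndarray  # (N, K) binary
    mastery_prob: np.ndarray  # (N, K) marginal posterior P(alpha_ik = 1 | x_i)


def irf_dina(g: float, s: float, alpha: np.ndarray, q_row: np.ndarray) -> float:
    """DINA success probability for one respondent profile on one item."""
    if not (0.0 <= g <= 1.0 and 0.0 <= s <= 1.0):
        raise ValueError(f"g and s must lie in [0, 1], got g={g}, s={s}")
    alpha = np.asarray(alpha)
    q_row = np.asarray(q_row)
    masters_all = bool((alpha[q_row == 1] == 1).all())
    return 1.0 - s if masters_all else g


def irf_gdina(item_table: np.ndarray, alpha: np.ndarray, q_row: np.ndarray) -> float:
    """G-DINA success probability: look up the matching reduced-class entry."""
    item_table = np.asarray(item_table, dtype=float)
    kstar = int(np.asarray(q_row).sum())
    if item_table.size != 2**kstar:
        raise ValueError(
            f"item table has {item_table.size} entries, expected {2 ** kstar}"
        )
    return float(item_table[reduce_profile(alpha, q_row)])


def _clamped_logs(prob_table: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.clip(prob_table, PROB_CLAMP, 1.0 - PROB_CLAMP)
    return np.log(p), np.log1p(-p)


def response_likelihood(
    x_i: np.ndarray,
    alpha: np.ndarray,
    params: ItemParamsDINA | ItemParamsGDINA,
    q: QMatrix,
) -> float:
    """Likelihood of one response vector under one attribute profile."""
    x_i = np.asarray(x_i, dtype=float)
    if x_i.size != q.J:
        raise ValueError(f"response vector has {x_i.size} items, Q-matrix {q.J}")
    table = params.success_table(q)
    idx = int(np.asarray(alpha) @ (1 << np.arange(q.K - 1, -1, -1)))
    logp, log1mp = _clamped_logs(table[:, idx])
    return float(np.exp((x_i * logp + (1.0 - x_i) * log1mp).sum()))


def loglik_matrix(
    x: np.ndarray, params: ItemParamsDINA | ItemParamsGDINA, q: QMatrix
) -> np.ndarray:
    """``(N, L)`` log-likelihood of each response vector under each profile.

    Computed as ``X @ (log p - log(1-p)) + sum_j log(1-p_j)`` per class, a
    single matrix product.
    """
    x = np.asarray(x, dtype=float)
    table = params.success_table(q)
    logp, log1mp = _clamped_logs(table)
    return x @ (logp - log1mp) + log1mp.sum(axis=0)


def posterior(
    x: np.ndarray,
    params: ItemParamsDINA | ItemParamsGDINA,
    pi: LatentDist,
    q: QMatrix,
) -> np.ndarray:
    """``(N, L)`` posterior profile probabilities, rows normalized.

    Row ``i``, class ``l`` is proportional to ``lik(x_i | alpha_l) * pi_l``.
    A row whose likelihood-prior products all vanish (possible when pi has
    exact zeros) falls back to the prior and a warning is logged.
    """
    ll = loglik_matrix(x, params, q)
    with np.errstate(divide="ignore"):
        a = ll + np.log(pi.pi)
    m = a.max(axis=1, keepdims=True)
    finite = np.isfinite(m[:, 0])
    post = np.zeros_like(a)
    if finite.any():
        w = np.exp(a[finite] - m[finite])
        post[finite] = w / w.sum(axis=1, keepdims=True)
    if not finite.all():
        n_bad = int((~finite).sum())
        logger.warning(
            "%d posterior row(s) had zero total mass; falling back to the prior",
            n_bad,
        )
        post[~finite] = pi.pi
    return post


def marginal_mastery(post: np.ndarray, profiles: np.ndarray) -> np.ndarray:
    """``(N, K)`` marginal posterior mastery probabilities.

    Entry ``(i, k)`` sums the posterior over all classes whose profile has
    ``alpha_lk = 1``.
    """
    return np.asarray(post, dtype=float) @ np.asarray(profiles, dtype=float)


def eap_classify(mastery_prob: np.ndarray, threshold: float = 0.5) -> Classification:
    """Threshold marginal mastery probabilities into binary classifications.

    A probability exactly at the threshold classifies as mastery.
    """
    mastery_prob = np.asarray(mastery_prob, dtype=float)
    if ((mastery_prob < 0) | (mastery_prob > 1)).any():
        raise ValueError("mastery probabilities must lie in [0, 1]")
    alpha_hat = (mastery_prob >= threshold).astype(np.int8)
    return Classification(alpha_hat=alpha_hat, mastery_prob=mastery_prob)
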