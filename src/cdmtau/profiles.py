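"""Attribute-profile space bookkeeping.

A cognitive diagnosis model over ``K`` binary attributes classifies each
respondent into one of ``L = 2**K`` latent classes, the *attribute profiles*.
Every module in this package indexes those classes with the same canonical
order: binary counting with attribute 1 as the most significant bit, e.g.
for ``K = 2`` the order is ``(0,0), (0,1), (1,0), (1,1)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "enumerate_profiles",
    "profile_index",
    "reduce_profile",
]


def enumerate_profiles(K: int) -> np.ndarray:
    """Return all ``2**K`` attribute profiles in canonical order.

    Parameters
    ----------
    K : int
        Number of attributes (``K >= 1``).

    Returns
    -------
    numpy.ndarray
        ``(2**K, K)`` int8 array; row ``l`` is the binary expansion of ``l``
        with attribute 1 as the most significant bit.
    """
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    ints = np.arange(2**K, dtype=np.int64)
    bits = (ints[:, None] >> np.arange(K - 1, -1, -1)) & 1
    return bits.astype(np.int8)


def profile_index(alpha: np.ndarray) -> np.ndarray:
    """Map profiles (rows of a ``(..., K)`` binary array) to class indices.

    Inverse of :func:`enumerate_profiles` row lookup: for the canonical order,
    ``enumerate_profiles(K)[profile_index(a)] == a``.
    """
    alpha = np.asarray(alpha)
    K = alpha.shape[-1]
    weights = 1 << np.arange(K - 1, -1, -1)
    return alpha @ weights


def reduce_profile(alpha: np.ndarray, q_row: np.ndarray) -> int:
    """Index of a profile within an item's reduced attribute space.

    An item requiring ``K*_j`` attributes (the ones with ``q_jk = 1``)
    distinguishes only ``2**K*_j`` *reduced* profiles.  The reduced space uses
    the same canonical binary-counting order, restricted to the required
    attributes in their original order.
    """
    alpha = np.asarray(alpha)
    q_row = np.asarray(q_row)
    if alpha.shape != q_row.shape:
        raise ValueError(
            f"profile and Q-row shapes differ: {alpha.shape} vs {q_row.shape}"
        )
    reduced = alpha[q_row == 1]
    return int(profile_index(reduced)) if reduced.size else 0
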