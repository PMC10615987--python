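"""Q-matrix: the items-by-attributes content specification of a test.

Entry ``q_jk = 1`` declares that solving item ``j`` requires attribute ``k``.
The Q-matrix fixes, for every item, which of the ``2**K`` attribute profiles
are distinguishable (the item's reduced profile space), and is therefore the
structural input shared by the item response functions, the EM estimator and
the simulation generators.
"""

from __future__ import annotations

from functools import cached_property

import numpy as np

from .profiles import enumerate_profiles

__all__ = ["QMatrix", "ValidationError"]


class ValidationError(ValueError):
    """Raised when an input matrix violates a structural invariant."""


class QMatrix:
    """Validated binary items × attributes specification.

    Parameters
    ----------
    entries : array-like
        ``(J, K)`` matrix of 0/1; every item row must require at least one
        attribute and every attribute must be required by at least one item.
    """

    def __init__(self, entries) -> None:
        q = np.asarray(entries)
        if q.ndim != 2:
            raise ValidationError(f"Q-matrix must be 2-D, got shape {q.shape}")
        if not np.isin(q, (0, 1)).all():
            bad = np.argwhere(~np.isin(q, (0, 1)))[0]
            raise ValidationError(
                f"non-binary Q-matrix entry at item {bad[0] + 1}, "
                f"attribute {bad[1] + 1}"
            )
        q = q.astype(np.int8)
        row_sums = q.sum(axis=1)
        if (row_sums == 0).any():
            j = int(np.argmax(row_sums == 0))
            raise ValidationError(f"item {j + 1} requires no attribute (all-zero row)")
        col_sums = q.sum(axis=0)
        if (col_sums == 0).any():
            k = int(np.argmax(col_sums == 0))
            raise ValidationError(
                f"attribute {k + 1} is measured by no item (all-zero column)"
            )
        self.entries = q
        self.entries.setflags(write=False)

    @property
    def J(self) -> int:
        return self.entries.shape[0]

    @property
    def K(self) -> int:
        return self.entries.shape[1]

    @property
    def kstar(self) -> np.ndarray:
        """Number of required attributes per item, ``K*_j``."""
        return self.entries.sum(axis=1).astype(np.int64)

    @cached_property
    def profiles(self) -> np.ndarray:
        """Full profile space ``(L, K)`` in canonical order."""
        return enumerate_profiles(self.K)

    @cached_property
    def full_mastery(self) -> np.ndarray:
        """``(J, L)`` boolean: does class ``l`` master all attributes of item ``j``.

        This is the DINA "ideal response" (eta) table.
        """
        counts = self.entries.astype(np.int64) @ self.profiles.T.astype(np.int64)
        return counts == self.kstar[:, None]

    @cached_property
    def reduced_index(self) -> np.ndarray:
        """``(J, L)`` int array: reduced-profile index of class ``l`` for item ``j``."""
        A = self.profiles.astype(np.int64)
        out = np.empty((self.J, A.shape[0]), dtype=np.int64)
        for j in range(self.J):
            req = np.flatnonzero(self.entries[j])
            weights = 1 << np.arange(req.size - 1, -1, -1)
            out[j] = A[:, req] @ weights
        out.setflags(write=False)
        return out

    def __eq__(self, other) -> bool:
        return isinstance(other, QMatrix) and np.array_equal(self.entries, other.entries)

    def __repr__(self) -> str:
        return f"QMatrix(J={self.J}, K={self.K})"
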