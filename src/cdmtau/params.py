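"""Item-parameter and latent-distribution containers.

Two item parameterizations are supported:

* DINA — conjunctive: each item has a guessing probability ``g_j`` (success
  without full mastery of the required attributes) and a slip probability
  ``s_j`` (failure despite full mastery).
* G-DINA — saturated, identity link: each item stores one success probability
  per reduced attribute profile (``2**K*_j`` values).  The delta coefficients
  of the saturated linear formulation are an invertible linear transform of
  this table; the per-class probabilities are the internal representation
  because the EM M-step is closed-form in them.

Both expose ``success_table(q)``: the ``(J, L)`` matrix of success
probabilities for every item under every full attribute profile, which is the
only thing the likelihood machinery needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .qmatrix import QMatrix

__all__ = ["ItemParamsDINA", "ItemParamsGDINA", "LatentDist"]


def _check_unit_interval(name: str, values: np.ndarray) -> None:
    if ((values < 0) | (values > 1)).any():
        raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class ItemParamsDINA:
    """Guess/slip parameters for the conjunctive DINA model."""

    guess: np.ndarray
    slip: np.ndarray

    def __post_init__(self) -> None:
        self.guess = np.asarray(self.guess, dtype=float)
        self.slip = np.asarray(self.slip, dtype=float)
        if self.guess.shape != self.slip.shape or self.guess.ndim != 1:
            raise ValueError("guess and slip must be 1-D vectors of equal length")
        _check_unit_interval("guess", self.guess)
        _check_unit_interval("slip", self.slip)

    @property
    def J(self) -> int:
        return self.guess.size

    def success_table(self, q: QMatrix) -> np.ndarray:
        """``(J, L)`` success probabilities: ``1 - s_j`` for full masters, else ``g_j``."""
        if q.J != self.J:
            raise ValueError(f"Q-matrix has {q.J} items, parameters have {self.J}")
        eta = q.full_mastery
        return np.where(eta, (1.0 - self.slip)[:, None], self.guess[:, None])

    def flat(self) -> np.ndarray:
        return np.concatenate([self.guess, self.slip])

    def copy(self) -> "ItemParamsDINA":
        return ItemParamsDINA(self.guess.copy(), self.slip.copy())


@dataclass
class ItemParamsGDINA:
    """Per-item reduced-class success probabilities for the saturated G-DINA model.

    ``tables[j]`` has length ``2**K*_j``, indexed in the canonical reduced-profile
    order (all-zero reduced profile first, all-one last).
    """

    tables: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.tables = [np.asarray(t, dtype=float) for t in self.tables]
        for j, t in enumerate(self.tables):
            if t.ndim != 1 or (t.size & (t.size - 1)) != 0:
                raise ValueError(
                    f"item {j + 1}: table length {t.size} is not a power of two"
                )
            _check_unit_interval(f"item {j + 1} probabilities", t)

    @property
    def J(self) -> int:
        return len(self.tables)

    def success_table(self, q: QMatrix) -> np.ndarray:
        if q.J != self.J:
            raise ValueError(f"Q-matrix has {q.J} items, parameters have {self.J}")
        for j, t in enumerate(self.tables):
            if t.size != 2 ** int(q.kstar[j]):
                raise ValueError(
                    f"item {j + 1}: expected {2 ** int(q.kstar[j])} reduced-class "
                    f"probabilities, got {t.size}"
                )
        L = 2**q.K
        out = np.empty((self.J, L))
        for j, t in enumerate(self.tables):
            out[j] = t[q.reduced_index[j]]
        return out

    def flat(self) -> np.ndarray:
        return np.concatenate(self.tables) if self.tables else np.empty(0)

    def copy(self) -> "ItemParamsGDINA":
        return ItemParamsGDINA([t.copy() for t in self.tables])

    @classmethod
    def from_dina(cls, dina: ItemParamsDINA, q: QMatrix) -> "ItemParamsGDINA":
        """Embed DINA parameters in the saturated table (DINA is nested in G-DINA)."""
        tables = []
        for j in range(q.J):
            size = 2 ** int(q.kstar[j])
            t = np.full(size, dina.guess[j])
            t[-1] = 1.0 - dina.slip[j]
            tables.append(t)
        return cls(tables)


@dataclass
class LatentDist:
    """Probability vector pi over the ``L = 2**K`` attribute profiles."""

    pi: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.ndim != 1:
            raise ValueError("pi must be a vector")
        if (self.pi < 0).any():
            raise ValueError("pi entries must be nonnegative")
        if abs(self.pi.sum() - 1.0) > 1e-10:
            raise ValueError(f"pi must sum to 1, got {self.pi.sum()!r}")

    @property
    def L(self) -> int:
        return self.pi.size

    @classmethod
    def uniform(cls, K: int) -> "LatentDist":
        L = 2**K
        return cls(np.full(L, 1.0 / L))
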