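"""Classification-accuracy indices and true-accuracy benchmarks.

The tau indices estimate, from posterior probabilities alone, how accurate a
set of EAP attribute classifications is:

* ``tau_k`` (attribute level) averages, over respondents, the posterior
  probability of the category each respondent was assigned to:
  ``alpha_hat * P + (1 - alpha_hat) * (1 - P)`` with ``P`` the marginal
  posterior mastery probability.  It estimates the proportion of correct
  attribute classifications (PCA).
* ``tau`` (profile level) averages the posterior probability of each
  respondent's EAP-implied profile (the profile assembled from the
  attribute-wise decisions, which may differ from the modal profile).  It
  estimates the proportion of exactly correct profiles (PCV).

When the generating profiles are known (simulation), PCA/PCV are computed
directly and RMSE measures how far replicate tau estimates sit from the
per-condition mean benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import Classification
from .profiles import profile_index

__all__ = [
    "ReliabilityReport",
    "AccuracyBenchmark",
    "profile_posterior_at",
    "tau",
    "tau_k",
    "reliability_report",
    "true_accuracy",
    "rmse",
]


@dataclass
class ReliabilityReport:
    """Profile- and attribute-level accuracy estimates for one dataset."""

    tau: float
    tau_k: np.ndarray
    method: str  # "EM" (point-estimate posteriors) or "MI" (imputation-corrected)
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "tau": float(self.tau),
            "tau_k": [float(v) for v in self.tau_k],
            **self.extra,
        }


@dataclass
class AccuracyBenchmark:
    """True classification accuracy against known generating profiles."""

    pcv: float
    pca_k: np.ndarray


def profile_posterior_at(post: np.ndarray, alpha_hat: np.ndarray) -> np.ndarray:
    """Posterior probability of each respondent's classified profile.

    ``post`` is ``(N, L)`` in canonical class order; ``alpha_hat`` is the
    ``(N, K)`` binary classification matrix.
    """
    post = np.asarray(post, dtype=float)
    idx = profile_index(np.asarray(alpha_hat))
    return post[np.arange(post.shape[0]), idx]


def tau(post_at_estimate: np.ndarray) -> float:
    """Profile-level accuracy index: mean posterior mass of the classified profile."""
    p = np.asarray(post_at_estimate, dtype=float)
    if p.size == 0:
        raise ValueError("tau requires at least one respondent")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("posterior probabilities must lie in [0, 1]")
    return float(p.mean())


def tau_k(alpha_hat: np.ndarray, mastery_prob: np.ndarray) -> np.ndarray:
    """Attribute-level accuracy indices.

    ``tau_k = mean_i [ alpha_hat_ik * P_ik + (1 - alpha_hat_ik) * (1 - P_ik) ]``
    with ``P_ik`` the marginal posterior mastery probability.
    """
    a = np.asarray(alpha_hat, dtype=float)
    p = np.asarray(mastery_prob, dtype=float)
    if a.shape != p.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {p.shape}")
    return (a * p + (1.0 - a) * (1.0 - p)).mean(axis=0)


def reliability_report(
    post: np.ndarray, classification: Classification, method: str = "EM"
) -> ReliabilityReport:
    """Bundle tau and tau_k for a posterior matrix and its classifications."""
    return ReliabilityReport(
        tau=tau(profile_posterior_at(post, classification.alpha_hat)),
        tau_k=tau_k(classification.alpha_hat, classification.mastery_prob),
        method=method,
    )


def true_accuracy(alpha_true: np.ndarray, alpha_hat: np.ndarray) -> AccuracyBenchmark:
    """PCV (exact profile matches) and per-attribute PCA against known truth."""
    t = np.asarray(alpha_true)
    h = np.asarray(alpha_hat)
    if t.shape != h.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {h.shape}")
    matches = t == h
    return AccuracyBenchmark(
        pcv=float(matches.all(axis=1).mean()),
        pca_k=matches.mean(axis=0),
    )


def rmse(estimates: np.ndarray, benchmark: float) -> float:
    """Root-mean-square deviation of replicate estimates from a benchmark value."""
    e = np.asarray(estimates, dtype=float)
    if e.size == 0:
        raise ValueError("rmse requires at least one replicate")
    return float(np.sqrt(np.mean((e - benchmark) ** 2)))
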