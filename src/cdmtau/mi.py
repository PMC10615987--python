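"""Multiple-imputation correction of classification-accuracy indices.

Posteriors computed at the EM point estimates treat the fitted item
parameters and latent-class distribution as known, so they are too peaked in
finite samples and the tau indices built from them overestimate accuracy.
The correction integrates the model parameters out of the posterior,

    P(alpha_l | x_i) = integral P(alpha_l | x_i, theta) P(theta | X) d theta,

approximating the sampling distribution ``P(theta | X)`` by nonparametric
bootstrap: respondents are resampled with replacement, the same model is
refit, and the (delta_r, pi_r) pair from each refit is kept jointly —
preserving their correlation.  The MI posterior is the average of the ``R``
per-draw posteriors; the tau indices are then recomputed from it while the
classifications stay fixed at the original full-sample EAP estimates (the
correction targets the certainty about those classifications, not the
classifications themselves).

Nonconverged bootstrap refits are discarded and redrawn (at most ``5 R``
attempts in total), so the ensemble always holds ``R`` converged draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .em import EstimationError, fit_em
from .model import Classification, marginal_mastery, posterior
from .params import ItemParamsDINA, ItemParamsGDINA, LatentDist
from .qmatrix import QMatrix
from .reliability import ReliabilityReport, profile_posterior_at, tau, tau_k

__all__ = [
    "BootstrapEnsemble",
    "bootstrap_resample",
    "build_ensemble",
    "mi_posterior",
    "tau_mi",
]

logger = logging.getLogger(__name__)


@dataclass
class BootstrapEnsemble:
    """R jointly-drawn (item parameters, latent distribution) bootstrap refits."""

    params: list  # R ItemParams* objects
    pis: list  # R LatentDist objects
    n_attempts: int  # bootstrap refits attempted, including discarded ones
    seed: int | None = None
    model: str = ""

    @property
    def R(self) -> int:
        return len(self.params)


def bootstrap_resample(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Resample the N respondent rows with replacement."""
    x = np.asarray(x)
    n = x.shape[0]
    if n < 1:
        raise ValueError("cannot resample an empty response matrix")
    return x[rng.integers(0, n, size=n)]


def build_ensemble(
    x: np.ndarray,
    q: QMatrix,
    model: str,
    R: int = 500,
    seed: int | None = None,
    *,
    max_attempts_factor: int = 5,
    **em_options,
) -> BootstrapEnsemble:
    """Refit the model on R bootstrap resamples and collect the converged draws."""
    if R < 1:
        raise ValueError(f"R must be >= 1, got {R}")
    rng = np.random.default_rng(seed)
    params: list = []
    pis: list = []
    attempts = 0
    cap = max_attempts_factor * R
    while len(params) < R:
        if attempts >= cap:
            raise EstimationError(
                f"bootstrap redraw cap exceeded: {attempts} attempts yielded "
                f"only {len(params)}/{R} converged fits"
            )
        attempts += 1
        xb = bootstrap_resample(x, rng)
        try:
            fit = fit_em(xb, q, model, **em_options)
        except EstimationError as err:  # pragma: no cover - defensive
            logger.warning("bootstrap refit %d failed: %s", attempts, err)
            continue
        if not fit.converged:
            logger.info("bootstrap refit %d did not converge; redrawing", attempts)
            continue
        params.append(fit.params)
        pis.append(fit.pi)
    if attempts > R:
        logger.info("bootstrap ensemble needed %d attempts for R=%d", attempts, R)
    return BootstrapEnsemble(
        params=params, pis=pis, n_attempts=attempts, seed=seed, model=model
    )


def mi_posterior(
    x: np.ndarray, ensemble: BootstrapEnsemble, q: QMatrix
) -> np.ndarray:
    """Average the per-draw posteriors: ``(1/R) sum_r P(alpha_l | x_i, theta_r)``."""
    if ensemble.R < 1:
        raise ValueError("ensemble is empty")
    x = np.asarray(x, dtype=float)
    acc = np.zeros((x.shape[0], 2**q.K))
    for p_r, pi_r in zip(ensemble.params, ensemble.pis):
        acc += posterior(x, p_r, pi_r, q)
    return acc / ensemble.R


def tau_mi(
    x: np.ndarray,
    q: QMatrix,
    classification: Classification,
    ensemble: BootstrapEnsemble,
) -> ReliabilityReport:
    """MI-corrected tau and tau_k.

    ``classification`` must come from the original full-sample fit; only the
    posteriors are replaced by their imputation-averaged counterparts.
    """
    post = mi_posterior(x, ensemble, q)
    mastery = marginal_mastery(post, q.profiles)
    return ReliabilityReport(
        tau=tau(profile_posterior_at(post, classification.alpha_hat)),
        tau_k=tau_k(classification.alpha_hat, mastery),
        method="MI",
        extra={"R": ensemble.R, "bootstrap_attempts": ensemble.n_attempts},
    )
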