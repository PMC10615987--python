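"""Monte-Carlo simulation harness for the accuracy indices and their MI correction.

The design emulated here crosses attribute structure (uniform vs
higher-order), fitted/generating model (DINA vs G-DINA), test length
(J = 15 or 30, fixed K = 5 Q-matrices), sample size and item quality
IQ = 1 - P(0) - P(1), where P(0) (guessing) and P(1) (slip) are the success
probabilities of respondents mastering none, respectively all, of an item's
required attributes; P(0) = P(1) = 0.3, 0.2, 0.1 for IQ = 0.4, 0.6, 0.8.

Each replication generates true profiles and item parameters, samples
responses, refits the generating model by EM, classifies by EAP, and computes
the tau indices (point-estimate and MI-corrected) together with the true
accuracy (PCA/PCV) of the classifications.  RMSE of each estimator is taken
against the per-condition mean PCV/PCA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .em import EstimationError, fit_em
from .mi import build_ensemble, tau_mi
from .model import eap_classify, marginal_mastery, posterior
from .params import ItemParamsDINA, ItemParamsGDINA
from .profiles import profile_index
from .qmatrix import QMatrix
from .reliability import (
    profile_posterior_at,
    reliability_report,
    rmse,
    tau,
    true_accuracy,
)

__all__ = [
    "ITEM_QUALITY_LEVELS",
    "HigherOrderSpec",
    "SimCondition",
    "ConditionSummary",
    "builtin_qmatrix",
    "ecpe_qmatrix",
    "gen_attributes_uniform",
    "gen_attributes_higher_order",
    "gen_item_params",
    "gen_responses",
    "run_condition",
    "stability_study",
    "subsample_study",
]

logger = logging.getLogger(__name__)

ITEM_QUALITY_LEVELS = (0.4, 0.6, 0.8)

# 30-item, K=5 simulation Q-matrix; the starred subset forms the J=15 test.
_Q30_ROWS = [
    "10000", "01000", "00100", "00010", "00001",
    "10000", "01000", "00100", "00010", "00001",
    "11000", "10100", "10010", "10001", "01100",
    "01010", "01001", "00110", "00101", "00011",
    "11100", "11010", "11001", "10110", "10101",
    "10011", "01110", "01101", "01011", "00111",
]
_J15_ITEMS = [6, 7, 8, 9, 10, 11, 14, 15, 18, 20, 21, 23, 26, 27, 30]  # 1-based

# 28-item, K=3 Q-matrix of the ECPE grammar section
# (skills: morphosyntactic, cohesive, lexical rules).
_ECPE_ROWS = [
    "110", "010", "101", "001", "001", "001", "101", "010", "001", "100",
    "101", "101", "100", "100", "001", "101", "011", "001", "001", "101",
    "101", "001", "010", "010", "100", "001", "100", "001",
]


def _rows_to_array(rows: list[str]) -> np.ndarray:
    return np.array([[int(c) for c in row] for row in rows], dtype=np.int8)


def builtin_qmatrix(J: int) -> QMatrix:
    """The built-in K=5 simulation Q-matrix for J = 15 or 30 items."""
    if J not in (15, 30):
        raise ValueError(f"built-in Q-matrices exist for J in {{15, 30}}, got {J}")
    q = _rows_to_array(_Q30_ROWS)
    if J == 15:
        q = q[[j - 1 for j in _J15_ITEMS]]
    return QMatrix(q)


def ecpe_qmatrix() -> QMatrix:
    """The 28 x 3 Q-matrix of the ECPE grammar section."""
    return QMatrix(_rows_to_array(_ECPE_ROWS))


@dataclass
class HigherOrderSpec:
    """2PL link from a common latent trait theta ~ N(0,1) to each attribute.

    The defaults (a_k = 1.5, b_k = 0) give every attribute an expected
    prevalence of 0.5 and pairwise attribute correlations around 0.3.
    """

    a: float = 1.5
    b: float = 0.0


@dataclass
class SimCondition:
    """One between-group cell of the simulation design."""

    structure: str = "uniform"  # "uniform" | "higher-order"
    model: str = "dina"  # "dina" | "gdina"
    J: int = 15
    N: int = 100
    iq: float = 0.4
    reps: int = 100
    K: int = 5

    def __post_init__(self) -> None:
        if self.structure not in ("uniform", "higher-order"):
            raise ValueError(f"unknown attribute structure {self.structure!r}")
        if self.model.lower() not in ("dina", "gdina"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.iq not in ITEM_QUALITY_LEVELS:
            raise ValueError(
                f"item quality must be one of {ITEM_QUALITY_LEVELS}, got {self.iq}"
            )


@dataclass
class ConditionSummary:
    """Aggregated results of one simulated condition."""

    condition: SimCondition
    records: pd.DataFrame  # one row per successful replication
    mean_pcv: float
    mean_pca: np.ndarray
    mean_tau_em: float
    mean_tau_mi: float
    mean_tau_k_em: np.ndarray
    mean_tau_k_mi: np.ndarray
    rmse_tau_em: float
    rmse_tau_mi: float
    rmse_tau_k_em: float
    rmse_tau_k_mi: float
    mae_tau_em: float
    mae_tau_mi: float
    n_failed: int = 0
    extra: dict = field(default_factory=dict)


def _child_seeds(seed: int | None, n: int) -> list[int]:
    """Derive n reproducible 31-bit child seeds from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in ss.spawn(n)]


def gen_attributes_uniform(N: int, K: int, seed=None) -> np.ndarray:
    """Independent Bernoulli(0.5) attributes: all 2**K profiles equiprobable."""
    if N < 0:
        raise ValueError(f"N must be >= 0, got {N}")
    rng = np.random.default_rng(seed)
    return (rng.random((N, K)) < 0.5).astype(np.int8)


def gen_attributes_higher_order(
    N: int, K: int, spec: HigherOrderSpec | None = None, seed=None
) -> np.ndarray:
    """Attributes linked to a common trait by a 2PL model.

    theta_i ~ N(0,1); alpha_ik ~ Bernoulli(1 / (1 + exp(-a_k (theta_i - b_k)))).
    """
    if N < 0:
        raise ValueError(f"N must be >= 0, got {N}")
    spec = spec or HigherOrderSpec()
    rng = np.random.default_rng(seed)
    theta = rng.standard_normal(N)
    prob = 1.0 / (1.0 + np.exp(-spec.a * (theta[:, None] - spec.b)))
    return (rng.random((N, K)) < prob).astype(np.int8)


def _dominance_pairs(kstar: int) -> list[tuple[int, int]]:
    """All strict subset pairs (c, c') of reduced-profile indices."""
    pairs = []
    for c in range(2**kstar):
        for c2 in range(2**kstar):
            if c != c2 and (c & c2) == c:
                pairs.append((c, c2))
    return pairs


def gen_item_params(
    model: str, q: QMatrix, iq: float, seed=None
) -> ItemParamsDINA | ItemParamsGDINA:
    """Draw generating item parameters at a given item quality.

    The endpoint probabilities are fixed by design: P(0) = (1 - IQ)/2 for the
    all-zero reduced profile and 1 - P(1) = (1 + IQ)/2 for the all-one one.
    DINA items have only those two parameters (g = P(0), s = P(1)).  G-DINA
    interior reduced-class probabilities are uniform on (P(0), 1 - P(1)),
    accepted only if strictly increasing along the componentwise dominance
    order of reduced profiles (rejection sampling), e.g.
    P(1,1) > P(1,0) > P(0,0).
    """
    if iq not in ITEM_QUALITY_LEVELS:
        raise ValueError(f"item quality must be one of {ITEM_QUALITY_LEVELS}, got {iq}")
    lo = (1.0 - iq) / 2.0
    hi = 1.0 - lo
    model = model.lower()
    if model == "dina":
        return ItemParamsDINA(np.full(q.J, lo), np.full(q.J, lo))
    if model != "gdina":
        raise ValueError(f"unknown model {model!r}")
    rng = np.random.default_rng(seed)
    tables = []
    for j in range(q.J):
        size = 2 ** int(q.kstar[j])
        pairs = [
            (c, c2) for c, c2 in _dominance_pairs(int(q.kstar[j]))
        ]
        t = np.empty(size)
        t[0], t[-1] = lo, hi
        while True:
            t[1:-1] = rng.uniform(lo, hi, size=max(size - 2, 0))
            if all(t[c] < t[c2] for c, c2 in pairs):
                break
        tables.append(t.copy())
    return ItemParamsGDINA(tables)


def gen_responses(
    alpha_true: np.ndarray,
    params: ItemParamsDINA | ItemParamsGDINA,
    q: QMatrix,
    seed=None,
) -> np.ndarray:
    """Sample binary responses x_ij ~ Bernoulli(P(x=1 | alpha_i, delta_j))."""
    rng = np.random.default_rng(seed)
    table = params.success_table(q)  # (J, L)
    cls = profile_index(np.asarray(alpha_true))
    probs = table[:, cls].T  # (N, J)
    return (rng.random(probs.shape) < probs).astype(np.int8)


def simulate_dataset(
    cond: SimCondition, seed=None
) -> tuple[np.ndarray, np.ndarray, ItemParamsDINA | ItemParamsGDINA, QMatrix]:
    """Generate one dataset under a design cell: (responses, true profiles, params, Q)."""
    q = builtin_qmatrix(cond.J)
    s_attr, s_par, s_resp = _child_seeds(seed, 3)
    if cond.structure == "uniform":
        alpha = gen_attributes_uniform(cond.N, cond.K, seed=s_attr)
    else:
        alpha = gen_attributes_higher_order(cond.N, cond.K, seed=s_attr)
    params = gen_item_params(cond.model, q, cond.iq, seed=s_par)
    x = gen_responses(alpha, params, q, seed=s_resp)
    return x, alpha, params, q


def run_condition(
    cond: SimCondition,
    R_boot: int = 100,
    seed: int | None = None,
    **em_options,
) -> ConditionSummary:
    """Run all replications of one design cell and aggregate.

    ``R_boot = 0`` skips the MI correction (its summaries become NaN), which
    is useful when only the point-estimate indices or the true accuracy are
    needed.
    """
    q = builtin_qmatrix(cond.J)
    K = cond.K
    rep_seeds = _child_seeds(seed, cond.reps)
    rows = []
    n_failed = 0
    for r, rep_seed in enumerate(rep_seeds):
        data_seed, boot_seed = _child_seeds(rep_seed, 2)
        x, alpha_true, _, _ = simulate_dataset(cond, seed=data_seed)
        try:
            fit = fit_em(x, q, cond.model, **em_options)
        except EstimationError as err:
            logger.warning("replication %d failed: %s", r, err)
            n_failed += 1
            continue
        mastery = marginal_mastery(fit.posteriors, q.profiles)
        cls = eap_classify(mastery)
        em_rep = reliability_report(fit.posteriors, cls, method="EM")
        bench = true_accuracy(alpha_true, cls.alpha_hat)
        row = {
            "rep": r,
            "pcv": bench.pcv,
            "tau_em": em_rep.tau,
            "em_iters": fit.n_iter,
            "em_converged": fit.converged,
        }
        row.update({f"pca_{k + 1}": bench.pca_k[k] for k in range(K)})
        row.update({f"tau_k_em_{k + 1}": em_rep.tau_k[k] for k in range(K)})
        if R_boot > 0:
            try:
                ens = build_ensemble(
                    x, q, cond.model, R=R_boot, seed=boot_seed, **em_options
                )
            except EstimationError as err:
                logger.warning("replication %d bootstrap failed: %s", r, err)
                n_failed += 1
                continue
            mi_rep = tau_mi(x, q, cls, ens)
            row["tau_mi"] = mi_rep.tau
            row.update({f"tau_k_mi_{k + 1}": mi_rep.tau_k[k] for k in range(K)})
            row["boot_attempts"] = ens.n_attempts
        else:
            row["tau_mi"] = np.nan
            row.update({f"tau_k_mi_{k + 1}": np.nan for k in range(K)})
        rows.append(row)
        logger.info("replication %d/%d done", r + 1, cond.reps)
    records = pd.DataFrame(rows)
    if records.empty:
        raise EstimationError("all replications failed")

    mean_pcv = float(records["pcv"].mean())
    mean_pca = records[[f"pca_{k + 1}" for k in range(K)]].mean().to_numpy()
    tau_em_vals = records["tau_em"].to_numpy()
    tau_mi_vals = records["tau_mi"].to_numpy()
    have_mi = R_boot > 0

    def _avg_rmse_k(prefix: str) -> float:
        vals = [
            rmse(records[f"{prefix}{k + 1}"].to_numpy(), mean_pca[k])
            for k in range(K)
        ]
        return float(np.mean(vals))

    return ConditionSummary(
        condition=cond,
        records=records,
        mean_pcv=mean_pcv,
        mean_pca=mean_pca,
        mean_tau_em=float(tau_em_vals.mean()),
        mean_tau_mi=float(tau_mi_vals.mean()) if have_mi else float("nan"),
        mean_tau_k_em=records[[f"tau_k_em_{k + 1}" for k in range(K)]]
        .mean()
        .to_numpy(),
        mean_tau_k_mi=records[[f"tau_k_mi_{k + 1}" for k in range(K)]]
        .mean()
        .to_numpy(),
        rmse_tau_em=rmse(tau_em_vals, mean_pcv),
        rmse_tau_mi=rmse(tau_mi_vals, mean_pcv) if have_mi else float("nan"),
        rmse_tau_k_em=_avg_rmse_k("tau_k_em_"),
        rmse_tau_k_mi=_avg_rmse_k("tau_k_mi_") if have_mi else float("nan"),
        mae_tau_em=float(np.abs(tau_em_vals - mean_pcv).mean()),
        mae_tau_mi=float(np.abs(tau_mi_vals - mean_pcv).mean())
        if have_mi
        else float("nan"),
        n_failed=n_failed,
        extra={"R_boot": R_boot, "seed": seed},
    )


def stability_study(
    x: np.ndarray,
    q: QMatrix,
    model: str,
    R_grid=(100,),
    n_repeat: int = 50,
    seed: int | None = None,
    **em_options,
) -> pd.DataFrame:
    """Repeat the MI tau estimate with fresh bootstrap seeds for each R.

    Returns a long DataFrame (columns ``R``, ``repeat``, ``tau_mi``); the
    Monte-Carlo SD per R is ``df.groupby("R")["tau_mi"].std()``.
    """
    if n_repeat < 2:
        raise ValueError(f"n_repeat must be >= 2, got {n_repeat}")
    fit = fit_em(x, q, model, **em_options)
    cls = eap_classify(marginal_mastery(fit.posteriors, q.profiles))
    seeds = _child_seeds(seed, len(R_grid) * n_repeat)
    rows = []
    i = 0
    for R in R_grid:
        for t in range(n_repeat):
            ens = build_ensemble(x, q, model, R=R, seed=seeds[i], **em_options)
            rows.append({"R": R, "repeat": t, "tau_mi": tau_mi(x, q, cls, ens).tau})
            i += 1
        logger.info("stability study: R=%d done", R)
    return pd.DataFrame(rows)


def subsample_study(
    x_full: np.ndarray,
    q: QMatrix,
    model: str,
    sizes,
    reps: int = 100,
    R_boot: int = 100,
    seed: int | None = None,
    **em_options,
) -> pd.DataFrame:
    """Study sample-size effects by subsampling a real dataset without replacement.

    For each subsample the model is refit and tau is computed with EM point
    estimates and (if ``R_boot > 0``) with the MI correction.  The benchmark
    column evaluates the posterior of the subsample's estimated profiles under
    the full-sample parameter estimates, an approximation to their true
    accuracy when the full sample is large enough to pin the parameters down.
    """
    x_full = np.asarray(x_full)
    n_full = x_full.shape[0]
    sizes = list(sizes)
    if max(sizes) > n_full:
        raise ValueError(f"subsample size {max(sizes)} exceeds N={n_full}")
    full_fit = fit_em(x_full, q, model, **em_options)
    rng = np.random.default_rng(seed)
    boot_seeds = _child_seeds(seed, len(sizes) * reps)
    rows = []
    i = 0
    for size in sizes:
        for r in range(reps):
            idx = rng.choice(n_full, size=size, replace=False)
            xs = x_full[idx]
            fit = fit_em(xs, q, model, **em_options)
            cls = eap_classify(marginal_mastery(fit.posteriors, q.profiles))
            row = {
                "size": size,
                "rep": r,
                "tau_em": tau(profile_posterior_at(fit.posteriors, cls.alpha_hat)),
            }
            post_full = posterior(xs, full_fit.params, full_fit.pi, q)
            row["benchmark"] = tau(profile_posterior_at(post_full, cls.alpha_hat))
            if R_boot > 0:
                ens = build_ensemble(
                    xs, q, model, R=R_boot, seed=boot_seeds[i], **em_options
                )
                row["tau_mi"] = tau_mi(xs, q, cls, ens).tau
            i += 1
            rows.append(row)
        logger.info("subsample study: size=%d done", size)
    return pd.DataFrame(rows)
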