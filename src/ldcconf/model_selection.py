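"""Comparing candidate confidence models.

Per participant and candidate, goodness of fit is summarized by a BIC
computed from the sum of squared proportion errors under a Gaussian
residual assumption:

    BIC = k * ln(n) + n * ln(SSE / n)

Candidates are compared by mean BIC distance from the best model, by
bootstrap distributions of the confidence contrast (mean confidence in the
pooled baseline-and-plus conditions minus the minus condition, separately
for corrects and errors), and at the group level by random-effects Bayesian
model selection: a variational Dirichlet posterior over model frequencies,
exceedance probabilities estimated from Dirichlet draws, and the Bayesian
omnibus risk (posterior probability that all models are equally frequent).
Model evidence per participant and candidate is taken as -BIC/2.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, logsumexp

from .ddm import simulate_dataset
from .fitting import FitResult

__all__ = [
    "bic",
    "bic_weights_log_evidence",
    "delta_bic_table",
    "confidence_contrast",
    "bootstrap_contrasts",
    "rfx_bms",
]

CONTRAST_CONDITIONS = ("minus", "baseline", "plus")


def bic(sse: float, k: int, n: int) -> float:
    """BIC from a least-squares fit with Gaussian residuals."""
    if n <= 0:
        raise ValueError("n must be > 0")
    if k < 0:
        raise ValueError("k must be >= 0")
    if sse <= 0:
        raise ValueError("sse must be > 0 (an exactly saturated fit has no BIC)")
    return k * math.log(n) + n * math.log(sse / n)


def bic_weights_log_evidence(bic_values) -> np.ndarray:
    """Per-model log evidence under the BIC-weight convention, -BIC/2."""
    return -0.5 * np.asarray(bic_values, dtype=float)


def delta_bic_table(bic_matrix: pd.DataFrame) -> pd.Series:
    """Mean BIC per candidate minus the minimum mean BIC (best shows 0).

    ``bic_matrix`` is participants x candidates; missing cells are an error
    because every participant must contribute to every candidate's mean.
    """
    if bic_matrix.isna().any().any():
        raise ValueError("bic_matrix has missing cells")
    mean = bic_matrix.mean(axis=0)
    return mean - mean.min()


def confidence_contrast(
    trials: pd.DataFrame, value_col: str = "rating"
) -> tuple[float, float, float]:
    """(contrast_correct, contrast_error, interaction).

    contrast_k = mean confidence over {baseline, plus} trials of accuracy k
    minus the mean over minus-condition trials of accuracy k; the
    interaction is the correct-trial contrast minus the error-trial one.
    """
    present = set(trials["condition"].unique())
    missing = set(CONTRAST_CONDITIONS) - present
    if missing:
        raise ValueError(f"missing conditions: {sorted(missing)}")
    out = []
    for k in (1, 0):
        sub = trials[trials["accuracy"] == k]
        pooled = sub.loc[sub["condition"].isin(("baseline", "plus")), value_col]
        minus = sub.loc[sub["condition"] == "minus", value_col]
        if len(pooled) == 0 or len(minus) == 0:
            raise ValueError("both accuracy classes must be present in all conditions")
        out.append(float(pooled.mean() - minus.mean()))
    return out[0], out[1], out[0] - out[1]


def bootstrap_contrasts(
    fit: FitResult,
    observed: pd.DataFrame,
    reps: int = 500,
    rng: np.random.Generator | None = None,
    value_col: str = "rating",
) -> dict:
    """Bootstrap distribution of the confidence contrasts under the fit.

    Simulates ``reps`` datasets of the observed design (conditions,
    difficulty mix, confidence-RT pool) from the fitted parameters and
    computes the mean contrasts of each replicate.  Returns the replicate
    arrays and their (.025, .975) quantiles, taken as order statistics
    (inverted-CDF convention).
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    if rng is None:
        rng = np.random.default_rng()
    missing = set(CONTRAST_CONDITIONS) - set(fit.ldc_by_condition)
    if missing:
        raise ValueError(f"fit lacks conditions: {sorted(missing)}")
    design = (
        observed.groupby(["condition", "difficulty"]).size().rename("n").reset_index()
    )
    conf_rt_pool = observed["confidence_rt"].to_numpy(float)
    draws = np.empty((reps, 3))
    for r in range(reps):
        table = simulate_dataset(
            fit.ddm,
            fit.ldc_by_condition,
            design,
            conf_rt_source=conf_rt_pool,
            rng=rng,
        )
        draws[r] = confidence_contrast(table, value_col=value_col)
    ci = np.quantile(draws, [0.025, 0.975], axis=0, method="inverted_cdf")
    return {
        "contrast_correct": draws[:, 0],
        "contrast_error": draws[:, 1],
        "interaction": draws[:, 2],
        "ci": {
            "contrast_correct": tuple(ci[:, 0]),
            "contrast_error": tuple(ci[:, 1]),
            "interaction": tuple(ci[:, 2]),
        },
    }


def _dirichlet_free_energy(log_ev, alpha, u, alpha0):
    """Variational free energy of the random-effects model at convergence."""
    a_sum = alpha.sum()
    k = len(alpha)
    f = float(np.sum(u * (log_ev - np.log(np.maximum(u, 1e-300)))))
    f += gammaln(k * alpha0) - k * gammaln(alpha0)
    f += float(np.sum(gammaln(alpha))) - gammaln(a_sum)
    # at the fixed point sum_n u_nk = alpha_k - alpha0, so the digamma terms
    # of the expected log-joint and the Dirichlet KL cancel exactly
    return f


def rfx_bms(
    log_evidence,
    alpha0: float = 1.0,
    n_draws: int = 100_000,
    tol: float = 1e-6,
    max_iter: int = 10_000,
    rng: np.random.Generator | None = None,
) -> dict:
    """Random-effects Bayesian model selection over candidates.

    ``log_evidence`` is participants x candidates (use -BIC/2).  Returns the
    Dirichlet parameters, expected model frequencies, exceedance
    probabilities (P(model m is the most frequent), by Monte Carlo over the
    Dirichlet posterior) and the Bayesian omnibus risk (posterior
    probability of the equal-frequency null against the frequency model).
    """
    log_ev = np.asarray(log_evidence, dtype=float)
    if log_ev.ndim != 2 or log_ev.shape[1] < 2:
        raise ValueError("log_evidence must be participants x (>=2) candidates")
    if not np.all(np.isfinite(log_ev)):
        raise ValueError("log evidences must be finite")
    if rng is None:
        rng = np.random.default_rng()
    n_sub, n_mod = log_ev.shape

    alpha = np.full(n_mod, alpha0, dtype=float)
    u = np.full((n_sub, n_mod), 1.0 / n_mod)
    for _ in range(max_iter):
        w = log_ev + digamma(alpha) - digamma(alpha.sum())
        u = np.exp(w - logsumexp(w, axis=1, keepdims=True))
        new_alpha = alpha0 + u.sum(axis=0)
        if np.max(np.abs(new_alpha - alpha)) < tol:
            alpha = new_alpha
            break
        alpha = new_alpha

    freq = alpha / alpha.sum()
    draws = rng.dirichlet(alpha, size=n_draws)
    ep = np.bincount(np.argmax(draws, axis=1), minlength=n_mod) / n_draws

    f1 = _dirichlet_free_energy(log_ev, alpha, u, alpha0)
    f0 = float(np.sum(logsumexp(log_ev, axis=1) - math.log(n_mod)))
    bor = 1.0 / (1.0 + math.exp(f1 - f0))
    return {
        "alpha": alpha,
        "frequencies": freq,
        "exceedance_probabilities": ep,
        "bor": bor,
    }
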