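"""Confidence readouts: Bayesian posterior, logistic approximation, heatmaps.

Under the drift-diffusion model with a symmetric prior over the drift sign,
the posterior probability that the chosen option is correct given accumulated
evidence ``e`` and accumulation time ``t`` is ``Phi(e / (sigma * sqrt(t)))``
(flat prior over drift magnitude) or a discrete Gaussian mixture over the
task's drift levels.  The low-dimensional confidence (LDC) model replaces the
probit readout with a two-parameter logistic:

    conf = 1 / (1 + exp(-(x * alpha * e + beta) / t**gamma))

which reduces to the probit approximation exactly at ``alpha = lam / sigma``,
``beta = 0`` (with ``lam ~ 1.7`` the classical logistic-probit constant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit, ndtr
from sklearn.base import BaseEstimator, RegressorMixin

from .params import LAMBDA_DEFAULT, SIGMA_DEFAULT, LDCParams

__all__ = [
    "bayes_p_correct",
    "logistic_probit_approx",
    "fit_lambda",
    "ldc_confidence",
    "ratings_from_confidence",
    "bayes_readout_mixture",
    "HeatMap",
    "build_heatmap",
    "fit_ldc_to_posterior",
    "LDCPosteriorRegressor",
]


def _check_time(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("elapsed time must be > 0")
    return t


def bayes_p_correct(e, t, sigma: float = SIGMA_DEFAULT, gamma: float = 0.5):
    """Posterior probability of a positive drift given evidence and time,
    ``Phi(e / (sigma * t**gamma))``.  ``gamma=0.5`` is the flat-prior Wiener
    posterior; it is exposed to support time-weighting variants."""
    t = _check_time(t)
    if not sigma > 0:
        raise ValueError("sigma must be > 0")
    return ndtr(np.asarray(e, dtype=float) / (sigma * t**gamma))


def logistic_probit_approx(z, lam: float = LAMBDA_DEFAULT):
    """Logistic approximation of the standard normal CDF, ``1/(1+exp(-lam*z))``."""
    if not lam > 0:
        raise ValueError("lam must be > 0")
    return expit(lam * np.asarray(z, dtype=float))


def fit_lambda(
    interval: tuple[float, float] = (1.5, 2.0),
    lam_step: float = 1e-4,
    z_max: float = 10.0,
    z_step: float = 1e-3,
) -> tuple[float, float]:
    """Grid-search the constant minimizing ``max_z |Phi(z) - logistic(lam*z)|``.

    Both functions satisfy ``f(-z) = 1 - f(z)``, so the deviation is even in
    ``z`` and the search can run on ``z >= 0``.  The deviation is unimodal
    in lambda, so a coarse pass brackets the minimum and a fine pass at
    ``lam_step`` inside the bracket returns the same grid argmin as the
    exhaustive scan, in a fraction of the time.  Returns ``(lam_star,
    max_deviation)``.
    """
    lo, hi = interval
    if not hi > lo:
        raise ValueError("empty search interval")
    z = np.arange(0.0, z_max + z_step / 2, z_step)
    phi = ndtr(z)

    def scan(lams):
        best_lam, best_dev = float("nan"), np.inf
        # chunk over lambda to bound memory at ~tens of MB
        for i in range(0, len(lams), 256):
            chunk = lams[i : i + 256]
            dev = np.abs(phi[None, :] - expit(chunk[:, None] * z[None, :])).max(axis=1)
            j = int(np.argmin(dev))
            if dev[j] < best_dev:
                best_dev = float(dev[j])
                best_lam = float(chunk[j])
        return best_lam, best_dev

    full = np.arange(lo, hi + lam_step / 2, lam_step)
    coarse_stride = max(len(full) // 100, 1)
    lam_c, _ = scan(full[::coarse_stride])
    half = (coarse_stride + 1) * lam_step
    fine = full[(full >= lam_c - 2 * half) & (full <= lam_c + 2 * half)]
    return scan(fine)


def ldc_confidence(e, t, x, params: LDCParams):
    """Low-dimensional confidence for evidence ``e``, elapsed time ``t`` and
    choice ``x`` (+1/-1): ``sigmoid((x * alpha * e + beta) / t**gamma)``.

    Monotone increasing in ``x*e``, in ``alpha`` (for ``x*e > 0``) and in
    ``beta``; the influence of ``beta`` fades as ``t`` grows.
    """
    t = _check_time(t)
    x = np.asarray(x)
    if not np.all(np.isin(x, (-1, 1))):
        raise ValueError("choice x must be +1 or -1")
    num = x * params.alpha * np.asarray(e, dtype=float) + params.beta
    return expit(num / t**params.gamma)


def ratings_from_confidence(conf, n_levels: int = 6) -> np.ndarray:
    """Bin confidence in [0, 1] into ``n_levels`` equal-width ratings
    (1..n_levels, right-closed at 1)."""
    conf = np.asarray(conf, dtype=float)
    return np.clip(np.ceil(conf * n_levels), 1, n_levels).astype(np.int64)


def bayes_readout_mixture(
    e,
    t,
    drift_rates,
    sigma: float = SIGMA_DEFAULT,
    prior=None,
):
    """Posterior that the drift sign matches a choice toward positive ``e``,
    under equiprobable signed drifts at known magnitudes:

        p = sum_i pi_i N(e; v_i t, sigma^2 t)
            / sum_i pi_i [N(e; v_i t, sigma^2 t) + N(e; -v_i t, sigma^2 t)]

    Computed on log densities for numerical stability.
    """
    t = _check_time(t)
    e = np.asarray(e, dtype=float)
    v = np.asarray(drift_rates, dtype=float)
    if prior is None:
        prior = np.full(len(v), 1.0 / len(v))
    prior = np.asarray(prior, dtype=float)
    if prior.shape != v.shape or np.any(prior < 0) or not np.isclose(prior.sum(), 1.0):
        raise ValueError("prior must be nonnegative weights over difficulties summing to 1")
    # log N(e; +-v t, sigma^2 t) up to a shared constant
    var = sigma**2 * t
    e_b = e[..., None]
    t_b = t[..., None] if t.ndim else t
    var_b = np.asarray(var)[..., None] if np.ndim(var) else var
    log_pos = -((e_b - v * t_b) ** 2) / (2 * var_b) + np.log(prior)
    log_neg = -((e_b + v * t_b) ** 2) / (2 * var_b) + np.log(prior)
    m = np.maximum(log_pos.max(axis=-1), log_neg.max(axis=-1))[..., None]
    num = np.exp(log_pos - m).sum(axis=-1)
    den = num + np.exp(log_neg - m).sum(axis=-1)
    return num / den


@dataclass(frozen=True)
class HeatMap:
    """Empirical p(correct) over the folded (evidence, time) plane."""

    evidence_edges: np.ndarray
    time_edges: np.ndarray
    p_correct: np.ndarray  # NaN where counts < min_count
    counts: np.ndarray
    min_count: int

    def to_frame(self) -> pd.DataFrame:
        """Long-format serialization: one row per cell."""
        ei, ti = np.meshgrid(
            np.arange(len(self.evidence_edges) - 1),
            np.arange(len(self.time_edges) - 1),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "e_low": self.evidence_edges[ei.ravel()],
                "e_high": self.evidence_edges[ei.ravel() + 1],
                "t_low": self.time_edges[ti.ravel()],
                "t_high": self.time_edges[ti.ravel() + 1],
                "p_correct": self.p_correct.ravel(),
                "count": self.counts.ravel().astype(int),
            }
        )


def build_heatmap(
    trials: pd.DataFrame,
    evidence_edges=None,
    time_edges=None,
    min_count: int = 50,
    n_bins: int = 50,
) -> HeatMap:
    """Empirical fraction correct per (evidence, time) cell.

    Trials are folded into the frame of the chosen option (evidence
    multiplied by the choice sign) so one half-plane summarizes both
    choices; the time axis is accumulation time.  Cells with fewer than
    ``min_count`` trials are undefined (NaN).
    """
    e = (trials["evidence_total"] * trials["choice"]).to_numpy(dtype=float)
    t = trials["acc_time"].to_numpy(dtype=float)
    acc = trials["accuracy"].to_numpy(dtype=float)
    if evidence_edges is None:
        evidence_edges = np.linspace(e.min(), e.max(), n_bins + 1)
    if time_edges is None:
        time_edges = np.linspace(t.min(), t.max(), n_bins + 1)
    evidence_edges = np.asarray(evidence_edges, dtype=float)
    time_edges = np.asarray(time_edges, dtype=float)
    if np.any(np.diff(evidence_edges) <= 0) or np.any(np.diff(time_edges) <= 0):
        raise ValueError("heatmap edges must be strictly increasing")
    counts, _, _ = np.histogram2d(e, t, bins=[evidence_edges, time_edges])
    hits, _, _ = np.histogram2d(e, t, bins=[evidence_edges, time_edges], weights=acc)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = hits / counts
    p[counts < min_count] = np.nan
    if np.all(np.isnan(p)):
        raise ValueError("all heatmap cells are below min_count")
    return HeatMap(evidence_edges, time_edges, p, counts, min_count)


def fit_ldc_to_posterior(
    evidence_signed,
    t,
    targets,
    gamma: float = 0.5,
    clip: float = 1e-6,
) -> tuple[float, float]:
    """Least-squares fit of (alpha, beta) to posterior targets.

    On the logit scale the model is linear in its parameters:
    ``logit(target) * t**gamma = alpha * (x*e) + beta``; the exact
    normal-equation solution is returned.  Targets are clipped away from
    {0, 1} so the logit is finite.
    """
    u = np.asarray(evidence_signed, dtype=float)
    t = _check_time(t)
    y = logit(np.clip(np.asarray(targets, dtype=float), clip, 1 - clip)) * t**gamma
    if u.size < 2 or np.ptp(u) == 0:
        raise ValueError("need >= 2 distinct signed-evidence points")
    X = np.column_stack([u, np.ones_like(u)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(coef[0]), float(coef[1])


class LDCPosteriorRegressor(RegressorMixin, BaseEstimator):
    """Fit the logistic confidence mapping to posterior-probability targets.

    A scikit-learn style estimator: ``X`` has two columns, signed evidence
    ``x*e`` and elapsed time ``t``; ``y`` holds posterior probabilities in
    (0, 1).  The fit is an exact linear solve on the logit scale.

    Attributes
    ----------
    alpha_, beta_ : float
        Fitted reliability weight and bias.
    """

    def __init__(self, gamma: float = 0.5, clip: float = 1e-6):
        self.gamma = gamma
        self.clip = clip

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have columns [signed_evidence, time]")
        self.alpha_, self.beta_ = fit_ldc_to_posterior(
            X[:, 0], X[:, 1], y, gamma=self.gamma, clip=self.clip
        )
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        params = LDCParams(alpha=max(self.alpha_, 0.0), beta=self.beta_, gamma=self.gamma)
        # X already carries signed evidence; evaluate in the chosen frame.
        return ldc_confidence(X[:, 0], X[:, 1], np.ones(len(X), dtype=int), params)
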