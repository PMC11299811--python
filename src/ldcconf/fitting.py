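"""Fitting the decision model and confidence mapping to trial tables.

The objective is quantile-proportion least squares: observed and predicted
trials are cross-classified by accuracy and six RT groups (bounded by the
.1/.3/.5/.7/.9 RT quantiles of the observed data, per accuracy class), and
by accuracy and six confidence levels.  The objective is

    SSE = sum_k sum_i (oRT_ik - pRT_ik)^2 + sum_j (oCJ_jk - pCJ_jk)^2

over k in {errors, corrects}.  Proportions are joint over (accuracy x
group), so accuracy itself constrains the fit.  Predictions come from
simulating ``oversample`` times the observed trial count, with each
observed confidence RT reused exactly ``oversample`` times as a
post-decision duration.

Minimization uses differential evolution (rand/1/bin, F=0.8, CR=0.9,
population 10x the number of free parameters, stop after 100 generations
without improvement).  All candidate vectors are evaluated on common random
numbers — one noise pool fixed per fit — so the objective is a
deterministic function of the parameters.  After the global search, the
parameters that do not require re-simulation (non-decision time and the
confidence parameters) are refined by a Nelder-Mead pass on the cached
simulation.

:class:`DDMConfidenceModel` is a scikit-learn style estimator around this
machinery; :func:`fit_participant` and :func:`two_stage_fit` are thin
functional wrappers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit
from scipy.stats import qmc
from sklearn.base import BaseEstimator

from ._kernels import walk_first_passage_pool
from .confidence import bayes_readout_mixture, ratings_from_confidence
from .ddm import MAX_TRIAL_DURATION, post_decision_evidence, simulate_decisions
from .params import DDMParams, LDCParams, SIGMA_DEFAULT

__all__ = [
    "RT_QUANTILES",
    "TrialSummary",
    "summarize",
    "predict_summary",
    "sse",
    "FitConfig",
    "ModelVariant",
    "VARIANTS",
    "FitResult",
    "DDMConfidenceModel",
    "fit_participant",
    "two_stage_fit",
    "ez_estimates",
]

RT_QUANTILES = (0.1, 0.3, 0.5, 0.7, 0.9)
N_LEVELS = 6


# ---------------------------------------------------------------------------
# summaries


@dataclass
class TrialSummary:
    """Joint (accuracy x RT-group) and (accuracy x confidence-level)
    proportions; row 0 = errors, row 1 = corrects."""

    rt_props: np.ndarray
    conf_props: np.ndarray
    rt_cutoffs: tuple
    n_trials: int


def _rt_group_props(rt, acc, cutoffs, n_total):
    props = np.zeros((2, N_LEVELS))
    for k in (0, 1):
        sel = acc == k
        if not np.any(sel):
            continue
        cuts = cutoffs[k]
        if cuts is None:
            # observed class was empty: no cutoffs exist; spread this mass
            # evenly so it is still penalized against the zero observation
            props[k, :] = np.sum(sel) / n_total / N_LEVELS
            continue
        grp = np.searchsorted(cuts, rt[sel], side="left")
        props[k, :] = np.bincount(grp, minlength=N_LEVELS) / n_total
    return props


def _conf_level_props(rating, acc, n_total):
    props = np.zeros((2, N_LEVELS))
    for k in (0, 1):
        sel = acc == k
        if np.any(sel):
            props[k, :] = (
                np.bincount(rating[sel] - 1, minlength=N_LEVELS) / n_total
            )
    return props


def summarize(trials: pd.DataFrame, cutoffs=None) -> TrialSummary:
    """Summarize a trial table into the proportions the objective matches.

    When ``cutoffs`` is None the RT quantiles are computed from ``trials``
    itself, separately for corrects and errors; an accuracy class with no
    trials gets undefined cutoffs (None) and zero proportions.
    """
    if len(trials) == 0:
        raise ValueError("cannot summarize an empty trial table")
    rating = trials["rating"].to_numpy(dtype=np.int64)
    if rating.min() < 1 or rating.max() > N_LEVELS:
        raise ValueError("ratings must be integers in 1..6")
    acc = trials["accuracy"].to_numpy(dtype=np.int64)
    rt = trials["decision_rt"].to_numpy(dtype=float)
    n = len(trials)
    if cutoffs is None:
        cutoffs = tuple(
            np.quantile(rt[acc == k], RT_QUANTILES) if np.any(acc == k) else None
            for k in (0, 1)
        )
    return TrialSummary(
        rt_props=_rt_group_props(rt, acc, cutoffs, n),
        conf_props=_conf_level_props(rating, acc, n),
        rt_cutoffs=tuple(cutoffs),
        n_trials=n,
    )


def sse(observed: TrialSummary, predicted: TrialSummary) -> float:
    """Sum of squared proportion errors over RT groups and confidence levels."""
    if (
        observed.rt_props.shape != predicted.rt_props.shape
        or observed.conf_props.shape != predicted.conf_props.shape
    ):
        raise ValueError("summary shapes do not match")
    return float(
        np.sum((observed.rt_props - predicted.rt_props) ** 2)
        + np.sum((observed.conf_props - predicted.conf_props) ** 2)
    )


def predict_summary(
    ddm: DDMParams,
    ldc: LDCParams,
    observed: pd.DataFrame,
    oversample: int = 20,
    rng: np.random.Generator | None = None,
    time_basis: str = "accumulation",
) -> TrialSummary:
    """Model-predicted summary for the design of ``observed``.

    Simulates ``oversample`` times the observed trial count; each observed
    trial's difficulty, stimulus side and confidence RT are replicated
    exactly ``oversample`` times (sampling without replacement), and
    proportions are computed against the observed RT cutoffs.
    """
    if rng is None:
        rng = np.random.default_rng()
    if oversample < 1:
        raise ValueError("oversample must be >= 1")
    if "confidence_rt" not in observed or observed["confidence_rt"].isna().any():
        raise ValueError("observed table must provide confidence RTs")
    obs_sum = summarize(observed)

    difficulty = np.repeat(observed["difficulty"].to_numpy(np.int64), oversample)
    stim_sign = np.repeat(observed["stim_sign"].to_numpy(np.int64), oversample)
    conf_rt = np.repeat(observed["confidence_rt"].to_numpy(float), oversample)

    choice, steps = simulate_decisions(ddm, difficulty, stim_sign, rng)
    acc = (choice == stim_sign).astype(np.int64)
    t_fp = steps * ddm.step
    decision_rt = t_fp + ddm.non_decision_time
    drift_signed = np.asarray(ddm.drift_rates)[difficulty] * stim_sign
    e_tot = post_decision_evidence(
        choice * ddm.bound, conf_rt, drift_signed, rng, ddm.noise, ddm.step
    )
    t_acc = t_fp + np.round(conf_rt / ddm.step) * ddm.step
    t_conf = t_acc if time_basis == "accumulation" else decision_rt + conf_rt
    conf = expit((choice * ldc.alpha * e_tot + ldc.beta) / t_conf**ldc.gamma)
    rating = ratings_from_confidence(conf)
    n_sim = len(difficulty)
    return TrialSummary(
        rt_props=_rt_group_props(decision_rt, acc, obs_sum.rt_cutoffs, n_sim),
        conf_props=_conf_level_props(rating, acc, n_sim),
        rt_cutoffs=obs_sum.rt_cutoffs,
        n_trials=n_sim,
    )


# ---------------------------------------------------------------------------
# configuration and model variants


def default_bounds(trials: pd.DataFrame | None = None) -> dict:
    """Default box bounds for the free parameters.

    Wide enough to bracket every parameterization used in the feedback
    presets (alpha up to 36, |beta| up to 1) with headroom.
    """
    ter_hi = 0.9
    if trials is not None and len(trials):
        ter_hi = min(ter_hi, 0.9 * float(trials["decision_rt"].min()))
    return {
        "ter": (0.05, max(ter_hi, 0.06)),
        "a": (0.01, 0.3),
        "v": (0.0, 1.0),
        "alpha": (0.0, 100.0),
        "beta": (-5.0, 5.0),
    }


@dataclass
class FitConfig:
    """Optimizer and simulation settings for a fit."""

    oversample: int = 20
    popsize_mult: int = 10
    mutation: float = 0.8
    recombination: float = 0.9
    maxiter: int = 1000
    stagnation: int = 100
    polish: bool = True
    gamma: float = 0.5
    time_basis: str = "accumulation"
    order_drifts: bool = True
    bounds: dict | None = None
    pool_size: int = 1 << 24
    max_duration: float = MAX_TRIAL_DURATION
    sigma: float = SIGMA_DEFAULT
    step: float = 0.001


@dataclass(frozen=True)
class ModelVariant:
    """Which confidence parameters vary between conditions.

    ``kind`` is "ldc" for the logistic readout or "readout" for the exact
    Bayesian mixture posterior; readout variants have no (alpha, beta) and
    differ in whether drift rates are re-fit per condition.
    """

    name: str
    kind: str = "ldc"
    alpha_free: bool = False
    beta_free: bool = False
    free_drifts: bool = False

    def n_conf_params(self, n_conditions: int, n_difficulties: int) -> int:
        if self.kind == "readout":
            return n_difficulties * n_conditions if self.free_drifts else 0
        k = n_conditions if self.alpha_free else 1
        k += n_conditions if self.beta_free else 1
        return k


VARIANTS: dict[str, ModelVariant] = {
    "null": ModelVariant("null"),
    "alpha_free": ModelVariant("alpha_free", alpha_free=True),
    "beta_free": ModelVariant("beta_free", beta_free=True),
    "full": ModelVariant("full", alpha_free=True, beta_free=True),
    "readout_fixed": ModelVariant("readout_fixed", kind="readout"),
    "readout_free": ModelVariant("readout_free", kind="readout", free_drifts=True),
}


@dataclass
class FitResult:
    """Fitted parameters and fit statistics for one participant."""

    ddm: DDMParams
    ldc_by_condition: dict[str, LDCParams]
    sse: float
    k: int
    n: int
    seed: int
    variant: str
    trace: list = field(default_factory=list)
    rt_sse: float | None = None
    conf_sse: float | None = None


# ---------------------------------------------------------------------------
# heuristic initialization


def ez_estimates(trials: pd.DataFrame, sigma: float = SIGMA_DEFAULT) -> dict:
    """Closed-form diffusion estimates from accuracy and correct-RT moments.

    Method-of-moments inversion of the unbiased two-bound diffusion (the
    "EZ" equations): per difficulty, the accuracy and the mean and variance
    of correct-trial RTs identify drift, bound and non-decision time.  Used
    to seed the global optimizer near the data-consistent region.
    """
    s2 = sigma**2
    drifts, bounds_, ters = [], [], []
    for d, grp in trials.groupby("difficulty"):
        n = len(grp)
        p = grp["accuracy"].mean()
        p = min(max(p, 0.5 + 1.0 / (2 * n)), 1 - 1.0 / (2 * n))
        rts = grp.loc[grp["accuracy"] == 1, "decision_rt"].to_numpy(float)
        if len(rts) < 3:
            rts = grp["decision_rt"].to_numpy(float)
        mrt, vrt = float(np.mean(rts)), float(np.var(rts))
        vrt = max(vrt, 1e-6)
        L = logit(p)
        x = L * (L * p**2 - L * p + p - 0.5) / vrt
        v = sigma * x**0.25
        a = s2 * L / v
        y = -v * a / s2
        mdt = (a / (2 * v)) * (1 - math.exp(y)) / (1 + math.exp(y))
        drifts.append(v)
        bounds_.append(a)
        ters.append(mrt - mdt)
    return {
        "drifts": np.array(drifts),
        "a": float(np.mean(bounds_)),
        "ter": float(np.mean(ters)),
    }


# ---------------------------------------------------------------------------
# simulation workspace (common random numbers)


class _SimWorkspace:
    """Pre-arranged simulation inputs and a fixed noise pool for one fit.

    Every objective evaluation simulates the same replicated design with the
    same noise, so the SSE surface is deterministic.  Walks that fail to
    reach a bound within ``max_duration`` are censored: the current evidence
    sign is taken as the choice and the cap as the first-passage time (such
    candidates live at the edge of the parameter box).
    """

    def __init__(self, trials: pd.DataFrame, config: FitConfig, sim_seed: int):
        self.config = config
        self.conditions = list(dict.fromkeys(trials["condition"]))
        self.obs = {
            c: summarize(trials[trials["condition"] == c]) for c in self.conditions
        }
        ov = config.oversample
        self.difficulty = np.repeat(trials["difficulty"].to_numpy(np.int64), ov)
        self.stim_sign = np.repeat(trials["stim_sign"].to_numpy(np.int64), ov)
        conf_rt = np.repeat(trials["confidence_rt"].to_numpy(float), ov)
        self.k_pd = np.round(conf_rt / config.step)
        self.t_pd = self.k_pd * config.step
        self.conf_rt = conf_rt
        cond_codes = pd.Categorical(
            np.repeat(trials["condition"].to_numpy(), ov), categories=self.conditions
        ).codes
        self.cond_masks = {
            c: cond_codes == i for i, c in enumerate(self.conditions)
        }
        self.n_sim = len(self.difficulty)
        self.n_difficulties = int(trials["difficulty"].max()) + 1

        rng = np.random.default_rng(sim_seed)
        scale = config.sigma * math.sqrt(config.step)
        self.pool = (scale * rng.standard_normal(config.pool_size)).astype(np.float32)
        self.offsets = rng.integers(0, config.pool_size, self.n_sim)
        self.pd_noise = rng.standard_normal(self.n_sim)
        self.max_steps = int(round(config.max_duration / config.step))
        self._cache_key = None
        self._cache = None

    # -- decision + post-decision stage (depends on a and drifts only) ------

    def simulate(self, a: float, drifts: np.ndarray):
        key = (float(a), tuple(np.round(np.asarray(drifts, float), 12)))
        if key == self._cache_key:
            return self._cache
        drift_signed = np.asarray(drifts, float)[self.difficulty] * self.stim_sign
        v_tau = (drift_signed * self.config.step).astype(np.float32)
        choice, steps = walk_first_passage_pool(
            v_tau,
            np.float32(0.0),
            np.float32(a),
            self.pool,
            self.offsets,
            self.max_steps,
        )
        choice = np.where(np.abs(choice) == 2, np.sign(choice), choice).astype(
            np.int64
        )
        choice[choice == 0] = 1
        acc = (choice == self.stim_sign).astype(np.int64)
        t_fp = steps * self.config.step
        e_tot = (
            choice * a
            + drift_signed * self.t_pd
            + self.config.sigma * np.sqrt(self.t_pd) * self.pd_noise
        )
        t_acc = t_fp + self.t_pd
        self._cache_key = key
        self._cache = (choice, acc, t_fp, e_tot, t_acc)
        return self._cache

    # -- objective terms -----------------------------------------------------

    def rt_sse(self, sim, ter: float) -> float:
        choice, acc, t_fp, _, _ = sim
        rt = t_fp + ter
        total = 0.0
        for c in self.conditions:
            m = self.cond_masks[c]
            props = _rt_group_props(rt[m], acc[m], self.obs[c].rt_cutoffs, m.sum())
            total += float(np.sum((self.obs[c].rt_props - props) ** 2))
        return total

    def conf_sse(
        self,
        sim,
        ter: float,
        alphas: Mapping[str, float],
        betas: Mapping[str, float],
    ) -> float:
        choice, acc, t_fp, e_tot, t_acc = sim
        if self.config.time_basis == "accumulation":
            t_conf = t_acc
        else:
            t_conf = t_fp + ter + self.conf_rt
        total = 0.0
        for c in self.conditions:
            m = self.cond_masks[c]
            conf = expit(
                (choice[m] * alphas[c] * e_tot[m] + betas[c])
                / t_conf[m] ** self.config.gamma
            )
            props = _conf_level_props(ratings_from_confidence(conf), acc[m], m.sum())
            total += float(np.sum((self.obs[c].conf_props - props) ** 2))
        return total

    def readout_conf_sse(self, sim, drifts_by_cond: Mapping[str, np.ndarray]) -> float:
        """Confidence term under the exact Bayesian mixture readout."""
        choice, acc, t_fp, e_tot, t_acc = sim
        total = 0.0
        for c in self.conditions:
            m = self.cond_masks[c]
            p = bayes_readout_mixture(
                choice[m] * e_tot[m], t_acc[m], drifts_by_cond[c], self.config.sigma
            )
            props = _conf_level_props(ratings_from_confidence(p), acc[m], m.sum())
            total += float(np.sum((self.obs[c].conf_props - props) ** 2))
        return total


# ---------------------------------------------------------------------------
# differential evolution driver


class _StagnationStop:
    """Stop DE after `patience` generations without improvement of the best
    objective value; also records the optimizer trace."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.stalled = 0
        self.trace: list[tuple[int, float]] = []

    def update(self, fbest: float) -> bool:
        gen = len(self.trace)
        if fbest < self.best - 1e-12:
            self.best = fbest
            self.stalled = 0
        else:
            self.stalled += 1
        self.trace.append((gen, self.best))
        return self.stalled >= self.patience


def _run_de(func, bounds, config: FitConfig, seed: int, init_extra=None):
    """rand/1/bin differential evolution with latin-hypercube init, optional
    extra seed rows, and the 100-stagnant-generation stopping rule."""
    nparam = len(bounds)
    npop = max(config.popsize_mult * nparam, 5)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    sampler = qmc.LatinHypercube(d=nparam, seed=seed)
    init = lo + sampler.random(npop) * (hi - lo)
    if init_extra is not None:
        extra = np.atleast_2d(np.clip(init_extra, lo, hi))
        init[: len(extra)] = extra

    stop = _StagnationStop(config.stagnation)
    result = optimize.differential_evolution(
        func,
        bounds,
        strategy="rand1bin",
        mutation=config.mutation,
        recombination=config.recombination,
        maxiter=config.maxiter,
        init=init,
        tol=0,
        atol=0,
        seed=seed,
        polish=False,
        updating="immediate",
        callback=lambda xk, convergence=None: stop.update(func(xk)),
    )
    return result.x, float(result.fun), stop.trace


# ---------------------------------------------------------------------------
# the estimator


class DDMConfidenceModel(BaseEstimator):
    """Joint fit of decision and confidence parameters to one participant.

    scikit-learn style estimator: ``fit`` takes a trial table (DataFrame
    with columns condition, difficulty, stim_sign, accuracy, decision_rt,
    confidence_rt, rating) and estimates non-decision time, bound, one
    drift per difficulty, and the confidence parameters dictated by
    ``variant`` (shared or per-condition alpha/beta).

    Parameters
    ----------
    variant : str or ModelVariant
        Free/fixed structure of the confidence parameters.
    config : FitConfig, optional
        Optimizer and simulation settings.
    seed : int
        Seeds both the common-random-number simulation and the optimizer.

    Attributes
    ----------
    ddm_params_ : DDMParams
    ldc_params_ : dict[str, LDCParams]
    sse_, k_, n_ : fit statistics
    result_ : FitResult
    """

    def __init__(self, variant="null", config: FitConfig | None = None, seed: int = 0):
        self.variant = variant
        self.config = config
        self.seed = seed

    # -- parameter vector layout --------------------------------------------

    def _layout(self, n_cond: int, n_diff: int, variant: ModelVariant):
        names = ["ter", "a"] + [f"v{d}" for d in range(n_diff)]
        n_alpha = n_cond if variant.alpha_free else 1
        n_beta = n_cond if variant.beta_free else 1
        return names, n_alpha, n_beta

    def _unpack(self, theta, n_cond, n_diff, variant, conditions, order_drifts=True):
        ter, a = theta[0], theta[1]
        drifts = np.asarray(theta[2 : 2 + n_diff])
        if order_drifts:
            # difficulty levels are ordered by design: level 0 is easiest
            drifts = np.sort(drifts)[::-1]
        rest = theta[2 + n_diff :]
        n_alpha = n_cond if variant.alpha_free else 1
        alphas_v = rest[:n_alpha]
        betas_v = rest[n_alpha:]
        alphas = {
            c: float(alphas_v[i if variant.alpha_free else 0])
            for i, c in enumerate(conditions)
        }
        betas = {
            c: float(betas_v[i if variant.beta_free else 0])
            for i, c in enumerate(conditions)
        }
        return ter, a, drifts, alphas, betas

    def fit(self, trials: pd.DataFrame, y=None):
        variant = (
            VARIANTS[self.variant] if isinstance(self.variant, str) else self.variant
        )
        if variant.kind != "ldc":
            raise ValueError(
                "joint fitting applies to LDC variants; use two_stage_fit for "
                "Bayesian-readout candidates"
            )
        config = self.config if self.config is not None else FitConfig()
        if len(trials) == 0:
            raise ValueError("empty trial table")
        for c, grp in trials.groupby("condition"):
            if len(grp) == 0:
                raise ValueError(f"empty condition {c!r}")

        ws = _SimWorkspace(trials, config, sim_seed=self.seed)
        conditions = ws.conditions
        n_cond, n_diff = len(conditions), ws.n_difficulties
        bounds_map = config.bounds or default_bounds(trials)
        n_alpha = n_cond if variant.alpha_free else 1
        n_beta = n_cond if variant.beta_free else 1
        bounds = (
            [bounds_map["ter"], bounds_map["a"]]
            + [bounds_map["v"]] * n_diff
            + [bounds_map["alpha"]] * n_alpha
            + [bounds_map["beta"]] * n_beta
        )
        for b in bounds:
            if b[1] <= b[0]:
                raise ValueError(f"invalid bounds {b}")

        def objective(theta):
            ter, a, drifts, alphas, betas = self._unpack(
                theta, n_cond, n_diff, variant, conditions, config.order_drifts
            )
            sim = ws.simulate(a, drifts)
            return ws.rt_sse(sim, ter) + ws.conf_sse(sim, ter, alphas, betas)

        # heuristic seeds: EZ moment estimates for the decision stage; for
        # the confidence stage the probit-equivalence value lam/sigma, plus
        # a second row whose (alpha, beta) are profiled on the EZ simulation
        ez = ez_estimates(trials, config.sigma)
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        ez_theta = np.clip(
            np.concatenate(
                [
                    [ez["ter"], ez["a"]],
                    np.resize(ez["drifts"], n_diff),
                    np.full(n_alpha, 1.7 / config.sigma),
                    np.zeros(n_beta),
                ]
            ),
            lo,
            hi,
        )
        profiled = self._profile_conf_params(
            ez_theta, ws, bounds, n_cond, n_diff, variant, conditions
        )
        theta, fval, trace = _run_de(
            objective,
            bounds,
            config,
            seed=self.seed,
            init_extra=np.vstack([ez_theta, profiled]),
        )

        if config.polish:
            # cheap pass over (ter, confidence params) on the cached
            # simulation, a full re-simulating Nelder-Mead pass, then the
            # cheap pass again at the refined decision parameters
            theta, fval = self._polish(
                theta, fval, ws, bounds, n_cond, n_diff, variant, conditions
            )
            res = optimize.minimize(
                lambda th: objective(np.clip(th, lo, hi)),
                theta,
                method="Nelder-Mead",
                options={"maxfev": 30 * len(bounds), "xatol": 1e-5, "fatol": 1e-10},
            )
            if res.fun < fval:
                theta, fval = np.clip(res.x, lo, hi), float(res.fun)
            theta, fval = self._polish(
                theta, fval, ws, bounds, n_cond, n_diff, variant, conditions
            )

        ter, a, drifts, alphas, betas = self._unpack(
            theta, n_cond, n_diff, variant, conditions, config.order_drifts
        )
        self.ddm_params_ = DDMParams(
            drift_rates=tuple(drifts),
            bound=float(a),
            non_decision_time=float(ter),
            noise=config.sigma,
            step=config.step,
        )
        self.ldc_params_ = {
            c: LDCParams(alpha=max(alphas[c], 0.0), beta=betas[c], gamma=config.gamma)
            for c in conditions
        }
        self.sse_ = fval
        self.k_ = 2 + n_diff + n_alpha + n_beta
        self.n_ = 4 * N_LEVELS * n_cond
        self.theta_ = np.asarray(theta, dtype=float)
        self._workspace = ws
        self._objective = objective
        self.result_ = FitResult(
            ddm=self.ddm_params_,
            ldc_by_condition=self.ldc_params_,
            sse=self.sse_,
            k=self.k_,
            n=self.n_,
            seed=self.seed,
            variant=variant.name,
            trace=trace,
        )
        return self

    def _polish(self, theta, fval, ws, bounds, n_cond, n_diff, variant, conditions):
        """Refine the parameters that reuse the cached simulation (ter and
        the confidence parameters) with bounded Nelder-Mead passes.

        Evaluations only re-bin RTs and re-map confidence (~fractions of a
        millisecond), so a fixed set of extra confidence-parameter starts is
        run as well, guarding against confidence-side local basins left by
        the global search."""
        order = ws.config.order_drifts
        _, a, drifts, _, _ = self._unpack(
            theta, n_cond, n_diff, variant, conditions, order
        )
        sim = ws.simulate(a, drifts)
        idx = [0] + list(range(2 + n_diff, len(theta)))
        lo = np.array([bounds[i][0] for i in idx])
        hi = np.array([bounds[i][1] for i in idx])

        def cheap(sub):
            sub = np.clip(sub, lo, hi)
            full = np.array(theta, dtype=float)
            full[idx] = sub
            ter, _, _, al, be = self._unpack(
                full, n_cond, n_diff, variant, conditions, order
            )
            return ws.rt_sse(sim, ter) + ws.conf_sse(sim, ter, al, be)

        x0 = np.clip(np.array(theta, dtype=float)[idx], lo, hi)
        n_alpha = n_cond if variant.alpha_free else 1
        n_beta = n_cond if variant.beta_free else 1
        starts = [x0]
        for a0, b0 in ((17.0, 0.0), (8.0, -1.0), (32.0, 1.0)):
            s = x0.copy()
            s[1 : 1 + n_alpha] = a0
            s[1 + n_alpha : 1 + n_alpha + n_beta] = b0
            starts.append(np.clip(s, lo, hi))

        best_x, best_f = np.asarray(theta, float), fval
        for s in starts:
            res = optimize.minimize(
                cheap,
                s,
                method="Nelder-Mead",
                options={"maxfev": 600, "xatol": 1e-6, "fatol": 1e-12},
            )
            if res.fun < best_f:
                out = np.array(theta, dtype=float)
                out[idx] = np.clip(res.x, lo, hi)
                best_x, best_f = out, float(res.fun)
        return best_x, best_f

    def _profile_conf_params(
        self, theta0, ws, bounds, n_cond, n_diff, variant, conditions
    ):
        """Candidate for the initial population: confidence parameters
        optimized on the simulation cached at ``theta0``'s decision stage."""
        out, _ = self._polish(
            np.array(theta0, dtype=float),
            np.inf,
            ws,
            bounds,
            n_cond,
            n_diff,
            variant,
            conditions,
        )
        return out

    def objective(self, theta) -> float:
        """Evaluate the fit's deterministic objective at any candidate."""
        if not hasattr(self, "_objective"):
            raise RuntimeError("call fit first")
        return self._objective(np.asarray(theta, dtype=float))


def fit_participant(
    trials: pd.DataFrame,
    variant="null",
    config: FitConfig | None = None,
    seed: int = 0,
) -> FitResult:
    """Fit one participant's trial table; see :class:`DDMConfidenceModel`."""
    model = DDMConfidenceModel(variant=variant, config=config, seed=seed)
    model.fit(trials)
    return model.result_


# ---------------------------------------------------------------------------
# two-stage fitting for model comparison


def two_stage_fit(
    trials: pd.DataFrame,
    variants: Sequence[ModelVariant | str] | None = None,
    config: FitConfig | None = None,
    seed: int = 0,
) -> list[FitResult]:
    """Stage 1 fits the decision parameters to the RT term alone; stage 2
    fits each candidate's confidence parameters to the confidence term with
    the decision parameters frozen and identical across candidates."""
    if variants is None:
        variants = ["null", "alpha_free", "beta_free", "full"]
    variants = [VARIANTS[v] if isinstance(v, str) else v for v in variants]
    config = config if config is not None else FitConfig()

    ws = _SimWorkspace(trials, config, sim_seed=seed)
    conditions = ws.conditions
    n_cond, n_diff = len(conditions), ws.n_difficulties
    bounds_map = config.bounds or default_bounds(trials)
    stage1_bounds = [bounds_map["ter"], bounds_map["a"]] + [bounds_map["v"]] * n_diff

    def rt_objective(theta):
        drifts = np.sort(theta[2:])[::-1] if config.order_drifts else theta[2:]
        sim = ws.simulate(theta[1], drifts)
        return ws.rt_sse(sim, theta[0])

    ez = ez_estimates(trials, config.sigma)
    seed_row = np.concatenate(
        [[ez["ter"], ez["a"]], np.resize(ez["drifts"], n_diff)]
    )
    theta1, rt_fval, trace1 = _run_de(
        rt_objective, stage1_bounds, config, seed=seed, init_extra=seed_row
    )
    ter, a = float(theta1[0]), float(theta1[1])
    drifts = np.asarray(theta1[2:], dtype=float)
    if config.order_drifts:
        drifts = np.sort(drifts)[::-1]
    ddm = DDMParams(
        drift_rates=tuple(drifts),
        bound=a,
        non_decision_time=ter,
        noise=config.sigma,
        step=config.step,
    )
    sim = ws.simulate(a, drifts)
    n_conf = 2 * N_LEVELS * n_cond
    # stage-2 objectives reuse the cached stage-1 simulation, so evaluations
    # are cheap: let the stagnation rule decide convergence even when the
    # stage-1 generation budget was capped
    stage2_cfg = replace(config, maxiter=max(config.maxiter, 300))

    results = []
    for variant in variants:
        if variant.kind == "readout":
            if not variant.free_drifts:
                fval = ws.readout_conf_sse(sim, {c: drifts for c in conditions})
                results.append(
                    FitResult(
                        ddm=ddm,
                        ldc_by_condition={},
                        sse=fval,
                        k=0,
                        n=n_conf,
                        seed=seed,
                        variant=variant.name,
                        rt_sse=rt_fval,
                        conf_sse=fval,
                    )
                )
            else:
                # candidate drifts enter the readout only; the simulated
                # decision process stays at the shared stage-1 parameters
                per_cond = {}
                for ci, c in enumerate(conditions):
                    def ro_obj(vv, cond=c):
                        d = {cc: drifts for cc in conditions}
                        d[cond] = np.asarray(vv)
                        return ws.readout_conf_sse(sim, d)

                    vx, fv, _ = _run_de(
                        ro_obj,
                        [bounds_map["v"]] * n_diff,
                        stage2_cfg,
                        seed=seed * 1000 + ci,
                        init_extra=drifts,
                    )
                    per_cond[c] = np.asarray(vx)
                fval = ws.readout_conf_sse(sim, per_cond)
                results.append(
                    FitResult(
                        ddm=ddm,
                        ldc_by_condition={},
                        sse=fval,
                        k=n_diff * n_cond,
                        n=n_conf,
                        seed=seed,
                        variant=variant.name,
                        rt_sse=rt_fval,
                        conf_sse=fval,
                    )
                )
            continue

        n_alpha = n_cond if variant.alpha_free else 1
        n_beta = n_cond if variant.beta_free else 1
        cbounds = [bounds_map["alpha"]] * n_alpha + [bounds_map["beta"]] * n_beta

        def conf_objective(phi, variant=variant, n_alpha=n_alpha):
            alphas = {
                c: float(phi[i if variant.alpha_free else 0])
                for i, c in enumerate(conditions)
            }
            betas = {
                c: float(phi[n_alpha + (i if variant.beta_free else 0)])
                for i, c in enumerate(conditions)
            }
            return ws.conf_sse(sim, ter, alphas, betas)

        seed_conf = np.concatenate(
            [np.full(n_alpha, 1.7 / config.sigma), np.zeros(n_beta)]
        )
        phi, fval, trace2 = _run_de(
            conf_objective, cbounds, stage2_cfg, seed=seed, init_extra=seed_conf
        )
        res = optimize.minimize(
            lambda p: conf_objective(np.clip(p, [b[0] for b in cbounds], [b[1] for b in cbounds])),
            phi,
            method="Nelder-Mead",
            options={"maxfev": 400},
        )
        if res.fun < fval:
            phi, fval = np.clip(res.x, [b[0] for b in cbounds], [b[1] for b in cbounds]), float(res.fun)
        alphas = {
            c: float(phi[i if variant.alpha_free else 0])
            for i, c in enumerate(conditions)
        }
        betas = {
            c: float(phi[n_alpha + (i if variant.beta_free else 0)])
            for i, c in enumerate(conditions)
        }
        results.append(
            FitResult(
                ddm=ddm,
                ldc_by_condition={
                    c: LDCParams(
                        alpha=max(alphas[c], 0.0), beta=betas[c], gamma=config.gamma
                    )
                    for c in conditions
                },
                sse=fval,
                k=variant.n_conf_params(n_cond, n_diff),
                n=n_conf,
                seed=seed,
                variant=variant.name,
                rt_sse=rt_fval,
                conf_sse=fval,
            )
        )
    return results
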