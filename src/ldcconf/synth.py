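"""Synthetic cohorts and the parameter-recovery harness.

A cohort is a set of simulated participants whose generative parameters
are drawn from declared ranges; recovery fits every participant back and
scores the generating-vs-recovered correlation per parameter.  Drift rates
are sampled per difficulty and sorted so level 0 is the easiest.

Default ranges (evidence units at sigma = 0.1): drift in [0.05, 0.4],
bound in [0.06, 0.16], non-decision time in [0.2, 0.5] s, alpha in
[5, 40], beta in [-1.5, 1.5] — bracketing the parameterizations used by
the feedback presets (alpha 9-36, |beta| <= 1) with headroom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .ddm import balanced_design, simulate_dataset
from .fitting import FitConfig, fit_participant
from .params import DDMParams, LDCParams

__all__ = [
    "ExperimentDesign",
    "generate_cohort",
    "recovery_study",
    "reduced_fit_config",
    "DEFAULT_RANGES",
]

def reduced_fit_config(**overrides) -> FitConfig:
    """Desk-scale optimizer settings for the recovery study: the population
    and stopping rules are unchanged, but the generation budget is capped at
    25 so one participant fits in tens of seconds.  The uncapped defaults of
    :class:`FitConfig` are the full-scale settings."""
    kwargs = {"oversample": 20, "maxiter": 25}
    kwargs.update(overrides)
    return FitConfig(**kwargs)


DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "v": (0.05, 0.4),
    "a": (0.06, 0.16),
    "ter": (0.2, 0.5),
    "alpha": (5.0, 40.0),
    "beta": (-1.5, 1.5),
}


@dataclass
class ExperimentDesign:
    """Layout of a synthetic experiment.

    ``trials_per_difficulty`` trials per difficulty level per condition;
    participant parameters sampled uniformly from ``ranges``.
    """

    participants: int = 20
    n_difficulties: int = 3
    trials_per_difficulty: int = 216
    conditions: tuple[str, ...] = ("baseline",)
    ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES)
    )
    gamma: float = 0.5

    def __post_init__(self):
        if self.participants < 1 or self.trials_per_difficulty < 1:
            raise ValueError("counts must be >= 1")
        for key, (lo, hi) in self.ranges.items():
            if hi < lo:
                raise ValueError(f"invalid range for {key}: ({lo}, {hi})")


def _sample_participant(design: ExperimentDesign, rng) -> tuple[DDMParams, LDCParams]:
    r = design.ranges
    # Individual differences in drift are dominated by a general ability
    # factor: a participant who accumulates evidence efficiently does so at
    # every difficulty level.  Drifts are therefore sampled as
    # ability x level ratio x small per-level jitter, which keeps the three
    # staircased levels distinct within a participant while spreading every
    # level widely across participants (as observed cohorts do), all within
    # the declared overall range.
    lo, hi = r["v"]
    k = design.n_difficulties
    ratios = np.linspace(1.0, 0.42, k)  # level 0 easiest
    scale_hi = hi / 1.1  # keep ability * jitter inside the declared range
    ability = rng.uniform(0.3 * scale_hi, scale_hi)
    jitter = rng.uniform(0.9, 1.1, size=k)
    drifts = np.sort(np.clip(ability * ratios * jitter, lo, hi))[::-1]
    ddm = DDMParams(
        drift_rates=tuple(drifts),
        bound=rng.uniform(*r["a"]),
        non_decision_time=rng.uniform(*r["ter"]),
    )
    ldc = LDCParams(
        alpha=rng.uniform(*r["alpha"]),
        beta=rng.uniform(*r["beta"]),
        gamma=design.gamma,
    )
    return ddm, ldc


def generate_cohort(
    design: ExperimentDesign,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort; returns (trial table, ground-truth parameters).

    Bit-reproducible under a fixed generator state.
    """
    if rng is None:
        rng = np.random.default_rng()
    layout = balanced_design(
        design.trials_per_difficulty, design.n_difficulties, design.conditions
    )
    tables, truth_rows = [], []
    for pid in range(design.participants):
        ddm, ldc = _sample_participant(design, rng)
        table = simulate_dataset(ddm, ldc, layout, rng=rng, participant=pid)
        tables.append(table)
        row = {"participant": pid, "a": ddm.bound, "ter": ddm.non_decision_time}
        for d, v in enumerate(ddm.drift_rates):
            row[f"v{d}"] = v
        row["alpha"] = ldc.alpha
        row["beta"] = ldc.beta
        truth_rows.append(row)
    return pd.concat(tables, ignore_index=True), pd.DataFrame(truth_rows)


def recovery_study(
    design: ExperimentDesign,
    config: FitConfig | None = None,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> dict:
    """Simulate-and-refit recovery of every model parameter.

    Fits each simulated participant with the quantile-SSE objective and
    differential evolution, then reports the Pearson correlation between
    generating and recovered values per parameter, plus the recovered
    alpha-beta cross-correlation (which should be near zero if the two
    confidence parameters do not trade off).  Failed fits are recorded and
    skipped, the study continues.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if config is None:
        # recovery fits search within the sampling ranges (widened slightly)
        config = FitConfig(bounds=_recovery_bounds(design))
    elif config.bounds is None:
        from dataclasses import replace as _replace

        config = _replace(config, bounds=_recovery_bounds(design))

    trials, truth = generate_cohort(design, rng)
    param_names = ["a", "ter"] + [f"v{d}" for d in range(design.n_difficulties)] + [
        "alpha",
        "beta",
    ]
    recovered_rows, failures = [], []
    for pid, table in trials.groupby("participant"):
        try:
            fit = fit_participant(
                table,
                variant="null",
                config=config,
                seed=(seed * 100_003 + int(pid)) % (2**31 - 1),
            )
        except Exception as err:  # keep going; record which fit failed
            failures.append({"participant": int(pid), "error": repr(err)})
            continue
        cond = next(iter(fit.ldc_by_condition))
        row = {
            "participant": int(pid),
            "a": fit.ddm.bound,
            "ter": fit.ddm.non_decision_time,
            "alpha": fit.ldc_by_condition[cond].alpha,
            "beta": fit.ldc_by_condition[cond].beta,
            "sse": fit.sse,
        }
        for d, v in enumerate(fit.ddm.drift_rates):
            row[f"v{d}"] = v
        recovered_rows.append(row)
    recovered = pd.DataFrame(recovered_rows)
    merged = truth.merge(recovered, on="participant", suffixes=("_true", "_fit"))
    correlations = {
        p: float(pearsonr(merged[f"{p}_true"], merged[f"{p}_fit"])[0])
        for p in param_names
    }
    r_ab, p_ab = pearsonr(merged["alpha_fit"], merged["beta_fit"])
    return {
        "correlations": correlations,
        "min_correlation": min(correlations.values()),
        "alpha_beta_r": float(r_ab),
        "alpha_beta_p": float(p_ab),
        "truth": truth,
        "recovered": recovered,
        "failures": failures,
    }


def posterior_correlation_study(
    n_sets: int = 20,
    trials_per_set: int = 6000,
    seed: int = 0,
    design: ExperimentDesign | None = None,
) -> dict:
    """How closely the fitted logistic readout tracks the exact posterior.

    Simulates trials with post-decisional accumulation from ``n_sets``
    decision-parameter sets drawn from the recovery ranges, computes the
    posterior probability correct p(v > 0 | e, t) = Phi(e / (sigma sqrt(t)))
    for each trial's (evidence, time, choice), fits (alpha, beta) per set by
    the logit-scale linear solve, and returns the pooled Spearman
    correlation between the fitted confidence and the posterior across all
    trials.
    """
    from scipy.special import expit
    from scipy.stats import spearmanr

    from .confidence import bayes_p_correct, fit_ldc_to_posterior

    if design is None:
        design = ExperimentDesign()
    rng = np.random.default_rng(seed)
    n_per = trials_per_set // design.n_difficulties
    conf_all, post_all = [], []
    fits = []
    for _ in range(n_sets):
        ddm, _ = _sample_participant(design, rng)
        table = simulate_dataset(
            ddm, LDCParams(alpha=17.0), balanced_design(n_per, design.n_difficulties), rng=rng
        )
        u = (table["evidence_total"] * table["choice"]).to_numpy()
        t = table["acc_time"].to_numpy()
        post = bayes_p_correct(u, t, ddm.noise, gamma=design.gamma)
        alpha, beta = fit_ldc_to_posterior(u, t, post, gamma=design.gamma)
        conf = expit((alpha * u + beta) / t**design.gamma)
        conf_all.append(conf)
        post_all.append(post)
        fits.append((alpha, beta))
    conf_all = np.concatenate(conf_all)
    post_all = np.concatenate(post_all)
    rho = spearmanr(conf_all, post_all).statistic
    return {
        "spearman_r": float(rho),
        "n_trials": int(len(conf_all)),
        "n_sets": n_sets,
        "fits": fits,
    }


def _recovery_bounds(design: ExperimentDesign) -> dict:
    """Search box for recovery fits: the sampling ranges widened by 25%
    (positive quantities stay positive)."""
    r = design.ranges

    def pad(lo, hi, floor=None, f=0.25):
        w = f * (hi - lo)
        lo2, hi2 = lo - w, hi + w
        return (max(lo2, floor) if floor is not None else lo2, hi2)

    return {
        "ter": pad(*r["ter"], floor=0.01),
        "a": pad(*r["a"], floor=0.02),
        "v": (0.0, pad(*r["v"])[1]),
        "alpha": (0.0, r["alpha"][1] + 10.0),
        "beta": pad(*r["beta"]),
    }
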