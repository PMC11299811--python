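"""Random-walk simulation of 2AFC decisions with post-decisional accumulation.

The decision stage is a discrete-time random walk (step ``tau``) between two
absorbing bounds; the post-decisional stage continues the same accumulation,
unbounded, for the duration of the confidence report.  Because a sum of
independent Gaussian step increments is itself Gaussian, the post-decision
stage is collapsed into a single exactly-distributed Gaussian draw.

:func:`simulate_dataset` composes the two stages with the logistic
confidence readout into a full trial table ready for fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._kernels import walk_first_passage
from .confidence import ldc_confidence, ratings_from_confidence
from .params import DDMParams, LDCParams

__all__ = [
    "TrialRecord",
    "simulate_trial",
    "simulate_decisions",
    "post_decision_accumulate",
    "post_decision_evidence",
    "simulate_dataset",
    "balanced_design",
    "default_confidence_rt",
    "MAX_TRIAL_DURATION",
]

#: Guard against non-terminating walks under degenerate parameters (seconds).
MAX_TRIAL_DURATION = 20.0

TRIAL_COLUMNS = [
    "participant",
    "condition",
    "difficulty",
    "stim_sign",
    "choice",
    "accuracy",
    "decision_rt",
    "confidence_rt",
    "rating",
]


@dataclass(frozen=True)
class TrialRecord:
    """A single simulated 2AFC trial, including latent evidence."""

    condition: str
    difficulty: int
    stim_sign: int
    choice: int
    accuracy: int
    decision_rt: float
    confidence_rt: float = 0.0
    evidence_at_decision: float = 0.0
    evidence_total: float = 0.0
    acc_time: float = 0.0  # accumulation time: first-passage + post-decision duration
    rating: int | None = None


def simulate_decisions(
    ddm: DDMParams,
    difficulty: np.ndarray,
    stim_sign: np.ndarray,
    rng: np.random.Generator,
    max_duration: float = MAX_TRIAL_DURATION,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the decision stage for a batch of trials.

    Returns ``(choice, steps)`` with ``choice`` in {-1, +1} and ``steps`` the
    number of accumulation steps.  Raises ``RuntimeError`` if any walk fails
    to reach a bound within ``max_duration`` (degenerate parameters).
    """
    difficulty = np.asarray(difficulty, dtype=np.int64)
    stim_sign = np.asarray(stim_sign, dtype=np.int64)
    if difficulty.min(initial=0) < 0 or difficulty.max(initial=0) >= ddm.n_difficulties:
        raise ValueError("difficulty index out of range")
    drifts = np.asarray(ddm.drift_rates)[difficulty] * stim_sign
    v_tau = drifts * ddm.step
    max_steps = int(round(max_duration / ddm.step))
    seed = int(rng.integers(0, 2**31 - 1))
    choice, steps = walk_first_passage(
        v_tau,
        ddm.start_fraction * ddm.bound,
        ddm.bound,
        ddm.noise * math.sqrt(ddm.step),
        max_steps,
        seed,
    )
    if np.any(np.abs(choice) == 2):
        raise RuntimeError(
            f"{int(np.sum(np.abs(choice) == 2))} walk(s) did not reach a bound "
            f"within {max_duration} s; parameters are degenerate"
        )
    return choice.astype(np.int64), steps


def simulate_trial(
    ddm: DDMParams,
    difficulty: int,
    stim_sign: int,
    rng: np.random.Generator,
    condition: str = "baseline",
    max_duration: float = MAX_TRIAL_DURATION,
) -> TrialRecord:
    """Simulate one trial's decision stage.

    Evidence at the moment of decision is recorded as exactly +/- the bound
    (any discrete-step overshoot is clipped to the threshold).
    """
    if stim_sign not in (-1, 1):
        raise ValueError("stim_sign must be +1 or -1")
    choice, steps = simulate_decisions(
        ddm, np.array([difficulty]), np.array([stim_sign]), rng, max_duration
    )
    x = int(choice[0])
    t_dec = float(steps[0]) * ddm.step
    return TrialRecord(
        condition=condition,
        difficulty=int(difficulty),
        stim_sign=int(stim_sign),
        choice=x,
        accuracy=int(x == stim_sign),
        decision_rt=t_dec + ddm.non_decision_time,
        evidence_at_decision=x * ddm.bound,
        evidence_total=x * ddm.bound,
        acc_time=t_dec,
    )


def post_decision_evidence(
    evidence_at_decision: np.ndarray,
    duration: np.ndarray,
    drift_signed: np.ndarray,
    rng: np.random.Generator,
    noise: float,
    step: float,
) -> np.ndarray:
    """Evidence after an unbounded post-decisional walk of given duration.

    The walk takes ``round(duration / step)`` Gaussian increments; their sum
    is Gaussian with mean ``drift * k * step`` and variance
    ``noise**2 * k * step``, so a single draw reproduces the walk's
    distribution exactly.
    """
    duration = np.asarray(duration, dtype=float)
    if np.any(duration < 0):
        raise ValueError("post-decision duration must be >= 0")
    k = np.round(duration / step)
    t_eff = k * step
    return (
        np.asarray(evidence_at_decision, dtype=float)
        + np.asarray(drift_signed, dtype=float) * t_eff
        + noise * np.sqrt(t_eff) * rng.standard_normal(duration.shape)
    )


def post_decision_accumulate(
    record: TrialRecord,
    duration: float,
    drift_signed: float,
    rng: np.random.Generator,
    noise: float = 0.1,
    step: float = 0.001,
) -> TrialRecord:
    """Continue accumulating evidence after the decision for ``duration`` s.

    A duration of 0 is the identity.  ``drift_signed`` is the signed drift of
    the post-decisional walk (the true stimulus drift in generative
    simulation; +/- the pilot drift by accuracy in feedback generation).
    """
    if duration < 0:
        raise ValueError("post-decision duration must be >= 0")
    if duration == 0:
        return replace(record, evidence_total=record.evidence_at_decision)
    e_tot = post_decision_evidence(
        np.array([record.evidence_at_decision]),
        np.array([duration]),
        np.array([drift_signed]),
        rng,
        noise,
        step,
    )[0]
    return replace(
        record,
        evidence_total=float(e_tot),
        confidence_rt=float(duration),
        acc_time=record.acc_time + float(np.round(duration / step) * step),
    )


def default_confidence_rt(rng: np.random.Generator, n: int) -> np.ndarray:
    """Stand-in confidence-RT distribution for pure simulation.

    Log-normal with median 0.5 s and log-sd 0.5 — a typical spread for the
    interval between a choice and its confidence report.
    """
    return np.exp(rng.normal(math.log(0.5), 0.5, size=n))


def balanced_design(
    n_per_difficulty: int,
    n_difficulties: int = 3,
    conditions: Sequence[str] = ("baseline",),
) -> pd.DataFrame:
    """Design with equal trial counts per (condition, difficulty) cell."""
    rows = [
        {"condition": c, "difficulty": d, "n": int(n_per_difficulty)}
        for c in conditions
        for d in range(n_difficulties)
    ]
    return pd.DataFrame(rows)


def _normalize_design(design) -> pd.DataFrame:
    if isinstance(design, pd.DataFrame):
        out = design[["condition", "difficulty", "n"]].copy()
    elif isinstance(design, Mapping):
        rows = []
        for cond, per_diff in design.items():
            for d, n in per_diff.items():
                rows.append({"condition": cond, "difficulty": int(d), "n": int(n)})
        out = pd.DataFrame(rows)
    else:
        raise TypeError("design must be a DataFrame or nested mapping")
    if len(out) == 0 or out["n"].sum() == 0:
        raise ValueError("empty design")
    return out


def simulate_dataset(
    ddm: DDMParams,
    ldc: LDCParams | Mapping[str, LDCParams],
    design,
    conf_rt_source: Callable | np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    participant: int = 0,
    time_basis: str = "accumulation",
    max_duration: float = MAX_TRIAL_DURATION,
) -> pd.DataFrame:
    """Simulate a full trial table: decisions, post-decisional accumulation
    and 6-level confidence ratings.

    ``ldc`` may be one parameter set for all conditions or a mapping from
    condition label to parameters.  ``conf_rt_source`` is either ``None``
    (log-normal stand-in), a callable ``(rng, n) -> durations`` or an array
    sampled from with replacement.  ``time_basis`` selects the elapsed time
    entering the confidence readout: ``"accumulation"`` (first-passage plus
    post-decision duration — the time the Bayesian posterior is defined on)
    or ``"response"`` (decision RT plus confidence RT).
    """
    if rng is None:
        rng = np.random.default_rng()
    if time_basis not in ("accumulation", "response"):
        raise ValueError("time_basis must be 'accumulation' or 'response'")
    design = _normalize_design(design)

    condition = np.repeat(design["condition"].to_numpy(), design["n"].to_numpy())
    difficulty = np.repeat(
        design["difficulty"].to_numpy().astype(np.int64), design["n"].to_numpy()
    )
    n = len(condition)
    stim_sign = rng.choice(np.array([-1, 1]), size=n)

    choice, steps = simulate_decisions(ddm, difficulty, stim_sign, rng, max_duration)
    t_fp = steps * ddm.step
    decision_rt = t_fp + ddm.non_decision_time

    if conf_rt_source is None:
        conf_rt = default_confidence_rt(rng, n)
    elif callable(conf_rt_source):
        conf_rt = np.asarray(conf_rt_source(rng, n), dtype=float)
    else:
        conf_rt = rng.choice(np.asarray(conf_rt_source, dtype=float), size=n)

    drift_signed = np.asarray(ddm.drift_rates)[difficulty] * stim_sign
    e_tot = post_decision_evidence(
        choice * ddm.bound, conf_rt, drift_signed, rng, ddm.noise, ddm.step
    )
    acc_time = t_fp + np.round(conf_rt / ddm.step) * ddm.step
    t_conf = acc_time if time_basis == "accumulation" else decision_rt + conf_rt

    if isinstance(ldc, LDCParams):
        ldc_map = {c: ldc for c in design["condition"].unique()}
    else:
        ldc_map = dict(ldc)
    conf = np.empty(n)
    for cond, p in ldc_map.items():
        m = condition == cond
        conf[m] = ldc_confidence(e_tot[m], t_conf[m], choice[m], p)

    table = pd.DataFrame(
        {
            "participant": participant,
            "condition": condition,
            "difficulty": difficulty,
            "stim_sign": stim_sign,
            "choice": choice,
            "accuracy": (choice == stim_sign).astype(int),
            "decision_rt": decision_rt,
            "confidence_rt": conf_rt,
            "rating": ratings_from_confidence(conf),
            "evidence_dec": choice * ddm.bound,
            "evidence_total": e_tot,
            "acc_time": acc_time,
            "confidence": conf,
        }
    )
    return table
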