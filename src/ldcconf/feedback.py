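"""Model-generated trial-by-trial probabilistic feedback.

Instead of binary correct/error feedback, the training-phase feedback is
the confidence the logistic readout would assign to the trial, computed
online from observable quantities only (decision RT, confidence RT,
accuracy) plus pilot-session averages of the decision threshold and drift:

* evidence at the moment of decision is taken to be the pilot threshold
  (in the frame of the chosen option);
* a post-decisional random walk runs for the confidence RT, its drift
  +pilot_drift on correct trials and -pilot_drift on errors;
* feedback = logistic confidence of the resulting total evidence at the
  total elapsed time, decision RT + confidence RT, under a fixed
  (alpha, beta) pairing.

Because alpha weighs evidence — which is confirming on corrects and
disconfirming on errors — raising alpha pushes feedback up on correct
trials while leaving error trials nearly unchanged; beta shifts feedback
on both.  The named presets reproduce the five training conditions:
baseline (alpha=18, beta=0), alpha-minus (9), alpha-plus (36), beta-minus
(beta=-1) and beta-plus (beta=+1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .confidence import ldc_confidence
from .ddm import default_confidence_rt, simulate_decisions
from .params import DDMParams, LDCParams, SIGMA_DEFAULT

__all__ = ["FeedbackSpec", "feedback_preset", "generate_feedback", "simulate_training_phase"]


@dataclass(frozen=True)
class FeedbackSpec:
    """Settings of the online feedback generator for one condition."""

    pilot_bound: float
    pilot_drift: float
    fb_params: LDCParams
    condition: str = "baseline"
    noise: float = SIGMA_DEFAULT
    step: float = 0.001

    def __post_init__(self):
        if not self.pilot_bound > 0:
            raise ValueError("pilot_bound must be > 0")
        if self.pilot_drift < 0:
            raise ValueError("pilot_drift must be >= 0")


#: (alpha, beta) per named training condition.
_PRESETS = {
    "baseline": (18.0, 0.0),
    "alpha_minus": (9.0, 0.0),
    "alpha_plus": (36.0, 0.0),
    "beta_minus": (18.0, -1.0),
    "beta_plus": (18.0, 1.0),
}


def feedback_preset(
    name: str,
    pilot_bound: float = 0.1,
    pilot_drift: float = 0.2,
    gamma: float = 0.5,
) -> FeedbackSpec:
    """Named feedback condition; pilot averages default to typical values
    (bound 0.1, drift 0.2 at sigma = 0.1) and can be set per task."""
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    alpha, beta = _PRESETS[name]
    return FeedbackSpec(
        pilot_bound=pilot_bound,
        pilot_drift=pilot_drift,
        fb_params=LDCParams(alpha=alpha, beta=beta, gamma=gamma),
        condition=name,
    )


def generate_feedback(
    decision_rt,
    confidence_rt,
    accuracy,
    spec: FeedbackSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Feedback value(s) in (0, 1) for one or more trials.

    Deterministic given (inputs, spec, generator state).  Total elapsed
    time is decision RT plus confidence RT — the quantities available
    online — rather than accumulation time.
    """
    scalar = np.isscalar(decision_rt) or np.ndim(decision_rt) == 0
    decision_rt = np.atleast_1d(np.asarray(decision_rt, dtype=float))
    confidence_rt = np.atleast_1d(np.asarray(confidence_rt, dtype=float))
    accuracy = np.atleast_1d(np.asarray(accuracy, dtype=int))
    if np.any(decision_rt <= 0) or np.any(confidence_rt <= 0):
        raise ValueError("decision and confidence RTs must be > 0")
    drift = np.where(accuracy == 1, spec.pilot_drift, -spec.pilot_drift)
    k = np.round(confidence_rt / spec.step)
    t_eff = k * spec.step
    e_total = (
        spec.pilot_bound
        + drift * t_eff
        + spec.noise * np.sqrt(t_eff) * rng.standard_normal(decision_rt.shape)
    )
    t_total = decision_rt + confidence_rt
    fb = ldc_confidence(e_total, t_total, np.ones_like(accuracy), spec.fb_params)
    return float(fb[0]) if scalar else fb


def simulate_training_phase(
    ddm: DDMParams,
    ldc: LDCParams,
    spec: FeedbackSpec,
    n_trials: int = 120,
    rng: np.random.Generator | None = None,
    conf_rt_source=None,
) -> pd.DataFrame:
    """Closed-loop training phase: decisions, confidence RT draws and
    model-generated feedback, one row per trial.

    The simulated participant's own confidence (their LDC parameters) is
    returned alongside the feedback they would have seen.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    n_diff = ddm.n_difficulties
    difficulty = rng.integers(0, n_diff, size=n_trials)
    stim_sign = rng.choice(np.array([-1, 1]), size=n_trials)
    choice, steps = simulate_decisions(ddm, difficulty, stim_sign, rng)
    accuracy = (choice == stim_sign).astype(int)
    decision_rt = steps * ddm.step + ddm.non_decision_time
    if conf_rt_source is None:
        conf_rt = default_confidence_rt(rng, n_trials)
    elif callable(conf_rt_source):
        conf_rt = np.asarray(conf_rt_source(rng, n_trials), dtype=float)
    else:
        conf_rt = rng.choice(np.asarray(conf_rt_source, dtype=float), size=n_trials)

    feedback = generate_feedback(decision_rt, conf_rt, accuracy, spec, rng)

    # the participant's own internal confidence, from their latent evidence
    from .ddm import post_decision_evidence

    drift_signed = np.asarray(ddm.drift_rates)[difficulty] * stim_sign
    e_tot = post_decision_evidence(
        choice * ddm.bound, conf_rt, drift_signed, rng, ddm.noise, ddm.step
    )
    t_acc = steps * ddm.step + np.round(conf_rt / ddm.step) * ddm.step
    own_conf = ldc_confidence(e_tot, t_acc, choice, ldc)

    return pd.DataFrame(
        {
            "participant": 0,
            "condition": spec.condition,
            "difficulty": difficulty,
            "stim_sign": stim_sign,
            "choice": choice,
            "accuracy": accuracy,
            "decision_rt": decision_rt,
            "confidence_rt": conf_rt,
            "confidence": own_conf,
            "feedback": feedback,
        }
    )
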