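"""Parameter containers for the decision process and the confidence mapping.

Two parameter sets drive everything in this package:

* :class:`DDMParams` — the generative decision process: a discrete-time
  random-walk approximation of the drift-diffusion model (DDM).  Evidence
  starts at ``z * a``, moves by ``v * tau + sigma * sqrt(tau) * N(0, 1)``
  each step, and a choice is issued when it crosses ``+a`` or ``-a``.

* :class:`LDCParams` — the low-dimensional confidence (LDC) mapping: a
  two-parameter logistic readout of accumulated evidence and elapsed time,
  ``conf = 1 / (1 + exp(-(x * alpha * e + beta) / t**gamma))``, where
  ``alpha`` weighs how reliable the evidence is taken to be and ``beta``
  is a stimulus-independent confidence bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

__all__ = ["DDMParams", "LDCParams", "LAMBDA_DEFAULT", "SIGMA_DEFAULT"]

#: Constant of the logistic approximation to the standard normal CDF.
LAMBDA_DEFAULT = 1.7

#: Conventional within-trial noise of the accumulator (evidence units / sqrt(s)).
SIGMA_DEFAULT = 0.1


@dataclass(frozen=True)
class DDMParams:
    """Generative parameters of the bounded random-walk decision process.

    Parameters
    ----------
    drift_rates
        Drift magnitude per difficulty level, in evidence units per second.
        By convention level 0 is the easiest (largest drift).
    bound
        Decision threshold ``a`` (evidence units); the walk terminates at
        ``+a`` or ``-a``.
    non_decision_time
        ``ter`` in seconds, added to the first-passage time to form the
        reported decision RT.
    start_fraction
        Relative starting point ``z`` in (-1, 1); the walk starts at ``z*a``.
    noise
        Within-trial noise ``sigma`` (evidence units per sqrt-second).
    step
        Simulation time step ``tau`` in seconds.
    """

    drift_rates: tuple[float, ...]
    bound: float
    non_decision_time: float
    start_fraction: float = 0.0
    noise: float = SIGMA_DEFAULT
    step: float = 0.001

    def __init__(
        self,
        drift_rates: Sequence[float],
        bound: float,
        non_decision_time: float,
        start_fraction: float = 0.0,
        noise: float = SIGMA_DEFAULT,
        step: float = 0.001,
    ) -> None:
        drift_rates = tuple(float(v) for v in drift_rates)
        if len(drift_rates) == 0:
            raise ValueError("drift_rates must contain at least one level")
        if not all(math.isfinite(v) for v in drift_rates):
            raise ValueError("all drift rates must be finite")
        if not bound > 0:
            raise ValueError(f"bound must be > 0, got {bound}")
        if non_decision_time < 0:
            raise ValueError(f"non_decision_time must be >= 0, got {non_decision_time}")
        if not abs(start_fraction) < 1:
            raise ValueError(f"|start_fraction| must be < 1, got {start_fraction}")
        if not noise > 0:
            raise ValueError(f"noise must be > 0, got {noise}")
        if not step > 0:
            raise ValueError(f"step must be > 0, got {step}")
        object.__setattr__(self, "drift_rates", drift_rates)
        object.__setattr__(self, "bound", float(bound))
        object.__setattr__(self, "non_decision_time", float(non_decision_time))
        object.__setattr__(self, "start_fraction", float(start_fraction))
        object.__setattr__(self, "noise", float(noise))
        object.__setattr__(self, "step", float(step))

    @property
    def n_difficulties(self) -> int:
        return len(self.drift_rates)

    def replace(self, **kwargs) -> "DDMParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class LDCParams:
    """Parameters of the low-dimensional logistic confidence readout.

    ``alpha`` is the reliability weight on evidence (inverse evidence units,
    >= 0), ``beta`` the stimulus-independent bias (unbounded), ``gamma`` the
    exponent of elapsed time in the denominator (0.5 matches the flat-prior
    Bayesian posterior of a Wiener process), and ``lam`` the fixed constant
    of the logistic-probit approximation.
    """

    alpha: float
    beta: float = 0.0
    gamma: float = 0.5
    lam: float = LAMBDA_DEFAULT

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if not self.gamma > 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if not self.lam > 0:
            raise ValueError(f"lam must be > 0, got {self.lam}")

    def replace(self, **kwargs) -> "LDCParams":
        return replace(self, **kwargs)
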