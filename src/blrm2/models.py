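"""Dose–toxicity models for dual-agent combinations.

Three parametric families map a dose pair (methadone ``m``, baclofen ``b``,
both in mg) to a probability of a dose-limiting toxicity (DLT):

* the five-parameter logistic combination model (the working model of the
  design): two-parameter logistic monotherapy curves on the log-dose scale,
  combined under independence and modulated by an interaction term acting
  multiplicatively on the odds;
* a covariate model in the style of Bailey: a single logistic methadone
  curve shifted by binary indicators of the baclofen dose level;
* a seven-parameter Bliss-type surface used to generate data under model
  misspecification.

All functions are vectorised over parameter draws: parameter arguments may
be scalars or arrays of shape ``(...,)`` and dose arguments may be scalars
or arrays broadcastable against them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ReferenceDoses",
    "ThetaVector",
    "BaileyParams",
    "BlissParams",
    "monotherapy_risk",
    "independence_risk",
    "combination_risk",
    "bailey_risk",
    "bliss_risk",
]

# Probabilities are clipped away from {0, 1} before odds transforms so that
# extreme parameter draws (MCMC tail excursions) cannot overflow.
_EPS = 1e-12


@dataclass(frozen=True)
class ReferenceDoses:
    """Reference doses (mg) of the combination model.

    ``m_star``/``b_star`` are the monotherapy reference doses at which the
    intercepts act directly; ``b_top`` is the highest planned dose of the
    escalated agent, which standardises the interaction term (the odds
    multiplier reaches ``exp(eta * m/m_star)`` at the top baclofen dose).
    """

    m_star: float = 60.0
    b_star: float = 30.0
    b_top: float = 90.0

    def __post_init__(self) -> None:
        if self.m_star <= 0 or self.b_star <= 0 or self.b_top <= 0:
            raise ValueError("reference doses must be strictly positive")


@dataclass(frozen=True)
class ThetaVector:
    """Parameters of the five-parameter logistic combination model.

    ``alpha01``/``alpha11`` are the methadone intercept and slope on the
    logit scale, ``alpha02``/``alpha12`` the baclofen ones, ``eta`` the
    interaction coefficient (positive = synergistic toxicity).
    """

    alpha01: float
    alpha11: float
    alpha02: float
    alpha12: float
    eta: float

    def __post_init__(self) -> None:
        if self.alpha11 <= 0 or self.alpha12 <= 0:
            raise ValueError("slopes must be strictly positive")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.alpha01, self.alpha11, self.alpha02, self.alpha12, self.eta]
        )

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "ThetaVector":
        return cls(*(float(v) for v in np.asarray(arr)))


@dataclass(frozen=True)
class BaileyParams:
    """Parameters of the binary-covariate comparator model.

    ``beta1..beta3`` are positive logit increments applied when the baclofen
    dose reaches 30, 60 and 90 mg respectively, so risk is nondecreasing in
    the baclofen dose level.
    """

    alpha01: float
    alpha11: float
    beta1: float
    beta2: float
    beta3: float

    def __post_init__(self) -> None:
        if self.alpha11 <= 0:
            raise ValueError("methadone slope must be strictly positive")
        if min(self.beta1, self.beta2, self.beta3) <= 0:
            raise ValueError("covariate increments must be strictly positive")


@dataclass(frozen=True)
class BlissParams:
    """Parameters of the seven-parameter Bliss-type toxicity surface.

    ``beta1`` is the asymptotic risk at very large doses, ``beta2`` the
    baseline risk at zero dose; ``beta3``/``beta4`` rescale the reference
    doses, ``beta5``/``beta6`` are shape exponents per agent and ``beta7``
    an outer exponent.  Surfaces with ``beta1 <= beta2`` (risk decreasing
    in dose) are permitted.
    """

    beta1: float
    beta2: float
    beta3: float
    beta4: float
    beta5: float
    beta6: float
    beta7: float

    def __post_init__(self) -> None:
        if not (0 < self.beta1 <= 0.4 and 0 < self.beta2 <= 0.25):
            raise ValueError("beta1 must lie in (0, 0.4] and beta2 in (0, 0.25]")
        if min(self.beta3, self.beta4, self.beta5, self.beta6, self.beta7) <= 0:
            raise ValueError("beta3..beta7 must be strictly positive")


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def monotherapy_risk(dose, ref_dose, intercept, slope):
    """DLT probability of a single agent: logit p = intercept + slope*log(d/d*).

    A dose of exactly zero yields probability zero (the log-dose model's
    continuous limit), avoiding ``log(0)`` arithmetic.
    """
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise ValueError("doses must be nonnegative")
    if ref_dose <= 0:
        raise ValueError("reference dose must be strictly positive")
    safe = np.where(dose > 0, dose, ref_dose)
    p = _expit(intercept + np.asarray(slope) * np.log(safe / ref_dose))
    return np.where(dose > 0, p, 0.0)


def independence_risk(p_m, p_b):
    """Combination risk assuming independent toxicity: 1-(1-p_m)(1-p_b)."""
    p_m = np.asarray(p_m, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    if np.any((p_m < 0) | (p_m > 1) | (p_b < 0) | (p_b > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return 1.0 - (1.0 - p_m) * (1.0 - p_b)


def interaction_covariate(m, b, refs: ReferenceDoses):
    """The standardised dose product (m/m*)*(b/b_top) multiplying eta."""
    m = np.asarray(m, dtype=float)
    b = np.asarray(b, dtype=float)
    return (m / refs.m_star) * (b / refs.b_top)


def combination_risk(theta, m, b, refs: ReferenceDoses = ReferenceDoses()):
    """Five-parameter logistic combination risk.

    ``odds(p) = odds(p0) * exp(eta * (m/m*) * (b/b_top))`` where ``p0`` is
    the independence combination of the two monotherapy risks.  ``theta`` may be
    a :class:`ThetaVector` or an array with last axis
    ``(alpha01, alpha11, alpha02, alpha12, eta)``; dose arguments broadcast
    against the leading axes.
    """
    if isinstance(theta, ThetaVector):
        a01, a11, a02, a12, eta = theta.as_array()
    else:
        arr = np.asarray(theta, dtype=float)
        a01, a11, a02, a12, eta = np.moveaxis(arr, -1, 0)
    p_m = monotherapy_risk(m, refs.m_star, a01, a11)
    p_b = monotherapy_risk(b, refs.b_star, a02, a12)
    p0 = independence_risk(p_m, p_b)
    # Degenerate p0 = 1 stays 1; clip before the odds transform otherwise.
    p0c = np.clip(p0, _EPS, 1.0 - _EPS)
    shift = eta * interaction_covariate(m, b, refs)
    # odds(p) = odds(p0) * e^shift, computed stably on the log-odds scale
    logit = np.log(p0c) - np.log1p(-p0c) + shift
    p = _expit(logit)
    # eta acts only when both agents are present
    both = (np.asarray(m, dtype=float) > 0) & (np.asarray(b, dtype=float) > 0)
    p = np.where(both, p, p0)
    return np.where(p0 >= 1.0 - _EPS, 1.0, p)


def bailey_risk(params, m, b, m_star: float = 60.0):
    """Binary-covariate comparator risk.

    logit p = alpha01 + alpha11*log(m/m*) + beta1*I(b>=30) + beta2*I(b>=60)
    + beta3*I(b>=90).  Indicators act on the administered dose, so the
    function is total in ``b``; ``m = 0`` gives risk 0.
    """
    if isinstance(params, BaileyParams):
        a01, a11, b1, b2, b3 = (
            params.alpha01,
            params.alpha11,
            params.beta1,
            params.beta2,
            params.beta3,
        )
    else:
        arr = np.asarray(params, dtype=float)
        a01, a11, b1, b2, b3 = np.moveaxis(arr, -1, 0)
    m = np.asarray(m, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(m < 0) or np.any(b < 0):
        raise ValueError("doses must be nonnegative")
    safe = np.where(m > 0, m, m_star)
    logit = (
        a01
        + a11 * np.log(safe / m_star)
        + b1 * (b >= 30)
        + b2 * (b >= 60)
        + b3 * (b >= 90)
    )
    return np.where(m > 0, _expit(logit), 0.0)


def bliss_risk(params, m, b, refs: ReferenceDoses = ReferenceDoses()):
    """Seven-parameter Bliss-type surface.

    p = beta2 + (beta1-beta2) * (1 - [ (1+m/(m* b3))^b5 (1+b/(b* b4))^b6 ]^(-b7))

    At (0, 0) the risk is ``beta2``; as both doses grow it approaches
    ``beta1``.  All outputs lie between ``min(beta1, beta2)`` and
    ``max(beta1, beta2)``.
    """
    if isinstance(params, BlissParams):
        b1, b2, b3, b4, b5, b6, b7 = (
            params.beta1,
            params.beta2,
            params.beta3,
            params.beta4,
            params.beta5,
            params.beta6,
            params.beta7,
        )
    else:
        arr = np.asarray(params, dtype=float)
        b1, b2, b3, b4, b5, b6, b7 = np.moveaxis(arr, -1, 0)
    m = np.asarray(m, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(m < 0) or np.any(b < 0):
        raise ValueError("doses must be nonnegative")
    inner = (1.0 + m / (refs.m_star * b3)) ** b5 * (1.0 + b / (refs.b_star * b4)) ** b6
    return b2 + (b1 - b2) * (1.0 - inner ** -b7)
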