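"""Naïve-Bayes integration of per-factor risk models into one posterior.

Each fitted dose-response curve plays the role of P(C=yes | f_k): the
probability of a complication given one factor's value. Bayes' theorem
inverts these to P(f_k | C), the class-conditional factor likelihoods, which
under the class-conditional-independence assumption multiply into
P(X | C) = prod_k P(f_k | C). Writing the two-class chain out and normalising,
the factor marginals P(f_k) cancel, leaving

    P(yes | X)  propto  P(yes)^(1-n) * prod_k q_k
    P(no  | X)  propto  (1-P(yes))^(1-n) * prod_k (1 - q_k)

with q_k = P(yes | f_k) taken from the 1-1 curve at the observed factor
value. Both scores are evaluated in log space so long factor lists cannot
underflow.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

from .curvefit import FittedCurve, predict

__all__ = [
    "ClassPrior",
    "FactorMarginal",
    "FactorObservation",
    "invert_conditional",
    "posterior_from_probs",
    "combine_posterior",
]

#: Risk-percent clip bounds applied to raw curve output before use as a probability.
RISK_CLIP_PERCENT = (1e-4, 100.0 - 1e-4)
#: Probability clip applied to q_k = risk/100 before entering the log-space chain.
PROB_CLIP = (1e-6, 1.0 - 1e-6)


@dataclass(frozen=True)
class ClassPrior:
    """Population prior P(C=yes) for one complication."""

    complication_name: str
    p_yes: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p_yes < 1.0):
            raise ValueError(f"p_yes must be in (0,1), got {self.p_yes}")


@dataclass(frozen=True)
class FactorMarginal:
    """Population probability P(f_k in ]lo, hi]) of one factor bin.

    Kept for priors reporting and CPT provenance; the two-class posterior
    itself does not need it (the marginals cancel on normalisation).
    """

    factor_name: str
    bin: tuple[float, float]  # half-open ]lo, hi]
    p: float

    def __post_init__(self) -> None:
        lo, hi = self.bin
        if not lo < hi:
            raise ValueError("bin must satisfy lo < hi")
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"bin probability must be in (0,1], got {self.p}")


@dataclass(frozen=True)
class FactorObservation:
    """One observed factor value for a patient."""

    factor_name: str
    value: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError("observed factor value must be finite")


def invert_conditional(p_c_given_f: float, p_f: float, p_c: float) -> float:
    """Bayes inversion P(f|C) = P(f) P(C|f) / P(C).

    Inconsistent inputs can push the ratio above 1; the result is then
    clipped to 1 with a warning, since a probability is required downstream.
    """
    if p_c <= 0:
        raise ValueError("class prior P(C) must be positive")
    for name, v in (("p_c_given_f", p_c_given_f), ("p_f", p_f), ("p_c", p_c)):
        if not (0.0 < v <= 1.0):
            raise ValueError(f"{name} must be in (0,1], got {v}")
    out = p_f * p_c_given_f / p_c
    if out > 1.0:
        warnings.warn(
            f"inverted conditional {out:.4g} exceeds 1 (inconsistent inputs); "
            "clipped to 1",
            stacklevel=2,
        )
        out = 1.0
    return out


def posterior_from_probs(qs: Sequence[float], p_yes: float) -> float:
    """Two-class naïve-Bayes posterior from per-factor P(yes|f_k) values.

    Evaluates s_yes = p_yes^(1-n) prod q_k and s_no = (1-p_yes)^(1-n)
    prod (1-q_k) in log space and returns s_yes / (s_yes + s_no). With a
    single factor this reduces exactly to q_1; with q_k = p_yes for all k the
    evidence is uninformative and the prior is returned.
    """
    if not (0.0 < p_yes < 1.0):
        raise ValueError(f"p_yes must be in (0,1), got {p_yes}")
    n = len(qs)
    if n == 0:
        return p_yes
    for q in qs:
        if not (0.0 < q < 1.0):
            raise ValueError(f"per-factor probabilities must be in (0,1), got {q}")
    log_yes = (1 - n) * math.log(p_yes) + sum(math.log(q) for q in qs)
    log_no = (1 - n) * math.log(1.0 - p_yes) + sum(math.log(1.0 - q) for q in qs)
    # logistic of the log-odds difference
    return 1.0 / (1.0 + math.exp(log_no - log_yes))


def _risk_to_prob(risk_percent: float, context: str) -> float:
    lo, hi = RISK_CLIP_PERCENT
    if risk_percent < lo or risk_percent > hi:
        warnings.warn(
            f"1-1 model risk {risk_percent:.4g}% for {context} outside [0,100]%; "
            f"clipped to [{lo}, {hi}]",
            stacklevel=3,
        )
        risk_percent = min(max(risk_percent, lo), hi)
    q = risk_percent / 100.0
    plo, phi = PROB_CLIP
    return min(max(q, plo), phi)


def combine_posterior(
    complication: str,
    observations: Sequence[FactorObservation],
    models: Mapping[str, FittedCurve],
    prior: ClassPrior,
) -> float:
    """Posterior probability of one complication given observed factors.

    Each observed factor must have a fitted 1-1 curve in ``models``; the
    curve's risk-percent prediction at the observed value, divided by 100 and
    clipped into (0,1), serves as q_k = P(C=yes | f_k). An empty observation
    list returns the prior.
    """
    if not observations:
        return prior.p_yes
    qs = []
    for obs in observations:
        if obs.factor_name not in models:
            raise ValueError(
                f"no 1-1 model for factor {obs.factor_name!r} "
                f"(complication {complication!r}); known factors: "
                f"{sorted(models)}"
            )
        risk = predict(models[obs.factor_name], obs.value)
        qs.append(_risk_to_prob(risk, f"{obs.factor_name}->{complication}"))
    return posterior_from_probs(qs, prior.p_yes)
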