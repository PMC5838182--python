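"""Prior elicitation from expected-coverage percentages.

The misclassification probability theta gets an informative Beta prior read
directly off the sender's percent coverage c: (a, b) = (100 - c, c), so the
prior mean a/(a+b) = (100 - c)/100 is exactly the coverage shortfall and
the effective prior sample size a + b is 100. A strength multiplier kappa
rescales (a, b) without moving the mean. Only the sender's coverage enters;
the receiver's surplus is left to the likelihood, since one rate is
reported per sender-receiver pair, indexed by the sender.

The Poisson incidence rates get weakly-informative Gamma hyperpriors; no
published choice exists for them, so the default is shape 1 with the prior
mean anchored at a crude observed rate, and everything is overridable.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BetaPrior:
    """Beta(a, b) prior on a probability."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError("Beta prior requires a > 0 and b > 0")

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def strength(self) -> float:
        """Effective prior sample size a + b."""
        return self.a + self.b

    def scaled(self, kappa: float) -> "BetaPrior":
        """Rescale strength by kappa > 0 without changing the mean."""
        if kappa <= 0:
            raise ValueError("kappa must be positive")
        return BetaPrior(self.a * kappa, self.b * kappa)


@dataclass(frozen=True)
class GammaPrior:
    """Gamma(shape, rate) prior on a Poisson rate per person-year."""

    shape: float
    rate: float

    def __post_init__(self) -> None:
        if not (self.shape > 0 and self.rate > 0):
            raise ValueError("Gamma prior requires shape > 0 and rate > 0")

    @property
    def mean(self) -> float:
        return self.shape / self.rate


class ElicitationError(ValueError):
    """No misclassification prior is definable from the given coverage."""


def beta_from_coverage(sender_coverage: float, kappa: float = 1.0) -> BetaPrior:
    """Beta prior for theta from a sender's percent coverage.

    (a, b) = kappa * (100 - c, c); the prior mean (100 - c)/100 is the
    sender's coverage shortfall. Only defined for 0 < c < 100: a province
    at or above full coverage has no shortfall to attribute.
    """
    if not 0.0 < sender_coverage < 100.0:
        raise ElicitationError(
            f"sender coverage must lie strictly between 0 and 100, got {sender_coverage}"
        )
    return BetaPrior(100.0 - sender_coverage, sender_coverage).scaled(kappa)


def default_rate_prior(scale_hint: float, exposure: float, shape: float = 1.0) -> GammaPrior:
    """Weakly-informative Gamma prior with mean rate = scale_hint / exposure.

    ``scale_hint`` is an expected caseload for the stratum and ``exposure``
    its person-years; shape 1 makes the prior exponential (variance equal
    to the squared mean), so the data dominate quickly.
    """
    if exposure <= 0:
        raise ValueError("exposure must be positive")
    if scale_hint <= 0:
        raise ValueError("scale_hint must be positive")
    if shape <= 0:
        raise ValueError("shape must be positive")
    mean_rate = scale_hint / exposure
    return GammaPrior(shape=shape, rate=shape / mean_rate)
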