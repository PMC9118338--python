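"""Test and relevance decisions for one-sided hypotheses.

The null H0: theta <= theta0 is rejected when the posterior null probability
falls below a threshold gamma.  Two cost conventions are supported:

* ``bf_reweighted`` — the test-error costs are divided by the prior hypothesis
  masses, so gamma depends on the analysis prior through P(theta <= theta0)
  and the decision is equivalent to thresholding the Bayes factor at c0'/c1'.
  This is the convention that makes the integrated risk a weighted sum of
  *average* type I and type II error rates.
* ``plain`` — gamma = c0'/(c0'+c1') irrespective of the prior.

Relevance is declared when the posterior median exceeds the relevance
threshold theta_R; combining the two flags classifies a trial outcome as a
success, a failure, or one of two indeterminate states.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .models import AnalysisPrior, TrialData, TrialModel, posterior_tail_prob

__all__ = [
    "Hypotheses",
    "CostSpec",
    "TestDecision",
    "TrialOutcome",
    "rejection_threshold",
    "decide_test",
    "bayes_factor",
    "decide_relevance",
    "classify_outcome",
]

BF_REWEIGHTED = "bf_reweighted"
PLAIN = "plain"


@dataclass(frozen=True)
class Hypotheses:
    """Significance threshold theta0 and relevance threshold thetaR >= theta0."""

    theta0: float
    thetaR: float

    def __post_init__(self) -> None:
        if self.thetaR < self.theta0:
            raise ValueError("relevance threshold must be >= significance threshold")


@dataclass(frozen=True)
class CostSpec:
    """Per-error costs c0' (false negative) and c1' (false positive)."""

    c0p: float
    c1p: float
    mode: str = BF_REWEIGHTED

    def __post_init__(self) -> None:
        if self.c0p <= 0 or self.c1p <= 0:
            raise ValueError("test error costs must be positive")
        if self.mode not in (BF_REWEIGHTED, PLAIN):
            raise ValueError(f"unknown cost mode {self.mode!r}")

    @property
    def ratio(self) -> float:
        """c0'/c1', the Bayes-factor rejection threshold."""
        return self.c0p / self.c1p


class TrialOutcome(enum.Enum):
    SUCCESS = "success"
    INDETERMINATE_SIGNIFICANT_ONLY = "indeterminate_significant_only"
    INDETERMINATE_RELEVANT_ONLY = "indeterminate_relevant_only"
    FAILURE = "failure"


@dataclass(frozen=True)
class TestDecision:
    reject: bool
    relevant: bool
    threshold: float
    posterior_null_prob: float
    log_bf: float


def rejection_threshold(prior: AnalysisPrior, costs: CostSpec, hyp: Hypotheses) -> float:
    """Posterior-probability rejection threshold gamma.

    In ``bf_reweighted`` mode
    gamma = c0' P(theta<=theta0) / {c0' P(theta<=theta0) + c1' (1 - P)},
    with P taken under the analysis prior; in ``plain`` mode c0'/(c0'+c1').
    """
    if costs.mode == PLAIN:
        return costs.c0p / (costs.c0p + costs.c1p)
    p = float(prior.cdf(hyp.theta0))
    if not 0.0 < p < 1.0:
        raise ValueError(
            "prior mass lies entirely on one side of theta0; the reweighted "
            "threshold is undefined (use plain mode or a two-sided prior)"
        )
    return costs.c0p * p / (costs.c0p * p + costs.c1p * (1.0 - p))


def decide_test(prior: AnalysisPrior, model: TrialModel, data: TrialData,
                costs: CostSpec, hyp: Hypotheses) -> TestDecision:
    """Full test decision; ties at the threshold keep the null.

    For data-dependent priors (empirical-Bayes power prior) the effective
    prior, and hence the threshold, is recomputed for the dataset at hand.
    """
    eff = prior.materialize(model, data)
    gamma = rejection_threshold(eff, costs, hyp)
    p_null = posterior_tail_prob(eff, model, data, hyp.theta0)
    reject = p_null < gamma
    relevant = decide_relevance(eff, model, data, hyp)
    log_bf = _log_bf(eff, model, data, hyp)
    return TestDecision(reject=reject, relevant=relevant, threshold=gamma,
                        posterior_null_prob=p_null, log_bf=log_bf)


def _log_odds(p: float) -> float:
    if p <= 0.0:
        return -math.inf
    if p >= 1.0:
        return math.inf
    return math.log(p) - math.log1p(-p)


def _log_bf(prior: AnalysisPrior, model: TrialModel, data: TrialData,
            hyp: Hypotheses) -> float:
    prior_mass = float(prior.cdf(hyp.theta0))
    if not 0.0 < prior_mass < 1.0:
        raise ValueError("Bayes factor requires prior mass on both sides of theta0")
    p_post = posterior_tail_prob(prior, model, data, hyp.theta0)
    return _log_odds(p_post) - _log_odds(prior_mass)


def bayes_factor(prior: AnalysisPrior, model: TrialModel, data: TrialData,
                 hyp: Hypotheses, log: bool = False) -> float:
    """Bayes factor of H0 vs H1 under theta0-truncated-and-renormalized priors.

    Computed through the posterior/prior odds identity
    BF = [P(theta<=theta0|y) / P(theta>theta0|y)] / [P(theta<=theta0) / P(theta>theta0)],
    which is numerically stable; direct truncated-marginal quadrature serves
    as an oracle in the test-suite.
    """
    eff = prior.materialize(model, data)
    lb = _log_bf(eff, model, data, hyp)
    return lb if log else math.exp(lb)


def decide_relevance(prior: AnalysisPrior, model: TrialModel, data: TrialData,
                     hyp: Hypotheses) -> bool:
    """Relevant iff P(theta <= thetaR | y) < 0.5 (posterior median > thetaR)."""
    eff = prior.materialize(model, data)
    return posterior_tail_prob(eff, model, data, hyp.thetaR) < 0.5


def classify_outcome(decision: TestDecision) -> TrialOutcome:
    """Success needs both significance and relevance; exactly one of the two
    gives an indeterminate outcome."""
    if decision.reject and decision.relevant:
        return TrialOutcome.SUCCESS
    if decision.reject:
        return TrialOutcome.INDETERMINATE_SIGNIFICANT_ONLY
    if decision.relevant:
        return TrialOutcome.INDETERMINATE_RELEVANT_ONLY
    return TrialOutcome.FAILURE
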