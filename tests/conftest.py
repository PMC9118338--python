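"""Shared scenario fixtures: a normal-outcome design scenario and a
single-arm binomial proof-of-concept scenario, each with the four analysis
prior families (vague/reference, informative, robust mixture, EB power)."""

import numpy as np
import pytest

import bdtdesign as bd


@pytest.fixture(scope="session")
def normal_model():
    return bd.TrialModel(bd.NORMAL, sigma2=1.0)


@pytest.fixture(scope="session")
def binomial_model():
    return bd.TrialModel(bd.BINOMIAL)


@pytest.fixture(scope="session")
def normal_hyp():
    return bd.Hypotheses(theta0=0.0, thetaR=0.15)


@pytest.fixture(scope="session")
def binomial_hyp():
    return bd.Hypotheses(theta0=0.075, thetaR=0.175)


@pytest.fixture(scope="session")
def costs():
    return bd.CostSpec(c0p=0.05, c1p=0.95)


@pytest.fixture(scope="session")
def normal_priors(normal_model):
    hist = bd.HistoricalData(50, 0.25)
    vague = bd.NormalPrior(0.0, 100.0)
    informative = bd.NormalPrior(0.25, 1.0 / 50.0)
    return {
        "vague": vague,
        "informative": informative,
        "robust_mixture": bd.MixturePrior(
            (informative, bd.NormalPrior(0.25, 100.0)), (0.5, 0.5)),
        "eb_power": bd.PowerPrior(hist, vague, bd.EMPIRICAL_BAYES),
    }


@pytest.fixture(scope="session")
def binomial_priors():
    hist = bd.HistoricalData(38, (10, 28))
    uniform = bd.BetaPrior(1.0, 1.0)
    informative = bd.BetaPrior(11.0, 29.0)
    return {
        "rsn": bd.BetaPrior(0.0811, 1.0),
        "informative": informative,
        "robust_mixture": bd.MixturePrior((informative, uniform), (0.5, 0.5)),
        "eb_power": bd.PowerPrior(hist, uniform, bd.EMPIRICAL_BAYES),
    }


@pytest.fixture(scope="session")
def normal_sp():
    return bd.SamplingPrior(bd.NormalPrior(0.25, 1.0 / 50.0))


@pytest.fixture(scope="session")
def binomial_sp():
    return bd.SamplingPrior(bd.BetaPrior(11.0, 29.0))


@pytest.fixture(scope="session")
def normal_curve(normal_priors, normal_model, costs, normal_hyp, normal_sp):
    """Vague-prior operating-characteristic curve over n = 2..300 (step 2)."""
    return bd.oc_curve(normal_priors["vague"], normal_model, costs, normal_hyp,
                       normal_sp, np.arange(2, 301, 2), include_monitors=False)


@pytest.fixture(scope="session")
def binomial_curve(binomial_priors, binomial_model, costs, binomial_hyp, binomial_sp):
    """RSN-prior operating-characteristic curve over n = 1..150."""
    return bd.oc_curve(binomial_priors["rsn"], binomial_model, costs,
                       binomial_hyp, binomial_sp, np.arange(1, 151),
                       include_monitors=False)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
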