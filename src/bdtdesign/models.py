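"""Outcome models, prior families, and conjugate posterior machinery.

Two conjugate outcome families are supported: a normal outcome with known
variance, summarized by the sample mean ``ybar ~ N(theta, sigma2/n)``, and a
binomial outcome summarized by the success count ``y ~ Bin(n, theta)``.  Priors
come in five flavours: normal, beta, point mass, finite mixtures, and power
priors built from historical data with a discount exponent ``a0`` (fixed or
selected by empirical-Bayes marginal-likelihood maximization).

All posterior summaries (tail probabilities, means, marginal likelihoods) are
available both as scalar operations on a :class:`TrialData` and as vectorized
"curves" over an array of sufficient statistics; the latter are the engine of
the operating-characteristic modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy import optimize, special, stats

NORMAL = "normal_known_variance"
BINOMIAL = "binomial"

EMPIRICAL_BAYES = "empirical_bayes"

__all__ = [
    "NORMAL",
    "BINOMIAL",
    "EMPIRICAL_BAYES",
    "TrialModel",
    "TrialData",
    "HistoricalData",
    "AnalysisPrior",
    "NormalPrior",
    "BetaPrior",
    "PointMassPrior",
    "MixturePrior",
    "PowerPrior",
    "SamplingPrior",
    "posterior",
    "posterior_tail_prob",
    "posterior_mean",
    "prior_mass_below",
    "log_marginal",
    "eb_a0",
]


# --------------------------------------------------------------------------
# model and data containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TrialModel:
    """Outcome family; ``sigma2`` is the known outcome variance (normal only)."""

    family: str
    sigma2: float | None = None

    def __post_init__(self) -> None:
        if self.family == NORMAL:
            if self.sigma2 is None or self.sigma2 <= 0:
                raise ValueError("normal family requires sigma2 > 0")
        elif self.family == BINOMIAL:
            if self.sigma2 is not None:
                raise ValueError("sigma2 is meaningless for the binomial family")
        else:
            raise ValueError(f"unknown outcome family {self.family!r}")

    def stat_sd(self, n: int | float) -> float:
        """Standard deviation of the sufficient statistic ybar (normal only)."""
        if self.family != NORMAL:
            raise ValueError("stat_sd is defined for the normal family only")
        return math.sqrt(self.sigma2 / n)


@dataclass(frozen=True)
class TrialData:
    """Sufficient statistic of the current trial.

    ``stat`` is the sample mean (normal) or the integer success count
    (binomial).  ``n = 0`` encodes "no data yet" and leaves priors unchanged.
    """

    n: int
    stat: float

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("sample size must be nonnegative")

    def validate(self, model: TrialModel) -> None:
        if model.family == BINOMIAL:
            if not float(self.stat).is_integer():
                raise ValueError("binomial success count must be an integer")
            if not 0 <= self.stat <= self.n:
                raise ValueError("success count must lie in {0..n}")


@dataclass(frozen=True)
class HistoricalData:
    """Historical study summary: mean ``ybar0`` (normal) or a
    ``(successes, failures)`` pair (binomial)."""

    n0: int
    summary: Union[float, tuple]

    def __post_init__(self) -> None:
        if self.n0 <= 0:
            raise ValueError("historical sample size must be positive")
        if isinstance(self.summary, tuple):
            s, f = self.summary
            if s + f != self.n0:
                raise ValueError("successes + failures must equal n0")


# --------------------------------------------------------------------------
# posterior curve protocol
# --------------------------------------------------------------------------


class PosteriorCurves:
    """Vectorized posterior summaries over an array of sufficient statistics.

    For data-dependent priors (empirical-Bayes power priors) the effective
    prior itself varies with the statistic, and so does its mass below a
    threshold; ``prior_mass_below`` therefore returns an array aligned with
    the statistics.
    """

    def tail(self, t: float) -> np.ndarray:  # P(theta <= t | data)
        raise NotImplementedError

    def mean(self) -> np.ndarray:  # E[theta | data]
        raise NotImplementedError

    def log_marginal(self) -> np.ndarray:  # log m(stat)
        raise NotImplementedError

    def prior_mass_below(self, t: float) -> np.ndarray:  # P^{pi_a}(theta <= t)
        raise NotImplementedError


# --------------------------------------------------------------------------
# prior families
# --------------------------------------------------------------------------


class AnalysisPrior:
    """Base class for analysis-prior families."""

    #: True when the effective prior depends on the current data (EB power prior)
    data_dependent: bool = False

    def cdf(self, t: float):
        raise NotImplementedError

    def mean(self) -> float:
        raise NotImplementedError

    def ppf(self, q: float) -> float:
        raise NotImplementedError

    def materialize(self, model: TrialModel, data: TrialData) -> "AnalysisPrior":
        """Resolve any data dependence, returning a concrete prior."""
        return self

    def curves(self, model: TrialModel, n: int, stats_arr: np.ndarray) -> PosteriorCurves:
        raise NotImplementedError


@dataclass(frozen=True)
class NormalPrior(AnalysisPrior):
    mu: float
    variance: float

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValueError("normal prior variance must be positive")

    def cdf(self, t):
        return stats.norm.cdf(t, self.mu, math.sqrt(self.variance))

    def mean(self) -> float:
        return self.mu

    def ppf(self, q):
        return stats.norm.ppf(q, self.mu, math.sqrt(self.variance))

    def curves(self, model, n, stats_arr):
        if model.family != NORMAL:
            raise ValueError("normal prior requires the normal outcome family")
        return _NormalCurves(self, model, n, np.asarray(stats_arr, dtype=float))


class _NormalCurves(PosteriorCurves):
    def __init__(self, prior: NormalPrior, model: TrialModel, n: int, ybar: np.ndarray):
        self.prior = prior
        self.model = model
        self.n = n
        self.ybar = ybar
        if n == 0:
            self.post_var = prior.variance
            self.post_mu = np.full_like(ybar, prior.mu)
        else:
            s2 = model.sigma2 / n
            prec = 1.0 / prior.variance + 1.0 / s2
            self.post_var = 1.0 / prec
            self.post_mu = self.post_var * (prior.mu / prior.variance + ybar / s2)

    def tail(self, t):
        return stats.norm.cdf(t, self.post_mu, math.sqrt(self.post_var))

    def mean(self):
        return self.post_mu

    def log_marginal(self):
        if self.n == 0:
            raise ValueError("marginal likelihood undefined without data")
        s2 = self.model.sigma2 / self.n
        return stats.norm.logpdf(self.ybar, self.prior.mu, math.sqrt(self.prior.variance + s2))

    def prior_mass_below(self, t):
        return np.full_like(self.ybar, self.prior.cdf(t))


@dataclass(frozen=True)
class BetaPrior(AnalysisPrior):
    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("beta prior parameters must be positive")

    def cdf(self, t):
        return stats.beta.cdf(t, self.a, self.b)

    def mean(self) -> float:
        return self.a / (self.a + self.b)

    def ppf(self, q):
        return stats.beta.ppf(q, self.a, self.b)

    def curves(self, model, n, stats_arr):
        if model.family != BINOMIAL:
            raise ValueError("beta prior requires the binomial outcome family")
        return _BetaCurves(self, n, np.asarray(stats_arr, dtype=float))


class _BetaCurves(PosteriorCurves):
    def __init__(self, prior: BetaPrior, n: int, y: np.ndarray):
        self.prior = prior
        self.n = n
        self.y = y
        self.post_a = prior.a + y
        self.post_b = prior.b + n - y

    def tail(self, t):
        return special.betainc(self.post_a, self.post_b, t)

    def mean(self):
        return self.post_a / (self.post_a + self.post_b)

    def log_marginal(self):
        if self.n == 0:
            raise ValueError("marginal likelihood undefined without data")
        n, y = self.n, self.y
        return (
            special.gammaln(n + 1)
            - special.gammaln(y + 1)
            - special.gammaln(n - y + 1)
            + special.betaln(self.post_a, self.post_b)
            - special.betaln(self.prior.a, self.prior.b)
        )

    def prior_mass_below(self, t):
        return np.full_like(self.y, self.prior.cdf(t))


@dataclass(frozen=True)
class PointMassPrior(AnalysisPrior):
    location: float

    def cdf(self, t):
        return 1.0 if self.location <= t else 0.0

    def mean(self) -> float:
        return self.location

    def ppf(self, q):
        return self.location

    def curves(self, model, n, stats_arr):
        return _PointMassCurves(self, model, n, np.asarray(stats_arr, dtype=float))


class _PointMassCurves(PosteriorCurves):
    def __init__(self, prior, model, n, stats_arr):
        self.prior = prior
        self.model = model
        self.n = n
        self.stats_arr = stats_arr

    def tail(self, t):
        return np.full_like(self.stats_arr, self.prior.cdf(t))

    def mean(self):
        return np.full_like(self.stats_arr, self.prior.location)

    def log_marginal(self):
        if self.n == 0:
            raise ValueError("marginal likelihood undefined without data")
        return _loglik(self.model, self.n, self.stats_arr, self.prior.location)

    def prior_mass_below(self, t):
        return np.full_like(self.stats_arr, self.prior.cdf(t))


def _loglik(model: TrialModel, n: int, stats_arr: np.ndarray, theta: float) -> np.ndarray:
    """Log density/pmf of the sufficient statistic at a fixed theta."""
    if model.family == NORMAL:
        return stats.norm.logpdf(stats_arr, theta, model.stat_sd(n))
    return stats.binom.logpmf(np.round(stats_arr).astype(int), n, theta)


@dataclass(frozen=True)
class MixturePrior(AnalysisPrior):
    components: tuple
    weights: tuple

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if len(self.components) != len(w):
            raise ValueError("one weight per component required")
        if np.any(w < 0) or not math.isclose(w.sum(), 1.0, abs_tol=1e-12):
            raise ValueError("mixture weights must be nonnegative and sum to 1")

    def collapse(self) -> AnalysisPrior:
        """Drop zero-weight components; a single survivor is returned bare."""
        keep = [(c, w) for c, w in zip(self.components, self.weights) if w > 0]
        if len(keep) == 1:
            return keep[0][0]
        return MixturePrior(tuple(c for c, _ in keep), tuple(w for _, w in keep))

    def cdf(self, t):
        return float(sum(w * c.cdf(t) for c, w in zip(self.components, self.weights)))

    def mean(self) -> float:
        return float(sum(w * c.mean() for c, w in zip(self.components, self.weights)))

    def ppf(self, q):
        lo = min(c.ppf(1e-12) for c in self.components)
        hi = max(c.ppf(1 - 1e-12) for c in self.components)
        return optimize.brentq(lambda t: self.cdf(t) - q, lo, hi)

    def curves(self, model, n, stats_arr):
        prior = self.collapse()
        if not isinstance(prior, MixturePrior):
            return prior.curves(model, n, stats_arr)
        return _MixtureCurves(prior, model, n, np.asarray(stats_arr, dtype=float))


class _MixtureCurves(PosteriorCurves):
    """Standard conjugate-mixture algebra: posterior component weights are
    proportional to prior weight times component marginal likelihood."""

    def __init__(self, prior: MixturePrior, model, n, stats_arr):
        self.prior = prior
        self.comp_curves = [c.curves(model, n, stats_arr) for c in prior.components]
        self.stats_arr = stats_arr
        logw = np.log(np.asarray(prior.weights, dtype=float))
        if n == 0:
            self.post_logw = np.tile(logw[:, None], (1, stats_arr.size))
        else:
            logm = np.stack([cc.log_marginal() for cc in self.comp_curves])
            lw = logw[:, None] + logm
            self.post_logw = lw - special.logsumexp(lw, axis=0, keepdims=True)

    def posterior_weights(self) -> np.ndarray:
        return np.exp(self.post_logw)

    def tail(self, t):
        tails = np.stack([cc.tail(t) for cc in self.comp_curves])
        return np.sum(np.exp(self.post_logw) * tails, axis=0)

    def mean(self):
        means = np.stack([cc.mean() for cc in self.comp_curves])
        return np.sum(np.exp(self.post_logw) * means, axis=0)

    def log_marginal(self):
        logw = np.log(np.asarray(self.prior.weights, dtype=float))[:, None]
        logm = np.stack([cc.log_marginal() for cc in self.comp_curves])
        return special.logsumexp(logw + logm, axis=0)

    def prior_mass_below(self, t):
        return np.full_like(self.stats_arr, self.prior.cdf(t))


@dataclass(frozen=True)
class PowerPrior(AnalysisPrior):
    """Historical-data prior with discount exponent ``a0``.

    The effective prior is the baseline updated by the historical likelihood
    raised to the power ``a0``: for the normal family a conjugate update with
    effective sample size ``a0 * n0``; for the binomial family
    ``Beta(a + a0*s, b + a0*f)``.  ``a0`` may be a number in [0, 1] or the flag
    ``"empirical_bayes"``, in which case it is chosen per dataset to maximize
    the marginal likelihood of the current data.
    """

    historical: HistoricalData
    baseline: AnalysisPrior
    a0: Union[float, str] = EMPIRICAL_BAYES

    def __post_init__(self) -> None:
        if isinstance(self.a0, str):
            if self.a0 != EMPIRICAL_BAYES:
                raise ValueError(f"unknown a0 flag {self.a0!r}")
        elif not 0.0 <= self.a0 <= 1.0:
            raise ValueError("a0 must lie in [0, 1]")

    @property
    def data_dependent(self) -> bool:  # type: ignore[override]
        return self.a0 == EMPIRICAL_BAYES

    def with_a0(self, a0: float, model: TrialModel) -> AnalysisPrior:
        """Effective (materialized) prior for a fixed discount a0."""
        if a0 == 0.0:
            return self.baseline
        if isinstance(self.baseline, NormalPrior):
            ybar0 = float(self.historical.summary)
            return _power_normal(self.baseline, ybar0, a0 * self.historical.n0, model.sigma2)
        if isinstance(self.baseline, BetaPrior):
            s, f = self.historical.summary
            return BetaPrior(self.baseline.a + a0 * s, self.baseline.b + a0 * f)
        raise ValueError("power prior baseline must be normal or beta")

    def materialize(self, model: TrialModel, data: TrialData) -> AnalysisPrior:
        if not self.data_dependent:
            return self.with_a0(float(self.a0), model)
        a0 = eb_a0(self.historical, self.baseline, model, data)
        return self.with_a0(a0, model)

    def cdf(self, t):
        if self.data_dependent:
            raise ValueError("EB power prior has no data-free cdf; materialize first")
        raise ValueError("materialize the power prior (needs the outcome model)")

    def mean(self):
        raise ValueError("materialize the power prior first")

    def ppf(self, q):
        raise ValueError("materialize the power prior first")

    def curves(self, model, n, stats_arr):
        stats_arr = np.asarray(stats_arr, dtype=float)
        if not self.data_dependent:
            return self.with_a0(float(self.a0), model).curves(model, n, stats_arr)
        if n == 0:
            raise ValueError(
                "empirical-Bayes a0 is undefined without current data "
                "(the marginal likelihood m(y) does not exist for n = 0)"
            )
        return _EBPowerCurves(self, model, n, stats_arr)


def _power_normal(baseline: NormalPrior, ybar0: float, n_eff: float, sigma2: float) -> NormalPrior:
    prec = 1.0 / baseline.variance + n_eff / sigma2
    mu = (baseline.mu / baseline.variance + n_eff * ybar0 / sigma2) / prec
    return NormalPrior(mu, 1.0 / prec)


_A0_GRID = np.linspace(0.0, 1.0, 201)


class _EBPowerCurves(PosteriorCurves):
    """Per-statistic empirical-Bayes discount selection, fully vectorized.

    A 201-point grid scan over a0 is followed by a local parabolic refinement
    around the grid maximizer; ties break toward smaller a0 (first argmax).
    """

    def __init__(self, prior: PowerPrior, model, n, stats_arr):
        self.prior = prior
        self.model = model
        self.n = n
        self.stats_arr = stats_arr
        logm = np.stack(
            [prior.with_a0(a, model).curves(model, n, stats_arr).log_marginal() for a in _A0_GRID]
        )
        idx = np.argmax(logm, axis=0)
        a0 = _A0_GRID[idx]
        # parabolic refinement for interior maximizers
        interior = (idx > 0) & (idx < len(_A0_GRID) - 1)
        if np.any(interior):
            i = idx[interior]
            cols = np.flatnonzero(interior)
            f0, f1, f2 = logm[i - 1, cols], logm[i, cols], logm[i + 1, cols]
            denom = f0 - 2 * f1 + f2
            shift = np.where(denom < 0, 0.5 * (f0 - f2) / denom, 0.0)
            h = _A0_GRID[1] - _A0_GRID[0]
            a0 = a0.copy()
            a0[interior] = np.clip(_A0_GRID[i] + shift * h, 0.0, 1.0)
        self.a0 = a0
        self.logm = logm[idx, np.arange(stats_arr.size)]
        self._eff = self._effective_params()

    def _effective_params(self):
        hist = self.prior.historical
        base = self.prior.baseline
        if isinstance(base, NormalPrior):
            prec = 1.0 / base.variance + self.a0 * hist.n0 / self.model.sigma2
            mu = (
                base.mu / base.variance
                + self.a0 * hist.n0 * float(hist.summary) / self.model.sigma2
            ) / prec
            return ("normal", mu, 1.0 / prec)
        s, f = hist.summary
        return ("beta", base.a + self.a0 * s, base.b + self.a0 * f)

    def _posterior_params(self):
        kind, p1, p2 = self._eff
        if kind == "normal":
            s2 = self.model.sigma2 / self.n
            prec = 1.0 / p2 + 1.0 / s2
            mu = (p1 / p2 + self.stats_arr / s2) / prec
            return kind, mu, 1.0 / prec
        return kind, p1 + self.stats_arr, p2 + self.n - self.stats_arr

    def tail(self, t):
        kind, p1, p2 = self._posterior_params()
        if kind == "normal":
            return stats.norm.cdf(t, p1, np.sqrt(p2))
        return special.betainc(p1, p2, t)

    def mean(self):
        kind, p1, p2 = self._posterior_params()
        if kind == "normal":
            return p1
        return p1 / (p1 + p2)

    def log_marginal(self):
        return self.logm

    def prior_mass_below(self, t):
        kind, p1, p2 = self._eff
        if kind == "normal":
            return stats.norm.cdf(t, p1, np.sqrt(p2))
        return special.betainc(p1, p2, t)


# --------------------------------------------------------------------------
# sampling prior
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SamplingPrior:
    """Distribution of the data-generating effect; optionally truncated.

    A point-mass base reduces every averaged quantity to its conditional
    value, recovering frequentist operating characteristics.
    """

    base: AnalysisPrior
    truncation: tuple | None = None  # (lo, hi); either may be +/- inf

    def __post_init__(self) -> None:
        if self.truncation is not None:
            lo, hi = self.truncation
            if not lo < hi:
                raise ValueError("truncation interval must be nondegenerate")
            if self.mass(lo, hi) <= 0:
                raise ValueError("truncation interval has zero sampling-prior mass")

    @property
    def is_point(self) -> bool:
        return isinstance(self.base, PointMassPrior)

    def mass(self, lo: float, hi: float) -> float:
        return self.base.cdf(hi) - self.base.cdf(min(lo, hi))

    def bounds(self) -> tuple:
        lo, hi = -np.inf, np.inf
        if self.truncation is not None:
            lo, hi = self.truncation
        return lo, hi


# --------------------------------------------------------------------------
# scalar operations
# --------------------------------------------------------------------------


def _scalar_curves(prior: AnalysisPrior, model: TrialModel, data: TrialData) -> PosteriorCurves:
    data.validate(model)
    return prior.curves(model, data.n, np.asarray([data.stat], dtype=float))


def posterior(prior: AnalysisPrior, model: TrialModel, data: TrialData) -> AnalysisPrior:
    """Posterior distribution in the same representational family."""
    data.validate(model)
    prior = prior.materialize(model, data)
    if isinstance(prior, MixturePrior):
        prior = prior.collapse()
    if isinstance(prior, PointMassPrior) or data.n == 0:
        return prior
    if isinstance(prior, NormalPrior):
        cur = prior.curves(model, data.n, np.asarray([data.stat]))
        return NormalPrior(float(cur.post_mu[0]), float(cur.post_var))
    if isinstance(prior, BetaPrior):
        return BetaPrior(prior.a + data.stat, prior.b + data.n - data.stat)
    if isinstance(prior, MixturePrior):
        cur = prior.curves(model, data.n, np.asarray([data.stat], dtype=float))
        comps = tuple(posterior(c, model, data) for c in prior.components)
        w = tuple(float(x) for x in cur.posterior_weights()[:, 0])
        return MixturePrior(comps, w)
    raise TypeError(f"unsupported prior {type(prior).__name__}")


def posterior_tail_prob(prior, model, data, t: float) -> float:
    """P(theta <= t | data) under the (materialized) analysis prior."""
    prior = prior.materialize(model, data)
    return float(_scalar_curves(prior, model, data).tail(t)[0])


def posterior_mean(prior, model, data) -> float:
    """Posterior expectation of theta; the quadratic-loss estimator."""
    prior = prior.materialize(model, data)
    return float(_scalar_curves(prior, model, data).mean()[0])


def prior_mass_below(prior: AnalysisPrior, t: float) -> float:
    """CDF of the (proper, data-free) prior at ``t``."""
    if getattr(prior, "data_dependent", False):
        raise ValueError("EB power prior mass is data-dependent; materialize first")
    return float(prior.cdf(t))


def log_marginal(prior, model, data) -> float:
    """Log prior-predictive density of the observed sufficient statistic."""
    if data.n == 0:
        raise ValueError("marginal likelihood undefined without data")
    prior = prior.materialize(model, data)
    return float(_scalar_curves(prior, model, data).log_marginal()[0])


def eb_a0(historical: HistoricalData, baseline: AnalysisPrior, model: TrialModel,
          data: TrialData) -> float:
    """Empirical-Bayes discount: argmax over [0,1] of the marginal likelihood.

    Coarse 201-point grid scan followed by bounded scalar refinement; ties
    break toward the smaller a0.
    """
    if data.n < 1:
        raise ValueError("empirical-Bayes a0 requires at least one observation")
    pp = PowerPrior(historical, baseline, a0=0.5)
    stat = np.asarray([data.stat], dtype=float)

    def neg_logm(a0: float) -> float:
        return -float(pp.with_a0(a0, model).curves(model, data.n, stat).log_marginal()[0])

    vals = np.array([neg_logm(a) for a in _A0_GRID])
    i = int(np.argmin(vals))
    lo = _A0_GRID[max(i - 1, 0)]
    hi = _A0_GRID[min(i + 1, len(_A0_GRID) - 1)]
    if lo == hi:
        return float(_A0_GRID[i])
    res = optimize.minimize_scalar(neg_logm, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    # keep the grid point if the refinement did not actually improve
    if res.fun <= vals[i]:
        return float(np.clip(res.x, 0.0, 1.0))
    return float(_A0_GRID[i])
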