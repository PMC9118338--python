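"""Operating characteristics conditional on a fixed true effect theta.

For the binomial family everything is computed by exact enumeration over the
outcome space y in {0..n}.  For the normal family the decision functions are
evaluated on a fixed scan grid of the sufficient statistic ybar, every
decision boundary is then sharpened by root-finding on the continuous
posterior-probability margins, and conditional rejection/relevance
probabilities become exact Gaussian interval masses.  Smooth integrands
(mean squared error, Phase-III loss distributions) are integrated by
Gauss–Hermite quadrature on ybar ~ N(theta, sigma2/n).

The decision indicators depend on the analysis prior, the costs and the
sample size — never on theta — so one :class:`RejectionProfile` per sample
size serves every theta at which the design is probed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy import optimize, stats

from .decisions import CostSpec, Hypotheses, PLAIN
from .models import (
    BINOMIAL,
    NORMAL,
    AnalysisPrior,
    SamplingPrior,
    TrialModel,
)

__all__ = [
    "OutcomeGrid",
    "RejectionProfile",
    "ConditionalOC",
    "Phase3Spec",
    "make_outcome_grid",
    "rejection_profile",
    "cond_error_rate",
    "cond_mse",
    "cond_indeterminate",
    "phase3_realized",
    "cond_loss_quantiles",
]

GH_ORDER = 199
SCAN_POINTS = 1601
SCAN_PAD_SD = 8.5


@dataclass(frozen=True)
class Phase3Spec:
    """Targets for the follow-up Phase III trial.

    ``target_power`` is the power the Phase III trial is sized for (taking the
    current posterior mean as the true effect), ``alpha3`` its one-sided test
    level, and ``1 - zeta`` the quantile used to summarize "extreme" power
    loss and sample-size gain.  ``n_cap`` bounds the computed Phase III sample
    size, which diverges as the estimated effect approaches theta0.
    """

    target_power: float = 0.9
    alpha3: float = 0.025
    zeta: float = 0.2
    n_cap: float = 1e6

    def __post_init__(self) -> None:
        if not 0 < self.target_power < 1:
            raise ValueError("target_power must lie in (0,1)")
        if not 0 < self.alpha3 < 0.5:
            raise ValueError("alpha3 must lie in (0,0.5)")
        if not 0 < self.zeta < 1:
            raise ValueError("zeta must lie in (0,1)")


@dataclass(frozen=True)
class OutcomeGrid:
    """Outcome space of the sufficient statistic for one sample size.

    Binomial: ``nodes`` are all counts 0..n and ``weights(theta)`` the exact
    pmf.  Normal: ``nodes`` form a fixed scan grid used to locate decision
    boundaries; ``weights(theta)`` returns Gauss–Hermite points/probabilities
    centered at theta for smooth integrands.
    """

    family: str
    n: int
    nodes: np.ndarray
    stat_sd: float | None = None  # sigma/sqrt(n), normal only
    gh_order: int = GH_ORDER

    def weights(self, theta: float) -> tuple[np.ndarray, np.ndarray]:
        """(points, probabilities) of the outcome distribution at theta."""
        if self.family == BINOMIAL:
            return self.nodes, stats.binom.pmf(self.nodes, self.n, theta)
        x, w = hermegauss(self.gh_order)
        return theta + self.stat_sd * x, w / np.sqrt(2.0 * np.pi)


def make_outcome_grid(model: TrialModel, n: int, span: tuple | None = None,
                      sp: SamplingPrior | None = None,
                      scan_points: int = SCAN_POINTS,
                      gh_order: int = GH_ORDER) -> OutcomeGrid:
    """Build the outcome grid; the normal scan span must cover every theta the
    grid will be probed at, widened by ``SCAN_PAD_SD`` statistic SDs."""
    if model.family == BINOMIAL:
        return OutcomeGrid(BINOMIAL, n, np.arange(n + 1))
    sd = model.stat_sd(n)
    if span is None:
        if sp is None:
            raise ValueError("normal outcome grid needs a span or a sampling prior")
        lo = sp.base.ppf(1e-10)
        hi = sp.base.ppf(1 - 1e-10)
        tlo, thi = sp.bounds()
        lo, hi = max(lo, tlo), min(hi, thi)
        span = (lo, hi)
    nodes = np.linspace(span[0] - SCAN_PAD_SD * sd, span[1] + SCAN_PAD_SD * sd, scan_points)
    return OutcomeGrid(NORMAL, n, nodes, stat_sd=sd, gh_order=gh_order)


# --------------------------------------------------------------------------
# rejection profile
# --------------------------------------------------------------------------


@dataclass
class RejectionProfile:
    """Per-node decisions plus (normal family) refined decision boundaries.

    ``reject_breaks`` / ``relevant_breaks`` are sorted breakpoint arrays: the
    decision region is the union of intervals (breaks[0], breaks[1]),
    (breaks[2], breaks[3]), ... with +/- inf endpoints allowed.
    """

    grid: OutcomeGrid
    reject: np.ndarray
    relevant: np.ndarray
    post_mean: np.ndarray
    reject_breaks: np.ndarray | None = None
    relevant_breaks: np.ndarray | None = None
    post_mean_fn: Callable[[np.ndarray], np.ndarray] | None = None

    def reject_at(self, points: np.ndarray) -> np.ndarray:
        if self.grid.family == BINOMIAL:
            return self.reject[np.round(points).astype(int)]
        return _in_union(self.reject_breaks, points)

    def relevant_at(self, points: np.ndarray) -> np.ndarray:
        if self.grid.family == BINOMIAL:
            return self.relevant[np.round(points).astype(int)]
        return _in_union(self.relevant_breaks, points)


def _in_union(breaks: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Membership of x in the interval union encoded by sorted breakpoints."""
    return np.searchsorted(breaks, x, side="right") % 2 == 1


def _union_mass(breaks: np.ndarray, theta: np.ndarray, sd: float) -> np.ndarray:
    """P(ybar in union | theta) for ybar ~ N(theta, sd^2); vectorized in theta."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    cdf = stats.norm.cdf((breaks[None, :] - theta[:, None]) / sd)
    return np.sum(cdf[:, 1::2] - cdf[:, 0::2], axis=1)


def _indicator_to_breaks(flags: np.ndarray, nodes: np.ndarray,
                         margin: Callable[[float], float]) -> np.ndarray:
    """Refine a scanned indicator into precise interval breakpoints.

    ``margin`` is a continuous function positive exactly where the indicator
    holds; each sign change between adjacent scan nodes is located by Brent's
    method.  Regions touching the scan ends extend to +/- infinity (the scan
    span is padded far beyond any probed theta, so the associated mass is
    negligible even if the asymptotic decision were misjudged).
    """
    breaks: list[float] = []
    if flags[0]:
        breaks.append(-np.inf)
    idx = np.flatnonzero(flags[:-1] != flags[1:])
    for i in idx:
        a, b = nodes[i], nodes[i + 1]
        fa, fb = margin(a), margin(b)
        if fa == 0.0 or fb == 0.0 or fa * fb > 0:
            breaks.append(0.5 * (a + b))
        else:
            breaks.append(optimize.brentq(margin, a, b, xtol=1e-13))
    if flags[-1]:
        breaks.append(np.inf)
    return np.asarray(breaks)


def rejection_profile(prior: AnalysisPrior, model: TrialModel, n: int,
                      costs: CostSpec, hyp: Hypotheses,
                      grid: OutcomeGrid) -> RejectionProfile:
    """Evaluate the test/relevance decisions and posterior mean on the grid.

    No monotonicity of the rejection region is assumed: adaptive priors
    (mixtures, EB power priors) may produce non-interval regions, which the
    breakpoint representation captures.
    """
    if grid.n != n:
        raise ValueError("grid was built for a different sample size")

    def evaluate(points: np.ndarray):
        cur = prior.curves(model, n, points)
        tail0 = cur.tail(hyp.theta0)
        tailR = cur.tail(hyp.thetaR)
        if costs.mode == PLAIN:
            gamma = np.full_like(tail0, costs.c0p / (costs.c0p + costs.c1p))
        else:
            p = cur.prior_mass_below(hyp.theta0)
            if np.any((p <= 0) | (p >= 1)):
                raise ValueError("prior mass on one side of theta0; threshold undefined")
            gamma = costs.c0p * p / (costs.c0p * p + costs.c1p * (1.0 - p))
        return tail0, tailR, gamma, cur.mean()

    tail0, tailR, gamma, pmean = evaluate(grid.nodes.astype(float))
    reject = tail0 < gamma
    relevant = tailR < 0.5

    if grid.family == BINOMIAL:
        return RejectionProfile(grid, reject, relevant, pmean)

    def reject_margin(y: float) -> float:
        t0, _, g, _ = evaluate(np.asarray([y]))
        return float(g[0] - t0[0])

    def relevant_margin(y: float) -> float:
        _, tR, _, _ = evaluate(np.asarray([y]))
        return float(0.5 - tR[0])

    return RejectionProfile(
        grid, reject, relevant, pmean,
        reject_breaks=_indicator_to_breaks(reject, grid.nodes, reject_margin),
        relevant_breaks=_indicator_to_breaks(relevant, grid.nodes, relevant_margin),
        post_mean_fn=lambda pts: prior.curves(model, n, pts).mean(),
    )


# --------------------------------------------------------------------------
# conditional quantities
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ConditionalOC:
    error_rate: float  # alpha(theta) for theta <= theta0, beta(theta) otherwise
    mse: float
    p_indeterminate: float


def p_reject(theta, profile: RejectionProfile) -> np.ndarray:
    """P(reject H0 | theta), vectorized in theta."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    g = profile.grid
    if g.family == BINOMIAL:
        pmf = stats.binom.pmf(g.nodes[None, :], g.n, theta[:, None])
        return pmf[:, profile.reject].sum(axis=1)
    return _union_mass(profile.reject_breaks, theta, g.stat_sd)


def cond_error_rate(theta: float, profile: RejectionProfile, grid: OutcomeGrid,
                    hyp: Hypotheses) -> float:
    """alpha(theta) = P(reject|theta) for theta <= theta0, else
    beta(theta) = 1 - P(reject|theta)."""
    pr = float(p_reject(theta, profile)[0])
    return pr if theta <= hyp.theta0 else 1.0 - pr


def cond_mse(theta, prior: AnalysisPrior, model: TrialModel, n: int,
             grid: OutcomeGrid) -> np.ndarray | float:
    """Mean squared error of the posterior mean at true effect theta."""
    scalar = np.isscalar(theta)
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    if grid.family == BINOMIAL:
        pm = prior.curves(model, n, grid.nodes.astype(float)).mean()
        pmf = stats.binom.pmf(grid.nodes[None, :], n, theta[:, None])
        out = np.sum(pmf * (pm[None, :] - theta[:, None]) ** 2, axis=1)
    else:
        x, w = hermegauss(grid.gh_order)
        w = w / np.sqrt(2.0 * np.pi)
        ybar = theta[:, None] + grid.stat_sd * x[None, :]
        pm = prior.curves(model, n, ybar.ravel()).mean().reshape(ybar.shape)
        out = np.sum(w[None, :] * (pm - theta[:, None]) ** 2, axis=1)
    return float(out[0]) if scalar else out


def cond_indeterminate(theta, profile: RejectionProfile, grid: OutcomeGrid) -> np.ndarray | float:
    """P(exactly one of significance and relevance | theta)."""
    scalar = np.isscalar(theta)
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    if grid.family == BINOMIAL:
        pmf = stats.binom.pmf(grid.nodes[None, :], grid.n, theta[:, None])
        xor = profile.reject ^ profile.relevant
        out = pmf[:, xor].sum(axis=1)
    else:
        p_r = _union_mass(profile.reject_breaks, theta, grid.stat_sd)
        p_v = _union_mass(profile.relevant_breaks, theta, grid.stat_sd)
        inter = _intersect_unions(profile.reject_breaks, profile.relevant_breaks)
        p_both = _union_mass(inter, theta, grid.stat_sd)
        out = p_r + p_v - 2.0 * p_both
    return float(out[0]) if scalar else out


def _intersect_unions(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Breakpoints of the intersection of two interval unions."""
    out: list[float] = []
    for i in range(0, len(a), 2):
        for j in range(0, len(b), 2):
            lo = max(a[i], b[j])
            hi = min(a[i + 1], b[j + 1])
            if lo < hi:
                out.extend((lo, hi))
    return np.asarray(out)


# --------------------------------------------------------------------------
# Phase III consequences
# --------------------------------------------------------------------------


def _effect_sd(model: TrialModel, theta) -> np.ndarray:
    """Per-observation SD used in the normal-approximation power formula."""
    if model.family == NORMAL:
        return np.sqrt(model.sigma2) * np.ones_like(theta)
    return np.sqrt(np.clip(theta * (1.0 - theta), 1e-12, None))


def phase3_required_n(theta_hat, theta0: float, model: TrialModel,
                      spec: Phase3Spec) -> np.ndarray:
    """Standard one-sided z-formula sample size at effect theta_hat - theta0,
    capped at ``spec.n_cap`` (the formula diverges as the effect vanishes)."""
    theta_hat = np.asarray(theta_hat, dtype=float)
    z = stats.norm.ppf(1 - spec.alpha3) + stats.norm.ppf(spec.target_power)
    effect = theta_hat - theta0
    sd = _effect_sd(model, theta_hat)
    with np.errstate(divide="ignore", over="ignore"):
        n3 = np.where(effect > 0, (z * sd / np.where(effect > 0, effect, 1.0)) ** 2, np.inf)
    return np.minimum(n3, spec.n_cap)


def phase3_power(n3, theta_true: float, theta0: float, model: TrialModel,
                 spec: Phase3Spec) -> np.ndarray:
    """Power of a Phase III trial of size n3 at the true effect."""
    sd = _effect_sd(model, np.asarray(theta_true, dtype=float))
    zcrit = stats.norm.ppf(1 - spec.alpha3)
    return stats.norm.cdf((theta_true - theta0) * np.sqrt(n3) / sd - zcrit)


def phase3_realized(outcome_posterior_mean, success, theta_true: float,
                    model: TrialModel, spec: Phase3Spec,
                    hyp: Hypotheses) -> tuple[np.ndarray, np.ndarray]:
    """(realized power, realized sample size) of the follow-up trial.

    Unsuccessful current trials (no significance, or no relevance) yield
    (0, 0): the Phase III trial is not run.  Successful ones size the trial
    by the z-formula with the current posterior mean playing the true effect,
    and the realized power is evaluated at the actual true effect.
    """
    theta_hat = np.asarray(outcome_posterior_mean, dtype=float)
    success = np.asarray(success, dtype=bool)
    n3 = phase3_required_n(theta_hat, hyp.theta0, model, spec)
    power = phase3_power(n3, theta_true, hyp.theta0, model, spec)
    return np.where(success, power, 0.0), np.where(success, n3, 0.0)


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    """Left-continuous (type 1) inverse-CDF quantile of a weighted sample."""
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    cum /= cum[-1]
    return float(v[np.searchsorted(cum, q, side="left")])


def cond_loss_quantiles(theta: float, prior: AnalysisPrior, model: TrialModel,
                        n: int, profile: RejectionProfile, grid: OutcomeGrid,
                        spec: Phase3Spec, hyp: Hypotheses) -> tuple[float, float]:
    """(1 - zeta) quantiles, over the outcome distribution at theta, of the
    Phase III power loss and sample-size gain.

    Power loss is target power minus realized power; sample-size gain is the
    realized size minus the size a trial at the *true* effect would need.
    Unsuccessful outcomes realize (0, 0), so their loss is the full target
    power and their gain is minus the reference size.
    """
    points, probs = grid.weights(theta)
    success = profile.reject_at(points) & profile.relevant_at(points)
    if grid.family == BINOMIAL:
        theta_hat = prior.curves(model, n, points.astype(float)).mean()
    else:
        theta_hat = profile.post_mean_fn(points)
    r_power, r_n = phase3_realized(theta_hat, success, theta, model, spec, hyp)
    ref_n = float(phase3_required_n(np.asarray([theta]), hyp.theta0, model, spec)[0])
    power_loss = spec.target_power - r_power
    n_gain = np.where(success, r_n - ref_n, -ref_n)
    q = 1.0 - spec.zeta
    return (_weighted_quantile(power_loss, probs, q),
            _weighted_quantile(n_gain, probs, q))
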