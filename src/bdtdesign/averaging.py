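"""Averages of conditional operating characteristics over the sampling prior.

Average error rates follow the convention that the type I rate averages over
the sampling prior renormalized to the null region (theta <= theta0) and the
type II rate over the alternative region; with the prior-odds-reweighted
costs this makes the test part of the integrated risk exactly
``c1' * avg_type1 + c0' * avg_type2`` — the weighted sum of average test
error rates (SATE).  The average MSE (AMSE) integrates over the whole
sampling prior, while the indeterminate-outcome probability and the extreme
Phase-III losses average over the sampling prior truncated from below at the
relevance threshold.

theta-integration runs in CDF space: Gauss–Legendre nodes on the quantile
scale u with theta = F_s^{-1}(u), which renormalizes truncations exactly and
absorbs unbounded beta densities at the support boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from numpy.polynomial.legendre import leggauss

from .conditional import (
    OutcomeGrid,
    Phase3Spec,
    RejectionProfile,
    cond_loss_quantiles,
    cond_mse,
    cond_indeterminate,
    make_outcome_grid,
    p_reject,
    rejection_profile,
)
from .decisions import CostSpec, Hypotheses
from .models import AnalysisPrior, SamplingPrior, TrialModel

__all__ = ["AveragedOC", "average_over_prior", "averaged_oc", "sampling_prior_costs"]

THETA_ORDER = 199
_QTAIL = 1e-8


@dataclass(frozen=True)
class AveragedOC:
    """Sampling-prior-averaged operating characteristics at one sample size."""

    avg_type1: float
    avg_type2: float
    sate: float
    amse: float
    avg_indeterminate: float | None = None
    avg_extreme_power_loss: float | None = None
    avg_extreme_n_gain: float | None = None


def average_over_prior(f: Callable[[np.ndarray], np.ndarray], sp: SamplingPrior,
                       truncation: tuple | None = None,
                       order: int = THETA_ORDER) -> float:
    """E[f(theta)] under the sampling prior, optionally truncated.

    ``f`` must accept a vector of theta values.  A point-mass sampling prior
    returns f at the mass point (after checking it lies in the truncation).
    """
    lo, hi = (-np.inf, np.inf) if truncation is None else truncation
    tlo, thi = sp.bounds()
    lo, hi = max(lo, tlo), min(hi, thi)
    if sp.is_point:
        point = sp.base.location
        if not lo <= point <= hi:
            raise ValueError("point-mass sampling prior lies outside the truncation")
        return float(np.atleast_1d(f(np.asarray([point])))[0])
    u_lo = sp.base.cdf(lo) if np.isfinite(lo) else 0.0
    u_hi = sp.base.cdf(hi) if np.isfinite(hi) else 1.0
    theta, w = _theta_nodes(sp, u_lo, u_hi, order)
    vals = np.asarray(f(theta))
    return float(np.sum(w * vals))


def _theta_nodes(sp: SamplingPrior, u_lo: float, u_hi: float,
                 order: int) -> tuple[np.ndarray, np.ndarray]:
    """Quantile-space Gauss–Legendre nodes mapped to theta, with weights
    normalized to sum to one (a conditional average over the truncation)."""
    u_lo, u_hi = max(u_lo, _QTAIL), min(u_hi, 1.0 - _QTAIL)
    if u_hi <= u_lo:
        raise ValueError("truncation interval carries no sampling-prior mass")
    x, w = leggauss(order)
    u = 0.5 * (u_hi - u_lo) * x + 0.5 * (u_hi + u_lo)
    theta = np.asarray([sp.base.ppf(ui) for ui in u]) if _needs_loop(sp) else sp.base.ppf(u)
    return np.asarray(theta, dtype=float), w / 2.0


def _needs_loop(sp: SamplingPrior) -> bool:
    # mixture ppf is scalar root-finding; normal/beta ppf vectorize
    return not hasattr(sp.base, "a") and not hasattr(sp.base, "mu")


def averaged_oc(prior: AnalysisPrior, model: TrialModel, n: int, costs: CostSpec,
                hyp: Hypotheses, sp: SamplingPrior,
                p3: Phase3Spec | None = None,
                grid: OutcomeGrid | None = None,
                profile: RejectionProfile | None = None,
                include_monitors: bool = True,
                theta_order: int = THETA_ORDER) -> AveragedOC:
    """All sampling-prior-averaged operating characteristics at sample size n.

    With a point-mass sampling prior the error rate on the side of theta0
    holding the mass point is the conditional rate there and the other rate
    (whose truncation has no mass) is NaN, as is the SATE.
    """
    if grid is None:
        grid = make_outcome_grid(model, n, sp=sp)
    if profile is None:
        profile = rejection_profile(prior, model, n, costs, hyp, grid)

    alpha = lambda th: p_reject(th, profile)
    beta = lambda th: 1.0 - p_reject(th, profile)

    lo, hi = sp.bounds()
    if sp.is_point:
        point = sp.base.location
        if point <= hyp.theta0:
            a_bar, b_bar = float(alpha(np.asarray([point]))[0]), np.nan
        else:
            a_bar, b_bar = np.nan, float(beta(np.asarray([point]))[0])
    else:
        has_null = sp.mass(lo, min(hyp.theta0, hi)) > 0
        has_alt = sp.mass(max(hyp.theta0, lo), hi) > 0
        a_bar = (average_over_prior(alpha, sp, (lo, hyp.theta0), theta_order)
                 if has_null else np.nan)
        b_bar = (average_over_prior(beta, sp, (hyp.theta0, hi), theta_order)
                 if has_alt else np.nan)
    sate = costs.c1p * a_bar + costs.c0p * b_bar

    amse = average_over_prior(
        lambda th: cond_mse(th, prior, model, n, grid), sp, None, theta_order)

    if not include_monitors:
        return AveragedOC(a_bar, b_bar, sate, amse)

    p3 = p3 or Phase3Spec()
    rel_trunc = (hyp.thetaR, hi)

    if sp.is_point:
        point = sp.base.location
        ind = cond_indeterminate(point, profile, grid)
        if point <= hyp.thetaR:  # monitors are defined for theta > thetaR only
            return AveragedOC(a_bar, b_bar, sate, amse, ind, np.nan, np.nan)
        pl, ng = cond_loss_quantiles(point, prior, model, n, profile, grid, p3, hyp)
        return AveragedOC(a_bar, b_bar, sate, amse, ind, pl, ng)

    ind = average_over_prior(
        lambda th: cond_indeterminate(th, profile, grid), sp, rel_trunc, theta_order)

    nodes, w = _theta_nodes(sp, sp.base.cdf(max(hyp.thetaR, lo)),
                            1.0 if not np.isfinite(hi) else sp.base.cdf(hi),
                            theta_order)
    losses = np.asarray([
        cond_loss_quantiles(float(t), prior, model, n, profile, grid, p3, hyp)
        for t in nodes
    ])
    avg_pl = float(np.sum(w * losses[:, 0]))
    avg_ng = float(np.sum(w * losses[:, 1]))
    return AveragedOC(a_bar, b_bar, sate, amse, ind, avg_pl, avg_ng)


def sampling_prior_costs(costs: CostSpec, sp: SamplingPrior,
                         hyp: Hypotheses) -> tuple[float, float]:
    """Reweighted test-error costs under the sampling prior:
    c0 = c0'/P(theta>theta0), c1 = c1'/P(theta<=theta0)."""
    p = float(sp.base.cdf(hyp.theta0))
    if not 0.0 < p < 1.0:
        raise ValueError(
            "sampling prior has mass on one side of theta0 only; use a "
            "point-mass sampling prior for frequentist operating characteristics"
        )
    return costs.c0p / (1.0 - p), costs.c1p / p
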