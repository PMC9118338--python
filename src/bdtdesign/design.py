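"""Sample-size selection by integrated-risk minimization and goal sampling.

The workflow mirrors how a trial statistician would use the framework:

1. :func:`oc_curve` tabulates SATE(n), AMSE(n) and the monitoring quantities
   over a sample-size grid for a chosen analysis/sampling prior pair.
2. Goal sampling picks the smallest n meeting operating-characteristic
   targets (:func:`goal_n`); the per-observation costs implicit in those
   choices follow from the curve derivatives (:func:`unit_cost`,
   :func:`elicit_costs`), together with the testing-vs-estimation weight
   w = n_SATE / (n_SATE + n_AMSE).
3. :func:`integrated_risk` assembles
   r(n) = (w/c_n^SATE) SATE(n) + ((1-w)/c_n^AMSE) AMSE(n) + n
   and :func:`optimal_n` minimizes it over the grid.
4. :func:`sensitivity_scan` repeats the optimization over grids of sampling
   priors (and several analysis priors) with the cost elicitation held fixed,
   exposing how prior-data conflict moves the optimum.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .averaging import AveragedOC, averaged_oc, sampling_prior_costs
from .conditional import Phase3Spec
from .decisions import CostSpec, Hypotheses
from .models import AnalysisPrior, SamplingPrior, TrialModel

logger = logging.getLogger(__name__)

__all__ = [
    "GoalTargets",
    "CostElicitation",
    "RiskCurve",
    "DesignResult",
    "oc_curve",
    "smooth_curve",
    "unit_cost",
    "elicit_costs",
    "integrated_risk",
    "integrated_risk_raw",
    "optimal_n",
    "goal_n",
    "sensitivity_scan",
]


@dataclass(frozen=True)
class GoalTargets:
    """Sample sizes implied by testing (n_sate) and estimation (n_amse) goals."""

    n_sate: int
    n_amse: int
    target_sate: float | None = None
    target_amse: float | None = None

    def __post_init__(self) -> None:
        if self.n_sate < 1 or self.n_amse < 1:
            raise ValueError("goal sample sizes must be >= 1")


@dataclass(frozen=True)
class CostElicitation:
    """Per-observation costs and the derived risk weights.

    The identities cq = (1-w) cn_sate / (w cn_amse) and cn = cn_sate / w link
    the two-curve normalization back to the explicit-cost parameterization.
    """

    cn_sate: float
    cn_amse: float
    w: float

    def __post_init__(self) -> None:
        if self.cn_sate <= 0 or self.cn_amse <= 0:
            raise ValueError("unit costs must be positive")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("w must lie in [0,1]")

    @property
    def cq(self) -> float:
        return (1.0 - self.w) * self.cn_sate / (self.w * self.cn_amse)

    @property
    def cn(self) -> float:
        return self.cn_sate / self.w


@dataclass
class RiskCurve:
    """Operating characteristics (and, once costs are known, the risk) per n."""

    n_grid: np.ndarray
    sate: np.ndarray
    amse: np.ndarray
    avg_type1: np.ndarray
    avg_type2: np.ndarray
    avg_indeterminate: np.ndarray | None = None
    avg_extreme_power_loss: np.ndarray | None = None
    avg_extreme_n_gain: np.ndarray | None = None
    risk: np.ndarray | None = None
    costs: CostElicitation | None = None

    def to_frame(self) -> pd.DataFrame:
        cols = {"n": self.n_grid, "sate": self.sate, "amse": self.amse,
                "avg_type1": self.avg_type1, "avg_type2": self.avg_type2}
        for name in ("avg_indeterminate", "avg_extreme_power_loss",
                     "avg_extreme_n_gain", "risk"):
            val = getattr(self, name)
            if val is not None:
                cols[name] = val
        return pd.DataFrame(cols)


@dataclass(frozen=True)
class DesignResult:
    n_opt: int
    risk_at_opt: float
    oc_at_opt: AveragedOC


def oc_curve(prior: AnalysisPrior, model: TrialModel, costs: CostSpec,
             hyp: Hypotheses, sp: SamplingPrior,
             n_grid: Sequence[int],
             p3: Phase3Spec | None = None,
             include_monitors: bool = True,
             theta_order: int | None = None) -> RiskCurve:
    """Tabulate averaged operating characteristics over a sample-size grid."""
    n_grid = np.asarray(list(n_grid), dtype=int)
    if n_grid.size == 0 or np.any(np.diff(n_grid) <= 0):
        raise ValueError("n_grid must be nonempty and strictly increasing")
    kw = {} if theta_order is None else {"theta_order": theta_order}
    rows = [averaged_oc(prior, model, int(n), costs, hyp, sp, p3=p3,
                        include_monitors=include_monitors, **kw)
            for n in n_grid]
    get = lambda name: np.asarray([getattr(r, name) for r in rows], dtype=float)
    curve = RiskCurve(n_grid, get("sate"), get("amse"), get("avg_type1"),
                      get("avg_type2"))
    if include_monitors:
        curve.avg_indeterminate = get("avg_indeterminate")
        curve.avg_extreme_power_loss = get("avg_extreme_power_loss")
        curve.avg_extreme_n_gain = get("avg_extreme_n_gain")
    return curve


def smooth_curve(values: np.ndarray, n_grid: np.ndarray,
                 bandwidth: int = 15) -> np.ndarray:
    """Local quadratic least-squares smoothing over a window of grid points.

    Reproduces polynomials up to degree two exactly; used before numerical
    differentiation of the jagged binomial operating-characteristic curves.
    """
    values = np.asarray(values, dtype=float)
    if bandwidth < 3:
        raise ValueError("bandwidth must be at least 3 grid points")
    if bandwidth > len(values):
        warnings.warn("smoothing bandwidth exceeds grid length; clamping")
        bandwidth = len(values)
    if bandwidth % 2 == 0:
        bandwidth -= 1
    if bandwidth < 3:
        return values.copy()
    return savgol_filter(values, bandwidth, polyorder=2, mode="interp")


def unit_cost(curve_values: np.ndarray, n_grid: np.ndarray, n_star: int,
              smooth: bool = False, bandwidth: int = 15) -> float:
    """Implicit per-observation cost: minus the curve slope at n_star.

    Central finite difference over adjacent grid points (one-sided at the
    grid ends), optionally after local-quadratic smoothing.
    """
    values = np.asarray(curve_values, dtype=float)
    n_grid = np.asarray(n_grid)
    if smooth:
        values = smooth_curve(values, n_grid, bandwidth)
    idx = int(np.flatnonzero(n_grid == n_star)[0]) if n_star in n_grid else None
    if idx is None:
        raise ValueError(f"n_star={n_star} is not on the grid")
    i0, i1 = max(idx - 1, 0), min(idx + 1, len(n_grid) - 1)
    cost = -(values[i1] - values[i0]) / (n_grid[i1] - n_grid[i0])
    if cost <= 0:
        raise ValueError(
            "curve is locally non-decreasing at n_star (cost would be <= 0); "
            "consider smoothing the curve first"
        )
    return float(cost)


def elicit_costs(targets: GoalTargets, sate_curve: np.ndarray,
                 amse_curve: np.ndarray, n_grid: np.ndarray,
                 smooth_sate: bool = False, smooth_amse: bool = False,
                 bandwidth_sate: int = 101, bandwidth_amse: int = 15) -> CostElicitation:
    """Per-observation costs at the goal sample sizes and the weight
    w = n_sate / (n_sate + n_amse).

    The smoothing bandwidths are separate because the two binomial curves are
    jagged on very different amplitudes: the SATE sawtooth (the rejection
    boundary advances every ~1/theta_R sample sizes) dwarfs its own trend
    slope, so recovering the trend derivative needs a window spanning many
    tooth periods, while the AMSE teeth are two orders of magnitude smaller
    and a short window avoids biasing the derivative with trend curvature.
    """
    cn_sate = unit_cost(sate_curve, n_grid, targets.n_sate, smooth_sate, bandwidth_sate)
    cn_amse = unit_cost(amse_curve, n_grid, targets.n_amse, smooth_amse, bandwidth_amse)
    w = targets.n_sate / (targets.n_sate + targets.n_amse)
    return CostElicitation(cn_sate, cn_amse, w)


def integrated_risk(curve: RiskCurve, costs: CostElicitation) -> RiskCurve:
    """Fill r(n) = (w/cn_sate) SATE(n) + ((1-w)/cn_amse) AMSE(n) + n."""
    risk = (costs.w / costs.cn_sate * curve.sate
            + (1.0 - costs.w) / costs.cn_amse * curve.amse
            + curve.n_grid)
    return replace(curve, risk=risk, costs=costs)


def integrated_risk_raw(curve: RiskCurve, c0: float, c1: float, cq: float,
                        cn: float, sp: SamplingPrior, hyp: Hypotheses) -> np.ndarray:
    """Explicit-cost parameterization of the risk, for users with actual
    (e.g. monetary) costs: c1*P_s(H0)*avg_type1 + c0*P_s(H1)*avg_type2
    + cq*AMSE + cn*n."""
    p0 = float(sp.base.cdf(hyp.theta0))
    return (c1 * p0 * curve.avg_type1 + c0 * (1 - p0) * curve.avg_type2
            + cq * curve.amse + cn * curve.n_grid)


def optimal_n(curve: RiskCurve) -> DesignResult:
    """Grid argmin of the filled risk; ties break toward the smallest n."""
    if curve.risk is None:
        raise ValueError("risk not filled; call integrated_risk first")
    idx = int(np.argmin(curve.risk))
    if idx == len(curve.n_grid) - 1:
        warnings.warn("risk minimum attained at the upper grid boundary; "
                      "the grid truncation may be active")
    oc = AveragedOC(curve.avg_type1[idx], curve.avg_type2[idx], curve.sate[idx],
                    curve.amse[idx])
    return DesignResult(int(curve.n_grid[idx]), float(curve.risk[idx]), oc)


def goal_n(curve: RiskCurve, target_sate: float | None = None,
           target_amse: float | None = None,
           target_type1: float | None = None,
           target_type2: float | None = None,
           monitor_bounds: dict | None = None,
           n_sate: int | None = None,
           n_amse: int | None = None) -> GoalTargets:
    """Goal sampling: smallest n meeting each target *and every larger grid n*
    (the "holds from here on" rule guards binomial non-monotonicity).

    The testing goal may be a SATE bound or bounds on the average error
    rates; the estimation goal an AMSE bound and/or bounds on the monitors
    (``avg_indeterminate``, ``avg_extreme_power_loss``, ``avg_extreme_n_gain``).
    Either goal sample size may instead be fixed directly (``n_sate`` /
    ``n_amse``), reflecting a size the investigator deems acceptable after
    inspecting the curves.
    """
    def first_holding(ok: np.ndarray, what: str, best) -> int:
        holds = np.flip(np.logical_and.accumulate(np.flip(ok)))
        if not holds.any():
            raise ValueError(f"{what} target unachievable on the grid "
                             f"(best achieved: {best:.4g})")
        return int(curve.n_grid[int(np.argmax(holds))])

    if n_sate is not None:
        pass
    elif target_type1 is not None or target_type2 is not None:
        ok = np.ones(len(curve.n_grid), dtype=bool)
        best = np.inf
        if target_type1 is not None:
            ok &= curve.avg_type1 <= target_type1
            best = float(np.nanmin(curve.avg_type1))
        if target_type2 is not None:
            ok &= curve.avg_type2 <= target_type2
            best = float(np.nanmin(curve.avg_type2))
        n_sate = first_holding(ok, "average error rate", best)
    elif target_sate is not None:
        n_sate = first_holding(curve.sate <= target_sate, "SATE", np.nanmin(curve.sate))
    else:
        raise ValueError("a testing target (SATE or error-rate bound) is required")

    if n_amse is None:
        ok = np.ones(len(curve.n_grid), dtype=bool)
        best = np.inf
        if target_amse is not None:
            ok &= curve.amse <= target_amse
            best = float(np.nanmin(curve.amse))
        for name, bound in (monitor_bounds or {}).items():
            vals = getattr(curve, name)
            if vals is None:
                raise ValueError(f"monitor {name!r} was not computed on this curve")
            ok &= vals <= bound
        if target_amse is None and not monitor_bounds:
            raise ValueError("an estimation target (AMSE or monitor bounds) is required")
        n_amse = first_holding(ok, "estimation", best)
    return GoalTargets(n_sate, n_amse, target_sate, target_amse)


def sensitivity_scan(analysis_priors: dict, sp_grid: Sequence[SamplingPrior],
                     model: TrialModel, costs: CostSpec,
                     elicitation: CostElicitation, hyp: Hypotheses,
                     n_grid: Sequence[int],
                     p3: Phase3Spec | None = None,
                     fixed_n: int | None = None,
                     sp_labels: Sequence | None = None) -> pd.DataFrame:
    """Long-format sensitivity table over sampling-prior and analysis-prior
    grids, reusing one frozen cost elicitation for every cell.

    With ``fixed_n`` the optimization is skipped and the risk is evaluated at
    that single sample size.  Failed cells are recorded with NaNs and the
    scan continues.
    """
    records = []
    labels = sp_labels if sp_labels is not None else range(len(sp_grid))
    for sp_label, sp in zip(labels, sp_grid):
        for prior_name, prior in analysis_priors.items():
            rec = {"sampling_prior": sp_label, "analysis_prior": prior_name}
            try:
                c0, c1 = sampling_prior_costs(costs, sp, hyp)
                grid_ns = [fixed_n] if fixed_n is not None else n_grid
                curve = oc_curve(prior, model, costs, hyp, sp, grid_ns,
                                 p3=p3, include_monitors=False)
                curve = integrated_risk(curve, elicitation)
                if fixed_n is not None:
                    idx = 0
                    n_sel = fixed_n
                else:
                    res = optimal_n(curve)
                    n_sel = res.n_opt
                    idx = int(np.flatnonzero(curve.n_grid == n_sel)[0])
                rec.update(n=n_sel, risk=float(curve.risk[idx]),
                           avg_type1=float(curve.avg_type1[idx]),
                           avg_type2=float(curve.avg_type2[idx]),
                           amse=float(curve.amse[idx]), c0=c0, c1=c1)
            except Exception as exc:  # noqa: BLE001 - record and continue
                logger.warning("scan cell (%s, %s) failed: %s", sp_label,
                               prior_name, exc)
                rec.update(n=np.nan, risk=np.nan, avg_type1=np.nan,
                           avg_type2=np.nan, amse=np.nan, c0=np.nan, c1=np.nan,
                           error=str(exc))
            records.append(rec)
    return pd.DataFrame.from_records(records)
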