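"""End-to-end reproduction of the two built-in scenarios.

Each entry pairs a quantity recomputed from scratch by the package with the
reference value reported for that scenario in the literature.  The normal
scenario designs under the vague analysis prior; the binomial proof-of-concept
scenario under the RSN prior, including the conditional power of the original
25-patient design under the plain 0.95 posterior-probability rule.
"""

from __future__ import annotations

import numpy as np

from .conditional import make_outcome_grid, p_reject, rejection_profile
from .config import load_fixture
from .decisions import CostSpec
from .design import (
    CostElicitation,
    elicit_costs,
    goal_n,
    integrated_risk,
    oc_curve,
    optimal_n,
)

#: published reference values for the shipped scenarios
REFERENCES = {
    "normal_conjugate": {
        "n_sate": 160, "sate_at_n_sate": 0.027, "amse_at_n_amse": 0.006,
        "cn_sate": 8.511e-5, "cn_amse": 3.098e-5, "w": 0.471,
    },
    "binomial_poc": {
        "power_0275_n25": 0.858, "n_sate": 21, "n_amse": 74,
        "sate_at_n_sate": 0.058, "amse_at_n_amse": 0.0026,
        "cn_sate": 2.04e-4, "cn_amse": 3.421e-5, "w": 0.221,
        "n_opt_published_costs": 64,
    },
}

#: costs under which the published binomial optimum was derived
PUBLISHED_BINOMIAL_COSTS = CostElicitation(cn_sate=2.04e-4, cn_amse=3.421e-5, w=0.221)


def _entry(value: float, reference: float | None) -> dict:
    return {"value": float(value), "reference": reference}


def reproduce_normal() -> dict:
    cfg = load_fixture("normal_conjugate")
    prior = cfg.priors()["vague"]
    curve = oc_curve(prior, cfg.trial_model(), cfg.cost_spec(), cfg.hyp(),
                     cfg.sampling_prior(), cfg.n_grid(), include_monitors=False)
    targets = goal_n(curve, target_type2=cfg.goals.type2_max,
                     n_amse=cfg.goals.n_amse)
    sm = cfg.numerics.smoothing
    el = elicit_costs(targets, curve.sate, curve.amse, curve.n_grid,
                      smooth_sate=sm.smooth_sate, smooth_amse=sm.smooth_amse,
                      bandwidth_sate=sm.bandwidth_sate,
                      bandwidth_amse=sm.bandwidth_amse)
    ref = REFERENCES["normal_conjugate"]
    i_s = int(np.flatnonzero(curve.n_grid == targets.n_sate)[0])
    i_a = int(np.flatnonzero(curve.n_grid == targets.n_amse)[0])
    return {
        "n_sate": _entry(targets.n_sate, ref["n_sate"]),
        "sate_at_n_sate": _entry(curve.sate[i_s], ref["sate_at_n_sate"]),
        "amse_at_n_amse": _entry(curve.amse[i_a], ref["amse_at_n_amse"]),
        "cn_sate": _entry(el.cn_sate, ref["cn_sate"]),
        "cn_amse": _entry(el.cn_amse, ref["cn_amse"]),
        "w": _entry(el.w, ref["w"]),
    }


def reproduce_binomial() -> dict:
    cfg = load_fixture("binomial_poc")
    model, hyp, costs = cfg.trial_model(), cfg.hyp(), cfg.cost_spec()
    prior = cfg.priors()["rsn"]
    sp = cfg.sampling_prior()
    ref = REFERENCES["binomial_poc"]

    # conditional power of the original design: n=25, plain 0.05 threshold
    grid25 = make_outcome_grid(model, 25)
    plain = CostSpec(costs.c0p, costs.c1p, "plain")
    prof25 = rejection_profile(prior, model, 25, plain, hyp, grid25)
    power = float(p_reject(0.275, prof25)[0])

    curve = oc_curve(prior, model, costs, hyp, sp, cfg.n_grid(),
                     p3=cfg.phase3_spec(), include_monitors=True)
    targets = goal_n(curve, target_type1=cfg.goals.type1_max,
                     target_type2=cfg.goals.type2_max,
                     monitor_bounds={"avg_indeterminate": cfg.goals.indeterminate_max})
    sm = cfg.numerics.smoothing
    el = elicit_costs(targets, curve.sate, curve.amse, curve.n_grid,
                      smooth_sate=sm.smooth_sate, smooth_amse=sm.smooth_amse,
                      bandwidth_sate=sm.bandwidth_sate,
                      bandwidth_amse=sm.bandwidth_amse)
    i_s = int(np.flatnonzero(curve.n_grid == targets.n_sate)[0])
    i_a = int(np.flatnonzero(curve.n_grid == targets.n_amse)[0])
    risk_pub = integrated_risk(curve, PUBLISHED_BINOMIAL_COSTS)
    n_opt_pub = optimal_n(risk_pub).n_opt
    risk_el = integrated_risk(curve, el)
    n_opt_el = optimal_n(risk_el).n_opt
    return {
        "power_0275_n25": _entry(power, ref["power_0275_n25"]),
        "n_sate": _entry(targets.n_sate, ref["n_sate"]),
        "n_amse": _entry(targets.n_amse, ref["n_amse"]),
        "sate_at_n_sate": _entry(curve.sate[i_s], ref["sate_at_n_sate"]),
        "amse_at_n_amse": _entry(curve.amse[i_a], ref["amse_at_n_amse"]),
        "cn_sate": _entry(el.cn_sate, ref["cn_sate"]),
        "cn_amse": _entry(el.cn_amse, ref["cn_amse"]),
        "w": _entry(el.w, ref["w"]),
        "n_opt_published_costs": _entry(n_opt_pub, ref["n_opt_published_costs"]),
        "n_opt_elicited_costs": _entry(n_opt_el, None),
    }


def reproduce() -> dict:
    """Run both scenarios; returns {scenario: {quantity: {value, reference}}}."""
    return {
        "normal_conjugate": reproduce_normal(),
        "binomial_poc": reproduce_binomial(),
    }
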