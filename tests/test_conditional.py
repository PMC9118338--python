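"""Conditional operating characteristics: error rates, MSE, indeterminate
outcomes, and Phase-III power-loss/sample-size consequences."""

import math

import numpy as np
import pytest
from scipy import stats

import bdtdesign as bd
from bdtdesign.conditional import (
    Phase3Spec,
    cond_error_rate,
    cond_indeterminate,
    cond_loss_quantiles,
    cond_mse,
    make_outcome_grid,
    p_reject,
    phase3_realized,
    rejection_profile,
)


@pytest.fixture(scope="module")
def plain_costs():
    return bd.CostSpec(0.05, 0.95, "plain")


class TestRejectionProfile:
    def test_binomial_region_is_upper_tail(self, binomial_model, binomial_hyp,
                                           plain_costs):
        grid = make_outcome_grid(binomial_model, 25)
        prof = rejection_profile(bd.BetaPrior(0.0811, 1.0), binomial_model, 25,
                                 plain_costs, binomial_hyp, grid)
        assert list(prof.reject) == [y >= 5 for y in range(26)]

    def test_point_mass_prior_constant_profile(self, binomial_model, binomial_hyp,
                                               plain_costs):
        grid = make_outcome_grid(binomial_model, 10)
        prof = rejection_profile(bd.PointMassPrior(0.3), binomial_model, 10,
                                 plain_costs, binomial_hyp, grid)
        assert len(set(prof.reject.tolist())) == 1
        assert len(set(prof.relevant.tolist())) == 1

    def test_normal_region_is_half_line(self, normal_model, normal_hyp, costs,
                                        normal_sp):
        """A single-component normal prior has a monotone posterior tail, so
        the rejection region is one upper half-line whose boundary matches a
        direct root-find on the posterior probability."""
        n = 100
        grid = make_outcome_grid(normal_model, n, sp=normal_sp)
        prof = rejection_profile(bd.NormalPrior(0.0, 100.0), normal_model, n,
                                 costs, normal_hyp, grid)
        assert len(prof.reject_breaks) == 2
        assert prof.reject_breaks[1] == np.inf
        # oracle: gamma = 0.05 for this prior; critical ybar from the z-quantile
        prec = 1 / 100.0 + n
        crit = None
        from scipy.optimize import brentq
        crit = brentq(lambda yb: stats.norm.cdf(
            -(n * yb / prec) * math.sqrt(prec)) - 0.05, -1, 1)
        assert prof.reject_breaks[0] == pytest.approx(crit, abs=1e-10)


class TestConditionalErrorRate:
    def test_published_conditional_power(self, binomial_model, binomial_hyp,
                                         plain_costs):
        grid = make_outcome_grid(binomial_model, 25)
        prof = rejection_profile(bd.BetaPrior(0.0811, 1.0), binomial_model, 25,
                                 plain_costs, binomial_hyp, grid)
        beta = cond_error_rate(0.275, prof, grid, binomial_hyp)
        assert 1 - beta == pytest.approx(0.858, abs=2e-3)

    def test_alpha_at_theta0_matches_frequentist_level(self, normal_model,
                                                       normal_hyp, costs,
                                                       normal_sp):
        grid = make_outcome_grid(normal_model, 100, sp=normal_sp)
        prof = rejection_profile(bd.NormalPrior(0.0, 1e8), normal_model, 100,
                                 costs, normal_hyp, grid)
        assert cond_error_rate(0.0, prof, grid, normal_hyp) == \
            pytest.approx(0.05, abs=1e-4)

    def test_alpha_vanishes_far_below_threshold(self, normal_model, normal_hyp,
                                                costs, normal_sp):
        grid = make_outcome_grid(normal_model, 100, sp=normal_sp)
        prof = rejection_profile(bd.NormalPrior(0.25, 1 / 50), normal_model, 100,
                                 costs, normal_hyp, grid)
        assert cond_error_rate(-0.8, prof, grid, normal_hyp) < 1e-8

    def test_alpha_monotone_in_theta(self, normal_model, normal_hyp, costs,
                                     normal_sp, normal_priors):
        grid = make_outcome_grid(normal_model, 60, sp=normal_sp)
        prof = rejection_profile(normal_priors["informative"], normal_model, 60,
                                 costs, normal_hyp, grid)
        pr = p_reject(np.linspace(-0.5, 0.7, 49), prof)
        assert np.all(np.diff(pr) >= -1e-12)

    def test_exact_enumeration_vs_monte_carlo(self, binomial_model, binomial_hyp,
                                              costs, rng):
        """Exact binomial operating characteristics match simulated trials."""
        n, theta, reps = 40, 0.2, 10**5
        grid = make_outcome_grid(binomial_model, n)
        prior = bd.BetaPrior(0.0811, 1.0)
        prof = rejection_profile(prior, binomial_model, n, costs, binomial_hyp, grid)
        y = rng.binomial(n, theta, reps)
        sim_reject = prof.reject[y].mean()
        exact = float(p_reject(theta, prof)[0])
        se = math.sqrt(exact * (1 - exact) / reps)
        assert abs(sim_reject - exact) < 3 * se
        # and the MSE of the posterior mean
        pm = prior.curves(binomial_model, n, y.astype(float)).mean()
        sim_mse = np.mean((pm - theta) ** 2)
        exact_mse = cond_mse(theta, prior, binomial_model, n, grid)
        se_mse = np.std((pm - theta) ** 2) / math.sqrt(reps)
        assert abs(sim_mse - exact_mse) < 3 * se_mse


class TestConditionalMSE:
    def test_point_mass_prior(self, normal_model, normal_sp):
        grid = make_outcome_grid(normal_model, 50, sp=normal_sp)
        mse = cond_mse(0.1, bd.PointMassPrior(0.3), normal_model, 50, grid)
        assert mse == pytest.approx((0.1 - 0.3) ** 2, rel=1e-12)

    def test_vague_prior_approaches_sampling_variance(self, normal_model, normal_sp):
        grid = make_outcome_grid(normal_model, 200, sp=normal_sp)
        mse = cond_mse(0.25, bd.NormalPrior(0.0, 1e6), normal_model, 200, grid)
        assert mse == pytest.approx(1.0 / 200, rel=1e-3)

    @pytest.mark.parametrize("theta", [-0.2, 0.0, 0.15, 0.3])
    def test_conjugate_closed_form(self, theta, normal_model, normal_sp):
        """Quadrature equals shrinkage bias^2 + k^2 sigma^2/n to 1e-8."""
        n, prior = 80, bd.NormalPrior(0.25, 1 / 50)
        grid = make_outcome_grid(normal_model, n, sp=normal_sp)
        k = n / (1 / prior.variance + n)  # weight on ybar
        closed = ((1 - k) * (prior.mu - theta)) ** 2 + k**2 / n
        assert cond_mse(theta, prior, normal_model, n, grid) == \
            pytest.approx(closed, abs=1e-8)


class TestIndeterminate:
    def test_degenerate_profiles(self, binomial_model, binomial_hyp, plain_costs):
        grid = make_outcome_grid(binomial_model, 10)
        prof = rejection_profile(bd.BetaPrior(1, 1), binomial_model, 10,
                                 plain_costs, binomial_hyp, grid)
        prof.relevant = prof.reject.copy()
        assert cond_indeterminate(0.3, prof, grid) == 0.0
        prof.relevant = ~prof.reject
        assert cond_indeterminate(0.3, prof, grid) == pytest.approx(1.0)

    @pytest.mark.parametrize("family", ["binomial", "normal"])
    def test_outcome_probabilities_partition(self, family, binomial_model,
                                             normal_model, binomial_hyp,
                                             normal_hyp, costs, binomial_sp,
                                             normal_sp, binomial_priors,
                                             normal_priors):
        """P(success) + P(failure) + P(indeterminate) = 1 at every theta."""
        if family == "binomial":
            model, hyp, sp = binomial_model, binomial_hyp, binomial_sp
            prior, n, thetas = binomial_priors["rsn"], 30, [0.05, 0.15, 0.3]
        else:
            model, hyp, sp = normal_model, normal_hyp, normal_sp
            prior, n, thetas = normal_priors["robust_mixture"], 60, [-0.1, 0.1, 0.3]
        grid = make_outcome_grid(model, n, sp=sp)
        prof = rejection_profile(prior, model, n, costs, hyp, grid)
        for theta in thetas:
            if family == "binomial":
                _, probs = grid.weights(theta)
                succ = probs[prof.reject & prof.relevant].sum()
                fail = probs[~prof.reject & ~prof.relevant].sum()
                tol = 1e-12
            else:
                # independent oracle: dense Riemann sum of the decision
                # indicators against the outcome density
                sd = model.stat_sd(n)
                pts = np.linspace(theta - 8 * sd, theta + 8 * sd, 200001)
                probs = stats.norm.pdf(pts, theta, sd)
                probs /= probs.sum()
                r, v = prof.reject_at(pts), prof.relevant_at(pts)
                succ = probs[r & v].sum()
                fail = probs[~r & ~v].sum()
                tol = 1e-4
            ind = cond_indeterminate(theta, prof, grid)
            assert succ + fail + ind == pytest.approx(1.0, abs=tol)


class TestPhase3:
    def test_self_consistency(self, normal_model, normal_hyp):
        """Estimate equal to the truth realizes exactly the target power."""
        spec = Phase3Spec()
        power, n3 = phase3_realized(0.3, True, 0.3, normal_model, spec, normal_hyp)
        assert float(power) == pytest.approx(spec.target_power, rel=1e-12)
        z = stats.norm.ppf(0.975) + stats.norm.ppf(0.9)
        assert float(n3) == pytest.approx((z / 0.3) ** 2, rel=1e-12)

    def test_self_consistency_binomial(self, binomial_model, binomial_hyp):
        spec = Phase3Spec()
        power, _ = phase3_realized(0.275, True, 0.275, binomial_model, spec,
                                   binomial_hyp)
        assert float(power) == pytest.approx(spec.target_power, rel=1e-12)

    def test_unsuccessful_trial_realizes_nothing(self, normal_model, normal_hyp):
        spec = Phase3Spec()
        power, n3 = phase3_realized(0.3, False, 0.3, normal_model, spec, normal_hyp)
        assert float(power) == 0.0 and float(n3) == 0.0

    def test_overestimate_underpowers(self, normal_model, normal_hyp):
        """Sizing on an inflated estimate gives less than the target power."""
        spec = Phase3Spec()
        power, _ = phase3_realized(0.4, True, 0.25, normal_model, spec, normal_hyp)
        assert float(power) < spec.target_power

    def test_estimate_at_null_hits_the_cap(self, normal_model, normal_hyp):
        spec = Phase3Spec()
        _, n3 = phase3_realized(-0.01, True, 0.3, normal_model, spec, normal_hyp)
        assert float(n3) == spec.n_cap


class TestLossQuantiles:
    def test_all_failures_lose_full_target(self, binomial_model, binomial_hyp,
                                           plain_costs):
        grid = make_outcome_grid(binomial_model, 20)
        prior = bd.BetaPrior(0.0811, 1.0)
        prof = rejection_profile(prior, binomial_model, 20, plain_costs,
                                 binomial_hyp, grid)
        prof.reject = np.zeros_like(prof.reject)  # force no successes
        spec = Phase3Spec()
        pl, ng = cond_loss_quantiles(0.3, prior, binomial_model, 20, prof, grid,
                                     spec, binomial_hyp)
        assert pl == pytest.approx(spec.target_power)
        assert ng < 0  # gain is minus the reference size

    def test_perfect_estimation_zero_loss(self, normal_model, normal_hyp):
        """A point-mass analysis prior at the truth with certain success
        realizes the target exactly."""
        n = 50
        grid = make_outcome_grid(normal_model, n, span=(0.0, 0.6))
        prior = bd.PointMassPrior(0.3)
        prof = bd.RejectionProfile(
            grid,
            reject=np.ones(len(grid.nodes), dtype=bool),
            relevant=np.ones(len(grid.nodes), dtype=bool),
            post_mean=np.full(len(grid.nodes), 0.3),
            reject_breaks=np.asarray([-np.inf, np.inf]),
            relevant_breaks=np.asarray([-np.inf, np.inf]),
            post_mean_fn=lambda pts: np.full_like(pts, 0.3),
        )
        pl, ng = cond_loss_quantiles(0.3, prior, normal_model, n, prof, grid,
                                     Phase3Spec(), normal_hyp)
        assert pl == pytest.approx(0.0, abs=1e-12)
        assert ng == pytest.approx(0.0, abs=1e-9)
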