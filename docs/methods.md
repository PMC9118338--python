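# Methods

## Model and decision rules

Outcomes are conjugate throughout.  The normal family works exclusively on
the sufficient statistic ȳ ~ N(θ, σ²/n) with σ² known (default 1); the
binomial family on the success count y ~ Bin(n, θ).  Analysis priors are
normal, beta, point-mass, finite mixtures, or power priors built from a
historical summary: the baseline prior updated by the historical likelihood
raised to a₀ ∈ [0, 1] (normal: a conjugate update with effective sample size
a₀n₀; binomial: Beta(a + a₀s, b + a₀f)).  The empirical-Bayes variant picks
a₀ per dataset by maximizing the marginal likelihood of the *current* data, by
a 201-point grid scan refined with bounded scalar minimization (vectorized
paths use a parabolic refinement of the grid maximizer instead); ties break
toward the smaller a₀, i.e. toward less borrowing.  Mixture posteriors follow
standard conjugate-mixture algebra, with component weights updated on the log
scale via log-sum-exp; zero-weight components are dropped before updating.

The test rejects H₀: θ ≤ θ₀ when P^{π_a}(θ ≤ θ₀ | y) < γ.  In the default
`bf_reweighted` cost mode γ = c₀′P/(c₀′P + c₁′(1−P)) with P the analysis
prior's own null mass, which makes the rule equivalent to rejecting when the
Bayes factor of H₀ vs H₁ (under θ₀-truncated renormalized priors) drops below
c₀′/c₁′; the `plain` mode uses γ = c₀′/(c₀′+c₁′) regardless of the prior.
Ties at the threshold keep H₀ (the Bayes-factor inequality is non-strict on
the keep side).  For the empirical-Bayes power prior the effective prior, and
hence γ, is recomputed per outcome, so its rejection region need not be an
interval.  The Bayes factor itself is computed through the posterior/prior
odds identity rather than truncated-marginal quadrature; the test-suite keeps
the quadrature route as an independent oracle.  Relevance is declared when
P^{π_a}(θ ≤ θ_R | y) < 0.5 (strict; a posterior median exactly at θ_R is not
relevant).  A trial outcome is a success when both significance and relevance
hold, a failure when neither does, and indeterminate otherwise.

## Conditional operating characteristics

Binomial quantities are exact sums over y = 0..n.  For the normal family the
decision functions are evaluated on a fixed scan grid of ȳ (default 1601
points spanning the sampling prior's 10⁻¹⁰…1−10⁻¹⁰ quantile range widened by
8.5 statistic standard deviations), every sign change of the continuous
decision margins is sharpened by Brent root-finding, and the rejection /
relevance regions become unions of intervals with precise endpoints.  Error
rates and the indeterminate probability are then exact Gaussian interval
masses — far more accurate than quadrature of a discontinuous indicator —
while smooth integrands (the MSE of the posterior mean, the Phase-III loss
distributions) use Gauss–Hermite quadrature of order 199 centered at the true
θ.  Regions touching the scan ends extend to ±∞; the padding makes the
associated mass ≤ Φ(−8.5) ≈ 10⁻¹⁷ for every θ probed.

Phase III consequences: a successful Phase II trial sizes the follow-up trial
with the standard one-sided z-formula at effect θ̂ − θ₀, where θ̂ is the
Phase II posterior mean, targeting power 0.9 at one-sided level α₃ = 0.025
(both configurable; the per-observation variance is σ² for the normal family
and p(1−p) evaluated consistently in the sizing and power formulas for the
binomial family, so that θ̂ equal to the truth realizes the target power
exactly).  The realized power evaluates that trial at the true effect.
Unsuccessful Phase II trials realize power and sample size 0.  Power loss is
target minus realized power; sample-size gain is realized size minus the size
a trial at the true effect would need (hence minus the reference size for
unsuccessful outcomes).  The computed Phase III size is capped at 10⁶, since
the z-formula diverges as θ̂ → θ₀.  "Extreme" loss summaries are
left-continuous (type-1) weighted quantiles at level 1 − ζ = 0.8 of the
per-outcome loss distributions.  α₃, the cap, and the sign convention for
unsuccessful-trial sample-size gain are genuinely open conventions; they are
configurable and chosen here for self-consistency, and they affect only the
monitoring quantities, not the error rates, SATE, or AMSE.

## Averaging over the sampling prior

Average type I error truncates the sampling prior to (−∞, θ₀] and
renormalizes; average type II error to (θ₀, ∞); AMSE integrates over the full
sampling prior; the indeterminate probability and the extreme Phase-III
losses average over the sampling prior truncated from below at θ_R.  With the
reweighted costs this makes the testing part of the risk exactly
c₁′ᾱ + c₀′β̄, an identity asserted on every evaluation.  θ-integration uses
199-node Gauss–Legendre quadrature *in CDF space* (θ = F_s⁻¹(u)), which
renormalizes truncations exactly and absorbs unbounded beta densities at the
support boundaries without special-casing; the outer 10⁻⁸ quantile tails are
clipped.  A point-mass sampling prior short-circuits every average to the
conditional value at the mass point, which is how frequentist operating
characteristics are recovered; the error rate on the empty side of θ₀ is
reported as NaN in that case.

## Cost elicitation and sample-size selection

Goal sampling picks the smallest grid n from which a target holds *for every
larger grid n* — on binomial grids the operating characteristics are
sawtoothed (the rejection boundary advances roughly every 1/θ-scale sample
sizes) and a plain first crossing would be a transient dip.  Unit costs are
negative central finite differences of the (optionally smoothed) curves at
the goal sizes, with one-sided differences at grid ends; grids default to
steps of 2 (normal, n ≤ 300) and 1 (binomial, n ≤ 150).  Normal-family
curves are smooth and are differentiated unsmoothed.  Binomial curves are
smoothed first with a local-quadratic (Savitzky–Golay) filter.  The two
default bandwidths differ deliberately: the SATE sawtooth amplitude (~0.09 in
the proof-of-concept scenario) dwarfs its own trend slope (~2·10⁻⁴ per
patient), so extracting the trend derivative requires a window spanning many
tooth periods (default 101 grid points), whereas the AMSE teeth are two
orders of magnitude smaller and a short window (default 15) avoids biasing
the derivative with trend curvature.  Both bandwidths are configurable per
scenario.  The weight is w = n_SATE/(n_SATE + n_AMSE), the combined risk
r(n) = (w/c_n^SATE)·SATE(n) + ((1−w)/c_n^AMSE)·AMSE(n) + n is minimized by
grid argmin with ties toward the smaller n, and a minimum on the upper grid
boundary raises a truncation warning.  An explicit-cost parameterization
(c₀, c₁, c_q, c_n) is exposed for users with actual monetary costs.
Sensitivity scans rerun the optimization over grids of sampling priors and
several analysis priors while *reusing one frozen cost elicitation*, so that
risks are comparable across cells; failed cells are recorded and skipped.

## Shipped scenarios

Two fixtures define the study conditions end to end.  `normal_conjugate`:
σ² = 1, θ₀ = 0, θ_R = 0.15, c₀′ = 0.05, c₁′ = 0.95; analysis priors
N(0, 10²) (vague), N(0.25, 1/50) (informative, matching a historical mean of
0.25 from n₀ = 50), a 0.5/0.5 robust mixture of the informative prior with
N(0.25, 10²), and the EB power prior on the vague baseline; the sampling
prior equals the informative prior.  The testing goal is β̄ ≤ 0.2 (giving
n_SATE = 160); the estimation size 180 is fixed directly as a size deemed
acceptable after inspecting the AMSE curve and monitors.  `binomial_poc`:
θ₀ = 0.075, θ_R = 0.175, RSN prior Beta(0.0811, 1), informative Beta(11, 29)
from 10/38 historical responses under a uniform baseline, the corresponding
robust mixture and EB power priors, sampling prior Beta(11, 29).  Goals:
ᾱ ≤ 0.15 and β̄ ≤ 0.2 (n_SATE = 21) and indeterminate probability ≤ 0.1
(n_AMSE = 74).  These scenarios are analytic constructions, not data: they
exercise every code path under realistic Phase-II magnitudes, but passing
them says nothing about model misspecification (non-conjugate outcomes,
nuisance parameters, interim analyses), which the package does not model.

## Known limitations

One-arm, one-parameter conjugate designs only; no MCMC, so no non-conjugate
likelihoods.  Binomial Phase III sizing uses the normal approximation, not
exact binomial calculations.  The commensurate prior is not implemented
separately: for normal outcomes its empirical-Bayes form coincides with the
EB power prior, which is.  Bayes factors for point-null hypotheses are out of
scope.  Elicited unit costs inherit the smoothing bandwidth's uncertainty on
jagged binomial curves — reported cost values should be read at the ~10%
level, though the induced optimal n is far less sensitive.
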