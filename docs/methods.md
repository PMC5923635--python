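# Methods

## The model

`scsmap` fits a shared-component spatial model (SCSM) for two outcome
counts observed on one areal lattice of n areas. Counts are
conditionally independent Poisson,

    O_i1 ~ Poisson(e_i1 r_1i),   O_i2 ~ Poisson(e_i2 r_2i),

with expected counts e_ik from internal standardization (region-wide
rate of outcome k times the area population, so Σe = ΣO per outcome)
and relative risks

    r_1i = exp(α1 + δ θ_i + s_1i + u_1i)
    r_2i = exp(α2 + (1/δ) θ_i + s_2i + u_2i).

θ is a latent spatial surface shared by both outcomes — the "true"
underlying risk surface when the two data sources measure the same
phenomenon; δ > 0 lets the shared surface carry different risk
gradients for the two outcomes, and δ² is the ratio of those gradients.
s_1, s_2 are outcome-specific spatial residual surfaces and u_1, u_2
unstructured normal residuals.

θ, s_1 and s_2 carry intrinsic conditional autoregressive (ICAR)
priors on the 0–1 contiguity graph: each area's value is conditionally
normal around the mean of its neighbours with variance 1/(τ·m_i). The
improper joint density used throughout is, up to a constant,

    ((n − c)/2)·log τ − (τ/2)·Σ_{i~j} (x_i − x_j)²,

with c the number of connected components (the rank deficiency of the
graph Laplacian). Note a consequence worth stating explicitly: on a
two-area lattice this density makes the contrast x_1 − x_2 Normal(0,
1/τ), which is the convention consistent with the conditional variance
1/(τ·m_i); the tests and the exact field sampler both assert it.

Priors: near-flat Normal(0, sd 1000) on α1, α2; log δ ~ Normal(0,
precision 5.9 = 1/0.17), i.e. a prior median of 1 for δ and 95% prior
probability that δ² lies in (1/5, 5); Gamma shape/rate hyperpriors on
the five precisions. The default preset ("held") is Gamma(1.0, 0.01)
everywhere — mode of the implied variance at 0.005, infinite mean and
variance; the sensitivity preset ("ancelet") uses Gamma(0.1, 0.1) for
spatial and Gamma(0.01, 0.01) for unstructured precisions. The natural
logarithm is used for log δ throughout (the prior-interval arithmetic
above only closes in base e).

Identifiability: the ICAR fields are translation-invariant and compete
with the intercepts, so after every sweep θ, s_1, s_2 are recentred to
sum to zero and the means are absorbed into α1, α2 exactly (relative
risks are unchanged to machine precision). Areas without neighbours
(islands) are excluded from spatial updates, keeping their structured
effects at zero; they contribute through the unstructured terms only.
Multi-year observation windows are handled by dividing counts by the
span in years before fitting; the resulting fractional counts enter the
likelihood through a continuous log-density (log-gamma replacing the
factorial).

## Sampling

The sampler is Metropolis-within-Gibbs with a fixed sweep order per
iteration: single-site random-walk updates of θ, s_1, s_2, u_1, u_2
(sites grouped by a graph colouring so one colour class updates in a
single vectorized step — exactly equivalent to a site-by-site sweep,
since same-coloured sites share no edge); scalar random-walk updates of
α1, α2 and log δ; conjugate Gamma draws of the five precisions; and
recentring. Proposal scales adapt by Robbins–Monro toward 0.44
acceptance during burn-in only, then freeze, so the post-burn-in chain
targets the exact posterior.

Single-site updates alone, however, renew the *amplitudes* of the
latent surfaces — and everything tied to them, δ above all — only
through a slow random walk: δ given the fields is far tighter than its
marginal. Three standard accelerations are layered on top, all exact
MH updates of the same posterior:

1. **One-block (log δ, θ) updates** in the style recommended for
   hyperparameters of Gaussian Markov random fields: propose log δ by
   random walk and θ from the Laplace (Gaussian) approximation of its
   log-concave full conditional under the proposed δ; accept the pair
   jointly with both proposal densities in the ratio. Run three times
   per iteration; the δ step adapts toward 0.25 acceptance because the
   field-refresh mismatch multiplies into the rate.
2. **Laplace independence refreshes** of θ, s_1, s_2 (acceptance
   typically 0.75–0.95 at the count levels targeted here), and
   **one-block (log τ, field) moves** for s_1, s_2, u_1, u_2 that
   traverse the precision/amplitude funnel.
3. **Non-centered (interweaved) precision moves**: a random-walk step
   on log τ holding φ = √τ·x fixed, i.e. rescaling the field against
   the likelihood, alternated with the centered conjugate Gibbs draw.

`MCMCConfig(simple_updates=True)` disables all of (1)–(3), leaving the
plain single-site sampler; the test suite verifies on a small lattice
that both samplers produce the same posterior (medians and posterior
mean surfaces agree within Monte Carlo error). The accelerated blocks
assume a lattice without islands and switch themselves off otherwise.

The default run protocol mirrors the two-chain, 20,000-iteration
burn-in, thinning-100, 20,000-kept-draws-per-chain convention of the
applied literature; `MCMCConfig.reduced()` (2 chains × 5,000
iterations, 2,000 burn-in, thinning 5) is the desk-scale protocol used
for all tests and for the acceptance script, sized so a full recovery
replicate fits in about 1.5 minutes on one CPU.

Deviance (−2 log likelihood) is stored per kept draw. DIC uses the
plug-in deviance at the posterior means of the Poisson means λ_ik
(likelihood-level focus), pD = D̄ − D(λ̄). The Gelman–Rubin statistic is
the plain variance-ratio PSRF √[(W(m−1)/m + B/m)/W] — not the
rank-normalized split-chain variant of newer libraries, and not the
BGR interval ratio some legacy software displayed. Monte Carlo error is
batch means with 50 batches, computed within chains and pooled; the
monitoring rule flags any parameter whose MC error reaches 5% of its
posterior sd.

## Synthetic data

No per-area counts are deposited for the motivating study, so recovery
experiments use data generated forward from the model itself at the
study's scale: 140 areas on a 14×10 queen-contiguity lattice (the
paper does not state the contiguity rule used for the real
neighbourhoods; queen is the package default and rook is available),
populations uniform on 7,000–10,000, and a minimum of five counts per
area enforced by redrawing offending counts (with the default rates the
floor binds with probability < 1% per area, so the induced truncation
bias is negligible).

ICAR fields are sampled exactly by eigendecomposition of the component
Laplacian, restricted to the sum-to-zero subspace — deliberately
independent of the MCMC engine so prior-equivalence tests of the
sampler are meaningful.

Scenario defaults (chosen once, as a realistic desk-scale analogue of
a two-source mental-health utilization study):

| scenario        | δ   | τ_θ | τ_s | τ_u | rate₁ | rate₂ |
|-----------------|-----|-----|-----|-----|-------|-------|
| shared_dominant | 0.5 | 10  | 100 | 400 | 0.03  | 0.0015|
| discrepant      | 1.0 | 200 | 10  | 400 | 0.03  | 0.0015|
| null            | 1.0 | —   | —   | —   | 0.03  | 0.0015|

rate₁ ≈ a frequent outcome (doctor-visit-like, e ≈ 210–300 per area);
rate₂ ≈ a rare one (hospital-admission-like, e ≈ 10–15). With τ_θ = 10
the shared surface has sd ≈ 0.13 on the log scale, so outcome-2 risks
under δ = 0.5 span roughly e^±0.5 — stronger than the gentle gradients
of the real study (whose maximum risks were 1.16 and 1.76) but
informative enough that δ is recoverable at desk scale. What passing
recovery tests show is therefore that the machinery is correct and
well calibrated at realistic-to-generous signal-to-noise; they do not
certify performance on weaker real-data signals, on irregular
lattices, or under the detection biases and geocoding errors real
utilization data carry.

## Summaries

Per-area posterior medians and 95% credible intervals of r_1, r_2 and
exp(θ); exceedance probabilities P(exp(θ_i) > 1) as the fraction of
draws strictly greater than 1 (strictness is a determinism convention;
ties have probability zero for continuous draws); δ with its CI; the
risk-gradient ratio δ² per draw; and the fraction of total variation
in log relative risk explained by the shared component, computed per
draw as Var(δθ)/[Var(δθ)+Var(s₁)+Var(u₁)] (and analogously with
(1/δ)θ, s₂, u₂), with Var the empirical variance across areas. The
variance scale (not sd) is a package convention — the operational
definition behind the published fractions is not stated, and the
variance-scale decomposition is the standard shared-component choice.
Quantile map classes use value-based quantile breaks, so tied values
share a class and an all-constant surface is a single class.

## Numerical conventions and edge cases

- Poisson means are guarded against overflow; non-finite proposals are
  rejected, never crash the chain.
- Cholesky failures inside Laplace fits reject the move.
- Gamma draws use shape/rate; `numpy`'s scale parameterization is
  inverted at the call site.
- A constant series has undefined autocorrelation (reported NaN) and
  zero MC error; a degenerate posterior gives pD = 0. Negative pD on
  poorly converged runs is reported with a warning, not an error.
- Chain seeds derive from one root seed via `numpy.random.SeedSequence`
  spawning; identical configuration and data give bit-identical draws.

## Known limitations

- The binomial likelihood alternative for high-rate outcomes is out of
  scope, as are covariate terms and interactions between components.
- DIC's plug-in at λ̄ is one of several defensible focuses; model
  comparison across focuses is not attempted.
- The one-block and refresh moves require an island-free lattice; with
  islands the sampler falls back to single-site updates and mixes more
  slowly.
- Exceedance probabilities and variance fractions are Monte Carlo
  estimates; at the desk-scale protocol their MC error is a few
  percentage points.
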