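# Methods

## Reconstruction from published summaries

Trials print an adjusted mean difference (MD) on the endpoint scale with a
95% CI and per-arm counts. The SE is recovered as
|CI_upper − CI_lower| / (2 t_{df,0.975}); above df = 120 the t quantile is
replaced by the fixed normal quantile 1.959964, which matches it to three
decimals. The df convention is `total` (df = n_a + n_b) by default — the
convention of the source analysis this package was validated against — with
`conventional` (n_a + n_b − 2) available; at trial sample sizes the two
change Bayes factors by under 1e-4.

The "SD of effect" column of a reconstructed table is defined as
SD = SE·√(n_a n_b/(n_a+n_b)), i.e. the root of the effective sample size
times the SE. This is a reconstruction choice: it is the unique definition
under which Cohen's d = MD/SD and T = MD/SE satisfy the exact identity
T = d·√(n_a n_b/(n_a+n_b)), and it reproduces published SD columns to
±0.03. Printed tables round aggressively; reconstructed t-statistics can
differ from printed ones in the second decimal (e.g. −1.367 vs a printed
−1.36 that was rounded from less-rounded inputs). The reproduction pipeline
therefore feeds the *printed* t-statistics to the Bayes factor stage — they
are the inputs the original evidence computation used — while the
reconstruction stage keeps full precision. Both routes give Bayes factors
within ±0.01 of each other on the packaged data.

Numeric fields in input CSVs may contain the Unicode minus (U+2212), which
copy-pasting from journal tables produces; the reader normalizes it.

## Bayes factor t-tests from summary statistics

Under H₁ the t-statistic follows a noncentral t with noncentrality
δ·√n_eff, n_eff = n_a n_b/(n_a+n_b); under H₀ a central t. With a prior
π(δ) on the standardized effect,

BF₁₀ = ∫ f_NCT(t; ν, δ√n_eff) π(δ) dδ / f_T(t; ν).

Priors:

- **Default (JZS):** zero-centered Cauchy, scale r = 0.707 (= √2/2).
  Robustness curves evaluate BF₁₀ on 150 log-spaced scales in [0.01, 1.5];
  as r → 0 the alternative collapses onto the null and BF₁₀ → 1.
- **Informed ("adversarial"):** shifted/scaled Student t with 3 df, centred
  on the effect a hypothetical optimist expects (e.g. an earlier trial's
  point estimate on the standardized scale), with scale SE·√(df/(df−2)) so
  the prior SD equals that estimate's SE. The prior is used two-sided (not
  folded). The informed prior's location is interpreted on the
  standardized-effect scale; the printed location/scale values of the
  packaged analysis are used as-is, which is the interpretation that
  reproduces its published Bayes factors. Priors on the raw MD scale can be
  expressed by dividing location and scale by the implied effect SD before
  constructing the prior.

**Noncentral-t density.** scipy's implementation overflows or returns NaN
at large df combined with moderate-to-large noncentrality — exactly the
regime heavy-tailed priors visit. `trialbayes._nct` evaluates the
log-density through the chi scale-mixture representation
f(t; ν, a) = ∫₀^∞ h_ν(s)·s·φ(st − a) ds. The integrand is log-concave in s
with a closed-form maximiser (root of a quadratic), so a 96-node
Gauss–Legendre rule on a ±13-Laplace-SD window is exact to near machine
precision; the unit tests pin it to scipy at ~1e-10 where scipy works and
to exact calculus (normalization, central-t reduction) elsewhere.

**Marginalization over δ.** Adaptive quadrature (QUADPACK) on segments split
at the prior's location ± {1, 10, 100}·scale and at the likelihood peak
t/√n_eff, in exponent-shifted linear space. The accumulated absolute error
must stay below 1e-9 of the integral, comfortably inside the documented
1e-6 reproducibility contract; otherwise a `NumericalError` with
diagnostics is raised. One-sided variants truncate and renormalize the
prior; they satisfy m₁(two-sided) = mass-weighted average of the one-sided
marginals, which the tests check.

**Evidence bands.** Bayes factor bands at 3, 10, 30, 100 (and reciprocals)
labelled anecdotal / moderate / strong / very strong / extreme, for H₁
above 1 and H₀ below; exactly 1 is "no evidence". The bands are applied
literally: BF₁₀ = 0.353 lies just above 1/3 and is classified anecdotal,
even though a verbal report might round it to "three to one against".

## Random-effects meta-analysis (NNHM)

Model: y_i ~ N(θ_i, σ_i²), θ_i ~ N(μ, τ²), μ ~ N(0, mu_prior_sd²) with
mu_prior_sd = 1 by default, and τ either half-normal(sd = 0.5) — a weakly
informative choice consistent with empirical heterogeneity surveys — or the
Fisher-information ("Jeffreys") prior

π(τ) ∝ τ·√(Σ_i (σ_i² + τ²)^{-2}),

which is improper, vanishes at τ = 0, and decays like 1/τ. "Jeffreys prior
for heterogeneity" admits variants; this functional form (the square root
of the Fisher information for τ in the marginal model, the form used by the
established Bayesian meta-analysis packages) is the one that reproduces the
published sensitivity results this package was validated against, including
the characteristic nonzero lower credible bound for τ.

**Integration.** Conditional on τ, the μ posterior is conjugate normal with
precision 1/mu_prior_sd² + Σ 1/(σ_i²+τ²); only the τ marginal needs
numerics. It is evaluated on a dense linear grid (default 3200 nodes,
minimum 1600) whose upper bound starts at four times the precision-weighted
data-plus-σ scale (precision weighting keeps an arbitrarily noisy study
from inflating the grid) and doubles until the top half of the range holds
under 1e-3 of the mass; heavy-tailed posteriors (the Jeffreys prior's tail
decays only like τ^{-3}) then get geometric tail segments until the
relative tail contribution is below 1e-6. Failure to capture the mass
raises `NumericalError`. The grid specification is stored on the fitted
object, making every downstream quantity bit-reproducible.

**Summaries.** μ point estimate: median of the τ-mixture of conditional
normals (mean available; the two differ by < 0.01 on the packaged data);
μ intervals equal-tailed, τ intervals shortest-coverage (lower bound may be
0), both styles exposed. τ point estimate: posterior median by default.
Shrinkage for study i mixes θ_i | τ ~ N(k y_i + (1−k) m(τ), k σ_i² +
(1−k)² v(τ)), k = τ²/(σ_i²+τ²), over the τ marginal; the posterior
predictive for a new study adds τ² to the conditional variance.

**Bayes factors.** Two null specifications:

- `no_effect` (default, the headline "BF for an effect of treatment"): the
  marginal likelihood of the random-effects model against the global point
  null μ = 0, τ = 0 — treatment does nothing in any study. This is the
  comparison whose value (0.254 on the packaged data) matches the published
  headline Bayes factor. With an improper τ prior the H₁ marginal
  likelihood is defined relative to the grid-normalized prior; the
  sensitivity table notes this.
- `mu_zero`: the nested null μ = 0 with τ free, computed two independent
  ways — the Savage–Dickey density ratio (posterior/prior density of μ at
  0, exact from the mixture) and the marginal-likelihood ratio — which must
  agree to 1e-4 relative (they agree to ~1e-10). On the packaged data this
  gives 0.312: the μ-only null is penalized less than the global null
  because it retains the heterogeneity parameter.

A 2D brute-force grid integration of the joint posterior serves as an
independent oracle in the tests for both the posterior summaries and the
Savage–Dickey density.

## Sensitivity analyses

Variants: SE inflation by a fraction f (SE′ = (1+f)·SE, f = 0.2 for the
standard suite, guarding against imprecision in inputs digitized from
plots), the Jeffreys heterogeneity prior, and mu_prior_sd = 4. "Preserved"
means the meta Bayes factor stays on the same side of 1 as the baseline —
the evidence keeps its direction. Band equality is deliberately not
required: widening a prior typically *strengthens* the evidence for the
null (the Occam penalty grows), and flagging that as "not preserved" would
misread strengthened evidence as inconsistency. The per-variant evidence
band is reported so users can apply a stricter criterion.

## Synthetic data and what passing tests show

The trial generator draws i.i.d. normal outcomes per arm and summarises
exactly as a journal table would (MD, normal-quantile 95% CI, counts).
Defaults mirror the packaged subgroup magnitudes (n 123/97, outcome SD 2.2,
delta −0.41, giving E[SE] ≈ 0.30). It does not model dropout, repeated
measures/MMRM adjustment, or covariate adjustment — the analysis consumes
only (MD, CI, n), so those features would only change how the summaries
arise, not how they are processed. Recovery experiments on the NNHM
(defaults: 10 studies, μ = −0.3, τ = 0.3, σ_i = 0.3, 200 replicates) check
95% CrI coverage for μ within binomial tolerance of nominal. Passing these
tests shows the machinery is calibrated under its own assumptions; it does
not validate the normality or exchangeability of any particular real trial
pair, and with only two real studies the τ posterior is strongly
prior-driven (visible in the half-normal vs Jeffreys comparison, 0.33 vs
0.59).

All generators are pure functions of their seed (NumPy PCG64, recorded in
reports).

## Degenerate inputs and tie-breaks

Zero-width CIs give SE = 0, which reconstruction reports but the t-stage
rejects with a diagnostic. A half-normal τ prior with tiny sd collapses the
fit to the conjugate fixed-effect closed form (tested to 1e-6). A study
with enormous σ leaves all posteriors unchanged to 1e-6. Evidence-band
boundaries classify strictly ("moderate" starts strictly above 3, etc.).
Reported values round half-away-from-zero only at the reporting layer;
internal computation keeps full precision.

## Known limitations

- The Bayes factor t-test treats the reconstructed T as an
  independent-samples t-statistic; adjusted mean differences from
  covariate-adjusted models are only approximately t-distributed with the
  stated df.
- The `no_effect` Bayes factor with an improper heterogeneity prior depends
  on the prior's grid normalization (documented, deterministic); use the
  `mu_zero` null when the τ prior is improper and a normalization-free
  number is needed.
- No meta-regression, network structure, multiple endpoints, or MCMC; the
  grid approach is exact-for-practical-purposes in 1D τ but is not meant
  for models with more hierarchy.
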