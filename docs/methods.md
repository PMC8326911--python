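# Methods

This note documents the models implemented in `metaneutral`, the
conventions and numerical choices behind them, what the synthetic-data
generator does and does not emulate, and the package's known
limitations.

## Sloan near-neutral model (`metaneutral.sloan`)

**Process.**  A saturated local community of `N_T` individuals evolves
by single-individual death/replacement.  With probability `m` the
replacement is an immigrant drawn by the source community frequencies
`p_i`; with probability `1 − m` it is the offspring of one of the
remaining `N_T − 1` residents.  The one-event transition probabilities
for a focal taxon at abundance `N_i` are

    P(gain) = (1 − N_i/N_T) · [m·p_i + (1−m)·N_i/(N_T−1)]
    P(loss) = (N_i/N_T) · [m·(1−p_i) + (1−m)·(N_T−N_i)/(N_T−1)]
    P(stay) = 1 − P(gain) − P(loss)

(`P(stay)` also has an explicit two-case form, which the test suite
checks against the complement to 1e-12).  The stationary law of the
relative abundance `x_i = N_i/N_T` is `Beta(N_T·m·p_i, N_T·m·(1−p_i))`,
so the probability that taxon *i* is detected above a limit `d` is the
Beta upper tail — a curve in `p_i` with the single free parameter
`N_T·m`.

**Fitting conventions.**

- `p_i` = mean relative abundance of taxon *i* across source samples;
  taxa absent from the source are *unclassifiable* and excluded.
- Observed occurrence = fraction of destination samples with ≥ 1 read.
- `N_T` = mean read depth of the **destination** samples; `m̂ = N_T·m /
  N_T`.
- `N_T·m` is fitted by bounded least squares on occurrence (bounds
  `[1e-3, 10·N_T]`), matching the `R²` semantics usual for this fit;
  `R²` may be negative and is reported as computed.
- Detection limit: `d = ln 2 / N_T` by default.  Presence by ≥ 1 read of
  depth `D` has probability `1 − E[(1−x)^D] ≈ 1 − E[e^{−Dx}]`; the sharp
  threshold whose step function best matches that kernel is its median
  `x = ln2/D`.  The cruder `1/N_T` limit biases `N_T·m` upward by
  roughly 10% on recovery simulations; `d` can be overridden.
- 95% band: Wilson score interval for a proportion equal to the
  predicted occurrence over `n` destination samples — the spread
  expected from sampling noise alone under neutrality.  Wilson is used
  because it is bounded and well behaved at occurrence 0 and 1.  A taxon
  is *above* if its observed occurrence strictly exceeds the upper
  bound, *below* if under the lower bound, else *neutral*.  As
  `alpha → 0` the band widens and labels can only move toward neutral.
- Class shares between two fits are compared per class with two-sided
  Fisher exact tests on 2×2 (class vs. not) × (fit A vs. fit B) tables.

## Multi-site neutral model (`metaneutral.msn`)

**Model.**  Metacommunity relative abundances `p ~` stick-breaking with
biodiversity number `θ`; counts at site *j* follow a
Dirichlet-multinomial with concentration parameter `I_j·p` at the
observed depth.  `I_j` is the fundamental dispersal number of site *j*;
its average over sites is reported as the `M`-value of the
metacommunity.

**Gibbs sampler.**  A collapsed sampler alternates:

1. latent ancestor counts `a_ij` per (taxon, site) cell via the
   Chinese-restaurant construction — `a = Σ_k Bernoulli(w/(w+k))`,
   `w = I_j·p_i` — implemented as one flattened Bernoulli ladder per
   sweep (cost proportional to the total read count);
2. metacommunity frequencies by direct assignment: `(p, p_unseen) ~
   Dirichlet(a_1·, …, a_S·, θ)`, keeping an explicit slack component for
   never-observed species (`p` sums to < 1).  Renormalizing over
   observed taxa instead inflates large `I_j` estimates substantially;
3. `θ` by the Escobar–West auxiliary-variable update given the total
   ancestor count and the number of distinct species;
4. each `I_j` by the same auxiliary scheme given its depth and ancestor
   total.

Hyperpriors are vague `Gamma(1, 0.001)` on `θ` and every `I_j`.  Point
estimates are posterior medians (`p̂` the posterior mean); library
defaults are 20,000 iterations, 5,000 burn-in, thinning 10, and a
mandatory seed.  The reported observed components are `L_M` (Ewens
sampling-formula log-probability of the point-estimate ancestor
configuration at `θ̂`), `L_L` (summed Dirichlet-multinomial
log-likelihood given `p̂` and `Î`), and `L_O = L_M + L_L`.  This
additive decomposition is this package's operationalization; the
component statistics used by the neutrality tests are defined next.

**Neutrality tests.**  Both tests are posterior-predictive pseudo-p
tests: simulate `N_sim` replicate datasets from the fitted model at the
observed depths, count how many have a component statistic below the
observed one, and report `p = N_below/N_sim` exactly, passing when
`p ≥ 0.05` (one-sided lower tail: the observed data must not look less
likely than the model's own replicates).  Two design choices make the
test calibrated rather than merely plausible:

- *Pivotal statistic.*  Every dataset — observed or replicate — is
  scored at its own short standardized Gibbs refit (60 sweeps, second
  half retained), not at the full fit's estimates.  Scoring replicates
  at parameters fitted to the *observed* data systematically favours
  whichever side the estimation error lands on.
- *Posterior-predictive generation.*  Each replicate is generated from a
  randomly retained posterior draw `(θ, I, p)` rather than the point
  estimates, propagating parameter uncertainty; the unseen-species slack
  mass of the drawn `p` is expanded into fresh stick-breaking atoms so
  replicates grow rare-species tails the way real data do.

At the metacommunity level the statistic is the Ewens log-probability of
the refit ancestor configuration and replicates draw an entirely fresh
metacommunity; at the local level the statistic is the summed
Dirichlet-multinomial log-likelihood given the refit frequencies and the
drawn metacommunity is kept.  On data simulated from the fitted model
the false-rejection rate is ≈ 5% at nominal 5% (checked by an
exchangeability construction in the test suite).  A batch replicate
"passes neutrality" when both levels pass.

## Niche-neutral hybrid model (`metaneutral.nnh`)

Each sample (or group) is a niche; within a niche assembly is neutral.
The niche-level expected SAD is the dispersal-limited neutral
expectation

    <phi_n> = θ·C(J,n)·Γ(γ)/Γ(J+γ) ·
              ∫₀^γ Γ(n+y)/Γ(1+y) · Γ(J−n+γ−y)/Γ(γ−y) · (1−y/γ)^{θ−1} dy

with `γ = m(J−1)/(1−m)`.  The `(1−y/γ)^{θ−1}` kernel is the exact
dispersal-limited sampling form; the `e^{−yθ/γ}` kernel sometimes quoted
in its place is its large-`γ` approximation and fails for small
communities (at `J = 2` the exact kernel reproduces the two-individual
urn enumeration `E[φ₁] = 2·(I/(I+1))·(θ/(θ+1))`; the approximate one
does not).  The integral is evaluated by 160-node Gauss–Legendre
quadrature on `y = γt` in log space; for `J > 512` the integrand is
evaluated exactly on a log-spaced abundance grid and interpolated
(monotone cubic in log-log), accurate to ~1e-4 where expected counts are
non-negligible.  Internal consistency `Σ n·<phi_n> = J` holds to within
quadrature error, and the `m → 1` limit converges to the Ewens
sampling-formula expectation of a `J`-sample from the metacommunity.

**Fit and test.**  One `(θ, m)` pair is shared across all niches (each
contributing its own size `J_k`), fitted by maximizing the pooled
Poisson likelihood of octave-binned SAD counts with Nelder–Mead on
`(log θ, logit m)` and three seeded restarts.  The metacommunity
log-series parameter `x` is the MLE on the pooled abundances (solving
`mean(n) = x/((1−x)(−ln(1−x)))`).  Binning uses Preston octaves with
boundaries at powers of two and half-counting of boundary species;
octaves are merged from the rare tail until every expected count
reaches 1.  The decision statistic is `χ² = Σ_k Σ_bins (obs−exp)²/exp`
pooled over niches, `df = bins − 3 − 1`, `p` from the asymptotic χ²
upper tail; the hybrid is accepted when `p > 0.05`.  `R²` is computed
over the pooled binned counts, and `γ` is reported at the mean niche
size.  Single-species niches are excluded with a warning; fewer than 5
retained bins is an error.

## Synthetic data (`metaneutral.simulate`)

The generator emulates a three-group tissue-microbiome study: 23 + 12 +
33 samples by default, lognormal read depths (σ = 0.3) around group
means near 12,000 / 15,700 / 9,100, one shared stick-breaking
metacommunity (default `θ = 300`, truncated at `S_max = 2000` taxa),
group migration rates of order 10⁻³, and a few planted singleton OTUs so
the singleton filter always has work to do.

Two equivalent routes generate a local community, linked by the
convention `I = N_T·m`:

- the exact stationary law: Dirichlet(`I·meta`) relative abundances
  followed by multinomial read sampling;
- the forward Moran process of the transition probabilities above,
  run event-by-event (default burn-in 100·`N_T` events, endpoint
  sampling only).  Agreement of the two routes in distribution — Moran
  endpoints passing a KS test against the stationary Beta — is the
  package's central self-consistency check.  The event loop is
  numba-compiled when numba is importable, with an identical pure-Python
  fallback.

Selection enters as per-taxon multiplicative reproduction weights in the
Moran process (immigration stays neutral) — the minimal departure from
neutrality a near-neutral classifier should detect.  Groups opt in or
out of selection individually (`GroupSpec.selected`), reflecting designs
where tumor tissue exerts selection and normal tissue does not; with a
selected source the source frequencies already absorb the advantage and
the species-level signal is hidden by construction.

What the generator does **not** emulate: sequencing error, chimeras and
taxonomic mis-assignment; compositional artifacts of library
preparation; phylogenetic correlation between taxa; within-subject
pairing of samples.  Tests passing on these data therefore show that the
estimators recover the parameters of the idealized sampling processes,
not that real amplicon pipelines are free of upstream artifacts.

## Study pipeline (`metaneutral.pipeline`)

Combinations are drawn without replacement from the full product space
(sizes 9108 for the default triples; 276, 759, 396 for the pairs),
seeded and deterministic; per-replicate seeds derive from the plan seed
and replicate index so replicates are independent yet reproducible.
Aggregates report the mean and standard error (SD/√n) of each parameter
over converged replicates; replicate failures are logged and counted,
and a batch aborts if more than 20% fail.  `M`-value contrasts use the
two-sided Wilcoxon rank-sum test (exact null when both sides have ≤ 25
untied replicates, asymptotic otherwise).  No multiple-testing
correction is applied across the three pairwise contrasts; raw p-values
are reported.

Singleton OTUs (total count 1 across **all** samples) are discarded once
on the full table before any subsetting, so cross-group singletons are
handled consistently.  Zero-total taxa arising from subsetting are kept
as structural zeros in tables but dropped before model fits.

## Problem sizes

Library defaults follow the full-study scale (Gibbs 20,000 iterations,
`N_sim = 2500`, 1000 triple re-samples).  The test suite and the
acceptance script run the same code paths at demonstration scale — a few
thousand Gibbs sweeps, `N_sim` of 60–300, and a handful of re-samples —
chosen so the full verification cycle completes in minutes while leaving
every statistical check meaningful at its stated tolerance.

## Known limitations

- The Sloan fit ignores the read-sampling layer beyond the detection
  limit convention; with shallow sequencing or very uneven depths the
  occurrence curve is only an approximation, and `m̂` inherits
  attenuation from noisy source-frequency estimates.
- MSN point estimates for per-site `I` from a single sample per site are
  intrinsically wide (posterior spread of order ±30–40% at depths near
  10⁴); rank orders are much more stable than magnitudes.
- The NNH χ² uses the asymptotic reference distribution; with very few
  retained octaves the test is conservative rather than exact, and the
  shared-`(θ, m)` convention cannot represent niches with genuinely
  different internal dynamics.
- The pseudo-p neutrality tests are Monte-Carlo estimates; with
  `N_sim = 100` the standard error of a p near 0.05 is ≈ 0.02, which is
  why the library default is 2500.
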