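# Methods

## Problem and estimands

An ensemble is an n × p matrix: n observations (e.g. independently
sampled kinetic models) of p variables (e.g. the flux control
coefficients, FCCs, of one target flux). The estimands are the population
means μ_1 … μ_p; a variable is called significant when its interval is
bounded away from zero. All intervals here are *simultaneous*: the
family-wise coverage P(all p intervals contain their μ_j) is the
controlled quantity, at level 1 − α_S (default 0.95). Coverage is a
repeated-sampling probability, which is exactly what the simulation
harness estimates.

## Preprocessing

Variables with sample SD below a tolerance (default 10⁻⁹) are removed
before analysis — they are numerically constant, carry no inferential
content, and make the correlation matrix singular. Sample SDs use the
n − 1 denominator everywhere. Variables are reported ranked by decreasing
absolute mean, ties keeping input order.

## The three constructions

**Bonferroni (BCI).** Each interval is the univariate t interval at
α = α_S / p. Family-wise validity follows from the union bound under any
dependence; each marginal interval is conservative (level 1 − α >
1 − α_S). t with n − 1 degrees of freedom is used for the marginal
quantile; at the ensemble sizes this package targets (n in the thousands)
t and z are indistinguishable.

**Exact normal (ENCI).** Intervals mean_j ± c · s_j/√n share one critical
value c, the (1 − α_S) equicoordinate quantile of max_j |Z_j| with
Z ~ N_p(0, Γ̂) and Γ̂ the Pearson correlation of the observations. c is
computed by Monte Carlo: M draws (default 100,000) through the Cholesky
factor of Γ̂, empirical quantile of the max-abs statistic, fully
determined by the seed. The MC standard error of c is
√(α_S(1−α_S)/M) / f(c), with f the density of max|Z| — about 0.005 at
p = 10, α_S = 0.05, M = 100,000; tests compare against the Šidák closed
form Φ⁻¹((1 + (1−α_S)^{1/p})/2) under an identity correlation at a
3-standard-error tolerance. Γ̂ is symmetrized and, if an eigenvalue dips
below zero, repaired by clipping eigenvalues at zero and re-normalizing
the unit diagonal (minimal intervention; with n ≫ p this rarely
triggers). A deterministic numerical equicoordinate CDF was deliberately
not implemented: the seeded MC route is simple and its error is
quantifiable.

**Balanced bootstrap (BootCI).** B (default 2,000) with-replacement
resamples of the n rows — drawn jointly across variables, so the
dependence structure survives — give a B × p matrix of resampled means.
Each column is pre-pivoted through its own bootstrap ECDF via fractional
midranks r_bj = rank_j(b)/(B+1); the balance root of replicate b is
u_b = max_j max(r_bj, 1 − r_bj), its (1 − α_S) empirical quantile q
(clipped to [1/2, B/(B+1)]; hitting the ceiling logs a warning that B is
too small for the requested level at this p) calibrates every interval:
CI_j = [Q_j(1−q), Q_j(q)] with Q_j the linearly interpolated empirical
quantile function of column j. One shared q yields, in the bootstrap
world exactly and in the sampling world asymptotically: target
simultaneous coverage, equal marginal coverages, and equal
out-probability 1 − q per tail. The construction operates on raw mean
roots (not studentized); this is an assumption of the implementation,
made because the ECDF pre-pivot already equalizes marginal scales.
Intervals are asymmetric whenever the bootstrap distribution is —
the upper arm stretches on right-skewed variables.

Width ordering on any dataset: univariate ≤ ENCI ≤ BCI per variable
(ENCI vs BCI up to the MC tolerance of c), hence the univariate method
flags at least as many variables significant as any corrected method.

## Case comparisons

k cases compared along v selected variables form one family of
q_total = C(k,2) · v mean differences d = mean_A − mean_B with SE
√(s²_A/n_A + s²_B/n_B); the correction is *global* over all q_total
estimates, never per pair. Difference intervals use z quantiles (the
exact-normal construction is normal-based and the target n makes Welch-t
moot). The ENCI calibration draws from the q_total-dimensional normal
whose covariance is assembled from per-case sample covariances: the
diagonal blocks are Σ_A/n_A + Σ_B/n_B and comparisons sharing a case are
correlated through that case's block with orientation sign
(Cov(d^{AB}, d^{AC}) = +Σ_A/n_A, Cov(d^{AB}, d^{CB}) = +Σ_B/n_B,
Cov(d^{AB}, d^{BC}) = −Σ_B/n_B). Whether to model this cross-pair
correlation was a genuinely open choice; it is on by default
(`cross_case_correlation=True`) with a block-diagonal opt-out, since
ignoring real positive correlation wastes width. The bootstrap
calibration resamples every case independently within each replicate,
recomputes all q_total differences, and applies the balanced max-rank
construction in difference space.

Preselection mirrors ensemble practice: per case, the k (default 7)
largest-|mean| variables among those whose bootstrap simultaneous CI
excludes zero; the union across cases, sorted by name, defines the
comparison family.

## Sample size

Only Bonferroni admits an explicit formula:
n = ⌈(z_{1−α_S/(2p)} · max_j s_j / E)²⌉ for a maximal margin of error E
over the family, with s_j estimated a-posteriori from the sample in hand
(per-comparison difference SDs √(s²_A + s²_B) when sizing comparisons,
assuming equal per-case n). z rather than t because n is the unknown; at
the resulting n the difference vanishes. The self-consistency check
regenerates data at the returned n and verifies the realized maximal
half-width meets E up to SD re-estimation noise (O(1/√(2n)) relative).

## Synthetic generators and what they do (not) show

**Toy control-analysis pathway.** An unbranched chain of r reactions
(m = r − 1 internal metabolites, unit reference flux) with scaled
elasticities drawn uniformly — substrates in (0, 1), products in (−1, 0)
on the participation pattern. FCCs come from the control-matrix identity
C = I − E (N D_v E)⁻¹ N D_v; steady state (N v = 0) makes the summation
theorem (rows of C sum to 1) and the connectivity theorem (C E = 0) exact
algebraic identities, which every accepted sample must satisfy to 10⁻⁸.
Draws with condition number of N D_v E above 10⁸ are rejected and
redrawn, mirroring the practice of keeping only stable models; the run
aborts if acceptance falls below 1%. The resulting FCC marginals are
skewed ratio statistics with built-in correlation (the summation
constraint alone induces it) — the data shape that motivates the
bootstrap method — but the generator is a deliberately small stand-in: it
has no thermodynamics, no branching, no genome-scale structure, so
passing tests demonstrate statistical correctness of the intervals, not
biological fidelity of any particular network.

**Gaussian copula with known truth.** A latent N_p(0, R) draw is pushed
through per-variable marginal transforms — normal; shifted lognormal
(skew parameter = log-scale σ); shifted gamma (skew parameter = 2/√shape);
negative parameters mirror — each standardized *in distribution* and then
affinely mapped to the requested true mean and SD. True means are thus
exact by construction, which is what coverage experiments require. For
non-normal marginals the observed Pearson correlation differs somewhat
from the latent R, as in real data. The marginal families are a modeling
choice for validation; real FCC marginals follow no known family.

**Coverage harness.** For a spec, method and level: generate `reps`
independent ensembles, build the intervals, and tally simultaneous
coverage, per-variable marginal coverage and left/right miss rates
(coverage + left + right = 1 per variable). MC standard error of a
coverage estimate is √(c(1−c)/reps); tests use 3-SE bands.

**Four-case comparison fixture.** Twenty variables per case at n = 500
(defaults), exchangeable latent correlation 0.2, SD 0.1, mixed
normal/lognormal/gamma marginals. Each case plants large means
(1.0 … 0.4) on exactly seven variables — four shared across all cases,
three case-specific — so the per-case top-7-significant sets union to 15
variables and four cases yield a 90-comparison family with known true
differences and true nulls, making family-wise error directly checkable.

## Problem sizes and numerical choices

Validation simulations run at p = 5–20, n = 200–500, reps = 400–1,000,
B = 1,000–2,000, M up to 100,000 — sizes chosen so each contract is
tested at 3-MC-SE resolution while the whole suite completes in about a
minute of CPU. Empirical quantiles interpolate order statistics linearly
(numpy default); rank ties use midranks; all randomness flows from
numpy `default_rng` seeds, so every stochastic output is reproducible
bit-for-bit from the recorded seed.

## Known limitations

* BootCI is a single-level balanced scheme: no iterated-bootstrap
  calibration, no BCa acceleration, no studentization. At small n with
  extreme skew its finite-sample simultaneous coverage runs a few points
  below nominal (the usual percentile-type bias); at the n in the
  hundreds-and-up regime it tracks nominal within the tested tolerances.
* The ENCI quantile is Monte Carlo, so two seeds differ at the ~0.005
  scale in c; increase M for tighter calibration.
* Bonferroni's width (and hence its sample-size formula) is conservative
  under strong dependence — the price of its generality.
* I/O accepts complete numeric matrices only; missing values are
  rejected, not imputed.
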