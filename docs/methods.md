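# Methods

This note records the models implemented by `assocdesign`, the numerical
choices behind them, and what the test suite's synthetic constructions do
and do not establish about real data.

## Gametic LD and the frequency bound on r²

All LD statistics are computed from haplotype (gamete) frequencies, never
from diploid genotype counts; composite genotypic disequilibrium is out of
scope. For a 2×2 gamete table, D = p_AB − p_A p_B and
r = D/√(p_A p_a p_B p_b). Canonicalization folds each allele frequency to
its minor form and orders the pair so p_B ≤ p_A ≤ ½, recording the
relabellings; the ceiling r²max = (1−p_A)p_B/[p_A(1−p_B)] is then sharp,
attained at p_AB = min over the Fréchet interval, and equals 1 iff
p_A = p_B. r² is a quadratic in p_AB, so the test suite's brute-force
oracle (a grid over the Fréchet-feasible p_AB, whose endpoints the grid
hits exactly) agrees with the closed form to machine-level accuracy.

Input hygiene: haplotype frequencies must be non-negative and sum to 1.
Sums off by ≤ 1e−9 are renormalized (silently below 1e−12, the scale of
float accumulation noise; with a warning above it); larger deviations are
rejected. Construction from margins validates both Fréchet bounds and
names the violated one.

## Variant-discovery design under a folded SFS

The detection probability (both alleles seen in n diploids) is
1 − (1−p)^{2n} − p^{2n}, evaluated with `log1p`/`expm1` so that p near 0
or n in the tens of thousands do not lose precision. The k-threshold
probability P_k(p) = P(k ≤ X ≤ 2n−k), X ~ Bin(2n, p), is evaluated via
the regularized incomplete beta representation of the binomial survival
function (scipy's `betainc`), never by naive summation; this is stable to
at least n = 10⁵.

The folded neutral SFS for a constant-size, random-mating,
infinitely-many-sites population has density ∝ 1/p + 1/(1−p) =
1/[p(1−p)] on (0, ½]. All uses are ratios, so the density is left
unnormalized. Sensitivity and PPV are the weighted means of P_k over
[c, ½] and the ratio of the [c, ½] mass of P_k·f to its (0, ½] mass
respectively. Numerical choices:

* Adaptive quadrature (QUADPACK) with relative tolerance 1e−8, absolute
  1e−12, on [0, c] and [c, ½] **separately**: the PPV integrand is only
  C⁰ at the cutoff c as assembled, and the endpoint p → 0 is improper.
* At p → 0 the integrand P_k(p)/[p(1−p)] behaves like C(2n,k)p^{k−1}:
  zero limit for k ≥ 2, limit 2n for k = 1. The integrand function
  returns that analytic limit at p ≤ 0 instead of exposing the 1/p pole
  to the integrator. A quadrature result that misses its requested
  tolerance raises rather than returning silently degraded values.
* The [c, ½] normalizer uses the closed form ∫ dp/[p(1−p)] =
  log[p/(1−p)].
* Finite populations of N diploids use the discrete spectrum
  p = i/(2N), i = 1..N with the same weights; by construction it
  converges to the continuous values as N grows (checked at N = 10⁴
  against the continuous case to 1e−3). Growth-skewed or otherwise
  non-neutral spectra enter only as user-supplied `custom` tables; no
  demographic inference is attempted.

The design planner scans n upward and, within each n, exploits that
sensitivity is non-increasing in k while PPV is (numerically, not
provably) non-decreasing: two integer bisections find the candidate k,
and the returned pair is re-verified against both targets before being
reported, so the monotonicity assumption can only cost completeness,
never correctness. At reference scale (targets 93.3% sensitivity / 99%
PPV at c = 0.05) the planner returns (n=209, k=25) in about a second.

## Allelic power and the 1/r² inflation factor

The committed test is the 1-df Pearson chi-square on case/control allele
counts (2n alleles per group of n diploids) without continuity
correction; genotypic (2×3) and trend tests are out of scope. Power uses
the noncentral chi-square distribution with the two-proportion
noncentrality λ = (q_case−q_control)² / [q̄(1−q̄)(1/(2n₁)+1/(2n₀))], q̄
the allele-count-pooled frequency. This is an asymptotic convention
validated against simulation, not a printed formula: across a grid of
effect sizes and sample sizes it matches empirical rejection rates within
Monte-Carlo error at 10⁵ replicates, but in discreteness-heavy regimes
(allele frequencies near ½, moderate n, mid-range power) the lattice of
attainable tables shifts the true rejection probability by up to ~0.01
absolute from the smooth approximation; one unit test allows exactly that
margin. Required sample sizes are found by geometric bracketing plus
integer bisection, so the returned n is a fixed point (power(n) ≥ target
> power(n−1)).

Haplotype disease models are evaluated exactly. Cases and controls are
retrospective i.i.d. draws from the Bayes-inverted conditional
distributions q_case = P(allele | disease), q_control =
P(allele | healthy); population prevalence enters only through the
inversion. A disease rule is a penetrance pair (f₁, f₀) on one locus, a
thresholded phenotype, or an explicit per-haplotype disease probability.
The marker-vs-causal comparison (`inflation_check`) first determines,
from the disease probabilities themselves, which loci the rule actually
depends on, and refuses tables with more than one causal locus: that is
precisely the regime in which the conditional-independence assumption
behind 1/r² fails and the exact conditional frequencies
(`marker_case_control_freqs`) are the honest answer. In the small-effect
limit the exact required-n ratio converges to 1/r²; integer sample sizes
make the approach non-monotone at the last few percent.

One caveat the module surfaces rather than resolves: in the cancelling
risk+protective construction the *signed* phenotype is uncorrelated with
the marker (no test on the quantitative phenotype has power), yet a
binary disease coding of the same model can retain a case/control
frequency difference at the marker. Both codings are computable and the
package reports whichever the caller specifies.

## Stratification confounding

The condition is implemented as the γ-weighted covariance between
subpopulation prevalence and allele frequency; it is algebraically
identical to "q_case ≠ q_control" under the mixture sampling scheme, and
the sign of the covariance is the sign of the frequency difference (both
facts are property-tested). The magnitude is reported as
`delta_case_control_freq_diff` = |q_case − q_control|; this is the
module's operationalization of the stratification-magnitude parameter and
no equivalence with other published δ definitions is claimed. Among the
built-in scenarios, the three-subpopulation example reproduces its
published parameters verbatim but those parameters give covariance
11/21600 ≠ 0 — a small residual confounding at odds with the example's
original description — so its builder emits a warning and it is excluded
from calibration checks.

## Simulation oracles

All stochastic routines draw from one root seed through named,
crc32-keyed child streams of numpy's `SeedSequence`, so identical configs
reproduce results bit-for-bit across processes. Panels are sampled
retrospectively: binomial allele counts at the conditional frequencies
(the `hw_genotype` mode draws per-person Hardy–Weinberg dosages and sums
them — distributionally identical, exercised as a separate code path).
Replicates with a zero table margin, where the chi-square statistic is
undefined, are counted and reported separately rather than silently
dropped. SFS sampling inverts the CDF on a 10⁴-point log-spaced grid
over (10⁻⁴, ½] for the continuous neutral density (which is steep near
zero) and samples the support directly for discrete spectra.

What the synthetic models emulate — exact multinomial haplotype
populations, deterministic phenotype maps, independent chromosomes,
discrete subpopulations — is the idealized regime in which the closed
forms are theorems. They deliberately omit genotyping error,
environmental noise, linkage decay with distance, admixture and
continuous structure, and within-study relatedness. Passing tests
therefore certify the calculators' internal correctness and calibration
under their stated assumptions, not the behaviour of any real cohort.

## Problem sizes

The default suite runs ~170 tests in a few seconds on one CPU: Monte-Carlo
cross-checks use 10⁵ replicates (binomial sampling is vectorized), the
brute-force LD bound check uses 10⁴ random margin pairs × 10⁴-point
grids, and enumeration oracles cover a few hundred random haplotype
tables. These sizes were chosen to make every Monte-Carlo interval
decisive (3 standard errors ≈ 0.2–0.5 percentage points) while keeping
the whole suite interactive.
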