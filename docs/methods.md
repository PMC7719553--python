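# Methods

## Model

Two (or more) quantitative traits are controlled by `n` unlinked, fully
pleiotropic diploid loci. An individual's multivariate phenotype is
`z = x + e`, where the breeding value `x` is the sum of the `2n` allelic
effect vectors (no dominance, no epistasis on the phenotype) and the
residual `e` is multivariate normal with covariance **E** (identity by
default). Each allele mutates with probability μ per generation; a mutation
adds to the current allelic value an increment drawn from N(0, **M**)
(continuum of alleles). For two traits **M** is parameterized as
`M = Vα·[[1, ρm√ϕm], [ρm√ϕm, ϕm]]`: Vα is the mutational variance of
trait 1 per mutation (squared trait units), ϕm the ratio of mutational
variances (trait 2 / trait 1), ρm the mutational correlation.

Stabilizing selection is a Gaussian fitness peak centered on the origin:
`W(z) = exp(−zᵀΩ⁻¹z / 2)` on phenotypes. Averaging over the residual,
selection on breeding values has width matrix `V = Ω + E`, parameterized as
`V = Vs·[[1, ρs√ϕs], [ρs√ϕs, ϕs]]`: Vs is the squared peak width for
trait 1 (large Vs = weak selection), ϕs the ratio of squared widths, ρs the
correlational-selection coefficient. All equilibrium formulas are written in
**V**; simulator inputs are transformed to `Ω = V − E` before a run, which
requires `V − E` positive-definite.

## Equilibrium theory

**Gaussian regime (frequent, small mutations), no drift.** The expected
equilibrium is

    G = n √(2μ) · V^{1/2} (V^{-1/2} M V^{-1/2})^{1/2} V^{1/2},

the matrix geometric mean of (scaled) **M** and **V**; for one trait it
reduces to the per-locus balance variance `√(2 μ Vα Vs)` summed over loci.
Every aspect of G's *shape* — correlations, orientation, eigenvalue ratios —
is invariant to rescaling Vs or Vα alone; only G's size changes.

**Gaussian regime with drift.** Adding a per-generation heterozygosity loss
of `1/(2Ne)` gives

    Ḡ = n √(2μ) · V^{1/2} [ (κ'² I + V^{-1/2} M V^{-1/2})^{1/2} − κ' I ] V^{1/2},
    κ' = 1 / (4 Ne √(2μ)),

equivalently, in the scalar parameterization, governed by the compound
parameter `κ = √(Vs / ((4Ne)² · 2μVα))` = κ'·√(Vs/Vα). Contracts built into
the implementation and enforced by tests: κ → 0 recovers the
infinite-population balance; κ → ∞ gives the neutral mutation–drift
equilibrium `Ḡ → 4 Ne n μ M` (correlation ρm); and for a single trait Ḡ
equals `n` times the fixed point of the per-locus recursion
`Δv = 2μVα − v²/Vs − v/(2Ne)`. These three limits — standard single- and
multi-trait theory — are treated as normative for the transcription of the
scalar prefactor and of κ, whose typeset radicals are fragile; they pin both
uniquely.

**House-of-Cards regime (rare, large mutations).** Without drift the
genetic correlation has the closed form

    ρG = [ρs√(1−ρm²) + ρm√(1−ρs²)]
         / √[ 2 − (ρm²+ρs²) + √((1−ρs²)(1−ρm²)) (√ϕ + 1/√ϕ) ],  ϕ = ϕs/ϕm,

which is invariant under ϕ → 1/ϕ and at ϕ = 1 collapses to
`(ρs√(1−ρm²) + ρm√(1−ρs²)) / (√(1−ρm²) + √(1−ρs²))`. The compound ϕ is the
*ratio* of the two shape ratios: the ratio of selection strengths between
the traits times the ratio of their mutational variances. (A product form
ϕmϕs is sometimes quoted; it coincides with the ratio form whenever either
ϕ equals 1, but only the ratio form reproduces the Gaussian matrix
equilibrium exactly — `wishart_compare` verifies the agreement to ~1e−16
over random covariance pairs, which is the package's strongest internal
consistency check.) With drift, the stochastic House-of-Cards expectation

    Ḡ = 4 Ne n μ · E[ α αᵀ / (1 + Ne αᵀ V⁻¹ α) ],  α ~ N(0, M)

is estimated by Monte Carlo (default 10,000 draws, seed required; the
standard error of ρG is estimated from 10 batch means of the ratio
estimator). The scalar `Vs/(Ne·Vα)` governs its balance: ≪ 1 recovers the
closed-form ρG, ≫ 1 the neutral limit ρG → ρm.

**Shared eigenvectors.** When **M** and **V** commute (e.g. ϕm = ϕs = 1),
the equilibrium Ḡ keeps their common eigenbasis at every drift level:
selection strength and drift re-weight the eigenvalues without rotating the
axes, even while ρG moves over a wide range. Note the *leading* eigenvector
can jump discontinuously between the two fixed axes when the eigenvalue
ranking changes (ρG crossing zero); the invariant quantity reported is the
maximal principal angle between Ḡ's eigenbasis and **V**'s.

## Effective population size under selection on residual variation

Selection on the non-heritable phenotypic component makes fitness vary among
parents of identical breeding value, which intensifies drift. Near the
optimum the reduction is

    Ne = N · det[ I − ((Ω + E)⁻¹ E)² ],

implemented in `effective_size`; `census_for_target_ne` inverts it (rounding
to the nearest integer, an O(1/N) error in Ne) so simulation runs can hold
Ne constant while Vs varies. The formula is a near-optimum approximation —
it is derived for breeding values close to the optimum and is not
extrapolated beyond that regime. Its direct empirical counterpart,
`reproductive_effective_size`, Monte-Carloes the actual reproduction step of
the simulator (monomorphic population, fitness from residuals only) and
converts mean offspring-number variance Vk to `Ne = (4N−2)/(Vk+2)`; the two
agree within the package's 5% test tolerance at the tested selection
strengths, and the Monte-Carlo value is the arbiter where they differ.

## Individual-based simulator

One generation: (1) phenotypes and expected fitness `exp(−zᵀΩ⁻¹z/2)`;
(2) N mating events, each drawing two parents with probability proportional
to fitness, with replacement across events; selfing is excluded by redrawing
the second parent (sequential redraw; the alternative of redrawing the pair
jointly differs at O(1/N)); each event yields exactly one offspring, so
census size is exactly N every generation; (3) each offspring receives one
random allele per locus from each parent (free recombination) and each
transmitted allele mutates with probability μ. Expected fitness is used
directly as the sampling weight — no additional viability lottery — since
fitness-proportional mating realizes the intended selection process.

Runs start monomorphic at the optimum (fastest approach to stationarity, no
arbitrary standing variation) and are deterministic given a seed. The
realized G is the covariance of breeding values (denominator N−1), sampled
every 10 generations after a burn-in of 30% of the run by default (both
configurable; interval 1 reproduces every-generation sampling). Stationary
summaries average the post-burn-in samples; the standard error of ρG uses 10
batch means, robust to chain autocorrelation. The genic/association
decomposition splits realized G into the sum of per-allele-slot covariances
(the no-association expectation) and the remainder due to between-locus
associations ("hidden" linkage-disequilibrium variance), which are equal to
G by construction.

## Numerical choices

* Symmetry and positive-semidefiniteness are enforced with a relative
  tolerance of 1e−12 (double-precision eigenvalue noise); matrix square
  roots are principal symmetric PSD roots via eigendecomposition with
  eigenvalues clipped at 1e−14 relative.
* The drift term `(κ'²I + C)^{1/2} − κ'I` is evaluated on C's eigenvalues in
  the cancellation-free form `w / (√(κ'² + w) + κ')`; the naive form loses
  all precision in the strong-drift limit (κ'² ≫ ‖C‖).
* Eigenvector alignment is measured through the sine (residual norm) rather
  than arccos of the dot product, which saturates near 1.5e−8 for perfectly
  aligned vectors.
* First eigenvectors are reported with non-negative trait-1 loading, angle
  in (−π/2, π/2]; a zero covariance matrix has no defined correlation or
  orientation and is rejected explicitly.
* Wishart draws for the regime comparison use df = 10 with scale I/df
  (expectation I, substantial shape variation); df is configurable and must
  be at least dimension + 1.
* Parent sampling uses cumulative-sum inversion of the fitness weights; a
  numerically all-zero fitness vector aborts with an explicit error.
* All randomness flows through `numpy.random.Generator`; sweep drivers
  derive per-cell seeds from the base seed and grid indices via
  `SeedSequence`, and record them in the output table.

## Default problem sizes

Desk-scale defaults, chosen so the full test-and-reproduction cycle runs in
minutes on one CPU: simulation checks use 20,000 generations (10,000
burn-in), Ne ≤ 150, 5 replicate chains; Monte-Carlo expectations use 10⁴
draws (10⁵ in limit checks); effective-size Monte Carlo uses 2,000 replicate
generations at N = 200. The CLI's `--full-scale` flag restores 100,000
generations with every-generation sampling for sweeps. At desk scale the
simulator-vs-theory comparisons are made at a ±0.10 tolerance on ρG with
replicate averaging.

## What the generator emulates, and limitations

The simulator realizes the model's own assumptions — universal pleiotropy,
free recombination, Gaussian mutation increments, a fixed optimum,
hermaphroditic random mating without selfing, non-overlapping generations —
so passing tests demonstrate internal consistency of theory and process, not
realism of those assumptions. Features of real systems deliberately outside
scope: linkage (recombination < 0.5), dominance and epistasis on phenotype,
restricted or modular pleiotropy, moving or fluctuating optima,
frequency-dependent or disruptive selection, age structure, separate sexes.

Known approximation limits, visible in the package's own diagnostics: the
Gaussian-regime equilibrium assumes frequent mutations (it is used here with
μ = 0.01 per locus, loci being read as effectively non-recombining genomic
blocks rather than genes); at strong selection (small Vs) between-locus
associations depress realized G below the no-association theory and the
simulated ρG deviates from the analytic expectation by a few hundredths
(within the stated tolerance at the tested design points); the stochastic
House-of-Cards expectation is a heterozygosity-reduction approximation and
is less accurate than its Gaussian counterpart in the corresponding regime;
and the effective-size formula is first-order near the optimum, with the
Monte-Carlo reproduction-step check agreeing to a few percent rather than
exactly. The deviation of Ḡ from the infinite-population balance is first
order in κ, so "effectively infinite" is a statement about κ, not Ne alone:
at Ne = 5000 with the default mutation kernel, ρG still moves by ~0.07
across Vs ∈ [5, 100].
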