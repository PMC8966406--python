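# Methods

## Genome and meiosis

The genome is 29 autosomes totalling 2,922 cM (equal lengths by default);
loci are addressed by genetic position only — there are no base-pair
coordinates, and the PLINK MAP export synthesises bp = round(cM × 10⁶).
Markers and QTLs are placed uniformly over the total map length
(chromosome chosen with probability proportional to its length) and both
are biallelic.

Crossovers follow a **stationary gamma renewal process**: inter-crossover
distances are i.i.d. Gamma(shape ν, scale 1/ν) Morgans, so the expected
crossover count equals the map length in Morgans for every ν, and ν = 1
reduces to the Poisson (no-interference) model.  The first point on each
chromosome is a forward recurrence time, sampled as U·Gamma(ν + 1, 1/ν)
(the length-biased-interval construction), which makes the process
stationary rather than anchored at the telomere; there is no obligate
chiasma.  The default ν = 5.0 follows ruminant practice.  The starting
strand is Bernoulli(1/2) per chromosome.  Recurrent mutation flips each
allele independently at 9.4 × 10⁻⁶ per locus per generation (markers and
QTLs alike); the flip set is sampled exactly as a Binomial count plus a
uniform site subset, which is the conditional law of independent flips.

Founder haplotypes start at allele frequency 1/2 at every locus; the
5,500-generation drift phase then shapes the frequency spectrum toward
mutation–drift equilibrium.  Because most loci drift to fixation or below
the MAF floor, the candidate map is oversampled (`candidate_factor`,
default 3×) and the panel is finalised after the historical phase: exactly
the requested numbers of segregating markers (MAF ≥ 0.05) and segregating
QTLs are kept by random subsampling, and haplotypes are re-indexed.  The
MAF floor of 0.05 is the conventional chip-design threshold; it is
configurable.

## Population process

*Historical*: discrete non-overlapping generations, random union of
gametes (sires and dams drawn with replacement), no selection; phase 2
interpolates the size linearly to 3,000 with a terminal split of 400 males
/ 2,600 females.  *Expansion*: the configured founders (400 M / 2,600 F)
are sampled from the last historical generation; every dam leaves 5
offspring with a random sire; a population cap (default 15,000) bounds the
otherwise geometric growth by random culling that preserves the realised
sex ratio — the cap is a design choice of this package, since unbounded
5-per-dam growth for ten generations is astronomically large.
*Recent*: 40 sires and 400 dams; each season every dam produces
1 + Bernoulli(1/2) progeny (the "one or two progeny per dam per year"
rule) by a randomly assigned sire; progeny sex is Bernoulli(1/2); all
progeny are phenotyped; a pedigree-BLUP evaluation over every record to
date ranks candidates, and ⌊0.8 × 40⌋ sires and ⌊0.3 × 400⌋ dams are
replaced by the top-ranked young animals in the trait's selection
direction, with parents beyond 5 breeding seasons age-culled first.  The
two traits are simulated in separate single-trait runs; no selection index
is used.

## Trait model

TBV = Σ (allele count × effect) − offset over the QTLs.  Raw effect
magnitudes are Gamma(0.40, 1) with independent random signs; a single
multiplicative constant is applied so that the empirical Var(TBV) of the
base recent generation equals h²σ²_P, and the offset centres the base mean
at zero.  Phenotype = TBV + N(0, σ²_P(1 − h²)).  Variance components are
treated as known truths throughout (no REML inside the generation loop):
h² is an input of the study, not an estimate.

## Pedigree BLUP

A⁻¹ is assembled sparsely with Henderson's rules and inbreeding from a
Meuwissen–Luo-style recursion (compiled with numba); the dense tabular A
serves as the small-case oracle.  The animal-model mixed-model equations
use the overall mean as the only fixed effect and λ = (1 − h²)/h²; they
are solved by sparse LU by default, with a conjugate-gradient option that
the tests check against the direct solve.

## GEBV methods

All marker-based methods centre allele counts at twice the reference
allele frequency.  **GBLUP** is solved in covariance form: with
K = M_cM_cᵀ/(2Σp_jq_j), V = σ²_aK + σ²_eI, the GLS mean and the marker
representation u = σ²_a/(2Σpq)·M_cᵀV⁻¹(y − μ̂) give predictions identical
to the joint mixed-model GEBV for animals with missing phenotypes (the
tests verify both the RR-BLUP and the G-based-MME routes).  Because V is
positive definite by construction, no stabilising blend is needed; the
`blend` parameter (toward the identity) exists but defaults to 0.

**ssGBLUP** builds H⁻¹ = A⁻¹ + [0 0; 0 G_w⁻¹ − A₂₂⁻¹].  G is tuned
(a + bG) so its mean diagonal and mean element match A₂₂ (the standard
compatibility adjustment for base-population allele frequencies), then
blended G_w = 0.95·G_tuned + 0.05·A₂₂ to guarantee invertibility;
blend = 1 collapses exactly to pedigree BLUP.  A₂₂ is extracted from the
sparse A⁻¹ factorisation rather than by building the dense A.

**Bayesian alphabet** (single-site Gibbs, numba kernel): intercept, marker
effects, per-marker variances (BayesA), inclusion indicators with prior
mass π = 0.95 at zero (BayesB), a common variance (BRR), or
exponential-mixture scales with λ² ~ Gamma(0.55, rate 0.1) (Bayesian
LASSO), plus the residual variance.  Prior elicitation follows the
expectation-matching rule: ν = 4.2 and the scale S solved so
E[σ²_gj] = h²σ²_P/(2Σp_jq_j) (divided by 1 − π for BayesB); the residual
prior matches (1 − h²)σ²_P the same way.  Chain defaults are 20,000
iterations, 5,000 burn-in, thinning 10, with an explicit integer seed;
reported effects are posterior means over the kept samples.  Gibbs updates
are conjugate throughout; the inverse-Gaussian draw for the LASSO uses the
Michael–Schucany–Haas transform.  GEBV for new animals is the centred
genotype row times the posterior-mean effects.

## Evaluation

Reference animals are sampled from recent generations 2–7, validation
animals from 8–10, disjointly and with exact sex counts when a composition
is requested.  Accuracy is the Pearson correlation between validation GEBV
and the **true breeding values** by default.  Realised phenotypes are
available as an option, but several benchmark accuracies (e.g. 0.72 at
h² = 0.34) exceed the phenotype-prediction ceiling √h² ≈ 0.58, so TBV is
the only realised vector consistent with those magnitudes; the
discrepancy is flagged rather than resolved.

The experiment is one-factor-at-a-time around a per-trait baseline cell
(FD: 60 K markers, 1,500 reference, 150 QTLs; LBW: 45 K, 3,000, 100 —
inferred from the repeated cells of the results tables and configurable).
ANOVA uses an additive fixed-effects model with sequential (Type I) sums
of squares in the listed factor order — the design is not a full
factorial, so an orthogonal Type III decomposition is not defined without
extra convention.  Duncan's multiple range test uses the protected level
α_p = 1 − (1 − α)^(p−1), studentized-range quantiles from scipy, the
harmonic mean of level counts within a span, and assigns letters to
maximal homogeneous runs of the ordered means (letters are therefore
always contiguous, which enforces order-consistency).

## Problem sizes, profiles, and what the tests show

Two bundled profiles: `paper-scale` is the full design (5,500 historical
generations, up to 60 K markers, 216-record main study; hours to days of
compute) and `desk-scale` shrinks the history to 300 generations at
N = 200 with 3,000 markers and 50 QTLs so that a complete
simulate–predict–evaluate cycle runs in seconds to minutes.  The test
suite runs only desk-scale and smaller problems: exact identities and
closed forms at tiny sizes, distributional calibrations at n = 10,000, and
the qualitative accuracy orderings over 10–12 replicated desk-scale
populations with one-sided paired t-tests.

One desk-scale subtlety is documented here because it affects what the
tests show: with 40 sires and 400 dams, prediction information is
dominated by large half-sib families, which compensates low heritability
and nearly equalises the two traits' accuracies.  The heritability
ordering (h² = 0.34 beating h² = 0.11) is therefore tested in the
LD-dominated regime — a denser panel (3,000 markers) over a smaller-Ne
(N = 100) history — where per-phenotype information scales with h², as it
does in the full-scale design.  The full-scale quantitative cell means are
an overnight target via the paper-scale profile, not part of the default
suite.

The simulator emulates drift-generated LD, family structure, selection
response, and Bulmer-type variance depletion.  It does not emulate
genotyping error, non-uniform recombination, sex chromosomes, dominance or
epistasis, maternal effects, or repeated records, so passing tests say
nothing about those features of real data.

## Numerical choices and degenerate inputs

Strictly duplicate locus positions are resampled; monomorphic panels,
all-missing phenotypes, cyclic pedigrees, infeasible sex compositions, and
MAF thresholds ≥ 0.5 raise errors rather than being repaired.  Gibbs
kernels skip zero-variance marker columns.  All randomness flows from a
single master seed through `numpy.random.SeedSequence` spawning; pipeline
artifacts are stamped with a configuration hash and the seed, and a rerun
with the same configuration is byte-identical.
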