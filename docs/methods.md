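# Methods

## The moment system

`ldmoments` evolves expectations of a family of one- and two-locus statistics
for `P` randomly mating populations. With `p_i`, `q_i` the derived-allele
frequencies at the left and right locus in population `i`, and
`D_i = f_AB f_ab − f_Ab f_aB` the haplotype covariance, the basis contains

- `E[D_i D_j]` — variances and covariances of signed LD,
- `E[D_i z_{jk}]` with `z_{jk} = (1 − 2 p_j)(1 − 2 q_k)` — the covariance of
  `D` with low-frequency-allele signal; strongly elevated by admixture from
  diverged lineages,
- `E[π₂(i,j;k,l)]` — joint heterozygosity across the two loci,
  `¼ (p_i(1−p_j) + p_j(1−p_i)) (q_k(1−q_l) + q_l(1−q_k))`,
- `E[H_{ij}] = E[p_i(1−p_j) + p_j(1−p_i)]` — single-locus heterozygosity
  within and between populations,
- the constant `1`, appended so the infinite-sites mutation source is an
  ordinary matrix column and the whole system is linear, `ẏ = A y`.

Because all these quantities are genome-wide averages over pairs of loci,
they are invariant under exchanging the two loci and under the index
symmetries of each family; labels are stored canonically (sorted index
slots) and the basis for `P` populations has `Q + PQ + Q(Q+1)/2 + Q + 1`
entries with `Q = P(P+1)/2` (5, 19, 52, 116 for `P` = 1..4).

### Operator construction by enumeration

No operator entry is transcribed by hand. Each basis statistic is a
polynomial in per-population haplotype frequencies; its expectation after one
Wright–Fisher generation is computed symbolically — deterministic
recombination and migration substituted into the polynomial, followed by
exact multinomial resampling moments — keeping terms to first order in the
small quantities `1/2N_i`, `r`, `m_ij`, `u` and discarding their cross
products. The image polynomial is then re-expressed exactly (rational
arithmetic, modulo the simplex constraint `Σ_h f_h = 1`) as a linear
combination of basis statistics; this yields one sparse matrix per small
parameter. For one population the machinery reproduces the classical drift
matrix `[[−3,1,1],[4,−5,0],[0,1,−2]]/(2N)` and recombination matrix
`r·diag(−2,−1,0)` of the `(D², Dz, π₂)` recursion exactly, and the
cross-population `E[D₁D₂]` decay rate `1/2N₁ + 1/2N₂ + 2r`; for `P = 2` the
migration rows reproduce the heterozygosity recursion
`E[H₁₂]' = m₁₂E[H₁] + m₂₁E[H₂] + (1−m₁₂−m₂₁)E[H₁₂]`.

Mutation follows the infinite-sites model: a new mutation arising in
population `a` (rate `2N_a u` per generation) creates a site at frequency
`1/2N_a` on a random background haplotype, and pairs with standing variation
at the other locus. Worked through the same enumeration, this injects
`(u/2)(H_{ij} + H_{kl})` per generation into `π₂(i,j;k,l)` and `2u` into
every `H` row, and contributes nothing at leading order to the `D`-moments
(the new allele lands on a random background, so its association with the
other locus has mean zero). In particular the `Dz` rows receive **no**
mutation source at this order — the one-population equilibrium then
reproduces the classical `σ_d² = E[D²]/E[π₂] = (10+ρ)/(22+13ρ+ρ²)`, which
is a sharp check on both the drift block and the mutation source.

A projection subtlety: the re-expression step is done after symmetrizing the
image over locus exchange, and the same coefficients are obtained without
symmetrization (verified for `P ≤ 3`), so the recursion is valid
state-by-state, not merely for locus-exchangeable ensembles.

### Scaling and integration

Time is measured in units of `2 N_ref` generations; the generator is
`A = Σ_i D_i/ν_i + Σ_{ij} m̃_ij M_ij + (ρ/2) R + (θ/2) U` with
`ν_i = N_i/N_ref`, `m̃ = 2N_ref m`, `ρ = 4N_ref r`, `θ = 4N_ref u`.
Epochs integrate with a Crank–Nicolson scheme (second order; halving the
step shrinks errors fourfold), with the generator evaluated at step midpoints
when sizes change within an epoch. The default step is
`min(10⁻³, duration/50)`; models used inside optimization loops typically
use `dt ≈ 10⁻²`, where the discretization error is a few parts in 10⁴ for
`ρ ≤ 10`. Stationary states solve `A y = 0` with the constant entry pinned
to one (requires `θ > 0`). The coefficient matrices depend only on the
number of populations and are constructed once per process and cached;
building them takes a fraction of a second for one population and tens of
seconds for four, after which a four-population model with splits,
migration, and an admixture pulse evaluates twelve recombination bins in
well under a second.

### Events

At a **split**, every statistic obtained by replacing any subset of parental
indices with either child equals the parental statistic (lineages drawn from
the two children are exchangeable with parental lineages at that instant);
in particular `E[D_{c1}D_{c2}] = E[D²_parent]` and all three heterozygosities
equal the parental one. An **admixture** pulse draws each lineage of the new
population from source 1 with probability `f`, source 2 otherwise; the
admixed haplotype frequencies are the exact mixture, and every moment of the
enlarged basis is expanded symbolically and re-expressed exactly in pre-event
moments. The expansion reproduces, coefficient by coefficient,

    E[D_adm]  = f E[D₁] + (1−f) E[D₂] + f(1−f) E[δ],
    E[D²_adm] = f²E[D₁²] + (1−f)²E[D₂²] + 2f(1−f)E[D₁D₂]
                + 2f²(1−f)E[D₁δ] + 2f(1−f)²E[D₂δ] + f²(1−f)²E[δ²],

with `δ = (p₁−p₂)(q₁−q₂)`, and analogous expansions for every other moment
(δ-terms re-expand into the `Dz` and `π₂` families). Pulses into an existing
population are admixture followed by marginalizing the stand-in source.

## The Wright–Fisher oracle

An independent discrete simulator validates every operator and transform: a
two-locus, multi-deme Wright–Fisher model with deterministic recombination,
(optional) symmetric two-allele mutation and migration applied to expected
haplotype frequencies, followed by multinomial resampling of `2N_i`
haplotypes per deme, vectorized over 10⁵ replicates. Trajectory
comparisons use the exact per-generation recursion (matrix powers of
`I + Σ D_i/2N_i + R r + Σ M_ij m_ij`), so they probe the leading-order
operators themselves, not the additional time-discretization error of the
continuous limit.

The simulator's regime is chosen so that the neglected second-order terms
stay below Monte-Carlo resolution: the per-generation truncation error is of
relative order `(λ/2N)²` for a statistic decaying at scaled rate
`λ ≈ 3 + ρ`, plus `m²` migration products, and both accumulate linearly in
the number of generations. Diagnostics during development showed the `m²`
products can be amplified by near-cancelling cross-population `Dz`
statistics, so the random validation configurations cap per-generation
migration at `7·10⁻⁴` (scaled rates `m̃` up to ≈ 0.7), `r ≤ 0.003`,
`N ∈ [200, 500]`, and 20–80 generations. With ~500 simultaneous z-scores, a
correct implementation exceeds 3 standard errors somewhere most of the time
by chance alone; comparisons therefore use a familywise-calibrated threshold
(the normal quantile at which a correct implementation fails anywhere with
the same 0.27% probability as a single 3-SE comparison) plus the requirement
that at least 99% of comparisons lie within 3 SE.

The same machinery generates synthetic data: panels of independent SNP-pair
systems sampled into diploid genotypes by random union of gametes and written
as plain-text VCF with a matching sample–population map and HapMap-format
recombination map. Pairs are laid out on synthetic chromosomes with
within-pair base-pair distances reproducing the true `r` under a uniform map
and inter-pair distances far beyond any analysis `r_max`, so the genome-wide
pair-enumeration path of the data module applies unchanged. The panels
emulate ideal sequencing (no genotyping error, no missingness, known map);
conclusions about robustness to real-data artifacts are limited to the
down-sampling checks in the test suite.

## Estimation from unphased genotypes

The statistics cannot be computed directly from unphased diploid data (the
double heterozygote hides phase). The classical genotype-count estimator

    D̂ = (1/2n_d)(2n_AABB + n_AABb + n_AaBB + ½ n_AaBb) − (n_A/2n_d)(n_B/2n_d)

is implemented as printed but is biased — under random union of gametes its
expectation is `½(1 − 1/n_d) D` — so genome-wide inference uses
bias-corrected estimators derived symbolically: under multinomial sampling
of `n_d` diploids from a population in Hardy–Weinberg proportions, the
expectation of any product of falling factorials of the nine two-locus
genotype counts is an exact polynomial in haplotype frequencies, and the
linear map from population moments to these count-polynomial expectations is
inverted in exact rational arithmetic (per population, with cross-population
moments factorizing over independent samples). The resulting estimators are
exactly unbiased for every basis statistic at every haplotype-frequency
state; phase-ambiguous components (a bare `D`, or `p·q` within one
population) require one more factorial order than naive degree counting, and
the minimal order is bumped automatically when needed. Because the inverse
is not unique, the particular solution is averaged over the four-element
allele-relabeling group, which makes the estimates exactly invariant under
relabeling the counted allele at either locus. One representation-dependent
property is deliberately not guaranteed: an all-homozygote table (which is
effectively phased) need not reproduce plug-in haplotype-count formulas,
because an equally valid representation may, for instance, measure
heterozygosity through heterozygote counts; unbiasedness over the sampling
distribution is the invariant property and is what the tests assert,
including on a maximal-LD two-haplotype population where most sampled
tables are homozygous. Individuals
enter a pair only when both sites are called; pairs below a configurable
minimum of complete diploids (default 20) are skipped.

Pairs are assigned recombination distances by linear interpolation of a
cumulative genetic map (extrapolation is refused), filtered to
`r_min ≤ r ≤ r_max` (defaults `10⁻⁵` and `2·10⁻³`; the lower bound guards
against short-range mutation-rate correlation and map resolution), and
binned into half-open, roughly log-spaced bins (default 12). Bin means of
the raw pair estimators are normalized by the bin's mean `π̂₂` of a chosen
population (`Ĥ` rows by that population's `Ĥ`), making all curves
independent of the overall mutation rate. Covariances come from a block
bootstrap: pairs stay attached to the genomic block of their left SNP
(fixed 5-Mb spans by default, or whole chromosomes), blocks are resampled
with replacement, and the full normalized vector is recomputed per
replicate, which propagates normalization noise and the local dependence of
overlapping pairs.

## Inference

Each bin's observed vector is modeled as Gaussian around the model curve
with the bootstrap covariance; the composite log-likelihood sums over bins,
ignoring between-bin dependence. Model curves are evaluated at
`ρ = 4 N_ref r` at the geometric mean of each bin's edges (bin placement is
smooth on the log scale, and with locally log-uniform pair density the mean
log distance per bin coincides with that representative; the residual
within-bin curvature effect was measured at ≲10⁻³ relative). The rows that
are identically one under the normalization (the normalizing population's
`π₂` and `H`) are excluded from the objective; any statistic subset can be
masked (e.g. the `Dz` rows, the diagnostic that historically exposed model
misspecification). Optimization is bounded Nelder–Mead on log-transformed
positive parameters with seeded multi-start; `N_ref` is a parameter, made
identifiable by the `r → ρ` scaling of the bins.

Two numerical safeguards matter in practice. The bootstrap covariance of
many strongly correlated statistics is rank-deficient or has severely
downward-biased small eigenvalues when the number of bootstrap replicates is
comparable to the dimension; eigenvalues are floored at `10⁻⁶·tr(Σ)/k`, and
an optional diagonal shrinkage `(1−α)Σ + α·diag(Σ)` (α = 1, i.e. pure
per-statistic weighting, in the validation study) prevents the objective
from leaning on directions whose variance is essentially unknown — without
it, parameter uncertainties are underestimated roughly twofold.
Uncertainties come from refitting bootstrap replicate vectors (covariance
held fixed, simplex restarted from the optimum). With only a few dozen
affordable refits, percentile endpoints sit systematically inside the true
quantiles (the extreme order statistics of a small sample are biased
inward), so intervals may also be formed as estimate ± z·sd(refits); the
percentile method remains available and is the default of `bootstrap_ci`.

## The end-to-end recovery study

The calibration study simulates a two-population split-with-migration truth
entirely inside the oracle: a single ancestral state at linkage equilibrium
with both allele frequencies ½ splits into two populations of `N = 500`
diploids exchanging migrants at `m = 10⁻³` per generation (`m̃ = 1`) for 160
generations; 10⁵ SNP pairs with log-uniform `r` spanning `ρ ∈ [0.4, 6]` are
sampled into 20 diploids per population, and the three parameters
`(N_ref, T, m)` are refit from six normalized bins with per-statistic
weighting and 28 bootstrap refits per interval. These conditions were set by
an explicit validity-regime analysis: the accumulated leading-order
truncation error (`G·(λ/2N)²`, plus the discrete-generation versus
continuous-time gap) tilts the model curves by a few parts per thousand
here, well below parameter standard errors of 3–5%; at twice the drift
intensity the tilt reaches 2–3% and dominates the sampling error, in which
case the truth generator is no longer described by the fitted model and
coverage degrades for reasons unrelated to the inference machinery. Across
20 seeded runs the pooled 95% interval coverage over the three parameters is
at the nominal level within binomial error, with median parameter errors of
≈ 4%.

## Known limitations

- All operators are leading-order in `1/2N`, `r`, `u`, `m`; loosely linked
  loci (`r` approaching ½) and strong migration need higher-order terms and
  are outside scope (curve evaluation refuses `r ≥ 0.1`).
- The infinite-sites mutation source assumes per-site heterozygosity of
  order `θ ≪ 1`; the finite-sites oracle mode is used for stationarity
  checks only at `θ ≤ 10⁻³`, where the relative finite-sites bias is of
  order `θ`.
- Genotype estimators assume random union of gametes within populations;
  inbreeding or substructure within a labeled population violates the
  derivation.
- The composite likelihood ignores between-bin dependence; its curvature is
  not a valid uncertainty estimate, which is why uncertainties are obtained
  by bootstrap refitting.
- Higher-order moments of `D`, the full two-locus haplotype spectrum, and
  selection are not implemented.
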