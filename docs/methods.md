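# Methods

`bmdemog` re-implements the demographic-inference machinery used to ask
whether the Bering-Chukchi-Beaufort Seas (BCB) bowhead whale stock carries a
genetic signature of the 1848-1914 commercial-whaling bottleneck, and what
older demographic events shaped its variation. The observed data the
package ships are the study's printed per-locus summaries (22
microsatellite loci typed in 324 whales: allele counts 6-28, unbiased
expected heterozygosities 0.551-0.939) and scalar descriptors of a 2494-bp
three-gene mtDNA concatenation in 168 whales; the raw genotypes were never
deposited, so every analysis that needs more than those summaries runs on
simulated or synthetic data.

## Coalescent engine

All microsatellite machinery rests on one simulator: the Kingman
n-coalescent under piecewise-constant diploid effective size, with
exponential waiting times carried across epoch boundaries (the residual
standard-exponential deviate is re-scaled by the next epoch's rate, valid
by memorylessness). Within an epoch of size `N`, `c` lineages coalesce at
rate `c(c-1)/2` per `2*N*s` generations; the marker scaling `s` is 1 for
autosomes and 1/4 for mtDNA under the study's 1:1 sex ratio (haploid,
maternal). Mutations are Poisson on branches. Mutation families:

* **SMM** — ±1 repeat, equiprobable;
* **IAM** — every mutation creates a novel allele;
* **TPM** — single step with probability `1 - p_multistep`, otherwise a
  ± geometric step whose parameter is solved from the requested multistep
  variance (default 30, the heterozygosity-excess-test literature's
  default). The study's TPM99/95/90/70 labels map to 1/5/10/30% multistep
  mutations;
* **GSM** — every step geometric. The conventional "parameter 0.22" is the
  continuation probability, i.e. mean step `1/(1-0.22) ≈ 1.28` repeats.
  This matters: a geometric with *success* probability 0.22 (mean 4.5)
  produces far less size homoplasy, many more alleles per unit diversity,
  and a qualitatively different ABC reference table.

The per-locus simulation is implemented twice: a readable single-genealogy
path (`simulate_genealogy` + `mutate_msat`) and batched numba kernels
(~60 µs per 648-gene genealogy) used wherever millions of replicates are
needed; the two are cross-checked against each other, against closed forms
(E[T2] = 2N; SMM equilibrium He = 1 − 1/√(1+2θ); IAM He = θ/(1+θ) and
Ewens E[K]), and against msprime (Kolmogorov-Smirnov on TMRCA
distributions).

Sequence evolution is HKY with invariant sites and gamma rate variation
(study model: HKY + I(0.5) + G(0.05); κ defaults to 20, not printed in the
study). Events per branch-site are Poisson with the embedded jump chain
applied per event; at equal base frequencies the transition fraction per
event is κ/(κ+2).

## Sequence statistics

Pairwise differences are uncorrected, skipping sites with a gap or N in
either pair member; θ̂ for both neutrality tests is the mean pairwise
difference count. Tajima's D uses the 1989 variance constants and is
undefined (raises) at S = 0 rather than silently zero. Its p-value is the
fraction of neutral constant-size coalescent replicates (θ = mpd, infinite
sites) with D at or below the observed. Fu's Fs uses the Ewens sampling
formula, with unsigned Stirling numbers of the first kind computed by the
log-space recurrence |s(n,k)| = |s(n−1,k−1)| + (n−1)|s(n−1,k)| (stable at
the study's n = 168); `S' = P(K ≥ k_obs)` and `Fs = ln(S'/(1−S'))`, +∞ when
every sequence is identical.

The mismatch fit uses the exact sudden-expansion expectation obtained from
the pair-coalescence density (hazard 1/θ1 since the expansion at τ
mutational units, 1/θ0 before):

    F_j = θ1^j/(1+θ1)^(j+1) · P(j+1, τ(1+θ1)/θ1)
        + e^(−τ/θ1) · [geom(θ0) ⊛ Poisson(τ)]_j

with P the regularized lower incomplete gamma and ⊛ discrete convolution.
(τ, θ0, θ1) minimize the SSD against the observed relative spectrum
(multi-start Nelder-Mead on log parameters, clipped to avoid overflow).
Because the model is τ-invariant when θ0 = θ1, a stationary fit (τ = 0) is
preferred whenever it matches the best SSD — an equilibrium spectrum
therefore reports τ = 0, not an arbitrary τ. Significance comes from a
parametric bootstrap that re-simulates spectra under the fitted demography
and refits each replicate (SSD), and compares raggedness with the
trailing-zero convention r = Σ_{i=1..d+1}(x_i − x_{i−1})², x_{d+1} = 0.
Calendar dating is t = τ/(2 μ L) generations × 52 years. With the study's
printed inputs (τ = 4.34, μ = 6.14e−7, L = 2494) this gives ≈ 73,700 years
before present; the study prints 75,296, so its effective L or unrounded μ
differed — the three knobs are exposed and no printed value is hard-coded.

## Heterozygosity-excess battery

For each locus, the gene diversity expected at mutation-drift equilibrium
given the observed allele count (`Heq`) is simulated: θ is tuned so
E[K] = k — exactly via the Ewens formula under the IAM, via inversion of a
simulated monotone E[K]-vs-log θ curve for the stepwise families (25
log-spaced grid points, 20,000 replicates each, giving |E[K] − k| well
under 0.1) — then equilibrium replicates with K ≠ k are rejected and the
unbiased gene diversity of the accepted ones forms the Heq distribution
(10,000 accepted replicates per locus by default; adaptive batch sizing
keeps the rejection overhead near the theoretical acceptance rate, with a
hard error below acceptance 1e−4). Aggregation over loci: a sign test
(binomial at the mean per-locus expected excess probability, i.e. the
fraction of Heq draws above the Heq mean, ties split), the standardized
differences test T2 = ΣD_i/√L against a standard normal, and Wilcoxon
signed-rank tests (scipy, one-tailed both directions and two-tailed) on
He_obs − mean(Heq). The mode-shift check bins pooled allele frequencies
into ten 0.1-wide classes; "L-shaped" iff the (0, 0.1] class is strictly
modal.

Calibration: under the battery's own null hypothesis — observed He a draw
from the conditional Heq distribution given the locus's allele count — the
two-tailed Wilcoxon rejects at the nominal rate (4.8% measured at α = 0.05
over 250 replicate panels). On datasets simulated unconditionally at a
single θ and then pushed through the k-conditioning, it over-rejects by
roughly a factor two (10-15% across sample sizes 120-648); this is the
conditioning's information loss, inherent to the heterozygosity-excess
method, and worth keeping in mind when interpreting borderline p-values
from it.

On the printed panel the battery reproduces the published
mutation-model dependence: all 22 loci in excess under the IAM, a large
deficiency majority under the SMM, and the sign reversal across the TPM
family. The exact SMM split is borderline at one locus: our conditional
Heq mean at k = 22 is 0.9215, and with printed He values 0.926/0.925 at
the two k = 22 loci the excess count lands at 6 rather than the printed
5 — the published split implies the original program's Heq(k = 22) lay
0.004 higher, a difference the printed methods do not let us reconstruct.

## ABC model comparison

Two four-epoch scenarios, backward in time: contemporary Ne to t1
(uniform integer 1-6 generations, the whaling window), a bottleneck-window
Ne to t2, historic Ne to t3, ancestral Ne beyond; t2 and t3 are two
uniform draws on 7-357 generations, sorted. The models are identical
except the bottleneck model confines the bottleneck-window Ne to 1-2000.
Ne priors are uniform 1-N_max (N_max 20,000 by default; 10k/50k/100k in
the sensitivity sweep); the GSM mean rate is uniform 1e−5 to 1e−3 per
locus per generation.

Each simulated dataset is 324 diploids × 22 GSM loci reduced to the
summary pair (mean allele count, mean unbiased expected heterozygosity) —
the mtDNA statistics are deliberately not part of the fitted vector (the
study found simulated mtDNA a poor fit at these time depths) and are
available only through the `rank_observed` fit diagnostic. Per-locus
mutation rates scatter around the dataset's drawn mean rate as
Gamma(shape 2, mean μ̄). This heterogeneity is the package's deliberate
default and is load-bearing: microsatellite panels genuinely mix slow and
fast loci, and because E[K] keeps growing with rate while He saturates,
rate scatter raises a dataset's mean allele count relative to its mean
heterozygosity. The observed pair (15.7, 0.821) sits on the equilibrium
manifold of the heterogeneous simulator but off that of a single-rate
simulator — with a single shared rate the analysis mistakes the panel's
rate variance for a population expansion. `rate_gamma_shape=None`
restores the single-rate variant.

Inference is classic rejection + local-linear regression: statistics are
standardized by their reference-table SDs, Euclidean distances taken, the
closest 1% retained with Epanechnikov weights `1 − (d/d_max)²`. Model
choice regresses the model indicator on the centered statistics and
evaluates at the observed point (clipped to [0, 1]); model posteriors and
raw acceptance ratios agree on separable toys. Parameter posteriors use
the weighted regression adjustment on log scale (all parameters are
positive with scale-spanning priors), back-transformed and clipped into
the prior's support — the log-scale correction can otherwise overshoot a
uniform prior's edge, which the original tooling prevented with logit
transforms. Error rates classify pseudo-observed datasets drawn from each
model's own priors by their higher model posterior; Type I is the fraction
of best-model pods not recovered, Type II the fraction of alternative-model
pods classified as the best model. Marginal posteriors are summarized by
mean, median and 5/95% quantiles with a Gaussian-kernel density, and a
posterior indistinguishable from its prior (two-sample KS p > 0.5) is
flagged uninformative — the study's flat-posterior diagnostic.

Problem sizes: the package defaults to 50,000-100,000 simulated datasets
per model (the original analysis used 10⁶); at these sizes the model
posterior, the historic-Ne posterior median, and both error rates
reproduce the published values within their Monte-Carlo spread.

## Heterozygosity-loss grid

The post-hoc question — how much diversity should the whaling era have
erased — is answered by a hybrid simulation: the contemporary population's
`2*Ne_contemporary` gene copies start from an equilibrium coalescent
sample (SMM, θ = 4·Ne_ancestral·μ, μ = 1e−4, Ne_ancestral = 10,000), drift
forward through explicit multinomial Wright-Fisher resampling with
mutation for the bottleneck duration, and are then sampled down to 324
individuals (or the whole population if smaller) for the unbiased gene
diversity. The nine-point grid crosses contemporary Ne {50, 500, 1000}
with durations {5, 50, 500} generations; the bowhead-like combination
(1000, 5) loses under half a percent of heterozygosity, matching the
drift expectation `(1 − 1/(2Ne))^t = 0.9975`. The closed form tracks the
simulations within 2% wherever μ·t ≪ 1; at (50, 500) and (500, 500)
mutation replenishment puts the simulated values visibly above pure drift,
which is the expected physics, not an error.

## Synthetic data

Target-driven genotype tables realize per-locus (k, He) pairs by solving a
geometric-decay frequency profile (with a small frequency floor so rare
alleles survive sampling) by bisection — diversity is monotone in the
decay rate — then drawing diploids under Hardy-Weinberg proportions and
retrying until the realized k is exact and He within 0.02. An optional
null-allele mode adds a non-amplifying allele: null homozygotes become
missing calls, null heterozygotes appear as visible homozygotes, which is
precisely the Ho deficit the Chakraborty estimator `(He−Ho)/(He+Ho)`
detects. Expansion alignments are coalescent samples simulated directly in
mutational units (hazard 1/θ, mutation intensity 1/2 per branch unit) with
uniformly placed HKY substitutions; with L far above the expected mutation
count they realize the infinite-sites mismatch model with known (θ0, θ1,
τ), which is how the τ-recovery property (±20% median over 200 datasets)
is tested.

What the generators do not emulate: linkage disequilibrium between loci
(loci are independent), genotyping error and allelic dropout other than
the explicit null-allele mode, population structure, and overlapping
generations. Passing tests therefore show the estimators and the inference
chain are correct on data satisfying their own assumptions, not that those
assumptions hold for any particular real dataset.

## Numerical choices and degenerate inputs

* Gene diversity is Nei's unbiased `n/(n−1)(1 − Σp²)` everywhere.
* GENEPOP codes: 2- and 3-digit dialects auto-detected; a cell is missing
  iff any allele code is zero; half-missing calls are normalized to fully
  missing; allele pairs are stored unordered.
* The fixture assumes complete genotypes (n_genes = 648 at every locus);
  per-locus missingness was not reported.
* HWE: Monte-Carlo exact test re-pairing gene copies, Levene conditional
  probabilities compared in log space with a 1e−12 tie guard; monomorphic
  loci return p = 1 by convention.
* Monomorphic loci are excluded from the battery with an error if fewer
  than two polymorphic loci remain; an all-unique locus (k = n) has a
  degenerate Heq ≡ 1 distribution and is rejected by the battery's
  sd > 0 guard.
* Mismatch fits on spectra with all mass at class zero return τ = 0 with
  a `degenerate` flag instead of fitting.
* Times drawn in the ABC are integer generations; drawn Ne values are
  integers ≥ 1.
* Seeds: every stochastic entry point takes a seed or Generator; numba
  kernels are seeded independently per batch with integers below 2³¹.
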