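# Methods

This note documents the models behind each module, the parameters that
matter, the numerical choices made where several were defensible, and what
the synthetic-data validation does and does not establish.

## Local ancestry inference (PCA-window HMM)

Phased reference haplotypes from K putative ancestral populations are pooled
and, chromosome by chromosome, partitioned into non-overlapping windows of
`window_size` SNPs (default 70; a trailing remainder shorter than a full
window is merged into the last full window rather than kept as an unstable
tiny window).  Within each window, PCA is computed on the column-centered
pooled reference alleles, and the first two PC scores of each reference
population are summarized by a mean vector and covariance.  Covariances are
shrunk as Σ + εI with ε = 10⁻⁴ × mean diagonal (floor 10⁻⁸·10⁻⁴), which
guarantees positive-definiteness with reference panels of a few dozen
haplotypes.  Windows monomorphic across all references are flagged
uninformative and contribute a flat emission.

An admixed haplotype's window scores give per-window log-likelihoods of
membership in each panel; a hidden Markov chain over windows uses the pulse
transition kernel

    P(i → j) = e^(−g·d) δᵢⱼ + (1 − e^(−g·d)) qⱼ

with d the inter-window distance in Morgans (midpoint-to-midpoint cM / 100 —
the convention is a package choice), q the genome-wide ancestry proportions
(also the chain's initial and stationary distribution) and g an effective
"generations since admixture" parameter.  g is fitted per population by
golden-section search on log g over [1, 500], maximizing the summed forward
log-likelihood; a warning is logged when the optimum sits at a bound.  g is
an *effective* parameter: window-resolution blurring of tract boundaries
biases it downward relative to the true admixture time, which is why
recovery tests accept a factor-two band.

Two decoders serve different consumers, as the downstream analyses require:
forward–backward posteriors thresholded at 0.9 ("unknown" below threshold)
feed ASPCA masking; the Viterbi path (ties broken toward the lowest ancestry
index, deterministically) feeds tract-length analyses.  Consecutive
same-label windows merge into tracts whose boundaries are the midpoints
between flanking windows' edge variants in both cM and bp; a tract spanning
every window of a chromosome carries a whole-chromosome flag.

Window PCA pools all reference panels rather than fitting one basis per
panel; with disjoint panels per-panel bases would not give comparable score
spaces.

**Within-block deconvolution.** To resolve sub-continental ancestry inside
previously called continental blocks, a separate window model and HMM are
fitted per block, restricted to the block's variants — J disjoint HMMs for J
blocks, with no information flow across block boundaries.  Blocks shorter
than one window are skipped with a warning.  Because a block descends from a
single migrant lineage, a small g (≈2) is appropriate within blocks.  The
per-bin "fraction called sub-source A" statistic counts only windows whose
posterior reaches the confidence threshold (default 0.9).

## Ancestry-specific PCA

Masking keeps an admixed haplotype's alleles only at variants inside windows
called the target ancestry at the 0.9 posterior threshold; haplotypes whose
genome-wide fraction of target-called windows falls below a cutoff (3% for
sparse ancestries, 25% for well-represented ones, per the analysis design)
are excluded.  Reference haplotypes enter fully observed, and reference and
admixed rows are factorized jointly.

The factorization is a regularized alternating least squares (ALS) subspace
PCA on the observed entries:

    min_{U,W}  Σ_observed (x_rc − μ_c − u_r·w_c)² + λ(‖U‖² + ‖W‖²)

with μ_c the observed-entry column mean, λ defaulting to
10⁻³ × (observed entries)/(rows), convergence when the relative objective
decrease falls below `tol` (default 10⁻⁶), and a warning plus partial result
at `max_iter`.  Columns observed in fewer than two rows are dropped; rows
with fewer than `min_observed` sites (default 500) are rejected.  The final
factors are orthonormalized through an SVD of the fitted low-rank matrix and
sign-fixed so each component's largest-magnitude loading is positive.  The
objective is provably non-increasing (each half-step is an exact
least-squares solve), and with no missing data and λ = 0 the converged
scores equal classical PCA scores up to sign — both properties are tested.
ALS was chosen as the estimator family for subspace PCA with missing data;
it is simple, monotone, and exact in the fully observed limit.

**Centroid-deviation bootstrap test.** The observed statistic is Fisher's
combination S = −2(ln p₁ + ln p₂) of two-sample Welch t-tests comparing the
admixed group against the pooled reference subgroups on each of the first
two axes.  The null resamples the two reference subgroups (e.g. Portuguese
and Spanish) with replacement and computes the same statistic between them,
modeling the reference cluster's intrinsic structure;
p = (1 + #{S_null ≥ S_obs})/(n_boot + 1) with 10,000 bootstraps by default.
Only the reference subgroups are resampled, not the admixed group.  Note a
structural property of this construction: each null replicate carries the
*fixed* subgroup mean offset plus resampling noise, roughly doubling the
null statistic's scale relative to the observed comparison.  The test is
therefore conservative by design — its p-values are super-uniform under a
same-distribution null (simulated type-I error ≈ 0.02 at nominal 0.05).
It answers "does the admixed group deviate more than the reference's own
internal structure?", not "is it drawn from the same distribution?".

**Size-stratified source assignment.** Tracts split at 50 cM (short < 50,
long ≥ 50; the boundary value closes the long class, since strict "<50/<50"
would leave it unassigned), with an optional (5, 50) cM medium class
guarding against very-short-tract misassignment.  For each class, PCA is
rerun on the sites inside that class's tracts; reference clusters get ML
bivariate normal fits (same εI shrinkage; populations with < 3 rows are
dropped); each admixed haplotype's class scores give posterior source
probabilities φ normalized in log space; per-population means with SEM are
reported and rescaled to sum to one.  Rescaling is applied to the population
means, not per individual, following the stated order of operations.

**Rank test.** Wilcoxon rank-sum on one score axis, exact when the combined
sample size is ≤ 20 and tie-free, otherwise the tie-corrected normal
approximation.

## Tract-length demographic inference

The ancestry process along a present-day chromosome is modeled as a Markov
chain over extended states (ancestry s, arrival time t): a lineage that
entered the admixed population t generations ago has undergone t − 1
meioses, so it recombines at rate t − 1 per Morgan; a recombination that
occurred u generations ago (u uniform over the lineage's meioses) hands the
position to a random chromosome of the generation-u population, whose state
distribution follows from the migration history.  Writing m(t, s) for the
migration matrix (founding proportions at T₁, pulse magnitudes later) and
C(u) = Π_{v<u}(1 − M_v) for the fraction of the present genome surviving
replacement since time u, the stationary state weights are
π_{(s,t)} = m(t, s)·C(t) and the generator has off-diagonal entries
Q_ij = π_j · H(min(tᵢ, tⱼ)) with H(x) = ∫₁ˣ du/C(u).  One can check
πQ = 0 exactly, so the length-weighted ancestry proportions equal the
migration-recursion present-day proportions — an identity the tests assert
to 10⁻⁶.  Times are treated as continuous during optimization (the
piecewise-constant C(u) generalizes directly) and reported rounded to whole
generations.

Tract lengths within an ancestry are then phase-type distributed.  Expected
bin counts integrate the phase-type density over each of 50 equal-width bins
on [0, longest chromosome], handling three censoring cases separately
(tracts starting at a chromosome end, interior tracts, and tracts running
into the far end) plus the whole-chromosome mass π_a·exp(T·L)·1, which fills
the 51st bin.  The integrals are evaluated spectrally (eigendecomposition of
the within-ancestry sub-generator, with a series guard for near-zero
eigenvalues); each chromosome is modeled at its own length and expectations
summed, times the number of haploid genomes.

Observed counts per bin are modeled as independent Poisson draws
(LL = Σ o·ln e − e − ln o!, expected counts floored at 10⁻⁹), maximized by
Nelder–Mead over transformed parameters (log for the founding time,
logistic mappings keeping pulse times inside (1, T₁) and proportions in
(0, 1)) from random restarts; fitting an extended structure can warm-start
from its nested simple fit padded with a near-zero pulse, which preserves
the likelihood ordering of nested models.  Model structures compared are a
two-source founding plus African pulse, optionally with one extra European
or African pulse (k = 4, 6, 6 free parameters); selection is by
BIC = −2 log L + k log n with n the number of Poisson data points —
3 ancestries × 51 bins = 153.  Ties go to the smaller model.

A vectorized Monte Carlo painting sampler simulates the same jump process
directly and serves as the independent oracle: expected histograms agree
with it by χ² (not rejected at α = 0.01) for all three structures, a single
pulse gives log-linear tract abundance (R² > 0.99), and a second
same-ancestry pulse bows the curve (a two-exponential mixture is log-convex,
i.e. steeper at short lengths and flatter in the tail — the fitted quadratic
term in log-counts is positive).

## Cohort statistics

* **X vs autosomes:** Wilcoxon signed-rank on per-female (X − autosome)
  differences for one ancestry; zero differences dropped (count logged);
  exact null for n ≤ 25.  The median difference conveys direction, which the
  two-sided test by itself does not.
* **Assortative mating:** Pearson correlation of maternal vs paternal
  proportions for one ancestry component at a time; the null permutes
  paternal assignments (globally, or within population labels to control
  for stratification), p with the +1 finite-sample correction so it never
  returns 0.  Components are analyzed one at a time even though the three
  proportions sum to one and the tests are therefore not independent.
* **Summed pairwise IBD:** segment lengths ≥ 2 Mb summed per pair,
  normalized by |A|·|B| between groups or C(|A|, 2) within.
* **F_ST:** Nei-style 1 − H_S/H_T on allele frequencies (ratio of
  locus-averaged heterozygosities).  The clustering software whose output
  this mirrors does not print its internal formula; this estimator is the
  standard frequency-based choice and is isolated behind one function.

## Forward simulator

The generator provides the study conditions for every validation:

* Continental founder frequencies are Balding–Nichols draws
  Beta(p(1−F)/F, (1−p)(1−F)/F) around a shared Uniform(0.05, 0.95)
  ancestral vector; the default continental divergence F = 0.15 reflects
  typical inter-continental differentiation at array SNPs, and
  sub-continental panels use F = 0.05 within a continent.
* The admixed population is a diploid Wright–Fisher population of N
  individuals (default 5000 — large enough that drift is secondary at the
  simulated depths while staying tractable); each generation every haplotype
  is a gamete of a random individual with Poisson(length in Morgans)
  crossovers placed uniformly in genetic coordinates (no interference), and
  at pulse times a fraction m of individuals is replaced by unadmixed
  migrants (a replaced individual contributes two unadmixed haplotypes).
  This is a forward simulation, not a coalescent one, because the tract
  model assumes Markov paintings along the chromosome.
* Ground truth is recorded as the exact painting of every sampled
  haplotype; alleles are then drawn Bernoulli(source frequency) per site.
  Sites are therefore in linkage equilibrium within ancestral populations —
  real panels have background LD, which makes real-data windows less
  informative per SNP than simulated ones.  Passing accuracy tests here
  bounds the method's behaviour under its own assumptions; it does not
  certify accuracy on array data with thin reference panels.
* Parent pairs: the first ancestry proportion of each parent is a clipped
  Gaussian pair with the requested Pearson correlation; the remaining mass
  splits between the other two ancestries by a Beta(5, 5) draw.
  X-chromosome proportions are the autosomal vector shifted toward a
  designated ancestry, x = (1−b)a + b·e, and are *generated*, not
  transmitted — X genetics is out of scope.
* One master seed; each component derives child seeds deterministically via
  `numpy.random.SeedSequence`.

## Validation problem sizes

The test suite and the acceptance script run everything at desk scale,
chosen to keep each study's Monte Carlo error well inside its acceptance
margin: cohorts of 12–16 samples on 1.5–5.5 Morgans with 2,000–4,600 SNPs
for painting and ASPCA studies; 400 haploid genomes on the 22 realistic
autosome lengths for demographic fitting (20 replicates for the recovery
study); 2,000–20,000 Markov paintings for the engine χ² checks; 200
replicates for each type-I calibration.  Exact-arithmetic checks (HMM vs
path enumeration, ASPCA vs PCA, BIC arithmetic) are size-independent.

## Known limitations

* The HMM's g is an effective parameter, not an unbiased admixture-time
  estimator; demographic dating should come from the tract-length model.
* The Markov painting assumption ignores pedigree correlations; forward
  simulations show a ~5–8% downward bias in mean tract length relative to
  the closed-form Markov expectation at short depths, within the tolerances
  used here but systematic.
* The centroid-deviation bootstrap is conservative by construction (see
  above).
* ASPCA assumes masking errors are rare; mis-called windows contaminate the
  target-ancestry matrix, which is why very short tracts get a guard class
  in size-stratified analyses.
* Continuous or repeated migration is represented only through discrete
  pulses; fitted pulses should be read as time points that real, more
  continuous flows spanned.
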