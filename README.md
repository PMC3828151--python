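# admixkit

Admixture-deconvolution toolkit for phased SNP data from recently admixed
populations — the analysis stack used to reconstruct post-colonial admixture
histories such as those of Caribbean and mainland Latin American cohorts.

It provides, as a single coherent pipeline:

* **Local ancestry inference** — a PCA-window hidden Markov model: PCA is
  computed in windows of 70 SNPs on pooled reference panels, per-population
  window scores are modeled as bivariate normals, and a hidden Markov chain
  with transition probabilities
  `P(i→j) = e^(−g·d)·δᵢⱼ + (1 − e^(−g·d))·qⱼ` is decoded by the
  forward–backward algorithm (posterior calls at a 0.9 threshold) and by
  Viterbi (for tract-length analyses).  A disjoint-HMM mode deconvolves
  sub-continental ancestry *within* previously called blocks.
* **Ancestry-specific PCA (ASPCA)** — subspace PCA on haplotypes masked to
  one continental ancestry, solved by regularized alternating least squares
  over the observed entries, so phased haploid genomes with large amounts of
  missing data can be projected jointly with reference panels.  Includes the
  centroid-deviation bootstrap test, a rank test along one axis, and
  size-stratified source assignment from bivariate normal cluster fits.
* **Tract-length demographic inference** — ancestry tracts are tallied into
  50 equal length bins per ancestry plus a whole-chromosome bin; a Markov
  chromosome-painting model over (ancestry, arrival time) states yields
  expected counts per bin; bin counts are Poisson, and migration models
  (founding event plus later pulses) are fitted by maximum likelihood and
  compared by BIC = −2 log L + k log n (n = 153 for three ancestries).
* **Cohort statistics** — X-vs-autosome signed-rank test for sex-biased
  gene flow, assortative-mating permutation tests, summed pairwise IBD, and
  allele-frequency F_ST.
* **A forward simulator** — Balding–Nichols founder populations, forward
  Wright–Fisher admixture with Poisson recombination, ground-truth ancestry
  paintings, and parent-pair tables with tunable assortative mating and
  sex bias — so every method can be validated end to end without access to
  controlled genotype data.

## Worked example

Fit the three standard migration histories to tracts sampled under a simple
pulse model (European/Native founding 16 generations ago, African pulse of
20% at generation 10) and select by BIC:

```python
from admixkit import MigrationModel, bin_tract_lengths, bic_select, \
    fit_migration_model
from admixkit.tracts_model import default_chrom_lengths, sample_tracts_mc

chroms = default_chrom_lengths()            # 22 autosomes, Morgans
truth = MigrationModel(16, {"EUR": 0.3, "NAT": 0.7}, [(10, "AFR", 0.2)])
tracts = sample_tracts_mc(truth, chroms, 400, seed=100)
hist = bin_tract_lengths(tracts, chroms, n_haplotypes=400,
                         ancestries=["EUR", "NAT", "AFR"])
print(hist.n_datapoints)
f1 = fit_migration_model(hist, "EUR,NAT+AFR", n_restarts=2, seed=0)
f2 = fit_migration_model(hist, "EUR,NAT+AFR+EUR", n_restarts=1, seed=0,
                         warm_start=f1)
f3 = fit_migration_model(hist, "EUR,NAT+AFR+AFR", n_restarts=1, seed=0,
                         warm_start=f1)
best = bic_select([f1, f2, f3])
print(best.structure, round(f1.model.T1, 2), round(f1.bic, 1))
```

Output:

```
153
EUR,NAT+AFR 16.07 509.2
```

`153` is the number of Poisson data points entering the likelihood (3
ancestries × 51 bins).  The fitted founding time (16.07 generations, truth
16) and the selected structure (the generating simple model) illustrate the
parameter-recovery behaviour quantified in the test suite.  A
fitted time of ~16 generations corresponds to roughly 480 years at 30 years
per generation — the kind of agreement with the 1492 first-contact date that
this style of analysis is designed to probe.

The same pipeline is exposed on the command line:

```bash
admixkit simulate --config model.yaml --out sim
admixkit paint --vcf sim.vcf --refs refs.vcf --ref-labels labels.tsv --out painted
admixkit tracts-fit --bed painted.tracts.bed --out fits.tsv
admixkit stats fst --freqs freqs.tsv
```

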