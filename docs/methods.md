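# Methods

## The problem

When a breeding program genotypes animals on many different SNP chips and
imputes everyone to one fixed marker list (the *imputation set*), any
statistic computed on the imputed genotypes inherits imputation error in
proportion to how little of the imputation set the animal's chip covered.
`inbredkit` studies this for individual inbreeding coefficients: each
synthetic animal gets two coefficient estimates per panel — one from the
panel's genotyped SNP only, one from the full imputation set after masking
and re-imputing the rest — and their agreement (Pearson and Spearman, over
animals) measures the distortion.

Because real reference genotypes are proprietary in this setting, the study
runs on a gene-drop population in which true autozygosity is known exactly,
so "which estimate is right" has a ground-truth answer.

## Estimators

All genomic estimators take the dosage matrix **X** (counted-allele copies,
missing excluded as described) and frequencies estimated from the analysis
cohort itself; frequencies are re-estimated on whichever dataset (panel
subset or imputation set) an estimator runs on.

* **Excess homozygosity `F`** — (O − E)/(N − E) per animal, where O and N are
  the observed homozygous and total non-missing polymorphic SNP counts and
  E = Σ (1 − 2p·q·n̂/(n̂−1)) is the expected homozygous count with the
  small-sample correction n̂/(n̂−1) (n̂ = called samples at the SNP); a flag
  disables the correction.
* **`F_hat1..3`** — the three frequency-weighted moment estimators
  (standardized-dosage variance; per-SNP excess homozygosity; correlation of
  uniting gametes). Sums run over each animal's non-missing SNP with
  0 < p < 1 and n is adjusted per animal. At p = 0.5 for every SNP the three
  coincide with each other and with `F_grm` for *any* genotype vector
  (algebraic identity, verified to 1e-10 in the tests).
* **`F_grm`** — GRM method-1 diagonal minus 1 with observed frequencies:
  diag(ZZ′)/2Σp(1−p) − 1, Z = X − 2p. Missing dosages contribute zero to Z
  while the denominator stays over the full SNP set; monomorphic SNP drop
  out of both.
* **`F_grm2`** — the allele-frequency-free variant: diag(XX′) is regressed
  on F_ped (OLS) and each diagonal element is rescaled as
  (d − intercept)/slope − 1. The rescaled value sits on the usual inbreeding
  scale around F_ped − 1, hence its characteristically negative mean
  (≈ −0.95 when mean F_ped ≈ 0.05). An `offset="intercept"` variant
  subtracts the regression intercept instead; the two differ by an additive
  constant only, so every correlation downstream is identical.
* **`F_roh`** — consecutive-runs ROH detection followed by the covered
  genome fraction. The scanner emits every *maximal* window of consecutive
  SNP whose heterozygote count (≤1), missing count (≤1) and adjacent-marker
  gaps (≤1 Mbp) stay within bounds, then keeps windows with ≥15 SNP spanning
  ≥1 Mbp. Maximal windows can overlap when an allowed heterozygote splits a
  long homozygous stretch, so F_roh uses the per-animal interval *union*
  over segments, divided by the SNP-covered genome length (first-to-last SNP
  per chromosome). Both choices keep F_roh in [0, 1] by construction and
  make it computable from the data at hand without an assembly length.
  Of the five scan parameters only three are commonly fixed in the
  literature; the missing-call allowance (1) and maximum gap (1 Mbp) are
  package defaults and all five are configurable.

`F_ped` uses the Meuwissen–Luo ancestor-trace algorithm (linear memory,
suitable for national-scale pedigrees); the tabular relationship matrix
serves as the independent oracle in the tests. `max_depth` (default 10)
truncates each animal's pedigree at that many ancestral generations: when
the pedigree is shallower than the horizon a single exact global pass is
used, otherwise each animal's truncated subpedigree (ancestors at minimum
path depth ≤ depth, links beyond cut) is solved exactly. Unknown parents
contribute zero relationship, so founders have F = 0. The completeness
index is MacCluer-style: per parental line C = (1/d) Σᵢ kᵢ/2ⁱ over
generations i = 1..d (kᵢ = known ancestor slots), combined as
4·C_s·C_d/(C_s + C_d), zero if either line is empty.

## Quality control

Five per-SNP rules, each evaluated on the input dataset (order-free), all
with strict inequalities: call rate < 0.95, parent–offspring mismatch
(opposing homozygotes among genotyped pairs) > 0.01, MAF < 0.02, any
genotype-class frequency among called genotypes < 0.001, and exact
two-sided Hardy–Weinberg p < 0.005. The HWE test is the conditional exact
test (all heterozygote counts no more probable than observed, allele counts
fixed), evaluated stably through log-gamma; a chi-square alternative was
deliberately not used because the synthetic toys exercise very small
counts. SNP whose Mendel rate has no informative pair pass that rule. The
"genotype frequency" rule reads the threshold as the minimum class
frequency among called genotypes (parallel to the MAF rule); this is a
documented interpretation choice.

## Imputation emulator

The imputation stage is a deliberately simple, seeded stand-in for a
production pedigree-based imputer, not a reimplementation of one: (1)
missing cells whose parental transmissions are Mendelian-certain are forced;
(2) cells with at least one parental genotype take the most probable
genotype given parental transmission probabilities and the population
frequency (ties toward the lower dosage); (3) cells with no parental
information are drawn from Hardy–Weinberg proportions at the reference
frequencies with a seeded generator. Observed genotypes always pass through
bit-identical. The emulator's only promises are reproducibility and an
error rate that rises as the genotyped fraction falls — which is all the
concordance study needs. Rule-3 fills match HWE proportions statistically,
and accuracy strictly improves when parents are genotyped (both are tested).

## Synthetic population

Defaults (all configurable): 200 founders plus 6 discrete generations of
200 offspring; 5 sires per generation (a dairy-AI-like bottleneck that
accumulates mean F_ped ≈ 0.05 by the last generation); 5 chromosomes of
100 Mbp with 2,000 SNP each at uniform random positions; founder frequencies
uniform on [0.05, 0.95]; recombination with Poisson crossover counts at
1 cM/Mb (Haldane, no interference). Founder haplotypes carry distinct
origin labels that recombine alongside the alleles, so each animal's true
autozygosity — the genome fraction where its two haplotypes descend from
the same founder haplotype — is computed exactly from segment
intersections, not estimated. Across seeded replicates the population mean
of true autozygosity matches mean F_ped within Monte-Carlo error (tested at
3 standard errors over 30 replicates).

Panels are uniform random SNP subsets at overlap fractions 0.9462, 0.9128,
0.4763, 0.3237, 0.1997 and 0.1642 — the documented coverage of two
high-density and four medium-density commercial bovine chips relative to an
84,445-SNP imputation set. Real chips have structured, non-uniform spacing
("mixtures of distributions"); only the overlap fraction and density are
modelled, which is the acknowledged fidelity limit of the generator.
The desk-scale defaults keep a full six-panel study around half a minute.

## Numerical and reproducibility choices

* Estimator sums are computed by a fixed-order reduction kernel (per-dosage
  term tables), making results bit-reproducible regardless of array layout —
  identical inputs give correlations of exactly 1, which the identity-panel
  invariant relies on. BLAS reductions were rejected because their
  summation order depends on memory alignment.
* Correlations are pairwise-complete over animals; zero-variance or
  <2-point cells are reported as missing (NaN), never as zero.
* All study randomness flows from one root seed, split per stage
  (pedigree, panels, per-panel imputation), so reruns are byte-identical.
* Degenerate inputs raise informative errors: empty panel intersections,
  all-monomorphic GRM denominators, zero-slope F_grm2 regressions,
  unsorted maps for ROH scanning, pedigree cycles (named individual).

## Known limitations

* `F_hat1` is unstable in drifted cohorts: homozygotes for rare alleles
  contribute terms of order 1/2pq, and its correlation with true
  autozygosity can be negative at desk scale. This mirrors its documented
  erratic behaviour on real cattle data and is why multi-estimator studies
  summarize over estimators.
* The two highest-overlap panels (94.6% and 91.3%) produce concordances
  that differ by ~3×10⁻⁴ at 10k SNP — below the study's Monte-Carlo noise —
  so their relative ordering is not reproducible replicate-by-replicate at
  desk scale, although the high-vs-medium-density ordering always is.
* The imputation emulator does no phasing or LD modelling; absolute
  accuracy values are not transferable to production imputers, only the
  qualitative dependence on panel overlap and parental genotyping.
* X-chromosome handling and sample-level QC are out of scope.
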