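# Methods

`troutsim` simulates a closed sib-testing breeding program for rainbow trout
in which the breeding goal is performance in a commercial grow-out
environment (C) while selection candidates are kept and phenotyped in the
breeding/nucleus environment (B).  Genotype-by-environment interaction makes
the B- and C-measured trait two distinct, genetically correlated traits; the
genetic correlation `r_g` is the single G×E parameter.  The package exists to
study how phenotype-based *selective genotyping* — spending a fixed
genotyping budget on phenotypically extreme fish — changes genetic gain,
inbreeding, prediction accuracy, dispersion bias and variance-component
estimates in this design.

## Genome and trait model

The synthetic founder genome replaces an unavailable real genotype panel.
Loci are biallelic, laid out on equal-length chromosomes (default 29
chromosomes, 2927.1 cM, 36,451 loci at full scale) with near-equal locus
counts per chromosome and uniform positions; the real marker layout is not
published, so a uniform layout is the neutral choice.  Founder haplotypes
start in linkage equilibrium with allele frequencies uniform on
[`maf_low`, `maf_high`] (default 0.05–0.5) and are passed through
`n_mixing_generations` (default 10) of random mating, which builds realistic
within-chromosome LD while keeping the generator fully seedable.  Loci lost
to drift during mixing are re-seeded from their initial frequency so every
locus segregates; this touches a small fraction of loci and only their local
LD.

Meiosis follows the Haldane model (no crossover interference).  It is
implemented in interval form — independent phase switches between adjacent
loci with probability `(1 − e^(−2d/100))/2` for spacing `d` cM, and a fresh
random phase at each chromosome start — which has exactly the same joint
distribution over transmitted alleles as Poisson crossover counts with
uniform positions, and vectorizes over whole cohorts.  There is no mutation:
over seven generations its contribution would be negligible.

A random subset of loci (default 3,742 of 36,451) act as QTL controlling
both traits; the rest are the markers used for prediction.  Per-QTL effect
pairs are bivariate normal with correlation `r_g` and are rescaled so each
trait's founder genetic variance is exactly 1 (the realized founder TBV
correlation then matches `r_g` up to QTL sampling noise).  Phenotypes are
`TBV(own environment) + N(0, σ²_e)` with `σ²_e = (1 − h²)/h²`, i.e.
phenotypic variance 1/h² on the founder scale.  Simulated year effects are
zero, but the evaluation model always fits year-within-environment means, as
a field analysis would.

## Breeding cycle

Each year (full scale): 50 three-year-old sires and 50 dams — drawn from a
pool of 400 selected females aged 3 or 4 — are mated in a random degree-2
partly factorial design (every sire to two distinct dams and vice versa),
giving 100 full-sib families of 200 and 20,000 offspring.  A fixed share
(`prop_genotyping_C`, default 20%) of offspring goes to C; the genotyping
budget (1,000/year) is split in the same proportion.  Offspring born in year
t are phenotyped, genotyped and selected in year t+3; years 1–3 use parents
drawn at random from the founder base.  Runs last 21 years (seven
overlapping generations).

Genotyping strategies screen disjoint random groups of 20 fish, each fish
getting exactly one chance: `Random` (uniform), `Top1_1` (best of each
group), `T1_1B1_1` (best and worst of each group), `T1_2B1_2` (best/worst per
group, then best of each random pair of tops and worst of each pair of
bottoms) and `T3_4B1_4` (best three of each four tops, worst one of each four
bottoms; B only).  The budgets and cohort sizes are chosen so the groups
exactly tile the cohort (1-in-20 screening).  Group leftovers smaller than a
group are unscreened; infeasible budget/cohort combinations are rejected
rather than silently degraded.  Phenotype ties break toward the lower id for
determinism.

Sires are the top genotyped 3-year-old B males ranked on the C-trait GEBV
when C records exist (breeding-goal weight 1 on C, 0 on B), otherwise on the
B-trait GEBV.  Females are selected phenotypically (best of each group of 20
among B females) unless `genotype_females` is set, in which case selection
and retention use GEBV.  Under 100% retention, 200 new 3-year-olds are
selected and all are kept a second year (pool 400); under 11% retention, 360
are selected and 40 retained.  Dams are 50 uniform draws from the pool.
Retained 4-year-olds are dropped after their second season.

Sex handling: with sex-reversal technology the offspring sex ratio is free,
so `male_fraction_B` is a configuration lever.  Genotype screening in B is
sex-blind (the published group counts tile the whole cohort), and the
default "auto" rule makes the B cohort exactly `20 × n_new_females` female —
enough to fill the phenotypic female-selection groups — and the remainder
male, which maximizes the number of genotyped male candidates.  This stands
in for a supplementary sex-ratio optimization whose per-scenario values are
not recoverable; `optimize_sex_ratio` offers a brute-force pilot-run grid
search instead.

## Genomic evaluation

The genomic relationship matrix is VanRaden method 1,
`G = WW′ / 2Σp(1−p)`, with genotypes centered at founder-generation allele
frequencies (fixed frequency base, stable across years).

GEBV solve a bivariate GBLUP with `Var(g) = Σ_g ⊗ G`, heterogeneous
diagonal residuals by environment, and fixed year-within-environment
classes; scenarios with no C records use the univariate special case.  Only
genotyped fish carry records (the design assumes unregistered field
pedigrees), every genotyped fish from all years accumulates into each
evaluation, and the in-loop evaluation uses the *true* variance components,
isolating selective-genotyping effects from estimation error.  Because each
genotyped fish has exactly one record, the mixed-model equations are solved
in their exact record-space form
(`V = Σ_g[env,env] ∘ G + R`, GLS for the year effects,
`ĝ = Cov(g, y) V⁻¹ (y − Xb̂)`), which needs no inverse of G; the general
mixed-model-equation path (with Cholesky inversion of G, ridge-stabilized
by the smallest of {1e-8, 1e-6, 1e-4, 1e-2}·mean(diag) only when singular
and reported when applied) is kept for arbitrary record structures, and the
two are cross-checked in the tests along with a direct inverse-of-V oracle
(agreement to 1e-8 on small instances).

Variance components are estimated (as a side-channel snapshot, by default at
year 10) by average-information REML on the same model, with exact analytic
scores.  The record-space iteration works on the explicit projection matrix
with Levenberg-damped AI updates; the MME iteration uses AI with
likelihood-guarded step halving and EM-REML fallback steps (with optional
step-lengthening), the EM step expressed through the gradient identity
`Σ_new = Σ + (2/n) Σ D Σ`.  Proposals outside the parameter space are
projected back onto the positive-definite cone, so the search can move
along the `|r_g| = 1` or zero-variance boundaries, and every accepted step
increases the restricted likelihood.  Convergence is declared at relative
parameter change < 1e-6 or when the likelihood stalls; the scenario runner
caps snapshot REML at 50 iterations — enough for the typical 6–10 AI
iterations, while truncating slow boundary crawls whose remaining parameter
movement is in the third decimal — and flags capped replicates as
non-converged.

## Outcome measures

* **Rate of gain** ΔG: mean C-trait TBV of all fish born per year;
  `ΔG = [(G19+G20+G21) − (G5+G6+G7)] / 42` at full horizon, with both
  windows configurable for shortened runs.
* **Inbreeding** F_t: exact Wright coefficients.  Inside the simulator each
  cohort's mean F is the mean coancestry of its mating pairs, tracked by a
  rolling kinship matrix over founders and selected parents (equal family
  sizes make this exact); the public `pedigree_inbreeding` recurses over an
  arbitrary sorted pedigree and agrees with a path-counting oracle.
  `ΔF(%) = (1 − e^β)·100` with β the slope of `ln(1 − F_t)` on `t/3` over
  years 5–21; the fixed 3-year generation interval is the candidate age (the
  small 4-year-old dam fraction perturbs the true interval negligibly, and a
  fixed interval keeps the rate comparable across scenarios).
* **Accuracy and bias**: per evaluation year (default 10–12), the Pearson
  correlation and the TBV-on-GEBV regression slope over the 3-year-old
  genotyped B fish, averaged over the three years; slope < 1 means inflated
  (over-dispersed) GEBV.  In no-C scenarios the B-trait GEBV is used against
  the C-trait TBV, with analytic expectations `r_g` (accuracy/bias with
  equal variances; in general `r_g·sqrt(σ²_gC/σ²_gB)` for the slope).
* Replicates are aggregated as mean ± SE (sample SD/√R).

## Scale profiles

* `full_scale()` — the published scheme (20,000 offspring, 1,000 genotyped,
  32,709 markers).  Correct but hours per replicate; not used by the tests.
* `desk()` — 2,000 offspring and 100 genotyped per year (80 B / 20 C at the
  default allocation), 10 sires, 10 dams, 80-female pool, 20 families of
  100, ~3,000 markers + 400 QTL on the same 29-chromosome map, 200 founders,
  21 years.  Every structural ratio that drives the selective-genotyping
  distortions is preserved: groups of 20, budget = cohort/20, degree-2
  factorial mating, 3-year lag, dams = pool/8.  The acceptance checks run
  this profile for 20 replicates; bias targets run to year 12 (the
  evaluation window) and REML targets to year 10.
* `micro()` — 200 offspring/year with groups of 5, for tests and examples.

What the desk profile does *not* preserve: absolute reference-population
size (hundreds instead of thousands of records), the sire-selection
intensity (10 of ~40 genotyped males instead of 50 of ~600), and drift
magnitude.  Quantities driven by the screening structure (dispersion bias
under selective C genotyping, the direction and rough size of REML
distortions) transfer well; quantities sensitive to absolute reference size
transfer only approximately.  In particular, the heritability collapse under
`Top1_1` B genotyping is *stronger* at desk scale (ĥ²_B ≈ 0.09 vs 0.157
published at full scale): with a tenfold smaller genotyped sample the
within-group truncation leaves even less usable genetic contrast.  Passing
desk-scale checks therefore demonstrates mechanism fidelity, not full-scale
numerical equality.

## Reproducibility

All randomness flows from one seed through named `SeedSequence` substreams
(map, founders, architecture, phenotypes, genotyping, mating, selection), so
scenarios sharing a replicate index share founder genomes.  Per-replicate
seeds are derived from the master seed, a CRC-32 hash of the configuration
and the replicate index: adding scenarios never perturbs existing ones, and
identical manifests give bit-identical outputs.

## Known limitations

No mortality, mutation, variable family sizes, non-additive genetic effects,
multi-trait economic indices, single-step (pedigree + genomic) evaluation,
or genome-based inbreeding.  The 11%-retention factor level can be
infeasible at reduced scale (the 0.9·pool female selection outgrows the
female cohort); such cells are rejected at validation rather than run
degraded.
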