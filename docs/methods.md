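# Methods

## Statistical model

Association testing uses the linear mixed model

    y = 1μ + xb + Zu + e,   u ~ N(0, G σ²_u),   e ~ N(0, I σ²_e)

where `y` is the ordinal gill score treated as a continuous response
(exactly as the linear mixed models used on such scores do), `x` the SNP
dosage coded 0/1/2 copies of the effect allele, and `G` the VanRaden
method-1 genomic relationship matrix built from pooled-frequency-centred
genotypes, `G = WW′ / 2Σpₖ(1−pₖ)`.

Variance components are estimated once per scan by REML under the null
(no candidate SNP). Working in the eigenbasis of `G + 10⁻⁶ I` (the
diagonal jitter guarantees a well-conditioned factorisation) turns
`V = σ²_u G + σ²_e I` into a diagonal matrix, so the restricted likelihood
is profiled down to a 1-D bounded search in log(σ²_u/σ²_e); the boundary
σ²_u = 0 is compared explicitly. The per-SNP scan is then generalized
least squares with `V` held fixed at the null estimates (the standard MLMA
convention; the candidate's chromosome is *not* excluded from the GRM, so
mild deflation from proximal contamination is expected and observed,
λ ≈ 0.96–0.98 on the preset). Standard errors include the null-model
residual scale `σ̂² = r′V⁻¹r/(n−p)`, which is ≈1 at the REML optimum and
makes (b, SE) invariant to rescaling `V` by a constant. Wald p-values use
(b/SE)² ~ χ²(1).

The mega-analysis is the same scan on the pooled panel with population
indicator covariates. Conditional association analysis re-estimates the
variance components each round with the accumulated lead-SNP covariates,
and records the span of each round's significant SNPs (on the lead's
chromosome) as that round's QTL region; both per-round regions and their
union are reported, since the interval arithmetic for multi-round cases is
genuinely ambiguous and single-signal datasets never exercise it.
Lead-SNP ties break deterministically: smallest p, then largest |b|, then
lowest (chromosome, bp).

## Meta-analysis

Per-population tables are harmonized to a common effect allele (effects,
z-scores and frequencies flipped where A1/A2 are swapped; irreconcilable
allele pairs dropped and counted). Estimators, per SNP over the N
contributing populations:

* Stouffer Z: `Zᵢⱼ = Φ⁻¹(1−pᵢⱼ/2)·sign(bᵢⱼ)`, combined with √n weights;
  p-values of exactly 0 are clamped to the smallest positive double and
  logged.
* IVW: inverse-squared-SE weights; Cochran's Q with a significance flag at
  α = 0.10 on χ²(N−1); `I² = (Q−(N−1))/Q × 100` truncated to [0, 100] and
  defined as 0 for Q = 0 or N = 1, with the 25/50/75 heterogeneity bands.
* Random effects: DerSimonian–Laird
  `τ² = max(0, (Q−(N−1)) / (Σw − Σw²/Σw))` and the decomposed statistic
  `S_rand = S_FE + S_Het`; `S_FE` coincides with the IVW χ² identically.
  The p-value uses the boundary-LRT asymptotic null, an equal mixture of
  χ²(1) and χ²(2): the between-study variance is on the boundary of its
  parameter space under H₀, so the usual χ²(2) reference would be
  conservative. A seeded Monte-Carlo null sampler (`meta.mc_rand_null`) is
  provided for small-N empirical calibration; the tabulated small-sample
  corrections some meta-analysis software ships are not reproduced.
* `z_to_beta_se` converts z-scores to effect/SE via
  `b = z/√(2p(1−p)(n+z²))`, preserving b/SE = z exactly, so Z-score meta
  output can feed the summary-statistic signal methods.

λ is median observed χ² over the χ²(1) median (0.4549, reported as 0.455);
the decomposed convention for the random-effects scan sums the λ of the
S_FE and S_Het statistic vectors. λ > 1.1 (strict) flags confounding.

## Secondary signals

COJO reconstructs least-squares normal equations from summary statistics:
`D_k = n_k·var(x_k)` from the reference panel forms the diagonal of X′X,
off-diagonals are `r_kl √(D_k D_l)` with r from reference-panel dosage
correlations, zeroed beyond the 100 Mb window or across chromosomes;
`X′y_k = D_k b_k`; `y′y` is the median over SNPs of
`D_k b_k² + D_k SE_k²(n_k−1)`. Stepwise selection seeds with the lead SNP,
adds the best conditional candidate below the threshold unless its r² with
any selected SNP reaches the collinearity bound (0.05 — strict, because
long-range LD in small-Nₑ breeding populations biases conditional
estimates; such candidates get conditional p = 1), drops non-significant
members after each joint fit, and iterates to a fixed point. Clumping is
the greedy PLINK rule (p ≤ p1, r² ≥ 0.05 to the lead, ≤ 5 Mb, boundary
inclusive); r² is the squared Pearson correlation of dosages, pooled raw
genotypes serving as the reference for multi-population runs.

## QC

Filter order: SNP call rate ≥ 0.95 → sample call rate ≥ 0.95 → sample
heterozygosity within [0.25, 0.45] (computed on raw pre-imputation calls)
→ MAF ≥ 0.01 → exact HWE test p ≥ 1e-25. The HWE threshold is written
"10e−25" in some protocols, which literally reads 1e−24; we take the
scientific-notation-typo reading 1e−25 (configurable — the threshold is far
from any decision boundary either way). The exact test enumerates all
heterozygote counts of the observed parity and sums the probabilities of
configurations no more probable than the observed one. HWE runs within
population by default, removing a SNP that fails in any population;
a pooled mode is available because protocols rarely state which was used.
Sporadic missing genotypes are then imputed to the within-population modal
genotype (ties toward the major-allele genotype) — a simple deterministic
stand-in for unspecified production imputers.

The working significance threshold at FDR < 0.05 is the largest
BH-significant p-value (the rejection set is identical to BH step-up with
the strict `P_i < qk/m` rule); `fdr_at_threshold` additionally reports the
classical `m·P/#{p ≤ P}` FDR estimate of any working threshold.

## The synthetic-data generator

The generator emulates four related salmon breeding populations of sizes
2006/640/2911/2949 (scalable by `--scale`):

* **Drift**: per-population allele frequencies follow Balding–Nichols Beta
  distributions (Fst = 0.03) around ancestral frequencies uniform on
  [0.05, 0.95].
* **Relatedness, admixture and LD phase**: each population owns a pool of
  12 founder haplotypes; founder genomes copy 500 kb blocks from pools
  chosen by the admixture matrix (rows ≈ 0.55 self, remainder spread over
  the other populations). Small pools create within-population LD and
  haplotype sharing; cross-pool copying creates cryptic relatedness across
  populations and population-specific LD phase — the three ingredients that
  inflate summary-statistic combination.
* **Families**: full-sib families (pop size/10 families; parents are
  disjoint founder pairs) with offspring produced by meiosis at one
  crossover per chromosome per meiosis on average, uniform positions.
* **Phenotype**: liability = population shift + QTL dosage effects +
  polygenic term + Gaussian noise. The polygenic term spreads heritability
  h² = 0.40 over 600 causal markers (a causal subset keeps the per-locus
  signal independent of panel density); the non-QTL liability variance is 1
  by construction. Genetic terms are centred within population so that the
  severity differences between populations are governed solely by the
  configured shifts (0.62/0.30/0/0) — every association model fits a
  population intercept, so this affects no test statistic. Thresholds
  (−0.7, 0.15, 0.45, 2.15, 2.45) were chosen by matching
  Gaussian-liability category moments so per-population score means (~2.25,
  1.9, 1.57, 1.57) and SDs (~1.2–1.3) sit inside the observed-data range.
  The default preset plants one QTL (allele-substitution effect 0.55 on
  the liability scale) on the middle marker of chromosome 5.
* **Missingness**: uniform 1% sporadic missingness so QC has work to do.

Everything derives from one integer seed and is bit-reproducible.

What the generator does **not** emulate: coalescent-grade haplotype
structure, recombination hotspots or interference, genotyping error beyond
uniform missingness, selection, sex chromosomes, and non-additive gene
action. Passing tests therefore show that the analysis machinery behaves
correctly under the stated population-genetic structure — not that any
particular real dataset would produce the same numbers.

## Problem sizes and expected magnitudes

Validation runs use scale 0.14 (~1,190 samples across the four
populations) with 5,000 markers on 10 chromosomes, 20 replicate seeds for
the inflation contrast and the method-ordering checks, 10 seeds for
QTL-recovery, and 20 trait draws for REML recovery. At this scale the
inflation contrast is directional rather than full-magnitude: λ − 1 grows
roughly with sample size, so the pooled analysis sits at λ ≈ 0.96–0.98
while the meta-analyses exceed it by ~0.03–0.08 on average (at the
original cohort sizes the same mechanism produces substantially larger
inflation). A planted QTL can drift to near-fixation in a replicate and
legitimately become undetectable; such replicates report zero signals for
all methods.

## Known limitations

* The ordinal score is analysed as a linear trait; no threshold/ordinal
  mixed model is provided.
* COJO uses per-SNP effective n and a median-based y′y estimate; with
  heterogeneous per-SNP sample sizes the joint SEs are approximate.
* GRMs are dense; memory is O(n²) (fine for ~10⁴ samples).
* No LOCO scans, dominance GRMs, sample-overlap correction, or LD-score
  regression.
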