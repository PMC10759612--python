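# Methods

`larchgp` dissects additive and non-additive genetic variation in
open-pollinated (OP) forest-tree progeny trials and compares genomic
prediction strategies.  Because the motivating kind of dataset (single-site
OP progeny trial with GBS SNPs) is rarely public, the package ships a
synthetic-trial generator whose output has exactly the statistical
structure the estimation machinery assumes; every claim the test suite
makes is therefore a claim about this synthetic world, a point discussed
at the end of this note.

## The model

For a single trait measured on n trees,

    y = X beta + Z_p p + Z_a a + Z_d d + Z_i i + Z_e e + eps

where `beta` holds a grand mean and fixed block effects of the randomized
complete block design; `p ~ N(0, I sigma2_p)` are random row-plot effects;
`a, d, i, e` are additive, dominance, imprinting (parent-of-origin) and
additive-by-additive epistatic genetic values with covariances
`sigma2_a K_a`, `sigma2_d K_d`, `sigma2_i K_i`, `sigma2_e K_e`; and
`eps ~ N(0, I sigma2_eps)`.  The model families differ only in which terms
are present and which covariance stands behind each:

| family       | terms          | covariances                              |
|--------------|----------------|------------------------------------------|
| ABLUP-OP     | plot, a        | pedigree A (maternity only)              |
| ABLUP-FS-A   | plot, a        | pedigree A (reconstructed full-sib view) |
| ABLUP-FS-AD  | plot, a, d     | pedigree A and D                         |
| GBLUP-A      | plot, a        | genomic G_A                              |
| GBLUP-AD     | plot, a, d     | G_A, G_D                                 |
| GBLUP-ADI    | plot, a, d, i  | G_A, G_D, G_I                            |
| GBLUP-ADIE   | plot, a, d, i, e | G_A, G_D, G_I, G_AA                    |
| RKHS         | any subset     | Gaussian kernels K = exp(-h d^2)         |

### Relationship matrices

Pedigree A is the numerator relationship matrix by the tabular method
(unknown parents contribute zero, so the OP view yields maternal half-sib
coefficients of 1/4); pedigree D uses
`D_ij = (A_{s(i)s(j)}A_{d(i)d(j)} + A_{s(i)d(j)}A_{d(i)s(j)})/4`.

Genomic matrices are built from marker codings with `p_j` the observed
minor-allele frequency (loci are re-oriented so the counted allele is
minor):

* additive: `M_A = dosage - 2 p_j`, `G_A = M_A M_A' / (2 Σ p_j(1-p_j))`
  (VanRaden scaling, mean diagonal ≈ 1 under HWE);
* dominance: `M_D ∈ {-2p², 2pq, -2q²}`, denominator `Σ (2pq)²`;
* imprinting: `M_I ∈ {0, +1, -1, 0}` for maternal-first ordered genotypes
  A1A1 / A1A2 / A2A1 / A2A2, same denominator as dominance;
* epistasis: `G_AA = G_A ∘ G_A` (Hadamard square; PSD by the Schur product
  theorem).

Two numerical facts about these definitions matter in practice.  First,
`G_I`'s numerator is a heterozygote count, so its mean diagonal is
`Σ 2pq / Σ (2pq)²` ≈ 2–3 rather than 1: a raw `sigma2_i` therefore
understates the realized imprinting variance by that factor, and raw
variance-share tables inherit the distortion.  Second, any matrix whose
smallest eigenvalue falls below 1e-10 is bent by adding a ridge of
1e-8 × (mean diagonal), doubled until PSD, before entering a fit.

Parental origin of heterozygotes is taken from the generator when
simulated, or deduced where the dam is genotyped homozygous
(`resolve_phase`); unresolved heterozygotes contribute 0 to `M_I` and are
counted in a phasing-rate report rather than dropping the tree.

### REML

Variance components maximize the restricted likelihood.  With
`V = Σ_k θ_k C_k` (`C_k = Z_k K_k Z_k'`, identity for the residual) the
average-information algorithm iterates

    score_k = -(1/2)[tr(P C_k) - y'P C_k P y]
    AI_kl   =  (1/2) y'P C_k P C_l P y
    θ  <-  θ + AI^{-1} score,

with step-halving whenever a step would not increase the likelihood, one
EM warm-up iteration, and an EM fallback when the AI step fails; the exact
EM update divides by the per-term level count `q_k`, which makes it
provably monotone.  All components are constrained above a floor of
1e-6 × var(y); a component held at the floor still counts in the parameter
count ρ (pre-specified model forms are compared as such, never silently
reduced).  Convergence is declared when the largest relative parameter
change drops below the tolerance (default 1e-8) or, for AI-driven fits,
when the likelihood change falls below 1e-9 — the latter is needed because
a component bouncing within rounding error of the floor never satisfies a
pure parameter-change criterion.  Pure-EM fits additionally test the
constrained boundary directly every 10 iterations (EM approaches a zero
variance only at rate O(1/t)) and jump there when it does not lower the
likelihood.  The asymptotic covariance of the components is the inverse
AI matrix at convergence.

`AIC = -2 logL + 2ρ` with ρ the number of (co)variance parameters (fixed
effects are absorbed by REML; a switch includes them).  `BIC` defaults to
the standard `-2 logL + log(n) ρ`; the variant `bic_variant="paper"`
doubles the penalty (`2 log(n) ρ`), reproducing a formula that sometimes
appears in print — it is exposed, not silently corrected.  Models within
ΔAIC ≤ 2 are reported as tied.

Heritabilities are `h² = σ²_a/σ²_P` and `H² = σ²_g/σ²_P`, with `σ²_g` the
sum of exactly the genetic components in the fitted model and `σ²_P` the
sum of all components; standard errors come from the delta method on the
inverse-AI covariance.

### RKHS regression

Kernels are `K_xy = exp(-h d²_xy)` with `d²` the squared Euclidean
distance between marker-coding rows normalized by its own off-diagonal
mean (so a constant marker rescaling cancels and one bandwidth grid fits
any panel).  Defaults: the additive kernel is built on `M_A` rows, the
dominance/imprinting kernels on `M_D`/`M_I` rows, and the epistatic kernel
is the Hadamard square of the additive kernel; multi-kernel averaging over
h ∈ {0.25, 1, 5} fits one variance component per bandwidth, and a single-h
mode is available.  The bandwidth set, the distance definition, and the
priors are this package's choices — the approach they follow leaves all
three to the analyst.

Inference is a blocked Gibbs sampler.  Each kernel term is
reparameterized through its eigendecomposition `K = U Λ U'` as
`u = U Λ^{1/2} α`, making the conditional posterior of α coordinatewise
independent; grouped i.i.d. terms (plot) use their incidence matrix
directly, whose crossproduct is diagonal.  Fixed effects get a flat prior;
variances get scaled-inverse-χ² priors with 5 degrees of freedom and
scales set so the prior mode splits var(y) equally across terms — a
weakly-informative default that keeps draws proper on small folds.  The
reference chain is 20,000 iterations, 2,000 burn-in, thinning 100 (180
retained draws); the configuration object refuses settings that retain
fewer than 50 draws.  Cross-validation fits use 3,000/500/10 (250 retained
draws): chain-length experiments showed fold-level predictive abilities
identical to 12,000-iteration chains, and the shorter chain keeps a
10-fold × 10-replicate comparison affordable.  Validation trees receive
kriging predictions `u_new = K_{new,train} K_train^{-1} ū` through the
truncated eigenbasis.

### Cross-validated predictive ability

Folds are seeded simple-random partitions (10-fold × 10 replicates by
default; family-stratified folding is available since OP families create
relatedness leakage between training and validation).  The evaluation
target is the phenotype adjusted for block effects by OLS on all
phenotyped trees — the adjustment defines the target, not a training-set
quantity, though a per-fold variant exists.  The benchmark GBLUP-A is
scored on additive BLUPs; "optimal" models (GS-GBLUP, GS-RKHS) keep the
genetic terms whose variance share reaches 5% in the full genomic fit
(additive always retained; an AIC-based selector is the alternative) and
are scored on total genetic value.  Predictive ability is the Pearson
correlation over validation trees; folds with fewer than 3 scored trees or
zero variance are excluded and logged, as are folds whose fit does not
converge.  Model pairs are compared by a paired two-sided t-test on
fold-level scores matched by (replicate, fold), with a Wilcoxon
signed-rank companion and 0.05/0.01 significance stars; per-replicate
summaries are also reported.

## The synthetic trial

The generator emulates a single-site OP progeny trial: 66 maternal parents
each found a family of 9–12 trees (~661 total), pollinated uniformly at
random from a pool of 97 fathers (panmixia; no external pollen).  Founder
allele frequencies are uniform on [0.05, 0.5] at 11,333 independent
biallelic loci; genotypes are in Hardy–Weinberg proportions, and progeny
are Mendelian gametes with the maternal allele recorded first, so parental
origin is known exactly.  Trees are laid out in 5 complete blocks with
contiguous single-family row plots of up to 5 trees on a 2 × 2 m grid.
Genotype calls are masked completely at random at rate 0.177, and loci
falling below a 40% call rate are flagged for the filter.

Phenotypes are the sum of fixed block draws (SD 0.5), i.i.d. plot and
residual effects, and genetic values drawn as zero-mean multivariate
normals whose covariances are the *realized* relationship matrices of the
simulated genotypes, each standardized to unit mean diagonal so that a
nominal variance share is also the realized per-individual variance.  The
default shares (additive 0.25, dominance 0.05, imprinting 0.05, epistasis
0.15, plot 0.05, residual 0.45) describe a moderately heritable growth
trait with a visible epistatic component.  Because estimation uses the same
matrices, the fitted model is correctly specified and parameter recovery
is a clean test of the estimator.  A second generator mode
(`effect_model="marker_effects"`) instead builds genetic values from
explicit per-marker effects — additive/dominance/imprinting codings times
normal coefficients, and epistasis from 250 random locus-pair products —
for studies where the genetic signal must be a real function of the
genotypes rather than a draw.

## What the synthetic world can and cannot show

Two findings from this package's own validation runs deserve emphasis,
because they bound what a pass or a fail on synthetic data means for real
trials.

**Non-additive variance components are weakly identified at n ≈ 400.**
With independent loci and OP family structure, `G_AA = G_A ∘ G_A` is
almost the identity matrix: additive off-diagonals concentrate near their
pedigree expectations (SD ≈ 0.055 at 2,000 loci), so their squares are
≈ 0.06 for half sibs and ≈ 0 elsewhere.  The profile likelihood along the
σ²_e ↔ σ²_eps direction is then nearly flat — in epistasis-dominated
simulations the restricted likelihood at the truth sits within ~2 units of
a boundary optimum with σ²_e = 0, even when the optimizer is started at
the truth.  Under the architecture-matched model the additive, dominance and
plot shares recover with |bias| ≲ 0.05 averaged over replicates, but the
epistatic share is truncated at zero in a visible fraction of replicates
(the restricted likelihood itself peaks at the boundary there), giving a
downward bias of ≈ 0.1 at a true share of 0.6; single-replicate estimates
scatter widely (SD ≈ 0.3), and a simple additive- vs epistasis-dominated
classification from one trial plateaus around 50–80% accuracy depending
on architecture.  This is an information
limit of the design (no linkage disequilibrium, ~10-tree half-sib
families), not an estimator defect; real data with LD and deeper
relatedness can be more — or differently — informative.

**RKHS and GBLUP-A are nearly equivalent predictors here.**  Under the
Gaussian-process generator the epistatic deviations of validation trees
are, by construction, unpredictable beyond their (tiny) `G_AA` covariance
with training trees, so kernel regression has nothing extra to find; the
cross-validation pattern checks therefore use the marker-effect generator,
where a real epistatic signal exists in the genotypes.  Even there, with
2,000 independent markers and n = 400 the Gaussian kernel captures only a
sliver of it: across simulated trials GS-RKHS edges GBLUP-A by roughly
+0.005 to +0.02 in mean predictive ability, usually winning most CV
replicates but with the margin varying by dataset — and, notably, a
similar tiny (≈ +0.008) fold-consistent edge appears even under a purely
additive architecture, attributable to Bayesian averaging over variance
components rather than to nonlinearity (it survives when the RKHS model
is reduced to the additive kernel alone).  A *markedly* better RKHS on
epistatic traits — the pattern reported for real conifer growth data — is
not reproduced in this synthetic world, and a "no advantage on additive
traits" null is rejected by a paired fold-level test despite the
practically negligible effect size; tests encoding those expectations
document the discrepancy rather than hide it.

## Numerical choices and conventions

* Positivity floor 1e-6 × var(y); matrix bending ridge 1e-8 × mean
  diagonal until the smallest eigenvalue ≥ 1e-10.
* `p_j` is computed from observed (pre-imputation) calls; random
  imputation draws Binomial(2, p_j) and flags imputed cells; imputation
  precedes matrix construction.
* Relationship matrices are symmetrized exactly on construction and must
  be symmetric to 1e-10 on input.
* Eigenvalues below max(1e-8 λ_max, 1e-12) are dropped from kernel
  eigenbases in the Gibbs sampler.
* Every random draw flows from an explicit seed; stage-level generators
  are derived as `default_rng([seed, stage])`, so stages are independently
  reproducible and identical seeds give byte-identical datasets.
* Problem sizes in the test suite: unit tests run trials of ~80–200 trees
  with 100–600 loci; end-to-end recovery and cross-validation checks run
  n = 400 trees (40 families × 10, 68 fathers) with 2,000 loci, 50
  replicates for recovery and 10 CV replicates, the package's standard
  desk-scale configuration.

## Known limitations

* No linkage disequilibrium, mutation, or genotyping-error model; loci
  segregate independently, which understates the relatedness spread real
  GBS panels show.
* Uniform pollen contribution; real seed orchards have skewed paternity.
* Missingness is completely at random, while GBS missingness is
  depth-dependent.
* Single trait, single site; no genotype-by-environment or spatial
  residual structure beyond the plot term.
* The RKHS prior and bandwidth defaults are pragmatic choices; posterior
  inferences for variance components under few retained draws should be
  treated as approximate (effective sample sizes are reported).
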