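# Methods

## Scope

`tetraped` implements the pedigree-based quantitative-genetic analysis of an
autotetraploid (potato-type) breeding program: relationship matrices that
account for double reduction, multi-trait REML estimation of additive,
line, specific-combining-ability (SCA), genotype x trial x year and residual
(co)variances, a profile-likelihood estimate of the double-reduction rate,
plot-level heritabilities, likelihood-ratio model comparison, and two
cross-validation schemes for predicted breeding values.  Because real
breeding-program phenotypes of this kind are proprietary, the package ships
a first-class synthetic-data generator whose output has exactly the
covariance structure of the analysis model.

## The relationship matrix under double reduction

Double reduction is the tetrasomic meiosis event in which both chromatids
of one parental chromosome enter the same gamete; at rate `alpha` per
meiosis it raises gametic homozygosity and hence inbreeding.  Writing
`Theta_ij` for the kinship (probability that a random allele of i and one
of j are identical by descent) and `F_i` for the inbreeding coefficient
(IBD probability of two distinct alleles of one individual), the recursion
over a topologically ordered pedigree is

    phi_i    = 1/4 + (3/4) F_i                    (self-kinship)
    gamma_p  = alpha + (1 - alpha) F_p            (within-gamete IBD;
                                                   alpha if p is unknown)
    F_i      = gamma_s/6 + gamma_d/6 + (2/3) kappa_sd
    Theta_ij = (Theta_sj + Theta_dj)/2            (j before i)

with `kappa_sd` the parents' kinship (`phi_s` for selfing, 0 if either
parent is unknown).  The matrix is reported on the founder-at-1 scale,
`A_ij = 4 Theta_ij` off the diagonal and `A_ii = 1 + 3 F_i`, the common
convention for tetraploid numerator relationship matrices; the additive
variance is interpreted on this scale and `d(A)`, the average diagonal,
rescales it in heritability formulas.  Unknown parents are treated as
unrelated, non-inbred base individuals in which double reduction still
occurs (`gamma = alpha`).

Anchors recovered exactly: founder diagonal 1; parent-offspring and
full-sib relationship 0.5 at any `alpha` in non-inbred pedigrees; a
founder-cross offspring has `F = alpha/3` (diagonal `1 + alpha`); selfing a
non-inbred tetraploid without double reduction gives `F = 1/6`.  Every
entry of A is additionally verified against a Monte-Carlo gene-dropping
estimate of IBD (the simulator's single-locus mode) within 4 standard
errors, across random pedigrees including selfing and unknown parents.

## The mixed models

Plot-level phenotypes of one or two traits follow

    y = X b + Z1 a + Z2 g + Z3 i [+ Z4 s] + e

with fixed trial, year, and trial x year effects per trait
(reference-level coding, singular columns dropped by pivoted QR), additive
effects `a ~ N(0, A (x) Sigma_a)`, iid clone ("line") effects capturing
remaining non-additive genetic variation, genotype x trial x year effects
per clone-trial-year cell, SCA effects keyed by unordered parent pair
(reciprocal crosses share a level; lines with an unknown parent get
singleton levels that contribute through shrinkage only), and residuals.
All cross-trait blocks are unstructured 2 x 2.  The baseline model M1 omits
SCA; M2 adds it.  Rows missing one trait contribute only their observed
block (missingness at random assumed).

### Implementation

The clone-level terms are folded into one combined clone effect with
covariance `Sigma_a (x) A_ff + Sigma_g (x) I + Sigma_s (x) SS'` (`A_ff`
restricted to phenotyped clones, `S` the clone-to-parent-pair incidence),
and the G x T x Y and residual terms into block-diagonal per-cell residual
covariance.  Restricting A to phenotyped clones changes nothing: the
likelihood depends on ancestors only through the marginal covariance of
the phenotyped clones, and BLUPs of unphenotyped individuals are recovered
exactly as conditional means through A (an unphenotyped, childless
offspring's prediction equals its parents' average, verified numerically).
The mixed-model equations therefore stay at dimension
(number of traits) x (number of phenotyped clones) plus fixed effects, and
one likelihood evaluation costs a few dense Cholesky factorizations at
that dimension.  The likelihood identity
`log|V| + log|X'V^-1 X| = log|R| + log|G| + log|C|` ties the MME
representation to the dense-V REML deviance; the test suite checks the two
against each other to 1e-8 and checks all analytic first derivatives
against finite differences of the dense form.

### AI-REML

The REML criterion is maximized by average-information updates.  Each
covariance block is parameterized by its Cholesky factor with
log-diagonals, which keeps every block positive (semi)definite, with
variance floors at 1e-10 of the phenotypic variance.  Scores use the MME
trace identities (`Z'PZ` for G-side parameters, `tr(R^-1 R_dot) -
tr(C^-1 W'R^-1 R_dot R^-1 W)` for residual-side ones); the AI matrix is
`0.5 f_k' P f_l` with `f_k = V_dot_k P y`.  Because a log-Cholesky step
cannot leave the PSD cone, the safeguard when a step fails to improve the
criterion is step-halving with a remembered step fraction, then a ridge on
the AI matrix, then scaled steepest ascent; a trust region caps each step
at 2 units in log-scale coordinates, where the surface flattens near
variance floors.  Convergence is declared when both the deviance change
and the largest parameter change fall below the tolerance (1e-8 by
default), or when the deviance is flat to tolerance on two consecutive
iterations (a ridge at a variance floor).  Starting values split the
phenotypic variance equally across terms with zero cross-trait
covariances; bivariate fits first run two cheap loosely-converged
univariate fits and start from those variances, which roughly halves the
iteration count without changing the optimum.  Standard errors come from
the inverse AI matrix at convergence.

### Known numerical behavior

Masked re-solves in cross-validation can lose fixed-effect rank (a
trial-year cell with all its clones masked); a small ridge on the
fixed-effect block then pins the unidentified contrasts near zero.  This
path is never taken during REML estimation.

## Double-reduction profile

The model is refitted over the standard grid {0.05, 0.1, 0.2, ..., 0.9},
rebuilding A at each rate and warm-starting from the previous grid point;
the fixed-effect structure is constant so deviances are commensurable.
The argmin estimates the rate, with ties broken toward the smallest rate
(profiles are flat at the low end when the data carry little double
reduction signal, and the flat region is reported).  A cold-start audit
refits the argmin from default starts and warns if the deviance moves by
more than 1e-4.  Grid fits use a 1e-6 tolerance, far below the grid-scale
deviance differences they resolve.

The rate is identified only through contrasts in inbreeding trajectories:
in shallow pedigrees A(alpha) is nearly a rescaling of A(0) and the
profile is flat, which the property suite asserts by comparing profile
ranges across pedigree depths.

## The synthetic generator

`simulate_pedigree` builds a multi-cycle program: founders, then each
cycle crosses a selected fraction of the recent cycles' clones
(overlapping generations, reused parents, optional selfing), recording
crossing years.  `gene_drop` transmits founder-allele labels through
tetraploid meiosis with double reduction at `alpha_true`.  Phenotypes add
fixed trial/year/trial x year effects and draws of every random term of the
model, with unstructured cross-trait blocks; replication mimics an uneven
breeding program (76% of clones in one trial, 14% in two, 10% in three,
about a third of cells with two plots, a few percent missing values per
trait).

Additive values are polygenic: `n_loci` unlinked loci (100 by default;
the double-reduction recovery experiment uses 400) are gene dropped and
each founder allele at each locus carries an effect with variance
`sigma_a^2 / (4 n_loci)`, so the realized additive covariance converges
to `sigma_a^2 A(alpha_true)` at rate `1/sqrt(n_loci)`.  A
single-locus drop is deliberately not used for phenotypes: conditioning on
one realized IBD configuration makes the realized relationship matrix of a
deep pedigree deviate far from its expectation, which buries the
double-reduction signal in realization noise (verified by comparing
profiles on exact multivariate-normal versus single-locus additive
values).  The single-locus mode remains the Monte-Carlo IBD oracle.

The default two-trait regime mirrors a dry-matter-content-like trait
(additive share near 70%, small SCA) paired with a yield-like trait
(residual-dominated), with modest positive cross-trait correlations; the
cross-trait correlations are illustrative, as such programs rarely report
them.  What the generator does not emulate: selection on phenotype (parents
advance at random), spatial field trends, linkage, locus-specific
double-reduction rates (the centromere-telomere gradient), or
heterogeneous residual variances across trials.  Passing tests therefore
show correctness of the machinery under the stated covariance model, not
robustness to these real-data features.

## Cross-validation

Five-fold CV partitions phenotyped clones at random (seeded, row-order
invariant; all plots of a clone stay together).  Leave-one-breeding-cycle-
out (LBCO) makes one fold per crossing year and additionally masks every
phenotyped clone sharing a known parent with the cycle - its full and half
siblings - so a new generation is predicted from parental and historical
data only.  Masked clones' rows are removed from the training data
entirely, so masking is total by construction (asserted bit-identically).
Variance components stay fixed at the full-data REML estimates and only
the mixed-model equations are re-solved per fold (a flag enables per-fold
re-estimation); fixed effects for the corrected clone means
`y_c = y - X b_hat` come from the full-data fit.  Predictive ability is
the pooled Pearson correlation between corrected clone means and
masked-model predictions (each clone counted in its own fold), the
accuracy ratio correlates masked with full-data predictions, and the
theoretical maximum of PA is reconstructed as `sqrt(h2)` of the corrected
clone mean with `var(y_c_bar) = d(A) sa2 + sg2 + ss2 + si2/t + se2/n`
using harmonic-mean cells `t` and plots `n` per clone.

## Problem sizes used in the checks

The shipped test suite and acceptance script run everything on simulated
programs sized for a desk machine, chosen as the smallest sizes at which
each property is informative: oracle agreement on 25-individual pedigrees
at 1e5 gene-dropping replicates; bivariate variance-component recovery on
a ~2,000-line, 14-cycle program; double-reduction-rate recovery on a deep
12-cycle, ~1,500-line design with 30% selfing (without inbreeding
variation the profile is flat at any feasible size, so the recovery
experiment deliberately uses a selfing-rich design); LRT calibration on
200 replicates of a 90-line program; cross-validation behavior on
~500-line programs.  The acceptance script analyses a single ~800-line
bivariate program end to end.

## Known limitations

- One genome-wide double-reduction rate; no locus-specific rates.
- At most two traits jointly; no spatial models, no heterogeneous residual
  variances per trial, no Bayesian sampling.
- The LRT uses the plain chi-square reference with df equal to the number
  of added (co)variance parameters, as is conventional; it is conservative
  because the null pins variances to the boundary (the calibration test
  bounds the size at nominal 5% by 7.5%).
- Heritability standard errors are not propagated (no delta method).
- Dense linear algebra throughout: practical to roughly 10^4 phenotyped
  clones on a workstation.
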