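# Methods

## The model

Inbreeding depression is modelled as the expression of ancestor-specific
*inbreeding loads*: each animal j carries an additive quantity i_j (the
expected phenotypic change in a descendant fully inbred on j's alleles), and
an inbred individual x expresses a mixture of the loads of the ancestors in
which its two gametic lineages coalesce. The observation model for a record y
on animal x is

    y = f d [+ t c] + X b + W h + Z u + K i [+ L p] + e

where f is x's pedigree inbreeding coefficient (so d is the mean depression at
F = 1), t an optional centred age-at-recording covariate, b fixed effects
(overall mean plus factors such as sex), h ~ N(0, I sigma_h^2) random
herd-year-season effects, u additive genetic effects, p ~ N(0, I sigma_p^2)
permanent-environment effects for repeated records, and e ~ N(0, I sigma_e^2).
The load incidence is K = T(I − P): T holds the partial inbreeding
coefficients F_x^(j), and (I − P) (P has 0.5 at each animal-parent pair)
converts ancestor loads into their Mendelian-sampling residuals, so the load
expressed through coalescence at j is the part of i_j not inherited from j's
own parents. The genetic prior is bivariate,

    (u, i) ~ N(0, V ⊗ H),   V = [[sigma_u^2, sigma_ui], [sigma_ui, sigma_i^2]],

with H the single-step relationship matrix combining pedigree and genomic
information.

## Partial inbreeding coefficients

F_x^(j) is defined as the probability that the two gametic lineages of x first
share an allele-copy node in ancestor j (first-coalescence attribution). It is
computed exactly by a per-ancestor tabular recursion over j's descendants:

    r_j(j, j) = 1
    r_j(x, y) = 0.5 (r_j(s_x, y) + r_j(d_x, y))    x a descendant, y ≠ x
    r_j(x, x) = 0.5 r_j(s_x, d_x)
    F_x^(j)   = 0.5 r_j(s_x, d_x)

The descendant diagonal carries no own-coalescence term because coalescence at
x is x's own event, and the seed is 1 (not 1 + F_j) because coalescence above
j is attributed above j. Under this partition every coalescence event belongs
to exactly one ancestor, so the partials are nonnegative, vanish unless j is a
common ancestor of x's parents, and sum over j exactly to the Meuwissen–Luo
inbreeding coefficient — the package's central conservation identity, tested
to 1e-10 on random pedigrees.

An alternative partition exists (seeding each ancestor with its
Mendelian-sampling variance, A = TDT'), which pushes part of an inbred
ancestor's contribution onto that ancestor's own parents. The two conventions
agree whenever the responsible ancestors are founders and disagree otherwise;
the first-coalescence convention is used here because it is the one the
gene-dropping experiment measures and the one under which K = T(I − P) has the
intended interpretation. A Monte-Carlo gene-dropping oracle (uniquely
labelled allele copies dropped through the pedigree; an autozygous replicate
is attributed to the animal owning the most recent shared allele-copy node)
validates the exact recursion; at 1e5 replicates the two agree within binomial
error on random pedigrees.

## Relationship matrices

A⁻¹ uses Henderson's rules with inbreeding (Mendelian-sampling variances
0.5 − 0.25(F_s + F_d), with the usual adjustments for unknown parents); F by
the Meuwissen–Luo algorithm; A22 blocks by the tabular method on the
ancestor-pruned pedigree (exact and simple at these scales). G is VanRaden's
first method, W_g W_g' / Σ 2p̂(1−p̂), with allele frequencies estimated from
the genotyped sample after QC. The QC filters (applied in order: autosomal
only, call rate ≥ 0.95, MAF ≥ 0.05 — the MAF exclusion is strict "< 0.05")
are followed by mean imputation of the remaining missing genotypes (to 2p̂,
preserving column means). H⁻¹ = A⁻¹ augmented on the genotyped block with
G*⁻¹ − A22⁻¹, where G* = (1 − w) G + w A22 blends toward the pedigree (default
w = 0.05, standard single-step practice) and an optional tuning step matches
the mean diagonal/off-diagonal of G to A22 first. Both knobs are exposed; no
numerical equivalence with any particular ssGBLUP implementation is claimed.

## Gibbs sampler

All location effects get single-site Gaussian updates except (u_j, i_j),
which are drawn jointly per animal from their bivariate full conditional using
the V⁻¹ ⊗ H⁻¹ sparsity — block sampling is required for acceptable mixing when
sigma_ui is large relative to the variances. Variance priors are uniform on
the parametric space, implemented as limiting conjugate full conditionals:
scalar variances as InvGamma(q/2 − 1, SS/2) (the scaled inverse chi-square
with the flat-prior exponent), and V as inverse-Wishart IW(S, nu = q − 3) with
S the 2×2 matrix of H⁻¹ quadratic forms in (u, i); nu = q − 3 makes the
density exponent |V|^(−q/2), i.e. exactly the flat-prior full conditional.
The Wishart draw uses the Bartlett construction; a non-positive-definite draw
is rejected and redrawn. The core loop is compiled (numba), single-threaded,
and bit-reproducible given the seed.

Defaults are 50,000 iterations, 10,000 burn-in, thinning 10 — chain lengths
chosen for the package's synthetic problem sizes (hundreds to a few thousand
records); longer chains are configuration. Posterior means and SDs of u and i
are accumulated over every post-burn-in iteration. Fixed effects under flat
priors may be mutually confounded (mean + factors); their individual chains
then random-walk in the null space while every estimable quantity (contrasts,
d, c, h, u, i, variances) remains identified — the direct mixed-model-equation
solver used for verification therefore returns the minimum-norm solution and
comparisons are made on estimable quantities only.

Prediction accuracy uses the reliability form acc = sqrt(1 − PSD² / (H_jj
sigma²)), clamped to [0, 1]; PSD is the posterior SD of the effect, H_jj the
diagonal of H (computed exactly from the blended G*, A22 and the pedigree
blocks), sigma² the posterior-mean variance.

## Derived statistics

Depression percentages are D%-M = 100·|d|/mean and D%-SD = 100·|d|/SD, with
their posterior SDs obtained by the same linear transform of the posterior SD
of d. The proportion of phenotypic variance explained by the load at
inbreeding level F is F²·sigma_i² / (sigma_u² + sigma_h² + sigma_p² +
sigma_e² + F²·sigma_i²); heritability uses the same denominator. The inclusive
denominator (load term included) is adopted because it is the only convention
under which the published heritability extremes and the birth-weight ratio
are jointly reproduced from the published posterior means; both functions
accept posterior samples, so either the ratio-of-means or the posterior of
the ratio can be reported (skewed load-variance posteriors make the two
differ noticeably).

## Back-solving and window scans

SNP effects are recovered from animal-level posterior means by
s = W_g' G⁻¹ a / Σ 2p̂(1−p̂), separately for u and i. The linear solve is
minimum-norm (G built from observed frequencies is singular along the ones
vector; for values in the range of G, W_g s reproduces them exactly — the
GBLUP↔SNP-BLUP equivalence tested to 1e-8). Per-SNP variance is
2p̂(1−p̂)s²; windows of 25 or 50 consecutive SNPs within a chromosome (sliding
by default, disjoint optional — both emitted with the mode recorded) sum the
per-SNP variances, and percentages are of the genome-wide sum. This ignores
LD covariances between markers and is an approximation to the true regional
genetic variance. Regions are overlapping qualifying windows (> 1% of the
component's summed variance) merged per chromosome.

## Synthetic data generator

The generator emulates a managed livestock population with inbred matings:
discrete generations; a configurable fraction of matings between full sibs
(or sire–daughter when no sib pair is available) to induce inbreeding;
biallelic SNPs gene-dropped from founder frequencies drawn uniform on
(0.1, 0.9); and phenotypes built term-by-term from the model equation.
(u, i) are drawn from N(0, V ⊗ A) by the pedigree recursion — a Cholesky
factor of V scaled by each animal's Mendelian-sampling variance — so truth
generation never touches the genomic machinery being tested. The default
variance preset mirrors the published birth-weight magnitudes (sigma_u² 9.27,
sigma_i² 57.97, sigma_ui −11.03, sigma_h² 7.89, sigma_e² 29.49, d −1.20) so
recovery runs at realistic signal-to-noise.

What the generator does not emulate: linkage (SNPs segregate independently,
so the scans have no LD structure and simulated load variance is not
physically localised), selection, major genes, age structure or overlapping
generations, heterogeneous genotyping by cohort, and the real population's
scale (5·10⁵ animals). Passing tests therefore demonstrate the correctness of
the algebra, the sampler and the attribution logic — not field-scale accuracy
of variance estimates.

Problem sizes in the test suite are the package's choices for desk-scale
verification: recovery experiments use 80 founders, 8 generations of 60
matings × 3 offspring, close-mating fraction 0.5 and 3 records per animal
(~1500 animals, ~4300 records, mean F of inbred animals ≈ 0.2), with 50,000
iteration chains. The high close-mating fraction is deliberate: the
information on sigma_ui and sigma_i² scales with the number of inbred
descendants per ancestor, which the real population accumulates through sheer
size instead. At this scale the load variance is weakly identified, with
right-skewed posteriors; interval coverage is honest (HPD95 covers the truth
in ≳ 80–100% of replicates per parameter) but point estimates of sigma_i² can
exceed the truth substantially in individual replicates, and the posterior
probability of a negative u–i correlation fluctuates between replicates
because the realized correlation among a finite founder sample fluctuates.

## Numerical choices and degenerate inputs

- Topological sort with ties broken by birth year then input order; unknown
  parents coded 0; duplicated ids, unknown parent labels and cycles are hard
  errors.
- The one-pass ±3 SD outlier filter computes mean and SD on the input set.
- V may be positive semidefinite in the generator (zero-variance presets use
  a symmetric eigendecomposition square root instead of Cholesky); the
  sampler itself requires a positive-definite start.
- Sampling sigma_h² (or sigma_p²) under the flat prior requires at least 3
  levels; fewer levels is an error rather than an improper posterior.
- HPD intervals are shortest sorted-window intervals.
- Empty genotype set: H⁻¹ = A⁻¹ exactly. Singular blended G* raises an error
  advising a larger blend weight.

## Known limitations

- Single-trait analyses only; no REML alternative; convergence diagnostics
  are limited to trace export and batch-means MC error in the tests.
- The per-ancestor decomposition is O(Σ_j |desc(j)|²); fine for 10³–10⁴
  animal pedigrees, not engineered for the 5·10⁵-animal scale.
- Window percentages ignore LD covariance; region calls are descriptive, not
  significance-tested.
- Gene annotation of regions is out of scope.
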