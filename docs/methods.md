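# Methods

## Model

Individuals are sampled from K discrete populations with sizes n_1..n_K
(n total).  For a random biallelic marker, the allele frequency vector
f = (f_1..f_K) across populations is random with mean mu and covariance
matrix psi; given f, the allele count of an individual from population s is
Binomial(2, f_s) (Hardy–Weinberg), independent across individuals.  Markers
are independent realizations (no linkage disequilibrium).

The covariance of the n-vector of allele counts is then block
compound-symmetric, with

    sigma2_s = 2 mu_s (1 - mu_s) + 2 psi_ss      (diagonal)
    c_s      = 4 psi_ss                          (within-population)
    d_st     = 4 psi_st                          (between populations)

All between-individual covariance is inherited from the shared frequency
draw; with psi = 0 individuals are exactly independent, and with
psi_ss = mu_s(1 - mu_s) (frequencies degenerate at 0/1) two individuals
from one population are perfectly correlated.  These moment maps are
verified in the test suite against a brute-force Monte-Carlo oracle that
simulates the two-stage draw directly.

Throughout, `d` is stored as a K x K symmetric matrix whose diagonal holds
`c` — the convention under which all later identities are single matrix
expressions.

## Mean adjustment

Genotype PCA is performed on per-marker centered data.  Subtracting the
grand individual mean transforms the parameters as

    r_s  = (1/n) [ sigma2_s + (n_s - 1) c_s + sum_{t != s} n_t d_st ]
    g    = (1/n^2) [ sum_t n_t sigma2_t + sum_t n_t (n_t - 1) c_t
                     + sum_{t != u} n_t n_u d_tu ]
    sigma2~_s = sigma2_s - 2 r_s + g
    c~_s      = c_s - 2 r_s + g
    d~_st     = d_st - r_s - r_t + g

Two exact consequences anchor the implementation: the within-population
differences sigma2_s - c_s are unchanged (the "small" eigenvalues survive
adjustment), and every row of the adjusted system satisfies the zero-sum
identity (sigma2~_t - c~_t) + n_t c~_t + sum_{s != t} n_s d~_st = 0, which
is what makes the constant vector an eigenvector with eigenvalue zero.
`mean_adjust` is validated against the projection oracle
P Gamma P with P = I - J/n on the dense matrix.

## Reduced eigenproblem

The adjusted covariance has n - K small eigenvalues sigma2_s - c_s
(multiplicity n_s - 1 each) and K large eigenpairs with eigenvectors
constant within populations.  Writing a_s for the per-population value, the
large pairs solve the K x K system R a = lambda a with

    R_st = n_t d~_st + delta_st (sigma2~_s - c~_s),   d~_ss = c~_s.

Numerically we solve the symmetrized form B = S R S^-1 with
S = diag(sqrt n_s) (a real symmetric eigenproblem), map back
a = b / sqrt(n_s), and normalize sum_s n_s a_s^2 = 1.  The trivial solution
(lambda = 0, constant a) is identified by a relative tolerance of 1e-9 on
|lambda| and reported, not dropped.  All K - 1 nontrivial axes satisfy
sum n_s a_s = 0 and are weighted-orthogonal.  Correctness is pinned by an
oracle test: for hundreds of random parameter sets the reduced eigenvalues
plus the small eigenvalues reproduce the dense n x n spectrum to 1e-8, and
the expanded axes are dense eigenvectors.

Sign convention: per axis the coefficient of largest magnitude is made
positive (PC scatter plots are mirror-ambiguous otherwise).  Eigenvalue
ties from exchangeable populations are broken by the population index of
each axis's dominant coefficient.

Two populations admit a closed form: the single structure axis is
a = (sqrt(n2/(n1 n)), -sqrt(n1/(n2 n))) — fixed entirely by the two
constraints, hence by the sample-size ratio alone — with eigenvalue
-n d~_12 (derived from the zero-sum identity; the solver reproduces it to
1e-10).

## Asymptotics and the critical size

At fixed proportions w_s = n_s/n, dividing the reduced system by n and
dropping the O(1/n) terms gives the limit problem A a = lambda a with
A_st = w_t d~_st, where the tilde now denotes the limit adjustment
r_s = sum_t w_t d_st, g = w' D w.  Consequences implemented and tested:
large eigenvalues grow linearly in n; axis coefficients become independent
of n *and of the variances sigma2_s* (perturbing sigma2 leaves the limit
axes bitwise unchanged); the finite-n axes converge to the limit axes
(weighted-norm distance < 1e-3 by n = 1e4 for the subtle-structure
scenario).

The neglected term is (sigma2_s - c_s)/n per population.  Equating it to
the smallest structure eigenvalue of A in the exchangeable case (equal
sigma2, c, d; limit eigenvalue (c - d)/K) gives the critical size

    n* = K (sigma2 - c) / (c - d),

beyond which the PC-plot pattern is essentially asymptotic.  n* diverges as
d -> c: near-identical populations need ever larger samples.  The constant
prefactor is a convention (we use 1); only the scaling and monotonicity are
asserted.  With K = 2 the axis is size-determined at any n, so
`critical_size` warns.  For non-exchangeable parameters
`asymptotic_error_ratio` reports the neglected-to-signal ratio as a
function of n instead.

## Estimation

`sample_cov` computes the covariance of individuals across markers with
per-individual centering, pairwise-complete over missing genotypes (each
pair uses the markers where both are observed, with means over those same
markers).  With `marker_adjust=True` each marker row is first centered
across individuals; the eigenvectors of that matrix are the sample PCs.
`sample_pca` drops markers monomorphic across the sample (they are
identically zero after marker centering) and logs the count.

`estimate_params` block-averages the raw (individual-centered, not
marker-centered) covariance: diagonal cells -> sigma2_s, within-block
off-diagonal cells -> c_s, cross-block cells -> d_st.  Adjusted parameters
are then obtained analytically through `mean_adjust` rather than
re-estimated, keeping the zero-sum identity exact.  Standard errors treat
the averaged cells as independent; they share individuals, so these are
first-order gauges, not exact sampling errors (documented on the type).
Populations with a single member have no within-population covariance and
raise an explicit error rather than yielding NaN.

Correlations rho_st = d_st / sqrt(sigma2_s sigma2_t) (with c_s on the
diagonal) are exposed as the sample-size-free summary of population
distances.  `representative_points` runs the estimate -> adjust -> reduce ->
solve pipeline; on simulated data the points sit at the centroids of the
sample-PC clusters (asserted at three combined standard errors in the test
suite).

No per-marker 1/sqrt(p(1-p)) standardization is applied anywhere: the
theory is formulated on raw allele counts, and in our experiments
standardizing the PCA panel changed the PC subspace accuracy negligibly.

## Stratification-corrected association tests

The Armitage trend test is computed as chi2 = N r^2, r the Pearson
correlation between allele count (scores 0/1/2) and case status, referred
to a 1-df chi-square; this equals the classical 2 x 3 table formula (cross-
checked against a textbook implementation).  The generalized version runs
on residualized vectors with an optional degrees-of-freedom deduction
`df_loss` (default 0).

Corrections:

- **popu-Eigenstrat** subtracts per-population mean allele counts.  The
  K - 1 nontrivial axes, expanded to individuals, are an orthonormal basis
  of the population-indicator span orthogonal to the constant vector, so
  this equals regressing out the representative PCs exactly; the identity
  is asserted to 1e-10 and is the module's core correctness test.  No
  covariance parameters are needed at test time, only memberships.
- **Eigenstrat** regresses out the top L sample PCs (default L = 2, PCs
  from the structure-informative null panel).
- **Covariate adjustment** is a 1-df likelihood-ratio test of the genotype
  term in a logistic model with K - 1 population indicators (statsmodels;
  the genotype-free null model is fitted once per scan).  Separation or
  non-convergence flags a SNP untestable.

Residualization convention: both PC-based corrections residualize the
*genotype only* by default; the phenotype enters the correlation with its
raw variance.  When case fractions differ across populations this deflates
the statistic by var(y_res)/var(y) (about 0.90 under the benchmark design)
and makes the corrected tests mildly conservative — which is the behaviour
of the published implementations this package mirrors, where corrected
type-I error rates fall visibly below alpha.  `residualize_phenotype=True`
gives the fully calibrated double residualization instead.

Untestable SNPs (monomorphic, zero residual variance, non-converged
logistic fits) are excluded from both numerators and denominators of
rejection proportions, with counts logged and reported.

## Simulator and the benchmark study

Balding–Nichols draws: ancestral frequency p ~ Uniform(0.1, 0.9) per
marker, then f_s ~ Beta(p(1-F_s)/F_s, (1-p)(1-F_s)/F_s) independently given
p, so E[f|p] = p and Var(f|p) = F p(1-p); F = 0 degenerates to f = p.
Monomorphic markers are retained (the draw is unconditioned) and handled
downstream.

Benchmark design (defaults are the study conditions, not tuning knobs):
three populations, expected case counts 30/60/150 (prevalence ratio 1:2:5,
equal sampling priors) and controls 80/80/80; 10,000 SNPs per category;
four categories — Null/Causal StruInfo (Balding–Nichols at the given F) and
Null/Causal Specific with fixed frequency sets (0.75, 0.30, 0.15) and
(0.15, 0.30, 0.75), aligned and anti-aligned with the case-count gradient.
Case genotypes under relative risk r follow P(g|case) proportional to
HW(g) r^g, which normalizes to Binomial(2, rf/(1 - f + rf)) (identity
verified in tests).  Causal power is direction-aware: a rejection counts
only if the genotype-phenotype correlation points at the simulated risk
allele.  Under anti-aligned stratification the uncorrected test is
"significant" with the wrong sign for essentially every SNP, giving the
striking 0.0000 uncorrected power alongside a ~0.99 null rejection rate.

Two constants of the benchmark are calibrated conventions: the significance
threshold alpha = 0.01 and the relative risk r = 1.5 (chosen so corrected
power lands in the mid-0.4 range under the design); both are configurable
and recorded in every manifest.

The subtle-structure scenario generates P1, P2, P4 by Balding–Nichols at
F = 0.003 and sets P3's frequency vector to P2's plus an independent
Uniform(-delta, +delta) per marker (default delta = 0.01, chosen so the
P2/P3 contrast is an axis-3 feature invisible on axes 1–2; clipped to
[0, 1] with a logged count).  Its exact frequency moments
(psi_33 = psi_22 + delta^2/3, psi_23 = psi_22) are available analytically
for the asymptotic and convergence tests.

## What the simulations do and do not show

The generator emulates independent biallelic SNPs under pure drift-style
frequency divergence with known memberships.  It has no linkage
disequilibrium, no admixed individuals, no genotyping error or missingness
process (missing data is supported at the estimation layer but not
generated), and fixed case/control counts (expected values, not sampled).
Passing tests therefore certify the algebra, the estimators and the
relative behaviour of the corrections under clean stratification — not
performance on real GWAS data with LD and admixture.

Problem sizes in the test suite are chosen to keep the full run in minutes
on one CPU: the benchmark runs at its native 10,000 SNPs per category; the
dense-oracle comparisons use n <= 300; parameter-recovery uses 1e5 markers
in 20 batches (batch scatter supplies the Monte-Carlo standard error); the
PC-scatter assertions use panels of 5e3–2e4 markers, above the PCA
detection threshold for their scenarios.

## Known limitations

- Standard errors of parameter estimates ignore cell correlation.
- The sample-PC (Eigenstrat) arm inherits PC-estimation leakage on SNPs
  outside its panel; with a 10^4-SNP panel at n = 480 and F = 0.01 the
  PC subspace misses the indicator subspace by principal angles of ~0.1
  rad, which inflates its fixed-frequency null cells relative to the
  group-mean correction.  This is a property of sample PCs, not a solver
  artefact.
- `covariate_trend` fits one logistic model per SNP (vector-free); large
  scans pay ~0.6 ms per SNP.
- Admixture is out of scope: every individual belongs to exactly one
  population.
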