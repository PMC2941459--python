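# stratpca

Population-level principal components analysis for detecting and correcting
population stratification in genetic association studies.

## The problem

Case-control association tests are confounded when cases and controls are
drawn unevenly from ancestrally distinct populations: allele-frequency
differences between populations masquerade as disease associations.  The
standard remedy (the Eigenstrat approach) regresses the top principal
components of the genotype matrix out of each SNP before testing.  This
package implements the *population* formulation of that procedure: instead
of working only with the n x n sample covariance of the individuals, it
models it.

For individuals sampled from K populations, the allele count X of a random
marker has a block compound-symmetric covariance described by 2K + K(K-1)/2
parameters:

- `sigma2_s` — variance of one individual's allele count in population s,
- `c_s` — covariance of two distinct individuals in population s,
- `d_st` — covariance of individuals from populations s and t.

Under the diploid frequency model (X | f ~ Binomial(2, f_s), frequencies
random across markers with mean `mu_s` and covariance `psi_st`):
`sigma2_s = 2 mu_s (1 - mu_s) + 2 psi_ss`, `c_s = 4 psi_ss`,
`d_st = 4 psi_st`.

After per-marker mean adjustment (subtracting the grand mean over
individuals), the spectrum of this covariance splits into n - K "small"
within-population eigenvalues `sigma2_s - c_s` (multiplicity `n_s - 1`) and
K "large" eigenpairs whose eigenvectors are constant within populations —
the **axes of variation**.  The large pairs solve a K x K reduced
eigen-equation with matrix `R_st = n_t d~_st + delta_st (sigma2~_s - c~_s)`
(tildes denote adjusted parameters, `d~_ss = c~_s`); one solution is trivial
(eigenvalue 0, constant coefficients) and the K - 1 others satisfy the
contrast and normalization constraints `sum_s n_s a_s = 0`,
`sum_s n_s a_s^2 = 1`.  Each population becomes a single representative
point per axis, which is where the scattered per-individual sample PCs of an
Eigenstrat analysis cluster.

On top of the model the package provides:

- estimation of `(sigma2, c, d)` from a genotype matrix by block-averaging
  the sample covariance, with correlations `rho_st = d_st /
  sqrt(sigma2_s sigma2_t)` as size-free population distances;
- the asymptotic (n -> infinity) form of the eigenproblem, which depends
  only on covariances and population proportions — useful for reading PC
  plots of large samples;
- the **popu-Eigenstrat** correction: regressing out the representative PCs,
  which is provably identical to subtracting per-population mean allele
  counts, plus the classical Eigenstrat (sample-PC) and covariate-adjustment
  corrections around the (generalized) Armitage trend test;
- a Balding–Nichols simulator and the full case-control benchmark study
  comparing the corrections.

## Worked example

Axes of variation for three populations with identical variance-covariance
parameters (`sigma2 = 1`, `c = 0.8`, `d = 0.1`) but unbalanced sample sizes
5 / 10 / 100:

```sh
$ cat params.txt
labels: P1 P2 P3
sizes: 5 10 100
sigma2: 1.0 1.0 1.0
c: 0.8 0.8 0.8
d_P1_P2: 0.1
d_P1_P3: 0.1
d_P2_P3: 0.1
$ stratpca reduce --config params.txt --out-dir out
$ cat out/eigenvalues.tsv
axis    eigenvalue              trivial
axis1   14.644980149220881      0
axis2   4.6245850681704255      0
axis3   2.708630411634186e-15   1
$ cat out/axes.tsv
population  axis1                 axis2                  axis3
P1          0.18109005213965976   0.3981340739526602     0.09325048082403134
P2          0.266223278795091     -0.14293184968256098   0.09325048082403144
P3          -0.03567683048649209  -0.005613518729376912  0.09325048082403137
```

Axis 3 is the trivial solution (eigenvalue 0, constant coefficients — a
by-product of the mean adjustment).  On the two structure axes the smallest
population (P1, radius 0.44) sits farthest from the origin and the largest
(P3, radius 0.036) nearest: with identical population parameters the PC-plot
pattern reflects sample sizes alone, as the contrast constraint forces.

The same library solves the problem from data: `stratpca estimate` / `axes`
read an EIGENSTRAT geno/snp/ind triple or a TSV matrix, estimate the
parameters with standard errors, and write the estimated axes.

The simulation benchmark (three populations, cases 30/60/150 vs controls
80/80/80, four SNP categories, alpha = 0.01, relative risk 1.5):

```sh
$ stratpca table5 --fst 0.01 --snps-per-category 2000 --seed 1 --out-dir t5
Fst=0.01:
                    none  eigenstrat   popu  covariate
null_struinfo     0.0260      0.0090 0.0090     0.0115
causal_struinfo   0.5370      0.4480 0.4570     0.5020
null_specific_a   0.9710      0.0075 0.0060     0.0115
causal_specific_a 0.0000      0.2670 0.4160     0.4820
null_specific_b   0.9940      0.0040 0.0055     0.0100
causal_specific_b 1.0000      0.4900 0.4605     0.4990
```

Rows are SNP categories (structure-informative Balding–Nichols SNPs, and
SNPs with fixed frequencies (0.75, 0.30, 0.15) = set a or (0.15, 0.30, 0.75)
= set b); columns are correction methods; null rows show type-I error at
alpha = 0.01, causal rows direction-aware power.  Uncorrected fixed-frequency
null SNPs are rejected ~97-99% of the time, and causal SNPs whose frequency
gradient opposes the case-sampling gradient (set a) have *zero* uncorrected
power — their tests are significant but point at the wrong allele.  All
three corrections restore both size and power.

## Layout

| module | contents |
| --- | --- |
| `stratpca.model` | layout, frequency model, `(sigma2, c, d)`, mean adjustment, dense-oracle constructor |
| `stratpca.reduced` | reduced eigenproblem, closed forms, asymptotics, critical size |
| `stratpca.estimate` | sample covariance, parameter estimates, sample PCA, representative points |
| `stratpca.assoc` | residualizations, (generalized) Armitage and covariate tests, benchmark runner |
| `stratpca.simulate` | Balding–Nichols draws, risk model, study designs |
| `stratpca.io`, `stratpca.cli` | EIGENSTRAT/TSV formats, configs, manifests, `stratpca` CLI |

See `docs/methods.md` for the statistical details and design choices.
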