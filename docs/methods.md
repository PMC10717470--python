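# Methods

This note records the statistical model, the numerical choices, and the
design decisions behind `epiblup`, in the spirit of the methods notes
that accompany packages such as statsmodels or msprime. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Model and relationship structures

The linear mixed model is

y = Xβ + f b + Σ_t Z u_t + ε,  u_t ~ N(0, G_t σ²_t),  ε ~ N(0, I σ²_ε),

where t ranges over the random terms of the chosen model: additive (A),
dominance (D), additive-by-additive (AA), additive-by-dominance (AD),
dominance-by-dominance (DD) and permanent environment (identity). Z is
the record→animal incidence matrix, so repeated records of one animal
share all of its genetic and permanent environmental values. `f` is the
per-animal inbreeding coefficient; its regression coefficient b is the
inbreeding depression, fitted as a fixed covariate in every model whose
name contains "I".

Genomic relationship matrices:

* **Additive** (VanRaden): `G_A = MM′ / (2 Σ p_i q_i)` with M the dosage
  of allele A1 centered at `2p_i` (entries `2−2p`, `1−2p`, `−2p`).
* **Dominance** (Vitezica): `G_D = WW′ / (4 Σ p_i² q_i²)` with W entries
  `−2q²`, `2pq`, `−2p²` for the three genotypes.
* **Epistatic** (Hadamard): `G_AA = (G_A ⊙ G_A) / (tr(G_A ⊙ G_A)/n)`,
  and analogously for AD and DD, so each epistatic matrix has trace
  exactly n.

Allele frequencies for centering are the *observed* post-QC frequencies
of the analyzed sample. This makes the row sums of G_A exactly zero and
matches common GBLUP practice; HWE-expected proportions would be an
alternative for G_D, but with no basis to prefer them we use one
frequency source coherently everywhere. Missing calls enter the codings
at their expectation (0 after centering), which preserves allele
frequencies.

Pedigree inbreeding is the diagonal of the numerator relationship matrix
minus one, computed by the tabular recursion in topological pedigree
order (founders unrelated, F = 0). Genomic inbreeding is
`diag(G_A) − 1`, the VanRaden-consistent choice; it feeds both the
optional covariate and the accuracy denominator of the LR method from
one definition.

## Model catalogue

Sixteen named variants are hard-coded so that outputs can be
cross-checked against the vocabulary used in the animal-breeding
literature: `MA`, `MAI`, `MAE`, `MAIE`, `MAD`, `MAID`, `MADE1`,
`MAIDE1`, `MADE2`, `MAIDE2`, `MADE3`, `MAIDE3` for single-record traits,
and the repeatability variants `MAIpe`, `MAIDpe`, `MAIEpe`, `MAIDEpe`.
Free-form `ModelSpec` objects cover anything else. A permanent
environmental term is rejected unless the data contain repeated records,
where it would otherwise be wholly confounded with the residual.

## REML estimation

The restricted log-likelihood is
`−½ [log|V| + log|X′V⁻¹X| + y′Py]` with
`V = Σ_t Z G_t Z′ σ²_t + I σ²_ε`, evaluated by dense Cholesky
factorization (the intended scale is up to a few thousand records, where
dense double precision is simplest and fastest).

Optimization is average-information (AI) REML:

* **Start:** the sample phenotypic variance split equally across all
  components — deterministic and scale-free.
* **AI step:** Newton step with the average-information matrix
  `AI_ij = ½ y′P V_i P V_j P y`. Components pinned at the boundary whose
  gradient points outward are held fixed during the solve.
* **Boundary:** the parameter floor is `1e-8 ×` sample phenotypic
  variance. An AI update crossing the floor lands on it; this keeps V
  invertible and reproduces the near-zero printed estimates (order
  1e-8) that boundary components show in published tables.
* **Ascent safeguard:** a step that decreases the likelihood is halved
  up to 12 times; if that fails, a guaranteed-ascent
  expectation-maximization update
  `σ²_new = σ² + (σ⁴/n)(y′P V_i P y − tr(P V_i))` replaces it.
* **Convergence:** relative log-likelihood change below 1e-8 *and*
  maximum relative parameter change below 1e-7, within 200 iterations;
  non-convergence returns the last state with `converged=False` so a
  model battery can proceed and flag the failure.
* **Uncertainty:** standard errors from the inverse AI matrix at the
  optimum; ratio standard errors by the delta method using that same
  covariance.
* **BLUP:** `û_t = σ²_t G_t Z′Py`; the additive term's solution is the
  GEBV used for ranking and validation. Fixed-effect solutions are GLS
  at the final variances.

AIC is `−2 loglik + 2t` with t the number of *variance* parameters;
REML likelihoods (and hence AIC and LRTs) are compared only between
models with identical fixed structure, so models with and without the
inbreeding covariate are never tested against each other.

The fixed design is intercept + dummy-coded factors (first sorted level
as reference) + covariates; a factor written `"a:b"` is the observed
cross-product (concatenation) of the named columns. Rank-deficient
columns are dropped by pivoted QR with a log entry, and single-level
factors are dropped with a log entry.

## LR-method validation

Folding is by animal: all records of a fold's animals are removed
together, which prevents leakage through repeated records. Each partial
fit re-estimates the variance components (the conservative reading of
"fitting each partial dataset with the same procedure"). For the masked
animals,

* bias `μ_wp = mean(û_p) − mean(û_w)`,
* dispersion `b_w,p = cov(û_p, û_w) / var(û_p)`,
* accuracy `acc_p = sqrt( cov(û_p, û_w) / ((1 − F̄) σ̂²_a) )`,

with `F̄` the masked animals' mean inbreeding and `σ̂²_a` from the
whole-data fit of the same model. Statistics are computed over masked
animals only and averaged arithmetically over folds. A negative
partial–whole covariance leaves the accuracy undefined (reported
missing, logged); an accuracy above one is clipped with the raw value
logged.

## Model comparison

`LRT = −2(loglik_reduced − loglik_complete)` referred to χ²(Δk), where
Δk is the difference in variance-parameter counts. Because the null
value of a variance lies on the boundary of its parameter space, the
χ² reference is conservative; the package documents this rather than
switching to a 50:50 mixture, matching how such tests are usually
reported in this literature. The null simulation in the test suite
verifies the rejection rate stays at or below ~7% at nominal 5%.
Re-ranking is summarized by Spearman's ρ (average ranks for ties) and
by top-1/5/10/20% selection overlap with selection size
`ceil(fraction × n)` and ties broken by stable animal order.

## Synthetic data

The generator produces data with exactly the statistical structure the
models assume. Genetic vectors are drawn from N(0, G_t σ²_t) using an
eigen-decomposition factor with negative eigenvalues clipped at zero
(Hadamard products can be numerically semidefinite; clipping is logged).
Drawing from the model's own covariance structures — rather than from
per-SNP effects — guarantees the fitted model is correctly specified,
making parameter recovery a clean test surface; the flip side is that
the simulation cannot probe model misspecification (LD-induced
non-orthogonality between additive and epistatic terms, directional
dominance, marker-QTL disequilibrium), so passing recovery tests says
nothing about those effects in real data.

Genotypes come either from independent Binomial(2, p) draws (HWE) or
from gene-dropping founder alleles through a simulated pedigree, which
creates identity-by-descent consistent with pedigree inbreeding. Allele
frequencies default to Uniform(0.05, 0.5) so every simulated SNP clears
a 1% MAF filter. An important consequence used throughout the tests: in
an *unrelated* HWE sample the epistatic matrix G_AA is numerically close
to the identity, so additive-by-additive variance is confounded with the
residual; family structure (gene-dropped pedigrees) is what identifies
non-additive components, exactly as in the real nucleus-herd and
crossbred populations this kind of analysis targets. Repeatability
traits are simulated with a configurable number of records per animal
(the crossbred thermoregulatory data average roughly 15 records per
sow); repeated records require a positive permanent environmental
variance.

Default problem sizes in the tests and the acceptance script were
chosen as the smallest scales at which the quantities of interest are
identified with useful precision on a single desktop core: parameter
recovery uses 500 animals (100 founders, two gene-dropped generations)
by 2,000 SNPs with truth (σ²_a, σ²_d, σ²_aa, σ²_ε) = (0.3, 0.1, 0.2,
0.4) over 5 replicates; LR calibration uses 300 animals by 1,000 SNPs
over 20 replicates of 10-fold cross-validation; the null LRT uses 200
replicates of 120 animals by 300 SNPs.

## Quality control

Filters run in a single pass: individual call rate first (when
enabled), then SNP call rate, monomorphism, MAF and the 1-df χ²
Hardy-Weinberg test (no continuity correction), each evaluated on the
matrix entering that filter. Monomorphic SNPs are always removed — they
contribute nothing to any G denominator and break the dominance coding.
Common published thresholds (call rate 0.90, MAF 0.01, HWE p < 1e-5)
are the defaults. Remaining missing calls are mean-imputed (dosage 2p)
for matrix construction only.

## Known limitations

* Single-trait, Gaussian models only; categorical traits (scores) would
  need threshold models.
* No marker-effect (SNP-BLUP) equivalent formulation; matrices are
  dense, limiting n to desk scale (a few thousand animals).
* No residual weighting for records that are progeny means, and no
  single-step (pedigree + genomic) blending.
* The LR statistics are computed over masked animals with re-estimated
  partial variances; other conventions (all animals, fixed variances)
  exist and would give slightly different numbers.
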