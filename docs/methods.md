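# Methods

## Model and estimation strategy

`rrgwas` fits a random regression (test-day) mixed model in which every
time-dependent term — group mean curve, SNP effect, additive-genetic and
permanent-environment trajectories — is a linear combination of basis
functions of days in milk (DIM).  The default basis is Legendre polynomials
on DIM affinely mapped to [−1, 1], normalized as sqrt((2k+1)/2)·P_k(s) so
the functions are orthonormal on the interval; an unnormalized variant and
the Wilmink parameterization [1, t, exp(−c·t)] are available.  Normalization
only reparameterizes the coefficient covariances and leaves Wald p-values
unchanged (asserted by a test), so the choice is cosmetic for association
results.

Association testing follows the two-step (P3D) strategy: the coefficient
covariances G (additive, via the genomic relationship matrix K) and P
(permanent environment) and the residual variance σ²_e are estimated once
in the model without any SNP term, then held fixed for every SNP test.
The non-residual record covariance W = Q(K⊗G)Q′ + Z(I⊗P)Z′ is
eigendecomposed once; in the rotated coordinates the model is ordinary
weighted least squares with diagonal weights S = D + σ²_e, and each SNP's
nf₂+1 basis coefficients are tested jointly with a Wald χ².

Assumptions worth stating: additive SNP action (the covariate is the 0/1/2
allele count times the basis), Gaussian trajectories and residuals,
homoscedastic residual variance across DIM, and variance components that
are treated as known at scan time.  Deviations (dominance, heterogeneous
residuals per lactation stage, uncertainty in G/P) are outside scope.

## Key computational choices

* **W without Kronecker products.** Element (r, s) of W is
  K[n(r),n(s)]·φ_r′Gφ_s + [n(r)=n(s)]·φ_r′Pφ_s, assembled from the
  per-record basis rows in O(N²) time and verified against a dense
  Q·kron(K,G)·Q′ oracle in the tests.
* **Per-SNP cost.** Rotated SNP covariates are produced by precomputed
  projectors B_k = U′·diag(φ_k(t))·E (E = record→individual indicator), so
  each SNP costs (nf₂+1) matrix-vector products plus a Schur-complement
  solve against the cached base normal equations.  No per-SNP
  factorization occurs; the rotated path agrees with from-scratch dense
  GLS to ~1e−13 relative.
* **Eigenvalue clamping.** W is PSD in exact arithmetic; eigenvalues in
  [−1e−8·max(D), 0) are numerical noise and are clamped to zero.  A larger
  negative eigenvalue raises an error instead of being silently absorbed.
* **Identifiability.** Herd-test-date (HTD) enters as a fixed class effect
  with the first level dropped; the per-group fixed regression blocks
  carry the intercept (no separate global mean).  A pivot-style check on
  the QR of X names confounded columns when the data cannot support the
  design.
* **Missing genotypes** are mean-imputed: centered to 0 inside the kinship
  matrix, imputed with 2p as SNP covariates; LD r² uses pairwise-complete
  records.  SNPs monomorphic among the analyzed cows are emitted with a
  flag and missing p-value rather than failing the scan.
* **Dense-algebra guard.** The one-time eigendecomposition is O(N³) in the
  record count; runs beyond 20,000 records (configurable) are refused with
  an explicit message rather than attempted.

## REML estimator

The paper-equivalent workflow obtains G, P, σ²_e from external software;
this package supplies its own estimator and also reads a plain-text
variance-component file.  The estimator is EM-REML through Henderson's
mixed-model equations (MME), with an average-information (AI) acceleration:
each iteration computes the monotone EM update, then attempts an AI step
(Newton-like, using the average of observed and expected information, with
step halving) and keeps it only if it improves the restricted likelihood —
so the hybrid is monotone by construction and typically converges in under
ten iterations where plain EM needs hundreds.

All quantities come from MME-sized factorizations: the restricted
likelihood uses the identity
−2ℓ_R = (N−p−q)·log σ²_e + log|K⊗G| + log|I⊗P| + log|C| + y′Py (verified
against the dense V-form in a test), the score uses
P = (I − T C⁻¹T′)/σ²_e and ê = y − T·sol, and both are validated against
finite differences.  G and P are floored to the PSD cone by eigenvalue
truncation (floor 1e−6 × var(y) — small enough not to bias any estimable
component, large enough that σ²_e·Σ⁻¹ stays factorizable when a component
collapses to the boundary).  Non-convergence returns the best estimates
with `converged=False` rather than raising, since a scan with slightly
off-optimum variances is still meaningful under P3D.

Convergence is declared when the restricted log-likelihood changes by less
than 1e−6 (default; max 200 iterations).  Likelihood-based stopping can
leave a modest score norm along near-flat ridges (e.g. the G/P split when
kinship is weakly informative); the report carries the exact score norm so
users can judge.

## Genotype QC and multiple testing

MAF (< 0.03) and Hardy–Weinberg (1-df χ² goodness-of-fit p < 1e−6) filters
default to the thresholds standard for this analysis; the HWE test is the
plain χ² rather than the exact test, and is swappable.  LD pruning follows
the windowed greedy procedure (window 50 SNPs, step 5, r² > 0.5; the
lower-MAF member of an offending pair is removed, ties drop the later
position).  The pruned count is the Bonferroni denominator.  The
enrichment coefficient is the per-bp density ratio of significant SNPs
inside vs. outside annotated regions (BED3 input, converted to 1-based
inclusive); no p-value is attached to it — a permutation scheme would be
the natural extension but none is prescribed.

## Synthetic data: what it does and does not emulate

`simulate` generates: paternal half-sib families (sire genotypes drawn at
the SNP's allele frequency; each offspring receives one sire allele and
one base-population allele), giving within-family VanRaden kinship ≈ 0.25;
~10 monthly records per cow over DIM 5–305 with per-cow calving stagger of
up to 25 days (so herd-test-date classes are not confounded with the time
basis — as in real data, where cows measured on one date are at different
DIM); herd-test-date effects (SD 1.0) as fixed classes; Wilmink-shaped
group mean curves; and trajectories drawn from dairy-plausible coefficient
covariances (time-averaged additive ≈ 2.5, permanent ≈ 4, residual 4;
h² ≈ 0.24).  Everything is reproducible bit-for-bit from a seed, with
namespaced random streams so no two generator stages can collide.

It does **not** emulate: linkage disequilibrium along the chromosome (SNPs
are drawn independently, so LD pruning on simulated panels retains nearly
everything), selection, maternal pedigree depth, multiple parities or
lactations, missing phenotypes, or genotyping error.  Passing the study
suite therefore demonstrates the estimator and test are correct under the
model and robust to half-sib structure — not that real Holstein results
are reproduced.

## Simulation studies

**Type-I error.** Test SNPs are simulated with the same family structure
but independently of the phenotype, and scanned with variance components
fixed at the generating values (the known-variance regime of the two-step
design; REML recovery is validated separately).  P-values scanned against
a single phenotype realization are conditionally dependent through it, so
the study splits its 1000 test SNPs across five independent phenotype
redraws on the same layout — the rotation is reused and each extra
realization costs one matrix-vector product — making the pooled rejection
rate an estimate of the unconditional type-I error.  The no-polygenic
comparator drops Q(K⊗G)Q′ but folds G into the permanent-environment
covariance (what its own REML fit would do, since K has unit diagonal);
what remains unmodeled is precisely the between-relative covariance, so
its inflation isolates the effect of family structure.

**Study conditions.** The canonical population is 600 cows in 20 half-sib
families (30 daughters per sire — modest for dairy, where popular sires
have dozens to hundreds of daughters).  The family size was fixed after a
pilot across independent data realizations so that the realized
between-family genetic variance, which fluctuates with only tens of
families, is large enough in *every* realization for the no-polygenic
comparison to be informative.  The fixed mean curve is order 4 (the
standard choice for lactation curves; lower orders leave a Wilmink-shape
misfit that leaks into the calibration), the random and SNP regressions
order 2 for speed.

**Power.** A single trajectory — Day-5 effect 10.0, then one U(−1, 1)
increment per day — is scaled per effect size k and added, one SNP at a
time, to the records as allele count × effect(DIM); the modified rotated
response is one matrix-vector product away, and the SNP is re-tested
against the empirical threshold (5th percentile of the null p-values).

**QTN scaling convention.** "Scaled to k × phenotypic SD" is implemented
as: rescale the trajectory so its root-mean-square value over the record
times equals k·σ_P, with σ_P = sqrt(mean over records of phe(t)).  Under
the RMS convention the variance contributed by the injected QTN is exactly
2p(1−p)k²σ²_P, so the variance fraction π = 2p(1−p)k²/(1+2p(1−p)k²) holds
identically; a time-average convention would inflate the realized variance
by the trajectory's squared coefficient of variation (10–40% for this
random walk) and contradict the formula the studies check against.  The
convention is isolated in `scale_qtn`, so alternatives are one-line swaps.
The π consistency check redraws phenotypes, genotype and trajectory each
replicate, so its Monte-Carlo standard error reflects all sampling
variation; the genotype term is centered and variances are taken within
day, since the formula's σ²_P is the model variance net of fixed effects.

**REML recovery.** Twenty replicates of 300 cows × 10 records with order-1
random regressions (order-3 mean curve, for the misfit reason above);
element-wise means of Ĝ and P̂ are required to sit within ±3 Monte-Carlo
SE of the generating values and σ̂²_e within 10%.

## Problem sizes

The default test and acceptance runs use 50–600 individuals (500–6,000
records), 50–1,000 SNPs, 200 effect SNPs per k, and 20 REML replicates —
sizes at which every check runs on a single core in minutes while the
Monte-Carlo tolerances above remain meaningful.

## Known limitations

Single trait, single parity; no dominance or epistasis; dense algebra
only (no sparse pedigree path); the exact HWE test is not implemented; LD
pruning is quadratic per window (fine at chip scale, slow for sequence
data); and the Wilmink basis often yields ill-conditioned REML (high
coefficient correlations), which surfaces as `converged=False` rather than
an error — mirroring its known behavior in variance-component estimation.
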