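# Methods

## Model

`bmtme` fits a Gaussian mixed model for multi-trait, multi-environment plant
(or animal) breeding trials with replicated plots.  Let y<sub>ijk</sub> be the
L-vector of trait values for replicate k of line j in environment i
(i = 1..I, j = 1..J, k = 1..K).  Stacking observations environment-major with
traits innermost,

    Y = Xβ + Z1 b1 + Z2 b2 + e

* **β** (I·L entries, trait-major) — environment-by-trait means; the
  trait × environment interaction lives here.
* **b1 ~ N(0, G<sub>g</sub> ⊗ Σ<sub>t</sub>)** — additive genetic values per
  line and trait (the trait × genotype interaction), with G<sub>g</sub> the
  J×J genomic relationship matrix and Σ<sub>t</sub> the L×L genetic covariance
  among traits.
* **b2 ~ N(0, Σ<sub>E</sub> ⊗ G<sub>g</sub> ⊗ Σ<sub>t</sub>)** — the
  three-way trait × genotype × environment interaction;
  Σ<sub>E</sub> = diag(σ²<sub>E1</sub>…σ²<sub>EI</sub>) scales the interaction
  per environment and its diagonality encodes conditional independence of the
  interaction across environments.
* **e ~ N(0, I<sub>n</sub> ⊗ R<sub>e</sub>)** — plot residuals, correlated
  across traits within a plot through the L×L matrix R<sub>e</sub>.

The separable (Kronecker) structure keeps the three-way covariance
parsimonious: instead of the IJL(IJL+1)/2 parameters of an unstructured
covariance, only the factor matrices are estimated (G<sub>g</sub> is supplied).

### Priors

Weak informativity is achieved with the Huang–Wand scale-mixture family.
Under the inverse-Wishart convention
P(Ω) ∝ |B|^{κ/2} |Ω|^{−(κ+p+1)/2} exp(−tr(BΩ⁻¹)/2):

* β | σ²<sub>β</sub> ~ N(β0, σ²<sub>β</sub> Σ0), σ²<sub>β</sub> | a<sub>β</sub> ~
  IW(ν<sub>β</sub>, 2ν<sub>β</sub>/a<sub>β</sub>), a<sub>β</sub> ~ IG(1/2, 1/A²<sub>β</sub>);
* Σ<sub>t</sub> | a ~ IW(ν<sub>t</sub>+L−1, 2ν<sub>t</sub> diag(1/a<sub>l</sub>)),
  a<sub>l</sub> ~ IG(1/2, 1/A²<sub>l</sub>); likewise R<sub>e</sub> with
  (ν<sub>e</sub>, A<sub>el</sub>) and each σ²<sub>Ei</sub> with the scalar
  (p = 1) version.

Each implied prior standard deviation is Half-t(ν, A); at ν = 2 every prior
correlation is uniform on (−1, 1) — both properties are verified by
quantile/KS tests in the suite.  Defaults (ν = 2 everywhere, A = 100,000,
β0 = 0, Σ0 = 10,000·I) make all priors effectively flat on the data scale of
typical standardized traits; because the Half-t family is weakly informative
by construction, posterior inference is insensitive to A over several orders
of magnitude.

### Gibbs sampler

All full conditionals are conjugate, giving an exact 11-step Gibbs scan per
sweep (β; σ²<sub>β</sub>; a<sub>β</sub>; b1; b2; Σ<sub>t</sub>; a;
σ²<sub>Ei</sub>; a<sub>Ei</sub>; R<sub>e</sub>; a<sub>el</sub>).  The forms
worth noting:

* the Σ<sub>t</sub> conditional is IW with degrees of freedom
  ν<sub>t</sub>+L−1+J+I·J and scale
  2ν<sub>t</sub> diag(1/a) + B1ᵀG<sub>g</sub>⁻¹B1 + Σ<sub>i</sub> σ<sub>Ei</sub>⁻²
  B2<sub>i</sub>ᵀG<sub>g</sub>⁻¹B2<sub>i</sub> — both b1 and b2 inform
  Σ<sub>t</sub> because it appears in both Kronecker priors;
* the R<sub>e</sub> conditional adds the count of observation vectors to the
  degrees of freedom and the per-plot residual outer products to the scale;
* the b2 conditional factorizes into I independent (J·L)-blocks because
  Σ<sub>E</sub> is diagonal and every plot touches exactly one environment;
  the implementation exploits this, so a sweep costs a handful of (J·L)³/3
  Cholesky factorizations;
* 1×1 inverse-Wishart updates (σ²<sub>β</sub>, σ²<sub>Ei</sub>) are routed
  through the scalar identity IW(κ, B)|<sub>p=1</sub> = IG(κ/2, B/2) to avoid
  a degenerate matrix path.

Correctness of the full set of conditionals is certified by a
joint-distribution (Geweke-style) test: a chain alternating one Gibbs scan
with a redraw of the data given the parameters must match independent
prior/model draws in distribution.  Because the ν = 2 priors have no finite
variance, the comparison uses bounded statistics (correlations, v/(1+v) of
variances, tanh of fixed effects) with batch-means standard errors; all
statistics agree within 4 SE over 2×10⁴ sweeps at I=2, J=4, K=1, L=2 with
moderate scales (A = 1, Σ0 = I).

Three covariance structures are available for (Σ<sub>t</sub>, R<sub>e</sub>):
**unstructured** (full SPD), **diagonal** (per-trait variances, independent
Half-t priors), and **standard** (σ²·I with one Half-t scale).  At L = 1 the
three samplers target the same posterior, which the suite checks by comparing
posterior means across variants.

### Missing data

Observation vectors with every trait missing are excluded from the likelihood
entirely (their random effects are still drawn, shrunk through G<sub>g</sub>
and the trait covariances — that is what out-of-sample prediction uses).
A vector with only some traits missing would break the I<sub>n</sub> ⊗
R<sub>e</sub> conjugacy of the R<sub>e</sub> update if its rows were dropped,
so the missing traits are instead treated as latent: each sweep they are
redrawn from their conditional normal given the observed traits and current
parameters.  This is exact Gibbs for the marginal likelihood of the observed
entries and only ever activates for partially observed records (the CV2
situation); fully masked records never touch the chain.

### Numerics and defaults

* Chain defaults: 60,000 iterations, 30,000 burn-in, thinning fixed to 1
  (subsampling only wastes information when the target quantities are means).
* Initialization: β at environment-trait data means, random effects at 0,
  covariances at identity, auxiliaries at 1.  Deterministic; two chains with
  different seeds agree within Monte-Carlo error (tested).
* G<sub>g</sub> is symmetrized and, only if its Cholesky fails, jittered by
  10⁻⁶·mean(diag) on the diagonal; Σ<sub>t</sub> and R<sub>e</sub> are never
  silently regularized — a non-SPD conditional scale raises.
* All randomness flows from one `numpy` SeedSequence; CV folds and chains use
  derived child streams, so every result is bit-reproducible from (inputs,
  seed).
* Split-chain R̂ and a crude ESS are available on request
  (`split_rhat_ess`); chain length is fixed, not adaptive.

## Genomic relationship matrix

`compute_grm` implements the marker-frequency-centered cross-product
G = WWᵀ / (2Σ<sub>m</sub> p<sub>m</sub>(1−p<sub>m</sub>)), with W the 0/1/2
dosages centered at 2p<sub>m</sub> and p<sub>m</sub> the observed allele
frequency.  Both −1/0/1 and 0/1/2 input codings are accepted; markers are
filtered by missing fraction and minor-allele frequency (strict `<` on the
MAF threshold; zero-variance columns are always dropped) and then
mean-imputed per marker.

## Cross-validation and metrics

* **CV1** masks, per fold and environment, 20 % of the lines for all
  replicates — the situation of lines phenotyped in some environments but
  missing in others.  Masked units can be whole line-by-environment cells
  (all traits; default), single traits of a cell (`granularity="trait"`), or
  whole lines everywhere (`by_line`).  Within a fold the masked groups are
  disjoint across environments (and traits), so every tested line keeps I−1
  observed environments; when the groups can tile the lines the folds
  partition the maskable units exactly.
* **CV2** holds out one target trait in one whole environment per fold.
* Predictions are posterior means of the linear predictor
  Xβ + Z1b1 + Z2b2 at the masked cells (by linearity, identical to plugging
  posterior means into the predictor); no residual draw is added because the
  target is genetic merit, not a new plot measurement.
* Scoring: Pearson correlation and mean squared error of prediction (MSEP)
  per environment-trait combination within each fold over all masked records
  (replicates included), then mean ± SE (SD/√folds) across folds, plus an
  overall average row.  A zero-variance prediction vector yields a missing
  correlation for that fold (warned, excluded from the mean).
* Structures are compared by ranking each environment-trait row per
  criterion (1 = best; ties get the average of the spanned ranks) and
  averaging ranks per structure.

## Synthetic data

`simulate_dataset` draws directly from the generative model above with exact
Kronecker sampling (Cholesky factors of G<sub>g</sub>, Σ<sub>t</sub>,
R<sub>e</sub>).  Two study designs are built in:

* **Parameter recovery** — I = 3, L = 3, J = 80,
  β = [15, 8, 7, 12, 6, 7, 14, 9, 8] (environment-major), Σ<sub>t</sub> and
  R<sub>e</sub> with variances (0.60, 0.50, 0.70) / (0.15, 0.12, 0.13) and all
  pairwise trait correlations 0.85, Σ<sub>E</sub> = diag(0.65, 0.55, 0.75),
  G<sub>g</sub> = 0.7·I + 0.3·𝟙 (compound symmetry).  The reference scale is
  50 datasets with K = 20 and 20,000/10,000 MCMC; the package's desk-scale
  default, used by the acceptance script and tests, is 5 datasets, K = 5 and
  4,000/2,000 — K only sharpens the residual likelihood, so the estimands are
  unchanged and only Monte-Carlo spread grows.  The across-dataset SD of
  posterior means and the mean within-chain posterior SD are both reported,
  since "posterior SD" is ambiguous between the two.
* **CV comparison** — same design with Σ<sub>E</sub> = I and a common trait
  correlation (0.85 or 0.2) imposed on both Σ<sub>t</sub> and R<sub>e</sub>;
  one dataset per level, CV1 with 5 folds and 2,000/1,000 MCMC.  The
  experiment masks at trait granularity: with all traits of a cell masked the
  three-way effect of the masked cell is unidentifiable and (under the
  compound-symmetric G<sub>g</sub>, which carries no line-specific kinship
  information) prediction accuracy caps near
  √(0.7Σ<sub>t,ll</sub> / (0.7Σ<sub>t,ll</sub>(1+σ²<sub>Ei</sub>) + R<sub>e,ll</sub>))
  *independently of the trait correlation*; only trait-granularity masking
  lets accuracy grow with the between-trait correlation, which is the
  phenomenon the experiment exists to show.

### What the generator does and does not emulate

The generator produces balanced, complete, Gaussian three-way data with a
*known* kinship and exactly separable covariances.  Real trials add
incomplete blocks and spatial trends (no preadjustment is implemented here),
marker-estimated (noisy, low-rank) G<sub>g</sub>, unbalanced replication,
non-Gaussian traits, and covariances that need not factor as Kronecker
products.  Green tests therefore certify the sampler, the estimator algebra
and the CV machinery — not that the model is adequate for any particular
field dataset.

## Known limitations

* Posterior draws of b2 are stored densely; at the default 30,000 retained
  draws with J = 80 this is ≈170 MB (use the HDF5 store or shorter chains if
  memory-bound).
* Compound-symmetric kinship makes whole-line holdouts uninformative beyond a
  common shift; `by_line` CV1 is provided for completeness but is only
  meaningful with an informative (marker-derived) G<sub>g</sub>.
* The environment variance components σ²<sub>Ei</sub> are mildly
  overestimated at moderate replication — a property of the model/prior
  combination that the recovery experiment reproduces rather than corrects.
* No thinning, adaptive MCMC, marginal-likelihood computation, or
  non-Gaussian trait support.
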