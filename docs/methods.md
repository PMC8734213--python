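# Methods

## Model

For one genomic region (an ATAC peak window or a gene) and cells
i = 1..n, let a_i be the number of reads assigned to the maternal haplotype
and d_i the total number of haplotype-assignable reads.  The latent per-cell
allelic rate is modelled on the logit scale,

    u ~ N(1·α + Xβ, σ²K),      μ_i = sigmoid(u_i),
    a_i | μ_i, d_i ~ BetaBinom(μ_i/θ, (1−μ_i)/θ),

where α is homogeneous (pervasive) imbalance shared by all cells, X holds
optional fixed-effect covariates (e.g. donor one-hots), K = EEᵀ is a
cell-state kernel built from a low-dimensional representation E of total
counts, σ² scales heterogeneous (cell-state-specific) imbalance, and θ > 0
is extra-binomial overdispersion (the Beta-Binomial shape parameters μ/θ and
(1−μ)/θ keep the mean at μ for any θ).  Cells with d_i = 0 carry no
information about allelic rates and are excluded from all likelihoods; they
still receive rate predictions (below).

Three score tests are implemented:

* **het**:   H0: σ² = 0 (α, β, θ estimated under the null);
* **hom**:   H0: α = 0 (two-sided; intercept pinned to logit(r_base), β and
  θ estimated);
* **joint**: H0: α = 0 and σ² = 0, realised as the variance-component test
  on the augmented factor [s·1 | E].

The base rate r_base defaults to 0.5 (autosomes of a diploid); sex
chromosomes are excluded from counting by default because their base rate is
not well defined.

## Null-model fitting

Null models are maximised by Fisher scoring: Newton updates for (α, β) using
the exact Beta-Binomial score and a quasi-information curvature (the
Binomial-weighted information rescaled by the Beta-Binomial variance
inflation (1+dθ)/(1+θ)), alternated with safeguarded Newton steps for log θ.
Every step is accepted only if the exact log-likelihood does not decrease
(step halving), so the likelihood is non-decreasing across iterations.
Defaults: relative log-likelihood tolerance 1e−8, at most 100 iterations,
θ bounded to [1e−8, 1e3], initialisation from the pooled rate and a
method-of-moments overdispersion estimate.  Overdispersion is estimated per
region under each null.  Fitting is vectorised over batches of regions
sharing one design matrix, which is what makes the genome-scale workflows
and the parametric bootstrap cheap.

## Score statistics and their null distributions

With working residuals r_i = a_i − d_i μ̂_i from the fitted null, the
variance-component statistic is Q = rᵀEEᵀr and the homogeneous statistic is
U = Σ_i r_i.  Working residuals depend on the estimated nuisances only
through the fitted mean — a smooth, low-dimensional map — which keeps the
statistic's sampling distribution very close to its linearised form even in
small samples.  (An exact-score variant, using the digamma-based
Beta-Binomial score in place of r, was evaluated during development; its
nonlinear sensitivity to the refitted overdispersion produces a visible
second-order mismatch between the analytic null and a refitted parametric
bootstrap at n ≤ 100, so the working-residual form is used.)

Asymptotically Q ~ Σ_j λ_j χ²₁ with weights λ_j the eigenvalues of EᵀCE,
where C = Σ_r − DM⁻¹Dᵀ combines the exact Beta-Binomial residual variances
Σ_r = diag(d μ(1−μ)(1+dθ)/(1+θ)) with the projection of the estimated
nuisance directions: D holds the deterministic sensitivities
∂r_i/∂(α,β) = −d_i μ_i(1−μ_i)·[1, x_i] (and 0 for θ), and M is the exact
Fisher information of the nuisances, computed by enumerating the count
support of every cell (cross-information between the mean parameters and θ
included).  U's variance uses the same construction with E replaced by 1;
U²/Var(U) is referred to χ²₁.

Tail probabilities of the weighted-χ² mixture are computed by Imhof
characteristic-function inversion; a Lugannani–Rice saddlepoint
approximation takes over in the deep tail (below ~1e−6, where quadrature
loses precision), and Satterthwaite moment matching is the last-resort
fallback.  P-values are clipped to (1e−300, 1]; eigenvalues below
1e−10 of the largest are dropped.

### Small-sample null

Scores from shallow counts are strongly non-Gaussian: the exact second
cumulant of Q under the fitted null can be up to ~20% below the
Gaussian-score mixture value and the skewness substantially different.  For
≤ 500 observed cells and covariate-free nulls, the null distribution is
therefore refined:

* kernel rank ≤ 2: the linearised statistic is Q = ‖Σ_i F_i v_i‖² with
  v_i = (r_i, s_i, t_i) the per-cell residual and nuisance scores and F_i a
  known projection map; the characteristic function of the 2-D sum
  factorises over cells and is evaluated exactly on a grid from the
  enumerated per-cell distributions, and FFT inversion yields the null tail
  to roughly 1e−4 in probability (the far tail falls back to the mixture).
* higher rank: the exact second and third cumulants of the linearised
  statistic are computed from enumerated per-cell moments (to order six) and
  a three-moment shifted-gamma fit supplies the body of the null, blending
  back into the plain mixture in the upper range where the shifted support
  would distort it.

Both refinements vanish asymptotically; large-sample analyses use the plain
mixture.  A parametric bootstrap — simulate from the fitted null, refit,
recompute Q — is the independent oracle for the whole construction; measured
agreement on 60–100-cell instances with deep allelic totals is within ~2
bootstrap Monte-Carlo standard errors.  For ultra-sparse small samples
(mean allelic depth ≲ 2 at n ≲ 100) the analytic null remains approximate at
the few-percent level; the bootstrap is recommended there.

### Joint test weighting

The joint test augments the factor with an intercept column s·1.  The
column's scale fixes how the statistic balances homogeneous against
heterogeneous evidence: s² = trK/n (whole-kernel weight) favours homogeneous
signals, s² = trK/(nk) (per-column weight) favours heterogeneous ones.  The
compromise s = sqrt(trK/n)·k^(−0.29) is used, with the exponent calibrated
once on the power benchmark so that the homogeneous- and heterogeneous-side
power dilutions balance; the joint test then stays within a few points of
the better single test at both pure-signal extremes.

### Kernel standardisation

Embedding factors are centered per column and scaled so tr(K)/n = 1 before
testing (the workflow applies this by default; the kernels module returns
raw factors so that K = EEᵀ holds exactly as constructed).  Mixture p-values
are invariant to the overall kernel scale, and the score-test projection
removes the intercept direction, so standardisation mainly makes variance
scales comparable across kernels.  Cluster, lineage-contrast and polynomial
time factors are used raw.

## Allelic rate estimation

For regions with heterogeneous imbalance the Beta-Binomial likelihood is
replaced by a Gaussian likelihood on empirical rates y_i = a_i/d_i (the
field is modelled on the rate scale, not the logit scale; reported
posterior means are clipped to [0, 1] with the raw field kept alongside).
Noise is heteroscedastic with variance σ_n²/d_i — rates from deeper cells
are more precise, following the binomial-proportion variance argument.  The
mean is α (+ covariates); the covariance is a linear kernel σ_k²·EEᵀ.
Inference is collapsed sparse variational GP regression with at most 1000
inducing points chosen as seeded k-means centers of the observed cells in
cell-state space; hyperparameters (α, β, log σ_k², log σ_n²) maximise the
collapsed bound by L-BFGS-B, whose line search makes the recorded bound
trace non-decreasing.  With a linear kernel any inducing set spanning the
factor's column space reproduces dense GP regression exactly, so the
inducing points bound cost rather than accuracy; the full-inducing-set
configuration is verified against a dense GP oracle to 1e−4.  Cells with
d = 0 receive posterior predictions; a cell orthogonal to all observed
cell states reverts to the fitted mean α.

Effect size: Qdiff10 is the difference between the 90% and 10% quantiles of
the estimated per-cell rate field — the rate contrast between the most
extreme cell populations.

## Workflows

Per-region tests are BH-adjusted per test family; a lineage scan (one
single-lineage indicator kernel per lineage, contrasting that lineage's mean
rate against all other cells) forms one combined family across regions and
lineages; NA p-values (regions with < 2 observed cells) are excluded from
the BH denominator.  The pseudotime scan restricts to one lineage's cells,
uses the polynomial basis (E_time)_ij = t_i^(j−1), j = 1..degree (default
3), and keeps regions with within-lineage mean allelic total ≥ 0.1 — the
same inclusive threshold as the global accessibility filter (the
within-lineage filter direction is stated inconsistently in some
descriptions of this procedure; "keep accessible regions" is the
interpretation adopted).  The within-group permutation diagnostic shuffles
factor rows within donors and checks calibration with and without donor
one-hot covariates (first level dropped so the design stays full rank).

## Haplotype-aware counting

Reads from a coordinate-sorted SAM/BAM with cell barcodes (default tag CB)
are assigned through the phased heterozygous SNVs they cover: at least one
covered variant is required; among several, one is chosen uniformly at random
with an rng seeded per read name (so assignment is order-independent and
reproducible); the read's base at that position decides maternal vs
paternal, with mismatches to both alleles leaving the read unassigned.
The maternal allele is the first allele of the phased genotype (M|P).
Internally coordinates are BED-style 0-based half-open; VCF positions are
converted on read.  A read counts toward every window it overlaps by any
amount.  PCR duplicates, secondary/supplementary alignments and unknown
barcodes are skipped; malformed records are counted and skipped with a
warning.  Regions keep/drop by mean allelic total count across cells with
an inclusive ≥ 0.1 boundary.

## Cell-state VAE

The VAE models binarized accessibility x_ij with a size-factor-adjusted
Bernoulli likelihood p(x_ij = 1) = 1 − (1 − ρ_ij)^{l_i}: if l_i were the
integer read count, this is the probability of at least one read hitting
peak j.  The size factor is treated as observed (per-cell total count), and
its per-batch log-normal prior parameters are the maximum-likelihood
estimates of the log totals (variance floored at 1e−6).  Peak activities
ρ_i are independent sigmoids of the decoder output (no sum-to-one
constraint; the normalisation hinted at in some descriptions of this model
family is incomplete and independent activities are the interpretation
adopted).  Batch one-hots feed both encoder and decoder so the latent space
integrates batches.  Coarse collection times y_i ∈ {1..t} couple to the
latent space through an ordinal probit likelihood
p(y|z) = Φ(w_y − f_y(z)) − Φ(w_{y−1} − f_y(z)) with w_0 = −∞, w_t = ∞,
strict threshold ordering enforced by parameterising gaps as exponentials,
and a linear pseudotime map f_y.  Training is amortised variational
inference (reparameterisation trick) with hand-derived gradients and Adam;
encoder and decoder have two hidden layers of width 128 (tanh); defaults:
latent dimension 8, 30 epochs, learning rate 1e−3, batch size 128, time-loss
weight 1.0.  The implementation is pure numpy.  This module is optional: the
tests accept any externally produced embedding.

## Synthetic data

The generators emulate the statistical structure of the data the model was
designed for, not any particular organism:

* cell states: an 8-dimensional Gaussian-mixture embedding with 24
  components standing in for discrete cell types, a per-cluster baseline
  developmental time with the continuous time signal embedded in the first
  latent dimension;
* allelic totals: zero-inflated negative binomial counts (zero inflation
  0.4, shape 1.5) calibrated to a target mean allelic total, default 1.0 —
  within the 0.1–2 range typical of haplotype-assignable single-cell ATAC
  coverage.  Small-instance oracle checks use deeper totals (mean 15, zero
  inflation 0.2), emulating full-length scRNA allelic counts where
  60–100-cell analyses arise in practice;
* counts: drawn from the generative model above, with per-region
  α ~ N(0, ρν²) and σ² = (1−ρ)ν² following the printed generative
  convention in which ρ multiplies the homogeneous variance (a
  `rho_is_het_fraction` flag flips the convention, and the power sweeps
  use the heterogeneous-fraction parameterisation for readability);
  simulation kernels are trace-normalised by default (flag-controlled);
* binary accessibility for the VAE: four latent factors, one tied to a
  uniform latent time, mapped through random loadings to ~20%-dense binary
  profiles with batch-specific depth and offsets.

What passing these benchmarks shows is that the inference machinery is
correct and calibrated under the model's own assumptions at realistic
sparsity; it does not certify robustness to features real data may add
(mapping bias surviving upstream filters, genotyping errors, cell-state
representations correlated with allelic rates through technical artefacts,
non-linear batch effects).

## Benchmark problem sizes

Calibration: 1000 regions × 2000 cells per overdispersion level
(θ ∈ {2, 5}); the heterogeneity-test null draws pervasive imbalance
α ~ N(0, 0.05), which its free intercept must absorb.  Power sweeps: 200
regions × 2000 cells × 12 seed replicates per grid point at ν² = 0.05.
Baseline miscalibration: 300 regions for the OLS-LRT at 24 cluster
dimensions and 250 observed cells.  Oracle agreement: 30 instances,
20,000 bootstrap draws each.  Recovery: 25 replicates at 5000 cells
(pervasive imbalance α = 0.5 recovered at low overdispersion θ = 0.1;
θ ∈ {2, 5} recovered at the study levels).  Donor diagnostic: 400 regions ×
1500 cells × 20 donors with donor embedding offsets (s.d. 1.2 of the
within-donor spread) and donor rate offsets (s.d. 0.3 on the logit scale).

## Known limitations

* The analytic null for ultra-sparse small samples (n ≲ 100 cells at mean
  allelic depth ≲ 2) is accurate only to a few percent in p; use the
  parametric bootstrap there.
* The Gaussian rate-field model ignores the discreteness of shallow counts;
  its posteriors are for visualisation and effect-size estimation, not
  testing.
* The joint test's intercept weighting is a fixed compromise, not an
  adaptive combination (no SKAT-O-style ρ-grid search).
* The VAE is a compact CPU implementation intended for tens of thousands of
  cells and a few thousand peaks, not GPU-scale corpora.
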