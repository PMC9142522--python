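# Methods

## The bleed model

A raw slide consists of `K` spots: `K_t` tissue spots and `K_b = K - K_t`
background spots. Background spots carry no true expression; every read they
collect was swapped in from tissue. For gene `g` in tissue spot `t` with
true expression `mu[g,t]`, the observed count at spot `j` is a superposition
of independent Poisson components:

    stay:   S[g,t]   ~ Poisson( mu[g,t] (1 - r_beta) )
    bleed:  B[g,t,j] ~ Poisson( mu[g,t] r_beta [ (1 - r_gamma) w[t,j] + r_gamma / K ] )

so `X[g,j] ~ Poisson(eta[g,j])` with `eta = mu @ A` and transfer rates

    A[t,j] = (1 - r_beta) 1{t=j} + r_beta [ (1 - r_gamma) w[t,j] + r_gamma / K ].

Assumptions worth stating explicitly:

- **Global rates.** One `(r_beta, r_gamma, sigma)` triple per slide; the
  model does not allow gene- or region-specific bleeding.
- **Independent Poisson counts.** No overdispersion beyond what the latent
  spatial structure in `mu` induces.
- **Kernel-shaped proximal bleed.** Proximal weights are a normalized
  distance kernel; the Gaussian family is the default and the fitting
  assumption, with linear / Laplace / Cauchy families available as
  *generating* kernels for robustness experiments.
- **Self-exclusion.** `w[t,t] = 0` and the kernel normalization runs over
  `j' != t`: the bled component consists of reads that leave their spot. The
  uniform distal term `r_gamma / K` runs over all `K` spots including the
  source, which makes every row of `A` sum to exactly one, so expected reads
  are conserved. (Whether the original normalization includes the self spot
  is ambiguous; we chose exact conservation.)
- **Distances** are Euclidean in image pixels as given by the positions
  file. No scale-factor metadata is needed because distances only enter
  ratios with the fitted bandwidth.

## Parameter estimation

**Global stage.** Summing over genes, per-spot totals obey
`X_tot[j] ~ approx Poisson(eta_tot[j])` with `eta_tot = mu_tot @ A`. We
minimize `sum_j (X_tot[j] - eta_tot[j])^2` jointly over
`(r_beta, r_gamma, mu_tot)` with L-BFGS-B under box constraints
(`r in [0,1]`, `mu_tot >= 0`) and analytic gradients (`eta` is linear in
`mu_tot` and bilinear in the rates), for each candidate `sigma` on a grid;
the `sigma` with smallest RSS wins, ties to the smallest value. Choices:

- **Initial values** (the problem is not convex): `mu_tot` starts at the
  tissue totals scaled up to the slide's grand total; `r_beta` starts at
  (mean background total) / (mean total over all spots); `r_gamma` starts at
  the mean of the 25th–50th-percentile band of background totals over the
  background mean, clipped to [0,1]. The percentile band uses ascending
  ranks `[floor(0.25 K_b), floor(0.5 K_b))`.
- **sigma grid**: `{1/3, 1/2, 1, 3/2, 2, 3}` times the median
  nearest-neighbor spot distance, making the grid invariant to image
  resolution.
- **Scaling.** The totals are normalized to mean one inside the optimizer
  (the RSS is equivariant under joint rescaling of `X` and `mu`). Without
  this, deep slides put the `mu` block and the rate block of the gradient on
  wildly different scales and L-BFGS-B stalls far from the optimum; with it,
  convergence is depth-independent. Outputs are rescaled back.
- **Stopping**: relative objective change below 1e-8 or 200 iterations per
  grid point. The reported optimum never exceeds the RSS of the initial
  point (descent contract).
- **Totals** are computed over the selected gene set, since the model is
  defined on that set.

**Identifiability.** With zero background spots there are more free
parameters than observations and contamination is confounded with
expression: the fit raises. Below 25% background it warns
(`strict_background` upgrades this to an error).

**EM stage.** Given the fitted globals, independent Poisson components
conditioned on their sum are multinomial with probabilities proportional to
their rates, so the E-step attributes `X[g,j]` to source `t` with
responsibility `mu[g,t] A[t,j] / eta[g,j]` and the M-step is

    mu_next[g,t] = sum_j X[g,j] mu[g,t] A[t,j] / eta[g,j]

(using unit row sums of `A`). Consequences used as test invariants: each
gene's total is conserved exactly at every iteration, and the observed-data
log-likelihood is non-decreasing. Initialization scales each gene's tissue
counts up to its total over all spots (genes with zero tissue signal start
uniform across tissue spots; all-zero genes are skipped and output as
zeros). Convergence is elementwise — mean absolute relative change of `mu`
below 1e-4, capped at 30 iterations — because conservation makes totals
uninformative. These defaults are declared choices of this package.

The per-spot contamination rate is evaluated at the EM limit:

    c_t = [ sum_g sum_{t' != t} mu[g,t'] r_beta ((1-r_gamma) w[t',t] + r_gamma/K) ]
          / [ sum_g eta[g,t] ]

which lies in [0,1] by construction; a zero denominator yields 0 with a
warning.

**Gene selection.** Default: union of genes with mean tissue expression
above 1 UMI/spot and the top 2000 by standardized variance. The
standardized variance uses a quadratic fit of log10 variance on log10 mean
as the mean–variance trend, standardizes counts by the trend-expected
standard deviation with clipping at sqrt(K_t), and ranks genes by the
variance of the standardized values. This is a self-contained
variance-stabilized ranking in the spirit of the common
`FindVariableFeatures`-style selection; an explicit gene list overrides it.
Genes outside the selected set pass through the export unchanged.

## The synthetic-data generator

`synth_slide` emulates a raw slide: a rectangular lattice (default pitch
100 px; Visium's hexagonal offsets change nothing structural for the model,
which only consumes pairwise distances), a centered contiguous rectangular
tissue region (default half the lattice; above 75% tissue it warns), and
spatially structured expression: per-gene lognormal baselines (sigma 1.5,
matching the heavy right skew of real expression) modulated alternately by
elevated rectangular blocks (3–8x) or smooth linear gradients, scaled so
the mean total per tissue spot equals a target (default 20,000 UMIs — a
typical Visium spot depth; the gene count, default 300, is scaled down for
tractability, so per-gene depth is higher than a real panel's).
`simulate_contamination` computes `eta` under any kernel family and draws
`X ~ Poisson(eta)`. `simI_preprocess` instead derives simulation inputs
from an existing slide: top-3000 genes by total UMI, moment-rule rates, and
bandwidth 10 px.

What the generator does **not** emulate: overdispersion beyond Poisson,
segmentation errors in the tissue mask, platform-specific artifacts
(diffusion anisotropy, fiducial regions), or empty-droplet-style ambient
profiles. Passing benchmarks on these slides therefore demonstrates
correctness of the estimator under its own model class and robustness to
kernel shape — not performance on any particular real tissue.

## Benchmarks computed by the test suite and acceptance script

- Full-pipeline MSE reduction on Gaussian-kernel contaminated slides
  (30x30 spots, 60% tissue, 300 genes, `r_beta=0.3, r_gamma=0.1,
  sigma=200 px`), median over three seeds — the acceptance script reports
  this number.
- Global parameter recovery over `r_beta in {0.1, 0.3, 0.5} x r_gamma in
  {0.05, 0.2}` on 20x20 slides (a size chosen to keep the suite fast; the
  estimator's cost is dominated by `K_t x K` matrix products).
- EM–oracle agreement on a 2-gene, 3-tissue + 2-background instance versus
  direct numerical maximization of the observed-data likelihood.
- Conservation, likelihood monotonicity and analytic-gradient correctness
  as property tests on random instances.
- Direction-only robustness: linear/Laplace/Cauchy generating kernels,
  Gaussian fitting, decontaminated MSE strictly below raw.

## Known limitations

- Dense `K_t x K` weight and transfer matrices: memory grows as
  `K_t * K`; fine for Visium-scale slides (~5k spots), not for
  bead-resolution platforms with hundreds of thousands of barcodes.
- Deconvolution amplifies shot noise: at very shallow depth (a few UMIs per
  gene per spot) the EM estimate can be noisier than the raw counts even
  though the contamination bias is removed. The benefit grows with depth
  and with the sharpness of spatial structure.
- The totals-based global fit assumes the selected gene set dominates the
  slide's counts; pathological gene sets (a handful of low-count genes) can
  make `r_beta` poorly determined.
- Reader supports Matrix Market + TSV/CSV layouts (plain or gzip); HDF5
  feature-barcode matrices are out of scope.
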