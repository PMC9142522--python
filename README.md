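# debleed

**Correction of spot swapping (local mRNA bleed) on spatial transcriptomics
slides.**

On barcoded-spot platforms such as 10x Visium, transcripts released from the
tissue above one spot can diffuse and bind the capture probes of nearby
spots — *spot swapping*. The result is contaminated UMI counts: background
spots (not covered by tissue) show substantial signal, and tissue spots
receive reads that originated elsewhere. `debleed` estimates the extent of
this contamination directly from a **raw (unfiltered)** slide and recovers
decontaminated per-spot expression. It is aimed at anyone analyzing raw
spatial count matrices who wants expression estimates, marker patterns, or
downstream clustering that are not blurred by local bleed.

## Model

Let `K` spots comprise tissue spots `I_t` (count `K_t`) and background spots
`I_b`. For gene `g` and tissue spot `t` with true expression level
`mu[g,t]`, observed counts arise as a superposition of independent Poisson
components:

- reads that stay: `S[g,t] ~ Poisson(mu[g,t] * (1 - r_beta))`
- reads bleeding from `t` to any spot `j`:
  `B[g,t,j] ~ Poisson(mu[g,t] * r_beta * ((1 - r_gamma) * w[t,j] + r_gamma / K))`

where `r_beta` is the global **bleeding rate**, `r_gamma` the **distal
contamination rate** (bled reads spread uniformly over the slide), and
`w[t,j]` are Gaussian-kernel weights
`w[t,j] = exp(-d[t,j]^2 / 2 sigma^2) / sum_j' exp(-d[t,j']^2 / 2 sigma^2)`
over pixel distances `d[t,j]`, with bandwidth `sigma`. Observed counts are
`X[g,j] ~ Poisson(eta[g,j])` with `eta = mu @ A` for the transfer matrix
`A[t,j] = (1-r_beta)·1{t=j} + r_beta((1-r_gamma) w[t,j] + r_gamma/K)`,
whose rows sum to one (reads are conserved in expectation).

Estimation is in two stages:

1. **Global fit** — `(r_beta, r_gamma, sigma, {mu_tot[t]})` minimize the
   residual sum of squares between observed per-spot totals and their model
   expectation, by box-constrained L-BFGS-B with analytic gradients over a
   grid of candidate `sigma`.
2. **EM decontamination** — given the fitted globals, per-gene expression
   `mu[g,t]` is estimated by EM on the Poisson superposition (independent
   Poisson components conditioned on their sum are multinomial), which
   conserves each gene's total reads exactly and has monotone likelihood.

A per-spot contamination rate `c_t` (expected bleed-in received over the
spot's expected total) is reported alongside.

## Worked example

```python
from debleed import SpotBleedCorrector
from debleed.simulate import synth_slide, simulate_contamination, mse

# a 30x30-spot slide, 60% tissue, 300 spatially patterned genes,
# contaminated at r_beta=0.3, r_gamma=0.1, sigma = 2x spot pitch
truth, geometry = synth_slide(30, 30, 300, tissue_fraction=0.6, seed=1)
sim = simulate_contamination(truth, geometry, "gaussian",
                             r_beta=0.3, r_gamma=0.1, sigma=200.0, seed=1)

est = SpotBleedCorrector(gene_list=sim.observed.gene_ids)
mu_hat = est.fit_transform((sim.observed, geometry))
print(f"r_beta={est.r_beta_:.3f} r_gamma={est.r_gamma_:.3f} sigma={est.sigma_:.0f}")

raw = sim.observed.counts[:, geometry.tissue_indices]
print(f"MSE raw {mse(truth, raw)[1]:.1f} -> decontaminated {mse(truth, mu_hat)[1]:.1f}")
```

prints

```
r_beta=0.300 r_gamma=0.100 sigma=200
MSE raw 463.1 -> decontaminated 129.8
```

The fitted bleeding rate, distal rate and bandwidth match the generating
values, and the decontaminated matrix is roughly 3.5x closer to the true
expression (in mean squared error) than the raw contaminated counts.

The same pipeline is available from the shell on Visium-style raw
directories (Matrix Market counts, barcode/feature TSVs, tissue-positions
CSV in either the headerless v1 or headered v2 dialect, plain or gzip):

```sh
debleed simulate --output slide/ --seed 1
debleed decontaminate --input slide/ --output cleaned/
debleed diagnose --input slide/ --truth slide/truth.mtx
```

## Limitations

With no background spots the model is unidentifiable (contamination is
confounded with expression) and the fit refuses to run; below 25%
background it warns. See `docs/methods.md` for modeling details, parameter
defaults, and what the synthetic benchmark does and does not establish.
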