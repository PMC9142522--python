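"""EM decontamination of per-gene, per-spot expression.

Observed counts decompose as a superposition of independent Poisson
components: reads staying at their spot of origin plus bleed-ins from every
tissue spot.  Conditional on their sum, independent Poisson counts are
multinomial with probabilities proportional to their rates, so the E-step
splits each observed count X[g, j] among candidate source spots t with
responsibility mu[g, t] * a[t, j] / eta[g, j], and the M-step re-estimates

    mu_next[g, t] = sum_j X[g, j] * mu[g, t] * a[t, j] / eta[g, j]

(using that the rows of the transfer matrix ``a`` sum to one).  This
conserves each gene's total reads exactly at every iteration and the
observed-data log-likelihood is non-decreasing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .containers import SlideCounts, SpotGeometry
from .fitting import GlobalContaminationParams
from .kernels import MixingModel

__all__ = [
    "DecontaminationResult",
    "select_genes",
    "em_step",
    "poisson_loglik",
    "decontaminate",
    "spot_contamination_rate",
]


@dataclass
class DecontaminationResult:
    """Decontaminated expression with convergence diagnostics."""

    mu_hat: np.ndarray                 # genes x K_t
    gene_ids: np.ndarray
    barcodes: np.ndarray               # tissue barcodes
    contamination_rate: np.ndarray     # length K_t, in [0, 1]
    iterations: int
    loglik_trace: np.ndarray
    params: GlobalContaminationParams
    converged: bool = True
    decontaminated_mask: np.ndarray | None = field(default=None)


def select_genes(tissue_counts: np.ndarray, gene_ids: np.ndarray,
                 mean_threshold: float = 1.0, n_top: int = 2000) -> np.ndarray:
    """Default gene set: highly expressed, highly variable, or both.

    Highly expressed means mean tissue expression above ``mean_threshold``
    UMIs per spot.  Highly variable means top ``n_top`` by standardized
    variance: per-gene counts are standardized by the variance expected at
    their mean under a smooth mean-variance trend (a quadratic fit of
    log10 variance on log10 mean), clipped at sqrt(K_t), and ranked by the
    variance of the standardized values.  All-zero genes are never selected.
    """
    tissue_counts = np.asarray(tissue_counts, dtype=float)
    gene_ids = np.asarray(gene_ids, dtype=object)
    n_genes, n_spots = tissue_counts.shape
    means = tissue_counts.mean(axis=1)
    variances = tissue_counts.var(axis=1, ddof=1) if n_spots > 1 else np.zeros(n_genes)

    expressed = means > mean_threshold

    positive = (means > 0) & (variances > 0)
    variable = np.zeros(n_genes, dtype=bool)
    if positive.sum() >= 3:
        log_mean = np.log10(means[positive])
        log_var = np.log10(variances[positive])
        coeffs = np.polyfit(log_mean, log_var, deg=min(2, positive.sum() - 1))
        expected_sd = np.sqrt(10.0 ** np.polyval(coeffs, log_mean))
        z = (tissue_counts[positive] - means[positive, None]) / expected_sd[:, None]
        z = np.clip(z, -np.sqrt(n_spots), np.sqrt(n_spots))
        std_var = z.var(axis=1, ddof=1)
        order = np.argsort(std_var)[::-1][: min(n_top, len(std_var))]
        variable[np.flatnonzero(positive)[order]] = True
    elif positive.any() and n_top > 0:
        # too few genes to anchor a trend: rank by raw variance
        idx = np.flatnonzero(positive)
        order = np.argsort(variances[idx])[::-1][: min(n_top, len(idx))]
        variable[idx[order]] = True

    selected = expressed | variable
    if not selected.any():
        raise ValueError(
            "default gene selection is empty; pass an explicit gene list or "
            "lower mean_threshold"
        )
    return gene_ids[selected]


def em_step(mu_current: np.ndarray, observed_counts: np.ndarray,
            transfer: np.ndarray) -> np.ndarray:
    """One E+M update of the per-gene source intensities.

    ``mu_current`` is genes x K_t, ``observed_counts`` genes x K and
    ``transfer`` K_t x K with unit row sums.
    """
    mu = np.asarray(mu_current, dtype=float)
    x = np.asarray(observed_counts, dtype=float)
    eta = mu @ transfer
    impossible = (eta == 0.0) & (x > 0.0)
    if impossible.any():
        g, j = np.argwhere(impossible)[0]
        raise ValueError(
            f"observed count X[{g}, {j}] = {x[g, j]:g} has zero model "
            "intensity: the current mu cannot explain the data"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(eta > 0.0, x / np.where(eta > 0.0, eta, 1.0), 0.0)
    return mu * (ratio @ transfer.T)


def poisson_loglik(mu: np.ndarray, observed_counts: np.ndarray,
                   transfer: np.ndarray) -> float:
    """Observed-data Poisson log-likelihood (with the log X! term)."""
    x = np.asarray(observed_counts, dtype=float)
    eta = np.asarray(mu, dtype=float) @ transfer
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(x > 0.0, x * np.log(np.where(eta > 0.0, eta, 1.0)), 0.0)
        term = np.where((x > 0.0) & (eta == 0.0), -np.inf, term)
    return float(term.sum() - eta.sum() - gammaln(x + 1.0).sum())


def _initial_mu(x: np.ndarray, tissue_cols: np.ndarray) -> np.ndarray:
    """Tissue counts scaled per gene so each gene's total matches the total
    over all spots; genes with zero tissue signal start uniform."""
    n_t = len(tissue_cols)
    mu0 = x[:, tissue_cols].astype(float).copy()
    gene_totals = x.sum(axis=1)
    tissue_totals = mu0.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(tissue_totals > 0.0, gene_totals / np.where(
            tissue_totals > 0.0, tissue_totals, 1.0), 0.0)
    mu0 *= scale[:, None]
    orphan = (tissue_totals == 0.0) & (gene_totals > 0.0)
    mu0[orphan] = gene_totals[orphan, None] / n_t
    return mu0


def decontaminate(slide: SlideCounts, geometry: SpotGeometry,
                  params: GlobalContaminationParams,
                  gene_set: np.ndarray | None = None,
                  tol: float = 1e-4, max_iter: int = 30) -> DecontaminationResult:
    """Estimate true expression mu[g, t] by EM under the fitted bleed model.

    Convergence is elementwise (per-gene totals are conserved by
    construction, so totals are uninformative): the iteration stops when the
    mean absolute relative change of mu drops below ``tol`` or after
    ``max_iter`` iterations.
    """
    if slide.n_spots != geometry.n_spots:
        raise ValueError("counts and geometry have different spot counts")
    gene_ids = slide.gene_ids
    counts = slide.counts
    if gene_set is not None:
        mask = np.isin(gene_ids, np.asarray(gene_set, dtype=object))
        if not mask.any():
            raise ValueError("gene_set matches no gene in the slide")
        gene_ids = gene_ids[mask]
        counts = counts[mask]
    x = counts.astype(float)

    model = MixingModel.from_geometry(geometry, params.sigma, params.kernel)
    transfer = model.transfer(params.r_beta, params.r_gamma)
    tissue_cols = geometry.tissue_indices

    live = x.sum(axis=1) > 0.0  # zero-total genes stay all-zero
    mu = np.zeros((x.shape[0], len(tissue_cols)))
    mu[live] = _initial_mu(x[live], tissue_cols)

    loglik = [poisson_loglik(mu[live], x[live], transfer)]
    if not np.isfinite(loglik[0]):
        raise RuntimeError("non-finite log-likelihood at initialization")
    converged = False
    iterations = 0
    for iteration in range(1, max_iter + 1):
        mu_next = mu.copy()
        mu_next[live] = em_step(mu[live], x[live], transfer)
        ll = poisson_loglik(mu_next[live], x[live], transfer)
        if not np.isfinite(ll):
            raise RuntimeError(f"non-finite log-likelihood at iteration {iteration}")
        loglik.append(ll)
        delta = np.abs(mu_next - mu)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.where(mu > 0.0, delta / np.where(mu > 0.0, mu, 1.0), 0.0)
        mu = mu_next
        iterations = iteration
        if rel.mean() < tol:
            converged = True
            break

    c_t = spot_contamination_rate(mu, model, params.r_beta, params.r_gamma)
    return DecontaminationResult(
        mu_hat=mu,
        gene_ids=gene_ids,
        barcodes=geometry.barcode[tissue_cols],
        contamination_rate=c_t,
        iterations=iterations,
        loglik_trace=np.asarray(loglik),
        params=params,
        converged=converged,
        decontaminated_mask=live,
    )


def spot_contamination_rate(mu_hat: np.ndarray, model: MixingModel,
                            r_beta: float, r_gamma: float) -> np.ndarray:
    """Per-tissue-spot contamination rate: expected bleed-in received from
    other tissue spots over the spot's expected contaminated total."""
    mu_hat = np.asarray(mu_hat, dtype=float)
    mu_tot = mu_hat.sum(axis=0)                        # length K_t
    bleed = model.bleed_rates(r_beta, r_gamma)         # K_t x K
    transfer = model.transfer(r_beta, r_gamma)
    tissue_cols = model.tissue_cols

    eta_tot = mu_tot @ transfer                        # length K
    received = mu_tot @ bleed[:, tissue_cols]          # from all tissue sources
    n_t = len(tissue_cols)
    received -= mu_tot * bleed[np.arange(n_t), tissue_cols]  # drop self source

    denom = eta_tot[tissue_cols]
    zero = denom == 0.0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} tissue spot(s) have zero expected total; "
            "their contamination rate is reported as 0",
            UserWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        c_t = np.where(zero, 0.0, received / np.where(zero, 1.0, denom))
    return np.clip(c_t, 0.0, 1.0)
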