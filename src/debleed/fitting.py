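"""Global contamination-parameter estimation.

The bleeding rate ``r_beta``, distal contamination rate ``r_gamma`` and the
kernel bandwidth ``sigma`` are global slide properties.  They are estimated
by minimizing the residual sum of squares between the observed per-spot
total counts (over the selected gene set) and their model expectation

    eta[j] = sum_t mu_tot[t] * a[t, j]

jointly over (r_beta, r_gamma, {mu_tot[t]}) with box constraints, per
candidate sigma on a grid; the sigma attaining the smallest RSS wins.
Gradients are analytic: eta is linear in mu_tot and bilinear in the rates.

Background spots are essential.  With no background, contaminated expression
is confounded with true expression and the problem is unidentifiable; with
under 25% background the fit proceeds but warns that estimates may be
unreliable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .containers import SlideCounts, SpotGeometry
from .kernels import MixingModel, median_nn_distance, mixing_matrix

__all__ = [
    "GlobalContaminationParams",
    "initial_bleed_rate",
    "initial_distal_rate",
    "expected_totals",
    "rss_and_gradients",
    "fit_global_params",
    "DEFAULT_SIGMA_MULTIPLIERS",
]

DEFAULT_SIGMA_MULTIPLIERS = (1 / 3, 1 / 2, 1.0, 3 / 2, 2.0, 3.0)

MIN_BACKGROUND_FRACTION = 0.25


class BackgroundFractionWarning(UserWarning):
    """Raised when fewer than 25% of spots are background."""


@dataclass
class GlobalContaminationParams:
    """Fitted global parameters of the bleed model."""

    r_beta: float
    r_gamma: float
    sigma: float
    mu_totals: np.ndarray
    rss: float
    sigma_grid_trace: list = field(default_factory=list)
    kernel: str = "gaussian"

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_beta <= 1.0:
            raise ValueError(f"r_beta outside [0, 1]: {self.r_beta}")
        if not 0.0 <= self.r_gamma <= 1.0:
            raise ValueError(f"r_gamma outside [0, 1]: {self.r_gamma}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive: {self.sigma}")
        self.mu_totals = np.asarray(self.mu_totals, dtype=float)


def check_background(geometry: SpotGeometry, strict: bool = False) -> None:
    """Warn (or raise) when background spots are too scarce for a reliable fit."""
    if geometry.n_background == 0:
        raise ValueError(
            "no background spots on the slide: contaminated expression is "
            "confounded with true expression and the model is unidentifiable"
        )
    frac = geometry.n_background / geometry.n_spots
    if frac < MIN_BACKGROUND_FRACTION:
        msg = (
            f"only {100 * frac:.1f}% of spots are background; at least 25% is "
            "recommended for reliable contamination estimation"
        )
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, BackgroundFractionWarning, stacklevel=3)


def initial_bleed_rate(totals: np.ndarray, geometry: SpotGeometry) -> float:
    """Average background total divided by average total over all spots."""
    totals = np.asarray(totals, dtype=float)
    if geometry.n_background == 0:
        raise ValueError("initial bleed rate needs at least one background spot")
    overall = totals.mean()
    if overall == 0.0:
        return 0.0
    rate = totals[~geometry.in_tissue].mean() / overall
    return float(np.clip(rate, 0.0, 1.0))


def initial_distal_rate(totals: np.ndarray, geometry: SpotGeometry) -> float:
    """Mean of the 25th-50th percentile band of background totals over the
    background mean, clipped to [0, 1].

    Background spots are ranked ascending by total counts and the band is
    ranks in [floor(0.25 K_b), floor(0.5 K_b)).
    """
    totals = np.asarray(totals, dtype=float)
    bg = np.sort(totals[~geometry.in_tissue])
    n_bg = len(bg)
    if n_bg < 4:
        raise ValueError(
            f"initial distal rate needs at least 4 background spots, got {n_bg}"
        )
    lo, hi = int(np.floor(0.25 * n_bg)), int(np.floor(0.5 * n_bg))
    band = bg[lo:hi]
    bg_mean = bg.mean()
    if bg_mean == 0.0 or band.size == 0:
        return 0.0
    return float(np.clip(band.mean() / bg_mean, 0.0, 1.0))


def expected_totals(mu_totals: np.ndarray, transfer: np.ndarray) -> np.ndarray:
    """Expected per-spot totals eta[j] = sum_t mu_tot[t] a[t, j]."""
    return np.asarray(mu_totals, dtype=float) @ np.asarray(transfer, dtype=float)


def rss_and_gradients(r_beta: float, r_gamma: float, mu_totals: np.ndarray,
                      observed_totals: np.ndarray, weights: np.ndarray,
                      tissue_cols: np.ndarray):
    """Residual sum of squares and its analytic gradients.

    Returns ``(rss, grads)`` with ``grads`` holding ``d_r_beta``,
    ``d_r_gamma`` and ``d_mu`` (length K_t).
    """
    mu = np.asarray(mu_totals, dtype=float)
    x = np.asarray(observed_totals, dtype=float)
    n_spots = weights.shape[1]
    transfer = mixing_matrix(weights, r_beta, r_gamma, tissue_cols)
    eta = mu @ transfer
    resid = eta - x
    rss = float(resid @ resid)

    # d eta / d r_beta: mu @ [ (1-r_gamma) w + r_gamma/K ] minus mu at self
    spread = mu @ ((1.0 - r_gamma) * weights) + (r_gamma / n_spots) * mu.sum()
    d_eta_d_beta = spread.copy()
    np.add.at(d_eta_d_beta, tissue_cols, -mu)
    # d eta / d r_gamma: r_beta * (sum(mu)/K - mu @ w)
    d_eta_d_gamma = r_beta * (mu.sum() / n_spots - mu @ weights)

    grads = {
        "d_r_beta": float(2.0 * resid @ d_eta_d_beta),
        "d_r_gamma": float(2.0 * resid @ d_eta_d_gamma),
        "d_mu": 2.0 * (transfer @ resid),
    }
    return rss, grads


def default_sigma_grid(geometry: SpotGeometry) -> np.ndarray:
    """Candidate bandwidths scaled by the slide's median nearest-neighbor
    spot distance, making the grid resolution-invariant."""
    pitch = median_nn_distance(geometry)
    return pitch * np.asarray(DEFAULT_SIGMA_MULTIPLIERS, dtype=float)


def fit_global_params(slide: SlideCounts, geometry: SpotGeometry,
                      gene_set: np.ndarray | None = None,
                      sigma_grid=None, kernel: str = "gaussian",
                      max_iter: int = 200, tol: float = 1e-8,
                      strict_background: bool = False) -> GlobalContaminationParams:
    """Fit (r_beta, r_gamma, sigma, mu_totals) by gridded RSS minimization.

    Per candidate sigma the objective is minimized over the rates and the
    tissue totals jointly with L-BFGS-B under box constraints (rates in
    [0, 1], totals nonnegative), starting from moment-based initial values;
    the sigma with minimal RSS (ties to the smallest sigma) is selected.
    The reported optimum never exceeds the RSS of the initial point.
    """
    check_background(geometry, strict=strict_background)
    if slide.n_spots != geometry.n_spots:
        raise ValueError("counts and geometry have different spot counts")

    counts = slide.counts
    if gene_set is not None:
        mask = np.isin(slide.gene_ids, np.asarray(gene_set, dtype=object))
        if not mask.any():
            raise ValueError("gene_set matches no gene in the slide")
        counts = counts[mask]
    totals = counts.sum(axis=0).astype(float)
    grand_total = totals.sum()
    if grand_total <= 0:
        raise ValueError("slide has zero total counts over the selected genes")

    tissue_cols = geometry.tissue_indices
    tissue_totals = totals[tissue_cols]
    if tissue_totals.sum() <= 0:
        raise ValueError("tissue spots have zero total counts")

    r_beta0 = initial_bleed_rate(totals, geometry)
    try:
        r_gamma0 = initial_distal_rate(totals, geometry)
    except ValueError:
        r_gamma0 = 0.5  # too few background spots to rank; neutral start
    mu0 = tissue_totals * (grand_total / tissue_totals.sum())

    if sigma_grid is None:
        sigma_grid = default_sigma_grid(geometry)
    sigma_grid = np.sort(np.asarray(sigma_grid, dtype=float))
    if (sigma_grid <= 0).any():
        raise ValueError("sigma grid values must be positive")

    # Work on mean-normalized totals: the RSS is equivariant under joint
    # rescaling of X and mu, and normalization keeps the rate and mu blocks
    # of the gradient on comparable scales regardless of sequencing depth.
    scale = totals.mean()
    totals_n = totals / scale
    mu0_n = mu0 / scale

    x0 = np.concatenate([[r_beta0, r_gamma0], mu0_n])
    bounds = [(0.0, 1.0), (0.0, 1.0)] + [(0.0, None)] * len(mu0_n)

    trace: list[tuple[float, float]] = []
    best = None
    failures = []
    for sigma in sigma_grid:
        try:
            model = MixingModel.from_geometry(geometry, float(sigma), kernel)
        except ValueError as exc:
            failures.append((float(sigma), str(exc)))
            continue
        weights = model.weights

        def objective(x):
            rss, grads = rss_and_gradients(
                x[0], x[1], x[2:], totals_n, weights, tissue_cols
            )
            grad = np.concatenate(
                [[grads["d_r_beta"], grads["d_r_gamma"]], grads["d_mu"]]
            )
            return rss, grad

        rss0 = objective(x0)[0]
        res = minimize(
            objective, x0, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": max_iter, "ftol": tol},
        )
        if not np.isfinite(res.fun):
            failures.append((float(sigma), res.message))
            continue
        # descent contract: never report worse than the initial point
        if res.fun <= rss0:
            rss, x_opt = float(res.fun), res.x
        else:
            rss, x_opt = float(rss0), x0
        trace.append((float(sigma), rss))
        if best is None or rss < best[0]:
            best = (rss, float(sigma), x_opt)

    if best is None:
        raise RuntimeError(
            f"optimization failed on every sigma grid point; trace: {failures}"
        )

    rss, sigma_hat, x_opt = best
    return GlobalContaminationParams(
        r_beta=float(np.clip(x_opt[0], 0.0, 1.0)),
        r_gamma=float(np.clip(x_opt[1], 0.0, 1.0)),
        sigma=sigma_hat,
        mu_totals=np.maximum(x_opt[2:], 0.0) * scale,
        rss=rss * scale ** 2,
        sigma_grid_trace=[(s, r * scale ** 2) for s, r in trace],
        kernel=kernel,
    )
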