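"""Spot distances, bleed-weight kernels, and the mixing (transfer) matrix.

The bleed model distributes each tissue spot's expected reads over the slide:
a fraction ``1 - r_beta`` stays at the spot, and the bled fraction ``r_beta``
splits into a proximal part (share ``1 - r_gamma``) following distance-kernel
weights ``w[t, j]`` and a distal part (share ``r_gamma``) spread uniformly
over all K spots.  The composite transfer rate is

    a[t, j] = (1 - r_beta) * 1{t == j}
              + r_beta * ((1 - r_gamma) * w[t, j] + r_gamma / K)

and every row of ``a`` sums to one, so expected reads are conserved.

Kernel weights exclude the source spot itself (``w[t, t] = 0``) and are
renormalized over the remaining spots: the bled component consists of reads
that leave their spot of origin.  The uniform distal term runs over all K
spots including the source, which keeps row sums exactly one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .containers import SpotGeometry

__all__ = [
    "KERNEL_FAMILIES",
    "pairwise_distances",
    "kernel_value",
    "bleed_weights",
    "mixing_matrix",
    "MixingModel",
]

KERNEL_FAMILIES = ("gaussian", "linear", "laplace", "cauchy")

# Weight entries below this are dropped before renormalization; the dropped
# mass is negligible relative to float64 row-sum accuracy.
_WEIGHT_FLOOR = 1e-300


def pairwise_distances(geometry: SpotGeometry) -> np.ndarray:
    """Euclidean pixel distances from each tissue spot to every spot (K_t x K)."""
    coords = geometry.coords
    return cdist(coords[geometry.tissue_indices], coords)


def kernel_value(d, sigma: float, family: str = "gaussian"):
    """Evaluate a distance kernel; 1 at d=0, non-increasing in d, in [0, 1].

    Families: ``gaussian`` exp(-d^2 / 2 sigma^2); ``linear``
    max(0, 1 - d / 3 sigma); ``laplace`` exp(-d / sigma); ``cauchy``
    1 / (1 + d^2 / sigma^2).  All share sigma as their single scale
    parameter.
    """
    if sigma <= 0:
        raise ValueError(f"kernel bandwidth must be positive, got {sigma}")
    d = np.asarray(d, dtype=float)
    if family == "gaussian":
        return np.exp(-(d ** 2) / (2.0 * sigma ** 2))
    if family == "linear":
        return np.maximum(0.0, 1.0 - d / (3.0 * sigma))
    if family == "laplace":
        return np.exp(-d / sigma)
    if family == "cauchy":
        return 1.0 / (1.0 + (d / sigma) ** 2)
    raise ValueError(f"unknown kernel family {family!r}; choose from {KERNEL_FAMILIES}")


def bleed_weights(distances: np.ndarray, sigma: float, family: str = "gaussian",
                  tissue_cols: np.ndarray | None = None) -> np.ndarray:
    """Row-normalized kernel weights w[t, j] with the self entry zeroed.

    ``tissue_cols[t]`` is the column (full-spot index) of tissue spot ``t``;
    if omitted it is inferred from zero-distance entries.
    """
    distances = np.asarray(distances, dtype=float)
    raw = kernel_value(distances, sigma, family)
    weights = np.array(raw, dtype=float)
    n_t = weights.shape[0]
    if tissue_cols is None:
        tissue_cols = np.argmin(distances, axis=1)
    weights[np.arange(n_t), tissue_cols] = 0.0
    weights[weights < _WEIGHT_FLOOR] = 0.0
    row_sums = weights.sum(axis=1)
    bad = np.flatnonzero(row_sums <= 0.0)
    if bad.size:
        raise ValueError(
            f"kernel underflow: tissue spot(s) {bad[:5].tolist()} have zero "
            f"weight on every other spot; increase sigma (got {sigma})"
        )
    return weights / row_sums[:, None]


def mixing_matrix(weights: np.ndarray, r_beta: float, r_gamma: float,
                  tissue_cols: np.ndarray) -> np.ndarray:
    """Composite transfer rates a[t, j]; every row sums to one."""
    for name, rate in (("r_beta", r_beta), ("r_gamma", r_gamma)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {rate}")
    weights = np.asarray(weights, dtype=float)
    n_t, n_spots = weights.shape
    transfer = r_beta * ((1.0 - r_gamma) * weights + r_gamma / n_spots)
    transfer[np.arange(n_t), tissue_cols] += 1.0 - r_beta
    return transfer


@dataclass
class MixingModel:
    """Distances, kernel weights and transfer rates for one (sigma, family)."""

    distances: np.ndarray
    sigma: float
    family: str
    weights: np.ndarray
    tissue_cols: np.ndarray

    @classmethod
    def from_geometry(cls, geometry: SpotGeometry, sigma: float,
                      family: str = "gaussian") -> "MixingModel":
        distances = pairwise_distances(geometry)
        tissue_cols = geometry.tissue_indices
        weights = bleed_weights(distances, sigma, family, tissue_cols)
        return cls(distances=distances, sigma=sigma, family=family,
                   weights=weights, tissue_cols=tissue_cols)

    @property
    def n_spots(self) -> int:
        return self.weights.shape[1]

    @property
    def n_tissue(self) -> int:
        return self.weights.shape[0]

    def transfer(self, r_beta: float, r_gamma: float) -> np.ndarray:
        return mixing_matrix(self.weights, r_beta, r_gamma, self.tissue_cols)

    def bleed_rates(self, r_beta: float, r_gamma: float) -> np.ndarray:
        """Per-pair bleed-only rates r_beta * ((1-r_gamma) w + r_gamma / K).

        Unlike :meth:`transfer` this excludes the stay-at-home term, so entry
        ``[t, j]`` is the expected share of spot t's reads received at j via
        bleeding alone.
        """
        for name, rate in (("r_beta", r_beta), ("r_gamma", r_gamma)):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {rate}")
        return r_beta * ((1.0 - r_gamma) * self.weights + r_gamma / self.n_spots)


def median_nn_distance(geometry: SpotGeometry) -> float:
    """Median nearest-neighbor distance over all spots, in pixels."""
    coords = geometry.coords
    d = cdist(coords, coords)
    np.fill_diagonal(d, np.inf)
    return float(np.median(d.min(axis=1)))
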