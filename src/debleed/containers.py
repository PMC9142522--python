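"""In-memory containers for raw-slide data.

The universe of spots is the full slide (tissue and background); filtered
matrices that drop background barcodes cannot support contamination
estimation, so every container here is aligned to the complete spot set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SpotGeometry", "SlideCounts", "DecontaminationExport"]


@dataclass
class SpotGeometry:
    """Spot barcodes, image-pixel coordinates, lattice indices, tissue flags.

    Coordinates are in pixels of the slide image, treated as a Euclidean
    plane; distances only ever enter ratios with a fitted bandwidth, so no
    scale-factor metadata is needed.
    """

    barcode: np.ndarray
    pixel_row: np.ndarray
    pixel_col: np.ndarray
    array_row: np.ndarray
    array_col: np.ndarray
    in_tissue: np.ndarray

    def __post_init__(self) -> None:
        self.barcode = np.asarray(self.barcode, dtype=object)
        self.pixel_row = np.asarray(self.pixel_row, dtype=float)
        self.pixel_col = np.asarray(self.pixel_col, dtype=float)
        self.array_row = np.asarray(self.array_row, dtype=int)
        self.array_col = np.asarray(self.array_col, dtype=int)
        self.in_tissue = np.asarray(self.in_tissue, dtype=bool)
        n = len(self.barcode)
        for name in ("pixel_row", "pixel_col", "array_row", "array_col", "in_tissue"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"geometry field {name!r} has length "
                                 f"{len(getattr(self, name))}, expected {n}")
        if len(np.unique(self.barcode)) != n:
            dupes = pd.Series(self.barcode).value_counts()
            dupes = dupes[dupes > 1].index.tolist()[:5]
            raise ValueError(f"duplicate barcodes in geometry: {dupes}")
        if not (np.isfinite(self.pixel_row).all() and np.isfinite(self.pixel_col).all()):
            raise ValueError("non-finite pixel coordinates in geometry")
        if self.n_tissue < 1:
            raise ValueError("geometry must contain at least one tissue spot")

    @property
    def n_spots(self) -> int:
        """Total number of spots K on the slide."""
        return len(self.barcode)

    @property
    def n_tissue(self) -> int:
        return int(self.in_tissue.sum())

    @property
    def n_background(self) -> int:
        return self.n_spots - self.n_tissue

    @property
    def tissue_indices(self) -> np.ndarray:
        """Column indices (into the full spot ordering) of tissue spots."""
        return np.flatnonzero(self.in_tissue)

    @property
    def coords(self) -> np.ndarray:
        """(K, 2) array of (pixel_row, pixel_col)."""
        return np.column_stack([self.pixel_row, self.pixel_col])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "barcode": self.barcode,
                "in_tissue": self.in_tissue.astype(int),
                "array_row": self.array_row,
                "array_col": self.array_col,
                "pixel_row": self.pixel_row,
                "pixel_col": self.pixel_col,
            }
        )

    def sorted_by_barcode(self) -> "SpotGeometry":
        order = np.argsort(self.barcode.astype(str), kind="stable")
        return SpotGeometry(
            self.barcode[order],
            self.pixel_row[order],
            self.pixel_col[order],
            self.array_row[order],
            self.array_col[order],
            self.in_tissue[order],
        )


@dataclass
class SlideCounts:
    """Genes x all-spots UMI count matrix, columns aligned to a geometry."""

    gene_ids: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D genes x spots matrix")
        if self.counts.shape[0] != len(self.gene_ids):
            raise ValueError(
                f"counts has {self.counts.shape[0]} rows but "
                f"{len(self.gene_ids)} gene ids"
            )
        if len(np.unique(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids are not unique")
        if (self.counts < 0).any():
            raise ValueError("counts contain negative entries")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_spots(self) -> int:
        return self.counts.shape[1]

    def tissue_counts(self, geometry: SpotGeometry) -> np.ndarray:
        if self.n_spots != geometry.n_spots:
            raise ValueError("counts and geometry have different spot counts")
        return self.counts[:, geometry.tissue_indices]


@dataclass
class DecontaminationExport:
    """Decontaminated matrix plus per-spot contamination rates, ready to write."""

    gene_ids: np.ndarray
    barcodes: np.ndarray              # tissue barcodes only
    matrix: np.ndarray                # genes x K_t, nonnegative reals
    contamination_rate: np.ndarray    # length K_t, in [0, 1]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.contamination_rate = np.asarray(self.contamination_rate, dtype=float)
        if self.matrix.shape != (len(self.gene_ids), len(self.barcodes)):
            raise ValueError("export matrix shape does not match gene/barcode lists")
        if len(self.contamination_rate) != len(self.barcodes):
            raise ValueError("contamination rate length does not match barcodes")
        if (self.matrix < 0).any():
            raise ValueError("decontaminated matrix has negative entries")
        if ((self.contamination_rate < 0) | (self.contamination_rate > 1)).any():
            raise ValueError("contamination rates outside [0, 1]")
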