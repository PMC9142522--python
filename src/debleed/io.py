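"""Reading and writing raw slides in 10x-Visium-style layouts.

Supports the SpaceRanger raw output convention: a Matrix Market count file,
barcode and feature TSVs, and a spot-positions CSV in either the headerless
v1 dialect (``tissue_positions_list.csv``) or the headered v2 dialect
(``tissue_positions.csv``).  All files may be gzip-compressed.  The reader
keeps background barcodes — the contamination model requires them — and
returns spots in sorted-barcode order regardless of file row order.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import DecontaminationExport, SlideCounts, SpotGeometry

__all__ = ["read_visium_raw", "write_visium_fixture", "write_decontaminated"]

_V1_COLUMNS = ["barcode", "in_tissue", "array_row", "array_col",
               "pixel_row", "pixel_col"]
_V2_HEADER = ["barcode", "in_tissue", "array_row", "array_col",
              "pxl_row_in_fullres", "pxl_col_in_fullres"]


def _find(directory: Path, names: list[str]) -> Path:
    for name in names:
        for candidate in (directory / name, directory / "spatial" / name):
            if candidate.exists():
                return candidate
    raise FileNotFoundError(
        f"none of {names} found in {directory} (or its spatial/ subdirectory)"
    )


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_positions(path: Path) -> SpotGeometry:
    """Parse a tissue-positions CSV, auto-detecting the v1/v2 dialect."""
    with _open_text(path) as fh:
        first = fh.readline().strip()
    has_header = first.split(",")[0].strip().lower() == "barcode"
    df = pd.read_csv(path, header=0 if has_header else None)
    if df.shape[1] != 6:
        raise ValueError(f"positions file {path} has {df.shape[1]} columns, expected 6")
    df.columns = _V1_COLUMNS
    return SpotGeometry(
        barcode=df["barcode"].to_numpy(dtype=object),
        pixel_row=df["pixel_row"].to_numpy(dtype=float),
        pixel_col=df["pixel_col"].to_numpy(dtype=float),
        array_row=df["array_row"].to_numpy(dtype=int),
        array_col=df["array_col"].to_numpy(dtype=int),
        in_tissue=df["in_tissue"].to_numpy(dtype=int).astype(bool),
    )


def read_visium_raw(directory) -> tuple[SlideCounts, SpotGeometry]:
    """Read a raw (unfiltered) slide directory.

    Returns counts and geometry aligned by barcode and sorted by barcode.
    Spots present in the positions file but absent from the matrix get zero
    columns; a matrix barcode missing from the positions file is an error.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"raw slide directory not found: {directory}")
    matrix_path = _find(directory, ["matrix.mtx", "matrix.mtx.gz"])
    barcodes_path = _find(directory, ["barcodes.tsv", "barcodes.tsv.gz"])
    features_path = _find(
        directory,
        ["features.tsv", "features.tsv.gz", "genes.tsv", "genes.tsv.gz"],
    )
    positions_path = _find(
        directory,
        [
            "tissue_positions.csv", "tissue_positions.csv.gz",
            "tissue_positions_list.csv", "tissue_positions_list.csv.gz",
        ],
    )

    mat = scipy.io.mmread(str(matrix_path))
    mat = scipy.sparse.csc_matrix(mat)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].to_numpy(dtype=object)
    features = pd.read_csv(features_path, sep="\t", header=None)
    gene_ids = features[0].to_numpy(dtype=object)
    if mat.shape != (len(gene_ids), len(barcodes)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match "
            f"{len(gene_ids)} features x {len(barcodes)} barcodes"
        )
    geometry = _read_positions(positions_path)

    pos_set = set(geometry.barcode.tolist())
    missing = [b for b in barcodes if b not in pos_set]
    if missing:
        raise ValueError(
            "matrix barcodes absent from positions file "
            f"(first offenders: {missing[:5]})"
        )

    geometry = geometry.sorted_by_barcode()
    col_of = {b: i for i, b in enumerate(barcodes)}
    dense = np.zeros((len(gene_ids), geometry.n_spots), dtype=np.int64)
    mat = mat.tocsc()
    for out_col, bc in enumerate(geometry.barcode):
        src = col_of.get(bc)
        if src is not None:
            dense[:, out_col] = mat[:, src].toarray().ravel()
    return SlideCounts(gene_ids=gene_ids, counts=dense), geometry


def write_visium_fixture(counts: SlideCounts, geometry: SpotGeometry,
                         directory, dialect: str = "v1",
                         compress: bool = False) -> None:
    """Write counts + geometry laid out as a raw SpaceRanger output."""
    if dialect not in ("v1", "v2"):
        raise ValueError(f"unknown positions dialect {dialect!r}")
    if counts.n_spots != geometry.n_spots:
        raise ValueError("counts and geometry have different spot counts")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if compress else ""

    sparse = scipy.sparse.coo_matrix(counts.counts)
    mtx_path = directory / f"matrix.mtx{suffix}"
    if compress:
        with gzip.open(mtx_path, "wb") as fh:
            scipy.io.mmwrite(fh, sparse)
    else:
        scipy.io.mmwrite(str(mtx_path), sparse)

    pd.DataFrame({"barcode": geometry.barcode}).to_csv(
        directory / f"barcodes.tsv{suffix}", sep="\t", header=False, index=False
    )
    pd.DataFrame(
        {"id": counts.gene_ids, "name": counts.gene_ids,
         "type": "Gene Expression"}
    ).to_csv(directory / f"features.tsv{suffix}", sep="\t", header=False, index=False)

    pos = geometry.to_frame()
    if dialect == "v1":
        pos.to_csv(directory / f"tissue_positions_list.csv{suffix}",
                   header=False, index=False)
    else:
        pos.columns = _V2_HEADER
        pos.to_csv(directory / f"tissue_positions.csv{suffix}",
                   header=True, index=False)


def write_decontaminated(result: DecontaminationExport, directory) -> None:
    """Export a decontamination result as MTX + TSV + CSV + parameter record."""
    if len(result.gene_ids) == 0:
        raise ValueError("refusing to write an export with an empty gene set")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(
        str(directory / "decontaminated.mtx"),
        scipy.sparse.coo_matrix(result.matrix),
        precision=12,
    )
    pd.DataFrame({"gene": result.gene_ids}).to_csv(
        directory / "genes.tsv", sep="\t", header=False, index=False
    )
    pd.DataFrame({"barcode": result.barcodes}).to_csv(
        directory / "barcodes.tsv", sep="\t", header=False, index=False
    )
    pd.DataFrame(
        {"barcode": result.barcodes,
         "contamination_rate": result.contamination_rate}
    ).to_csv(directory / "contamination_rates.csv", index=False)
    with open(directory / "parameters.txt", "w") as fh:
        for key, value in result.params.items():
            fh.write(f"{key}\t{value}\n")


def read_decontaminated(directory) -> DecontaminationExport:
    """Reload an export written by :func:`write_decontaminated`."""
    directory = Path(directory)
    matrix = np.asarray(
        scipy.sparse.csr_matrix(
            scipy.io.mmread(str(directory / "decontaminated.mtx"))
        ).todense(),
        dtype=float,
    )
    genes = pd.read_csv(directory / "genes.tsv", sep="\t", header=None)[0].to_numpy(object)
    barcodes = pd.read_csv(directory / "barcodes.tsv", sep="\t", header=None)[0].to_numpy(object)
    rates = pd.read_csv(directory / "contamination_rates.csv")
    params: dict = {}
    param_path = directory / "parameters.txt"
    if param_path.exists():
        with open(param_path) as fh:
            for line in fh:
                if line.strip():
                    key, _, value = line.rstrip("\n").partition("\t")
                    params[key] = value
    return DecontaminationExport(
        gene_ids=genes,
        barcodes=barcodes,
        matrix=matrix,
        contamination_rate=rates["contamination_rate"].to_numpy(float),
        params=params,
    )
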