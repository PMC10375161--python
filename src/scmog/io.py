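"""Core data types and readers/writers for 10x-style single-cell matrices.

Cells are rows and features are columns everywhere in this package; Cell
Ranger emits feature-major matrices, so both readers transpose on load.
Gzipped and plain text inputs are auto-detected by magic bytes.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Literal, Sequence

import h5py
import numpy as np
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

Modality = Literal["rna", "atac", "adt"]

#: Cell Ranger feature-type tags for each modality.
FEATURE_TYPE_TAGS = {
    "rna": "Gene Expression",
    "atac": "Peaks",
    "adt": "Antibody Capture",
}


class FormatError(ValueError):
    """Raised when an input file does not follow the expected layout."""


class MatrixValidationError(ValueError):
    """Raised when matrix contents violate a CountMatrix invariant."""


def _check_ids(ids: Sequence[str], axis: str, n: int) -> None:
    if len(ids) != n:
        raise MatrixValidationError(
            f"{axis} ids ({len(ids)}) do not match matrix {axis} count ({n})"
        )
    if len(set(ids)) != len(ids):
        raise MatrixValidationError(f"duplicate {axis} ids")


@dataclass
class CountMatrix:
    """Cells x features matrix of non-negative raw counts.

    ``values`` may be a dense ndarray or any scipy sparse matrix; it is
    normalised to CSR on construction so downstream code can rely on
    row-major access.  Feature ids are gene symbols, peak coordinates in
    ``chr:start-end`` form (1-based inclusive, as emitted by Cell Ranger),
    or antibody names depending on ``modality``.
    """

    values: sp.csr_matrix | np.ndarray
    cell_ids: list[str]
    feature_ids: list[str]
    modality: Modality
    genome_build: str | None = None

    def __post_init__(self) -> None:
        if sp.issparse(self.values):
            self.values = self.values.tocsr()
            if self.values.nnz and self.values.data.min() < 0:
                raise MatrixValidationError("negative entries in count matrix")
        else:
            self.values = np.asarray(self.values)
            if self.values.size and self.values.min() < 0:
                raise MatrixValidationError("negative entries in count matrix")
        if self.modality not in ("rna", "atac", "adt"):
            raise MatrixValidationError(f"unknown modality {self.modality!r}")
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        _check_ids(self.cell_ids, "cell", self.values.shape[0])
        _check_ids(self.feature_ids, "feature", self.values.shape[1])

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense())
        return self.values

    def subset_cells(self, index: np.ndarray) -> "CountMatrix":
        return CountMatrix(
            self.values[index],
            [self.cell_ids[i] for i in np.atleast_1d(index)],
            list(self.feature_ids),
            self.modality,
            self.genome_build,
        )

    def subset_features(self, index: np.ndarray) -> "CountMatrix":
        return CountMatrix(
            self.values[:, index],
            list(self.cell_ids),
            [self.feature_ids[i] for i in np.atleast_1d(index)],
            self.modality,
            self.genome_build,
        )


@dataclass
class PairedDataset:
    """Two modalities measured in the same cells, in the same cell order."""

    primary: CountMatrix
    secondary: CountMatrix

    def __post_init__(self) -> None:
        if self.primary.cell_ids != self.secondary.cell_ids:
            raise MatrixValidationError(
                "paired matrices must share identical cell_ids in identical order"
            )

    @property
    def n_cells(self) -> int:
        return self.primary.n_cells


def pair_by_cells(primary: CountMatrix, secondary: CountMatrix) -> PairedDataset:
    """Subset ``secondary`` to the cells of ``primary`` (in primary's order)
    and return the paired dataset.  Useful after a QC step has dropped cells
    from one modality only."""
    pos = {c: i for i, c in enumerate(secondary.cell_ids)}
    missing = [c for c in primary.cell_ids if c not in pos]
    if missing:
        raise MatrixValidationError(
            f"{len(missing)} cells of the primary matrix are absent from the "
            f"secondary (first: {missing[0]})"
        )
    idx = np.array([pos[c] for c in primary.cell_ids])
    return PairedDataset(primary, secondary.subset_cells(idx))


@dataclass
class SplitAssignment:
    """Per-cell train/validation/test labels.

    ``method`` records how the split was derived; the cluster-based method
    holds out whole Leiden clusters so the test partition is less similar to
    the training cells than a random split would be.
    """

    labels: np.ndarray  # array of {"train","validation","test"} strings
    method: str
    cluster_of_cell: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        bad = set(self.labels) - {"train", "validation", "test"}
        if bad:
            raise MatrixValidationError(f"unknown split labels: {sorted(bad)}")

    def indices(self, part: str) -> np.ndarray:
        return np.flatnonzero(self.labels == part)

    def counts(self) -> dict[str, int]:
        return {p: int((self.labels == p).sum()) for p in ("train", "validation", "test")}


# ---------------------------------------------------------------------------
# readers


def _open_maybe_gzip(path: str | Path) -> IO[bytes]:
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rb")
    return open(path, "rb")


def _read_tsv_lines(path: str | Path) -> list[list[str]]:
    with _open_maybe_gzip(path) as fh:
        text = fh.read().decode()
    return [line.split("\t") for line in text.splitlines() if line]


def _dedupe(ids: list[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for x in ids:
        if x in seen:
            seen[x] += 1
            out.append(f"{x}.{seen[x]}")
        else:
            seen[x] = 0
            out.append(x)
    if len(out) != len(set(ids)):
        logger.warning("made %d duplicate ids unique", len(ids) - len(set(ids)))
    return out


def read_mtx_triplet(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    modality: Modality,
) -> CountMatrix:
    """Read a Cell Ranger MTX triplet (matrix + features + barcodes).

    The MTX on disk is feature-major (rows = features, columns = cells) and
    is transposed to cells x features.  When the features file carries a
    third feature-type column (multiome output), only rows matching the
    requested ``modality`` are retained.
    """
    try:
        with _open_maybe_gzip(matrix_path) as fh:
            mat = scipy.io.mmread(fh)
    except ValueError as exc:
        raise FormatError(f"cannot parse MatrixMarket file {matrix_path}: {exc}") from exc
    mat = sp.coo_matrix(mat)

    feat_rows = _read_tsv_lines(features_path)
    barcodes = [row[0] for row in _read_tsv_lines(barcodes_path)]

    if mat.shape[0] != len(feat_rows):
        raise FormatError(
            f"MTX declares {mat.shape[0]} features but features file has {len(feat_rows)} lines"
        )
    if mat.shape[1] != len(barcodes):
        raise FormatError(
            f"MTX declares {mat.shape[1]} cells but barcodes file has {len(barcodes)} lines"
        )
    if mat.nnz and mat.data.min() < 0:
        raise MatrixValidationError("negative entry in MTX data")

    # prefer the human-readable name column when present
    names = [row[1] if len(row) > 1 else row[0] for row in feat_rows]
    cm = CountMatrix(
        mat.T.tocsr(),
        _dedupe(barcodes),
        _dedupe(names),
        modality,
    )
    if any(len(row) > 2 for row in feat_rows):
        tag = FEATURE_TYPE_TAGS[modality]
        keep = np.array([len(row) > 2 and row[2] == tag for row in feat_rows])
        cm = cm.subset_features(np.flatnonzero(keep))
    return cm


def read_10x_h5(path: str | Path, modality: Modality) -> CountMatrix:
    """Read a Cell Ranger v3 HDF5 matrix (``/matrix`` group layout)."""
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise FormatError(f"cannot open {path} as HDF5: {exc}") from exc
    with f:
        if "matrix" not in f:
            raise FormatError("missing group 'matrix'")
        g = f["matrix"]
        for key in ("data", "indices", "indptr", "shape", "barcodes"):
            if key not in g:
                raise FormatError(f"missing dataset 'matrix/{key}'")
        if "features" not in g or "id" not in g["features"]:
            raise FormatError("missing dataset 'matrix/features/id'")
        shape = tuple(g["shape"][...])  # (n_features, n_cells)
        mat = sp.csc_matrix(
            (g["data"][...], g["indices"][...], g["indptr"][...]), shape=shape
        )
        feats = g["features"]
        names = feats["name"][...] if "name" in feats else feats["id"][...]
        names = [n.decode() if isinstance(n, bytes) else str(n) for n in names]
        barcodes = [
            b.decode() if isinstance(b, bytes) else str(b) for b in g["barcodes"][...]
        ]
        genome = None
        if "genome" in feats and len(feats["genome"]) > 0:
            g0 = feats["genome"][0]
            genome = g0.decode() if isinstance(g0, bytes) else str(g0)
        ftypes = None
        if "feature_type" in feats:
            ftypes = [
                t.decode() if isinstance(t, bytes) else str(t)
                for t in feats["feature_type"][...]
            ]

    cm = CountMatrix(mat.T.tocsr(), _dedupe(barcodes), _dedupe(names), modality, genome)
    if ftypes is not None:
        tag = FEATURE_TYPE_TAGS[modality]
        keep = np.flatnonzero(np.array([t == tag for t in ftypes]))
        cm = cm.subset_features(keep)
    return cm


# ---------------------------------------------------------------------------
# writer


def write_matrix(matrix, path: str | Path, format: Literal["mtx", "h5"] = "mtx") -> list[Path]:
    """Write a CountMatrix (or any matrix-like with ids) to disk.

    ``mtx`` writes a Cell Ranger-style triplet into directory ``path``
    (matrix.mtx, features.tsv, barcodes.tsv, plain text); ``h5`` writes a
    single Cell Ranger v3 HDF5 file.  Output is feature-major, matching
    what the readers expect.  Returns the paths written.
    """
    values = matrix.values
    if not sp.issparse(values):
        values = sp.csr_matrix(np.asarray(values))
    feat_major = values.T.tocsc()
    tag = FEATURE_TYPE_TAGS[matrix.modality]
    path = Path(path)

    if format == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        mtx = path / "matrix.mtx"
        scipy.io.mmwrite(str(mtx), feat_major.tocoo())
        feats = path / "features.tsv"
        feats.write_text(
            "".join(f"{fid}\t{fid}\t{tag}\n" for fid in matrix.feature_ids)
        )
        bcs = path / "barcodes.tsv"
        bcs.write_text("".join(f"{c}\n" for c in matrix.cell_ids))
        return [mtx, feats, bcs]

    if format == "h5":
        with h5py.File(path, "w") as f:
            g = f.create_group("matrix")
            g.create_dataset("data", data=feat_major.data)
            g.create_dataset("indices", data=feat_major.indices)
            g.create_dataset("indptr", data=feat_major.indptr)
            g.create_dataset("shape", data=np.array(feat_major.shape, dtype=np.int64))
            g.create_dataset(
                "barcodes", data=np.array([c.encode() for c in matrix.cell_ids])
            )
            feats = g.create_group("features")
            ids = np.array([fid.encode() for fid in matrix.feature_ids])
            feats.create_dataset("id", data=ids)
            feats.create_dataset("name", data=ids)
            feats.create_dataset(
                "feature_type", data=np.array([tag.encode()] * len(matrix.feature_ids))
            )
            gb = matrix.genome_build or ""
            feats.create_dataset(
                "genome", data=np.array([gb.encode()] * len(matrix.feature_ids))
            )
        return [path]

    raise ValueError(f"unknown format {format!r}")
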