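"""Reading, writing and validation of drug-disease association data.

The package works on three in-memory objects: a binary drug x disease
association matrix ``R`` (rows are drugs, columns are diseases), a symmetric
drug-drug similarity matrix and a symmetric disease-disease similarity
matrix, both with values in [0, 1] and unit diagonal.  Similarities are
treated as opaque inputs: how they were derived (chemical fingerprints,
text mining, ...) is upstream of this package.

On disk, associations are stored either as a headerless TSV edge list
(``drug_id<TAB>disease_id[<TAB>1]``) or as a MatrixMarket coordinate file
with a sidecar ``.ids`` file (drug ids first, then disease ids, one per
line); similarities are CSV with ids as both header row and first column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Literal, Optional, Union

import numpy as np
import pandas as pd
from scipy import io as _spio
from scipy import sparse as _sparse

__all__ = [
    "AssociationMatrix",
    "SimilarityMatrix",
    "DatasetBundle",
    "Violation",
    "DataFormatError",
    "RangeError",
    "SymmetryError",
    "ShapeError",
    "read_association_edges",
    "read_similarity_matrix",
    "write_matrix",
    "sparsity",
    "validate_dataset",
]

Axis = Literal["drug", "disease"]

#: asymmetry up to this magnitude is silently symmetrized on read
SYMMETRIZE_TOL = 1e-6
#: asymmetry beyond this is an invariant violation
SYMMETRY_TOL = 1e-8
#: similarity entries may stray outside [0, 1] by at most this on read
RANGE_TOL = 1e-9


class DataFormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class RangeError(ValueError):
    """A similarity entry lies outside [0, 1] beyond tolerance."""


class SymmetryError(ValueError):
    """A similarity matrix is asymmetric beyond tolerance."""


class ShapeError(ValueError):
    """Array dimensions are inconsistent with the declared identifiers."""


@dataclass
class AssociationMatrix:
    """Binary drug x disease association matrix with stable string ids.

    Row ``i`` is the association vector of drug ``i`` over all diseases;
    column ``j`` is the association vector of disease ``j`` over all drugs.
    Cells are 1 for a known (verified) association and 0 otherwise; an
    unobserved pair is not distinguished from a verified negative
    (implicit-feedback convention).
    """

    values: np.ndarray
    drug_ids: List[str]
    disease_ids: List[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ShapeError("association values must be a 2-D array")
        self.drug_ids = [str(x) for x in self.drug_ids]
        self.disease_ids = [str(x) for x in self.disease_ids]
        if self.values.shape != (len(self.drug_ids), len(self.disease_ids)):
            raise ShapeError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.drug_ids)} drug ids x {len(self.disease_ids)} disease ids"
            )

    @property
    def n_drugs(self) -> int:
        return self.values.shape[0]

    @property
    def n_diseases(self) -> int:
        return self.values.shape[1]

    @property
    def n_associations(self) -> int:
        return int(np.count_nonzero(self.values))

    def drug_row(self, i: int) -> np.ndarray:
        """Association vector of drug ``i`` over all diseases."""
        return np.asarray(self.values[i], dtype=float)

    def disease_column(self, j: int) -> np.ndarray:
        """Association vector of disease ``j`` over all drugs."""
        return np.asarray(self.values[:, j], dtype=float)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AssociationMatrix):
            return NotImplemented
        return (
            self.drug_ids == other.drug_ids
            and self.disease_ids == other.disease_ids
            and np.array_equal(self.values, other.values)
        )


@dataclass
class SimilarityMatrix:
    """Symmetric similarity matrix over drugs or diseases, values in [0, 1]."""

    values: np.ndarray
    ids: List[str]
    axis: Axis

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ShapeError("similarity values must be a square 2-D array")
        self.ids = [str(x) for x in self.ids]
        if len(self.ids) != self.values.shape[0]:
            raise ShapeError(
                f"{len(self.ids)} ids inconsistent with shape {self.values.shape}"
            )
        if self.axis not in ("drug", "disease"):
            raise ValueError(f"axis must be 'drug' or 'disease', got {self.axis!r}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SimilarityMatrix):
            return NotImplemented
        return (
            self.ids == other.ids
            and self.axis == other.axis
            and np.array_equal(self.values, other.values)
        )


@dataclass
class DatasetBundle:
    """Associations plus the two similarity matrices, with aligned ids."""

    associations: AssociationMatrix
    drug_sim: SimilarityMatrix
    disease_sim: SimilarityMatrix


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate_dataset`."""

    kind: str  # id_mismatch | not_binary | range | asymmetry | diagonal | duplicate_ids
    location: str  # associations | drug_sim | disease_sim
    message: str


# ---------------------------------------------------------------------------
# readers


def _ids_sidecar(path: Union[str, Path]) -> Path:
    p = Path(path)
    return p.with_suffix(".ids") if p.suffix == ".mtx" else Path(str(p) + ".ids")


def read_association_edges(
    path: Union[str, Path], format: str = "tsv_edges"
) -> AssociationMatrix:
    """Read a binary association matrix from a TSV edge list or MatrixMarket file.

    TSV rows are ``drug_id<TAB>disease_id`` with an optional third column that
    must equal 1; ids are indexed in first-appearance order and duplicate
    edges collapse to a single 1.  The MatrixMarket route expects a sidecar
    ``.ids`` file giving drug ids then disease ids, one per line.
    """
    path = Path(path)
    if format == "tsv_edges":
        drug_order: dict = {}
        disease_order: dict = {}
        edges = []
        with open(path, "r", encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n").rstrip("\r")
                if line == "":
                    continue
                parts = line.split("\t")
                if len(parts) not in (2, 3) or not parts[0] or not parts[1]:
                    raise DataFormatError(
                        f"{path}: malformed edge row at line {lineno}: {line!r}"
                    )
                if len(parts) == 3 and parts[2] != "1":
                    raise DataFormatError(
                        f"{path}: line {lineno}: third column must be 1, got {parts[2]!r}"
                    )
                d, s = parts[0], parts[1]
                drug_order.setdefault(d, len(drug_order))
                disease_order.setdefault(s, len(disease_order))
                edges.append((drug_order[d], disease_order[s]))
        values = np.zeros((len(drug_order), len(disease_order)), dtype=np.int8)
        for i, j in edges:
            values[i, j] = 1
        return AssociationMatrix(values, list(drug_order), list(disease_order))
    if format == "mtx":
        mat = _spio.mmread(path)
        values = mat.toarray() if _sparse.issparse(mat) else np.asarray(mat)
        values = (values != 0).astype(np.int8)
        ids_path = _ids_sidecar(path)
        with open(ids_path, "r", encoding="utf-8") as fh:
            ids = [ln.rstrip("\n") for ln in fh if ln.rstrip("\n") != ""]
        m, n = values.shape
        if len(ids) != m + n:
            raise DataFormatError(
                f"{ids_path}: expected {m}+{n} ids, found {len(ids)}"
            )
        drug_ids, disease_ids = ids[:m], ids[m:]
        for name, lst in (("drug", drug_ids), ("disease", disease_ids)):
            if len(set(lst)) != len(lst):
                raise DataFormatError(f"{ids_path}: duplicate {name} ids in sidecar")
        return AssociationMatrix(values, drug_ids, disease_ids)
    raise ValueError(f"unknown association format {format!r}")


def read_similarity_matrix(path: Union[str, Path], axis: Axis) -> SimilarityMatrix:
    """Read and validate a similarity CSV (ids as header row and first column).

    Asymmetry up to ``SYMMETRIZE_TOL`` is removed by averaging with the
    transpose; anything larger raises :class:`SymmetryError`.  Entries must
    lie in [0, 1] (tolerance ``RANGE_TOL``) and the diagonal must equal 1.
    """
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    ids = [str(x) for x in df.index]
    cols = [str(x) for x in df.columns]
    if len(ids) != len(cols):
        raise ShapeError(f"{path}: similarity matrix is not square")
    if ids != cols:
        raise DataFormatError(f"{path}: header ids differ from first-column ids")
    a = df.to_numpy(dtype=float)
    if a.shape[0] != a.shape[1]:
        raise ShapeError(f"{path}: similarity matrix is not square")
    if a.size:
        if a.min() < -RANGE_TOL or a.max() > 1.0 + RANGE_TOL:
            raise RangeError(
                f"{path}: similarity entries outside [0, 1]: "
                f"min={a.min():.3g}, max={a.max():.3g}"
            )
        asym = float(np.abs(a - a.T).max())
        if asym > SYMMETRIZE_TOL:
            raise SymmetryError(f"{path}: asymmetry {asym:.3g} exceeds {SYMMETRIZE_TOL}")
        a = (a + a.T) / 2.0
        if np.abs(np.diag(a) - 1.0).max() > SYMMETRIZE_TOL:
            raise DataFormatError(f"{path}: diagonal entries must equal 1")
        a = np.clip(a, 0.0, 1.0)
        np.fill_diagonal(a, 1.0)
    return SimilarityMatrix(a, ids, axis)


# ---------------------------------------------------------------------------
# writers


def write_matrix(
    m: Union[AssociationMatrix, SimilarityMatrix],
    path: Union[str, Path],
    format: Optional[str] = None,
) -> None:
    """Write a matrix so the paired reader reconstructs an equal object.

    Associations default to the TSV edge list (``format='mtx'`` selects
    MatrixMarket + sidecar ids); similarities are always CSV.
    """
    path = Path(path)
    if isinstance(m, AssociationMatrix):
        fmt = format or "tsv_edges"
        if fmt == "tsv_edges":
            with open(path, "w", encoding="utf-8") as fh:
                for i, j in np.argwhere(m.values != 0):
                    fh.write(f"{m.drug_ids[i]}\t{m.disease_ids[j]}\t1\n")
        elif fmt == "mtx":
            coo = _sparse.coo_matrix(np.asarray(m.values, dtype=int))
            _spio.mmwrite(str(path), coo, field="integer")
            with open(_ids_sidecar(path), "w", encoding="utf-8") as fh:
                for ident in list(m.drug_ids) + list(m.disease_ids):
                    fh.write(ident + "\n")
        else:
            raise ValueError(f"unknown association format {fmt!r}")
        return
    if isinstance(m, SimilarityMatrix):
        pd.DataFrame(m.values, index=m.ids, columns=m.ids).to_csv(path)
        return
    raise TypeError(f"cannot write object of type {type(m).__name__}")


# ---------------------------------------------------------------------------
# statistics and validation


def sparsity(a: AssociationMatrix) -> float:
    """Fraction of observed associations, ``ones / (m * n)``."""
    if a.n_drugs == 0 or a.n_diseases == 0:
        raise ValueError("sparsity is undefined for an empty association matrix")
    return a.n_associations / (a.n_drugs * a.n_diseases)


def align_associations(
    a: AssociationMatrix, drug_ids: List[str], disease_ids: List[str]
) -> AssociationMatrix:
    """Re-index an association matrix onto the given id universe.

    Edge lists cannot carry drugs or diseases without associations, nor an
    id order; the similarity files can.  Every id present in ``a`` must
    appear in the target lists; missing drugs/diseases become all-zero rows
    or columns.
    """
    missing = (set(a.drug_ids) - set(drug_ids)) | (set(a.disease_ids) - set(disease_ids))
    if missing:
        raise DataFormatError(f"association ids absent from similarity ids: {sorted(missing)}")
    values = np.zeros((len(drug_ids), len(disease_ids)), dtype=np.int8)
    row = {d: i for i, d in enumerate(drug_ids)}
    col = {p: j for j, p in enumerate(disease_ids)}
    for i, j in np.argwhere(a.values != 0):
        values[row[a.drug_ids[i]], col[a.disease_ids[j]]] = 1
    return AssociationMatrix(values, list(drug_ids), list(disease_ids))


def _check_similarity(
    sim: SimilarityMatrix, expected_ids: List[str], location: str
) -> List[Violation]:
    out = []
    if sim.ids != expected_ids:
        out.append(
            Violation("id_mismatch", location, "ids differ from association ids")
        )
    a = sim.values
    if a.size:
        if a.min() < -RANGE_TOL or a.max() > 1.0 + RANGE_TOL:
            out.append(
                Violation(
                    "range",
                    location,
                    f"entries outside [0, 1]: min={a.min():.3g} max={a.max():.3g}",
                )
            )
        asym = float(np.abs(a - a.T).max())
        if asym > SYMMETRY_TOL:
            out.append(Violation("asymmetry", location, f"max asymmetry {asym:.3g}"))
        dd = float(np.abs(np.diag(a) - 1.0).max())
        if dd > SYMMETRY_TOL:
            out.append(
                Violation("diagonal", location, f"diagonal deviates from 1 by {dd:.3g}")
            )
    return out


def validate_dataset(d: DatasetBundle) -> List[Violation]:
    """Check every bundle invariant; returns one entry per violated invariant.

    Violations are report entries, never exceptions, so a partially corrupt
    bundle yields a complete report.  An empty report means the bundle is
    valid.
    """
    report: List[Violation] = []
    a = d.associations
    if not np.isin(a.values, (0, 1)).all():
        report.append(
            Violation("not_binary", "associations", "cells other than 0/1 present")
        )
    for name, ids in (("drug", a.drug_ids), ("disease", a.disease_ids)):
        if len(set(ids)) != len(ids):
            report.append(
                Violation("duplicate_ids", "associations", f"duplicate {name} ids")
            )
    report += _check_similarity(d.drug_sim, a.drug_ids, "drug_sim")
    report += _check_similarity(d.disease_sim, a.disease_ids, "disease_sim")
    return report
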