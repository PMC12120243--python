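"""In-memory containers for paired single-cell multi-omics data.

A :class:`CountMatrix` holds one modality (RNA or ATAC) as a sparse
cells × features count matrix with barcode and feature indices; a
:class:`PairedDataset` holds both modalities over the same ordered cell
set plus an optional per-cell label vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp

RNA = "RNA"
ATAC = "ATAC"
_MODALITIES = (RNA, ATAC)


def _as_str_array(values) -> np.ndarray:
    arr = np.asarray(values)
    if arr.dtype.kind not in ("U", "S", "O"):
        arr = arr.astype(str)
    return arr.astype(str)


@dataclass
class CountMatrix:
    """Non-negative cells × features counts for one modality.

    Parameters
    ----------
    values
        Sparse (or dense, converted) matrix, rows = cells, cols = features.
    barcodes
        Ordered cell identifiers; must be unique.
    feature_ids
        Ordered feature identifiers (genes or peaks); must be unique.
    modality
        Either ``"RNA"`` or ``"ATAC"``.
    """

    values: sp.csr_matrix
    barcodes: np.ndarray
    feature_ids: np.ndarray
    modality: str

    def __post_init__(self) -> None:
        if not sp.issparse(self.values):
            self.values = sp.csr_matrix(np.asarray(self.values))
        else:
            self.values = self.values.tocsr()
        self.barcodes = _as_str_array(self.barcodes)
        self.feature_ids = _as_str_array(self.feature_ids)
        if self.modality not in _MODALITIES:
            raise ValueError(f"modality must be one of {_MODALITIES}, got {self.modality!r}")
        n_cells, n_features = self.values.shape
        if len(self.barcodes) != n_cells:
            raise ValueError(f"{len(self.barcodes)} barcodes for {n_cells} matrix rows")
        if len(self.feature_ids) != n_features:
            raise ValueError(f"{len(self.feature_ids)} feature ids for {n_features} matrix columns")
        if len(np.unique(self.barcodes)) != n_cells:
            raise ValueError("duplicate barcodes")
        if len(np.unique(self.feature_ids)) != n_features:
            raise ValueError("duplicate feature ids")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())

    def subset_cells(self, index: np.ndarray) -> "CountMatrix":
        """Row subset by positional index, preserving order of `index`."""
        index = np.asarray(index)
        return CountMatrix(
            values=self.values[index],
            barcodes=self.barcodes[index],
            feature_ids=self.feature_ids,
            modality=self.modality,
        )

    def equals(self, other: "CountMatrix") -> bool:
        return (
            self.modality == other.modality
            and self.values.shape == other.values.shape
            and (self.values != other.values).nnz == 0
            and np.array_equal(self.barcodes, other.barcodes)
            and np.array_equal(self.feature_ids, other.feature_ids)
        )


@dataclass
class PairedDataset:
    """Aligned RNA + ATAC matrices over one ordered cell set.

    ``labels`` may be ``None`` for prediction-only data; when present it is
    aligned elementwise to the shared barcode order.
    """

    rna: CountMatrix
    atac: CountMatrix
    labels: Optional[np.ndarray] = field(default=None)

    def __post_init__(self) -> None:
        if not np.array_equal(self.rna.barcodes, self.atac.barcodes):
            raise ValueError("RNA and ATAC barcodes differ; modalities must be paired")
        if self.labels is not None:
            self.labels = _as_str_array(self.labels)
            if len(self.labels) != self.rna.n_cells:
                raise ValueError(
                    f"{len(self.labels)} labels for {self.rna.n_cells} cells"
                )

    @property
    def barcodes(self) -> np.ndarray:
        return self.rna.barcodes

    @property
    def n_cells(self) -> int:
        return self.rna.n_cells

    def subset_cells(self, index: np.ndarray) -> "PairedDataset":
        index = np.asarray(index)
        labels = self.labels[index] if self.labels is not None else None
        return PairedDataset(
            rna=self.rna.subset_cells(index),
            atac=self.atac.subset_cells(index),
            labels=labels,
        )
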