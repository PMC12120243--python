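"""Reading and per-modality preprocessing of paired matrices.

RNA: per-cell depth normalization to a fixed total, log1p, highly variable
gene (HVG) selection by dispersion. ATAC: optional binarization, removal of
peaks open in too few cells, TF-IDF weighting. The two blocks are then
independently standardized per column, clipped, and squashed into the
bounded input domain of the spline network.

Everything fitted on training cells (selected features, idf vector, column
scalers) is FROZEN into a :class:`Preprocessor` and re-applied verbatim to
test cells — test cells never influence selection or scaling. The module
contains no randomness.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import ATAC, RNA, CountMatrix, PairedDataset


class FormatError(ValueError):
    """Malformed on-disk matrix (header/dimension/nnz inconsistency)."""


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunable preprocessing parameters (all overridable).

    rna_target_sum : per-cell total after depth normalization.
    n_hvg : number of highly variable genes kept (capped at the number of
        genes present).
    atac_min_cell_fraction : peaks nonzero in fewer cells than this fraction
        are dropped.
    atac_binarize : reduce ATAC counts to open/closed before TF-IDF.
    clip_value : z-scores are clamped to +/- this bound.
    squash_to : closed interval the network inputs are squashed into
        (z-scores are divided by 3 before the final clamp, so +/-3 sigma
        spans the spline grid domain).
    """

    rna_target_sum: float = 1e4
    n_hvg: int = 3000
    atac_min_cell_fraction: float = 0.01
    atac_binarize: bool = True
    clip_value: float = 10.0
    squash_to: Tuple[float, float] = (-1.0, 1.0)

    def __post_init__(self) -> None:
        if self.rna_target_sum <= 0:
            raise ValueError("rna_target_sum must be > 0")
        if self.n_hvg <= 0:
            raise ValueError("n_hvg must be positive")
        if not 0.0 <= self.atac_min_cell_fraction <= 1.0:
            raise ValueError("atac_min_cell_fraction must lie in [0, 1]")
        if self.clip_value <= 0:
            raise ValueError("clip_value must be > 0")
        lo, hi = self.squash_to
        if not lo < hi:
            raise ValueError("squash_to interval is empty")


def read_mtx_triplet(directory: Union[str, Path], modality: str) -> CountMatrix:
    """Read `matrix.mtx` + `features.tsv` + `barcodes.tsv` from a directory.

    The on-disk matrix is Matrix Market coordinate format, 1-based, with
    rows = cells; indices are mapped to 0-based internally by the reader.
    """
    directory = Path(directory)
    for name in ("matrix.mtx", "features.tsv", "barcodes.tsv"):
        if not (directory / name).exists():
            raise FileNotFoundError(f"{directory / name} not found")
    try:
        mat = scipy.io.mmread(str(directory / "matrix.mtx"))
    except ValueError as exc:
        raise FormatError(f"malformed matrix.mtx in {directory}: {exc}") from exc
    features = pd.read_csv(directory / "features.tsv", sep="\t", header=None)[0].astype(str).values
    barcodes = pd.read_csv(directory / "barcodes.tsv", sep="\t", header=None)[0].astype(str).values
    n_cells, n_features = mat.shape
    if len(barcodes) != n_cells:
        raise FormatError(
            f"matrix declares {n_cells} cells but barcodes.tsv has {len(barcodes)} entries"
        )
    if len(features) != n_features:
        raise FormatError(
            f"matrix declares {n_features} features but features.tsv has {len(features)} entries"
        )
    return CountMatrix(sp.csr_matrix(mat), barcodes, features, modality)


def read_labels(path: Union[str, Path], barcodes: Optional[np.ndarray] = None) -> np.ndarray:
    """Read a `barcode,cell_type` CSV; align to `barcodes` when given."""
    df = pd.read_csv(path)
    if not {"barcode", "cell_type"}.issubset(df.columns):
        raise FormatError(f"{path} must have columns barcode,cell_type")
    if barcodes is None:
        return df["cell_type"].astype(str).values
    lookup = dict(zip(df["barcode"].astype(str), df["cell_type"].astype(str)))
    missing = [b for b in barcodes if b not in lookup]
    if missing:
        raise KeyError(f"labels missing for barcodes: {missing[:5]}")
    return np.array([lookup[b] for b in barcodes])


def read_paired_dataset(
    rna_dir: Union[str, Path],
    atac_dir: Union[str, Path],
    labels_path: Optional[Union[str, Path]] = None,
) -> PairedDataset:
    rna = read_mtx_triplet(rna_dir, RNA)
    atac = read_mtx_triplet(atac_dir, ATAC)
    labels = read_labels(labels_path, rna.barcodes) if labels_path is not None else None
    return PairedDataset(rna=rna, atac=atac, labels=labels)


def normalize_rna(m: CountMatrix, config: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Depth-normalize each cell to ``rna_target_sum`` total, then log1p.

    All-zero cells stay all-zero (their depth factor is left at 0 rather
    than dividing by zero).
    """
    if m.modality != RNA:
        raise ValueError(f"normalize_rna expects an RNA matrix, got {m.modality}")
    counts = m.dense().astype(float)
    if counts.min() < 0:
        raise ValueError("negative entries in count matrix")
    totals = counts.sum(axis=1, keepdims=True)
    scale = np.divide(
        config.rna_target_sum, totals, out=np.zeros_like(totals), where=totals > 0
    )
    return np.log1p(counts * scale)


def select_hvg(x_log: np.ndarray, n_hvg: int) -> Tuple[np.ndarray, np.ndarray]:
    """Keep the `n_hvg` features with highest dispersion (variance / mean).

    Dispersion is computed on the log-normalized matrix; features with zero
    mean get dispersion 0. Ties break toward the lower original feature
    index; the returned index array is sorted ascending so the selected
    block preserves the original feature order.
    """
    if n_hvg <= 0:
        raise ValueError("n_hvg must be positive")
    n_features = x_log.shape[1]
    if n_hvg > n_features:
        raise ValueError(f"n_hvg={n_hvg} exceeds the {n_features} available features")
    mean = x_log.mean(axis=0)
    var = x_log.var(axis=0)
    dispersion = np.divide(var, mean, out=np.zeros_like(var), where=mean > 0)
    order = np.argsort(-dispersion, kind="stable")  # stable: lower index wins ties
    selected = np.sort(order[:n_hvg])
    return x_log[:, selected], selected


def atac_idf(binary: np.ndarray) -> np.ndarray:
    """idf_p = log(1 + n_cells / (1 + n_cells with peak p open))."""
    n_cells = binary.shape[0]
    n_open = (binary > 0).sum(axis=0)
    return np.log1p(n_cells / (1.0 + n_open))


def preprocess_atac(
    m: CountMatrix,
    config: PreprocessConfig = PreprocessConfig(),
    keep: Optional[np.ndarray] = None,
    idf: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binarize, filter rarely-open peaks, TF-IDF weight.

    tf is the raw (binarized, when ``atac_binarize``) count; the transformed
    value is ``tf * idf``. Pass ``keep``/``idf`` fitted on training cells to
    re-apply a frozen transform; when omitted they are fitted here.

    Returns ``(x, keep, idf)`` where ``keep`` indexes the retained peaks of
    the input matrix and ``idf`` aligns to ``keep``.
    """
    if m.modality != ATAC:
        raise ValueError(f"preprocess_atac expects an ATAC matrix, got {m.modality}")
    counts = m.dense().astype(float)
    tf = (counts > 0).astype(float) if config.atac_binarize else counts
    if keep is None:
        open_fraction = (counts > 0).mean(axis=0)
        keep = np.flatnonzero(open_fraction >= config.atac_min_cell_fraction)
        if keep.size == 0:
            raise ValueError(
                "all peaks were filtered out; lower atac_min_cell_fraction "
                f"(current {config.atac_min_cell_fraction}) or check the matrix"
            )
    tf = tf[:, keep]
    if idf is None:
        idf = atac_idf(tf if config.atac_binarize else (tf > 0).astype(float))
    x = tf * idf[None, :]
    if not np.isfinite(x).all():
        raise ValueError("non-finite values after TF-IDF")
    return x, np.asarray(keep), np.asarray(idf)


@dataclass
class ColumnScaler:
    """Frozen per-column standardization: (x - mean) / std, zero-variance
    columns pass through unscaled."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray) -> "ColumnScaler":
        mean = x.mean(axis=0)
        std = x.std(axis=0)
        std = np.where(std > 0, std, 1.0)
        return cls(mean=mean, std=std)

    def apply(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.std


def concatenate_modalities(
    rna_x: np.ndarray,
    atac_x: np.ndarray,
    config: PreprocessConfig = PreprocessConfig(),
    scalers: Optional[Tuple[ColumnScaler, ColumnScaler]] = None,
) -> Tuple[np.ndarray, Tuple[ColumnScaler, ColumnScaler]]:
    """Standardize each block per column and squash into the input domain.

    Output columns are the RNA block followed by the ATAC block. Each block
    is z-scored (train statistics when ``scalers`` is given), clamped to
    +/- ``clip_value``, divided by 3 and clamped to ``squash_to`` so that
    +/- 3 sigma fills the spline grid domain.
    """
    if rna_x.shape[0] != atac_x.shape[0]:
        raise ValueError(
            f"cell count mismatch: RNA block has {rna_x.shape[0]} rows, "
            f"ATAC block has {atac_x.shape[0]}"
        )
    if scalers is None:
        scalers = (ColumnScaler.fit(rna_x), ColumnScaler.fit(atac_x))
    lo, hi = config.squash_to
    blocks = []
    for x, scaler in zip((rna_x, atac_x), scalers):
        z = np.clip(scaler.apply(x), -config.clip_value, config.clip_value)
        blocks.append(np.clip(z / 3.0, lo, hi))
    return np.concatenate(blocks, axis=1), scalers


@dataclass
class Preprocessor:
    """Fit-on-train / apply-to-test preprocessing for a paired dataset.

    ``fit`` learns the HVG set, peak filter, idf vector and column scalers
    from training cells only; ``transform`` applies them unchanged to any
    cells, so test data can never leak into the fitted statistics.
    """

    config: PreprocessConfig = field(default_factory=PreprocessConfig)
    genes_: Optional[np.ndarray] = None          # selected gene ids
    gene_index_: Optional[np.ndarray] = None     # positions in the fitted gene order
    peaks_: Optional[np.ndarray] = None
    peak_index_: Optional[np.ndarray] = None
    idf_: Optional[np.ndarray] = None
    scalers_: Optional[Tuple[ColumnScaler, ColumnScaler]] = None

    @property
    def rna_width(self) -> int:
        self._check_fitted()
        return len(self.gene_index_)

    @property
    def n_features(self) -> int:
        self._check_fitted()
        return len(self.gene_index_) + len(self.peak_index_)

    def _check_fitted(self) -> None:
        if self.gene_index_ is None:
            raise RuntimeError("Preprocessor is not fitted")

    def fit(self, data: PairedDataset) -> "Preprocessor":
        rna_log = normalize_rna(data.rna, self.config)
        n_hvg = min(self.config.n_hvg, data.rna.n_features)
        rna_sel, gene_index = select_hvg(rna_log, n_hvg)
        atac_x, keep, idf = preprocess_atac(data.atac, self.config)
        _, scalers = concatenate_modalities(rna_sel, atac_x, self.config)
        self.gene_index_ = gene_index
        self.genes_ = data.rna.feature_ids[gene_index]
        self.peak_index_ = keep
        self.peaks_ = data.atac.feature_ids[keep]
        self.idf_ = idf
        self.scalers_ = scalers
        return self

    def transform(self, data: PairedDataset) -> np.ndarray:
        self._check_fitted()
        if not np.array_equal(data.rna.feature_ids[self.gene_index_], self.genes_):
            raise ValueError("gene ids of the input do not match the fitted manifest")
        if not np.array_equal(data.atac.feature_ids[self.peak_index_], self.peaks_):
            raise ValueError("peak ids of the input do not match the fitted manifest")
        rna_log = normalize_rna(data.rna, self.config)[:, self.gene_index_]
        atac_x, _, _ = preprocess_atac(
            data.atac, self.config, keep=self.peak_index_, idf=self.idf_
        )
        x, _ = concatenate_modalities(rna_log, atac_x, self.config, scalers=self.scalers_)
        return x

    def fit_transform(self, data: PairedDataset) -> np.ndarray:
        return self.fit(data).transform(data)

    def manifest(self) -> dict:
        """JSON-serializable record of every fitted statistic."""
        self._check_fitted()
        return {
            "version": 1,
            "config": {
                "rna_target_sum": self.config.rna_target_sum,
                "n_hvg": self.config.n_hvg,
                "atac_min_cell_fraction": self.config.atac_min_cell_fraction,
                "atac_binarize": self.config.atac_binarize,
                "clip_value": self.config.clip_value,
                "squash_to": list(self.config.squash_to),
            },
            "genes": self.genes_.tolist(),
            "gene_index": self.gene_index_.tolist(),
            "peaks": self.peaks_.tolist(),
            "peak_index": self.peak_index_.tolist(),
            "idf": self.idf_.tolist(),
            "scalers": [
                {"mean": s.mean.tolist(), "std": s.std.tolist()} for s in self.scalers_
            ],
        }

    def manifest_hash(self) -> str:
        payload = json.dumps(self.manifest(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()

    def save_manifest(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.manifest(), sort_keys=True, indent=1))

    @classmethod
    def from_manifest(cls, manifest: dict) -> "Preprocessor":
        cfg = manifest["config"]
        config = PreprocessConfig(
            rna_target_sum=cfg["rna_target_sum"],
            n_hvg=cfg["n_hvg"],
            atac_min_cell_fraction=cfg["atac_min_cell_fraction"],
            atac_binarize=cfg["atac_binarize"],
            clip_value=cfg["clip_value"],
            squash_to=tuple(cfg["squash_to"]),
        )
        scalers = tuple(
            ColumnScaler(mean=np.array(s["mean"]), std=np.array(s["std"]))
            for s in manifest["scalers"]
        )
        return cls(
            config=config,
            genes_=np.array(manifest["genes"]),
            gene_index_=np.array(manifest["gene_index"]),
            peaks_=np.array(manifest["peaks"]),
            peak_index_=np.array(manifest["peak_index"]),
            idf_=np.array(manifest["idf"]),
            scalers_=scalers,
        )

    @classmethod
    def load_manifest(cls, path: Union[str, Path]) -> "Preprocessor":
        return cls.from_manifest(json.loads(Path(path).read_text()))
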