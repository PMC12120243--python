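"""Within-cell-type cross-modality data augmentation.

Two cells of the same type carry near-identical transcriptomic and
chromatin-accessibility programs, so the RNA profile of one cell can be
paired with the ATAC profile of another cell of the same type to form a
plausible synthetic training cell. Donors are ordered pairs (RNA donor,
ATAC donor) with self-pairing forbidden; sampling is seeded and, by
default, without replacement among the ordered pairs of each class.

Augmentation operates on PREPROCESSED feature rows inside a training fold:
a synthetic row is the RNA half of one donor's row concatenated with the
ATAC half of the other donor's row.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

Quota = Union[int, Dict[str, int], None]


@dataclass(frozen=True)
class AugmentationPlan:
    """How many synthetic cells to create per type.

    per_type_quota : an int applied to every type, a dict keyed by type
        name, or None for the default "balance" mode — every class is
        topped up to the largest class size, capped at twice its own size.
    allow_reuse : whether an ordered donor pair may repeat. Without reuse,
        a class with n cells can yield at most n*(n-1) synthetic cells.
    """

    per_type_quota: Quota = None
    allow_reuse: bool = False
    seed: int = 0


@dataclass(frozen=True)
class SyntheticCellRecord:
    rna_donor: str
    atac_donor: str
    cell_type: str

    def __post_init__(self) -> None:
        if self.rna_donor == self.atac_donor:
            raise ValueError("self-pairing is forbidden: donors must be distinct cells")


def _quota_for(plan: AugmentationPlan, cls: str, sizes: Dict[str, int]) -> int:
    n_c = sizes[cls]
    if plan.per_type_quota is None:
        target = min(max(sizes.values()), 2 * n_c)
        quota = max(0, target - n_c)
        if n_c < 2:
            return 0  # a singleton class contributes nothing in balance mode
        return quota
    if isinstance(plan.per_type_quota, dict):
        quota = int(plan.per_type_quota.get(cls, 0))
    else:
        quota = int(plan.per_type_quota)
    if quota < 0:
        raise ValueError(f"negative quota for class {cls!r}")
    return quota


def _pair_from_index(idx: int, n: int) -> Tuple[int, int]:
    """Bijection from 0..n(n-1)-1 to ordered pairs (i, j), i != j."""
    i, r = divmod(idx, n - 1)
    j = r + (r >= i)
    return i, j


def plan_augmentation(
    labels: Sequence[str],
    barcodes: Sequence[str],
    plan: AugmentationPlan,
) -> List[SyntheticCellRecord]:
    """Draw seeded donor pairs per class according to the plan.

    Without reuse, a quota at or above the number of ordered pairs yields
    every pair exactly once (in enumeration order); otherwise pairs are
    sampled uniformly without replacement. A class with a single cell and
    an explicit positive quota is an error naming the class; in balance
    mode it simply contributes nothing.
    """
    labels = np.asarray(labels, dtype=str)
    barcodes = np.asarray(barcodes, dtype=str)
    if len(labels) != len(barcodes):
        raise ValueError("labels and barcodes must align")
    rng = np.random.default_rng(plan.seed)
    classes = sorted(set(labels))
    sizes = {c: int((labels == c).sum()) for c in classes}
    records: List[SyntheticCellRecord] = []
    for cls in classes:
        quota = _quota_for(plan, cls, sizes)
        if quota == 0:
            continue
        members = barcodes[labels == cls]
        n = len(members)
        if n < 2:
            raise ValueError(
                f"class {cls!r} has {n} cell(s); at least 2 are needed for augmentation"
            )
        n_pairs = n * (n - 1)
        if plan.allow_reuse:
            idx = rng.integers(0, n_pairs, size=quota)
        elif quota >= n_pairs:
            idx = np.arange(n_pairs)
        else:
            idx = rng.choice(n_pairs, size=quota, replace=False)
        for k in idx:
            i, j = _pair_from_index(int(k), n)
            records.append(SyntheticCellRecord(members[i], members[j], cls))
    return records


def synthesize_cells(
    features: np.ndarray,
    barcodes: Sequence[str],
    rna_width: int,
    records: Sequence[SyntheticCellRecord],
) -> Tuple[np.ndarray, np.ndarray]:
    """Build synthetic feature rows from donor pairs.

    Each output row is ``concat(rna_block[rna_donor], atac_block[atac_donor])``
    where the RNA block is the first ``rna_width`` columns of ``features``.
    Returns ``(rows, labels)``; an empty record list yields a 0-row matrix
    of the right width.
    """
    barcodes = np.asarray(barcodes, dtype=str)
    pos = {b: i for i, b in enumerate(barcodes)}
    rows = np.empty((len(records), features.shape[1]), dtype=features.dtype)
    labels = np.empty(len(records), dtype=object)
    for r, rec in enumerate(records):
        for donor in (rec.rna_donor, rec.atac_donor):
            if donor not in pos:
                raise KeyError(f"unknown donor barcode {donor!r}")
        rows[r, :rna_width] = features[pos[rec.rna_donor], :rna_width]
        rows[r, rna_width:] = features[pos[rec.atac_donor], rna_width:]
        labels[r] = rec.cell_type
    return rows, labels.astype(str)


def augment_dataset(
    features: np.ndarray,
    labels: Sequence[str],
    barcodes: Sequence[str],
    rna_width: int,
    plan: AugmentationPlan,
) -> Tuple[np.ndarray, np.ndarray, List[SyntheticCellRecord]]:
    """Stack real training rows with planned synthetic rows.

    Real rows come first and are unchanged; only the given (training-fold)
    cells ever serve as donors.
    """
    labels = np.asarray(labels, dtype=str)
    records = plan_augmentation(labels, barcodes, plan)
    synth_x, synth_y = synthesize_cells(features, barcodes, rna_width, records)
    if len(records) == 0:
        return features, labels, records
    return (
        np.vstack([features, synth_x]),
        np.concatenate([labels, synth_y]),
        records,
    )


def records_to_frame(records: Sequence[SyntheticCellRecord]) -> pd.DataFrame:
    """Audit table of donor pairs (CSV-friendly)."""
    return pd.DataFrame(
        [(r.rna_donor, r.atac_donor, r.cell_type) for r in records],
        columns=["rna_donor", "atac_donor", "cell_type"],
    )
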