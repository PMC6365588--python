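"""Depth normalization by random subsampling of UMI counts per cell.

Sequencing-depth differences between cells are removed by drawing a
fixed number of UMIs from each cell's pool **without replacement**
(multivariate hypergeometric) and discarding cells whose total falls
below the target depth.  For multimodal experiments a cell is kept only
when it survives the subsampling of *both* modalities, so the retained
mRNA and ARC matrices stay matched cell-for-cell.

Each cell gets its own random stream derived from the global seed and
the cell's name, so results do not depend on cell order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .dataset import MultimodalDataset
from .matrix import CountMatrix

#: mRNA subsampling depths used across the emulated experiments
#: (cell-surface, fixation-comparison, intracellular).
MRNA_DEPTH_PRESETS = (10000, 40000, 4500)

#: ARC subsampling depths (cell-surface experiment, intracellular experiment).
ARC_DEPTH_PRESETS = (2750, 400)

#: Depths of the intracellular (fixed-cell) experiment.
INTRACELLULAR_MRNA_DEPTH = 4500
INTRACELLULAR_ARC_DEPTH = 400


@dataclass(frozen=True)
class DepthSpec:
    """Target depth per modality plus the subsampling seed."""

    mrna_depth: int = INTRACELLULAR_MRNA_DEPTH
    arc_depth: int = INTRACELLULAR_ARC_DEPTH
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mrna_depth <= 0 or self.arc_depth <= 0:
            raise ValueError("depths must be positive")


def _cell_rng(seed: int, cell_name: str, salt: int) -> np.random.Generator:
    """Per-cell stream split keyed by a stable hash of the cell name."""
    return np.random.default_rng([seed, salt, zlib.crc32(cell_name.encode())])


def subsample_cell(
    counts: np.ndarray, depth: int, rng: np.random.Generator
) -> Optional[np.ndarray]:
    """Draw exactly ``depth`` molecules from one cell's UMI pool.

    Sampling is uniform without replacement over the UMI-expanded pool
    (multivariate hypergeometric), so the output total equals ``depth``
    and no feature exceeds its raw count.  Returns ``None`` when the cell
    holds fewer than ``depth`` molecules (the cell is discarded).
    """
    counts = np.asarray(counts)
    if counts.size and counts.min() < 0:
        raise ValueError("counts must be non-negative")
    total = int(counts.sum())
    if total < depth:
        return None
    if total == depth:
        return counts.astype(np.int64, copy=True)
    return rng.multivariate_hypergeometric(counts.astype(np.int64), depth).astype(np.int64)


def subsample_matrix(
    matrix: CountMatrix, depth: int, seed: int
) -> Tuple[pd.DataFrame, List[str]]:
    """Subsample every cell of a matrix; return kept columns and discarded cells."""
    salt = 0 if matrix.modality == "mRNA" else 1
    kept: Dict[str, np.ndarray] = {}
    discarded: List[str] = []
    for cell in matrix.cell_names:
        vec = subsample_cell(
            matrix.data[cell].to_numpy(), depth, _cell_rng(seed, cell, salt)
        )
        if vec is None:
            discarded.append(cell)
        else:
            kept[cell] = vec
    if kept:
        data = pd.DataFrame(kept, index=matrix.data.index)
    else:
        data = pd.DataFrame(index=matrix.data.index)
    return data, discarded


def normalize_dataset(
    mrna: CountMatrix,
    arc: CountMatrix,
    spec: DepthSpec,
    cell_meta: Optional[pd.DataFrame] = None,
) -> MultimodalDataset:
    """Joint depth normalization of the two modalities.

    A cell is retained iff it survives both subsamplings; retained cells
    total exactly ``mrna_depth`` and ``arc_depth`` respectively, in
    identical cell order across modalities.  Discarded cells are listed
    in the dataset report with the modality that failed.
    """
    cells_m = set(mrna.cell_names)
    cells_a = set(arc.cell_names)
    if not cells_m & cells_a:
        raise ValueError("mRNA and ARC matrices share no cell names")
    if cells_m != cells_a:
        raise ValueError("mRNA and ARC matrices must cover the same cells")

    sub_m, drop_m = subsample_matrix(mrna, spec.mrna_depth, spec.seed)
    sub_a, drop_a = subsample_matrix(arc, spec.arc_depth, spec.seed)
    dropped = {c: "mRNA" for c in drop_m}
    for c in drop_a:
        dropped[c] = "mRNA+ARC" if c in dropped else "ARC"
    kept = [c for c in mrna.cell_names if c not in dropped]

    meta = pd.DataFrame(index=pd.Index(kept, name="cell"))
    if cell_meta is not None:
        meta = cell_meta.reindex(kept)
        meta.index.name = "cell"
    report = {
        "mrna_depth": spec.mrna_depth,
        "arc_depth": spec.arc_depth,
        "seed": spec.seed,
        "n_input_cells": len(cells_m),
        "n_kept_cells": len(kept),
        "discarded": dropped,
    }
    if not kept:
        import warnings

        warnings.warn("no cells passed the depth thresholds", stacklevel=2)
    return MultimodalDataset(
        cells=meta,
        mrna=CountMatrix("mRNA", sub_m[kept] if kept else sub_m),
        arc=CountMatrix("ARC", sub_a[kept] if kept else sub_a),
        report=report,
    )
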