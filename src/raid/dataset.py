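"""Matched multimodal container produced by depth normalization."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import pandas as pd

from .matrix import CountMatrix


@dataclass
class MultimodalDataset:
    """Depth-normalized mRNA + ARC matrices with shared cell ordering.

    ``cells`` holds per-cell metadata (group/batch labels when known);
    ``lognorm``, ``variable_genes`` and ``embedding`` are filled in by the
    analysis stage.  Every per-cell structure uses the identical cell
    order.
    """

    cells: pd.DataFrame               # index = cell names; optional columns: group, batch
    mrna: CountMatrix
    arc: CountMatrix
    lognorm: Optional[pd.DataFrame] = None        # genes x cells, ln(1 + cpX)
    variable_genes: Optional[List[str]] = None
    embedding: Optional[pd.DataFrame] = None      # cells x (tsne1, tsne2)
    pcs_used: Optional[range] = None
    report: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        order = list(self.cells.index)
        if self.mrna.cell_names != order or self.arc.cell_names != order:
            raise ValueError("cell ordering differs between modalities and metadata")

    @property
    def cell_names(self) -> List[str]:
        return list(self.cells.index)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cells_in_group(self, group: str) -> List[str]:
        if "group" not in self.cells.columns:
            raise KeyError("dataset has no group labels")
        return list(self.cells.index[self.cells["group"] == group])
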