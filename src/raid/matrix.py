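"""Features-by-cells UMI count tables shared by every pipeline stage.

A :class:`CountMatrix` is a thin, validated wrapper around a pandas
DataFrame with features (genes or antibodies) as rows and cells as
columns, tagged with the modality it carries.  Both modalities produced
from one library share the identical cell-name list so they can be
combined per cell without any joining logic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Set, Tuple

import numpy as np
import pandas as pd

MODALITIES = ("mRNA", "ARC")


@dataclass
class CountMatrix:
    """UMI-collapsed counts for one modality.

    Parameters
    ----------
    modality:
        Either ``"mRNA"`` (transcript counts keyed by the read-2 UMI) or
        ``"ARC"`` (antibody counts keyed by the 15-nt ARC UMI).
    data:
        Integer DataFrame, features as rows, cells as columns.
    """

    modality: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate feature names")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate cell names")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValueError("counts must be integers")
            self.data = self.data.astype(np.int64)
        if values.size and self.data.to_numpy().min() < 0:
            raise ValueError("counts must be non-negative")

    # -- basic accessors -------------------------------------------------
    @property
    def feature_names(self) -> list[str]:
        return list(self.data.index)

    @property
    def cell_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_cells(self) -> int:
        return self.data.shape[1]

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    def cell_totals(self) -> pd.Series:
        """Total UMI count per cell."""
        return self.data.sum(axis=0)

    def cell_vector(self, cell: str) -> np.ndarray:
        return self.data[cell].to_numpy()

    def select_cells(self, cells: Sequence[str]) -> "CountMatrix":
        missing = [c for c in cells if c not in self.data.columns]
        if missing:
            raise KeyError(f"cells not in matrix: {missing[:5]}")
        return CountMatrix(self.modality, self.data[list(cells)].copy())

    # -- construction ----------------------------------------------------
    @classmethod
    def from_tallies(
        cls,
        modality: str,
        tallies: Set[Tuple[str, str, str]],
        cell_names: Iterable[str],
        feature_names: Iterable[str],
    ) -> "CountMatrix":
        """Build a matrix from UMI-deduplicated ``(cell, feature, umi)`` tallies.

        Each distinct tuple contributes exactly one count; the matrix spans
        the full cell and feature universes including all-zero rows/columns.
        """
        cells = list(cell_names)
        feats = list(feature_names)
        data = pd.DataFrame(
            np.zeros((len(feats), len(cells)), dtype=np.int64), index=feats, columns=cells
        )
        for cell, feature, _umi in tallies:
            data.at[feature, cell] += 1
        return cls(modality, data)

    # -- plain-text I/O ---------------------------------------------------
    def to_tsv(self, path: str | Path) -> Path:
        """Write a TSV with features as rows and cells as columns."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.data.to_csv(path, sep="\t", index_label="feature")
        return path

    @classmethod
    def from_tsv(cls, path: str | Path, modality: str) -> "CountMatrix":
        data = pd.read_csv(path, sep="\t", index_col=0)
        data.index = data.index.astype(str).rename(None)
        data.columns = data.columns.astype(str)
        if data.empty:
            data = data.astype(np.int64)
        return cls(modality, data)

    def equals_up_to_order(self, other: "CountMatrix") -> bool:
        """True when both matrices hold identical counts after sorting names."""
        if set(self.feature_names) != set(other.feature_names):
            return False
        if set(self.cell_names) != set(other.cell_names):
            return False
        a = self.data.sort_index(axis=0).sort_index(axis=1)
        b = other.data.sort_index(axis=0).sort_index(axis=1)
        return bool((a.to_numpy() == b.to_numpy()).all())
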