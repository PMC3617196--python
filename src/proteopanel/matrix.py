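"""Quantitation matrices with explicit missingness.

The pipeline's central container is a feature x sample matrix of either
log2 relative abundances (discovery platform, measured against a pooled
reference channel) or linear concentrations (targeted validation
platforms).  Missing cells are a first-class concept: shotgun platforms
undersample, so a protein group simply goes unmeasured in some runs.
Internally a cell is unobserved iff it is NaN; the :attr:`QuantMatrix.observed`
mask makes that contract explicit for callers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

LOG2_RATIO = "log2_ratio"
LINEAR_CONCENTRATION = "linear_concentration"
_SCALES = (LOG2_RATIO, LINEAR_CONCENTRATION)


@dataclass
class QuantMatrix:
    """Feature (protein group / protein) x sample matrix with a missingness mask.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with sample ids as columns.  NaN
        encodes "not observed"; every non-NaN cell is a real measurement.
    scale
        Either ``"log2_ratio"`` or ``"linear_concentration"``.
    """

    values: pd.DataFrame
    scale: str = LOG2_RATIO

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise ValueError(f"scale must be one of {_SCALES}, got {self.scale!r}")
        if not self.values.index.is_unique:
            raise ValueError("row ids must be unique")
        if not self.values.columns.is_unique:
            raise ValueError("column (sample) ids must be unique")
        self.values = self.values.astype(float)

    # -- basic protocol ----------------------------------------------------
    @property
    def row_ids(self) -> list:
        return list(self.values.index)

    @property
    def col_ids(self) -> list:
        return list(self.values.columns)

    @property
    def observed(self) -> pd.DataFrame:
        """Boolean mask, True where a cell carries a real measurement."""
        return self.values.notna()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def is_complete(self) -> bool:
        return bool(self.values.notna().all().all())

    # -- views -------------------------------------------------------------
    def restrict_rows(self, rows: Sequence) -> "QuantMatrix":
        missing = [r for r in rows if r not in self.values.index]
        if missing:
            raise KeyError(f"rows not in matrix: {missing}")
        return QuantMatrix(self.values.loc[list(rows)].copy(), scale=self.scale)

    def restrict_cols(self, cols: Sequence) -> "QuantMatrix":
        missing = [c for c in cols if c not in self.values.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return QuantMatrix(self.values[list(cols)].copy(), scale=self.scale)

    def to_log2(self) -> "QuantMatrix":
        """Return a log2-scale view; linear concentrations must be positive."""
        if self.scale == LOG2_RATIO:
            return self
        vals = self.values
        if (vals <= 0).any().any():
            raise ValueError("non-positive concentrations cannot be log-transformed")
        return QuantMatrix(np.log2(vals), scale=LOG2_RATIO)

    # -- serialization -----------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV; unobserved cells are empty fields."""
        self.values.to_csv(path, sep="\t", index_label="id", na_rep="")

    @classmethod
    def from_tsv(cls, path: str | Path, scale: str = LOG2_RATIO) -> "QuantMatrix":
        df = pd.read_csv(path, sep="\t", index_col="id")
        return cls(df, scale=scale)

    @classmethod
    def from_csv(cls, path: str | Path, scale: str = LINEAR_CONCENTRATION) -> "QuantMatrix":
        """Read a protein x sample concentration table (first column = protein id)."""
        df = pd.read_csv(path, index_col=0)
        return cls(df, scale=scale)
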