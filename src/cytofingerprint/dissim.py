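"""Symmetric sample-by-sample dissimilarity matrices.

Every fingerprint comparison method in this package (Dalmatian Plot, CHIC,
CyBar, FlowFP) reduces a set of samples to one of these; the ordination and
dynamics indices consume them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DissimilarityMatrix"]

_SYM_TOL = 1e-12


@dataclass
class DissimilarityMatrix:
    """A symmetric, zero-diagonal, non-negative n x n matrix with sample ids.

    Parameters
    ----------
    ids
        Sample identifiers, one per row/column.
    values
        The n x n dissimilarities.
    method
        Free-text provenance tag, e.g. ``"chic"`` or ``"cybar/bray_curtis"``.
    """

    ids: list[str]
    values: np.ndarray
    method: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} sample ids"
            )
        if len(set(self.ids)) != n:
            raise ValueError("sample ids must be unique")
        if not np.allclose(self.values, self.values.T, atol=_SYM_TOL, rtol=0):
            raise ValueError("matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("dissimilarities must be non-negative")

    @property
    def n(self) -> int:
        return len(self.ids)

    def pair(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])

    def condensed(self) -> np.ndarray:
        """Strict upper triangle, row-major (scipy ``squareform`` order)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def reorder(self, ids: list[str]) -> "DissimilarityMatrix":
        idx = [self.ids.index(s) for s in ids]
        return DissimilarityMatrix(
            list(ids), self.values[np.ix_(idx, idx)], self.method, dict(self.meta)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path, method: str = "") -> "DissimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        ids = [str(s) for s in df.index]
        if [str(c) for c in df.columns] != ids:
            raise ValueError("row and column sample ids differ")
        return cls(ids, df.to_numpy(dtype=float), method=method)
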