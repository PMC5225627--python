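"""Shared result containers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class FstMatrix:
    """Symmetric pairwise F_ST matrix with an estimator tag.

    ``estimator`` is ``"WC84"`` for the Weir & Cockerham (1984)
    variance-components estimator on individual genotypes and ``"pool"``
    for the read-frequency estimator on pooled data.  Entries are
    reported as computed (negative values are not truncated at zero).
    """

    labels: list[str]
    values: np.ndarray
    estimator: str
    flags: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValueError(f"matrix shape {self.values.shape} != ({k}, {k})")
        if not np.allclose(np.diag(self.values), 0, equal_nan=True):
            raise ValueError("diagonal must be zero")
        finite = np.isfinite(self.values)
        sym_ok = np.allclose(
            self.values[finite & finite.T], self.values.T[finite & finite.T]
        )
        if not sym_ok:
            raise ValueError("matrix must be symmetric")
        if np.nanmax(self.values) > 1 + 1e-9:
            raise ValueError("F_ST entries must be <= 1")

    def condensed(self) -> np.ndarray:
        """Lower-triangle entries in row-major pair order."""
        idx = np.tril_indices(len(self.labels), k=-1)
        return self.values[idx]

    def pair_labels(self) -> list[tuple[str, str]]:
        out = []
        for i in range(1, len(self.labels)):
            for j in range(i):
                out.append((self.labels[j], self.labels[i]))
        return out

    def mean(self) -> float:
        return float(np.nanmean(self.condensed()))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    @classmethod
    def from_condensed(
        cls, labels: list[str], condensed: np.ndarray, estimator: str
    ) -> "FstMatrix":
        k = len(labels)
        values = np.zeros((k, k))
        idx = np.tril_indices(k, k=-1)
        values[idx] = condensed
        values[(idx[1], idx[0])] = condensed
        return cls(labels=labels, values=values, estimator=estimator)
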