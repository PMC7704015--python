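"""Count-table container for bilateral (paired-organ) binary response data.

Each patient contributes l in {0, 1, 2} responding organs; a study with g
groups is summarised by a 3 x g table of counts m_{li}.  Column sums are the
group sizes m_i, row sums the response-category totals S_l.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["BilateralTable"]


class BilateralTable:
    """A 3 x g table of bilateral response counts.

    Parameters
    ----------
    counts : array-like, shape (3, g)
        Nonnegative integer counts; row ``l`` holds the number of patients
        with ``l`` responding organs, column ``i`` the ``i``-th group.
    labels : sequence of str, optional
        Group labels; defaults to ``g1..gg``.
    """

    def __init__(self, counts, labels: Sequence[str] | None = None):
        arr = np.asarray(counts)
        if arr.ndim != 2 or arr.shape[0] != 3:
            raise ValueError(
                f"counts must have shape (3, g); got {arr.shape}"
            )
        if not np.issubdtype(arr.dtype, np.integer):
            rounded = np.rint(arr)
            if not np.all(np.isfinite(arr)) or np.any(np.abs(arr - rounded) > 0):
                raise ValueError("counts must be integers")
            arr = rounded.astype(np.int64)
        if np.any(arr < 0):
            raise ValueError("counts must be nonnegative")
        self.counts = arr.astype(np.int64)
        g = arr.shape[1]
        if labels is None:
            labels = [f"g{i + 1}" for i in range(g)]
        elif len(labels) != g:
            raise ValueError("number of labels must match number of groups")
        self.labels = [str(x) for x in labels]
        if np.any(self.group_sizes < 1):
            raise ValueError("every group must contain at least one patient")

    # -- derived margins ---------------------------------------------------

    @property
    def n_groups(self) -> int:
        return self.counts.shape[1]

    @property
    def group_sizes(self) -> np.ndarray:
        """Column sums m_i."""
        return self.counts.sum(axis=0)

    @property
    def response_totals(self) -> np.ndarray:
        """Row sums (S_0, S_1, S_2)."""
        return self.counts.sum(axis=1)

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_groups(cls, groups: Iterable[Sequence[int]], labels=None
                    ) -> "BilateralTable":
        """Build from per-group triples ``(m0, m1, m2)``."""
        cols = [np.asarray(gr) for gr in groups]
        if any(c.shape != (3,) for c in cols):
            raise ValueError("each group must be a triple (m0, m1, m2)")
        return cls(np.column_stack(cols), labels=labels)

    @classmethod
    def from_flat(cls, flat: Sequence[int], labels=None) -> "BilateralTable":
        """Build from a flat vector in column-major (group-by-group) order.

        ``(m01, m11, m21, m02, m12, m22, ...)`` — the conventional flattened
        m* notation.  Group sizes are derived from the data.
        """
        vec = np.asarray(flat).ravel()
        if vec.size % 3 != 0 or vec.size == 0:
            raise ValueError("flat vector length must be a positive multiple of 3")
        return cls(vec.reshape(-1, 3).T, labels=labels)

    @classmethod
    def from_csv(cls, path, sep: str | None = None) -> "BilateralTable":
        """Read a wide-layout table: header of group labels, 3 data rows
        indexed 0, 1, 2 (the number of responding organs)."""
        df = pd.read_csv(path, sep=sep, engine="python", index_col=0)
        if df.shape[0] != 3:
            raise ValueError(
                f"expected 3 data rows (responses 0,1,2); got {df.shape[0]}"
            )
        idx = [str(x).strip() for x in df.index]
        if idx != ["0", "1", "2"]:
            raise ValueError("row index must be the response counts 0,1,2")
        values = df.to_numpy()
        return cls(values, labels=list(df.columns))

    # -- serialization -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=[0, 1, 2], columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    def permuted(self, order: Sequence[int]) -> "BilateralTable":
        """Return the table with groups reordered (same data, new order)."""
        order = list(order)
        if sorted(order) != list(range(self.n_groups)):
            raise ValueError("order must be a permutation of the groups")
        return BilateralTable(self.counts[:, order],
                              labels=[self.labels[i] for i in order])

    # -- dunder ------------------------------------------------------------

    def __eq__(self, other) -> bool:
        return (isinstance(other, BilateralTable)
                and np.array_equal(self.counts, other.counts))

    def __hash__(self):
        return hash(self.counts.tobytes())

    def __repr__(self) -> str:
        return (f"BilateralTable(g={self.n_groups}, N={self.n_total}, "
                f"sizes={self.group_sizes.tolist()})")
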