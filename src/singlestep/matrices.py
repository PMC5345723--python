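"""Labelled symmetric relationship matrices.

Every square matrix that flows between modules (A, G, H, their blocks and
inverses) carries an explicit ordered id list, so no positional convention
ever leaks across module boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["RelationshipMatrix"]

_SYMMETRY_TOL = 1e-10

#: role tags a RelationshipMatrix may carry
ROLES = {
    "A", "A11", "A22", "A12", "G", "G_star", "G_w", "H",
    "A_inv", "H_inv", "G_inv", "A22_inv",
}


@dataclass
class RelationshipMatrix:
    """A symmetric matrix of additive-relationship coefficients over named ids.

    Parameters
    ----------
    ids
        Ordered individual identifiers; ``values[i, j]`` refers to the pair
        ``(ids[i], ids[j])``.
    values
        Square symmetric float array, ``len(ids) x len(ids)``.
    role
        Free-form tag recording what the matrix is (``"A"``, ``"G"``,
        ``"H_inv"``, ...). Purely informational.
    """

    ids: tuple[str, ...]
    values: np.ndarray
    role: str = "A"
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.ids = tuple(str(i) for i in self.ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} ids"
            )
        if n and not np.allclose(self.values, self.values.T, atol=_SYMMETRY_TOL, rtol=0.0):
            raise ValueError("relationship matrix is not symmetric to 1e-10")
        self._index = {ind: k for k, ind in enumerate(self.ids)}
        if len(self._index) != n:
            raise ValueError("duplicate ids in relationship matrix")

    # -- element access -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.ids)

    def loc(self, i: str, j: str) -> float:
        return float(self.values[self._index[i], self._index[j]])

    def indices_of(self, ids) -> np.ndarray:
        try:
            return np.array([self._index[i] for i in ids], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - message formatting
            raise KeyError(f"id {exc.args[0]!r} not present in matrix") from None

    def submatrix(self, ids, role: str | None = None) -> "RelationshipMatrix":
        """Rows/columns for ``ids``, reordered to match their order."""
        idx = self.indices_of(ids)
        return RelationshipMatrix(tuple(ids), self.values[np.ix_(idx, idx)],
                                  role or self.role)

    # -- I/O -------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="id")

    @classmethod
    def from_tsv(cls, path, role: str = "A") -> "RelationshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(tuple(df.index), df.to_numpy(dtype=float), role)

    def to_triplets(self, threshold: float = 0.0) -> pd.DataFrame:
        """Sparse (id_i, id_j, value) upper-triangle export."""
        iu, ju = np.triu_indices(self.n)
        vals = self.values[iu, ju]
        keep = np.abs(vals) > threshold
        return pd.DataFrame({
            "id_i": np.asarray(self.ids)[iu[keep]],
            "id_j": np.asarray(self.ids)[ju[keep]],
            "value": vals[keep],
        })
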