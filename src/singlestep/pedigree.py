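"""Pedigrees and the numerator relationship matrix A.

Reads and validates pedigree tables, orders them topologically, and builds
the average numerator relationship matrix (tabular method), its sparse
inverse (Henderson's rules with inbreeding), per-individual inbreeding
coefficients, and the genotyped/non-genotyped partition blocks used by the
single-step combination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .matrices import RelationshipMatrix

__all__ = [
    "PedigreeTable",
    "read_pedigree",
    "build_A",
    "build_A_inverse",
    "inbreeding",
    "extract_blocks",
]

#: id spellings treated as "parent unknown" by default
DEFAULT_UNKNOWN = ("", "0", "NA")


class PedigreeError(ValueError):
    """Invalid pedigree: duplicate ids, cycles, self-parenting."""


@dataclass
class PedigreeTable:
    """A validated, topologically sorted pedigree.

    ``ids`` is ordered so every parent precedes its offspring; ``dam`` and
    ``sire`` hold positional indices into ``ids`` (-1 for unknown).
    """

    ids: tuple[str, ...]
    dam: np.ndarray
    sire: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.dam = np.asarray(self.dam, dtype=np.int64)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self._index = {i: k for k, i in enumerate(self.ids)}

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, individual: str) -> int:
        return self._index[individual]

    def dam_of(self, individual: str) -> str | None:
        d = self.dam[self._index[individual]]
        return self.ids[d] if d >= 0 else None

    def sire_of(self, individual: str) -> str | None:
        s = self.sire[self._index[individual]]
        return self.ids[s] if s >= 0 else None

    def founders(self) -> list[str]:
        return [i for k, i in enumerate(self.ids)
                if self.dam[k] < 0 and self.sire[k] < 0]

    def families(self) -> dict[str, list[str]]:
        """Offspring grouped by dam id (individuals with a recorded dam)."""
        fams: dict[str, list[str]] = {}
        for k, i in enumerate(self.ids):
            if self.dam[k] >= 0:
                fams.setdefault(self.ids[self.dam[k]], []).append(i)
        return fams

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, str | None, str | None]],
        unknown: Sequence[str] = DEFAULT_UNKNOWN,
    ) -> "PedigreeTable":
        """Validate and topologically sort raw (individual, dam, sire) rows.

        Parents referenced but never declared are auto-inserted as founders
        with a warning; duplicate ids and cycles (including self-parenting)
        raise :class:`PedigreeError`.
        """
        unk = set(unknown) | {None}

        def norm(x) -> str | None:
            if x is None or (isinstance(x, float) and np.isnan(x)):
                return None
            s = str(x).strip()
            return None if s in unk else s

        parents: dict[str, tuple[str | None, str | None]] = {}
        order: list[str] = []
        for ind, dam, sire in records:
            ind = str(ind).strip()
            if not ind or ind in unk:
                raise PedigreeError(f"invalid individual id {ind!r}")
            if ind in parents:
                raise PedigreeError(f"duplicate individual id {ind!r}")
            parents[ind] = (norm(dam), norm(sire))
            order.append(ind)

        undeclared = [p for pr in parents.values() for p in pr
                      if p is not None and p not in parents]
        if undeclared:
            seen = sorted(set(undeclared))
            warnings.warn(
                f"{len(seen)} parent id(s) referenced but never declared; "
                f"inserted as founders: {seen[:5]}{'...' if len(seen) > 5 else ''}",
                stacklevel=2,
            )
            for p in seen:
                parents[p] = (None, None)
                order.append(p)

        # Kahn topological sort, stable w.r.t. file order.
        children: dict[str, list[str]] = {i: [] for i in parents}
        indeg = {i: 0 for i in parents}
        for ind, (d, s) in parents.items():
            if d == ind or s == ind:
                raise PedigreeError(f"individual {ind!r} is its own parent")
            for p in {d, s} - {None}:
                children[p].append(ind)
                indeg[ind] += 1
        ready = [i for i in order if indeg[i] == 0]
        sorted_ids: list[str] = []
        while ready:
            i = ready.pop(0)
            sorted_ids.append(i)
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    ready.append(c)
        if len(sorted_ids) != len(parents):
            cyclic = sorted(set(parents) - set(sorted_ids))
            raise PedigreeError(f"pedigree contains a cycle involving {cyclic[:5]}")

        pos = {i: k for k, i in enumerate(sorted_ids)}
        dam = np.array([pos[parents[i][0]] if parents[i][0] else -1 for i in sorted_ids])
        sire = np.array([pos[parents[i][1]] if parents[i][1] else -1 for i in sorted_ids])
        return cls(tuple(sorted_ids), dam, sire)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "individual": self.ids,
            "dam": [self.dam_of(i) or "" for i in self.ids],
            "sire": [self.sire_of(i) or "" for i in self.ids],
        })

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_pedigree(path, unknown: Sequence[str] = DEFAULT_UNKNOWN) -> PedigreeTable:
    """Read a CSV/TSV pedigree with columns individual, dam, sire.

    The delimiter is sniffed from the header line; ``unknown`` lists the id
    spellings that mean "parent not recorded".
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    cols = {c.lower().strip(): c for c in df.columns}
    missing = [c for c in ("individual", "dam", "sire") if c not in cols]
    if missing:
        raise PedigreeError(f"pedigree file lacks column(s) {missing}")
    rows = zip(df[cols["individual"]], df[cols["dam"]], df[cols["sire"]])
    return PedigreeTable.from_records(rows, unknown=unknown)


def build_A(ped: PedigreeTable) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    Founders are assumed non-inbred and unrelated; a(i,i) = 1 + F_i with
    F_i = half the relationship between i's parents.
    """
    n = ped.n
    a = np.zeros((n, n))
    dam, sire = ped.dam, ped.sire
    for i in range(n):
        d, s = dam[i], sire[i]
        # parents precede i after the topological sort
        row = np.zeros(i)
        if d >= 0:
            row += 0.5 * a[d, :i]
        if s >= 0:
            row += 0.5 * a[s, :i]
        a[i, :i] = row
        a[:i, i] = row
        f = 0.5 * a[d, s] if (d >= 0 and s >= 0) else 0.0
        a[i, i] = 1.0 + f
    return RelationshipMatrix(ped.ids, a, role="A")


def inbreeding(ped: PedigreeTable) -> dict[str, float]:
    """Per-individual inbreeding coefficients F_i = a(i,i) - 1."""
    diag = np.diag(build_A(ped).values)
    return {i: float(diag[k] - 1.0) for k, i in enumerate(ped.ids)}


def build_A_inverse(ped: PedigreeTable, as_dense: bool = True) -> RelationshipMatrix | sp.csr_matrix:
    """Sparse direct inverse of A by Henderson's rules with inbreeding.

    The Mendelian-sampling variance of each individual uses the parental
    inbreeding coefficients (obtained from the tabular A diagonal):
    d_i = 1 - 0.25 (1 + F_dam) - 0.25 (1 + F_sire), where an unknown
    parent's term is dropped (d_i = 1 for founders).

    Returns a dense :class:`RelationshipMatrix` tagged ``A_inv`` by default;
    with ``as_dense=False`` the raw ``scipy.sparse`` CSR matrix (same id
    order as ``ped.ids``) is returned.
    """
    n = ped.n
    f = np.diag(build_A(ped).values) - 1.0
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for i in range(n):
        par = [p for p in (ped.dam[i], ped.sire[i]) if p >= 0]
        d_i = 1.0 - sum(0.25 * (1.0 + f[p]) for p in par)
        inv_d = 1.0 / d_i
        coeff = [(i, 1.0)] + [(p, -0.5) for p in par]
        for j, cj in coeff:
            for k, ck in coeff:
                rows.append(j)
                cols.append(k)
                vals.append(cj * ck * inv_d)
    ainv = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    if not as_dense:
        return ainv
    return RelationshipMatrix(ped.ids, ainv.toarray(), role="A_inv")


@dataclass
class ABlocks:
    """Partition of A by genotyped status: A11 (non-genotyped), A22
    (genotyped, ordered to match the genotype matrix), the cross block A12,
    and the dense inverse of A22."""

    A11: RelationshipMatrix
    A12: pd.DataFrame
    A22: RelationshipMatrix
    A22_inv: RelationshipMatrix


def extract_blocks(A: RelationshipMatrix, genotyped_ids: Sequence[str]) -> ABlocks:
    """Split A into genotyped/non-genotyped blocks.

    ``genotyped_ids`` sets the row/column order of A22 (and of A12's
    columns) so downstream genomic matrices line up without further
    bookkeeping.
    """
    genotyped_ids = [str(i) for i in genotyped_ids]
    gset = set(genotyped_ids)
    if len(gset) != len(genotyped_ids):
        raise ValueError("duplicate ids in genotyped_ids")
    unknown = gset - set(A.ids)
    if unknown:
        raise KeyError(f"genotyped ids not present in A: {sorted(unknown)[:5]}")
    non_g = [i for i in A.ids if i not in gset]
    i1 = A.indices_of(non_g)
    i2 = A.indices_of(genotyped_ids)
    A11 = RelationshipMatrix(tuple(non_g), A.values[np.ix_(i1, i1)], "A11")
    A22 = RelationshipMatrix(tuple(genotyped_ids), A.values[np.ix_(i2, i2)], "A22")
    A12 = pd.DataFrame(A.values[np.ix_(i1, i2)], index=non_g, columns=genotyped_ids)
    if len(genotyped_ids):
        a22_inv = np.linalg.inv(A22.values)
        a22_inv = 0.5 * (a22_inv + a22_inv.T)
    else:
        a22_inv = np.zeros((0, 0))
    A22_inv = RelationshipMatrix(tuple(genotyped_ids), a22_inv, "A22_inv")
    return ABlocks(A11=A11, A12=A12, A22=A22, A22_inv=A22_inv)
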