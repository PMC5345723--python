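"""Combining pedigree and genomic relationships: G scaling, blending, H.

The genomic matrix is first scaled so its average diagonal and overall
average match those of the pedigree block A22 for the genotyped
individuals (G* = beta G + alpha), then blended with A22
(G_w = w G* + (1-w) A22, default w = 0.95) to guarantee invertibility, and
finally substituted into the single-step matrix

    H = [[A11 + A12 A22^-1 (G_w - A22) A22^-1 A21,  A12 A22^-1 G_w],
         [G_w A22^-1 A21,                            G_w          ]]

whose inverse has the sparse-friendly form
H^-1 = A^-1 + [[0, 0], [0, G_w^-1 - A22^-1]].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.linalg as sla

from .matrices import RelationshipMatrix
from .pedigree import extract_blocks

__all__ = [
    "ScalingCoefficients",
    "scale_G",
    "blend_G",
    "build_H",
    "build_H_inverse",
    "combined_relationship",
]


@dataclass
class ScalingCoefficients:
    """G* = beta * G + alpha (alpha added to every element)."""

    beta: float
    alpha: float


def _check_aligned(x: RelationshipMatrix, y: RelationshipMatrix) -> None:
    if x.ids != y.ids:
        raise ValueError(f"id order mismatch between {x.role} and {y.role}")


def scale_G(
    G: RelationshipMatrix,
    A22: RelationshipMatrix,
    include_diagonal_in_avg: bool = True,
) -> tuple[RelationshipMatrix, ScalingCoefficients]:
    """Solve the 2x2 system matching G's averages to A22's.

        Avg(diag(G)) beta + alpha = Avg(diag(A22))
        Avg(G)       beta + alpha = Avg(A22)

    ``Avg(.)`` without ``diag`` is the mean over all n^2 elements by
    default; set ``include_diagonal_in_avg=False`` to average off-diagonal
    elements only (the two conventions coincide as n grows).
    """
    _check_aligned(G, A22)
    n = G.n
    if n < 2:
        raise ValueError("scaling needs n >= 2 so both averages are defined")

    def avgs(m: np.ndarray) -> tuple[float, float]:
        d = float(np.mean(np.diag(m)))
        if include_diagonal_in_avg:
            o = float(np.mean(m))
        else:
            o = float((m.sum() - np.trace(m)) / (n * (n - 1)))
        return d, o

    gd, go = avgs(G.values)
    ad, ao = avgs(A22.values)
    spread = gd - go
    if abs(spread) < 1e-12:
        raise ValueError(
            "scaling system is singular: Avg(diag(G)) equals Avg(G); "
            "use identity scaling (beta=1, alpha=0) or skip scaling"
        )
    beta = (ad - ao) / spread
    alpha = ad - gd * beta
    g_star = beta * G.values + alpha
    return RelationshipMatrix(G.ids, g_star, "G_star"), ScalingCoefficients(beta, alpha)


def blend_G(
    G_star: RelationshipMatrix,
    A22: RelationshipMatrix,
    w: float = 0.95,
) -> RelationshipMatrix:
    """G_w = w G* + (1 - w) A22; 0 < w <= 1."""
    _check_aligned(G_star, A22)
    if not 0.0 < w <= 1.0:
        raise ValueError(f"blend weight must be in (0, 1], got {w}")
    return RelationshipMatrix(G_star.ids, w * G_star.values + (1.0 - w) * A22.values, "G_w")


def build_H(
    A: RelationshipMatrix,
    G_w: RelationshipMatrix,
    genotyped_ids: Sequence[str],
) -> RelationshipMatrix:
    """Assemble the combined matrix H (dense).

    The genotyped block of H is exactly G_w; with an empty genotyped set,
    or with G_w = A22, H reduces to A.
    """
    genotyped_ids = [str(i) for i in genotyped_ids]
    if not genotyped_ids:
        return RelationshipMatrix(A.ids, A.values.copy(), "H")
    if tuple(genotyped_ids) != G_w.ids:
        raise ValueError("genotyped_ids must match G_w id order")
    blocks = extract_blocks(A, genotyped_ids)
    a12 = blocks.A12.to_numpy()
    a22_inv = blocks.A22_inv.values
    g = G_w.values
    # P maps genotyped-deviation space back through the pedigree: A12 A22^-1
    proj = a12 @ a22_inv
    h11 = blocks.A11.values + proj @ (g - blocks.A22.values) @ proj.T
    h12 = proj @ g
    non_g = list(blocks.A11.ids)
    ids = tuple(non_g + genotyped_ids)
    n1, n2 = len(non_g), len(genotyped_ids)
    h = np.empty((n1 + n2, n1 + n2))
    h[:n1, :n1] = 0.5 * (h11 + h11.T)
    h[:n1, n1:] = h12
    h[n1:, :n1] = h12.T
    h[n1:, n1:] = g
    # return in A's original id order
    pos = {ind: k for k, ind in enumerate(ids)}
    order = np.array([pos[i] for i in A.ids])
    return RelationshipMatrix(A.ids, h[np.ix_(order, order)], "H")


def build_H_inverse(
    A_inv: RelationshipMatrix,
    G_w: RelationshipMatrix,
    A22: RelationshipMatrix,
    genotyped_ids: Sequence[str],
) -> RelationshipMatrix:
    """H^-1 = A^-1 + (G_w^-1 - A22^-1) in the genotyped block."""
    genotyped_ids = [str(i) for i in genotyped_ids]
    hinv = A_inv.values.copy()
    if genotyped_ids:
        if tuple(genotyped_ids) != G_w.ids or tuple(genotyped_ids) != A22.ids:
            raise ValueError("genotyped_ids must match G_w and A22 id order")
        try:
            g_inv = sla.inv(G_w.values)
        except sla.LinAlgError as exc:
            raise ValueError(
                "G_w is singular; blend with w < 1 to guarantee invertibility"
            ) from exc
        a22_inv = sla.inv(A22.values)
        corr = 0.5 * (g_inv + g_inv.T) - 0.5 * (a22_inv + a22_inv.T)
        idx = A_inv.indices_of(genotyped_ids)
        hinv[np.ix_(idx, idx)] += corr
    return RelationshipMatrix(A_inv.ids, hinv, "H_inv")


def combined_relationship(
    A: RelationshipMatrix,
    A_inv: RelationshipMatrix,
    G: RelationshipMatrix,
    w: float = 0.95,
    scale: bool = True,
    want_H: bool = True,
) -> tuple[RelationshipMatrix | None, RelationshipMatrix, ScalingCoefficients | None]:
    """One-call pipeline: scale, blend, and combine.

    Returns ``(H or None, H_inv, coefficients or None)`` for the genotyped
    set given by ``G.ids``. ``scale=False`` skips the average-matching
    step; scaling is the standard practice and the default.
    """
    genotyped_ids = list(G.ids)
    blocks = extract_blocks(A, genotyped_ids)
    coeff = None
    g_star = G
    if scale:
        g_star, coeff = scale_G(G, blocks.A22)
    g_w = blend_G(g_star, blocks.A22, w=w)
    H = build_H(A, g_w, genotyped_ids) if want_H else None
    H_inv = build_H_inverse(A_inv, g_w, blocks.A22, genotyped_ids)
    return H, H_inv, coeff
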