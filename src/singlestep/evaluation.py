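"""Derived genetic statistics and relationship-matrix diagnostics.

Heritability here follows the individual-tree convention for field trials:
block variance is excluded from the denominator, h2 = s2_a / (s2_a + s2_e).
Breeding-value accuracy is the prediction-error-variance form
r = sqrt(1 - SE_i^2 / ((1 + F_i) s2_a)).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .matrices import RelationshipMatrix
from .pedigree import PedigreeTable

__all__ = [
    "heritability",
    "genetic_correlation",
    "bv_accuracy",
    "spearman_rank",
    "top_fraction_overlap",
    "relationship_group_stats",
    "GroupStats",
    "heatmap_png",
]

#: order in which pair classes are reported
GROUP_ORDER = ("identity", "parent_parent", "parent_offspring", "half_sib", "unrelated")


def heritability(sigma2_a: float, sigma2_e: float) -> float:
    """Narrow-sense heritability s2_a / (s2_a + s2_e)."""
    if sigma2_a < 0 or sigma2_e <= 0:
        raise ValueError("need sigma2_a >= 0 and sigma2_e > 0")
    return sigma2_a / (sigma2_a + sigma2_e)


def genetic_correlation(cov12: float, sigma2_a1: float, sigma2_a2: float) -> float:
    """Additive genetic correlation cov / (sd1 * sd2)."""
    if sigma2_a1 <= 0 or sigma2_a2 <= 0:
        raise ValueError("additive variances must be positive")
    r = cov12 / math.sqrt(sigma2_a1 * sigma2_a2)
    if abs(r) > 1.0:
        warnings.warn(f"genetic correlation {r:.4f} outside [-1, 1]; reporting as-is")
    return r


def bv_accuracy(
    se_bv: np.ndarray,
    F: np.ndarray | float,
    sigma2_a: float,
    sqrt_form: bool = True,
) -> np.ndarray:
    """Per-individual theoretical accuracy from prediction SEs.

    ``sqrt_form=True`` (default) computes sqrt(1 - SE^2/((1+F) s2_a));
    the non-root reliability-style form is available behind the flag.
    Negative values inside the square root are clamped to zero with a
    warning (they arise when the PEV exceeds the additive variance).
    """
    if sigma2_a <= 0:
        raise ValueError("sigma2_a must be positive")
    se_bv = np.asarray(se_bv, dtype=float)
    F = np.broadcast_to(np.asarray(F, dtype=float), se_bv.shape)
    inner = 1.0 - se_bv ** 2 / ((1.0 + F) * sigma2_a)
    if (inner < 0).any():
        warnings.warn(
            f"{int((inner < 0).sum())} accuracy value(s) clamped to 0 "
            "(prediction error variance exceeds additive variance)"
        )
        inner = np.clip(inner, 0.0, None)
    return np.sqrt(inner) if sqrt_form else inner


def spearman_rank(bv_x: pd.Series, bv_y: pd.Series) -> float:
    """Spearman rank correlation over the common id set (average-rank ties)."""
    common = bv_x.index.intersection(bv_y.index)
    if len(common) < 3:
        raise ValueError("need at least 3 common ids for a rank correlation")
    rho = sps.spearmanr(bv_x.loc[common].to_numpy(), bv_y.loc[common].to_numpy())[0]
    return float(rho)


def top_fraction_overlap(bv_x: pd.Series, bv_y: pd.Series, fraction: float = 0.05) -> float:
    """Proportion of shared candidates in the top ``fraction`` of both
    rankings; k = ceil(fraction * n) over the common id set, ties broken
    deterministically by id order."""
    common = bv_x.index.intersection(bv_y.index)
    n = len(common)
    if n == 0:
        raise ValueError("empty id intersection")
    k = math.ceil(fraction * n)

    def topk(s: pd.Series) -> set:
        sub = s.loc[common]
        # sort by (-value, id): highest first, id as the deterministic tie-break
        order = sorted(sub.index, key=lambda i: (-sub[i], str(i)))
        return set(order[:k])

    return len(topk(bv_x) & topk(bv_y)) / k


@dataclass
class GroupStats:
    """Per-relationship-group descriptive statistics of a relationship
    matrix, plus overall summaries, as used to characterise A vs H."""

    per_group: pd.DataFrame          # index=group, cols: n, mean, sd, min, max
    overall_mean: float
    overall_variance: float
    pearson_r_with_ref: float | None


def _classify_pairs(ped: PedigreeTable, ids: tuple[str, ...]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Upper-triangle pair indices for each pedigree-defined class.

    Classification is by the recorded pedigree: diagonal -> identity;
    both individuals are parents -> parent-parent; one is a recorded
    parent of the other -> parent-offspring; shared recorded dam (or
    shared sire) -> half-sib / within-family; anything else unrelated.
    """
    n = len(ids)
    pidx = []
    for i in ids:
        if i not in ped._index:
            raise KeyError(f"id {i!r} present in matrix but not in pedigree")
        pidx.append(ped.index_of(i))
    pidx = np.array(pidx)
    dam = ped.dam[pidx]
    sire = ped.sire[pidx]
    parent_ids = set(ped.dam[ped.dam >= 0]) | set(ped.sire[ped.sire >= 0])
    is_parent = np.array([k in parent_ids for k in pidx])

    iu, ju = np.triu_indices(n, k=1)
    pi, pj = pidx[iu], pidx[ju]
    po = ((pi == dam[ju]) | (pi == sire[ju]) | (pj == dam[iu]) | (pj == sire[iu]))
    pp = is_parent[iu] & is_parent[ju] & ~po
    hs = (((dam[iu] >= 0) & (dam[iu] == dam[ju])) |
          ((sire[iu] >= 0) & (sire[iu] == sire[ju]))) & ~po & ~pp
    unrel = ~(po | pp | hs)
    dg = np.arange(n)
    return {
        "identity": (dg, dg),
        "parent_parent": (iu[pp], ju[pp]),
        "parent_offspring": (iu[po], ju[po]),
        "half_sib": (iu[hs], ju[hs]),
        "unrelated": (iu[unrel], ju[unrel]),
    }


def relationship_group_stats(
    K: RelationshipMatrix,
    ped: PedigreeTable,
    ref: RelationshipMatrix | None = None,
    include_diagonal_overall: bool = True,
) -> GroupStats:
    """Descriptive statistics of K by pedigree-defined pair class.

    The overall mean/variance are over the upper triangle including the
    diagonal by default (switchable); the Pearson correlation with ``ref``
    uses the same entries on the common id set.
    """
    groups = _classify_pairs(ped, K.ids)
    rows = []
    total_pairs = 0
    for name in GROUP_ORDER:
        gi, gj = groups[name]
        vals = K.values[gi, gj]
        total_pairs += len(vals)
        rows.append({
            "group": name,
            "n": len(vals),
            "mean": float(np.mean(vals)) if len(vals) else np.nan,
            "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
            "min": float(np.min(vals)) if len(vals) else np.nan,
            "max": float(np.max(vals)) if len(vals) else np.nan,
        })
    n = K.n
    assert total_pairs == n * (n + 1) // 2
    iu, ju = np.triu_indices(n, k=0 if include_diagonal_overall else 1)
    upper = K.values[iu, ju]
    r = None
    if ref is not None:
        common = [i for i in K.ids if i in set(ref.ids)]
        ksub = K.submatrix(common)
        rsub = ref.submatrix(common)
        ci, cj = np.triu_indices(len(common), k=0 if include_diagonal_overall else 1)
        r = float(np.corrcoef(ksub.values[ci, cj], rsub.values[ci, cj])[0, 1])
    return GroupStats(
        per_group=pd.DataFrame(rows).set_index("group"),
        overall_mean=float(np.mean(upper)),
        overall_variance=float(np.var(upper, ddof=1)),
        pearson_r_with_ref=r,
    )


def heatmap_png(K: RelationshipMatrix, path, order: list[str] | None = None,
                title: str | None = None) -> None:
    """Plain matrix-image export of a relationship matrix (optionally
    reordered, e.g. by provenance/family). Requires matplotlib."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = K.submatrix(order).values if order else K.values
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(mat, cmap="viridis", interpolation="nearest")
    fig.colorbar(im, ax=ax, label="relationship")
    ax.set_title(title or K.role)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
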