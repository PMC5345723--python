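"""Bivariate animal model: REML variance components and BLUP solutions.

The model for trait vector y (stacked over trees and traits) is

    y = X b + Z1 a + Z2 u + e,

with per-trait intercepts b, breeding values a ~ N(0, Sigma_a (x) K) for a
relationship kernel K (pedigree A or single-step H), block effects
u ~ N(0, Sigma_u (x) I) with diagonal Sigma_u, and residuals
e ~ N(0, Sigma_e (x) I) applied per tree over its observed traits
(missing-at-random single-trait records are handled through the
per-observation-pattern residual inverse).

Variance components are estimated by average-information REML: each
iteration solves Henderson's mixed-model equations once, evaluates the
restricted log-likelihood through the MME identity

    -2 l_R = const + log|R| + log|G| + log|C| + y'Py,

and updates the parameters with a Newton step using the AI matrix, with
Levenberg-Marquardt damping plus step halving whenever a plain step leaves
the feasible region or fails to improve the likelihood. The code is
written for a generic trait count and is exercised with one and two
traits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg.lapack import dpotrf, dpotri, dpotrs

from .matrices import RelationshipMatrix

__all__ = [
    "TraitDataset",
    "CovarianceStructures",
    "VarianceEstimates",
    "BlupSolution",
    "RemlOptions",
    "read_phenotypes",
    "standardize",
    "build_mme",
    "reml_fit",
    "blup_solve",
    "aic",
]

log = logging.getLogger(__name__)

#: variances are floored here to keep covariance structures invertible
#: while still allowing estimates pinned at (numerical) zero
VAR_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class TraitDataset:
    """Per-tree phenotypes, design labels and genotyped status."""

    tree_id: tuple[str, ...]
    family_id: tuple[str, ...]
    block_id: tuple[str, ...] | None
    traits: np.ndarray          # n_trees x n_traits, NaN = missing
    trait_names: tuple[str, ...]
    genotyped: np.ndarray       # bool per tree
    scaling: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        self.tree_id = tuple(str(i) for i in self.tree_id)
        self.family_id = tuple(str(i) for i in self.family_id)
        if self.block_id is not None:
            self.block_id = tuple(str(b) for b in self.block_id)
        self.traits = np.atleast_2d(np.asarray(self.traits, dtype=float))
        self.genotyped = np.asarray(self.genotyped, dtype=bool)
        n = len(self.tree_id)
        if len(set(self.tree_id)) != n:
            raise ValueError("tree ids are not unique")
        if self.traits.shape != (n, len(self.trait_names)):
            raise ValueError("trait array shape does not match ids/names")
        if len(self.genotyped) != n:
            raise ValueError("genotyped flag length mismatch")

    @property
    def n(self) -> int:
        return len(self.tree_id)

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"tree_id": self.tree_id, "family_id": self.family_id})
        if self.block_id is not None:
            df["block_id"] = self.block_id
        for k, name in enumerate(self.trait_names):
            df[name] = self.traits[:, k]
        df["genotyped"] = self.genotyped.astype(int)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path, trait_columns: Sequence[str] | None = None) -> TraitDataset:
    """Read a CSV/TSV design/phenotype table.

    Required columns: ``tree_id``, ``family_id``; optional ``block_id`` and
    ``genotyped`` (0/1). Remaining numeric columns are traits unless
    ``trait_columns`` names them explicitly.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower().strip(): c for c in df.columns}
    for req in ("tree_id", "family_id"):
        if req not in cols:
            raise ValueError(f"phenotype file lacks column {req!r}")
    reserved = {"tree_id", "family_id", "block_id", "genotyped"}
    if trait_columns is None:
        trait_columns = [c for c in df.columns if c.lower().strip() not in reserved]
    traits = df[list(trait_columns)].to_numpy(dtype=float)
    return TraitDataset(
        tree_id=tuple(df[cols["tree_id"]].astype(str)),
        family_id=tuple(df[cols["family_id"]].astype(str)),
        block_id=tuple(df[cols["block_id"]].astype(str)) if "block_id" in cols else None,
        traits=traits,
        trait_names=tuple(trait_columns),
        genotyped=df[cols["genotyped"]].to_numpy(dtype=bool)
        if "genotyped" in cols else np.zeros(len(df), dtype=bool),
    )


def standardize(ds: TraitDataset, ddof: int = 1) -> TraitDataset:
    """Z-score each trait over its non-missing records.

    Sample standard deviation (``ddof=1``) by default; the per-trait
    (mean, sd) pairs are retained in ``scaling`` for back-transformation.
    Already-standardized data pass through unchanged to numerical
    precision.
    """
    traits = ds.traits.copy()
    scaling: dict[str, tuple[float, float]] = {}
    for k, name in enumerate(ds.trait_names):
        col = traits[:, k]
        obs = col[~np.isnan(col)]
        if obs.size < 2:
            raise ValueError(f"trait {name!r} has fewer than 2 records")
        mu, sd = float(np.mean(obs)), float(np.std(obs, ddof=ddof))
        if sd == 0.0:
            raise ValueError(f"trait {name!r} has zero variance")
        traits[:, k] = (col - mu) / sd
        scaling[name] = (mu, sd)
    return replace(ds, traits=traits, scaling=scaling)


@dataclass
class CovarianceStructures:
    """The three (co)variance structures of the model.

    ``additive`` and ``residual`` are full symmetric t x t matrices;
    ``block`` holds the t per-trait block variances (diagonal structure),
    or ``None`` for a model without block effects.
    """

    additive: np.ndarray
    block: np.ndarray | None
    residual: np.ndarray

    def __post_init__(self) -> None:
        self.additive = np.atleast_2d(np.asarray(self.additive, dtype=float))
        self.residual = np.atleast_2d(np.asarray(self.residual, dtype=float))
        if self.block is not None:
            self.block = np.atleast_1d(np.asarray(self.block, dtype=float))

    @property
    def n_traits(self) -> int:
        return self.additive.shape[0]

    @property
    def has_block(self) -> bool:
        return self.block is not None

    @property
    def labels(self) -> list[str]:
        t = self.n_traits
        lab = [f"additive_{i + 1}{j + 1}" for i in range(t) for j in range(i, t)]
        if self.has_block:
            lab += [f"block_{i + 1}" for i in range(t)]
        lab += [f"residual_{i + 1}{j + 1}" for i in range(t) for j in range(i, t)]
        return lab

    @property
    def n_free(self) -> int:
        return len(self.labels)

    def to_vector(self) -> np.ndarray:
        t = self.n_traits
        iu = [(i, j) for i in range(t) for j in range(i, t)]
        parts = [np.array([self.additive[i, j] for i, j in iu])]
        if self.has_block:
            parts.append(np.asarray(self.block))
        parts.append(np.array([self.residual[i, j] for i, j in iu]))
        return np.concatenate(parts)

    @classmethod
    def from_vector(cls, vec: np.ndarray, n_traits: int, has_block: bool) -> "CovarianceStructures":
        t = n_traits
        iu = [(i, j) for i in range(t) for j in range(i, t)]
        nv = len(iu)
        add = np.zeros((t, t))
        for v, (i, j) in zip(vec[:nv], iu):
            add[i, j] = add[j, i] = v
        pos = nv
        blk = None
        if has_block:
            blk = np.asarray(vec[pos:pos + t], dtype=float)
            pos += t
        res = np.zeros((t, t))
        for v, (i, j) in zip(vec[pos:pos + nv], iu):
            res[i, j] = res[j, i] = v
        return cls(additive=add, block=blk, residual=res)


@dataclass
class VarianceEstimates:
    """REML results: components, AI-based SEs, fit statistics."""

    structures: CovarianceStructures
    se: dict[str, float]
    loglik: float
    aic: float
    converged: bool
    n_iter: int


@dataclass
class BlupSolution:
    """MME solution at fixed variance components."""

    ids: tuple[str, ...]
    trait_names: tuple[str, ...]
    breeding_values: pd.DataFrame     # individuals x traits
    se_bv: pd.DataFrame | None        # prediction SEs, same shape
    block_effects: pd.DataFrame | None
    fixed_effects: pd.Series

    def to_tsv(self, path) -> None:
        out = self.breeding_values.add_prefix("bv_")
        if self.se_bv is not None:
            out = out.join(self.se_bv.add_prefix("se_"))
        out.to_csv(path, sep="\t", index_label="id")


@dataclass
class RemlOptions:
    """Convergence configuration for :func:`reml_fit`."""

    max_iter: int = 200
    tol_loglik: float = 1e-8
    tol_params: float = 1e-6
    verbose: bool = False


def aic(loglik: float, t: int) -> float:
    """Akaike information criterion -2 loglik + 2 t for t free variance
    parameters (8 for the bivariate model with block effects: 3 additive +
    2 block + 3 residual)."""
    return -2.0 * loglik + 2.0 * t


# ---------------------------------------------------------------------------
# model frame: everything that does not depend on the variance parameters
# ---------------------------------------------------------------------------

class _ModelFrame:
    def __init__(self, ds: TraitDataset, K_inv: RelationshipMatrix):
        self.t = ds.n_traits
        self.ds = ds
        self.k_ids = K_inv.ids
        self.nK = K_inv.n
        self.Kinv = np.ascontiguousarray(K_inv.values)
        missing = set(ds.tree_id) - set(K_inv.ids)
        if missing:
            raise ValueError(
                f"{len(missing)} phenotyped tree(s) absent from the "
                f"relationship matrix, e.g. {sorted(missing)[:3]}"
            )
        self.ped_idx = K_inv.indices_of(ds.tree_id)

        if ds.block_id is not None:
            levels = sorted(set(ds.block_id))
            self.block_levels: tuple[str, ...] | None = tuple(levels)
            bpos = {b: k for k, b in enumerate(levels)}
            self.block_idx = np.array([bpos[b] for b in ds.block_id])
            self.nb = len(levels)
        else:
            self.block_levels = None
            self.block_idx = None
            self.nb = 0

        # observation bookkeeping: rows ordered by tree, then trait
        t, n = self.t, ds.n
        obs_mask = ~np.isnan(ds.traits)
        if not obs_mask.any(axis=1).all():
            raise ValueError("every tree needs at least one observed trait")
        self.obs_index = -np.ones((n, t), dtype=np.intp)
        rows = np.flatnonzero(obs_mask.ravel())
        self.obs_index.ravel()[rows] = np.arange(len(rows))
        self.n_obs = len(rows)
        tree_of = rows // t
        trait_of = rows % t
        self.tree_of, self.trait_of = tree_of, trait_of
        self.y = ds.traits[tree_of, trait_of]

        # column layout: [intercepts | additive (trait-major) | blocks]
        self.off_a = t
        self.off_u = t + t * self.nK
        self.p = t + t * self.nK + t * self.nb
        wr = np.arange(self.n_obs)
        cols = [trait_of, self.off_a + trait_of * self.nK + self.ped_idx[tree_of]]
        if self.nb:
            cols.append(self.off_u + trait_of * self.nb + self.block_idx[tree_of])
        rows_all = np.concatenate([wr] * len(cols))
        cols_all = np.concatenate(cols)
        data = np.ones(len(rows_all))
        self.W = sp.csr_matrix((data, (rows_all, cols_all)),
                               shape=(self.n_obs, self.p))

        # residual pattern groups: observed-trait tuple -> tree indices
        self.patterns: dict[tuple[int, ...], np.ndarray] = {}
        keys = [tuple(np.flatnonzero(obs_mask[i])) for i in range(n)]
        for key in set(keys):
            self.patterns[key] = np.array(
                [i for i, k in enumerate(keys) if k == key], dtype=np.intp)

        # log|K| = -log|K^-1| via Cholesky of the (PD) inverse kernel
        ck, info = dpotrf(self.Kinv, lower=1)
        if info != 0:
            raise ValueError("relationship inverse is not positive definite")
        self.logdet_K = -2.0 * float(np.sum(np.log(np.diag(ck))))

    # -- residual machinery --------------------------------------------
    def _residual_blocks(self, Se: np.ndarray):
        """Per-pattern residual inverse blocks and log|R|."""
        out = {}
        logdet = 0.0
        for key, trees in self.patterns.items():
            sub = Se[np.ix_(key, key)]
            c, info = dpotrf(sub, lower=1)
            if info != 0:
                return None, None
            inv = dpotri(c, lower=1)[0]
            inv = np.tril(inv) + np.tril(inv, -1).T
            out[key] = inv
            logdet += 2.0 * float(np.sum(np.log(np.diag(c)))) * len(trees)
        return out, logdet

    def _pattern_sparse(self, blocks: dict) -> sp.csr_matrix:
        """Assemble a block-diagonal (per tree) obs x obs sparse matrix from
        per-pattern t_obs x t_obs blocks."""
        rows, cols, vals = [], [], []
        for key, trees in self.patterns.items():
            blk = blocks[key]
            q = len(key)
            oi = self.obs_index[np.ix_(trees, key)]  # trees x q
            for a in range(q):
                for b in range(q):
                    if blk[a, b] == 0.0:
                        continue
                    rows.append(oi[:, a])
                    cols.append(oi[:, b])
                    vals.append(np.full(len(trees), blk[a, b]))
        return sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n_obs, self.n_obs))


class _FitState:
    """Factored MME and likelihood at one parameter value."""

    __slots__ = ("cs", "Rinv", "Rinv_blocks", "factor", "sol", "e_hat",
                 "Py", "loglik", "logdet_C")

    def __init__(self, **kw):
        for k, v in kw.items():
            setattr(self, k, v)


def _feasible(cs: CovarianceStructures) -> bool:
    for m in (cs.additive, cs.residual):
        if np.linalg.eigvalsh(m).min() <= 0:
            return False
    if cs.block is not None and (cs.block <= 0).any():
        return False
    return True


def _project(cs: CovarianceStructures) -> CovarianceStructures:
    """Push the structures back into the feasible region (eigenvalue floor
    for the symmetric matrices, plain floor for block variances)."""

    def fix(m: np.ndarray) -> np.ndarray:
        w, v = np.linalg.eigh(m)
        if w.min() >= VAR_FLOOR:
            return m
        w = np.maximum(w, VAR_FLOOR)
        return (v * w) @ v.T

    blk = None if cs.block is None else np.maximum(cs.block, VAR_FLOOR)
    return CovarianceStructures(fix(cs.additive), blk, fix(cs.residual))


def _assemble_C(frame: _ModelFrame, cs: CovarianceStructures,
                Rinv: sp.csr_matrix) -> tuple[np.ndarray, np.ndarray]:
    WtR = frame.W.T @ Rinv
    C = (WtR @ frame.W).toarray()
    rhs = WtR @ frame.y
    t, nK = frame.t, frame.nK
    Sa_inv = np.linalg.inv(cs.additive)
    a0 = frame.off_a
    for k in range(t):
        for l in range(t):
            C[a0 + k * nK:a0 + (k + 1) * nK,
              a0 + l * nK:a0 + (l + 1) * nK] += Sa_inv[k, l] * frame.Kinv
    if frame.nb:
        u0 = frame.off_u
        for k in range(t):
            idx = np.arange(u0 + k * frame.nb, u0 + (k + 1) * frame.nb)
            C[idx, idx] += 1.0 / cs.block[k]
    return C, rhs


def _evaluate(frame: _ModelFrame, cs: CovarianceStructures) -> _FitState | None:
    """Factor the MME at ``cs`` and return the restricted log-likelihood,
    or None when the structures are numerically infeasible."""
    if not _feasible(cs):
        return None
    Se = cs.residual
    blocks, logdet_R = frame._residual_blocks(Se)
    if blocks is None:
        return None
    Rinv = frame._pattern_sparse(blocks)
    C, rhs = _assemble_C(frame, cs, Rinv)
    factor, info = dpotrf(C, lower=1, overwrite_a=1)
    if info != 0:
        return None
    logdet_C = 2.0 * float(np.sum(np.log(np.diag(factor))))
    sol = dpotrs(factor, rhs, lower=1)[0]
    e_hat = frame.y - frame.W @ sol
    Py = Rinv @ e_hat
    yPy = float(frame.y @ Py)

    t = frame.t
    sign_a, logdet_Sa = np.linalg.slogdet(cs.additive)
    logdet_G = frame.nK * logdet_Sa + t * frame.logdet_K
    if frame.nb:
        logdet_G += frame.nb * float(np.sum(np.log(cs.block)))
    const = (frame.n_obs - t) * np.log(2.0 * np.pi)
    loglik = -0.5 * (const + logdet_R + logdet_G + logdet_C + yPy)
    return _FitState(cs=cs, Rinv=Rinv, Rinv_blocks=blocks, factor=factor,
                     sol=sol, e_hat=e_hat, Py=Py, loglik=loglik,
                     logdet_C=logdet_C)


def _derivatives(frame: _ModelFrame, state: _FitState):
    """REML score vector and average-information matrix at ``state``.

    Uses the standard MME identities: Z'PZ = G^-1 - G^-1 C^uu G^-1 for the
    random-effect structures and P = R^-1 - R^-1 W C^-1 W' R^-1 for the
    residual ones, so only C^-1 (from the existing Cholesky factor) and a
    handful of extra MME solves are needed.
    """
    t, nK, nb = frame.t, frame.nK, frame.nb
    cs = state.cs
    Sa_inv = np.linalg.inv(cs.additive)
    iu = [(i, j) for i in range(t) for j in range(i, t)]

    Cinv = dpotri(state.factor.copy(), lower=1)[0]
    d = np.diag(Cinv).copy()
    Cinv = np.tril(Cinv)
    Cinv += Cinv.T
    Cinv[np.diag_indices_from(Cinv)] = d

    a0, u0 = frame.off_a, frame.off_u
    a_hat = [state.sol[a0 + k * nK:a0 + (k + 1) * nK] for k in range(t)]
    Kinv_a = [frame.Kinv @ a_hat[k] for k in range(t)]
    # trace(K^-1 C^aa_kl) and a_k' K^-1 a_l
    T_a = np.empty((t, t))
    S_a = np.empty((t, t))
    for k in range(t):
        for l in range(k, t):
            blk = Cinv[a0 + k * nK:a0 + (k + 1) * nK, a0 + l * nK:a0 + (l + 1) * nK]
            T_a[k, l] = T_a[l, k] = float(np.einsum("ij,ij->", frame.Kinv, blk))
            S_a[k, l] = S_a[l, k] = float(a_hat[k] @ Kinv_a[l])

    scores: list[float] = []
    w_cols: list[np.ndarray] = []
    trait_rows = [np.flatnonzero(frame.trait_of == k) for k in range(t)]

    def d_mat(i: int, j: int) -> np.ndarray:
        d = np.zeros((t, t))
        d[i, j] = d[j, i] = 1.0
        return d

    # -- additive parameters -------------------------------------------
    for i, j in iu:
        D = d_mat(i, j)
        E = Sa_inv @ D @ Sa_inv
        tr_term = nK * float(np.sum(D * Sa_inv)) - float(np.sum(E * T_a))
        quad = float(np.sum(E * S_a))
        scores.append(-0.5 * (tr_term - quad))
        B = D @ Sa_inv
        w = np.zeros(frame.n_obs)
        for k in range(t):
            rows = trait_rows[k]
            val = np.zeros(len(rows))
            for l in range(t):
                if B[k, l] != 0.0:
                    val += B[k, l] * a_hat[l][frame.ped_idx[frame.tree_of[rows]]]
            w[rows] = val
        w_cols.append(w)

    # -- block parameters ----------------------------------------------
    if nb:
        u_hat = [state.sol[u0 + k * nb:u0 + (k + 1) * nb] for k in range(t)]
        for k in range(t):
            su = cs.block[k]
            cuu = Cinv[u0 + k * nb:u0 + (k + 1) * nb, u0 + k * nb:u0 + (k + 1) * nb]
            tr_term = nb / su - float(np.trace(cuu)) / su ** 2
            quad = float(u_hat[k] @ u_hat[k]) / su ** 2
            scores.append(-0.5 * (tr_term - quad))
            w = np.zeros(frame.n_obs)
            rows = trait_rows[k]
            w[rows] = u_hat[k][frame.block_idx[frame.tree_of[rows]]] / su
            w_cols.append(w)

    # -- residual parameters -------------------------------------------
    # padded Py per (tree, trait): zero where unobserved
    Py_pad = np.zeros((frame.ds.n, t))
    Py_pad[frame.tree_of, frame.trait_of] = state.Py
    for i, j in iu:
        D = d_mat(i, j)
        tr_RinvD = 0.0
        Fg = {}
        for key, trees in frame.patterns.items():
            Rinv_g = state.Rinv_blocks[key]
            Dg = D[np.ix_(key, key)]
            tr_RinvD += float(np.sum(Rinv_g * Dg)) * len(trees)
            Fg[key] = Rinv_g @ Dg @ Rinv_g
        F = frame._pattern_sparse(Fg)
        Q = (frame.W.T @ F @ frame.W).tocoo()
        tr_CQ = float(np.sum(Q.data * Cinv[Q.row, Q.col]))
        quad = float(state.e_hat @ (F @ state.e_hat))
        scores.append(-0.5 * (tr_RinvD - tr_CQ - quad))
        # w = dR/dtheta P y
        w = np.zeros(frame.n_obs)
        for k in range(t):
            rows = trait_rows[k]
            val = np.zeros(len(rows))
            for l in range(t):
                if D[k, l] != 0.0:
                    val += D[k, l] * Py_pad[frame.tree_of[rows], l]
            w[rows] = val
        w_cols.append(w)

    # -- average information -------------------------------------------
    Wmat = np.column_stack(w_cols)
    RW = state.Rinv @ Wmat
    rhs = frame.W.T @ RW
    sols = dpotrs(state.factor, rhs, lower=1)[0]
    PW = state.Rinv @ (Wmat - frame.W @ sols)
    AI = 0.5 * (Wmat.T @ PW)
    AI = 0.5 * (AI + AI.T)
    return np.asarray(scores), AI


def _default_start(ds: TraitDataset, has_block: bool) -> CovarianceStructures:
    """Half the phenotypic (co)variance to additive and residual each, 5%
    of the trait variances to blocks."""
    df = pd.DataFrame(ds.traits)
    S = df.cov(min_periods=2).to_numpy()
    S = np.where(np.isnan(S), 0.0, S)
    d = np.clip(np.diag(S).copy(), 1e-6, None)
    np.fill_diagonal(S, d)
    blk = 0.05 * d if has_block else None
    return CovarianceStructures(0.5 * S, blk, 0.5 * S)


def build_mme(
    ds: TraitDataset,
    K_inv: RelationshipMatrix,
    cs: CovarianceStructures,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Henderson's mixed-model equations at fixed components.

    Returns the dense coefficient matrix, the right-hand side, and an index
    map describing the column layout (intercepts, additive effects in
    trait-major order over ``K_inv.ids``, block effects).
    """
    frame = _ModelFrame(ds, K_inv)
    if not _feasible(cs):
        raise ValueError("additive or residual structure not positive definite")
    blocks, _ = frame._residual_blocks(cs.residual)
    if blocks is None:
        raise ValueError("residual structure not positive definite")
    Rinv = frame._pattern_sparse(blocks)
    C, rhs = _assemble_C(frame, cs, Rinv)
    maps = {
        "trait_names": ds.trait_names,
        "fixed": {name: k for k, name in enumerate(ds.trait_names)},
        "additive_offset": frame.off_a,
        "additive_ids": frame.k_ids,
        "block_offset": frame.off_u,
        "block_levels": frame.block_levels,
    }
    return C, rhs, maps


def reml_fit(
    ds: TraitDataset,
    K_inv: RelationshipMatrix,
    start: CovarianceStructures | None = None,
    opts: RemlOptions | None = None,
) -> VarianceEstimates:
    """Average-information REML for the (possibly bivariate) animal model.

    Non-convergence within ``opts.max_iter`` returns a flagged result
    rather than raising. Standard errors come from the inverse of the
    average-information matrix at the optimum.
    """
    opts = opts or RemlOptions()
    frame = _ModelFrame(ds, K_inv)
    has_block = frame.nb > 0
    cs = _project(start if start is not None else _default_start(ds, has_block))
    state = _evaluate(frame, cs)
    if state is None:
        raise ValueError("starting values are not feasible")

    t_free = cs.n_free
    converged = False
    n_iter = 0
    theta = cs.to_vector()
    score, AI = _derivatives(frame, state)
    # variance-type parameters (floored at the boundary); covariances are
    # constrained only through positive-definiteness projection
    var_idx = np.array([k for k, lab in enumerate(cs.labels)
                        if lab.startswith("block")
                        or lab[-2] == lab[-1]], dtype=np.intp)

    for n_iter in range(1, opts.max_iter + 1):
        # active set: variances pinned at the floor with an outward score
        # are frozen, otherwise the joint Newton step crawls at boundaries
        pinned = var_idx[(theta[var_idx] <= 10 * VAR_FLOOR) & (score[var_idx] < 0)]
        free = np.setdiff1d(np.arange(len(theta)), pinned)
        AI_f = AI[np.ix_(free, free)]
        score_f = score[free]
        scale = max(float(np.mean(np.abs(np.diag(AI_f)))), 1e-12)
        accepted = None
        for lam in (0.0, 0.1, 1.0, 10.0, 100.0, 1e4):
            M = AI_f + (lam * scale + 1e-12) * np.eye(len(free))
            try:
                delta_f = np.linalg.solve(M, score_f)
            except np.linalg.LinAlgError:
                continue
            delta = np.zeros(len(theta))
            delta[free] = delta_f
            for h in (1.0, 0.5, 0.25, 0.125, 1 / 16, 1 / 32):
                cand = _project(CovarianceStructures.from_vector(
                    theta + h * delta, frame.t, has_block))
                st = _evaluate(frame, cand)
                if st is not None and st.loglik >= state.loglik - 1e-10:
                    accepted = (cand, st)
                    break
            if accepted:
                break
        if accepted is None:
            # no uphill step found: treat as converged at a boundary
            converged = True
            break
        cand, st = accepted
        new_theta = cand.to_vector()
        d_ll = st.loglik - state.loglik
        rel = float(np.max(np.abs(new_theta - theta)) /
                    max(np.max(np.abs(new_theta)), 1e-3))
        if opts.verbose:
            log.info("iter %d loglik %.8f dll %.2e rel %.2e", n_iter,
                     st.loglik, d_ll, rel)
        theta, state = new_theta, st
        score, AI = _derivatives(frame, state)
        if abs(d_ll) < opts.tol_loglik and rel < opts.tol_params:
            converged = True
            break

    cs = state.cs
    labels = cs.labels
    try:
        cov = np.linalg.inv(AI)
        se_vec = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se_vec = np.full(t_free, np.nan)
    se = dict(zip(labels, se_vec))
    return VarianceEstimates(
        structures=cs,
        se=se,
        loglik=state.loglik,
        aic=aic(state.loglik, t_free),
        converged=converged,
        n_iter=n_iter,
    )


def blup_solve(
    ds: TraitDataset,
    K_inv: RelationshipMatrix,
    cs: CovarianceStructures,
    compute_se: bool = True,
) -> BlupSolution:
    """Solve the MME at fixed variance components.

    Breeding values cover every individual in ``K_inv.ids`` (parents
    included); prediction SEs are square roots of the corresponding
    diagonal entries of the inverse coefficient matrix.
    """
    frame = _ModelFrame(ds, K_inv)
    state = _evaluate(frame, cs)
    if state is None:
        raise ValueError("variance structures are not feasible")
    t, nK, nb = frame.t, frame.nK, frame.nb
    a0, u0 = frame.off_a, frame.off_u
    bv = np.column_stack([state.sol[a0 + k * nK:a0 + (k + 1) * nK] for k in range(t)])
    names = list(ds.trait_names)
    bv_df = pd.DataFrame(bv, index=list(frame.k_ids), columns=names)
    se_df = None
    if compute_se:
        Cinv = dpotri(state.factor.copy(), lower=1)[0]
        dg = np.diag(Cinv)
        se = np.column_stack([
            np.sqrt(np.clip(dg[a0 + k * nK:a0 + (k + 1) * nK], 0.0, None))
            for k in range(t)
        ])
        se_df = pd.DataFrame(se, index=list(frame.k_ids), columns=names)
    blocks_df = None
    if nb:
        ue = np.column_stack([state.sol[u0 + k * nb:u0 + (k + 1) * nb] for k in range(t)])
        blocks_df = pd.DataFrame(ue, index=list(frame.block_levels), columns=names)
    fixed = pd.Series(state.sol[:t], index=names)
    return BlupSolution(
        ids=frame.k_ids,
        trait_names=ds.trait_names,
        breeding_values=bv_df,
        se_bv=se_df,
        block_effects=blocks_df,
        fixed_effects=fixed,
    )
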