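"""The varying-genotyping-effort study.

For each effort level (percent of each family genotyped) the study
repeatedly subsamples the genotyped set, rebuilds the genomic matrix on
the retained trees (allele frequencies recomputed on that subset), rescales
and blends it against the matching pedigree block, assembles the
single-step inverse, refits the bivariate model by REML, and computes the
derived statistics. Breeding-value accuracies are computed in a second
pass with variance components fixed to the full-genotyping estimates, and
rankings are compared with the pedigree-only (ABLUP) baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import evaluation as ev
from .genomic import GenotypeMatrix, vanraden_G
from .hmatrix import combined_relationship
from .matrices import RelationshipMatrix
from .mixedmodel import (
    BlupSolution, CovarianceStructures, RemlOptions, TraitDataset,
    VarianceEstimates, blup_solve, reml_fit, standardize,
)
from .pedigree import PedigreeTable, build_A, build_A_inverse, inbreeding

__all__ = [
    "EffortScenario",
    "EffortResult",
    "StudyConfig",
    "subsample_genotyped",
    "run_effort_study",
    "accuracy_with_fixed_components",
]

log = logging.getLogger(__name__)

ACCURACY_CLASSES = ("maternal", "genotyped", "nongenotyped")


@dataclass
class EffortScenario:
    """One genotyping-effort level. Efforts 0 and 100 are deterministic
    (single replicate); intermediate levels are replicated."""

    effort: int
    n_reps: int = 30

    def __post_init__(self) -> None:
        if self.effort not in (0, 25, 50, 75, 100):
            raise ValueError("effort must be one of 0, 25, 50, 75, 100")
        if self.effort in (0, 100):
            self.n_reps = 1
        elif self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


@dataclass
class StudyConfig:
    """Knobs shared across the whole study."""

    blend_weight: float = 0.95
    scale_g: bool = True
    reml: RemlOptions = field(default_factory=RemlOptions)
    seed: int = 0
    top_fraction: float = 0.05
    group_stats: bool = True
    standardize: bool = True


@dataclass
class EffortResult:
    """Per-replicate scalar results for one effort level, plus aggregates
    (means/SDs over converged replicates only)."""

    effort: int
    replicates: pd.DataFrame
    rep_seeds: tuple[int, ...]

    @property
    def n_converged(self) -> int:
        return int(self.replicates["converged"].sum())

    def aggregate(self) -> pd.DataFrame:
        ok = self.replicates[self.replicates["converged"]]
        num = ok.select_dtypes(include=[float, int]).drop(columns=["replicate", "seed"],
                                                          errors="ignore")
        return pd.DataFrame({"mean": num.mean(), "sd": num.std(ddof=1)})


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def subsample_genotyped(
    families: Mapping[str, Sequence[str]],
    effort: int,
    rng: np.random.Generator | int,
) -> list[str]:
    """Randomly drop trees from each family's genotyped set.

    Per family, round((1 - effort/100) * n_f) members are removed
    (half-up rounding), so a family of eight loses exactly 6/4/2 trees at
    25/50/75% effort. Returns the retained ids in a deterministic order.
    """
    if effort not in (25, 50, 75):
        raise ValueError("subsampling applies to efforts 25, 50, 75")
    if not families:
        raise ValueError("empty family set")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    retained: list[str] = []
    for fam in sorted(families):
        members = list(families[fam])
        n_remove = _round_half_up((1.0 - effort / 100.0) * len(members))
        drop = set(rng.choice(len(members), size=n_remove, replace=False))
        retained.extend(m for k, m in enumerate(members) if k not in drop)
    return retained


def _accuracy_by_class(
    sol: BlupSolution,
    ds: TraitDataset,
    F: Mapping[str, float],
    cs_ref: CovarianceStructures,
    mothers: Sequence[str],
    genotyped: Sequence[str],
) -> dict[str, float]:
    """Mean Eq-style accuracy per individual class and trait; an empty
    class yields NaN (reported as not-applicable)."""
    gset = set(genotyped)
    prog = [i for i in ds.tree_id]
    classes = {
        "maternal": [m for m in mothers],
        "genotyped": [i for i in prog if i in gset],
        "nongenotyped": [i for i in prog if i not in gset],
    }
    out: dict[str, float] = {}
    for k, trait in enumerate(sol.trait_names):
        sa2 = float(cs_ref.additive[k, k])
        for cname, ids in classes.items():
            key = f"acc_{cname}_{trait}"
            if not ids:
                out[key] = np.nan
                continue
            se = sol.se_bv.loc[ids, trait].to_numpy()
            f = np.array([F.get(i, 0.0) for i in ids])
            out[key] = float(np.mean(ev.bv_accuracy(se, f, sa2)))
    return out


def accuracy_with_fixed_components(
    ds: TraitDataset,
    K_inv: RelationshipMatrix,
    cs_ref: CovarianceStructures,
    F: Mapping[str, float],
    mothers: Sequence[str],
    genotyped: Sequence[str],
) -> tuple[BlupSolution, dict[str, float]]:
    """BLUP at fixed reference components plus per-class mean accuracies."""
    sol = blup_solve(ds, K_inv, cs_ref, compute_se=True)
    return sol, _accuracy_by_class(sol, ds, F, cs_ref, mothers, genotyped)


def _fit_stats(est: VarianceEstimates, trait_names: Sequence[str]) -> dict[str, float]:
    out: dict[str, float] = {"loglik": est.loglik, "aic": est.aic,
                             "n_iter": float(est.n_iter)}
    add, res = est.structures.additive, est.structures.residual
    for k, name in enumerate(trait_names):
        out[f"sigma2_a_{name}"] = float(add[k, k])
        out[f"sigma2_e_{name}"] = float(res[k, k])
        if est.structures.block is not None:
            out[f"sigma2_b_{name}"] = float(est.structures.block[k])
        out[f"h2_{name}"] = ev.heritability(add[k, k], res[k, k])
    if len(trait_names) == 2:
        out["r_G"] = ev.genetic_correlation(add[0, 1], add[0, 0], add[1, 1])
    return out


def _ranking_stats(
    sol: BlupSolution,
    baseline: BlupSolution,
    mothers: Sequence[str],
    progeny: Sequence[str],
    top_fraction: float,
) -> dict[str, float]:
    out: dict[str, float] = {}
    for trait in sol.trait_names:
        for label, ids in (("maternal", list(mothers)), ("progeny", list(progeny))):
            x = sol.breeding_values.loc[ids, trait]
            y = baseline.breeding_values.loc[ids, trait]
            out[f"spearman_{label}_{trait}"] = ev.spearman_rank(x, y)
            out[f"top5_{label}_{trait}"] = ev.top_fraction_overlap(
                x, y, fraction=top_fraction)
    return out


def run_effort_study(
    ds: TraitDataset,
    ped: PedigreeTable,
    gm: GenotypeMatrix,
    scenarios: Sequence[EffortScenario],
    config: StudyConfig | None = None,
) -> list[EffortResult]:
    """Run the replicated genotyping-effort study.

    The pedigree-only model is fitted first (effort 0 baseline), then the
    full-genotyping single-step model, whose variance components are the
    fixed reference for all accuracy computations. Intermediate efforts
    subsample each family's genotyped set with per-replicate seeds spawned
    deterministically from ``config.seed``. Non-converged replicates are
    flagged, logged and excluded from aggregates.
    """
    config = config or StudyConfig()
    ds_fit = standardize(ds) if config.standardize else ds
    A = build_A(ped)
    A_inv = build_A_inverse(ped)
    F = inbreeding(ped)
    mothers = tuple(sorted(ped.families()))
    progeny = ds.tree_id
    genotyped_all = [i for i, g in zip(ds.tree_id, ds.genotyped) if g]
    fam_of = dict(zip(ds.tree_id, ds.family_id))
    families: dict[str, list[str]] = {}
    for i in genotyped_all:
        families.setdefault(fam_of[i], []).append(i)

    # --- baselines ------------------------------------------------------
    est_a = reml_fit(ds_fit, A_inv, opts=config.reml)
    log.info("ABLUP fit: loglik=%.3f converged=%s", est_a.loglik, est_a.converged)

    G_full = vanraden_G(gm.subset(genotyped_all))
    _, Hinv_full, _ = combined_relationship(
        A, A_inv, G_full, w=config.blend_weight, scale=config.scale_g, want_H=False)
    est_h100 = reml_fit(ds_fit, Hinv_full, start=est_a.structures, opts=config.reml)
    log.info("HBLUP(100) fit: loglik=%.3f converged=%s", est_h100.loglik,
             est_h100.converged)
    cs_ref = est_h100.structures

    sol_a, _ = accuracy_with_fixed_components(
        ds_fit, A_inv, cs_ref, F, mothers, genotyped=[])

    seed_seq = np.random.SeedSequence(config.seed)

    def one_replicate(effort: int, rep: int, seed: int) -> dict[str, float]:
        row: dict[str, float] = {"replicate": float(rep), "seed": float(seed)}
        if effort == 0:
            est, K_inv, retained = est_a, A_inv, []
            H = A if config.group_stats else None
        else:
            if effort == 100:
                retained = list(genotyped_all)
            else:
                retained = subsample_genotyped(
                    families, effort, np.random.default_rng(seed))
            G = vanraden_G(gm.subset(retained))
            H, K_inv, _ = combined_relationship(
                A, A_inv, G, w=config.blend_weight, scale=config.scale_g,
                want_H=config.group_stats)
            est = (est_h100 if effort == 100
                   else reml_fit(ds_fit, K_inv, start=cs_ref, opts=config.reml))
        row["converged"] = bool(est.converged)
        row.update(_fit_stats(est, ds_fit.trait_names))
        sol, acc = accuracy_with_fixed_components(
            ds_fit, K_inv, cs_ref, F, mothers, retained)
        row.update(acc)
        row.update(_ranking_stats(sol, sol_a, mothers, progeny,
                                  config.top_fraction))
        if config.group_stats and H is not None:
            gs = ev.relationship_group_stats(H, ped, ref=A)
            row["pearson_r_with_A"] = gs.pearson_r_with_ref
            row["half_sib_mean"] = float(gs.per_group.loc["half_sib", "mean"])
        if not est.converged:
            log.warning("effort %d replicate %d did not converge", effort, rep)
        log.info("effort=%d rep=%d seed=%d converged=%s loglik=%.3f",
                 effort, rep, seed, est.converged, est.loglik)
        return row

    results: list[EffortResult] = []
    for sc in scenarios:
        child_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                       for s in seed_seq.spawn(sc.n_reps)]
        rows = [one_replicate(sc.effort, r, child_seeds[r])
                for r in range(sc.n_reps)]
        df = pd.DataFrame(rows)
        df["converged"] = df["converged"].astype(bool)
        results.append(EffortResult(effort=sc.effort, replicates=df,
                                    rep_seeds=tuple(child_seeds)))
    return results
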