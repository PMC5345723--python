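"""Synthetic open-pollinated progeny trial with hidden relatedness.

Emulates the structure of a provenance-progeny test: maternal parents
drawn from provenances (with optional background coancestry realised
through an explicit unobserved grandparental generation), open-pollinated
families whose offspring share pollen donors at a configurable rate
(hidden full-sibs), selfing, and pedigree recording errors. Genotypes are
produced by gene drop (founder alleles Bernoulli(p_j), Mendelian
transmission); breeding values either sum random additive effects over the
gene-dropped marker genotypes (default) or follow the Mendelian-sampling
recursion on the true pedigree, and phenotypes are
mean + block + breeding value + residual.

The recorded pedigree lists only the (possibly mis-recorded) dam, so the
analysis sees a nominal half-sib structure while the truth contains
full-sibs, selfs and maternal coancestry — the situation the single-step
evaluation is designed to expose.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

from .genomic import GenotypeMatrix, allele_frequencies
from .mixedmodel import CovarianceStructures, TraitDataset
from .pedigree import PedigreeTable, build_A

__all__ = ["SimConfig", "TruthRecord", "simulate_population", "realized_summary"]


@dataclass
class SimConfig:
    """Generator settings; defaults emulate the white spruce trial scale.

    ``full_sib_proportion`` is the probability that an offspring reuses a
    pollen donor already used in its family (creating hidden full-sib
    sets); ``provenance_relatedness`` is the target mean additive
    relationship among maternal parents of the same provenance, realised
    by drawing each mother's two parents from an unobserved grandparental
    pool of size ~1/relatedness.

    ``genetic_mode`` selects how breeding values arise: ``"marker"``
    (default) sums random additive effects over the gene-dropped marker
    genotypes, so trait covariance follows realized genomic relationships
    as it does in real data; ``"pedigree"`` draws breeding values from the
    expected (true-pedigree) relationship structure via the
    Mendelian-sampling recursion, the exact generative assumption of the
    pedigree animal model.
    """

    n_provenances: int = 43
    n_families: int = 214
    mean_family_size: float = 7.9
    max_family_size: int = 12
    n_blocks: int = 6
    n_markers: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    full_sib_proportion: float = 0.2
    selfing_rate: float = 0.05
    pedigree_error_rate: float = 0.02
    provenance_relatedness: float = 0.05
    h2: tuple[float, float] = (0.3, 0.6)
    block_var_fraction: tuple[float, float] = (0.05, 0.01)
    r_G: float = 0.0
    residual_correlation: float = 0.0
    genetic_mode: str = "marker"
    trait_names: tuple[str, ...] = ("HT", "WD")
    trait_means: tuple[float, ...] = (230.0, 430.0)
    trait_sds: tuple[float, ...] = (60.0, 35.0)
    seed: int = 0

    def validate(self) -> None:
        for p in (self.full_sib_proportion, self.selfing_rate,
                  self.pedigree_error_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if not 0.0 <= self.provenance_relatedness < 0.5:
            raise ValueError("provenance_relatedness must be in [0, 0.5)")
        for h, b in zip(self.h2, self.block_var_fraction):
            if not 0.0 < h < 1.0:
                raise ValueError("h2 must be in (0, 1)")
            if not 0.0 <= b < 1.0:
                raise ValueError("block variance fraction must be in [0, 1)")
        if abs(self.r_G) > 1 or abs(self.residual_correlation) > 1:
            raise ValueError("correlations must be in [-1, 1]")
        if self.n_families < 1 or self.n_provenances < 1 or self.n_markers < 1:
            raise ValueError("counts must be positive")
        if self.genetic_mode not in ("marker", "pedigree"):
            raise ValueError("genetic_mode must be 'marker' or 'pedigree'")

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    def latent_components(self) -> CovarianceStructures:
        """True (co)variance structures on the latent standardized scale:
        s2_a + s2_e = 1 per trait, block variance = frac / (1 - frac)."""
        h2 = np.asarray(self.h2, dtype=float)
        sd_a = np.sqrt(h2)
        corr_a = np.eye(self.n_traits)
        corr_a[corr_a == 0] = self.r_G
        Sa = np.outer(sd_a, sd_a) * corr_a
        sd_e = np.sqrt(1.0 - h2)
        corr_e = np.eye(self.n_traits)
        corr_e[corr_e == 0] = self.residual_correlation
        Se = np.outer(sd_e, sd_e) * corr_e
        bf = np.asarray(self.block_var_fraction, dtype=float)
        Su = bf / (1.0 - bf)
        return CovarianceStructures(Sa, Su, Se)


@dataclass
class TruthRecord:
    """Ground truth behind one simulated trial."""

    true_pedigree: PedigreeTable
    true_components: CovarianceStructures
    true_bv: pd.DataFrame            # every pedigree individual x traits (latent scale)
    residuals: pd.DataFrame          # offspring x traits (latent scale)
    mothers: tuple[str, ...]
    offspring: tuple[str, ...]
    genotyped_ids: tuple[str, ...]
    provenance_of_mother: dict[str, str]
    true_dam: dict[str, str]         # offspring -> true dam (recorded may differ)
    true_sire: dict[str, str]
    recording_errors: tuple[str, ...]  # offspring whose recorded dam is wrong
    founder_freqs: np.ndarray
    founder_genotypes: GenotypeMatrix
    trait_scale: dict[str, tuple[float, float]]  # name -> (mean, sd)
    marker_effects: np.ndarray | None = None  # m x t, marker generative mode only


def _family_sizes(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    sizes = rng.poisson(cfg.mean_family_size, size=cfg.n_families)
    return np.clip(sizes, 1, cfg.max_family_size)


def simulate_population(
    cfg: SimConfig,
) -> tuple[PedigreeTable, TruthRecord, GenotypeMatrix, TraitDataset]:
    """Generate (recorded pedigree, truth, genotypes, phenotypes).

    All randomness flows from ``cfg.seed``; identical configurations give
    bitwise-identical outputs.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    t = cfg.n_traits

    # --- provenances and maternal parents ------------------------------
    mothers = [f"M{i + 1:03d}" for i in range(cfg.n_families)]
    prov_of = {m: f"P{(i % cfg.n_provenances) + 1:02d}"
               for i, m in enumerate(mothers)}
    true_records: list[tuple[str, str | None, str | None]] = []
    if cfg.provenance_relatedness > 0:
        pool_size = max(2, round(1.0 / cfg.provenance_relatedness))
        pools: dict[str, list[str]] = {}
        for p in sorted(set(prov_of.values())):
            pools[p] = [f"{p}_G{k + 1:02d}" for k in range(pool_size)]
            true_records += [(g, None, None) for g in pools[p]]
        for m in mothers:
            pool = pools[prov_of[m]]
            gp = rng.choice(len(pool), size=2, replace=False)
            true_records.append((m, pool[gp[0]], pool[gp[1]]))
    else:
        true_records += [(m, None, None) for m in mothers]

    # --- families: selfing and shared pollen donors --------------------
    sizes = _family_sizes(cfg, rng)
    offspring: list[str] = []
    true_dam: dict[str, str] = {}
    true_sire: dict[str, str] = {}
    donor_records: list[tuple[str, None, None]] = []
    n_donors = 0
    for fi, m in enumerate(mothers):
        donors: list[str] = []
        for j in range(sizes[fi]):
            o = f"{m}_O{j + 1:02d}"
            offspring.append(o)
            true_dam[o] = m
            if rng.random() < cfg.selfing_rate:
                sire = m
            elif donors and rng.random() < cfg.full_sib_proportion:
                sire = donors[rng.integers(len(donors))]
            else:
                n_donors += 1
                sire = f"D{n_donors:04d}"
                donors.append(sire)
                donor_records.append((sire, None, None))
            true_sire[o] = sire
    true_records += donor_records
    true_records += [(o, true_dam[o], true_sire[o]) for o in offspring]
    true_ped = PedigreeTable.from_records(true_records)

    # --- recorded pedigree (dams only, with recording errors) ----------
    recorded_dam = dict(true_dam)
    errors: list[str] = []
    if cfg.pedigree_error_rate > 0 and cfg.n_families > 1:
        for o in offspring:
            if rng.random() < cfg.pedigree_error_rate:
                other = [m for m in mothers if m != true_dam[o]]
                recorded_dam[o] = other[rng.integers(len(other))]
                errors.append(o)
    recorded = PedigreeTable.from_records(
        [(m, None, None) for m in mothers]
        + [(o, recorded_dam[o], None) for o in offspring]
    )

    # --- gene drop ------------------------------------------------------
    m_mark = cfg.n_markers
    p = rng.uniform(*cfg.maf_range, size=m_mark)
    nt = true_ped.n
    al1 = np.empty((nt, m_mark), dtype=np.int8)
    al2 = np.empty((nt, m_mark), dtype=np.int8)
    for i in range(nt):
        d, s = true_ped.dam[i], true_ped.sire[i]
        if d < 0:
            al1[i] = rng.random(m_mark) < p
        else:
            pick = rng.integers(0, 2, m_mark, dtype=np.int8)
            al1[i] = np.where(pick == 0, al1[d], al2[d])
        if s < 0:
            al2[i] = rng.random(m_mark) < p
        else:
            pick = rng.integers(0, 2, m_mark, dtype=np.int8)
            al2[i] = np.where(pick == 0, al1[s], al2[s])
    dose = (al1 + al2).astype(float)
    marker_ids = tuple(f"snp{j + 1:05d}" for j in range(m_mark))
    pos = {ind: k for k, ind in enumerate(true_ped.ids)}
    genotyped_ids = tuple(offspring)
    gm = GenotypeMatrix(genotyped_ids, marker_ids,
                        dose[[pos[o] for o in offspring]])
    founder_ids = tuple(i for k, i in enumerate(true_ped.ids)
                        if true_ped.dam[k] < 0 and true_ped.sire[k] < 0)
    founder_gm = GenotypeMatrix(founder_ids, marker_ids,
                                dose[[pos[f] for f in founder_ids]])

    # --- breeding values -------------------------------------------------
    comps = cfg.latent_components()
    marker_effects = None
    if cfg.genetic_mode == "marker":
        # additive effects on the panel itself: trait covariance follows
        # realized genomic relationships, as in real data where markers
        # tag the causal variation
        corr_a = np.eye(t)
        corr_a[corr_a == 0] = cfg.r_G
        eff = rng.standard_normal((m_mark, t)) @ np.linalg.cholesky(corr_a).T
        denom = float(np.sum(2.0 * p * (1.0 - p)))
        scale_k = np.sqrt(np.diag(comps.additive) / denom)
        marker_effects = eff * scale_k
        z_all = dose - 2.0 * p[None, :]
        bv = z_all @ marker_effects
    else:
        # Mendelian-sampling recursion = Cholesky of the true numerator
        # matrix in pedigree order
        La = np.linalg.cholesky(comps.additive)
        F = np.diag(build_A(true_ped).values) - 1.0
        bv = np.zeros((nt, t))
        for i in range(nt):
            d, s = true_ped.dam[i], true_ped.sire[i]
            if d < 0 and s < 0:
                bv[i] = La @ rng.standard_normal(t)
            else:
                mean = np.zeros(t)
                msv = 1.0
                for par in (d, s):
                    if par >= 0:
                        mean += 0.5 * bv[par]
                        msv -= 0.25 * (1.0 + F[par])
                bv[i] = mean + np.sqrt(msv) * (La @ rng.standard_normal(t))

    # --- phenotypes ------------------------------------------------------
    n_off = len(offspring)
    block_of = rng.integers(0, cfg.n_blocks, size=n_off)
    block_names = [f"B{b + 1}" for b in block_of]
    u = rng.standard_normal((cfg.n_blocks, t)) * np.sqrt(comps.block)
    Le = np.linalg.cholesky(comps.residual)
    e = rng.standard_normal((n_off, t)) @ Le.T
    a_off = bv[[pos[o] for o in offspring]]
    latent = a_off + u[block_of] + e
    means = np.asarray(cfg.trait_means, dtype=float)
    sds = np.asarray(cfg.trait_sds, dtype=float)
    raw = means + sds * latent

    ds = TraitDataset(
        tree_id=genotyped_ids,
        family_id=tuple(recorded_dam[o] for o in offspring),
        block_id=tuple(block_names),
        traits=raw,
        trait_names=cfg.trait_names,
        genotyped=np.ones(n_off, dtype=bool),
    )
    truth = TruthRecord(
        true_pedigree=true_ped,
        true_components=comps,
        true_bv=pd.DataFrame(bv, index=list(true_ped.ids), columns=list(cfg.trait_names)),
        residuals=pd.DataFrame(e, index=list(offspring), columns=list(cfg.trait_names)),
        mothers=tuple(mothers),
        offspring=tuple(offspring),
        genotyped_ids=genotyped_ids,
        provenance_of_mother=prov_of,
        true_dam=true_dam,
        true_sire=true_sire,
        recording_errors=tuple(errors),
        founder_freqs=p,
        founder_genotypes=founder_gm,
        trait_scale={n: (float(mu), float(sd))
                     for n, mu, sd in zip(cfg.trait_names, means, sds)},
        marker_effects=marker_effects,
    )
    return recorded, truth, gm, ds


def realized_summary(truth: TruthRecord, gm: GenotypeMatrix) -> dict:
    """Realized statistics of one simulated trial.

    Returns realized heritabilities (from the simulated effects), the
    within-family distribution of true additive relationships, the mean
    true within-family relationship, realized allele-frequency spectrum,
    and the fraction of selfed offspring.
    """
    A_true = build_A(truth.true_pedigree)
    fam_means: list[float] = []
    within_vals: list[np.ndarray] = []
    by_dam: dict[str, list[str]] = {}
    for o in truth.offspring:
        by_dam.setdefault(truth.true_dam[o], []).append(o)
    for fam in by_dam.values():
        if len(fam) < 2:
            continue
        sub = A_true.submatrix(fam).values
        iu, ju = np.triu_indices(len(fam), k=1)
        vals = sub[iu, ju]
        within_vals.append(vals)
        fam_means.append(float(np.mean(vals)))
    within = np.concatenate(within_vals) if within_vals else np.array([])

    a = truth.true_bv.loc[list(truth.offspring)].to_numpy()
    e = truth.residuals.loc[list(truth.offspring)].to_numpy()
    va = np.var(a, axis=0, ddof=1)
    ve = np.var(e, axis=0, ddof=1)
    h2 = va / (va + ve)

    freqs = allele_frequencies(gm)
    selfed = sum(1 for o in truth.offspring
                 if truth.true_sire[o] == truth.true_dam[o])
    return {
        "realized_h2": dict(zip(truth.true_bv.columns, h2)),
        "within_family_mean": float(np.mean(within)) if within.size else np.nan,
        "within_family_values": within,
        "family_mean_relationship": np.asarray(fam_means),
        "realized_maf": np.minimum(freqs.p, 1.0 - freqs.p),
        "selfing_fraction": selfed / max(len(truth.offspring), 1),
    }
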