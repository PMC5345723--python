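"""Genomic relationship matrix from SNP dosages (VanRaden method 1).

Genotypes are coded 0/1/2 copies of the reference allele, with missing
values allowed. Allele frequencies come from the genotyped set itself (the
genotyped population is the genomic base population); centered scores have
missing entries replaced by zero, i.e. mean imputation on the centered
scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .matrices import RelationshipMatrix

__all__ = [
    "GenotypeMatrix",
    "AlleleFrequencies",
    "read_genotypes",
    "read_genotypes_vcf",
    "allele_frequencies",
    "center_scores",
    "vanraden_G",
]

log = logging.getLogger(__name__)


@dataclass
class GenotypeMatrix:
    """n individuals x m markers of reference-allele dosages.

    ``scores`` is float with entries in {0, 1, 2, NaN}; NaN marks a missing
    call.
    """

    ids: tuple[str, ...]
    marker_ids: tuple[str, ...]
    scores: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.ids = tuple(str(i) for i in self.ids)
        self.marker_ids = tuple(str(m) for m in self.marker_ids)
        self.scores = np.asarray(self.scores, dtype=float)
        n, m = len(self.ids), len(self.marker_ids)
        if n < 1 or m < 1:
            raise ValueError("genotype matrix needs at least 1 individual and 1 marker")
        if self.scores.shape != (n, m):
            raise ValueError(f"scores shape {self.scores.shape} != ({n}, {m})")
        obs = self.scores[~np.isnan(self.scores)]
        if not np.isin(obs, (0.0, 1.0, 2.0)).all():
            bad = np.unique(obs[~np.isin(obs, (0.0, 1.0, 2.0))])
            raise ValueError(f"genotype scores outside {{0,1,2,missing}}: {bad[:5]}")
        self._index = {i: k for k, i in enumerate(self.ids)}
        if len(self._index) != n:
            raise ValueError("duplicate individual ids in genotype matrix")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def m(self) -> int:
        return len(self.marker_ids)

    def subset(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self._index[str(i)] for i in ids]
        return GenotypeMatrix(tuple(str(i) for i in ids), self.marker_ids,
                              self.scores[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=list(self.ids),
                            columns=list(self.marker_ids))

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="id", na_rep="NA")


def read_genotypes(path) -> GenotypeMatrix:
    """Read a TSV/CSV dosage table: rows = individuals (first column id),
    columns = markers, entries 0/1/2/NA."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    return GenotypeMatrix(tuple(str(i) for i in df.index),
                          tuple(str(c) for c in df.columns),
                          df.to_numpy(dtype=float))


def read_genotypes_vcf(path) -> GenotypeMatrix:
    """Read biallelic VCF records as reference-allele dosages.

    Multiallelic records are skipped with a warning. Requires ``cyvcf2``.
    """
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path), gts012=True)
    ids = tuple(vcf.samples)
    markers: list[str] = []
    rows: list[np.ndarray] = []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            skipped += 1
            continue
        # gt_types: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown; dosage of REF
        gt = np.asarray(var.gt_types, dtype=float)
        dose = np.where(gt == 3, np.nan, 2.0 - np.minimum(gt, 2.0))
        markers.append(var.ID or f"{var.CHROM}:{var.POS}")
        rows.append(dose)
    if skipped:
        warnings.warn(f"skipped {skipped} multiallelic VCF record(s)")
    return GenotypeMatrix(ids, tuple(markers), np.column_stack(rows))


@dataclass
class AlleleFrequencies:
    """Per-marker reference allele frequency, computed ignoring missing."""

    marker_ids: tuple[str, ...]
    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if ((self.p < 0) | (self.p > 1)).any():
            raise ValueError("allele frequencies outside [0, 1]")


def allele_frequencies(gm: GenotypeMatrix) -> AlleleFrequencies:
    """p_j = (sum of observed dosages at marker j) / (2 * observed count)."""
    obs = ~np.isnan(gm.scores)
    counts = obs.sum(axis=0)
    if (counts == 0).any():
        bad = [gm.marker_ids[j] for j in np.where(counts == 0)[0][:5]]
        raise ValueError(f"marker(s) with all scores missing: {bad}")
    sums = np.nansum(gm.scores, axis=0)
    return AlleleFrequencies(gm.marker_ids, sums / (2.0 * counts))


def center_scores(gm: GenotypeMatrix, freqs: AlleleFrequencies) -> np.ndarray:
    """Centered scores Z_ij = score_ij - 2 p_j; missing entries become 0."""
    z = gm.scores - 2.0 * freqs.p[None, :]
    return np.where(np.isnan(gm.scores), 0.0, z)


def vanraden_G(
    gm: GenotypeMatrix,
    maf_min: float = 0.0,
    call_rate_min: float = 0.0,
) -> RelationshipMatrix:
    """G = Z Z' / (2 sum_j p_j (1 - p_j)).

    Markers monomorphic among the scored individuals contribute zero to
    both numerator and denominator; they are excluded up front (with a
    logged count) so the degenerate all-monomorphic case raises a clear
    error instead of dividing by zero. Optional minor-allele-frequency and
    call-rate filters are off by default.
    """
    freqs = allele_frequencies(gm)
    p = freqs.p
    keep = p * (1.0 - p) > 0.0
    n_mono = int((~keep).sum())
    if n_mono:
        log.info("excluding %d monomorphic marker(s) before G", n_mono)
    if maf_min > 0.0:
        maf = np.minimum(p, 1.0 - p)
        keep &= maf >= maf_min
    if call_rate_min > 0.0:
        call = (~np.isnan(gm.scores)).mean(axis=0)
        keep &= call >= call_rate_min
    if not keep.any():
        raise ValueError(
            "no polymorphic markers left: denominator of the genomic "
            "relationship matrix would be zero"
        )
    sub = GenotypeMatrix(gm.ids, tuple(np.asarray(gm.marker_ids)[keep]),
                         gm.scores[:, keep])
    freqs = allele_frequencies(sub)
    z = center_scores(sub, freqs)
    denom = 2.0 * float(np.sum(freqs.p * (1.0 - freqs.p)))
    g = (z @ z.T) / denom
    g = 0.5 * (g + g.T)
    return RelationshipMatrix(gm.ids, g, role="G")
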