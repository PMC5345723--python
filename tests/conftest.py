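"""Shared fixtures: small pedigrees and one reduced synthetic trial."""

import numpy as np
import pytest

from singlestep import PedigreeTable, SimConfig, simulate_population


def random_pedigree(n: int, rng: np.random.Generator,
                    p_dam: float = 0.7, p_sire: float = 0.5) -> PedigreeTable:
    """Random multi-generation pedigree with inbreeding loops."""
    recs = []
    for i in range(n):
        dam = sire = None
        if i > 3:
            if rng.random() < p_dam:
                dam = f"I{rng.integers(0, i)}"
            if rng.random() < p_sire:
                sire = f"I{rng.integers(0, i)}"
            if dam == sire:
                sire = None
        recs.append((f"I{i}", dam, sire))
    return PedigreeTable.from_records(recs)


@pytest.fixture(scope="session")
def op_pedigree() -> PedigreeTable:
    """Open-pollinated pedigree: 12 founder dams, 5 offspring each,
    sires unknown."""
    recs = [(f"M{f}", None, None) for f in range(12)]
    recs += [(f"M{f}_O{j}", f"M{f}", None) for f in range(12) for j in range(5)]
    return PedigreeTable.from_records(recs)


@pytest.fixture(scope="session")
def small_trial():
    """One reduced synthetic trial with hidden relatedness (session-wide)."""
    cfg = SimConfig(n_families=40, n_provenances=8, n_markers=400, seed=17)
    return cfg, *simulate_population(cfg)


@pytest.fixture(scope="session")
def null_trial():
    """Reduced trial without any hidden structure (pure half-sibs)."""
    cfg = SimConfig(n_families=40, n_provenances=8, n_markers=400, seed=23,
                    full_sib_proportion=0.0, selfing_rate=0.0,
                    pedigree_error_rate=0.0, provenance_relatedness=0.0)
    return cfg, *simulate_population(cfg)
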