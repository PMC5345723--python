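"""Synthetic trial generator: structure, determinism, realized statistics."""

import numpy as np
import pytest
from scipy import stats as sps

from singlestep import (
    SimConfig, build_A, realized_summary, simulate_population,
)


class TestConfigValidation:
    def test_bad_probability(self):
        with pytest.raises(ValueError):
            SimConfig(selfing_rate=1.5).validate()

    def test_bad_h2(self):
        with pytest.raises(ValueError):
            SimConfig(h2=(0.0, 0.6)).validate()

    def test_bad_mode(self):
        with pytest.raises(ValueError):
            SimConfig(genetic_mode="oracle").validate()

    def test_latent_components_scale(self):
        cs = SimConfig(h2=(0.3, 0.6)).latent_components()
        assert np.allclose(np.diag(cs.additive) + np.diag(cs.residual), 1.0)
        assert cs.additive[0, 0] == pytest.approx(0.3)
        assert cs.block[0] == pytest.approx(0.05 / 0.95)


class TestStructure:
    def test_counts_and_recorded_pedigree_shape(self, small_trial):
        cfg, ped, truth, gm, ds = small_trial
        assert len(truth.mothers) == cfg.n_families
        assert len(truth.offspring) == ds.n == gm.n
        assert gm.m == cfg.n_markers
        # recorded pedigree: mothers are founders, offspring have dam only
        for m in truth.mothers:
            assert ped.dam_of(m) is None and ped.sire_of(m) is None
        for o in truth.offspring[:20]:
            assert ped.dam_of(o) is not None and ped.sire_of(o) is None
        # true family sizes respect the truncation bounds (recorded families
        # can deviate through injected dam-recording errors)
        true_sizes: dict[str, int] = {}
        for o in truth.offspring:
            true_sizes[truth.true_dam[o]] = true_sizes.get(truth.true_dam[o], 0) + 1
        assert max(true_sizes.values()) <= cfg.max_family_size
        assert min(true_sizes.values()) >= 1

    def test_recording_errors_are_the_only_dam_mismatches(self, small_trial):
        cfg, ped, truth, gm, ds = small_trial
        mism = {o for o in truth.offspring if ped.dam_of(o) != truth.true_dam[o]}
        assert mism == set(truth.recording_errors)

    def test_determinism_bitwise(self, small_trial):
        cfg, ped, truth, gm, ds = small_trial
        ped2, truth2, gm2, ds2 = simulate_population(cfg)
        assert ped2.ids == ped.ids
        assert np.array_equal(gm2.scores, gm.scores)
        assert np.array_equal(ds2.traits, ds.traits)
        assert truth2.true_sire == truth.true_sire

    def test_different_seed_differs(self, small_trial):
        cfg, _, _, gm, _ = small_trial
        cfg2 = SimConfig(**{**cfg.__dict__, "seed": cfg.seed + 1})
        _, _, gm2, _ = simulate_population(cfg2)
        assert not np.array_equal(gm2.scores, gm.scores)


class TestHiddenRelatedness:
    def test_null_configuration_is_pure_half_sib(self, null_trial):
        cfg, ped, truth, gm, ds = null_trial
        s = realized_summary(truth, gm)
        assert s["within_family_mean"] == pytest.approx(0.25, abs=1e-12)
        assert s["selfing_fraction"] == 0.0
        assert truth.recording_errors == ()

    def test_full_sib_proportion_raises_within_family_relatedness(self, small_trial):
        cfg, ped, truth, gm, ds = small_trial
        s = realized_summary(truth, gm)
        assert s["within_family_mean"] > 0.26

    def test_all_selfed(self):
        cfg = SimConfig(n_families=10, n_provenances=2, n_markers=50, seed=3,
                        selfing_rate=1.0, full_sib_proportion=0.0,
                        pedigree_error_rate=0.0, provenance_relatedness=0.0)
        _, truth, gm, _ = simulate_population(cfg)
        A_true = build_A(truth.true_pedigree)
        f = {i: A_true.loc(i, i) - 1.0 for i in truth.offspring}
        assert all(v == pytest.approx(0.5) for v in f.values())
        assert realized_summary(truth, gm)["selfing_fraction"] == 1.0

    def test_provenance_relatedness_among_mothers(self):
        cfg = SimConfig(n_families=60, n_provenances=6, n_markers=50, seed=4,
                        provenance_relatedness=0.1, full_sib_proportion=0.0,
                        selfing_rate=0.0, pedigree_error_rate=0.0)
        _, truth, _, _ = simulate_population(cfg)
        A_true = build_A(truth.true_pedigree)
        same, diff = [], []
        mothers = list(truth.mothers)
        for i in range(len(mothers)):
            for j in range(i + 1, len(mothers)):
                a = A_true.loc(mothers[i], mothers[j])
                if truth.provenance_of_mother[mothers[i]] == \
                        truth.provenance_of_mother[mothers[j]]:
                    same.append(a)
                else:
                    diff.append(a)
        assert np.mean(same) == pytest.approx(0.1, abs=0.05)
        assert np.mean(diff) == 0.0


class TestGenetics:
    def test_founder_genotypes_in_hardy_weinberg(self, null_trial):
        """Chi-square HWE screen across founder markers at alpha=0.001:
        rejections should stay near the nominal rate."""
        cfg, ped, truth, gm, ds = null_trial
        scores = truth.founder_genotypes.scores
        n = scores.shape[0]
        rejected = 0
        tested = 0
        for j in range(scores.shape[1]):
            col = scores[:, j]
            p = col.mean() / 2.0
            if p in (0.0, 1.0):
                continue
            exp = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
            obs = np.array([(col == 0).sum(), (col == 1).sum(), (col == 2).sum()])
            if exp.min() < 1:
                continue
            chi2 = ((obs - exp) ** 2 / exp).sum()
            tested += 1
            if chi2 > sps.chi2.ppf(1 - 0.001, 1):
                rejected += 1
        assert tested > 200
        assert rejected / tested < 0.01

    def test_realized_h2_near_target(self):
        cfg = SimConfig(n_families=120, n_provenances=12, n_markers=600, seed=9)
        _, truth, gm, _ = simulate_population(cfg)
        s = realized_summary(truth, gm)
        assert s["realized_h2"]["HT"] == pytest.approx(0.3, abs=0.06)
        assert s["realized_h2"]["WD"] == pytest.approx(0.6, abs=0.06)

    def test_marker_mode_bv_tracks_genotypes(self, small_trial):
        """In the marker generative mode the stored effects reproduce the
        breeding values exactly from the centered dosages."""
        cfg, ped, truth, gm, ds = small_trial
        z = gm.scores - 2.0 * truth.founder_freqs[None, :]
        bv = z @ truth.marker_effects
        stored = truth.true_bv.loc[list(truth.offspring)].to_numpy()
        assert np.abs(bv - stored).max() < 1e-10

    def test_pedigree_mode_bv_covariance(self):
        """Pedigree mode: empirical covariance of replicate founder/offspring
        draws matches the target additive structure."""
        cfg = SimConfig(n_families=6, n_provenances=2, n_markers=30, seed=0,
                        genetic_mode="pedigree", full_sib_proportion=0.0,
                        selfing_rate=0.0, pedigree_error_rate=0.0,
                        provenance_relatedness=0.0)
        bvs = []
        for seed in range(150):
            c = SimConfig(**{**cfg.__dict__, "seed": seed})
            _, truth, _, _ = simulate_population(c)
            bvs.append(truth.true_bv.loc[list(truth.offspring)].to_numpy()[0])
        bvs = np.array(bvs)
        cov = np.cov(bvs.T)
        assert cov[0, 0] == pytest.approx(0.3, abs=0.1)
        assert cov[1, 1] == pytest.approx(0.6, abs=0.15)
        assert abs(cov[0, 1]) < 0.1
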