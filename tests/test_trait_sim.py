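"""Population and trait simulator."""

import numpy as np
import pytest

from menet.trait_sim import (EnvProfile, PopulationSpec, TraitArchitecture,
                             correlated_env_profiles, simulate_genotypes,
                             simulate_trait)


class TestSimulateGenotypes:
    def test_seeded_determinism(self):
        spec = PopulationSpec(n_samples=50, n_markers=40, seed=5)
        a, la = simulate_genotypes(spec)
        b, lb = simulate_genotypes(spec)
        np.testing.assert_array_equal(a.codes, b.codes)
        np.testing.assert_array_equal(la, lb)

    def test_codes_domain_and_labels_partition(self):
        spec = PopulationSpec(n_samples=120, n_markers=60, n_populations=3,
                              seed=6)
        gm, labels = simulate_genotypes(spec)
        assert set(np.unique(gm.codes)) <= {-1.0, 0.0, 1.0}
        assert labels.shape == (120,)
        assert set(np.unique(labels)) == {0, 1, 2}

    def test_binomial_maf_at_half(self):
        # ld_block_size=1 draws alleles i.i.d., so the empirical frequency is
        # binomial: check markers sit within 3 standard errors of 0.5.
        n = 5000
        spec = PopulationSpec(n_samples=n, n_markers=50, n_populations=1,
                              divergence=0.0, ld_block_size=1, base_maf=0.5,
                              seed=7)
        gm, _ = simulate_genotypes(spec)
        freq = (gm.codes.mean(axis=0) + 1.0) / 2.0
        se = np.sqrt(0.25 / n)
        frac_ok = np.mean(np.abs(freq - 0.5) <= 3 * se)
        assert frac_ok >= 0.95

    def test_ld_within_blocks_exceeds_between(self):
        spec = PopulationSpec(n_samples=800, n_markers=40, n_populations=1,
                              ld_block_size=10, founder_pool=4, seed=8)
        gm, _ = simulate_genotypes(spec)
        C = np.corrcoef(gm.codes.T) ** 2
        within, between = [], []
        for i in range(40):
            for j in range(i + 1, 40):
                (within if i // 10 == j // 10 else between).append(C[i, j])
        assert np.mean(within) > 5 * np.mean(between)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            PopulationSpec(n_samples=2, n_populations=5)
        with pytest.raises(ValueError):
            PopulationSpec(n_markers=5, ld_block_size=10)


class TestSimulateTrait:
    def test_zero_noise_limit_matches_genetic_score(self, small_panel):
        gm, labels, _ = small_panel
        arch = TraitArchitecture(intercept=2.0,
                                 additive_effects={0: 1.5, 3: -0.5},
                                 target_h2=1.0, seed=1)
        phenos = simulate_trait(gm, None, arch)
        y = phenos.values_for(gm.samples)
        expected = 2.0 + 1.5 * gm.codes[:, 0] - 0.5 * gm.codes[:, 3]
        np.testing.assert_allclose(y, expected)

    def test_additive_dot_product_oracle(self):
        codes = np.array([[1, -1, 0, 1], [0, 0, 1, -1], [1, 1, 1, 1],
                          [-1, 0, -1, 0], [0, -1, 1, 1]], dtype=float)
        from menet.genotype_io import GenotypeMatrix, MarkerMeta
        gm = GenotypeMatrix(samples=list("abcde"),
                            markers=[MarkerMeta(f"m{i}", "1", i * 10)
                                     for i in range(4)],
                            codes=codes, encoded=True)
        beta = {0: 0.1, 1: 0.2, 2: -0.3, 3: 0.05}
        arch = TraitArchitecture(intercept=0.0, additive_effects=beta,
                                 target_h2=1.0, seed=0)
        y = simulate_trait(gm, None, arch).values_for(gm.samples)
        oracle = codes @ np.array([0.1, 0.2, -0.3, 0.05])
        np.testing.assert_allclose(y, oracle)

    def test_epistatic_term_is_product_coded(self):
        codes = np.array([[1.0, 1.0], [1.0, -1.0], [-1.0, -1.0], [0.0, 1.0]])
        from menet.genotype_io import GenotypeMatrix, MarkerMeta
        gm = GenotypeMatrix(samples=list("abcd"),
                            markers=[MarkerMeta("m0", "1", 0),
                                     MarkerMeta("m1", "1", 10)],
                            codes=codes, encoded=True)
        arch = TraitArchitecture(epistatic_pairs={(0, 1): 2.0},
                                 target_h2=1.0, seed=0)
        y = simulate_trait(gm, None, arch).values_for(gm.samples)
        np.testing.assert_allclose(y, 2.0 * codes[:, 0] * codes[:, 1])

    def test_zero_theta_pair_leaves_trait_unchanged(self, small_panel):
        gm, labels, _ = small_panel
        base = TraitArchitecture(additive_effects={1: 0.7}, target_h2=0.5,
                                 seed=3)
        plus = TraitArchitecture(additive_effects={1: 0.7},
                                 epistatic_pairs={(2, 5): 0.0},
                                 target_h2=0.5, seed=3)
        ya = simulate_trait(gm, labels, base).values_for(gm.samples)
        yb = simulate_trait(gm, labels, plus).values_for(gm.samples)
        np.testing.assert_array_equal(ya, yb)

    def test_heritability_calibration(self):
        spec = PopulationSpec(n_samples=5000, n_markers=100, seed=9)
        gm, labels = simulate_genotypes(spec)
        arch = TraitArchitecture(
            additive_effects={i: 0.3 for i in range(0, 100, 5)},
            target_h2=0.5, seed=10)
        y = simulate_trait(gm, labels, arch).values_for(gm.samples)
        noiseless = TraitArchitecture(
            additive_effects=arch.additive_effects, target_h2=1.0, seed=10)
        g = simulate_trait(gm, labels, noiseless).values_for(gm.samples)
        h2 = np.var(g) / np.var(y)
        assert 0.45 <= h2 <= 0.55

    def test_family_effect_constant_within_family(self, small_panel):
        gm, labels, _ = small_panel
        arch = TraitArchitecture(family_variance=3.0, target_h2=1.0, seed=4)
        y = simulate_trait(gm, labels, arch).values_for(gm.samples)
        for fam in np.unique(labels):
            assert np.ptp(y[labels == fam]) == 0.0
        assert np.ptp(y) > 0.0

    def test_identical_env_profiles_perfectly_correlated(self, small_panel):
        gm, labels, _ = small_panel
        profiles = [EnvProfile("E1"), EnvProfile("E2")]
        arch = TraitArchitecture(additive_effects={0: 1.0, 7: -2.0},
                                 env_profiles=profiles, target_h2=1.0, seed=5)
        tab = simulate_trait(gm, None, arch)
        y1 = tab.values_for(gm.samples, "E1")
        y2 = tab.values_for(gm.samples, "E2")
        assert abs(np.corrcoef(y1, y2)[0, 1] - 1.0) < 1e-12

    def test_correlated_profiles_hit_target_rho(self):
        spec = PopulationSpec(n_samples=3000, n_markers=300, seed=11)
        gm, labels = simulate_genotypes(spec)
        profiles = correlated_env_profiles(300, rho=0.7, seed=12)
        arch = TraitArchitecture(
            additive_effects={i: 0.2 for i in range(300)},
            env_profiles=profiles, target_h2=1.0, seed=13)
        tab = simulate_trait(gm, labels, arch)
        r = np.corrcoef(tab.values_for(gm.samples, "E1"),
                        tab.values_for(gm.samples, "E2"))[0, 1]
        assert 0.55 < r < 0.85

    def test_out_of_range_index_errors(self, small_panel):
        gm, labels, _ = small_panel
        arch = TraitArchitecture(additive_effects={10_000: 1.0}, seed=0)
        with pytest.raises(IndexError):
            simulate_trait(gm, labels, arch)
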