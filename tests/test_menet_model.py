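"""Dual-branch network architecture: VE branch, fusion, head, partitioning."""

import numpy as np
import pytest

import menet
from menet import _nn
from menet.genotype_io import GenotypeMatrix, MarkerMeta
from menet.menet_model import (CrossFusion, MeNetNetwork, ModelConfig,
                               PredictionHead, VENetwork, chromosome_partition)


def _gm(n, p, per_chrom=None):
    per_chrom = per_chrom or p
    markers = [MarkerMeta(f"m{i}", str(i // per_chrom + 1),
                          (i % per_chrom) * 100) for i in range(p)]
    rng = np.random.default_rng(p + n)
    codes = rng.choice([-1.0, 0.0, 1.0], size=(n, p))
    return GenotypeMatrix(samples=[f"s{i}" for i in range(n)], markers=markers,
                          codes=codes, encoded=True)


class TestVENetwork:
    def test_output_dim_independent_of_marker_count(self, rng):
        cfg = ModelConfig(ve_channels=2, embed_dim=16, pool_len=8)
        for p in (1000, 3000):
            net = VENetwork(p, cfg, np.random.default_rng(0))
            out = net.forward(rng.choice([-1.0, 0.0, 1.0], size=(4, p)))
            assert out.shape == (4, 16)

    def test_sample_permutation_equivariance(self, rng):
        cfg = ModelConfig(ve_channels=2, embed_dim=8, pool_len=8)
        net = VENetwork(50, cfg, np.random.default_rng(1))
        X = rng.choice([-1.0, 0.0, 1.0], size=(6, 50))
        perm = rng.permutation(6)
        np.testing.assert_allclose(net.forward(X[perm]),
                                   net.forward(X)[perm], atol=1e-12)

    def test_deterministic_forward(self, rng):
        cfg = ModelConfig(ve_channels=2, embed_dim=8, pool_len=4)
        net = VENetwork(30, cfg, np.random.default_rng(2))
        X = rng.choice([-1.0, 0.0, 1.0], size=(3, 30))
        np.testing.assert_array_equal(net.forward(X), net.forward(X))

    def test_short_segment_padded_with_warning(self):
        cfg = ModelConfig(ve_channels=2, embed_dim=8, pool_len=4)
        with pytest.warns(UserWarning, match="zero-padded"):
            net = VENetwork(2, cfg, np.random.default_rng(3))
        out = net.forward(np.array([[1.0, -1.0]]))
        assert out.shape == (1, 8)


class TestCrossFusion:
    def test_zero_initialized_corrections_are_identity(self, rng):
        fus = CrossFusion(8, np.random.default_rng(4))
        z = rng.normal(size=(5, 16))
        np.testing.assert_array_equal(fus.forward(z), z)

    def test_linear_toy_matches_hand_matrix_algebra(self):
        # strip the nonlinearity: replace each bottleneck with one linear map
        fus = CrossFusion(3, np.random.default_rng(5))
        rng = np.random.default_rng(6)
        W = rng.normal(size=(6, 3))
        fus.f_ve = _nn.Sequential(_nn.Dense(6, 3, rng))
        fus.f_repgeno = _nn.Sequential(_nn.Dense(6, 3, rng))
        fus.f_ve.layers[0].W.value[...] = W
        fus.f_ve.layers[0].b.value[...] = 0.0
        fus.f_repgeno.layers[0].W.value[...] = 2 * W
        fus.f_repgeno.layers[0].b.value[...] = 0.0
        z = rng.normal(size=(1, 6))
        out = fus.forward(z)
        expected = np.concatenate([z[:, :3] + z @ W, z[:, 3:] + z @ (2 * W)],
                                  axis=1)
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_shapes_preserved(self, rng):
        for e in (4, 16):
            fus = CrossFusion(e, np.random.default_rng(e))
            z = rng.normal(size=(7, 2 * e))
            assert fus.forward(z).shape == (7, 2 * e)

    def test_dimension_mismatch_raises(self, rng):
        fus = CrossFusion(8, np.random.default_rng(7))
        with pytest.raises(ValueError, match="fusion input width"):
            fus.forward(rng.normal(size=(2, 10)))


class TestPredictionHead:
    def test_zeroed_weights_give_constant_bias(self, rng):
        head = PredictionHead(4, (8, 4), np.random.default_rng(8))
        for _, p in head.params():
            p.value[...] = 0.0
        head.net.layers[-1].b.value[...] = 3.25
        out = head.forward(rng.normal(size=(6, 8)))
        np.testing.assert_allclose(out, 3.25)

    def test_batch_shape_and_determinism(self, rng):
        head = PredictionHead(4, (8, 4), np.random.default_rng(9))
        z = rng.normal(size=(11, 8))
        out = head.forward(z)
        assert out.shape == (11,)
        np.testing.assert_array_equal(out, head.forward(z))


class TestChromosomePartition:
    def test_single_segment_below_threshold(self):
        G = _gm(4, 500)
        segs = chromosome_partition(G, threshold=100_000)
        assert len(segs) == 1 and segs[0].size == 500

    def test_per_chromosome_partition_is_disjoint_cover(self):
        G = _gm(4, 300, per_chrom=100)  # 3 chromosomes
        segs = chromosome_partition(G, threshold=200)
        assert len(segs) == 3
        merged = np.sort(np.concatenate(segs))
        np.testing.assert_array_equal(merged, np.arange(300))

    def test_oversized_chromosome_splits_into_windows(self):
        G = _gm(2, 150, per_chrom=150)
        segs = chromosome_partition(G, threshold=100)
        assert len(segs) >= 2
        merged = np.sort(np.concatenate(segs))
        np.testing.assert_array_equal(merged, np.arange(150))


class TestMeNetNetwork:
    def _net(self, G, seed=0, threshold=100_000, train_encoder=False):
        enc = menet.RepGenoEncoder(
            G.n_markers, menet.TripletConfig(embed_dim=8, hidden_dim=16),
            seed=seed)
        cfg = ModelConfig(ve_channels=2, embed_dim=8, pool_len=8,
                          head_hidden=(8, 4), window_threshold=threshold)
        return MeNetNetwork(G, enc, cfg, seed=seed,
                            train_encoder=train_encoder)

    def test_forward_deterministic(self):
        G = _gm(6, 40)
        net = self._net(G)
        np.testing.assert_array_equal(net.forward(G.codes),
                                      net.forward(G.codes))

    def test_branch_ablations_run(self):
        G = _gm(6, 40)
        net = self._net(G)
        pair = net.branch_embeddings(G.codes)
        # RepGeno ablated -> pure CNN regressor path
        z = np.concatenate([pair.z_ve, np.zeros_like(pair.z_repgeno)], axis=1)
        out_cnn = net.head.forward(net.fusion.forward(z))
        # VE ablated -> relatedness-only regression path
        z = np.concatenate([np.zeros_like(pair.z_ve), pair.z_repgeno], axis=1)
        out_rel = net.head.forward(net.fusion.forward(z))
        assert out_cnn.shape == out_rel.shape == (6,)

    def test_partitioned_and_single_models_same_output_dim(self):
        G = _gm(5, 90, per_chrom=30)
        single = self._net(G, threshold=1000)
        multi = self._net(G, threshold=50)
        assert len(multi.segments) == 3
        assert single.forward(G.codes).shape == multi.forward(G.codes).shape

    def test_mismatched_embed_dims_rejected(self):
        G = _gm(4, 30)
        enc = menet.RepGenoEncoder(30, menet.TripletConfig(embed_dim=16),
                                   seed=0)
        with pytest.raises(ValueError, match="share embed_dim"):
            MeNetNetwork(G, enc, ModelConfig(embed_dim=8))

    def test_gradients_match_finite_differences(self):
        """End-to-end backprop check against central differences."""
        G = _gm(5, 20)
        net = self._net(G, seed=3, train_encoder=True)
        rng = np.random.default_rng(4)
        # move off the zero-init kinks so the loss is locally smooth
        for _, p in net.params():
            p.value += rng.normal(0, 0.05, size=p.value.shape)
        X = G.codes
        y = rng.normal(size=5)

        def loss():
            return float(np.abs(net.forward(X) - y).mean())

        net.forward(X)
        for _, p in net.params():
            p.zero_grad()
        net.backward(np.sign(net.forward(X) - y) / 5)
        checked = 0
        for name, p in net.params():
            flat = p.value.ravel()
            for k in rng.choice(flat.size, size=min(3, flat.size),
                                replace=False):
                h = 1e-6
                orig = flat[k]
                flat[k] = orig + h
                lp = loss()
                flat[k] = orig - h
                lm = loss()
                flat[k] = orig
                num = (lp - lm) / (2 * h)
                ana = p.grad.ravel()[k]
                assert abs(num - ana) <= 1e-5 * max(1.0, abs(num)), name
                checked += 1
        assert checked > 30
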