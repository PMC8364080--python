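"""Network engine and architecture: gradients, invariances, parameter counts."""

from __future__ import annotations

import numpy as np
import pytest

from allelecall.model import (
    ConfigurationError,
    HybridModel,
    ModelSpec,
    SinglePlatformModel,
    load_checkpoint,
    save_checkpoint,
    site_feature,
    superpose,
)
from allelecall.nnet import Adam, WNConv1d, count_parameters
from allelecall.training import site_loss

TINY = ModelSpec(
    in_channels=6, entry_channels=4, width=8, stage1_pairs=1, stage2_pairs=1,
    stage3_pairs=1, head_hidden=6, window=40,
)


@pytest.fixture
def tiny_model():
    return SinglePlatformModel(TINY, seed=3)


def random_encodings(n, channels=6, window=40, seed=0):
    rng = np.random.default_rng(seed)
    return rng.integers(0, 255, size=(n, channels, window)).astype(np.uint8)


class TestEngine:
    def test_weight_normalized_conv_parameter_count(self):
        conv = WNConv1d(6, 8, 3, np.random.default_rng(0))
        params = conv.parameters()
        # dense weight + bias = 6*8*3 + 8; the gain adds one scalar per filter
        assert params["v"].value.size + params["b"].value.size == 6 * 8 * 3 + 8 == 152
        assert count_parameters(conv) == 152 + 8

    def test_site_pass_gradients_match_finite_differences(self, tiny_model):
        enc = random_encodings(5)
        supports = [[0, 1, 2], [3, 4]]
        labels = [True, False]
        p = tiny_model.site_forward(enc, supports)
        _, dlogit = site_loss(p, labels)
        tiny_model.site_backward(dlogit)
        params = tiny_model.parameters()
        rng = np.random.default_rng(1)
        eps = 1e-6
        for name in rng.choice(sorted(params), size=6, replace=False):
            par = params[name]
            idx = int(rng.integers(par.value.size))
            orig = par.value.ravel()[idx]
            par.value.ravel()[idx] = orig + eps
            lp = site_loss(tiny_model.site_forward(enc, supports), labels)[0]
            par.value.ravel()[idx] = orig - eps
            lm = site_loss(tiny_model.site_forward(enc, supports), labels)[0]
            par.value.ravel()[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert par.grad.ravel()[idx] == pytest.approx(num, rel=1e-4, abs=1e-8)

    def test_adam_reduces_loss_on_an_overfit_batch(self, tiny_model):
        enc = random_encodings(6, seed=5)
        supports = [[0, 1], [2, 3], [4, 5]]
        labels = [True, False, True]
        opt = Adam(tiny_model.parameters(), lr=1e-2)
        losses = []
        for _ in range(100):
            opt.zero_grad()
            p = tiny_model.site_forward(enc, supports)
            loss, dlogit = site_loss(p, labels)
            tiny_model.site_backward(dlogit)
            opt.step()
            losses.append(loss)
        assert losses[-1] < 0.1 * losses[0]


class TestStageOperations:
    def test_read_cnn_is_deterministic_and_batch_consistent(self, tiny_model):
        enc = random_encodings(4, seed=9)
        batched = tiny_model.read_cnn(enc)
        looped = np.stack([tiny_model.read_cnn(e) for e in enc])
        np.testing.assert_allclose(batched, looped, atol=1e-5)
        np.testing.assert_array_equal(batched, tiny_model.read_cnn(enc))

    def test_all_pad_encoding_yields_finite_features(self, tiny_model):
        enc = np.zeros((1, 6, 40), dtype=np.uint8)
        assert np.all(np.isfinite(tiny_model.read_cnn(enc)))

    def test_channel_mismatch_is_a_configuration_error(self, tiny_model):
        with pytest.raises(ConfigurationError):
            tiny_model.read_cnn(random_encodings(2, channels=7))

    def test_superpose_identities(self):
        rng = np.random.default_rng(4)
        f = rng.normal(size=(8, 40))
        np.testing.assert_allclose(superpose([f, f]), 2 * f)
        np.testing.assert_allclose(superpose([f]), f)
        parts = [rng.normal(size=(8, 40)) for _ in range(5)]
        shuffled = [parts[i] for i in [3, 1, 4, 0, 2]]
        np.testing.assert_allclose(superpose(parts), superpose(shuffled), atol=1e-6)
        with pytest.raises(ValueError):
            superpose([])

    def test_site_feature_minus_one_allele_is_the_others_sum(self):
        rng = np.random.default_rng(5)
        alleles = [rng.normal(size=(8, 40)) for _ in range(4)]
        M = site_feature(alleles)
        for j in range(4):
            others = [a for i, a in enumerate(alleles) if i != j]
            np.testing.assert_allclose(M - alleles[j], site_feature(others), atol=1e-9)

    def test_comparison_input_identity(self, tiny_model):
        # CNN3(A_j - sum_{k!=j} A_k) == CNN3(2A_j - M): two spellings, one input
        from allelecall.nnet import sigmoid

        rng = np.random.default_rng(6)
        alleles = [rng.normal(size=(8, 40)) for _ in range(3)]
        M = site_feature(alleles)
        for j in range(3):
            others = site_feature([a for i, a in enumerate(alleles) if i != j])
            p_subtractive = float(
                sigmoid(tiny_model.cnn3.forward((alleles[j] - others)[None]))[0, 0]
            )
            p_pooled = tiny_model.compare_allele(alleles[j], M)
            assert p_subtractive == pytest.approx(p_pooled, abs=1e-6)

    def test_single_candidate_comparison_reduces_to_its_own_feature(self, tiny_model):
        rng = np.random.default_rng(8)
        a = rng.normal(size=(8, 40))
        p_single = tiny_model.compare_allele(a, a)  # M = A_1 when n = 1
        from allelecall.nnet import sigmoid

        logit = tiny_model.cnn3.forward(a[None])
        assert p_single == pytest.approx(float(sigmoid(logit)[0, 0]), abs=1e-9)

    def test_stage3_runs_exactly_once_per_candidate(self, tiny_model):
        enc = random_encodings(10, seed=11)
        supports = [[0, 1], [2, 3], [4, 5], [6, 7], [8, 9]]
        before = tiny_model.stage3_invocations
        tiny_model.site_forward(enc, supports)
        assert tiny_model.stage3_invocations - before == 5

    def test_probabilities_invariant_to_read_order_within_supports(self, tiny_model):
        enc = random_encodings(8, seed=12)
        p1 = tiny_model.site_forward(enc, [[0, 1, 2, 3], [4, 5, 6, 7]])
        p2 = tiny_model.site_forward(enc, [[3, 0, 2, 1], [7, 6, 5, 4]])
        np.testing.assert_allclose(p1, p2, atol=1e-5)

    def test_duplicating_every_read_doubles_stage_two_input(self, tiny_model):
        enc = random_encodings(3, seed=13)
        f = tiny_model.read_cnn(enc)
        once = superpose([f[0], f[1], f[2]])
        twice = superpose([f[0], f[1], f[2]] * 2)
        np.testing.assert_allclose(twice, 2 * once, atol=1e-9)


class TestParameterCounts:
    def test_haplotag_channel_gap_is_exactly_the_first_layer_weights(self):
        short = SinglePlatformModel(ModelSpec(in_channels=6), seed=0)
        tagged = SinglePlatformModel(ModelSpec(in_channels=7), seed=0)
        spec = short.spec
        assert (
            tagged.count_parameters() - short.count_parameters()
            == spec.entry_channels * spec.kernel
            == 48
        )

    def test_counts_are_pure_functions_of_the_spec(self):
        a = SinglePlatformModel(ModelSpec(in_channels=6), seed=0).count_parameters()
        b = SinglePlatformModel(ModelSpec(in_channels=6), seed=99).count_parameters()
        assert a == b

    def test_fusion_networks_are_two_layer(self):
        hybrid = HybridModel(ModelSpec(in_channels=6), ModelSpec(in_channels=7), seed=0)
        for fusion in (hybrid.fuse_allele_net, hybrid.fuse_site_net):
            convs = [l for l in fusion.net.layers if hasattr(l, "kernel")]
            assert len(convs) == 2

    def test_hybrid_reuses_tower_and_head_sizes(self):
        s6 = SinglePlatformModel(ModelSpec(in_channels=6), seed=0)
        s7 = SinglePlatformModel(ModelSpec(in_channels=7), seed=0)
        hybrid = HybridModel(ModelSpec(in_channels=6), ModelSpec(in_channels=7), seed=0)
        towers = (
            s6.count_parameters()
            + s7.count_parameters()
            - sum(p.value.size for p in s6.cnn3.parameters().values())
            - sum(p.value.size for p in s7.cnn3.parameters().values())
        )
        fusion = sum(
            p.value.size
            for net in (hybrid.fuse_allele_net.net, hybrid.fuse_site_net.net)
            for p in net.parameters().values()
        )
        head = sum(p.value.size for p in hybrid.cnn3.parameters().values())
        assert hybrid.count_parameters() == towers + fusion + head


class TestHybridModel:
    def make(self):
        spec_a = TINY
        spec_b = ModelSpec(**{**spec_a.__dict__, "in_channels": 7})
        return HybridModel(spec_a, spec_b, seed=2)

    def test_fusion_preserves_single_platform_feature_shape(self):
        hybrid = self.make()
        rng = np.random.default_rng(1)
        a = rng.normal(size=(8, 40))
        b = rng.normal(size=(8, 40))
        assert hybrid.fuse_allele(a, b).shape == a.shape
        assert hybrid.fuse_site(a, b).shape == a.shape

    def test_single_platform_candidate_gets_a_zero_feature(self):
        hybrid = self.make()
        enc_a = random_encodings(2, 6, seed=3)
        enc_b = random_encodings(2, 7, seed=4)
        p = hybrid.site_forward(enc_a, [[0, 1], []], enc_b, [[], [0, 1]])
        assert p.shape == (2,) and np.all(np.isfinite(p)) and np.all((p > 0) & (p < 1))

    def test_read_order_permutation_leaves_probabilities_unchanged(self):
        hybrid = self.make()
        enc_a = random_encodings(4, 6, seed=5)
        enc_b = random_encodings(4, 7, seed=6)
        p1 = hybrid.site_forward(enc_a, [[0, 1], [2, 3]], enc_b, [[0, 1], [2, 3]])
        p2 = hybrid.site_forward(enc_a, [[1, 0], [3, 2]], enc_b, [[1, 0], [3, 2]])
        np.testing.assert_allclose(p1, p2, atol=1e-5)

    def test_empty_site_is_an_error(self):
        hybrid = self.make()
        empty6 = np.zeros((0, 6, 40), dtype=np.uint8)
        empty7 = np.zeros((0, 7, 40), dtype=np.uint8)
        with pytest.raises(ValueError):
            hybrid.site_forward(empty6, [[]], empty7, [[]])


class TestCheckpoints:
    def test_roundtrip_reproduces_outputs_and_metadata(self, tmp_path, tiny_model):
        enc = random_encodings(4, seed=20)
        supports = [[0, 1], [2, 3]]
        p_before = tiny_model.site_forward(enc, supports)
        path = str(tmp_path / "model.npz")
        save_checkpoint(path, tiny_model, metadata={"seed": 3, "epoch": 1})
        loaded, meta = load_checkpoint(path)
        assert meta == {"seed": 3, "epoch": 1}
        np.testing.assert_allclose(loaded.site_forward(enc, supports), p_before, atol=1e-12)

    def test_hybrid_roundtrip(self, tmp_path):
        spec_b = ModelSpec(**{**TINY.__dict__, "in_channels": 7})
        hybrid = HybridModel(TINY, spec_b, seed=5)
        enc_a = random_encodings(2, 6, seed=7)
        enc_b = random_encodings(2, 7, seed=8)
        p_before = hybrid.site_forward(enc_a, [[0], [1]], enc_b, [[0], [1]])
        path = str(tmp_path / "hybrid.npz")
        save_checkpoint(path, hybrid)
        loaded, _ = load_checkpoint(path)
        np.testing.assert_allclose(
            loaded.site_forward(enc_a, [[0], [1]], enc_b, [[0], [1]]), p_before
        )
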