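import numpy as np
import pytest

from liverseg import nn
from liverseg.network import ClassScoreMap, NetworkConfig, build_network, forward
from liverseg.sampling import SliceStack


def tiny_cfg(**kw):
    defaults = dict(variant="net01", in_planes=3, base_channels=4, depth=2, rng_seed=0)
    defaults.update(kw)
    return NetworkConfig(**defaults)


def random_stack(rng, k=3, size=16):
    return SliceStack(planes=rng.uniform(0, 255, (k, size, size)), center_index_in_volume=0, k=k)


class TestGradients:
    """Analytic gradients of the layer library against central differences."""

    def test_composite_network_gradients_match_numeric(self):
        rng = np.random.default_rng(0)
        x0 = rng.normal(size=(2, 2, 4, 4))
        conv = nn.Conv2d(2, 3, 3, rng)
        bn = nn.BatchNorm2d(3)
        head = nn.Conv2d(3, 3, 1, rng, bias=True)
        target = rng.integers(0, 3, size=(2, 4, 4))
        weights = np.array([1.0, 2.0, 0.5])

        def run():
            xt = nn.Tensor(x0)
            h = nn.relu(bn(conv(xt), training=True))
            pooled, idx = nn.max_pool2x2(h)
            up = nn.max_unpool2x2(pooled, idx)
            up = nn.add(up, h)
            return xt, nn.weighted_cross_entropy(head(up), target, weights)

        xt, loss = run()
        loss.backward()

        def numgrad(arr):
            g = np.zeros_like(arr)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                arr[i] += 1e-6
                fp = run()[1].data.item()
                arr[i] -= 2e-6
                fm = run()[1].data.item()
                arr[i] += 1e-6
                g[i] = (fp - fm) / 2e-6
            return g

        for arr, grad in [(x0, xt.grad), (conv.W, conv.Wt.grad), (bn.gamma, bn.gt.grad), (head.b, head.bt.grad)]:
            num = numgrad(arr)
            assert np.abs(num - grad).max() / (np.abs(num).max() + 1e-12) < 1e-6


class TestLossClosedForms:
    def test_uniform_probabilities_give_log3_per_pixel(self):
        scores = nn.Tensor(np.zeros((1, 3, 4, 4)))
        loss = nn.weighted_cross_entropy(scores, np.zeros((1, 4, 4), dtype=int), np.ones(3))
        assert loss.data == pytest.approx(np.log(3))

    def test_confident_correct_prediction_loss_near_zero(self):
        scores = np.full((1, 3, 4, 4), -50.0)
        scores[0, 1] = 50.0
        loss = nn.weighted_cross_entropy(
            nn.Tensor(scores), np.ones((1, 4, 4), dtype=int), np.ones(3)
        )
        assert loss.data == pytest.approx(0.0, abs=1e-9)

    def test_loss_linear_in_class_weight(self, rng):
        scores = nn.Tensor(rng.normal(size=(1, 3, 4, 4)))
        target = np.full((1, 4, 4), 2)  # tumor-only image
        w1 = np.array([1.0, 1.0, 1.0])
        w2 = np.array([1.0, 1.0, 2.0])
        l1 = nn.weighted_cross_entropy(scores, target, w1).data
        l2 = nn.weighted_cross_entropy(scores, target, w2).data
        assert l2 == pytest.approx(2 * l1)


class TestArchitectureContracts:
    @pytest.mark.parametrize("variant", ["net01", "net02"])
    @pytest.mark.parametrize("k", [1, 3, 5])
    def test_shape_contract_and_probability_normalization(self, variant, k, rng):
        net = build_network(tiny_cfg(variant=variant, in_planes=k))
        score_map = forward(net, random_stack(rng, k=k))
        assert isinstance(score_map, ClassScoreMap)
        assert score_map.scores.shape == (3, 16, 16)
        np.testing.assert_allclose(score_map.probabilities.sum(axis=0), 1.0, atol=1e-5)
        assert np.all(score_map.probabilities >= 0)

    def test_net02_has_strictly_more_parameters(self):
        n1 = build_network(tiny_cfg(variant="net01")).num_parameters()
        n2 = build_network(tiny_cfg(variant="net02")).num_parameters()
        assert n2 > n1

    def test_same_seed_gives_identical_initial_weights(self):
        a = build_network(tiny_cfg(rng_seed=42))
        b = build_network(tiny_cfg(rng_seed=42))
        for pa, pb in zip(a.parameter_arrays(), b.parameter_arrays()):
            np.testing.assert_array_equal(pa, pb)

    def test_forward_deterministic_in_eval_mode(self, rng):
        net = build_network(tiny_cfg())
        stack = random_stack(rng)
        a = forward(net, stack).scores
        b = forward(net, stack).scores
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("short,long", [(False, True), (True, False), (False, False)])
    def test_ablation_switches_preserve_shape_contract(self, short, long, rng):
        net = build_network(tiny_cfg(use_short_skips=short, use_long_skips=long))
        score_map = forward(net, random_stack(rng))
        assert score_map.scores.shape == (3, 16, 16)

    def test_constant_input_yields_constant_interior_probabilities(self):
        # translation equivariance: away from padded borders a constant stack
        # must map to a spatially constant probability map; nearest-neighbor
        # upsampling is the decoder mode free of checkerboard artifacts
        net = build_network(tiny_cfg(base_channels=4, depth=2, upsample_mode="nearest"))
        stack = SliceStack(planes=np.full((3, 32, 32), 127.0), center_index_in_volume=0, k=3)
        probs = forward(net, stack).probabilities
        interior = probs[:, 10:22, 10:22]
        assert interior.var(axis=(1, 2)).max() < 1e-6

    def test_wrong_plane_count_rejected(self, rng):
        net = build_network(tiny_cfg(in_planes=3))
        with pytest.raises(ValueError, match="planes"):
            net.forward_scores(rng.uniform(0, 255, (1, 5, 16, 16)))

    def test_indivisible_spatial_size_rejected(self, rng):
        net = build_network(tiny_cfg(depth=2))
        with pytest.raises(ValueError, match="divisible"):
            net.forward_scores(rng.uniform(0, 255, (1, 3, 18, 18)))

    def test_even_stack_size_rejected(self):
        with pytest.raises(ValueError):
            tiny_cfg(in_planes=4)


class TestGradientFlow:
    @pytest.mark.parametrize("variant", ["net01", "net02"])
    def test_nearly_all_parameters_receive_gradient(self, variant):
        # one training step on a single sample; disconnected branches would
        # leave whole tensors at zero gradient
        net = build_network(
            NetworkConfig(variant=variant, in_planes=3, base_channels=8, depth=3, rng_seed=0)
        )
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 255, size=(1, 3, 64, 64))
        target = rng.integers(0, 3, size=(1, 64, 64))
        scores = net.forward_scores(x, training=True)
        loss = nn.weighted_cross_entropy(scores, target, np.ones(3))
        loss.backward()
        nonzero = total = 0
        for layer in net.layers():
            for owner, name in layer.parameters():
                tensor = getattr(owner, {"W": "Wt", "b": "bt", "gamma": "gt", "beta": "bt"}[name])
                grad = tensor.grad if tensor is not None else None
                arr = getattr(owner, name)
                nonzero += int(np.count_nonzero(grad)) if grad is not None else 0
                total += arr.size
        assert nonzero / total >= 0.99


class TestPersistence:
    def test_checkpoint_round_trip_reproduces_outputs(self, tmp_path, rng):
        net = build_network(tiny_cfg())
        stack = random_stack(rng)
        before = forward(net, stack).scores
        path = tmp_path / "net.ckpt"
        net.save(path)
        from liverseg.network import SegmentationNetwork

        loaded = SegmentationNetwork.load(path)
        np.testing.assert_array_equal(forward(loaded, stack).scores, before)
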