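import numpy as np
import pytest

from tumorkit.errors import ShapeError
from tumorkit.models import (binary_cross_entropy, build_detection_cnn,
                             build_feature_cnn, build_unet2d,
                             build_unet_multimodal, build_unetpp2d,
                             build_unetpp_multimodal, count_parameters,
                             dice_loss, hybrid_loss, infer_shapes)


class TestParameterAudits:
    """The published totals are the machine-checkable ground truth for the
    layer tables; see also the acceptance suite."""

    def test_detection_cnn(self):
        pc = count_parameters(build_detection_cnn())
        assert (pc.total, pc.non_trainable) == (352_609, 0)

    def test_feature_cnn_intensity_input(self):
        assert count_parameters(build_feature_cnn(4)).total == 2_817

    def test_unet2d(self):
        pc = count_parameters(build_unet2d())
        assert (pc.total, pc.non_trainable) == (22_718_529, 1_920)

    def test_unetpp2d(self):
        pc = count_parameters(build_unetpp2d())
        assert (pc.total, pc.trainable, pc.non_trainable) == (
            22_498_881, 22_496_961, 1_920)

    def test_unet_multimodal(self):
        pc = count_parameters(build_unet_multimodal())
        assert (pc.total, pc.non_trainable) == (31_055_873, 11_776)

    def test_param_count_identity(self):
        for build in (build_unet2d, build_unetpp_multimodal):
            pc = count_parameters(build())
            assert pc.total == pc.trainable + pc.non_trainable


class TestShapeTraces:
    def test_detection_table_trace(self):
        shapes = infer_shapes(build_detection_cnn())
        assert shapes["conv1"] == (249, 249, 32)
        assert shapes["pool1"] == (124, 124, 32)
        assert shapes["conv2"] == (117, 117, 64)
        assert shapes["pool2"] == (58, 58, 64)
        assert shapes["flat"] == (215_296,)

    def test_feature_cnn_trace(self):
        shapes = infer_shapes(build_feature_cnn(4))
        assert shapes["conv1"] == (3, 64)
        assert shapes["flat"] == (16,)

    @pytest.mark.parametrize("k", [3, 5, 10, 42])
    def test_feature_conv_length(self, k):
        assert infer_shapes(build_feature_cnn(k))["conv1"] == (k - 1, 64)

    def test_feature_cnn_rejects_single_feature(self):
        with pytest.raises(ShapeError):
            build_feature_cnn(1)

    def test_unet_bottleneck(self):
        shapes = infer_shapes(build_unet2d())
        assert shapes["bridge_b"] == (8, 8, 512)
        assert shapes["out"] == (128, 128, 1)

    def test_unetpp_head_concat_width(self):
        shapes = infer_shapes(build_unetpp2d())
        assert shapes["head_cat"] == (128, 128, 256)
        # the tabulated nested-skip concatenation widths
        assert shapes["cat01"][-1] == 128
        assert shapes["cat02"][-1] == 256
        assert shapes["cat11"][-1] == 256
        assert shapes["cat21"][-1] == 512
        assert shapes["cat12"][-1] == 384
        assert shapes["cat31"][-1] == 768

    def test_multimodal_bridge_and_io(self):
        shapes = infer_shapes(build_unet_multimodal())
        assert shapes["in"] == (128, 128, 4)
        assert shapes["bn_bridge_b"] == (8, 8, 1024)
        assert shapes["out"] == (128, 128, 1)

    def test_multimodal_unetpp_io(self):
        shapes = infer_shapes(build_unetpp_multimodal())
        assert shapes["in"] == (128, 128, 4)
        assert shapes["out"] == (128, 128, 1)

    def test_encoder_batchnorm_channel_bookkeeping(self):
        g = build_unetpp_multimodal()
        shapes = infer_shapes(g)
        bn_channels = sum(shapes[s.inbound[0]][-1]
                          for s in g.layers if s.kind == "batchnorm")
        assert bn_channels == 64 + 128 + 256 + 512
        assert count_parameters(g).non_trainable == 2 * bn_channels


class TestCountParameters:
    def test_single_dense(self):
        from tumorkit.models import _GraphBuilder

        b = _GraphBuilder("d")
        b.add("input", "in", shape=(10,))
        b.add("dense", "out", units=1)
        assert count_parameters(b.graph).total == 11

    def test_single_conv(self):
        from tumorkit.models import _GraphBuilder

        b = _GraphBuilder("c")
        b.add("input", "in", shape=(32, 32, 3))
        b.add("conv", "c1", filters=32, kernel=(8, 8), padding="valid")
        assert count_parameters(b.graph).total == 32 * (64 * 3 + 1) == 6_176

    def test_batchnorm_split(self):
        from tumorkit.models import _GraphBuilder

        b = _GraphBuilder("bn")
        b.add("input", "in", shape=(4, 4, 64))
        b.add("batchnorm", "bn", momentum=0.8)
        pc = count_parameters(b.graph)
        assert (pc.total, pc.non_trainable) == (256, 128)

    @pytest.mark.parametrize("build,args", [
        (build_detection_cnn, ()),
        (build_unet2d, ()),
        (build_unetpp2d, ()),
    ])
    def test_width_multiplier_one_is_identity(self, build, args):
        assert count_parameters(build(*args)) == count_parameters(
            build(*args, 1.0) if args else build(1.0))

    def test_width_multiplier_shrinks(self):
        assert count_parameters(build_unet2d(0.25)).total < \
            count_parameters(build_unet2d()).total / 10


class TestLosses:
    def test_dice_perfect_overlap(self):
        m = np.ones((6, 6))
        assert dice_loss(m, m) == pytest.approx(0.0, abs=1e-12)

    def test_dice_empty_empty_regularized(self):
        z = np.zeros((5, 5))
        assert dice_loss(z, z) == pytest.approx(0.0, abs=1e-12)

    def test_dice_half_mask_formula(self):
        n = 16
        truth = np.zeros(n)
        truth[: n // 2] = 1.0
        pred = np.ones(n)
        expected = 1 - (2 * (n / 2) + 1) / (n + n / 2 + 1)
        assert dice_loss(pred, truth) == pytest.approx(expected, abs=1e-12)

    def test_bce_half_probability_is_ln2(self):
        assert binary_cross_entropy(np.full(10, 0.5), np.ones(10)) == \
            pytest.approx(np.log(2.0), abs=1e-12)

    def test_hybrid_is_equal_weight_sum(self):
        rng = np.random.default_rng(0)
        pred = rng.random((4, 4))
        truth = (rng.random((4, 4)) > 0.5).astype(float)
        assert hybrid_loss(pred, truth) == pytest.approx(
            0.5 * dice_loss(pred, truth) + 0.5 * binary_cross_entropy(pred, truth),
            abs=1e-12)

    def test_perfect_binary_prediction_near_zero(self):
        truth = (np.random.default_rng(1).random((8, 8)) > 0.5).astype(float)
        assert hybrid_loss(truth, truth) <= 1e-5

    def test_shape_mismatch_raises(self):
        with pytest.raises(ShapeError):
            dice_loss(np.zeros((2, 2)), np.zeros((3, 3)))
        with pytest.raises(ShapeError):
            hybrid_loss(np.zeros((2, 2)), np.zeros((3, 3)))


class TestAuditExport:
    def test_json_summary_contains_per_layer_counts(self):
        import json

        g = build_feature_cnn(4)
        payload = json.loads(g.to_json())
        assert payload["name"] == "feature_cnn"
        totals = {row["name"]: row["params"] for row in payload["layers"]}
        assert totals["conv1"] == 192
        assert totals["dense1"] == 2_080
        assert totals["dense2"] == 528
        assert totals["out"] == 17
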