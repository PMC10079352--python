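"""Compound reduction factors, architecture rewriting, and the MAC cost model."""

import math

import numpy as np
import pytest

from patchal.nar import (ALPHA, BETA, GAMMA, ArchError, ArchSpec, LayerBlock,
                         build_trainable, estimate_flops, reduce_arch,
                         reference_cnn, restriction_product, scale_factors,
                         tiny_cnn)


class TestScaleFactors:
    def test_phi_zero_is_identity(self):
        f = scale_factors(0)
        assert (f.d, f.w, f.r) == (1.0, 1.0, 1.0)
        assert f.flops_multiplier == 1.0

    def test_phi_two_power_law(self):
        f = scale_factors(2)
        assert f.d == pytest.approx(1.2 ** -2)
        assert f.w == pytest.approx(1.1 ** -2)
        assert f.r == pytest.approx(1.15 ** -2)

    def test_phi_one_multiplier_is_about_half(self):
        f = scale_factors(1)
        assert f.flops_multiplier == pytest.approx(1 / (1.2 * 1.21 * 1.3225))
        assert round(1 / f.flops_multiplier) == 2

    def test_negative_phi_rejected(self):
        with pytest.raises(ValueError):
            scale_factors(-1)


class TestRestriction:
    def test_published_coefficients_balance_to_two(self):
        v = restriction_product(ALPHA, BETA, GAMMA)
        assert v == pytest.approx(1.2 * 1.21 * 1.3225, abs=1e-12)
        assert round(v) == 2

    @pytest.mark.parametrize("abc,expected", [((2, 1, 1), 2.0), ((1, 1, 1), 1.0)])
    def test_degenerate_cases(self, abc, expected):
        assert restriction_product(*abc) == expected


class TestReduceArch:
    def test_phi_zero_returns_spec_unchanged(self):
        spec = tiny_cnn()
        assert reduce_arch(spec, scale_factors(0)) == spec

    def test_repeat_rounding(self):
        spec = ArchSpec(input_size=240, blocks=tuple(
            LayerBlock("conv", repeats=r, out_channels=64, stride=2)
            for r in (4, 8, 4)))
        red = reduce_arch(spec, scale_factors(2))
        assert tuple(b.repeats for b in red.blocks) == (3, 6, 3)

    def test_channel_rounding_and_resolution(self):
        spec = ArchSpec(input_size=240, blocks=tuple(
            LayerBlock("conv", repeats=2, out_channels=c, stride=2)
            for c in (32, 64, 128)))
        red = reduce_arch(spec, scale_factors(2), channel_divisor=8)
        assert tuple(b.out_channels for b in red.blocks) == (24, 56, 104)
        assert red.input_size == 181

    def test_input_channels_never_scaled(self):
        red = reduce_arch(tiny_cnn(), scale_factors(3))
        assert red.input_channels == 3
        assert red.head_classes == tiny_cnn().head_classes
        assert red.dropout_rate == tiny_cnn().dropout_rate

    def test_spatial_collapse_names_the_block(self):
        spec = ArchSpec(input_size=16, blocks=(
            LayerBlock("conv", repeats=1, out_channels=8, stride=4),
            LayerBlock("conv", repeats=1, out_channels=8, stride=4),
            LayerBlock("conv", repeats=1, out_channels=8, stride=4),
        ))
        with pytest.raises(ArchError, match="block"):
            reduce_arch(spec, scale_factors(6))

    def test_floors_never_degenerate(self):
        spec = ArchSpec(input_size=224, blocks=(
            LayerBlock("conv", repeats=1, out_channels=8, stride=2),))
        for phi in (1, 3, 5):
            red = reduce_arch(spec, scale_factors(phi))
            assert red.blocks[0].repeats >= 1
            assert red.blocks[0].out_channels >= 8  # one channel_divisor


class TestEstimateFlops:
    def test_empty_block_list(self):
        assert estimate_flops(ArchSpec(input_size=8, blocks=())).macs == 0

    def test_one_by_one_conv_hand_count(self):
        spec = ArchSpec(input_size=4, blocks=(
            LayerBlock("conv", out_channels=8, kernel=(1, 1), stride=1),))
        assert estimate_flops(spec).macs == 4 * 4 * 8 * 1 * 1 * 3

    def test_strided_conv_hand_count(self):
        spec = ArchSpec(input_size=8, blocks=(
            LayerBlock("conv", out_channels=16, kernel=(3, 3), stride=2),))
        assert estimate_flops(spec).macs == 4 * 4 * 16 * 3 * 3 * 3

    def test_depthwise_pool_dense(self):
        spec = ArchSpec(input_size=8, blocks=(
            LayerBlock("conv", out_channels=4, kernel=(1, 1), stride=1),
            LayerBlock("depthwise_conv", out_channels=4, kernel=(3, 3), stride=1),
            LayerBlock("pool", out_channels=4, stride=2),
            LayerBlock("dense", out_channels=10),
        ))
        expect = 8 * 8 * 4 * 3 + 8 * 8 * 4 * 9 + 0 + 4 * 10
        assert estimate_flops(spec).macs == expect

    def test_monotone_in_phi(self):
        ref = reference_cnn()
        macs = [estimate_flops(reduce_arch(ref, scale_factors(phi))).macs
                for phi in range(7)]
        assert all(a >= b for a, b in zip(macs, macs[1:]))

    def test_ratio_tracks_compound_law(self):
        ref = reference_cnn()
        base = estimate_flops(ref).macs
        for phi in (1, 2, 3):
            f = scale_factors(phi)
            ratio = estimate_flops(reduce_arch(ref, f)).macs / base
            assert ratio == pytest.approx(f.flops_multiplier, rel=0.25)


class TestBuildTrainable:
    def test_seeded_init_is_deterministic(self):
        X = np.random.default_rng(0).random((4, 32, 32, 3)).astype(np.float32)
        a = build_trainable(tiny_cnn(32), seed=11).predict_proba(X)
        b = build_trainable(tiny_cnn(32), seed=11).predict_proba(X)
        assert (a == b).all()
        c = build_trainable(tiny_cnn(32), seed=12).predict_proba(X)
        assert not np.allclose(a, c)

    def test_softmax_contract(self):
        X = np.random.default_rng(1).random((6, 32, 32, 3)).astype(np.float32)
        p = build_trainable(tiny_cnn(32), seed=0).predict_proba(X)
        assert (p >= 0).all() and np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_hand_computed_forward_single_block(self):
        """1x1-conv net with hand-set weights on a fixed patch."""
        spec = ArchSpec(input_size=4, dropout_rate=0.0, blocks=(
            LayerBlock("conv", out_channels=2, kernel=(1, 1), stride=1),))
        model = build_trainable(spec, seed=0)
        conv = model.layers[0]
        conv.W[:] = np.array([[1.0, -1.0], [0.5, 0.5], [-0.25, 2.0]], dtype=np.float32)
        conv.b[:] = np.array([0.1, -0.2], dtype=np.float32)
        model.head_W[:] = np.eye(2, dtype=np.float32)
        model.head_b[:] = 0.0

        rng = np.random.default_rng(2)
        x = rng.random((1, 4, 4, 3)).astype(np.float32)
        # oracle: standardize, 1x1 conv + relu, GAP, identity head, softmax
        xs = x[0].astype(np.float64)
        xs = (xs - xs.mean(axis=(0, 1))) / xs.std(axis=(0, 1))
        z = xs @ conv.W.astype(np.float64) + conv.b.astype(np.float64)
        feats = np.maximum(z, 0).mean(axis=(0, 1))
        logits = feats
        expect = np.exp(logits - logits.max())
        expect /= expect.sum()
        got = model.predict_proba(x)[0]
        assert np.allclose(got, expect, atol=1e-5)

    def test_unsupported_block_kinds_rejected(self):
        spec = ArchSpec(input_size=16, blocks=(LayerBlock("dense", out_channels=4),))
        with pytest.raises(ArchError):
            build_trainable(spec, seed=0)

    def test_spatial_underflow_rejected(self):
        spec = ArchSpec(input_size=2, blocks=(
            LayerBlock("conv", out_channels=4, kernel=(5, 5), stride=1),))
        with pytest.raises(ArchError):
            build_trainable(spec, seed=0)


class TestSerialization:
    def test_yaml_round_trip(self, tmp_path):
        spec = tiny_cnn()
        spec.save(tmp_path / "arch.yaml")
        assert ArchSpec.load(tmp_path / "arch.yaml") == spec
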