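"""Architecture bookkeeping and gradient routing of the structural branch."""

import numpy as np
import pytest

from hmpi import nn
from hmpi.dspn import (
    EUKARYOTIC_BLOCKS,
    PROKARYOTIC_BLOCKS,
    DspnSpec,
    build_dspn,
    extract_structural_features,
    flatten_sp,
    predict_proba,
    train_dspn,
)


@pytest.fixture(scope="module")
def tiny_spec():
    # scaled-down block sizes, same topology; keeps unit tests fast
    return DspnSpec(block_sizes=(16, 32, 16, 24, 40, 32, 16), seed=1,
                    epochs=5, batch_size=32)


@pytest.fixture(scope="module")
def tiny_task():
    """Class separable by the mean of the input vector."""
    rng = np.random.default_rng(12)
    n, d = 160, 24
    y = np.arange(n) % 2
    x = rng.normal(size=(n, d)) + 0.8 * y[:, None]
    return x, y


class TestArchitecture:
    @pytest.mark.parametrize(
        "preset,length,widths",
        [
            (EUKARYOTIC_BLOCKS, 251, (250, 1000, 250, 1000, 1500, 1000, 128)),
            (PROKARYOTIC_BLOCKS, 81, (80, 500, 80, 150, 500, 500, 128)),
        ],
    )
    def test_preset_block_sizes(self, preset, length, widths):
        assert preset == widths
        d = 12 * (length - 1)
        model = build_dspn(DspnSpec(block_sizes=preset), input_dim=d)
        outs = [blk.layers[0].n_out for blk in model.blocks]
        assert tuple(outs) == widths

    def test_skip_concatenation_widths_eukaryotic(self):
        d = 12 * 250  # 3000
        model = build_dspn(DspnSpec.eukaryotic(), input_dim=d)
        widths = model.block_input_widths()
        assert widths[0] == d
        assert widths[2] == 1000 + d       # block 3: block-2 output + SP input
        assert widths[5] == 1500 + d + 1000  # block 6: block-5 + SP + block-2

    def test_skip_concatenation_widths_prokaryotic(self):
        d = 12 * 80  # 960
        model = build_dspn(DspnSpec.prokaryotic(), input_dim=d)
        widths = model.block_input_widths()
        assert widths[5] == 500 + 960 + 500

    def test_block_composition_order(self, tiny_spec):
        model = build_dspn(tiny_spec, input_dim=24)
        for blk in model.blocks:
            kinds = [type(layer) for layer in blk.layers]
            assert kinds == [nn.Dense, nn.LeakyReLU, nn.Dropout, nn.BatchNorm]
            assert blk.layers[1].alpha == 0.2
            assert blk.layers[2].rate == tiny_spec.dropout_rate

    def test_default_dropout_is_point_two(self):
        assert DspnSpec().dropout_rate == 0.2

    def test_seven_blocks_enforced(self):
        with pytest.raises(ValueError, match="seven"):
            DspnSpec(block_sizes=(10, 10, 10))

    def test_wrong_input_dim_reports_expected(self, tiny_spec):
        model = build_dspn(tiny_spec, input_dim=24)
        with pytest.raises(ValueError, match="24"):
            model.forward(np.zeros((2, 25)))

    def test_removing_skips_changes_parameter_count_by_concat_widths(self):
        d = 60
        sizes = (8, 12, 8, 10, 14, 12, 8)
        with_skips = build_dspn(DspnSpec(block_sizes=sizes), input_dim=d)
        n_with = sum(p.value.size for p in with_skips.parameters())
        # bookkeeping identity: each extra concat column adds block_size rows
        # of dense weights
        extra = d * sizes[2] + (d + sizes[1]) * sizes[5]
        plain_widths = [d, sizes[0], sizes[1], sizes[2], sizes[3], sizes[4], sizes[5]]
        n_plain = sum(
            (w + 1) * s for w, s in zip(plain_widths, sizes)
        ) + sum(2 * s for s in sizes) + (sizes[6] + 1) * 2  # bn + head
        assert n_with - n_plain == extra


class TestGradientRouting:
    def test_input_gradient_flows_through_skips_when_block1_severed(self, tiny_spec):
        model = build_dspn(tiny_spec, input_dim=24)
        # sever the direct path: zero block-1 dense weights, so any input
        # gradient must arrive via the skip concatenations into blocks 3 and 6
        model.blocks[0].layers[0].W.value[:] = 0.0
        x = np.random.default_rng(3).normal(size=(8, 24))
        logits = model.forward(x, train=False)
        dx = model.backward(np.ones_like(logits))
        assert np.abs(dx).max() > 0

    def test_input_gradient_matches_finite_difference(self):
        spec = DspnSpec(block_sizes=(4, 6, 4, 5, 7, 6, 4), dropout_rate=0.0, seed=2)
        model = build_dspn(spec, input_dim=6)
        rng = np.random.default_rng(4)
        x = rng.normal(size=(5, 6))
        w = rng.normal(size=(5, 2))
        model.forward(x, train=False)
        dx = model.backward(w)
        eps = 1e-6
        num = np.zeros_like(x)
        for i in range(x.shape[0]):
            for j in range(x.shape[1]):
                for sign in (1, -1):
                    x[i, j] += sign * eps
                    val = float((model.forward(x, train=False) * w).sum())
                    num[i, j] += sign * val / (2 * eps)
                    x[i, j] -= sign * eps
        assert np.allclose(dx, num, atol=1e-4)


class TestTraining:
    def test_learns_tiny_task(self, tiny_spec, tiny_task):
        x, y = tiny_task
        model = build_dspn(tiny_spec, input_dim=x.shape[1])
        log = train_dspn(model, x, y)
        acc = (predict_proba(model, x).argmax(axis=1) == y).mean()
        assert acc > 0.9
        assert log[-1]["train_loss"] < log[0]["train_loss"]

    def test_same_seed_identical_runs(self, tiny_task):
        x, y = tiny_task
        accs = []
        for _ in range(2):
            spec = DspnSpec(block_sizes=(16, 32, 16, 24, 40, 32, 16), seed=9, epochs=3)
            model = build_dspn(spec, input_dim=x.shape[1])
            train_dspn(model, x, y, x, y)
            accs.append(predict_proba(model, x))
        assert np.array_equal(accs[0], accs[1])

    def test_eval_mode_pure_function(self, tiny_spec, tiny_task):
        x, y = tiny_task
        model = build_dspn(tiny_spec, input_dim=x.shape[1])
        train_dspn(model, x, y)
        f1 = extract_structural_features(model, x[:7])
        f2 = extract_structural_features(model, x[:7])
        assert np.array_equal(f1, f2)
        assert f1.shape == (7, tiny_spec.block_sizes[-1])


def test_flatten_sp_is_property_major():
    sp = np.arange(24.0).reshape(1, 4, 6)
    flat = flatten_sp(sp)
    assert flat.shape == (1, 24)
    assert np.array_equal(flat[0, :6], sp[0, 0])
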