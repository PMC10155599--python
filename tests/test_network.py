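"""Differential operators, mesh convolution, U-Net structure, gradients,
head/backbone surgery."""

import numpy as np
import pytest

from surftask.icomesh import build_icosphere, pooling_map
from surftask.network import (
    ModelSpec,
    assemble_diff_ops,
    build_model,
    downsample,
    load_checkpoint,
    mesh_conv,
    replace_head,
    save_checkpoint,
    set_trainable,
    upsample,
)


@pytest.fixture(scope="module")
def ops2(mesh2_module):
    return assemble_diff_ops(mesh2_module)


@pytest.fixture(scope="module")
def mesh2_module():
    return build_icosphere(2)


class TestDiffOperators:
    def test_constant_field_annihilated(self, ops2, mesh2_module):
        ones = np.ones(mesh2_module.n_vertices)
        assert np.abs(ops2.d_ew @ ones).max() <= 1e-8
        assert np.abs(ops2.d_ns @ ones).max() <= 1e-8
        assert np.abs(ops2.lap @ ones).max() <= 1e-8

    def test_laplacian_row_sums_exactly_zero(self, ops2):
        np.testing.assert_allclose(np.asarray(ops2.lap.sum(axis=1)).ravel(), 0,
                                   atol=1e-15)

    def test_row_support_within_one_ring(self, ops2, mesh2_module):
        csr = ops2.d_ew.tocsr()
        for v in range(mesh2_module.n_vertices):
            support = set(csr.indices[csr.indptr[v]: csr.indptr[v + 1]])
            allowed = set(mesh2_module.one_ring[v]) | {v}
            assert support <= allowed

    def test_north_south_derivative_of_z(self):
        # f(v) = z = cos(theta); d/d(theta) = -sin(theta)
        mesh = build_icosphere(4)
        ops = assemble_diff_ops(mesh)
        z = mesh.vertices[:, 2]
        expected = -np.sqrt(np.clip(1 - z ** 2, 0, 1))
        assert np.abs(ops.d_ns @ z - expected).max() < 0.1

    def test_east_west_derivative_of_z_vanishes(self):
        mesh = build_icosphere(4)
        ops = assemble_diff_ops(mesh)
        z = mesh.vertices[:, 2]
        assert np.abs(ops.d_ew @ z).max() < 0.1


class TestMeshConv:
    def test_zero_weights_give_bias(self, ops2, mesh2_module, rng):
        x = rng.standard_normal((mesh2_module.n_vertices, 3))
        w = np.zeros((2, 3, 4))
        out = mesh_conv(x, ops2, w, bias=np.array([1.5, -2.0]))
        np.testing.assert_array_equal(out[:, 0], 1.5)
        np.testing.assert_array_equal(out[:, 1], -2.0)

    def test_identity_weights_return_input(self, ops2, mesh2_module, rng):
        x = rng.standard_normal((mesh2_module.n_vertices, 3))
        w = np.zeros((3, 3, 4))
        w[:, :, 0] = np.eye(3)
        np.testing.assert_allclose(mesh_conv(x, ops2, w), x, atol=1e-14)

    def test_matches_dense_loop_oracle(self, rng):
        mesh = build_icosphere(0)
        ops = assemble_diff_ops(mesh)
        x = rng.standard_normal((12, 2))
        w = rng.standard_normal((3, 2, 4))
        b = rng.standard_normal(3)
        dense = [np.eye(12), ops.d_ew.toarray(), ops.d_ns.toarray(), ops.lap.toarray()]
        expected = np.zeros((12, 3))
        for c in range(3):
            for k in range(2):
                for o in range(4):
                    expected[:, c] += w[c, k, o] * (dense[o] @ x[:, k])
            expected[:, c] += b[c]
        np.testing.assert_allclose(mesh_conv(x, ops, w, b), expected, atol=1e-10)

    def test_shape_mismatch_rejected(self, ops2, rng):
        with pytest.raises(ValueError):
            mesh_conv(rng.standard_normal((162, 3)), ops2, rng.standard_normal((2, 5, 4)))


class TestPoolingOps:
    def test_constant_survives_down_up(self):
        fine, coarse = build_icosphere(1), build_icosphere(0)
        pm = pooling_map(fine, coarse)
        x = np.full((12, 2), 4.0)
        up = upsample(x, pm)
        assert np.all(up == 4.0)
        np.testing.assert_array_equal(downsample(up, pm), x)

    def test_delta_upsamples_to_half_at_midpoints(self):
        fine, coarse = build_icosphere(1), build_icosphere(0)
        pm = pooling_map(fine, coarse)
        x = np.zeros((12, 1))
        x[3] = 1.0
        up = upsample(x, pm)
        assert up[3, 0] == 1.0
        for i, (a, b) in enumerate(pm.midpoint_parents):
            expected = 0.5 * (x[a, 0] + x[b, 0])
            assert up[12 + i, 0] == expected

    def test_down_of_up_is_identity(self, rng):
        fine, coarse = build_icosphere(2), build_icosphere(1)
        pm = pooling_map(fine, coarse)
        x = rng.standard_normal((coarse.n_vertices, 5))
        np.testing.assert_array_equal(downsample(upsample(x, pm), pm), x)


class TestSurfaceUNet:
    def test_forward_shape_contract(self, rng):
        spec = ModelSpec(level=3, in_channels=10, out_channels=6, depth=2,
                         widths=(8, 12, 16), seed=0)
        model = build_model(spec)
        out = model.forward(rng.standard_normal((642, 10)))
        assert out.shape == (642, 6)

    def test_same_seed_identical_parameters(self):
        spec = ModelSpec(level=2, in_channels=4, out_channels=2, depth=1,
                         widths=(6, 8), seed=42)
        a, b = build_model(spec), build_model(spec)
        for k, v in a.parameters().items():
            assert v.tobytes() == b.parameters()[k].tobytes()

    def test_skip_toggle_changes_decoder_widths(self):
        kw = dict(level=2, in_channels=4, out_channels=2, depth=1, widths=(6, 8), seed=0)
        with_skip = build_model(ModelSpec(skip_connections=True, **kw))
        without = build_model(ModelSpec(skip_connections=False, **kw))
        w_on = with_skip.parameters()["dec0.conv0.w"].shape
        w_off = without.parameters()["dec0.conv0.w"].shape
        assert w_on[1] - w_off[1] == 6  # encoder width concatenated

    def test_depth_exceeding_level_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(level=1, in_channels=2, out_channels=2, depth=3)

    def test_forward_is_deterministic(self, rng):
        spec = ModelSpec(level=2, in_channels=3, out_channels=2, depth=1,
                         widths=(5, 7), seed=3)
        model = build_model(spec)
        x = rng.standard_normal((162, 3))
        np.testing.assert_array_equal(model.forward(x), model.forward(x))

    def test_gradient_check(self, rng):
        """Analytic parameter and input gradients match numerical differences."""
        spec = ModelSpec(level=1, in_channels=2, out_channels=2, depth=1,
                         widths=(3, 4), seed=0)
        model = build_model(spec)
        x = rng.standard_normal((42, 2))
        t = rng.standard_normal((42, 2))

        def loss():
            y = model.forward(x)
            return 0.5 * np.sum((y - t) ** 2)

        y = model.forward(x)
        model.zero_grad()
        gx = model.backward(y - t)
        grads = {k: v.copy() for k, v in model.gradients().items()}
        params = model.parameters()
        eps = 1e-6
        for k, p in params.items():
            for flat in range(0, p.size, max(1, p.size // 4)):
                ix = tuple(np.unravel_index(flat, p.shape))
                old = p[ix]
                p[ix] = old + eps
                lp = loss()
                p[ix] = old - eps
                lm = loss()
                p[ix] = old
                num = (lp - lm) / (2 * eps)
                # absolute floor covers dead parameters (bias before norm)
                assert abs(num - grads[k][ix]) <= 1e-4 * max(1.0, abs(num)), k
        i, j = 5, 1
        old = x[i, j]
        x[i, j] = old + eps
        lp = loss()
        x[i, j] = old - eps
        lm = loss()
        x[i, j] = old
        assert abs((lp - lm) / (2 * eps) - gx[i, j]) <= 1e-4


class TestTransferSurgery:
    def _model(self):
        spec = ModelSpec(level=2, in_channels=3, out_channels=4, depth=1,
                         widths=(5, 6), seed=1)
        return build_model(spec)

    def test_replace_head_preserves_backbone(self, rng):
        model = self._model()
        head_names = model.head_param_names()
        before = {k: v.copy() for k, v in model.parameters().items()
                  if k not in head_names}
        old_head_w = model.parameters()["head.conv.w"].copy()
        replace_head(model, 3, seed=99)
        after = model.parameters()
        for k, v in before.items():
            assert after[k].tobytes() == v.tobytes()
        assert after["head.conv.w"].shape[0] == 3
        out = model.forward(rng.standard_normal((162, 3)))
        assert out.shape == (162, 3)
        # same-C replacement still re-initializes
        model2 = self._model()
        replace_head(model2, 4, seed=1)
        assert model2.parameters()["head.conv.w"].tobytes() != old_head_w.tobytes()

    def test_replace_head_invalid_channels(self):
        with pytest.raises(ValueError):
            replace_head(self._model(), 0, seed=0)

    def test_freeze_head_then_train_leaves_head_unchanged(self, rng):
        from surftask.train import train

        model = self._model()
        set_trainable(model, {"backbone"})
        head_before = {k: v.copy() for k, v in model.parameters().items()
                       if k in model.head_param_names()}
        backbone_key = "enc0.conv0.w"
        backbone_before = model.parameters()[backbone_key].copy()
        subjects = [{"inputs": [rng.standard_normal((162, 3))],
                     "target": rng.standard_normal((162, 4))} for _ in range(2)]
        train(model, subjects, [{"objective": "mse", "epochs": 2, "batch_size": 2}],
              seed=0)
        for k, v in head_before.items():
            assert model.parameters()[k].tobytes() == v.tobytes()
        assert model.parameters()[backbone_key].tobytes() != backbone_before.tobytes()

    def test_freeze_backbone_only_head_changes(self, rng):
        from surftask.train import train

        model = self._model()
        set_trainable(model, {"head"})
        backbone_before = model.parameters()["enc0.conv0.w"].copy()
        head_before = model.parameters()["head.conv.w"].copy()
        subjects = [{"inputs": [rng.standard_normal((162, 3))],
                     "target": rng.standard_normal((162, 4))} for _ in range(2)]
        train(model, subjects, [{"objective": "mse", "epochs": 2, "batch_size": 2}],
              seed=0)
        assert model.parameters()["enc0.conv0.w"].tobytes() == backbone_before.tobytes()
        assert model.parameters()["head.conv.w"].tobytes() != head_before.tobytes()

    def test_freeze_all_rejected(self):
        with pytest.raises(ValueError):
            set_trainable(self._model(), set())


def test_checkpoint_round_trip(tmp_path, rng):
    spec = ModelSpec(level=2, in_channels=3, out_channels=2, depth=1,
                     widths=(4, 5), seed=7)
    model = build_model(spec)
    stats = {"mean": rng.standard_normal(3), "sd": np.abs(rng.standard_normal(3)) + 0.5}
    path = tmp_path / "model.npz"
    save_checkpoint(model, path, norm_stats=stats, provenance={"phase": "mse"})
    back, stats2, prov = load_checkpoint(path)
    x = rng.standard_normal((162, 3))
    np.testing.assert_array_equal(back.forward(x), model.forward(x))
    np.testing.assert_array_equal(stats2["mean"], stats["mean"])
    assert prov == {"phase": "mse"}
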