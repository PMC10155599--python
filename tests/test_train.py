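"""Loss arithmetic, margin initialization and schedule, channel masking,
training determinism, finetuning modes, ensembling."""

import numpy as np
import pytest

from surftask.network import ModelSpec, build_model
from surftask.train import (
    LossConfig,
    ensemble_predict,
    finetune,
    init_margins,
    margin_schedule,
    mse_loss,
    rc_loss,
    train,
)


def _maps(rng, n, v=20, c=3):
    return [rng.standard_normal((v, c)) for _ in range(n)]


class TestRCLoss:
    def test_perfect_predictions_zero_loss(self, rng):
        targets = _maps(rng, 3)
        # L_R = 0; hinge2 = [0 - L_C + gamma]+ = 0 whenever L_C >= gamma
        cfg = LossConfig(alpha=0.0, gamma=1.0)
        rep = rc_loss([t.copy() for t in targets], targets, cfg)
        assert rep.L_R == 0.0
        assert rep.L_C > 1.0  # random targets are far apart
        assert rep.L_RC == 0.0

    def test_worked_hinge_arithmetic(self):
        # L_R=2, alpha=1, L_C=3, gamma=2 -> [2-1]+ + [2-3+2]+ = 1 + 1 = 2
        ones = np.ones((4, 1))
        p = 2 * np.sqrt(2) - np.sqrt(3)
        preds = [ones * np.sqrt(2), ones * p]
        targets = [ones * 0.0, ones * (p - np.sqrt(2))]
        cfg = LossConfig(alpha=1.0, gamma=2.0)
        rep = rc_loss(preds, targets, cfg)
        assert rep.L_R == pytest.approx(2.0)
        assert rep.L_C == pytest.approx(3.0)
        assert rep.L_RC == pytest.approx(2.0)

    def test_pair_count_n4(self, rng):
        preds, targets = _maps(rng, 4), _maps(rng, 4)
        cfg = LossConfig()
        rep = rc_loss(preds, targets, cfg)
        cross = [np.mean((preds[i] - targets[j]) ** 2)
                 for i in range(4) for j in range(i + 1, 4)]
        assert len(cross) == 6  # (4^2 - 4) / 2
        assert rep.L_C == pytest.approx(np.mean(cross))

    def test_batch_of_one_falls_back_to_reconstructive_hinge(self, rng):
        preds, targets = _maps(rng, 1), _maps(rng, 1)
        rep = rc_loss(preds, targets, LossConfig(alpha=0.1))
        assert np.isnan(rep.L_C)
        assert rep.L_RC == pytest.approx(max(rep.L_R - 0.1, 0.0))

    def test_large_alpha_reduces_to_contrast_gap(self, rng):
        preds, targets = _maps(rng, 3), _maps(rng, 3)
        rep = rc_loss(preds, targets, LossConfig(alpha=1e9, gamma=0.0))
        assert rep.L_RC == pytest.approx(max(rep.L_R - rep.L_C, 0.0))

    def test_huge_gamma_reduces_to_hinged_mse_plus_gap(self, rng):
        preds, targets = _maps(rng, 3), _maps(rng, 3)
        gamma = 1e9
        rep = rc_loss(preds, targets, LossConfig(alpha=0.0, gamma=gamma))
        assert rep.L_RC == pytest.approx(rep.L_R + (rep.L_R - rep.L_C + gamma))

    def test_gradients_match_numerical(self, rng):
        preds, targets = _maps(rng, 3, v=6, c=2), _maps(rng, 3, v=6, c=2)
        cfg = LossConfig(alpha=0.5, gamma=1.0)
        rep, grads = rc_loss(preds, targets, cfg, with_grads=True)
        eps = 1e-7
        for i in (0, 2):
            for ix in [(0, 0), (3, 1)]:
                old = preds[i][ix]
                preds[i][ix] = old + eps
                lp = rc_loss(preds, targets, cfg).L_RC
                preds[i][ix] = old - eps
                lm = rc_loss(preds, targets, cfg).L_RC
                preds[i][ix] = old
                assert abs((lp - lm) / (2 * eps) - grads[i][ix]) < 1e-6

    def test_channel_mask_removing_all_rejected(self):
        with pytest.raises(ValueError):
            LossConfig(channel_mask=np.zeros(3, dtype=bool))

    def test_negative_margin_rejected(self):
        with pytest.raises(ValueError):
            LossConfig(alpha=-1.0)


class TestMargins:
    def test_zero_error_model_gets_zero_alpha(self, rng):
        spec = ModelSpec(level=1, in_channels=2, out_channels=2, depth=1,
                         widths=(3, 3), seed=0)
        model = build_model(spec)
        x = [rng.standard_normal((42, 2)) for _ in range(3)]
        subjects = [{"inputs": [xi], "target": model.forward(xi)} for xi in x]
        alpha0, gamma0 = init_margins(model, subjects)
        assert alpha0 == pytest.approx(0.0, abs=1e-12)

    def test_both_gamma_rules(self, rng):
        # engineered: alternative rule returns L_C_bar, gap rule the difference
        spec = ModelSpec(level=1, in_channels=2, out_channels=1, depth=1,
                         widths=(3, 3), seed=0)
        model = build_model(spec)
        subjects = [{"inputs": [rng.standard_normal((42, 2))],
                     "target": rng.standard_normal((42, 1))} for _ in range(3)]
        a_gap, g_gap = init_margins(model, subjects, rule="gap")
        a_abs, g_abs = init_margins(model, subjects, rule="absolute")
        assert a_gap == a_abs
        assert g_abs == pytest.approx(g_gap + a_gap) or g_gap == 0.0

    def test_deterministic_recomputation(self, rng):
        spec = ModelSpec(level=1, in_channels=2, out_channels=1, depth=1,
                         widths=(3, 3), seed=0)
        model = build_model(spec)
        subjects = [{"inputs": [rng.standard_normal((42, 2))],
                     "target": rng.standard_normal((42, 1))} for _ in range(3)]
        assert init_margins(model, subjects) == init_margins(model, subjects)

    def test_single_subject_rejected(self, rng):
        spec = ModelSpec(level=1, in_channels=2, out_channels=1, depth=1,
                         widths=(3, 3), seed=0)
        model = build_model(spec)
        with pytest.raises(ValueError):
            init_margins(model, [{"inputs": [rng.standard_normal((42, 2))],
                                  "target": rng.standard_normal((42, 1))}])

    @pytest.mark.parametrize("epoch,factor", [(0, 1), (19, 1), (20, 2), (45, 4)])
    def test_margin_schedule(self, epoch, factor):
        a, g = margin_schedule(1.0, 3.0, epoch)
        assert a == pytest.approx(1.0 / factor)
        assert g == pytest.approx(3.0 * factor)


class TestTraining:
    def _subjects(self, rng, n=4, v=42, cin=2, c=2):
        return [{"inputs": [rng.standard_normal((v, cin)) for _ in range(2)],
                 "target": rng.standard_normal((v, c))} for _ in range(n)]

    def _spec(self):
        return ModelSpec(level=1, in_channels=2, out_channels=2, depth=1,
                         widths=(4, 5), seed=0)

    def test_mse_training_decreases_loss(self, rng):
        model = build_model(self._spec())
        subjects = self._subjects(rng)
        _, hist = train(model, subjects,
                        [{"objective": "mse", "epochs": 5, "batch_size": 2}], seed=0)
        losses = [h["L_R"] for h in hist]
        drops = sum(losses[i + 1] <= losses[i] for i in range(4))
        assert drops >= 4 or losses[-1] < losses[0]

    def test_same_seed_bitwise_identical(self, rng):
        subjects = self._subjects(rng)
        m1, h1 = train(build_model(self._spec()), subjects,
                       [{"objective": "mse", "epochs": 3, "batch_size": 2}], seed=5)
        m2, h2 = train(build_model(self._spec()), subjects,
                       [{"objective": "mse", "epochs": 3, "batch_size": 2}], seed=5)
        for k, v in m1.parameters().items():
            assert v.tobytes() == m2.parameters()[k].tobytes()
        for a, b in zip(h1, h2):
            for key in a:
                np.testing.assert_equal(a[key], b[key])  # NaN-tolerant

    def test_margins_change_at_schedule_boundaries(self, rng):
        subjects = self._subjects(rng)
        model = build_model(self._spec())
        _, hist = train(model, subjects,
                        [{"objective": "rc", "epochs": 45, "batch_size": 2,
                          "alpha": 1.0, "gamma": 2.0}], seed=0, margin_period=20)
        alphas = [h["alpha"] for h in hist]
        assert alphas[0] == alphas[19] == 1.0
        assert alphas[20] == alphas[39] == 0.5
        assert alphas[40] == 0.25
        gammas = [h["gamma"] for h in hist]
        assert gammas[20] == 4.0 and gammas[40] == 8.0

    def test_rc_batch_of_one_rejected(self, rng):
        model = build_model(self._spec())
        with pytest.raises(ValueError):
            train(model, self._subjects(rng),
                  [{"objective": "rc", "epochs": 1, "batch_size": 1}], seed=0)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            train(build_model(self._spec()), [],
                  [{"objective": "mse", "epochs": 1, "batch_size": 2}], seed=0)


class TestChannelMaskedFinetuning:
    def test_masked_channel_gradient_exactly_zero(self, rng):
        """Targets on a held-out channel never produce gradient."""
        spec = ModelSpec(level=1, in_channels=2, out_channels=3, depth=1,
                         widths=(4, 4), seed=0)
        model = build_model(spec)
        x = rng.standard_normal((42, 2))
        target = rng.standard_normal((42, 3))
        mask = np.array([True, True, False])
        cfg = LossConfig(channel_mask=mask)
        pred = model.forward(x)
        _, grads = mse_loss([pred], [target], cfg, with_grads=True)
        assert np.all(grads[0][:, 2] == 0.0)
        # changing the held-out target changes nothing
        target2 = target.copy()
        target2[:, 2] = rng.standard_normal(42)
        _, grads2 = mse_loss([pred], [target2], cfg, with_grads=True)
        np.testing.assert_array_equal(grads[0], grads2[0])

    def test_backbone_only_freezes_head_and_masks(self, rng):
        spec = ModelSpec(level=1, in_channels=2, out_channels=3, depth=1,
                         widths=(4, 4), seed=0)
        model = build_model(spec)
        head_before = model.parameters()["head.conv.w"].copy()
        subjects = [{"inputs": [rng.standard_normal((42, 2))],
                     "target": rng.standard_normal((42, 3))} for _ in range(2)]
        mask = np.array([True, True, False])
        model, _ = finetune(model, subjects, "backbone_only", seed=0, epochs=2,
                            channel_mask=mask)
        assert model.parameters()["head.conv.w"].tobytes() == head_before.tobytes()

    def test_full_with_new_head_changes_output_channels(self, rng):
        spec = ModelSpec(level=1, in_channels=2, out_channels=3, depth=1,
                         widths=(4, 4), seed=0)
        model = build_model(spec)
        subjects = [{"inputs": [rng.standard_normal((42, 2))],
                     "target": rng.standard_normal((42, 2))} for _ in range(2)]
        model, _ = finetune(model, subjects, "full_with_new_head", seed=0,
                            epochs=1, c_new=2)
        assert model.forward(rng.standard_normal((42, 2))).shape == (42, 2)

    def test_denovo_equals_build_plus_train(self, rng):
        spec = ModelSpec(level=1, in_channels=2, out_channels=2, depth=1,
                         widths=(4, 4), seed=0)
        pretrained = build_model(spec)
        subjects = [{"inputs": [rng.standard_normal((42, 2))],
                     "target": rng.standard_normal((42, 2))} for _ in range(2)]
        ft, _ = finetune(pretrained, subjects, "denovo", seed=11, epochs=2)
        import copy

        spec2 = copy.deepcopy(spec)
        spec2.seed = 11
        ref, _ = train(build_model(spec2), subjects,
                       [{"objective": "mse", "epochs": 2, "batch_size": 2}], seed=11)
        for k, v in ft.parameters().items():
            assert v.tobytes() == ref.parameters()[k].tobytes()


class TestEnsemblePredict:
    def _model(self):
        return build_model(ModelSpec(level=1, in_channels=2, out_channels=2,
                                     depth=1, widths=(3, 3), seed=0))

    def test_single_connectome_equals_forward(self, rng):
        model = self._model()
        x = rng.standard_normal((42, 2))
        np.testing.assert_array_equal(ensemble_predict(model, [x]), model.forward(x))

    def test_duplicates_equal_single(self, rng):
        model = self._model()
        x = rng.standard_normal((42, 2))
        np.testing.assert_allclose(ensemble_predict(model, [x] * 5),
                                   model.forward(x), atol=1e-14)

    def test_mean_of_two_forwards(self, rng):
        model = self._model()
        a, b = rng.standard_normal((42, 2)), rng.standard_normal((42, 2))
        expected = (model.forward(a) + model.forward(b)) / 2
        np.testing.assert_allclose(ensemble_predict(model, [a, b]), expected)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            ensemble_predict(self._model(), [])
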