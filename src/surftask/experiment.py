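"""End-to-end scaled experiments: benchmark and transfer-learning runs.

These runners wire the full pipeline together on synthetic cohorts —
generate rest/task data, build and normalize vertex-to-ROI connectomes,
train the surface U-Net in two phases (MSE, then reconstructive-contrastive
with scheduled margins), fit the group-average and parcel-wise linear
baselines, and evaluate Dice AUC, whole-brain R^2, subject identification
and reliability.  Problem sizes default to a single-CPU scale (icosphere
level 3, tens of subjects).
"""

from __future__ import annotations

import copy

import numpy as np

from .baselines import fit_parcel_linear, group_average, predict_parcel_linear
from .connectome import Connectome, normalize_channels
from .metrics import dice_auc, identification, reliability_screen, whole_brain_r2
from .network import ModelSpec, SurfaceUNet, build_model
from .surface_io import ContrastMaps
from .synthcohort import CohortConfig, build_connectome_inputs, make_cohort
from .train import ensemble_predict, finetune, train

__all__ = ["run_benchmark", "run_transfer", "clone_model"]


def clone_model(model: SurfaceUNet) -> SurfaceUNet:
    """Independent copy sharing the (immutable) meshes and operators."""
    spec = copy.deepcopy(model.spec)
    m = SurfaceUNet(spec, meshes=model.meshes, ops=model.ops)
    m.load_state_dict(model.state_dict())
    m.trainable = set(model.trainable)
    return m


def _mean_connectome(conns):
    data = np.mean([c.data for c in conns], axis=0)
    return Connectome(data=data, channel_names=list(conns[0].channel_names),
                      subject=conns[0].subject, vertex_mask=conns[0].vertex_mask)


def _prepare(cohort, n_train, stats=None):
    """Connectomes (normalized for the network, raw means for the baseline).

    ``stats`` overrides the per-channel normalization (a pretrained model's
    stored statistics); by default they are estimated on this cohort's
    training subjects.
    """
    parc, conns = build_connectome_inputs(cohort, scheme="halves")
    flat_train = [c for subj in conns[:n_train] for c in subj]
    if stats is None:
        _, stats = normalize_channels(flat_train)
    norm_conns = []
    for subj in conns:
        normed, _ = normalize_channels(subj, stats)
        norm_conns.append([c.data for c in normed])
    raw_means = [_mean_connectome(subj) for subj in conns]
    return parc, conns, norm_conns, raw_means, stats


def _subject_records(cohort, norm_conns, idx):
    return [
        {"inputs": norm_conns[i], "target": cohort.subjects[i]["visits"][0].data}
        for i in idx
    ]


def _mean_auc(pred_maps, target_maps):
    aucs = []
    for p, t in zip(pred_maps, target_maps):
        for c in range(t.shape[1]):
            aucs.append(dice_auc(p[:, c], t[:, c]).auc)
    return float(np.mean(aucs))


def _ident_accuracy(pred_maps, targets_cm):
    """Identification accuracy averaged over contrasts."""
    preds_cm = [ContrastMaps(p, names=t.names, subject=t.subject)
                for p, t in zip(pred_maps, targets_cm)]
    accs = [identification(preds_cm, targets_cm, contrast=c).accuracy
            for c in range(targets_cm[0].n_contrasts)]
    return float(np.mean(accs))


def run_benchmark(seed: int, n_train: int = 40, n_test: int = 10,
                  mse_epochs: int = 30, rc_epochs: int = 20,
                  widths=(32, 64, 96), depth: int = 2, lr: float = 2e-2,
                  lr_rc: float | None = None, convs_per_block: int = 1,
                  nonlinear: bool = True, cohort_kwargs: dict | None = None) -> dict:
    """Train the surface U-Net on a synthetic cohort and benchmark it.

    Returns a dict with mean Dice AUCs (model / group-average / linear
    baseline / repeat), identification accuracy after the MSE-only phase and
    after the R-C phase, whole-brain R^2, the final-phase margins and losses,
    and the count of individual-level reliable contrasts.
    """
    kw = dict(n_subjects=n_train + n_test, nonlinear=nonlinear, seed=seed)
    kw.update(cohort_kwargs or {})
    cfg = CohortConfig(**kw)
    cohort, truth = make_cohort(cfg)
    parc, conns, norm_conns, raw_means, stats = _prepare(cohort, n_train)

    train_idx = list(range(n_train))
    test_idx = list(range(n_train, n_train + n_test))
    train_subjects = _subject_records(cohort, norm_conns, train_idx)
    train_targets = [cohort.subjects[i]["visits"][0] for i in train_idx]
    test_targets = [cohort.subjects[i]["visits"][0] for i in test_idx]
    test_repeats = [cohort.subjects[i]["visits"][1] for i in test_idx]
    target_maps = [t.data for t in test_targets]

    spec = ModelSpec(level=cfg.level, in_channels=cfg.n_rois,
                     out_channels=cfg.n_contrasts, depth=depth,
                     widths=widths, convs_per_block=convs_per_block, seed=seed)
    model = build_model(spec)
    model, hist_mse = train(
        model, train_subjects,
        [{"objective": "mse", "epochs": mse_epochs, "batch_size": 2}],
        seed=seed, lr=lr)
    preds_mse = [ensemble_predict(model, norm_conns[i]) for i in test_idx]
    ident_mse = _ident_accuracy(preds_mse, test_targets)

    if rc_epochs > 0:
        model, hist_rc = train(
            model, train_subjects,
            [{"objective": "rc", "epochs": rc_epochs, "batch_size": 2}],
            seed=seed + 1, lr=lr_rc if lr_rc is not None else lr / 8)
    else:
        hist_rc = []
    preds = [ensemble_predict(model, norm_conns[i]) for i in test_idx]
    ident_rc = _ident_accuracy(preds, test_targets)

    # converged same-subject loss, measured the same way the margins were
    # initialized (single connectome per training subject)
    final_preds = [model.forward(s["inputs"][0]) for s in train_subjects]
    final_L_R = float(np.mean([np.mean((p - s["target"]) ** 2)
                               for p, s in zip(final_preds, train_subjects)]))

    grp = group_average(train_targets)
    linmodel = fit_parcel_linear([raw_means[i] for i in train_idx], train_targets, parc)
    lin_preds = [predict_parcel_linear(linmodel, raw_means[i], parc).data
                 for i in test_idx]

    r2_model = float(np.mean([whole_brain_r2(p, t)[1]
                              for p, t in zip(preds, target_maps)]))
    r2_lin = float(np.mean([whole_brain_r2(p, t)[1]
                            for p, t in zip(lin_preds, target_maps)]))
    reliable = reliability_screen(test_targets, test_repeats, grp)

    return {
        "config": cfg,
        "model": model,
        "history": hist_mse + hist_rc,
        "model_dice_auc": _mean_auc(preds, target_maps),
        "model_dice_auc_mse_only": _mean_auc(preds_mse, target_maps),
        "group_average_dice_auc": _mean_auc([grp.data] * n_test, target_maps),
        "linear_dice_auc": _mean_auc(lin_preds, target_maps),
        "repeat_dice_auc": _mean_auc([r.data for r in test_repeats], target_maps),
        "identification_mse": ident_mse,
        "identification_rc": ident_rc,
        "model_r2": r2_model,
        "linear_r2": r2_lin,
        "n_reliable_contrasts": int(reliable.sum()),
        "final_L_R": final_L_R,
        "final_alpha": hist_rc[-1]["alpha"] if hist_rc else float("nan"),
        "norm_stats": stats,
    }


def run_transfer(seed: int, pretrained: SurfaceUNet, n_train: int = 12,
                 n_test: int = 6, epochs: int = 15, backbone_epochs: int = 10,
                 held_out: int = 0, pretrain_stats: dict | None = None,
                 lr_finetune: float = 5e-3, lr_backbone: float = 1e-3,
                 cohort_kwargs: dict | None = None) -> dict:
    """Transfer the pretrained model to a shifted cohort.

    Three arms: full finetuning with a fresh head versus de-novo training at
    matched budget (mean Dice AUC over all contrasts), and backbone-only
    finetuning with contrast ``held_out`` masked out of the loss, evaluated
    on that held-out contrast against the non-finetuned pretrained model.
    """
    spec = pretrained.spec
    # same population structure as the pretraining cohort (structure_seed),
    # new subjects and noise, templates perturbed by the acquisition shift
    kw = dict(level=spec.level, n_subjects=n_train + n_test,
              n_rois=spec.in_channels, n_contrasts=spec.out_channels,
              nonlinear=True, template_shift=1.0, seed=seed + 7001,
              structure_seed=spec.seed)
    kw.update(cohort_kwargs or {})
    cfg = CohortConfig(**kw)
    cohort, _ = make_cohort(cfg)
    # inputs are scaled with the pretrained model's stored statistics: the new
    # site's connectome distribution shift reaches the model instead of being
    # silently absorbed by per-cohort re-normalization
    parc, conns, norm_conns, raw_means, stats = _prepare(cohort, n_train,
                                                         stats=pretrain_stats)

    n_val = max(2, n_train // 6)  # small held-back split for checkpointing
    train_idx = list(range(n_train - n_val))
    val_idx = list(range(n_train - n_val, n_train))
    test_idx = list(range(n_train, n_train + n_test))
    train_subjects = _subject_records(cohort, norm_conns, train_idx)
    val_subjects = _subject_records(cohort, norm_conns, val_idx)
    test_targets = [cohort.subjects[i]["visits"][0] for i in test_idx]
    target_maps = [t.data for t in test_targets]
    C = cfg.n_contrasts

    ft_model, _ = finetune(clone_model(pretrained), train_subjects,
                           "full_with_new_head", seed=seed, epochs=epochs,
                           c_new=C, lr=lr_finetune, val_subjects=val_subjects)
    dn_model, _ = finetune(clone_model(pretrained), train_subjects,
                           "denovo", seed=seed, epochs=epochs, lr=lr_finetune,
                           val_subjects=val_subjects)
    mask = np.ones(C, dtype=bool)
    mask[held_out] = False
    # gentler rate for backbone-only adaptation: the head is frozen and the
    # goal is recalibration, not re-learning
    bb_model, _ = finetune(clone_model(pretrained), train_subjects,
                           "backbone_only", seed=seed, epochs=backbone_epochs,
                           channel_mask=mask, lr=lr_backbone,
                           val_subjects=val_subjects)

    ft_preds = [ensemble_predict(ft_model, norm_conns[i]) for i in test_idx]
    dn_preds = [ensemble_predict(dn_model, norm_conns[i]) for i in test_idx]
    bb_preds = [ensemble_predict(bb_model, norm_conns[i]) for i in test_idx]
    pre_preds = [ensemble_predict(pretrained, norm_conns[i]) for i in test_idx]

    def _held_auc(pred_maps):
        return float(np.mean([
            dice_auc(p[:, held_out], t[:, held_out]).auc
            for p, t in zip(pred_maps, target_maps)
        ]))

    return {
        "config": cfg,
        "finetuned_dice_auc": _mean_auc(ft_preds, target_maps),
        "denovo_dice_auc": _mean_auc(dn_preds, target_maps),
        "backbone_heldout_dice_auc": _held_auc(bb_preds),
        "pretrained_heldout_dice_auc": _held_auc(pre_preds),
    }
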