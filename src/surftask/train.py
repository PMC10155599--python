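"""Training: reconstructive-contrastive loss, two-phase schedule, transfer modes.

The model is first trained with plain mean-squared error (the reconstructive
loss L_R).  At convergence the average reconstructive and contrastive losses
over the training set initialize the margins alpha and gamma, and training
continues with the combined hinge objective

    L_RC = [L_R - alpha]+  +  [L_R - L_C + gamma]+

which keeps the same-subject error within the alpha margin while pushing the
prediction-to-other-subject gap beyond gamma.  During phase 2 alpha is halved
and gamma doubled every 20 epochs.  Finetuning on small datasets uses MSE
only.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass

import numpy as np

from .network import SurfaceUNet, build_model, replace_head, set_trainable

logger = logging.getLogger(__name__)

__all__ = [
    "LossConfig",
    "LossReport",
    "rc_loss",
    "init_margins",
    "margin_schedule",
    "Adam",
    "train",
    "finetune",
    "ensemble_predict",
]


@dataclass
class LossConfig:
    """Margins and divergence configuration for the R-C loss.

    ``d`` is the mean squared difference over masked vertices and unmasked
    channels (mean rather than sum, so margins are independent of mesh
    resolution).  ``channel_mask`` selects which output channels enter the
    loss (True = included); ``vertex_mask`` restricts to cortex vertices.
    """

    alpha: float = 0.0
    gamma: float = 0.0
    channel_mask: np.ndarray = None
    vertex_mask: np.ndarray = None

    def __post_init__(self):
        if self.alpha < 0 or self.gamma < 0:
            raise ValueError("margins must be non-negative")
        if self.channel_mask is not None:
            self.channel_mask = np.asarray(self.channel_mask, dtype=bool)
            if not self.channel_mask.any():
                raise ValueError("channel mask removes all channels")


@dataclass
class LossReport:
    """Values of the loss components for one batch."""

    L_R: float
    L_C: float
    L_RC: float
    n: int


def _masked_sq_diff(a, b, cfg: LossConfig):
    """d(a, b): mean squared difference over the masked entries, plus gradient scale."""
    diff = a - b
    if cfg.channel_mask is not None:
        diff = diff[:, cfg.channel_mask]
    if cfg.vertex_mask is not None:
        diff = diff[cfg.vertex_mask]
    return float(np.mean(diff ** 2))


def _d_grad(a, b, cfg: LossConfig):
    """Gradient of d(a, b) wrt a, embedded back into the full (V, C) shape."""
    full = np.zeros_like(a)
    cmask = cfg.channel_mask if cfg.channel_mask is not None else np.ones(a.shape[1], bool)
    vmask = cfg.vertex_mask if cfg.vertex_mask is not None else np.ones(a.shape[0], bool)
    count = int(vmask.sum()) * int(cmask.sum())
    sub = 2.0 * (a[np.ix_(vmask, cmask)] - b[np.ix_(vmask, cmask)]) / count
    full[np.ix_(vmask, cmask)] = sub
    return full


def rc_loss(predictions: list, targets: list, cfg: LossConfig, with_grads: bool = False):
    """Reconstructive-contrastive loss over a batch of N subjects.

    ``L_R`` is the mean same-subject divergence; ``L_C`` averages
    d(prediction_i, target_j) over the (N^2 - N)/2 unordered cross pairs
    (i < j).  With N = 1 the contrastive term is undefined and the loss falls
    back to the reconstructive hinge alone (logged).

    Returns a :class:`LossReport`, and additionally the per-subject gradient
    arrays d L_RC / d prediction_i when ``with_grads`` is True.
    """
    N = len(predictions)
    if N != len(targets) or N < 1:
        raise ValueError("need matching non-empty prediction/target lists")
    d_same = [_masked_sq_diff(p, t, cfg) for p, t in zip(predictions, targets)]
    L_R = float(np.mean(d_same))

    pairs = [(i, j) for i in range(N) for j in range(i + 1, N)]
    if pairs:
        d_cross = {(i, j): _masked_sq_diff(predictions[i], targets[j], cfg) for i, j in pairs}
        L_C = float(np.mean(list(d_cross.values())))
    else:
        logger.info("batch of 1: contrastive term undefined, using reconstructive hinge only")
        L_C = float("nan")

    h1 = max(L_R - cfg.alpha, 0.0)
    h2 = max(L_R - L_C + cfg.gamma, 0.0) if pairs else 0.0
    report = LossReport(L_R=L_R, L_C=L_C, L_RC=h1 + h2, n=N)
    if not with_grads:
        return report

    dL_dLR = (1.0 if h1 > 0 else 0.0) + (1.0 if (pairs and h2 > 0) else 0.0)
    dL_dLC = -1.0 if (pairs and h2 > 0) else 0.0
    grads = []
    n_pairs = len(pairs) if pairs else 1
    for i in range(N):
        g = dL_dLR / N * _d_grad(predictions[i], targets[i], cfg)
        if dL_dLC != 0.0:
            for j in range(i + 1, N):
                g += dL_dLC / n_pairs * _d_grad(predictions[i], targets[j], cfg)
        grads.append(g)
    return report, grads


def mse_loss(predictions: list, targets: list, cfg: LossConfig, with_grads: bool = False):
    """Plain reconstructive loss L_R (phase-1 objective) and its gradients."""
    N = len(predictions)
    d_same = [_masked_sq_diff(p, t, cfg) for p, t in zip(predictions, targets)]
    L_R = float(np.mean(d_same))
    report = LossReport(L_R=L_R, L_C=float("nan"), L_RC=L_R, n=N)
    if not with_grads:
        return report
    grads = [_d_grad(p, t, cfg) / N for p, t in zip(predictions, targets)]
    return report, grads


def init_margins(model: SurfaceUNet, subjects: list, cfg: LossConfig | None = None,
                 rule: str = "gap"):
    """Initial margins from a converged phase-1 model.

    Computes the average reconstructive loss over all training subjects
    (L_R_bar) and the average cross-subject divergence over all unordered
    subject pairs (L_C_bar).  ``alpha0 = L_R_bar``; for gamma two rules exist:
    ``"gap"`` (default) sets ``gamma0 = max(L_C_bar - L_R_bar, 0)`` so the
    contrastive hinge starts exactly at its margin and can disengage once the
    gap is met; ``"absolute"`` sets ``gamma0 = L_C_bar``.
    """
    if len(subjects) < 2:
        raise ValueError("margin initialization needs at least 2 training subjects")
    cfg = cfg or LossConfig()
    preds = [model.forward(s["inputs"][0]) for s in subjects]
    targets = [s["target"] for s in subjects]
    L_R_bar = float(np.mean([_masked_sq_diff(p, t, cfg) for p, t in zip(preds, targets)]))
    cross = [
        _masked_sq_diff(preds[i], targets[j], cfg)
        for i in range(len(subjects))
        for j in range(i + 1, len(subjects))
    ]
    L_C_bar = float(np.mean(cross))
    if rule == "gap":
        gamma0 = max(L_C_bar - L_R_bar, 0.0)
    elif rule == "absolute":
        gamma0 = L_C_bar
    else:
        raise ValueError(f"unknown margin rule '{rule}'")
    return L_R_bar, gamma0


def margin_schedule(alpha0: float, gamma0: float, epoch: int, period: int = 20):
    """Margins at a phase-2 epoch: alpha halved and gamma doubled every ``period`` epochs."""
    k = epoch // period
    return alpha0 / 2 ** k, gamma0 * 2 ** k


class Adam:
    """Adam over a named parameter dict, skipping non-trainable entries."""

    def __init__(self, params: dict, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict, trainable: set):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for k in self.params:
            if k not in trainable:
                continue
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g ** 2
            self.params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def _batches(order, batch_size):
    for i in range(0, len(order), batch_size):
        yield order[i: i + batch_size]


def train(model: SurfaceUNet, subjects: list, phase_plan: list, seed: int,
          val_subjects: list | None = None, lr: float = 1e-3,
          loss_cfg: LossConfig | None = None, margin_rule: str = "gap",
          margin_period: int = 20):
    """Run a multi-phase training plan; returns (model, history).

    Parameters
    ----------
    subjects : list of dicts
        Each with ``"inputs"`` (list of (V, Cin) connectome arrays; one is
        randomly sampled per subject per epoch) and ``"target"`` ((V, C)
        contrast array).
    phase_plan : list of dicts
        Each with ``objective`` ("mse" or "rc"), ``epochs`` and
        ``batch_size``.  An "rc" phase initializes its margins from the
        current model unless ``alpha``/``gamma`` are given in the phase dict.
    seed : int
        Seeds connectome sampling and subject shuffling; training is
        deterministic (single-threaded) for a fixed seed.

    The best model (lowest validation loss; training loss when no validation
    set is given) is restored at the end.  History rows record per-epoch
    L_R / L_C / L_RC and the active margins.
    """
    if not subjects:
        raise ValueError("empty training cohort")
    rng = np.random.default_rng(seed)
    base_cfg = loss_cfg or LossConfig()
    opt = Adam(model.parameters(), lr=lr)
    history = []
    best = {"loss": np.inf, "state": model.state_dict()}

    for phase_idx, phase in enumerate(phase_plan):
        objective = phase["objective"]
        epochs = phase["epochs"]
        batch_size = phase.get("batch_size", 2)
        if objective == "rc":
            if batch_size < 2:
                raise ValueError("the contrastive term needs batch size >= 2")
            if "alpha" in phase and "gamma" in phase:
                alpha0, gamma0 = phase["alpha"], phase["gamma"]
            else:
                alpha0, gamma0 = init_margins(model, subjects, base_cfg, rule=margin_rule)
        for epoch in range(epochs):
            if objective == "rc":
                alpha, gamma = margin_schedule(alpha0, gamma0, epoch, period=margin_period)
            else:
                alpha, gamma = base_cfg.alpha, base_cfg.gamma
            cfg = LossConfig(alpha=alpha, gamma=gamma,
                             channel_mask=base_cfg.channel_mask,
                             vertex_mask=base_cfg.vertex_mask)
            order = rng.permutation(len(subjects))
            sample_idx = [rng.integers(len(s["inputs"])) for s in subjects]
            ep = {"L_R": [], "L_C": [], "L_RC": []}
            for batch in _batches(order, batch_size):
                model.zero_grad()
                preds, targets = [], []
                for si in batch:
                    s = subjects[si]
                    preds.append(model.forward(s["inputs"][sample_idx[si]]))
                    targets.append(s["target"])
                if objective == "rc":
                    report, grads = rc_loss(preds, targets, cfg, with_grads=True)
                else:
                    report, grads = mse_loss(preds, targets, cfg, with_grads=True)
                # forward caches are per-layer; re-run each forward just before
                # its backward so gradients use the right activations
                for si, g in zip(batch, grads):
                    s = subjects[si]
                    model.forward(s["inputs"][sample_idx[si]])
                    model.backward(g)
                opt.step(model.gradients(), model.trainable_param_names())
                ep["L_R"].append(report.L_R)
                ep["L_C"].append(report.L_C)
                ep["L_RC"].append(report.L_RC)
            row = {
                "phase": phase_idx,
                "objective": objective,
                "epoch": epoch,
                "L_R": float(np.mean(ep["L_R"])),
                "L_C": float(np.nanmean(ep["L_C"])) if not np.all(np.isnan(ep["L_C"])) else float("nan"),
                "L_RC": float(np.mean(ep["L_RC"])),
                "alpha": float(alpha),
                "gamma": float(gamma),
            }
            if val_subjects:
                vp = [ensemble_predict(model, s["inputs"]) for s in val_subjects]
                vt = [s["target"] for s in val_subjects]
                row["val_loss"] = mse_loss(vp, vt, cfg).L_R
            else:
                row["val_loss"] = row["L_RC"]
            history.append(row)
            if row["val_loss"] <= best["loss"]:
                best = {"loss": row["val_loss"], "state": model.state_dict()}
            logger.info(
                "phase %d (%s) epoch %d: L_R=%.5f L_C=%.5f L_RC=%.5f alpha=%.5f gamma=%.5f",
                phase_idx, objective, epoch, row["L_R"], row["L_C"], row["L_RC"], alpha, gamma,
            )
    model.load_state_dict(best["state"])
    return model, history


def finetune(model: SurfaceUNet, subjects: list, mode: str, seed: int,
             epochs: int = 20, batch_size: int = 2, lr: float = 1e-3,
             c_new: int | None = None, channel_mask: np.ndarray | None = None,
             vertex_mask: np.ndarray | None = None,
             val_subjects: list | None = None):
    """Adapt a pretrained model to a new cohort; MSE objective throughout.

    Modes
    -----
    "denovo"
        Ignore the pretrained weights: build a fresh model from the same spec
        with ``seed`` and train it (the random-initialization comparison arm).
    "full_with_new_head"
        Replace the head for ``c_new`` output contrasts and finetune all
        parameters (new-task-set transfer).
    "backbone_only"
        Freeze the head, finetune the backbone with the loss restricted to
        the unmasked channels; held-out (masked-out) channels contribute no
        gradient (leave-one-task-out transfer).
    """
    if mode == "denovo":
        spec = copy.deepcopy(model.spec)
        spec.seed = seed
        fresh = build_model(spec, meshes=model.meshes, ops=model.ops)
        cfg = LossConfig(channel_mask=channel_mask, vertex_mask=vertex_mask)
        return train(fresh, subjects,
                     [{"objective": "mse", "epochs": epochs, "batch_size": batch_size}],
                     seed=seed, lr=lr, loss_cfg=cfg, val_subjects=val_subjects)
    if mode == "full_with_new_head":
        if c_new is None:
            c_new = model.spec.out_channels
        replace_head(model, c_new, seed)
        set_trainable(model, {"backbone", "head"})
        cfg = LossConfig(channel_mask=channel_mask, vertex_mask=vertex_mask)
        return train(model, subjects,
                     [{"objective": "mse", "epochs": epochs, "batch_size": batch_size}],
                     seed=seed, lr=lr, loss_cfg=cfg, val_subjects=val_subjects)
    if mode == "backbone_only":
        if channel_mask is None or bool(np.all(channel_mask)):
            logger.warning("backbone_only finetuning without held-out channels")
        set_trainable(model, {"backbone"})
        cfg = LossConfig(channel_mask=channel_mask, vertex_mask=vertex_mask)
        out = train(model, subjects,
                    [{"objective": "mse", "epochs": epochs, "batch_size": batch_size}],
                    seed=seed, lr=lr, loss_cfg=cfg, val_subjects=val_subjects)
        set_trainable(model, {"backbone", "head"})
        return out
    raise ValueError(f"unknown finetuning mode '{mode}'")


def ensemble_predict(model: SurfaceUNet, connectomes: list) -> np.ndarray:
    """Test-time ensembling: vertex-wise mean prediction over connectomes."""
    if not connectomes:
        raise ValueError("need at least one connectome")
    out = model.forward(connectomes[0])
    for c in connectomes[1:]:
        out = out + model.forward(c)
    return out / len(connectomes)
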