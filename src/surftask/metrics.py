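"""Evaluation: thresholded Dice overlap, Dice AUC, whole-brain R^2,
subject identification, and reliability screening.

Dice at threshold fraction x compares the top-x% most activated vertex sets
of a prediction and its target; integrating Dice over x in {0.05, ..., 0.50}
with the composite trapezoidal rule gives the Dice AUC summary (0.45 for
perfect agreement, since the integration axis is the threshold fraction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "THRESHOLDS",
    "DiceCurve",
    "IdentMatrix",
    "top_frac_set",
    "dice_at",
    "dice_auc",
    "whole_brain_r2",
    "identification",
    "reliability_screen",
    "evaluation_report",
]

THRESHOLDS = np.round(np.arange(1, 11) * 0.05, 2)  # 0.05 ... 0.50


@dataclass
class DiceCurve:
    thresholds: np.ndarray
    dice: np.ndarray
    auc: float


@dataclass
class IdentMatrix:
    """N x N Dice-AUC matrix: rows = target subjects, columns = predictions."""

    auc_matrix: np.ndarray
    accuracy: float
    subjects: list


def _select_values(values: np.ndarray, mode: str) -> np.ndarray:
    if mode == "activated":
        return values
    if mode == "deactivated":
        return -values
    if mode == "absolute":
        return np.abs(values)
    raise ValueError(f"unknown activation mode '{mode}'")


def top_frac_set(values: np.ndarray, x: float, mask: np.ndarray | None = None,
                 mode: str = "activated") -> np.ndarray:
    """Indices of the top-x fraction most activated vertices.

    ``k = max(1, round(x * V_masked))`` with banker's rounding; ties resolve
    to the lower vertex index; masked-out vertices never enter the set.
    """
    values = np.asarray(values, dtype=np.float64)
    if not (0.0 < x <= 1.0):
        raise ValueError("threshold fraction must lie in (0, 1]")
    if mask is None:
        mask = np.ones(values.shape[0], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    candidates = np.flatnonzero(mask)
    if candidates.size == 0:
        raise ValueError("empty vertex mask")
    v = _select_values(values[candidates], mode)
    k = max(1, int(np.round(x * candidates.size)))
    order = np.argsort(-v, kind="stable")  # stable: lower index wins ties
    return np.sort(candidates[order[:k]])


def dice_at(pred: np.ndarray, target: np.ndarray, x: float,
            mask: np.ndarray | None = None, mode: str = "activated") -> float:
    """Dice overlap of the top-x% sets: 2|A n B| / (|A| + |B|)."""
    if np.asarray(pred).shape != np.asarray(target).shape:
        raise ValueError("prediction and target must share a mesh")
    a = top_frac_set(pred, x, mask, mode)
    b = top_frac_set(target, x, mask, mode)
    inter = np.intersect1d(a, b, assume_unique=True).size
    return 2.0 * inter / (a.size + b.size)


def dice_auc(pred: np.ndarray, target: np.ndarray, mask: np.ndarray | None = None,
             mode: str = "activated") -> DiceCurve:
    """Dice at the ten threshold fractions plus the trapezoidal AUC."""
    dice = np.array([dice_at(pred, target, x, mask, mode) for x in THRESHOLDS])
    auc = float(np.trapezoid(dice, THRESHOLDS))
    return DiceCurve(thresholds=THRESHOLDS.copy(), dice=dice, auc=auc)


def whole_brain_r2(pred: np.ndarray, target: np.ndarray,
                   mask: np.ndarray | None = None):
    """Coefficient of determination over masked vertices, per contrast.

    ``1 - sum((t - p)^2) / sum((t - mean(t))^2)``; a zero-variance target
    yields NaN for that contrast.  Returns (per-contrast array, mean).
    """
    pred = np.atleast_2d(np.asarray(pred, dtype=np.float64).T).T
    target = np.atleast_2d(np.asarray(target, dtype=np.float64).T).T
    if pred.shape != target.shape:
        raise ValueError("prediction and target must share a mesh")
    if mask is not None:
        pred = pred[np.asarray(mask, dtype=bool)]
        target = target[np.asarray(mask, dtype=bool)]
    ss_res = np.sum((target - pred) ** 2, axis=0)
    ss_tot = np.sum((target - target.mean(axis=0)) ** 2, axis=0)
    r2 = np.full(pred.shape[1], np.nan)
    ok = ss_tot > 0
    r2[ok] = 1.0 - ss_res[ok] / ss_tot[ok]
    mean = float(np.mean(r2[ok])) if ok.any() else float("nan")
    return r2, mean


def identification(preds: list, targets: list, contrast: int = 0,
                   mask: np.ndarray | None = None, subjects: list | None = None,
                   mode: str = "activated") -> IdentMatrix:
    """Subject identification from predicted maps.

    Entry (i, j) is the Dice AUC between subject j's prediction and subject
    i's target for the given contrast.  A subject is identified when its
    column's strict maximum sits on the diagonal; ties count as failures.
    """
    if len(preds) != len(targets) or len(preds) < 2:
        raise ValueError("need >= 2 subjects with matching predictions and targets")
    N = len(preds)
    mat = np.empty((N, N))
    for i in range(N):
        for j in range(N):
            mat[i, j] = dice_auc(preds[j].data[:, contrast], targets[i].data[:, contrast],
                                 mask, mode).auc
    hits = 0
    for j in range(N):
        col = mat[:, j]
        others = np.delete(col, j)
        if col[j] > others.max():
            hits += 1
    if subjects is None:
        subjects = [getattr(t, "subject", str(i)) for i, t in enumerate(targets)]
    return IdentMatrix(auc_matrix=mat, accuracy=hits / N, subjects=list(subjects))


def reliability_screen(targets: list, repeats: list, group_avg,
                       mask: np.ndarray | None = None) -> np.ndarray:
    """Flag individual-level reliable contrasts.

    A contrast is reliable when the mean (over test subjects) target-repeat
    Dice AUC exceeds the mean target-group-average Dice AUC, i.e. the repeat
    scan resembles the target better than the population mean does.
    """
    if len(targets) != len(repeats) or not targets:
        raise ValueError("each subject needs both a target and a repeat visit")
    C = targets[0].n_contrasts
    flags = np.zeros(C, dtype=bool)
    for c in range(C):
        rep = np.mean([
            dice_auc(r.data[:, c], t.data[:, c], mask).auc
            for t, r in zip(targets, repeats)
        ])
        grp = np.mean([
            dice_auc(group_avg.data[:, c], t.data[:, c], mask).auc
            for t in targets
        ])
        flags[c] = rep > grp
    return flags


def evaluation_report(rows: list) -> pd.DataFrame:
    """Tidy evaluation table: one row per (subject, contrast, comparator).

    Each input row is a dict with ``subject``, ``contrast``, ``comparator``,
    a :class:`DiceCurve` under ``curve`` and optionally ``r2``.
    """
    records = []
    for r in rows:
        rec = {"subject": r["subject"], "contrast": r["contrast"],
               "comparator": r["comparator"]}
        curve = r["curve"]
        for x, d in zip(curve.thresholds, curve.dice):
            rec[f"dice@{x:.2f}"] = d
        rec["auc"] = curve.auc
        if "r2" in r:
            rec["r2"] = r["r2"]
        records.append(rec)
    return pd.DataFrame.from_records(records)
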