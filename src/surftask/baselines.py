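"""Reference predictors: group-average maps and the ensembled parcel-wise
linear regression.

The linear baseline fits, for every training subject and every parcel, a
least-squares map from the subject's vertex-to-ROI connectivity features
(rows = parcel vertices, columns = ROIs) to the subject's activation values
in that parcel, with no intercept.  Test predictions use the coefficient
vectors averaged over training subjects, which by linearity equals the
average of the per-subject-model predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectome import Connectome, ParcellationLabels
from .surface_io import ContrastMaps

__all__ = ["ParcelLinearModel", "fit_parcel_linear", "predict_parcel_linear", "group_average"]

_PINV_RCOND = 1e-10


@dataclass
class ParcelLinearModel:
    """Averaged per-parcel regression coefficients.

    ``beta[k]`` has shape (M_features, C); ``n_vertices[k]`` is the parcel
    size used at fit time.
    """

    beta: dict
    n_features: int
    n_contrasts: int
    n_train: int
    contrast_names: list
    parcel_ids: list


def _parcel_vertices(parc: ParcellationLabels, mask: np.ndarray):
    out = {}
    labels = parc.labels.copy()
    labels[~mask] = -1
    for k in range(parc.n_rois):
        members = np.flatnonzero(labels == k)
        if members.size == 0:
            raise ValueError(f"parcel {k} has no member vertices")
        out[k] = members
    return out


def fit_parcel_linear(connectomes: list, targets: list, parc: ParcellationLabels,
                      intercept: bool = False) -> ParcelLinearModel:
    """Fit and ensemble the parcel-wise linear baseline.

    For subject i and parcel k, solve ``y_ik = X_ik beta_ik`` by minimum-norm
    least squares (pseudoinverse, relative cutoff 1e-10, no intercept unless
    requested), then average ``beta_ik`` over training subjects.  All
    contrasts are solved against the same feature matrix, one column of
    coefficients per contrast.
    """
    if len(connectomes) != len(targets) or not connectomes:
        raise ValueError("need matching, non-empty connectome/target lists")
    mask = connectomes[0].vertex_mask
    parcels = _parcel_vertices(parc, mask)
    M = connectomes[0].n_channels + (1 if intercept else 0)
    C = targets[0].n_contrasts
    beta_sum = {k: np.zeros((M, C)) for k in parcels}
    for conn, tgt in zip(connectomes, targets):
        for k, verts in parcels.items():
            X = conn.data[verts]
            if intercept:
                X = np.column_stack([X, np.ones(len(verts))])
            Y = tgt.data[verts]
            beta_sum[k] += np.linalg.pinv(X, rcond=_PINV_RCOND) @ Y
    n = len(connectomes)
    return ParcelLinearModel(
        beta={k: b / n for k, b in beta_sum.items()},
        n_features=M,
        n_contrasts=C,
        n_train=n,
        contrast_names=list(targets[0].names),
        parcel_ids=sorted(parcels),
    )


def predict_parcel_linear(model: ParcelLinearModel, connectome: Connectome,
                          parc: ParcellationLabels) -> ContrastMaps:
    """Predict a test subject's contrast maps from its connectome features."""
    intercept = model.n_features == connectome.n_channels + 1
    if not intercept and model.n_features != connectome.n_channels:
        raise ValueError(
            f"feature mismatch: model expects {model.n_features}, connectome has {connectome.n_channels}"
        )
    parcels = _parcel_vertices(parc, connectome.vertex_mask)
    out = np.zeros((connectome.data.shape[0], model.n_contrasts))
    for k, verts in parcels.items():
        X = connectome.data[verts]
        if intercept:
            X = np.column_stack([X, np.ones(len(verts))])
        out[verts] = X @ model.beta[k]
    return ContrastMaps(out, names=model.contrast_names, subject=connectome.subject,
                        vertex_mask=connectome.vertex_mask)


def group_average(targets: list) -> ContrastMaps:
    """Vertex-wise mean contrast maps over a cohort (the naive reference)."""
    if not targets:
        raise ValueError("empty cohort")
    data = np.mean([t.data for t in targets], axis=0)
    return ContrastMaps(data, names=list(targets[0].names), subject="group_average",
                        vertex_mask=targets[0].vertex_mask)
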