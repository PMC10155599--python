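"""Vertex-to-ROI functional connectomes.

The connectome of a subject is a multi-channel field on the mesh: channel j
at vertex i holds the Pearson correlation between the vertex's resting-state
timeseries and the mean timeseries of ROI j.  ROIs come from a winner-take-all
assignment of vertices to parcellation component maps (highest z-score wins).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .surface_io import SurfaceTimeseries

logger = logging.getLogger(__name__)

__all__ = [
    "ParcellationLabels",
    "Connectome",
    "winner_take_all",
    "roi_mean_timeseries",
    "vertex_to_roi_fc",
    "concat_hemispheres",
    "split_segments",
    "normalize_channels",
]


@dataclass
class ParcellationLabels:
    """Vertex labels in [0, M) (-1 = unassigned) plus optional source z-maps."""

    labels: np.ndarray
    n_rois: int
    zmaps: np.ndarray = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        assigned = self.labels[self.labels >= 0]
        if assigned.size and assigned.max() >= self.n_rois:
            raise ValueError("label exceeds ROI count")


@dataclass
class Connectome:
    """Per-subject V x M (or V x 2M bilateral) correlation field."""

    data: np.ndarray
    channel_names: list
    subject: str = ""
    vertex_mask: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.vertex_mask is None:
            self.vertex_mask = np.ones(self.data.shape[0], dtype=bool)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("connectome contains non-finite values")
        if np.any(np.abs(self.data) > 1.0 + 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


def winner_take_all(zmaps: np.ndarray, vertex_mask: np.ndarray | None = None,
                    z_floor: float | None = None) -> ParcellationLabels:
    """Assign each vertex to the component with the highest z-score.

    Ties break to the lowest component index.  Vertices outside
    ``vertex_mask`` (or below ``z_floor`` everywhere, if given) get label -1.
    """
    zmaps = np.asarray(zmaps, dtype=np.float64)
    if zmaps.ndim != 2 or zmaps.shape[1] < 1:
        raise ValueError("zmaps must be V x M with M >= 1")
    if not np.all(np.isfinite(zmaps)):
        raise ValueError("zmaps contain non-finite values")
    labels = np.argmax(zmaps, axis=1).astype(np.int64)  # argmax = lowest index on ties
    if z_floor is not None:
        labels[np.max(zmaps, axis=1) < z_floor] = -1
    if vertex_mask is not None:
        labels[~np.asarray(vertex_mask, dtype=bool)] = -1
    return ParcellationLabels(labels=labels, n_rois=zmaps.shape[1], zmaps=zmaps)


def roi_mean_timeseries(ts: SurfaceTimeseries, parc: ParcellationLabels) -> np.ndarray:
    """Unweighted mean timeseries per ROI, shape (M, T).

    Raises ValueError naming the ROI if any ROI has no member vertex (after
    masking).
    """
    labels = parc.labels.copy()
    labels[~ts.vertex_mask] = -1
    M, T = parc.n_rois, ts.n_timepoints
    out = np.empty((M, T))
    for j in range(M):
        members = labels == j
        if not members.any():
            raise ValueError(f"ROI {j} has no member vertices")
        out[j] = ts.data[members].mean(axis=0)
    return out


def _standardize_rows(x: np.ndarray):
    """Center rows and scale to unit norm; zero-variance rows become zero."""
    xc = x - x.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(xc, axis=1, keepdims=True)
    degenerate = norm[:, 0] <= 1e-300
    norm[degenerate] = 1.0
    return xc / norm, degenerate


def vertex_to_roi_fc(ts: SurfaceTimeseries, roi_ts: np.ndarray,
                     subject: str = "", channel_prefix: str = "roi") -> Connectome:
    """Pearson correlation of every vertex series with every ROI mean series.

    Zero-variance vertex or ROI series yield correlation 0 (logged) instead
    of NaN, keeping downstream tensors finite.
    """
    roi_ts = np.asarray(roi_ts, dtype=np.float64)
    if roi_ts.shape[1] != ts.n_timepoints:
        raise ValueError(
            f"timepoint mismatch: vertices have T={ts.n_timepoints}, ROIs T={roi_ts.shape[1]}"
        )
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints for a meaningful correlation")
    v_std, v_bad = _standardize_rows(ts.data)
    r_std, r_bad = _standardize_rows(roi_ts)
    n_bad = int(v_bad.sum() + r_bad.sum())
    if n_bad:
        logger.warning("%d degenerate (constant) series set to r=0", n_bad)
    corr = np.clip(v_std @ r_std.T, -1.0, 1.0)
    names = [f"{channel_prefix}{j}" for j in range(roi_ts.shape[0])]
    return Connectome(data=corr, channel_names=names, subject=subject,
                      vertex_mask=ts.vertex_mask)


def concat_hemispheres(left: Connectome, right: Connectome) -> Connectome:
    """Stack left and right hemisphere connectomes channel-wise (left first).

    Relies on the convention that identical vertex indices are contralateral
    homologs; channel names get L/R suffixes, giving 2M channels.
    """
    if left.data.shape != right.data.shape:
        raise ValueError("hemisphere connectomes must share V and M")
    data = np.concatenate([left.data, right.data], axis=1)
    names = [f"{n}_L" for n in left.channel_names] + [f"{n}_R" for n in right.channel_names]
    return Connectome(data=data, channel_names=names, subject=left.subject,
                      vertex_mask=left.vertex_mask & right.vertex_mask)


def split_segments(runs: list, scheme: str = "halves", length: int | None = None,
                   count: int | None = None, seed: int | None = None) -> list:
    """Cut resting-state runs into contiguous segments for augmentation.

    schemes
    -------
    "halves"
        Two non-overlapping halves per run (a 4-run, 1200-timepoint subject
        yields 8 segments of 600).
    "fixed"
        ``floor(T / length)`` non-overlapping segments of ``length`` per run.
    "random"
        ``count`` seeded random contiguous windows of ``length`` per run.
    """
    out = []
    rng = np.random.default_rng(seed) if scheme == "random" else None
    for ts in runs:
        T = ts.n_timepoints
        if scheme == "halves":
            half = T // 2
            windows = [(0, half), (half, 2 * half)]
        elif scheme == "fixed":
            if length is None or length > T:
                raise ValueError(f"segment length {length} exceeds run length {T}")
            windows = [(k * length, (k + 1) * length) for k in range(T // length)]
        elif scheme == "random":
            if length is None or length > T:
                raise ValueError(f"segment length {length} exceeds run length {T}")
            if count is None:
                raise ValueError("random scheme needs a segment count")
            starts = rng.integers(0, T - length + 1, size=count)
            windows = [(int(s), int(s) + length) for s in starts]
        else:
            raise ValueError(f"unknown segmentation scheme '{scheme}'")
        for a, b in windows:
            out.append(SurfaceTimeseries(ts.data[:, a:b], hemisphere=ts.hemisphere,
                                         tr=ts.tr, vertex_mask=ts.vertex_mask))
    return out


def normalize_channels(connectomes: list, stats: dict | None = None):
    """Per-channel z-scoring across a set of connectomes.

    Without ``stats``, channel means/sds are computed over all given
    connectomes (training mode) and returned for reuse; with ``stats``, the
    provided training statistics are applied (evaluation mode).  Zero-sd
    channels are left unscaled.
    """
    stacked = np.concatenate([c.data for c in connectomes], axis=0)
    if stats is None:
        mean = stacked.mean(axis=0)
        sd = stacked.std(axis=0)
        bad = sd <= 1e-12
        if bad.any():
            logger.warning("%d zero-variance channels left unscaled", int(bad.sum()))
        sd = np.where(bad, 1.0, sd)
        stats = {"mean": mean, "sd": sd}
    mean = np.asarray(stats["mean"])
    sd = np.asarray(stats["sd"])
    out = []
    for c in connectomes:
        z = (c.data - mean) / sd
        cc = Connectome.__new__(Connectome)
        cc.data = z
        cc.channel_names = list(c.channel_names)
        cc.subject = c.subject
        cc.vertex_mask = c.vertex_mask
        out.append(cc)
    return out, stats
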