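"""Surface-mapped data containers and GIFTI/CIFTI-2 adapters.

Internal convention: 0-based vertex indexing everywhere; data arrays are full
surface length V with a boolean ``vertex_mask`` marking cortex (True) versus
medial-wall/excluded vertices (False).  CIFTI files that store only masked-in
vertices are expanded back to full-surface indexing on load.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "SurfaceTimeseries",
    "ContrastMaps",
    "read_surface_data",
    "write_surface_data",
    "resample_nearest",
    "write_cohort_dir",
    "read_cohort_dir",
]


class FormatError(ValueError):
    """Raised when a surface file cannot be interpreted."""


@dataclass
class SurfaceTimeseries:
    """Per-hemisphere vertex x time resting-state series.

    ``data`` is (V, T); ``hemisphere`` is "L", "R" or "single"; ``tr`` is the
    repetition time in seconds.
    """

    data: np.ndarray
    hemisphere: str = "single"
    tr: float = 1.0
    vertex_mask: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[1] < 2:
            raise ValueError("timeseries must be V x T with T >= 2")
        if self.vertex_mask is None:
            self.vertex_mask = np.ones(self.data.shape[0], dtype=bool)
        self.vertex_mask = np.asarray(self.vertex_mask, dtype=bool)
        if self.vertex_mask.shape[0] != self.data.shape[0]:
            raise ValueError("vertex_mask length must equal V")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("timeseries contains non-finite values")

    @property
    def n_vertices(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class ContrastMaps:
    """Multi-channel vertex map: one channel per task contrast (V, C)."""

    data: np.ndarray
    names: list = None
    subject: str = ""
    vertex_mask: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim == 1:
            self.data = self.data[:, None]
        if self.data.shape[1] < 1:
            raise ValueError("need at least one contrast channel")
        if self.names is None:
            self.names = [f"contrast{i}" for i in range(self.data.shape[1])]
        self.names = list(self.names)
        if len(self.names) != self.data.shape[1]:
            raise ValueError("one name per channel required")
        if len(set(self.names)) != len(self.names):
            raise ValueError("contrast names must be unique")
        if self.vertex_mask is None:
            self.vertex_mask = np.ones(self.data.shape[0], dtype=bool)
        self.vertex_mask = np.asarray(self.vertex_mask, dtype=bool)

    @property
    def n_vertices(self) -> int:
        return self.data.shape[0]

    @property
    def n_contrasts(self) -> int:
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# GIFTI / CIFTI-2 adapters
# ---------------------------------------------------------------------------

def _load_gifti(path: Path, kind: str):
    import nibabel as nib

    img = nib.load(str(path))
    arrays = [np.asarray(d.data, dtype=np.float64) for d in img.darrays]
    if not arrays:
        raise FormatError(f"{path}: GIFTI file holds no data arrays")
    data = np.column_stack([a.ravel() for a in arrays])
    names = []
    for i, d in enumerate(img.darrays):
        name = d.meta.get("Name") if d.meta else None
        names.append(name if name else f"map{i}")
    for i, col in enumerate(data.T):
        if not np.all(np.isfinite(col)):
            raise FormatError(f"{path}: map '{names[i]}' contains non-finite values")
    if kind == "timeseries":
        return SurfaceTimeseries(data)
    return ContrastMaps(data, names=names)


def _load_cifti(path: Path, kind: str):
    import nibabel as nib
    from nibabel.cifti2 import cifti2_axes

    img = nib.load(str(path))
    mat = np.asarray(img.get_fdata(), dtype=np.float64)  # rows x brain-model
    ax0 = img.header.get_axis(0)
    ax1 = img.header.get_axis(1)
    if not isinstance(ax1, cifti2_axes.BrainModelAxis):
        raise FormatError(f"{path}: second CIFTI axis is not a brain-model axis")
    n_full = int(ax1.nvertices[next(iter(ax1.nvertices))])
    full = np.zeros((n_full, mat.shape[0]))
    mask = np.zeros(n_full, dtype=bool)
    vtx = ax1.vertex
    full[vtx, :] = mat.T
    mask[vtx] = True

    if isinstance(ax0, cifti2_axes.SeriesAxis):
        if kind == "maps":
            raise FormatError(f"{path}: dtseries file requested as contrast maps")
        return SurfaceTimeseries(full, tr=float(ax0.step), vertex_mask=mask)
    names = list(getattr(ax0, "name", [f"map{i}" for i in range(mat.shape[0])]))
    for i in range(full.shape[1]):
        if not np.all(np.isfinite(full[mask, i])):
            raise FormatError(f"{path}: map '{names[i]}' contains non-finite values")
    if kind == "timeseries":
        return SurfaceTimeseries(full, vertex_mask=mask)
    return ContrastMaps(full, names=names, vertex_mask=mask)


def read_surface_data(path, kind: str = "auto", n_vertices: int | None = None):
    """Load a GIFTI (.func.gii/.shape.gii) or CIFTI-2 (.dtseries.nii/.dscalar.nii) file.

    Parameters
    ----------
    kind : {"auto", "timeseries", "maps"}
        What to return; "auto" infers from the file suffix.
    n_vertices : int, optional
        Expected full-surface vertex count; a mismatch raises FormatError.
    """
    path = Path(path)
    name = path.name
    if kind == "auto":
        if name.endswith(".dtseries.nii"):
            kind = "timeseries"
        elif name.endswith(".dscalar.nii"):
            kind = "maps"
        elif name.endswith(".func.gii"):
            kind = "timeseries"
        elif name.endswith((".shape.gii", ".label.gii")):
            kind = "maps"
        else:
            raise FormatError(f"{path}: cannot infer data kind from suffix")
    if name.endswith(".nii"):
        out = _load_cifti(path, kind)
    elif name.endswith(".gii"):
        out = _load_gifti(path, kind)
    else:
        raise FormatError(f"{path}: unknown surface format")
    if n_vertices is not None and out.data.shape[0] != n_vertices:
        raise FormatError(
            f"{path}: has {out.data.shape[0]} vertices, expected {n_vertices}"
        )
    return out


def write_surface_data(obj, path) -> None:
    """Write a SurfaceTimeseries or ContrastMaps to GIFTI or CIFTI-2 by suffix."""
    import nibabel as nib
    from nibabel.cifti2 import cifti2_axes

    path = Path(path)
    name = path.name
    if name.endswith(".gii"):
        darrays = []
        if isinstance(obj, ContrastMaps):
            for i in range(obj.n_contrasts):
                d = nib.gifti.GiftiDataArray(
                    obj.data[:, i].astype(np.float32), intent="NIFTI_INTENT_NONE"
                )
                d.meta = nib.gifti.GiftiMetaData({"Name": obj.names[i]})
                darrays.append(d)
        else:
            for t in range(obj.n_timepoints):
                darrays.append(
                    nib.gifti.GiftiDataArray(
                        obj.data[:, t].astype(np.float32), intent="NIFTI_INTENT_TIME_SERIES"
                    )
                )
        nib.save(nib.gifti.GiftiImage(darrays=darrays), str(path))
        return
    if name.endswith((".dtseries.nii", ".dscalar.nii")):
        mask = obj.vertex_mask
        bm = cifti2_axes.BrainModelAxis.from_mask(
            mask, name="CIFTI_STRUCTURE_CORTEX_LEFT"
        )
        dense = obj.data[mask].T  # rows x vertices-in-mask
        if isinstance(obj, ContrastMaps):
            ax0 = cifti2_axes.ScalarAxis(obj.names)
        else:
            ax0 = cifti2_axes.SeriesAxis(start=0.0, step=obj.tr, size=obj.n_timepoints)
        img = nib.cifti2.Cifti2Image(dense, header=(ax0, bm))
        nib.save(img, str(path))
        return
    raise FormatError(f"{path}: unknown output format")


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_nearest(data: np.ndarray, source_vertices: np.ndarray, target_vertices: np.ndarray) -> np.ndarray:
    """Nearest-neighbour resampling between unit spheres.

    Each target vertex takes the value of its nearest source vertex by
    great-circle distance (equivalently chordal distance on the unit sphere);
    exact ties resolve to the lowest source index.
    """
    source_vertices = np.asarray(source_vertices, dtype=np.float64)
    target_vertices = np.asarray(target_vertices, dtype=np.float64)
    if source_vertices.size == 0:
        raise ValueError("empty source vertex set")
    # cosine similarity: larger is closer; argmax returns lowest index on ties
    sim = target_vertices @ source_vertices.T
    idx = np.argmax(sim, axis=1)
    return np.asarray(data)[idx]


# ---------------------------------------------------------------------------
# Cohort directory container
# ---------------------------------------------------------------------------

def write_cohort_dir(root, subjects: dict, tr: float = 1.0) -> None:
    """Write a cohort as one directory per subject plus a JSON manifest.

    ``subjects`` maps subject id -> dict with keys ``runs`` (list of
    SurfaceTimeseries) and ``visits`` (list of ContrastMaps).
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    manifest = {"tr": tr, "subjects": {}}
    for sid, entry in subjects.items():
        sdir = root / sid
        sdir.mkdir(exist_ok=True)
        runs, visits = [], []
        for i, ts in enumerate(entry["runs"]):
            fn = f"rest_run{i}.func.gii"
            write_surface_data(ts, sdir / fn)
            runs.append(fn)
        for i, cm in enumerate(entry["visits"]):
            fn = f"task_visit{i}.dscalar.nii"
            write_surface_data(cm, sdir / fn)
            visits.append(fn)
        manifest["subjects"][sid] = {"runs": runs, "visits": visits}
    (root / "cohort.json").write_text(json.dumps(manifest, indent=2))


def read_cohort_dir(root) -> dict:
    """Inverse of :func:`write_cohort_dir`."""
    root = Path(root)
    manifest = json.loads((root / "cohort.json").read_text())
    out = {}
    for sid, entry in manifest["subjects"].items():
        runs = [read_surface_data(root / sid / fn, kind="timeseries") for fn in entry["runs"]]
        visits = []
        for fn in entry["visits"]:
            cm = read_surface_data(root / sid / fn, kind="maps")
            cm.subject = sid
            visits.append(cm)
        out[sid] = {"runs": runs, "visits": visits}
    return out
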