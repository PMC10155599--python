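"""Seeded synthetic rest/task cohorts on the icosphere with known ground truth.

Each subject carries a low-dimensional latent fingerprint z_i.  Resting-state
vertex timeseries arise from latent ROI signals mixed through subject-specific
loadings (base spatial profile plus fingerprint-weighted smooth basis fields),
so the vertex-to-ROI correlation structure encodes z_i.  Task contrast maps
are a smooth group template plus a fingerprint-coupled deviation plus
visit-specific scan noise; a second visit shares the signal and differs only
in noise.  The rest->task link is linear in z by default; the ``nonlinear``
switch adds quadratic latent features to the coupling, creating the regime
where a nonlinear predictor can beat the parcel-wise linear baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .icomesh import SphereMesh, build_icosphere
from .surface_io import SurfaceTimeseries, ContrastMaps
from .connectome import (
    winner_take_all,
    roi_mean_timeseries,
    vertex_to_roi_fc,
    split_segments,
)

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "SyntheticCohort",
    "make_cohort",
    "oracle_predictor",
    "smoothing_operator",
    "build_connectome_inputs",
]


@dataclass
class CohortConfig:
    """Generator settings; the defaults define the package's study conditions.

    ``beta`` scales the latent fingerprint (z_i ~ N(0, beta^2 I)),
    ``sigma_ts`` the per-timepoint rest noise, ``sigma_scan`` the per-visit
    contrast scan noise, ``smooth_iters`` the iterated one-ring averaging
    applied to templates, deviations and contrast maps.
    """

    level: int = 3
    n_subjects: int = 50
    n_rois: int = 10
    n_contrasts: int = 6
    n_latent: int = 3
    n_timepoints: int = 400
    n_runs: int = 2
    visits: int = 2
    beta: float = 1.0
    sigma_ts: float = 0.4
    sigma_scan: float = 0.35
    smooth_iters: int = 2
    template_scale: float = 1.0
    deviation_scale: float = 1.2
    template_shift: float = 0.0
    # 0..1: how far the rest-data fingerprint encoding (loading basis fields)
    # rotates away from the structure-seed population; models site effects on
    # how individual differences manifest in the connectome
    fingerprint_shift: float = 0.0
    # contrasts share underlying activation systems: fraction of each
    # template/coupling field's variance carried by n_systems shared spatial
    # components (task batteries probe overlapping networks)
    contrast_share: float = 0.7
    n_systems: int = 3
    nonlinear: bool = False
    seed: int = 0
    # structural fields (parcellation, templates, coupling, loadings) are drawn
    # from structure_seed (default: seed); keeping it fixed while varying seed
    # yields a new cohort from the same "population" — the domain-shift setting
    structure_seed: int = None

    def __post_init__(self):
        if self.n_latent > self.n_rois:
            raise ValueError("n_latent must not exceed n_rois")
        if self.visits < 1:
            raise ValueError("need at least one visit")
        for name in ("n_subjects", "n_rois", "n_contrasts", "n_latent",
                     "n_timepoints", "n_runs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("beta", "sigma_ts", "sigma_scan", "template_scale",
                     "deviation_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class GroundTruth:
    """Everything the generator knows and the pipeline must not read."""

    z: np.ndarray                 # (n_subjects, K) latent fingerprints
    templates: np.ndarray         # (V, C) group templates
    coupling: np.ndarray          # (n_features, V, C) deviation fields
    feature_names: list           # latent feature labels matching coupling
    labels: np.ndarray            # (V,) ROI labels
    seeds: np.ndarray             # (M,) seed vertex indices
    base_loadings: np.ndarray     # (V, M)
    basis: np.ndarray             # (K, V, M) fingerprint loading basis


@dataclass
class SyntheticCohort:
    config: CohortConfig
    mesh: SphereMesh
    zmaps: np.ndarray             # (V, M) parcellation z-score maps
    subjects: list                # dicts: id, runs (SurfaceTimeseries), visits (ContrastMaps)


def smoothing_operator(mesh: SphereMesh) -> sp.csr_matrix:
    """One iteration of one-ring averaging (vertex plus its ring, equal weights)."""
    rows, cols, vals = [], [], []
    for v, ring in enumerate(mesh.one_ring):
        k = len(ring) + 1
        rows += [v] * k
        cols += [v] + list(ring)
        vals += [1.0 / k] * k
    V = mesh.n_vertices
    return sp.csr_matrix((vals, (rows, cols)), shape=(V, V))


def _smooth(S: sp.csr_matrix, x: np.ndarray, iters: int) -> np.ndarray:
    for _ in range(iters):
        x = S @ x
    return x


def _farthest_point_seeds(mesh: SphereMesh, m: int, rng) -> np.ndarray:
    """Greedy farthest-point sampling by great-circle distance."""
    start = int(rng.integers(mesh.n_vertices))
    seeds = [start]
    cos_min = mesh.vertices @ mesh.vertices[start]
    for _ in range(m - 1):
        nxt = int(np.argmin(cos_min))  # farthest = smallest cosine
        seeds.append(nxt)
        cos_min = np.maximum(cos_min, mesh.vertices @ mesh.vertices[nxt])
    return np.array(seeds, dtype=np.int64)


def _latent_features(z_row: np.ndarray, beta: float, nonlinear: bool) -> np.ndarray:
    """Standardized latent features driving the task deviation.

    Linear mode: z / beta.  Nonlinear mode additionally includes the
    centered squares and pairwise products of the standardized latents, all
    approximately unit-variance.
    """
    u = z_row / beta if beta > 0 else z_row
    feats = [u]
    if nonlinear:
        feats.append((u ** 2 - 1.0) / np.sqrt(2.0))
        K = u.shape[0]
        prods = [u[i] * u[j] for i in range(K) for j in range(i + 1, K)]
        if prods:
            feats.append(np.array(prods))
    return np.concatenate(feats)


def _feature_names(K: int, nonlinear: bool) -> list:
    names = [f"z{k}" for k in range(K)]
    if nonlinear:
        names += [f"z{k}^2" for k in range(K)]
        names += [f"z{i}*z{j}" for i in range(K) for j in range(i + 1, K)]
    return names


def _ar1(rng, shape, phi=0.5):
    """Stationary AR(1) rows (last axis = time), unit marginal variance."""
    *lead, T = shape
    x = np.empty(shape)
    innov_sd = np.sqrt(1 - phi ** 2)
    x[..., 0] = rng.normal(0.0, 1.0, size=lead)
    eps = rng.normal(0.0, innov_sd, size=shape)
    for t in range(1, T):
        x[..., t] = phi * x[..., t - 1] + eps[..., t]
    return x


def make_cohort(cfg: CohortConfig):
    """Generate a cohort; returns (SyntheticCohort, GroundTruth).

    Bit-identical for a fixed config (all randomness from ``cfg.seed``).
    """
    rng = np.random.default_rng(cfg.seed)
    rng_s = np.random.default_rng(
        cfg.seed if cfg.structure_seed is None else cfg.structure_seed)
    mesh = build_icosphere(cfg.level)
    V, M, C, K = mesh.n_vertices, cfg.n_rois, cfg.n_contrasts, cfg.n_latent
    S = smoothing_operator(mesh)

    # -- parcellation: seeds, labels, synthetic z-score bumps ---------------
    seeds = _farthest_point_seeds(mesh, M, rng_s)
    cosd = mesh.vertices @ mesh.vertices[seeds].T          # (V, M)
    arc = np.arccos(np.clip(cosd, -1.0, 1.0))
    labels = np.argmin(arc, axis=1).astype(np.int64)       # nearest seed
    width = 0.5 * np.median(np.sort(arc, axis=1)[:, 1])    # typical seed spacing
    zmaps = 3.0 * np.exp(-arc ** 2 / (2 * width ** 2))
    zmaps += 0.001 * rng_s.standard_normal(zmaps.shape)    # tiny z-score noise

    # -- ground-truth fields -------------------------------------------------
    def correlated_fields(rng_fields):
        """(V, C) smooth field whose channels share n_systems components."""
        unique = _smooth(S, rng_fields.standard_normal((V, C)), cfg.smooth_iters)
        if cfg.contrast_share <= 0:
            return unique
        systems = _smooth(S, rng_fields.standard_normal((V, cfg.n_systems)),
                          cfg.smooth_iters)
        mix = rng_fields.standard_normal((cfg.n_systems, C))
        mix /= np.linalg.norm(mix, axis=0, keepdims=True)
        w = cfg.contrast_share
        return np.sqrt(w) * systems @ mix + np.sqrt(1 - w) * unique

    templates = cfg.template_scale * correlated_fields(rng_s)
    if cfg.template_shift > 0:
        # acquisition/site shift: a smooth spatial field shared by all
        # contrasts (scanner and preprocessing effects hit every contrast
        # alike), drawn from the cohort's own seed
        shared = _smooth(S, rng.standard_normal((V, 1)), cfg.smooth_iters)
        templates = templates + cfg.template_shift * shared
    feat_names = _feature_names(K, cfg.nonlinear)
    F = len(feat_names)
    coupling = np.stack([correlated_fields(rng_s) for _ in range(F)])  # (F, V, C)
    base = np.exp(-arc ** 2 / (2 * (1.2 * width) ** 2))     # (V, M) own-ROI profile
    basis = 0.4 * np.stack([
        _smooth(S, rng_s.standard_normal((V, M)), cfg.smooth_iters) for _ in range(K)
    ])                                                      # (K, V, M)
    if cfg.fingerprint_shift > 0:
        w = cfg.fingerprint_shift
        fresh = 0.4 * np.stack([
            _smooth(S, rng.standard_normal((V, M)), cfg.smooth_iters)
            for _ in range(K)
        ])
        basis = np.sqrt(1 - w ** 2) * basis + w * fresh  # variance-preserving mix
    z = cfg.beta * rng.standard_normal((cfg.n_subjects, K))

    # -- per-subject data ----------------------------------------------------
    subjects = []
    for i in range(cfg.n_subjects):
        W = base + np.tensordot(z[i], basis, axes=(0, 0))   # (V, M)
        runs = []
        for _ in range(cfg.n_runs):
            signals = _ar1(rng, (M, cfg.n_timepoints))
            data = W @ signals
            data = data + cfg.sigma_ts * rng.standard_normal(data.shape)
            runs.append(SurfaceTimeseries(data))
        feats = _latent_features(z[i], cfg.beta, cfg.nonlinear)
        # 1/sqrt(F): deviation amplitude independent of the latent feature count,
        # so deviation_scale is the deviation/template amplitude ratio
        signal = templates + cfg.deviation_scale / np.sqrt(len(feats)) * np.tensordot(
            feats, coupling, axes=(0, 0))
        visits = []
        for _ in range(cfg.visits):
            noisy = signal + cfg.sigma_scan * rng.standard_normal(signal.shape)
            visits.append(ContrastMaps(
                _smooth(S, noisy, cfg.smooth_iters),
                names=[f"contrast{c}" for c in range(C)],
                subject=f"sub{i:03d}",
            ))
        subjects.append({"id": f"sub{i:03d}", "runs": runs, "visits": visits})

    cohort = SyntheticCohort(config=cfg, mesh=mesh, zmaps=zmaps, subjects=subjects)
    truth = GroundTruth(z=z, templates=templates, coupling=coupling,
                        feature_names=feat_names, labels=labels, seeds=seeds,
                        base_loadings=base, basis=basis)
    return cohort, truth


def oracle_predictor(cohort: SyntheticCohort, truth: GroundTruth, i: int) -> ContrastMaps:
    """Noise-free contrast maps of subject i from the generative equation.

    This is the cohort's performance ceiling; a subject with z = 0 collapses
    onto the (smoothed) group template.
    """
    cfg = cohort.config
    S = smoothing_operator(cohort.mesh)
    feats = _latent_features(truth.z[i], cfg.beta, cfg.nonlinear)
    signal = truth.templates + cfg.deviation_scale / np.sqrt(len(feats)) * np.tensordot(
        feats, truth.coupling, axes=(0, 0))
    return ContrastMaps(_smooth(S, signal, cfg.smooth_iters),
                        names=[f"contrast{c}" for c in range(cfg.n_contrasts)],
                        subject=cohort.subjects[i]["id"])


def build_connectome_inputs(cohort: SyntheticCohort, scheme: str = "halves",
                            **scheme_kwargs):
    """Standard input pipeline: parcellate, segment runs, correlate.

    Returns (parcellation, per-subject list of Connectome lists): each
    subject gets one vertex-to-ROI connectome per run segment (the
    augmentation samples; averaged at test time).
    """
    parc = winner_take_all(cohort.zmaps)
    out = []
    for s in cohort.subjects:
        segments = split_segments(s["runs"], scheme=scheme, **scheme_kwargs)
        conns = []
        for seg in segments:
            roi_ts = roi_mean_timeseries(seg, parc)
            conns.append(vertex_to_roi_fc(seg, roi_ts, subject=s["id"]))
        out.append(conns)
    return parc, out
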