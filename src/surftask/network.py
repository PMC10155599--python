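"""Spherical convolutional network on icosphere hierarchies.

Convolution on the sphere is parameterized through differential operators:
for each mesh level we assemble sparse matrices for the identity (implicit),
the east-west tangential derivative ``D_ew`` (direction of increasing
azimuth), the north-south derivative ``D_ns`` (direction of increasing polar
angle, i.e. southward) and a graph Laplacian ``Lap``.  A convolution layer
mixes ``[f, D_ew f, D_ns f, Lap f]`` with learned weights per channel pair.
The U-Net stacks such layers with index-prefix restriction (pooling) and
midpoint-averaging prolongation (unpooling) between consecutive icosphere
levels.

All layers carry hand-written backward passes; gradients are validated
against numerical differentiation in the test suite.  Model parameters are
partitioned into a ``backbone`` and a ``head`` (the final per-vertex linear
projection onto the output contrast channels), which is the unit of transfer
learning: the head can be replaced (new task set) or frozen (shared task set,
backbone-only finetuning).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import scipy.sparse as sp

from .icomesh import SphereMesh, build_icosphere, pooling_map

__all__ = [
    "DiffOperators",
    "ModelSpec",
    "SurfaceUNet",
    "assemble_diff_ops",
    "mesh_conv",
    "build_model",
    "replace_head",
    "set_trainable",
    "save_checkpoint",
    "load_checkpoint",
]

_POLE_TOL = 1e-8


@dataclass
class DiffOperators:
    """Sparse (V, V) tangential derivative and Laplacian operators for a mesh."""

    level: int
    d_ew: sp.csr_matrix
    d_ns: sp.csr_matrix
    lap: sp.csr_matrix


def _tangent_frame(p: np.ndarray):
    """(e_east, e_north) at unit vector p; None at the poles."""
    s = np.hypot(p[0], p[1])
    if s < _POLE_TOL:
        return None
    e_east = np.array([-p[1], p[0], 0.0]) / s
    e_north = np.cross(e_east, p)  # = e_theta, southward
    return e_east, e_north


def assemble_diff_ops(mesh: SphereMesh) -> DiffOperators:
    """Least-squares first-order derivative operators plus a uniform Laplacian.

    For each vertex the ring differences ``f(q) - f(p)`` are fit with a linear
    function of the neighbours' tangent-plane coordinates; the fitted slopes
    along the local east/north directions give one sparse row each.  At the
    (at most two) polar vertices where the east/north frame is undefined, the
    frame of the lowest-index non-degenerate ring neighbour is projected onto
    the pole's tangent plane.  All three operators annihilate constants by
    construction.
    """
    V = mesh.n_vertices
    verts = mesh.vertices
    rows_e, cols_e, vals_e = [], [], []
    rows_n, cols_n, vals_n = [], [], []
    rows_l, cols_l, vals_l = [], [], []

    for v in range(V):
        p = verts[v]
        ring = mesh.one_ring[v]
        frame = _tangent_frame(p)
        if frame is None:
            donor = None
            for q in sorted(ring):
                f = _tangent_frame(verts[q])
                if f is not None:
                    donor = f
                    break
            if donor is None:
                raise ValueError(f"degenerate ring geometry at vertex {v}")
            e = donor[0] - np.dot(donor[0], p) * p
            nrm = np.linalg.norm(e)
            if nrm < _POLE_TOL:
                e = donor[1] - np.dot(donor[1], p) * p
                nrm = np.linalg.norm(e)
            e_east = e / nrm
            e_north = np.cross(e_east, p)
        else:
            e_east, e_north = frame

        d = verts[ring] - p
        A = np.column_stack([d @ e_east, d @ e_north])  # (k, 2)
        P = np.linalg.pinv(A)  # (2, k): slope weights for ring differences
        if not np.all(np.isfinite(P)):
            raise ValueError(f"degenerate ring geometry at vertex {v}")
        k = len(ring)
        rows_e += [v] * (k + 1)
        cols_e += list(ring) + [v]
        vals_e += list(P[0]) + [-P[0].sum()]
        rows_n += [v] * (k + 1)
        cols_n += list(ring) + [v]
        vals_n += list(P[1]) + [-P[1].sum()]
        rows_l += [v] * (k + 1)
        cols_l += list(ring) + [v]
        vals_l += [1.0 / k] * k + [-1.0]

    shape = (V, V)
    return DiffOperators(
        level=mesh.level,
        d_ew=sp.csr_matrix((vals_e, (rows_e, cols_e)), shape=shape),
        d_ns=sp.csr_matrix((vals_n, (rows_n, cols_n)), shape=shape),
        lap=sp.csr_matrix((vals_l, (rows_l, cols_l)), shape=shape),
    )


def _op_stack(x: np.ndarray, ops: DiffOperators) -> np.ndarray:
    """Stack [x, D_ew x, D_ns x, Lap x] into shape (V, Cin, 4)."""
    return np.stack([x, ops.d_ew @ x, ops.d_ns @ x, ops.lap @ x], axis=2)


def mesh_conv(features: np.ndarray, ops: DiffOperators, weights: np.ndarray,
              bias: np.ndarray | None = None) -> np.ndarray:
    """Differential-operator convolution (functional form).

    ``out[:, c] = sum_k  w[c,k,0] f_k + w[c,k,1] D_ew f_k + w[c,k,2] D_ns f_k
    + w[c,k,3] Lap f_k + b_c``
    """
    features = np.asarray(features, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    if features.ndim != 2 or weights.ndim != 3 or weights.shape[2] != 4:
        raise ValueError("features must be (V, Cin) and weights (Cout, Cin, 4)")
    if weights.shape[1] != features.shape[1]:
        raise ValueError(
            f"channel mismatch: features have {features.shape[1]}, weights expect {weights.shape[1]}"
        )
    g = _op_stack(features, ops)
    out = np.einsum("vik,oik->vo", g, weights)
    if bias is not None:
        if np.asarray(bias).shape != (weights.shape[0],):
            raise ValueError("bias must have shape (Cout,)")
        out = out + bias
    return out


# ---------------------------------------------------------------------------
# Layers (forward caches + analytic backward)
# ---------------------------------------------------------------------------

class _MeshConvLayer:
    def __init__(self, name, cin, cout, ops, rng):
        self.name, self.cin, self.cout, self.ops = name, cin, cout, ops
        std = np.sqrt(2.0 / (cin * 4))
        self.w = rng.normal(0.0, std, size=(cout, cin, 4))
        self.b = np.zeros(cout)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._g = None

    def params(self):
        return {f"{self.name}.w": self.w, f"{self.name}.b": self.b}

    def grads(self):
        return {f"{self.name}.w": self.gw, f"{self.name}.b": self.gb}

    def forward(self, x):
        self._g = _op_stack(x, self.ops)
        return np.einsum("vik,oik->vo", self._g, self.w) + self.b

    def backward(self, gy):
        self.gw += np.einsum("vo,vik->oik", gy, self._g)
        self.gb += gy.sum(axis=0)
        gx = gy @ self.w[:, :, 0]
        gx += self.ops.d_ew.T @ (gy @ self.w[:, :, 1])
        gx += self.ops.d_ns.T @ (gy @ self.w[:, :, 2])
        gx += self.ops.lap.T @ (gy @ self.w[:, :, 3])
        return gx


class _InstanceNorm:
    EPS = 1e-5

    def __init__(self, name, c):
        self.name = name
        self.g = np.ones(c)
        self.b = np.zeros(c)
        self.gg = np.zeros_like(self.g)
        self.gb = np.zeros_like(self.b)
        self._cache = None

    def params(self):
        return {f"{self.name}.g": self.g, f"{self.name}.b": self.b}

    def grads(self):
        return {f"{self.name}.g": self.gg, f"{self.name}.b": self.gb}

    def forward(self, x):
        mu = x.mean(axis=0)
        var = x.var(axis=0)
        inv = 1.0 / np.sqrt(var + self.EPS)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return self.g * xhat + self.b

    def backward(self, gy):
        xhat, inv = self._cache
        V = xhat.shape[0]
        self.gg += (gy * xhat).sum(axis=0)
        self.gb += gy.sum(axis=0)
        gxhat = gy * self.g
        return inv / V * (
            V * gxhat - gxhat.sum(axis=0) - xhat * (gxhat * xhat).sum(axis=0)
        )


class _LeakyReLU:
    def __init__(self, slope=0.1):
        self.slope = slope
        self._mask = None

    def params(self):
        return {}

    def grads(self):
        return {}

    def forward(self, x):
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, gy):
        return np.where(self._mask, gy, self.slope * gy)


def _prolongation_matrix(pmap) -> sp.csr_matrix:
    """Sparse (n_fine, n_coarse) copy-then-average-midpoints operator."""
    n_c, n_f = pmap.n_coarse, pmap.n_fine
    rows = list(range(n_c))
    cols = list(range(n_c))
    vals = [1.0] * n_c
    for i, (a, b) in enumerate(pmap.midpoint_parents):
        rows += [n_c + i, n_c + i]
        cols += [int(a), int(b)]
        vals += [0.5, 0.5]
    return sp.csr_matrix((vals, (rows, cols)), shape=(n_f, n_c))


def downsample(features: np.ndarray, pmap) -> np.ndarray:
    """Restrict a fine-level field to the coarse index prefix."""
    if features.shape[0] != pmap.n_fine:
        raise ValueError("feature vertex count does not match the fine level")
    return features[: pmap.n_coarse]


def upsample(features: np.ndarray, pmap) -> np.ndarray:
    """Copy coarse values; set each midpoint to the mean of its two parents."""
    if features.shape[0] != pmap.n_coarse:
        raise ValueError("feature vertex count does not match the coarse level")
    return _prolongation_matrix(pmap) @ features


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Architecture description of the surface U-Net.

    ``level`` is the icosphere level of the input/output; ``depth`` the
    number of pooling stages (must not exceed ``level``); ``widths`` the
    encoder channel widths from the finest to the coarsest stage (length
    depth + 1, default doubling from 64); ``in_channels`` the connectome
    channel count and ``out_channels`` the number of predicted contrasts.
    """

    level: int
    in_channels: int
    out_channels: int
    depth: int = 3
    widths: tuple = None
    skip_connections: bool = True
    convs_per_block: int = 1
    normalization: str = "instance"  # "instance" | "none"
    nonlinearity: str = "leaky_relu"  # "leaky_relu" | "none"
    seed: int = 0

    def __post_init__(self):
        if self.depth > self.level:
            raise ValueError(f"depth {self.depth} exceeds mesh level {self.level}")
        if self.out_channels < 1 or self.in_channels < 1:
            raise ValueError("channel counts must be positive")
        if self.widths is None:
            self.widths = tuple(64 * 2 ** s for s in range(self.depth + 1))
        self.widths = tuple(int(w) for w in self.widths)
        if len(self.widths) != self.depth + 1:
            raise ValueError("widths must have length depth + 1")
        if any(w <= 0 for w in self.widths):
            raise ValueError("widths must be positive")
        if self.convs_per_block < 1:
            raise ValueError("convs_per_block must be >= 1")


class SurfaceUNet:
    """U-Net over the icosphere hierarchy with differential-operator convolutions.

    Encoder stages run at levels ``L, L-1, ..., L-depth`` (one conv block per
    stage, restriction between stages); the decoder mirrors them with
    midpoint-average upsampling and, when ``skip_connections`` is on,
    channel-wise concatenation of the matching encoder output.  The head is a
    single linear mesh convolution onto the output contrast channels at the
    input level.
    """

    def __init__(self, spec: ModelSpec, meshes=None, ops=None):
        self.spec = spec
        L, d = spec.level, spec.depth
        if meshes is None:
            meshes = {lv: build_icosphere(lv) for lv in range(L - d, L + 1)}
        self.meshes = meshes
        if ops is None:
            ops = {lv: assemble_diff_ops(meshes[lv]) for lv in range(L - d, L + 1)}
        self.ops = ops
        self.pmaps = {
            lv: pooling_map(meshes[lv], meshes[lv - 1]) for lv in range(L - d + 1, L + 1)
        }
        self.prolong = {lv: _prolongation_matrix(p) for lv, p in self.pmaps.items()}
        self.trainable = {"backbone", "head"}
        self._build(np.random.default_rng(spec.seed))

    # -- construction -----------------------------------------------------
    def _block(self, name, cin, cout, level, rng):
        layers = []
        for j in range(self.spec.convs_per_block):
            cj = cin if j == 0 else cout
            layers.append(_MeshConvLayer(f"{name}.conv{j}", cj, cout, self.ops[level], rng))
            if self.spec.normalization == "instance":
                layers.append(_InstanceNorm(f"{name}.norm{j}", cout))
            if self.spec.nonlinearity == "leaky_relu":
                layers.append(_LeakyReLU())
        return layers

    def _build(self, rng):
        s = self.spec
        L, d, w = s.level, s.depth, s.widths
        self.enc = []
        cin = s.in_channels
        for stage in range(d + 1):
            self.enc.append(self._block(f"enc{stage}", cin, w[stage], L - stage, rng))
            cin = w[stage]
        self.dec = []
        for stage in range(d - 1, -1, -1):
            cin_dec = w[stage + 1] + (w[stage] if s.skip_connections else 0)
            self.dec.append(self._block(f"dec{stage}", cin_dec, w[stage], L - stage, rng))
        self.head = _MeshConvLayer("head.conv", w[0], s.out_channels, self.ops[L], rng)

    def _init_head(self, rng):
        std = np.sqrt(2.0 / (self.head.cin * 4))
        self.head.w = rng.normal(0.0, std, size=self.head.w.shape)
        self.head.b = np.zeros_like(self.head.b)
        self.head.gw = np.zeros_like(self.head.w)
        self.head.gb = np.zeros_like(self.head.b)

    # -- parameter bookkeeping -------------------------------------------
    def _layers(self):
        for block in self.enc + self.dec:
            yield from block
        yield self.head

    def parameters(self) -> dict:
        out = {}
        for layer in self._layers():
            out.update(layer.params())
        return out

    def gradients(self) -> dict:
        out = {}
        for layer in self._layers():
            out.update(layer.grads())
        return out

    def head_param_names(self):
        return set(self.head.params())

    def trainable_param_names(self):
        head = self.head_param_names()
        names = set()
        if "head" in self.trainable:
            names |= head
        if "backbone" in self.trainable:
            names |= set(self.parameters()) - head
        return names

    def zero_grad(self):
        for g in self.gradients().values():
            g[...] = 0.0

    def state_dict(self) -> dict:
        return {k: v.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict):
        params = self.parameters()
        for k, v in state.items():
            params[k][...] = v

    # -- forward / backward ----------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        s = self.spec
        if x.shape != (self.meshes[s.level].n_vertices, s.in_channels):
            raise ValueError(
                f"input must be ({self.meshes[s.level].n_vertices}, {s.in_channels}), got {x.shape}"
            )
        self._enc_out = []
        h = x
        for stage, block in enumerate(self.enc):
            if stage > 0:
                h = h[: self.pmaps[s.level - stage + 1].n_coarse]  # restriction
            for layer in block:
                h = layer.forward(h)
            self._enc_out.append(h)
        self._skip_widths = []
        for i, block in enumerate(self.dec):
            stage = s.depth - 1 - i  # decoder target stage
            level = s.level - stage
            h = self.prolong[level] @ h
            if s.skip_connections:
                e = self._enc_out[stage]
                self._skip_widths.append(e.shape[1])
                h = np.concatenate([h, e], axis=1)
            else:
                self._skip_widths.append(0)
            for layer in block:
                h = layer.forward(h)
        return self.head.forward(h)

    def backward(self, gy: np.ndarray):
        """Accumulate parameter gradients for d(loss)/d(output) = gy."""
        s = self.spec
        g = self.head.backward(gy)
        # grad wrt each encoder output arriving through the skip connections
        skip_grads = [None] * (s.depth + 1)
        for i in range(len(self.dec) - 1, -1, -1):
            stage = s.depth - 1 - i
            level = s.level - stage
            for layer in reversed(self.dec[i]):
                g = layer.backward(g)
            if s.skip_connections:
                wup = g.shape[1] - self._skip_widths[i]
                skip_grads[stage] = g[:, wup:].copy()
                g = g[:, :wup]
            g = self.prolong[level].T @ g
        # g is now the grad wrt the bottleneck encoder output enc_out[depth]
        for stage in range(s.depth, -1, -1):
            if skip_grads[stage] is not None:
                g = g + skip_grads[stage]
            for layer in reversed(self.enc[stage]):
                g = layer.backward(g)
            if stage > 0:
                # adjoint of the index-prefix restriction: zero-pad to fine size
                pmap = self.pmaps[s.level - stage + 1]
                padded = np.zeros((pmap.n_fine, g.shape[1]))
                padded[: pmap.n_coarse] = g
                g = padded
        return g


def build_model(spec: ModelSpec, meshes=None, ops=None) -> SurfaceUNet:
    """Construct a seeded surface U-Net from its spec."""
    return SurfaceUNet(spec, meshes=meshes, ops=ops)


def replace_head(model: SurfaceUNet, c_new: int, seed: int) -> SurfaceUNet:
    """Swap the output projection for ``c_new`` channels, preserving the backbone.

    Backbone parameters are untouched (bit-exact); the new head is freshly
    initialized from ``seed``.
    """
    if c_new < 1:
        raise ValueError("output channel count must be >= 1")
    rng = np.random.default_rng(seed)
    model.spec.out_channels = c_new
    std = np.sqrt(2.0 / (model.head.cin * 4))
    model.head.w = rng.normal(0.0, std, size=(c_new, model.head.cin, 4))
    model.head.b = np.zeros(c_new)
    model.head.gw = np.zeros_like(model.head.w)
    model.head.gb = np.zeros_like(model.head.b)
    return model


def set_trainable(model: SurfaceUNet, parts) -> SurfaceUNet:
    """Restrict gradient updates to ``parts`` (subset of {"backbone", "head"})."""
    parts = set(parts)
    if not parts:
        raise ValueError("at least one of {'backbone', 'head'} must stay trainable")
    if not parts <= {"backbone", "head"}:
        raise ValueError(f"unknown parts: {parts - {'backbone', 'head'}}")
    model.trainable = parts
    return model


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: SurfaceUNet, path, norm_stats: dict | None = None,
                    provenance: dict | None = None) -> None:
    """Single .npz archive with parameters, ModelSpec, normalization stats and provenance."""
    payload = {f"param/{k}": v for k, v in model.parameters().items()}
    meta = {"spec": asdict(model.spec), "provenance": provenance or {}}
    if norm_stats is not None:
        payload["norm/mean"] = np.asarray(norm_stats["mean"])
        payload["norm/sd"] = np.asarray(norm_stats["sd"])
    payload["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **payload)


def load_checkpoint(path):
    """Returns (model, norm_stats or None, provenance dict)."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta_json"]).decode())
        spec = ModelSpec(**meta["spec"])
        model = SurfaceUNet(spec)
        params = model.parameters()
        for key in z.files:
            if key.startswith("param/"):
                params[key[len("param/"):]][...] = z[key]
        norm_stats = None
        if "norm/mean" in z.files:
            norm_stats = {"mean": z["norm/mean"], "sd": z["norm/sd"]}
    return model, norm_stats, meta["provenance"]
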