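"""Surface layers: 2-manifold meshes with a per-face-corner UV chart.

A *layer* is the basic anatomical primitive: a neuronal sheet (soma layer,
synaptic layer, or intermediate waypoint) represented as a triangle/quad mesh
embedded in 3D.  Every face corner additionally carries a 2D chart coordinate
(``uv``), the flattened-surface coordinate system that stands in for local
anatomical axes such as proximo-distal or septo-temporal.  Vertex coordinates
are millimetres; UV is dimensionless chart units.

The module provides Wavefront OBJ I/O (``v``/``vt``/``f v/vt`` records),
surface area, chart-to-surface lookup, area-proportional neuron placement
(optionally modulated by a density map over the chart), and along-surface
path length measured by discretizing a straight chart segment.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "SurfaceLayer",
    "SurfacePoint",
    "NeuronPopulation",
    "read_obj",
    "write_obj",
    "surface_area",
    "point_from_uv",
    "points_from_uv",
    "place_neurons",
    "neuron_count_from_density",
    "uv_path_length",
    "uv_path_lengths",
]

_BARY_TOL = 1e-9


class LayerError(ValueError):
    """Raised for malformed layers or unresolvable chart queries."""


@dataclass
class SurfaceLayer:
    """A 2-manifold mesh in 3D with a per-face-corner UV chart.

    Parameters
    ----------
    name:
        Identifier used to cross-reference populations and mapping chains.
    vertices:
        ``(V, 3)`` float array of positions in mm.
    faces:
        Sequence of corner index lists, each of length 3 or 4.  Quads are
        split deterministically into triangles ``(0, 1, 2)`` and ``(0, 2, 3)``
        in the triangulated view.
    uv_corners:
        One ``(k, 2)`` array per face giving the chart coordinate of each
        corner.  Per-corner storage means chart seams are representable.
    density_map:
        Optional non-negative 2D grid of relative neuron-density weights,
        bilinearly interpolated over the UV unit square (row -> v, col -> u).
    """

    name: str
    vertices: np.ndarray
    faces: list
    uv_corners: list
    density_map: np.ndarray | None = None
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = [tuple(int(i) for i in f) for f in self.faces]
        self.uv_corners = [np.asarray(u, dtype=float) for u in self.uv_corners]
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise LayerError(f"layer {self.name!r}: vertices must be (V, 3)")
        if not np.isfinite(self.vertices).all():
            raise LayerError(f"layer {self.name!r}: non-finite vertex coordinate")
        if len(self.faces) != len(self.uv_corners):
            raise LayerError(f"layer {self.name!r}: faces/uv_corners length mismatch")
        nv = len(self.vertices)
        for i, (f, uv) in enumerate(zip(self.faces, self.uv_corners)):
            if len(f) not in (3, 4):
                raise LayerError(f"layer {self.name!r}: face {i} has {len(f)} corners")
            if max(f) >= nv or min(f) < 0:
                raise LayerError(f"layer {self.name!r}: face {i} references missing vertex")
            if uv.shape != (len(f), 2):
                raise LayerError(
                    f"layer {self.name!r}: face {i} has {len(f)} corners but "
                    f"UV shape {uv.shape}"
                )
            if not np.isfinite(uv).all():
                raise LayerError(f"layer {self.name!r}: face {i} has non-finite UV")
        if self.density_map is not None:
            dm = np.asarray(self.density_map, dtype=float)
            if dm.ndim != 2 or (dm < 0).any() or not np.isfinite(dm).all():
                raise LayerError(f"layer {self.name!r}: density_map must be a non-negative 2D grid")
            self.density_map = dm
        if len(self.faces) and self.tri_areas.sum() <= 0:
            raise LayerError(f"layer {self.name!r}: triangulated surface has zero total area")

    # -- triangulated view ----------------------------------------------

    def _triangulate(self) -> None:
        tris, tri_uv, tri_face = [], [], []
        for fi, (f, uv) in enumerate(zip(self.faces, self.uv_corners)):
            corner_sets = [(0, 1, 2)] if len(f) == 3 else [(0, 1, 2), (0, 2, 3)]
            for cs in corner_sets:
                tris.append([f[c] for c in cs])
                tri_uv.append(uv[list(cs)])
                tri_face.append(fi)
        self._cache["tris"] = np.asarray(tris, dtype=np.intp).reshape(-1, 3)
        self._cache["tri_uv"] = (
            np.asarray(tri_uv, dtype=float).reshape(-1, 3, 2)
        )
        self._cache["tri_face"] = np.asarray(tri_face, dtype=np.intp)

    @property
    def tris(self) -> np.ndarray:
        """``(T, 3)`` vertex indices of the triangulated view."""
        if "tris" not in self._cache:
            self._triangulate()
        return self._cache["tris"]

    @property
    def tri_uv(self) -> np.ndarray:
        """``(T, 3, 2)`` chart coordinates of triangle corners."""
        if "tri_uv" not in self._cache:
            self._triangulate()
        return self._cache["tri_uv"]

    @property
    def tri_face(self) -> np.ndarray:
        if "tri_face" not in self._cache:
            self._triangulate()
        return self._cache["tri_face"]

    @property
    def tri_xyz(self) -> np.ndarray:
        """``(T, 3, 3)`` vertex positions of triangle corners (mm)."""
        if "tri_xyz" not in self._cache:
            self._cache["tri_xyz"] = self.vertices[self.tris]
        return self._cache["tri_xyz"]

    @property
    def tri_areas(self) -> np.ndarray:
        if "tri_areas" not in self._cache:
            p = self.tri_xyz
            cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
            self._cache["tri_areas"] = 0.5 * np.linalg.norm(cross, axis=1)
        return self._cache["tri_areas"]

    @property
    def vertex_normals(self) -> np.ndarray:
        """Angle-weighted vertex normals, unit length where defined."""
        if "vertex_normals" not in self._cache:
            p = self.tri_xyz
            fn = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
            norms = np.linalg.norm(fn, axis=1, keepdims=True)
            fn_unit = np.divide(fn, norms, out=np.zeros_like(fn), where=norms > 0)
            acc = np.zeros_like(self.vertices)
            for c in range(3):
                a = self.tri_xyz[:, (c + 1) % 3] - self.tri_xyz[:, c]
                b = self.tri_xyz[:, (c + 2) % 3] - self.tri_xyz[:, c]
                na = np.linalg.norm(a, axis=1)
                nb = np.linalg.norm(b, axis=1)
                ok = (na > 0) & (nb > 0)
                cosang = np.zeros(len(a))
                cosang[ok] = np.einsum("ij,ij->i", a[ok], b[ok]) / (na[ok] * nb[ok])
                ang = np.arccos(np.clip(cosang, -1.0, 1.0))
                np.add.at(acc, self.tris[:, c], fn_unit * ang[:, None])
            n = np.linalg.norm(acc, axis=1, keepdims=True)
            self._cache["vertex_normals"] = np.divide(
                acc, n, out=np.zeros_like(acc), where=n > 0
            )
        return self._cache["vertex_normals"]

    # -- chart index -----------------------------------------------------

    @property
    def uv_bounds(self) -> tuple:
        """(umin, umax, vmin, vmax) bounding rectangle of the chart."""
        uv = self.tri_uv.reshape(-1, 2)
        return (uv[:, 0].min(), uv[:, 0].max(), uv[:, 1].min(), uv[:, 1].max())

    @property
    def min_uv_edge(self) -> float:
        """Shortest non-zero UV edge length of the triangulated view."""
        if "min_uv_edge" not in self._cache:
            uv = self.tri_uv
            e = np.concatenate(
                [uv[:, 1] - uv[:, 0], uv[:, 2] - uv[:, 1], uv[:, 0] - uv[:, 2]]
            )
            lengths = np.linalg.norm(e, axis=1)
            lengths = lengths[lengths > 0]
            self._cache["min_uv_edge"] = float(lengths.min()) if len(lengths) else 0.0
        return self._cache["min_uv_edge"]

    def _chart_index(self):
        """Uniform-grid spatial index over UV triangle bounding boxes."""
        if "chart_index" not in self._cache:
            uv = self.tri_uv
            umin, umax, vmin, vmax = self.uv_bounds
            span_u = max(umax - umin, 1e-30)
            span_v = max(vmax - vmin, 1e-30)
            # aim at O(1) triangles per cell
            ncell = max(1, int(np.sqrt(len(uv))))
            cu = cv = ncell
            lo = np.floor(
                np.stack(
                    [
                        (uv[..., 0].min(axis=1) - umin) / span_u * cu,
                        (uv[..., 1].min(axis=1) - vmin) / span_v * cv,
                    ],
                    axis=1,
                )
            ).astype(int)
            hi = np.floor(
                np.stack(
                    [
                        (uv[..., 0].max(axis=1) - umin) / span_u * cu,
                        (uv[..., 1].max(axis=1) - vmin) / span_v * cv,
                    ],
                    axis=1,
                )
            ).astype(int)
            lo = np.clip(lo, 0, [cu - 1, cv - 1])
            hi = np.clip(hi, 0, [cu - 1, cv - 1])
            cells: dict = {}
            for t in range(len(uv)):
                for iu in range(lo[t, 0], hi[t, 0] + 1):
                    for iv in range(lo[t, 1], hi[t, 1] + 1):
                        cells.setdefault((iu, iv), []).append(t)
            cells = {k: np.asarray(v, dtype=np.intp) for k, v in cells.items()}
            self._cache["chart_index"] = (cells, cu, cv, umin, vmin, span_u, span_v)
        return self._cache["chart_index"]

    # -- derived quantities ---------------------------------------------

    def bary_to_xyz(self, tri_index, bary) -> np.ndarray:
        tri_index = np.asarray(tri_index, dtype=np.intp)
        bary = np.asarray(bary, dtype=float)
        return np.einsum("...c,...cd->...d", bary, self.tri_xyz[tri_index])

    def bary_to_uv(self, tri_index, bary) -> np.ndarray:
        tri_index = np.asarray(tri_index, dtype=np.intp)
        bary = np.asarray(bary, dtype=float)
        return np.einsum("...c,...cd->...d", bary, self.tri_uv[tri_index])

    def density_at(self, uv: np.ndarray) -> np.ndarray:
        """Bilinear density-map sample at chart points (1.0 when no map)."""
        uv = np.atleast_2d(np.asarray(uv, dtype=float))
        if self.density_map is None:
            return np.ones(len(uv))
        nr, nc = self.density_map.shape
        rows = np.clip(uv[:, 1] * (nr - 1), 0, nr - 1)
        cols = np.clip(uv[:, 0] * (nc - 1), 0, nc - 1)
        return ndimage.map_coordinates(
            self.density_map, np.vstack([rows, cols]), order=1, mode="nearest"
        )

    def copy(self, name: str | None = None) -> "SurfaceLayer":
        return SurfaceLayer(
            name=name or self.name,
            vertices=self.vertices.copy(),
            faces=[tuple(f) for f in self.faces],
            uv_corners=[u.copy() for u in self.uv_corners],
            density_map=None if self.density_map is None else self.density_map.copy(),
        )


@dataclass(frozen=True)
class SurfacePoint:
    """A location on a layer: triangle index + barycentric coordinates.

    ``xyz`` (mm) and ``uv`` (chart units) are derived from the barycentric
    combination of the triangle's corner data.  This is the representation of
    both neuron somata and synapse locations.
    """

    layer: str
    tri_index: int
    bary: tuple
    xyz: tuple
    uv: tuple

    @classmethod
    def from_bary(cls, layer: SurfaceLayer, tri_index: int, bary) -> "SurfacePoint":
        bary = np.asarray(bary, dtype=float)
        if (bary < -_BARY_TOL).any() or abs(bary.sum() - 1.0) > 1e-9:
            raise LayerError(f"invalid barycentric coordinates {bary}")
        xyz = layer.bary_to_xyz(tri_index, bary)
        uv = layer.bary_to_uv(tri_index, bary)
        return cls(layer.name, int(tri_index), tuple(bary), tuple(xyz), tuple(uv))


@dataclass
class NeuronPopulation:
    """Neurons placed on a layer, ids contiguous from 0.

    Positions are stored as parallel arrays (triangle index, barycentric
    coordinates, and the derived xyz/uv) for vectorized downstream use.
    """

    layer: str
    size: int
    tri_index: np.ndarray
    bary: np.ndarray
    xyz: np.ndarray
    uv: np.ndarray
    seed: int | None = None

    def point(self, i: int, layer: SurfaceLayer) -> SurfacePoint:
        return SurfacePoint.from_bary(layer, self.tri_index[i], self.bary[i])

    def __len__(self) -> int:
        return self.size


# ---------------------------------------------------------------------------
# OBJ I/O
# ---------------------------------------------------------------------------

def read_obj(path, name: str | None = None) -> SurfaceLayer:
    """Read a Wavefront OBJ file with ``v``, ``vt`` and ``f v/vt`` records.

    1-based OBJ indices are converted to 0-based; quads are preserved as
    quads.  Faces must reference a texture coordinate per corner, since the
    chart is what makes a layer usable downstream.
    """
    verts, uvs, faces, face_uv = [], [], [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            parts = raw.strip().split()
            if not parts or parts[0].startswith("#"):
                continue
            tag = parts[0]
            if tag == "v":
                verts.append([float(x) for x in parts[1:4]])
            elif tag == "vt":
                uvs.append([float(x) for x in parts[1:3]])
            elif tag == "f":
                vi, ti = [], []
                for tok in parts[1:]:
                    sub = tok.split("/")
                    if len(sub) < 2 or not sub[1]:
                        raise LayerError(
                            f"{path}: face at line {lineno} lacks a vt reference "
                            f"(corner {tok!r})"
                        )
                    vi.append(int(sub[0]) - 1)
                    ti.append(int(sub[1]) - 1)
                faces.append(tuple(vi))
                face_uv.append(ti)
    uvs = np.asarray(uvs, dtype=float).reshape(-1, 2)
    uv_corners = [uvs[idx] for idx in face_uv]
    if name is None:
        import os

        name = os.path.splitext(os.path.basename(str(path)))[0]
    return SurfaceLayer(
        name=name, vertices=np.asarray(verts, dtype=float), faces=faces,
        uv_corners=uv_corners,
    )


def write_obj(layer: SurfaceLayer, path) -> None:
    """Write a layer in ``f v/vt`` form, 1-based indices, LF line endings.

    UV corners are deduplicated bit-exactly so that write/read round-trips
    preserve vertex, face and UV content identically.
    """
    lines = [f"# layer {layer.name}"]
    for v in layer.vertices:
        lines.append(f"v {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}")
    uv_index: dict = {}
    uv_list: list = []
    face_uv_idx = []
    for uv in layer.uv_corners:
        idx = []
        for c in uv:
            key = (float(c[0]), float(c[1]))
            if key not in uv_index:
                uv_index[key] = len(uv_list)
                uv_list.append(key)
            idx.append(uv_index[key])
        face_uv_idx.append(idx)
    for u, v in uv_list:
        lines.append(f"vt {u:.17g} {v:.17g}")
    for f, ti in zip(layer.faces, face_uv_idx):
        toks = " ".join(f"{vi + 1}/{uvi + 1}" for vi, uvi in zip(f, ti))
        lines.append(f"f {toks}")
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Geometry over the chart
# ---------------------------------------------------------------------------

def surface_area(layer: SurfaceLayer) -> float:
    """Total area (mm^2) of the triangulated view; degenerate faces add 0."""
    return float(layer.tri_areas.sum())


def _uv_bary(layer: SurfaceLayer, tri_idx: np.ndarray, uv: np.ndarray) -> np.ndarray:
    """Barycentric coordinates of chart points w.r.t. UV triangles.

    Rows with degenerate (zero chart area) triangles come back as -inf,
    which never passes the containment test.
    """
    corners = layer.tri_uv[tri_idx]
    a, b, c = corners[:, 0], corners[:, 1], corners[:, 2]
    v0 = b - a
    v1 = c - a
    v2 = uv - a
    det = v0[:, 0] * v1[:, 1] - v0[:, 1] * v1[:, 0]
    ok = np.abs(det) > 0
    inv = np.where(ok, det, 1.0)
    b1 = (v2[:, 0] * v1[:, 1] - v2[:, 1] * v1[:, 0]) / inv
    b2 = (v0[:, 0] * v2[:, 1] - v0[:, 1] * v2[:, 0]) / inv
    b0 = 1.0 - b1 - b2
    bary = np.stack([b0, b1, b2], axis=1)
    bary[~ok] = -np.inf
    return bary


def points_from_uv(layer: SurfaceLayer, uvs: np.ndarray, tol: float = 1e-9):
    """Vectorized chart lookup.

    Returns ``(tri_index, bary, found)``; ``tri_index`` is -1 where the chart
    point lies outside every UV triangle.  Chart overlaps resolve to the
    lowest triangle index.
    """
    uvs = np.atleast_2d(np.asarray(uvs, dtype=float))
    n = len(uvs)
    out_tri = np.full(n, -1, dtype=np.intp)
    out_bary = np.zeros((n, 3))
    cells, cu, cv, umin, vmin, span_u, span_v = layer._chart_index()
    ci = np.clip(((uvs[:, 0] - umin) / span_u * cu).astype(int), 0, cu - 1)
    cj = np.clip(((uvs[:, 1] - vmin) / span_v * cv).astype(int), 0, cv - 1)
    key = ci * cv + cj
    order = np.argsort(key, kind="stable")
    i = 0
    while i < n:
        j = i
        while j < n and key[order[j]] == key[order[i]]:
            j += 1
        q = order[i:j]
        cand = cells.get((ci[q[0]], cj[q[0]]))
        i = j
        if cand is None:
            continue
        # (len(q), len(cand)) containment test
        rep_q = np.repeat(q, len(cand))
        rep_t = np.tile(cand, len(q))
        bary = _uv_bary(layer, rep_t, uvs[rep_q])
        inside = (bary >= -tol).all(axis=1)
        if not inside.any():
            continue
        bary = bary.reshape(len(q), len(cand), 3)
        inside = inside.reshape(len(q), len(cand))
        # lowest triangle index wins: candidates are sorted ascending
        csort = np.argsort(cand, kind="stable")
        for qi in range(len(q)):
            hit = csort[inside[qi][csort]]
            if len(hit):
                k = hit[0]
                out_tri[q[qi]] = cand[k]
                b = np.clip(bary[qi, k], 0.0, None)
                out_bary[q[qi]] = b / b.sum()
    return out_tri, out_bary, out_tri >= 0


def point_from_uv(layer: SurfaceLayer, uv) -> SurfacePoint | None:
    """Locate a chart coordinate on the surface, or ``None`` if off-chart."""
    uv = np.asarray(uv, dtype=float)
    if not np.isfinite(uv).all():
        raise LayerError("uv must be finite")
    tri, bary, found = points_from_uv(layer, uv[None, :])
    if not found[0]:
        return None
    return SurfacePoint.from_bary(layer, tri[0], bary[0])


# ---------------------------------------------------------------------------
# Neuron placement
# ---------------------------------------------------------------------------

def neuron_count_from_density(area_mm2: float, density_per_mm2: float) -> int:
    """Round(area x density): total neuron count implied by a surface density."""
    if area_mm2 < 0 or density_per_mm2 < 0:
        raise ValueError("area and density must be non-negative")
    return int(round(area_mm2 * density_per_mm2))


def _face_density_bounds(layer: SurfaceLayer) -> tuple:
    """Per-triangle (mean corner density, upper bound on density).

    The upper bound takes the maximum grid value over the triangle's UV
    bounding box padded by one cell, a safe envelope for bilinear
    interpolation (whose extrema lie on grid nodes or region boundary).
    """
    T = len(layer.tris)
    if layer.density_map is None:
        return np.ones(T), np.ones(T)
    corner_uv = layer.tri_uv.reshape(-1, 2)
    corner_d = layer.density_at(corner_uv).reshape(T, 3)
    mean_d = corner_d.mean(axis=1)
    dm = layer.density_map
    nr, nc = dm.shape
    ub = np.empty(T)
    lo_c = np.clip(np.floor(layer.tri_uv[..., 0].min(axis=1) * (nc - 1)).astype(int), 0, nc - 1)
    hi_c = np.clip(np.ceil(layer.tri_uv[..., 0].max(axis=1) * (nc - 1)).astype(int), 0, nc - 1)
    lo_r = np.clip(np.floor(layer.tri_uv[..., 1].min(axis=1) * (nr - 1)).astype(int), 0, nr - 1)
    hi_r = np.clip(np.ceil(layer.tri_uv[..., 1].max(axis=1) * (nr - 1)).astype(int), 0, nr - 1)
    for t in range(T):
        ub[t] = dm[lo_r[t] : hi_r[t] + 1, lo_c[t] : hi_c[t] + 1].max()
    return mean_d, ub


def _uniform_bary(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform barycentric coordinates via the square-root construction."""
    r1 = np.sqrt(rng.random(n))
    r2 = rng.random(n)
    return np.stack([1.0 - r1, r1 * (1.0 - r2), r1 * r2], axis=1)


def place_neurons(
    layer: SurfaceLayer, n: int, seed: int, use_density: bool = False
) -> NeuronPopulation:
    """Distribute ``n`` somata over the layer, uniformly per unit area.

    With ``use_density`` the area weight is modulated by the layer's density
    map: triangles are drawn proportionally to area times a per-triangle
    density envelope and candidate points are accepted against the local
    bilinear density value, yielding a point density proportional to
    area x density.  Reproducible for a fixed seed.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    areas = layer.tri_areas
    if use_density and layer.density_map is not None:
        _, ub = _face_density_bounds(layer)
        weights = areas * ub
    else:
        ub = None
        weights = areas.copy()
    total = weights.sum()
    if total <= 0:
        raise LayerError("no admissible surface: total placement weight is zero")
    p = weights / total
    tri_out = np.empty(n, dtype=np.intp)
    bary_out = np.empty((n, 3))
    filled = 0
    while filled < n:
        batch = max(n - filled, 1)
        cand_tri = rng.choice(len(areas), size=batch, p=p)
        cand_bary = _uniform_bary(rng, batch)
        if ub is not None:
            uv = layer.bary_to_uv(cand_tri, cand_bary)
            dens = layer.density_at(uv)
            accept = rng.random(batch) * ub[cand_tri] < dens
        else:
            accept = np.ones(batch, dtype=bool)
        k = min(int(accept.sum()), n - filled)
        idx = np.nonzero(accept)[0][:k]
        tri_out[filled : filled + k] = cand_tri[idx]
        bary_out[filled : filled + k] = cand_bary[idx]
        filled += k
    return NeuronPopulation(
        layer=layer.name,
        size=n,
        tri_index=tri_out,
        bary=bary_out,
        xyz=layer.bary_to_xyz(tri_out, bary_out),
        uv=layer.bary_to_uv(tri_out, bary_out),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Along-surface path length
# ---------------------------------------------------------------------------

def _default_max_step(layer: SurfaceLayer) -> float:
    step = 0.5 * layer.min_uv_edge
    if step <= 0:
        raise LayerError("layer has no usable UV edges")
    return step


def uv_path_lengths(
    layer: SurfaceLayer,
    uv_a: np.ndarray,
    uv_b: np.ndarray,
    max_step: float | None = None,
) -> np.ndarray:
    """Vectorized along-surface lengths of straight chart segments (mm).

    Each segment is discretized into chart steps of length <= ``max_step``
    (default: half the minimum UV edge length), every sample mapped to 3D
    through the chart, and chord lengths summed.  All samples must resolve on
    the chart.
    """
    uv_a = np.atleast_2d(np.asarray(uv_a, dtype=float))
    uv_b = np.atleast_2d(np.asarray(uv_b, dtype=float))
    if max_step is None:
        max_step = _default_max_step(layer)
    seg = np.linalg.norm(uv_b - uv_a, axis=1)
    nstep = np.maximum(np.ceil(seg / max_step).astype(int), 1)
    counts = nstep + 1
    offsets = np.concatenate([[0], np.cumsum(counts)])
    samples = np.empty((offsets[-1], 2))
    for i in range(len(uv_a)):
        t = np.linspace(0.0, 1.0, counts[i])[:, None]
        samples[offsets[i] : offsets[i + 1]] = uv_a[i] * (1 - t) + uv_b[i] * t
    tri, bary, found = points_from_uv(layer, samples)
    if not found.all():
        raise LayerError("uv path leaves chart")
    xyz = layer.bary_to_xyz(tri, bary)
    chord = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
    # zero out chords that straddle segment boundaries
    out = np.empty(len(uv_a))
    for i in range(len(uv_a)):
        out[i] = chord[offsets[i] : offsets[i + 1] - 1].sum()
    return out


def uv_path_length(
    layer: SurfaceLayer, uv_a, uv_b, max_step: float | None = None
) -> float:
    """Along-surface length (mm) of the straight chart segment a -> b."""
    return float(uv_path_lengths(layer, np.asarray(uv_a)[None], np.asarray(uv_b)[None], max_step)[0])
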