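"""Inter-layer mapping operators and their composition along chains.

Four operators carry a point from one layer to the next:

* **topological** — same triangle index and barycentric coordinates on a
  layer with identical face/corner structure (deformed copies).
* **normal** — intersect the smoothly interpolated surface normal line
  (both directions) with the target; no intersection means no connection,
  which is how sub-populations are masked out of a projection.
* **euclidean** — globally closest point on the target surface.
* **random** — area-uniform point on the target, independent of the query.

``traverse_chain`` composes steps toward the synaptic layer; a normal-mapping
miss aborts the whole chain (that neuron projects nowhere).

Geometry queries (closest point on mesh, line-mesh intersection) are exact
vectorized closed forms over candidate triangles; candidates are pruned with
a bounding-sphere bound around a KD-tree estimate, with results identical to
exhaustive search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .layers import NeuronPopulation, SurfaceLayer, SurfacePoint

__all__ = [
    "MappingStep",
    "MappingChain",
    "map_topological",
    "map_normal",
    "map_euclidean",
    "map_random",
    "traverse_chain",
    "closest_point_on_layer",
    "intersect_normal_lines",
    "MAPPING_KINDS",
    "DISTANCE_MODES",
]

MAPPING_KINDS = ("topological", "normal", "euclidean", "random")
DISTANCE_MODES = ("euclidean", "euclideanUV", "normal", "normalUV", "jump", "jumpUV")


class MappingError(ValueError):
    """Raised when a mapping's structural precondition fails."""


@dataclass(frozen=True)
class MappingStep:
    """One hop of a chain: target layer, mapping kind, distance mode."""

    target_layer: str
    mapping: str = "euclidean"
    distance_mode: str = "euclidean"

    def __post_init__(self):
        if self.mapping not in MAPPING_KINDS:
            raise ValueError(f"unknown mapping {self.mapping!r}")
        if self.distance_mode not in DISTANCE_MODES:
            raise ValueError(f"unknown distance mode {self.distance_mode!r}")


@dataclass
class MappingChain:
    """A projection definition: two chains of steps meeting on a synaptic layer.

    ``pre_steps`` carry the pre-synaptic population from its soma layer via
    any intermediate layers onto the synaptic layer; ``post_steps`` likewise
    for the post-synaptic side.  Kernels weight where on the synaptic layer
    each side forms synapses; ``n_synapses_per_pre`` is the outgoing synapse
    budget of each pre-synaptic neuron.
    """

    name: str
    layers: dict
    pre_population: NeuronPopulation
    post_population: NeuronPopulation
    pre_steps: list
    post_steps: list
    kernel_pre: object = None
    kernel_post: object = None
    n_synapses_per_pre: int = 1

    def __post_init__(self):
        if self.n_synapses_per_pre < 0:
            raise ValueError("n_synapses_per_pre must be >= 0")
        pre_end = self.pre_steps[-1].target_layer if self.pre_steps else self.pre_population.layer
        post_end = self.post_steps[-1].target_layer if self.post_steps else self.post_population.layer
        if pre_end != post_end:
            raise ValueError(
                f"chain {self.name!r}: pre side ends on {pre_end!r} but post side "
                f"on {post_end!r}; both must end on the synaptic layer"
            )
        self.synaptic_layer_name = pre_end

    @property
    def synaptic_layer(self) -> SurfaceLayer:
        return self.layers[self.synaptic_layer_name]


# ---------------------------------------------------------------------------
# Exact geometry kernels
# ---------------------------------------------------------------------------

def _closest_point_tri(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest points on triangles for paired queries.

    ``p``: (n, 3) query points, ``tri``: (n, 3, 3) triangle corners.
    Standard region classification of the point against the triangle's
    Voronoi regions (vertices, edges, interior); exact closed form.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    m = (d1 <= 0) & (d2 <= 0)                      # vertex a
    out[m] = a[m]
    done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)           # vertex b
    out[m] = b[m]
    done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)           # vertex c
    out[m] = c[m]
    done |= m

    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)  # edge ab
    with np.errstate(invalid="ignore", divide="ignore"):
        t = d1 / (d1 - d3)
    out[m] = a[m] + t[m, None] * ab[m]
    done |= m

    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)  # edge ac
    with np.errstate(invalid="ignore", divide="ignore"):
        t = d2 / (d2 - d6)
    out[m] = a[m] + t[m, None] * ac[m]
    done |= m

    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)  # edge bc
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (d4 - d3) / ((d4 - d3) + (d5 - d6))
    out[m] = b[m] + t[m, None] * (c[m] - b[m])
    done |= m

    m = ~done                                       # interior
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = va + vb + vc
        v = vb / denom
        w = vc / denom
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return out


def _xyz_to_bary(layer: SurfaceLayer, tri_idx: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Barycentric coordinates of on-triangle 3D points (least squares)."""
    tri = layer.tri_xyz[tri_idx]
    a = tri[:, 0]
    e1 = tri[:, 1] - a
    e2 = tri[:, 2] - a
    d = pts - a
    g11 = np.einsum("ij,ij->i", e1, e1)
    g12 = np.einsum("ij,ij->i", e1, e2)
    g22 = np.einsum("ij,ij->i", e2, e2)
    r1 = np.einsum("ij,ij->i", d, e1)
    r2 = np.einsum("ij,ij->i", d, e2)
    det = g11 * g22 - g12 * g12
    det = np.where(np.abs(det) > 0, det, 1.0)
    b1 = (g22 * r1 - g12 * r2) / det
    b2 = (g11 * r2 - g12 * r1) / det
    bary = np.stack([1.0 - b1 - b2, b1, b2], axis=1)
    bary = np.clip(bary, 0.0, None)
    return bary / bary.sum(axis=1, keepdims=True)


def closest_point_on_layer(
    layer: SurfaceLayer, points: np.ndarray, exhaustive: bool = False
):
    """Globally closest surface points for a batch of 3D queries.

    Returns ``(tri_index, closest_xyz, distance)``.  Distance ties resolve to
    the lowest triangle index.  Candidate triangles are pruned by comparing a
    KD-tree vertex-distance upper bound against per-triangle bounding
    spheres; the result is identical to ``exhaustive=True``.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    T = len(layer.tris)
    tri_xyz = layer.tri_xyz
    centers = tri_xyz.mean(axis=1)
    radii = np.linalg.norm(tri_xyz - centers[:, None, :], axis=2).max(axis=1)

    out_tri = np.empty(len(points), dtype=np.intp)
    out_xyz = np.empty((len(points), 3))
    out_d = np.empty(len(points))

    if exhaustive or T <= 64:
        cand_iter = ((i, np.arange(T)) for i in range(len(points)))
    else:
        tree = cKDTree(layer.vertices)
        ub, _ = tree.query(points)

        def gen():
            for i in range(len(points)):
                d_center = np.linalg.norm(centers - points[i], axis=1)
                yield i, np.nonzero(d_center - radii <= ub[i] + 1e-12)[0]

        cand_iter = gen()

    for i, cand in cand_iter:
        cp = _closest_point_tri(
            np.broadcast_to(points[i], (len(cand), 3)).copy(), tri_xyz[cand]
        )
        d = np.linalg.norm(cp - points[i], axis=1)
        k = int(np.argmin(d))  # first minimum -> lowest triangle index
        out_tri[i] = cand[k]
        out_xyz[i] = cp[k]
        out_d[i] = d[k]
    return out_tri, out_xyz, out_d


def _interp_normals(layer: SurfaceLayer, tri_idx: np.ndarray, bary: np.ndarray) -> np.ndarray:
    """Barycentric interpolation of angle-weighted vertex normals."""
    vn = layer.vertex_normals[layer.tris[tri_idx]]
    n = np.einsum("ic,icd->id", bary, vn)
    ln = np.linalg.norm(n, axis=1, keepdims=True)
    return np.divide(n, ln, out=np.zeros_like(n), where=ln > 0)


def intersect_normal_lines(
    target: SurfaceLayer, origins: np.ndarray, directions: np.ndarray,
    chunk: int = 256,
):
    """Intersect full lines (both directions) with a layer's triangles.

    Vectorized Moller-Trumbore.  Returns ``(tri_index, points, t, hit)``
    where ``t`` is the signed line parameter of the chosen intersection:
    the nearest by ``|t|``, ties broken toward the positive direction.
    Degenerate (zero) directions simply miss.
    """
    origins = np.atleast_2d(np.asarray(origins, dtype=float))
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    tri = target.tri_xyz
    v0, e1, e2 = tri[:, 0], tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]

    n = len(origins)
    out_tri = np.full(n, -1, dtype=np.intp)
    out_t = np.full(n, np.nan)
    out_pt = np.full((n, 3), np.nan)

    eps = 1e-12
    for s in range(0, n, chunk):
        o = origins[s : s + chunk][:, None, :]       # (q, 1, 3)
        d = directions[s : s + chunk][:, None, :]
        h = np.cross(d, e2[None, :, :])              # (q, T, 3)
        a = np.einsum("qtd,td->qt", h, e1)
        valid = np.abs(a) > eps
        inv_a = np.where(valid, a, 1.0) ** -1
        sv = o - v0[None, :, :]
        u = np.einsum("qtd,qtd->qt", sv, h) * inv_a
        q = np.cross(sv, e1[None, :, :])
        v = np.einsum("qtd,qtd->qt", q, np.broadcast_to(d, q.shape)) * inv_a
        t = np.einsum("qtd,td->qt", q, e2) * inv_a
        bt = 1e-9
        hitm = valid & (u >= -bt) & (v >= -bt) & (u + v <= 1 + bt)
        # nearest |t|, ties toward positive t, then lowest triangle index
        key = np.where(hitm, np.abs(t), np.inf)
        key = key + np.where(hitm & (t < 0), 1e-15 * (1 + np.abs(t)), 0.0)
        best = np.argmin(key, axis=1)
        rows = np.arange(key.shape[0])
        found = np.isfinite(key[rows, best])
        idx = s + rows[found]
        out_tri[idx] = best[found]
        out_t[idx] = t[rows[found], best[found]]
        out_pt[idx] = (
            origins[idx] + out_t[idx][:, None] * directions[s : s + chunk][rows[found]]
        )
    return out_tri, out_pt, out_t, out_tri >= 0


# ---------------------------------------------------------------------------
# Batch mapping primitives (arrays in, arrays out)
# ---------------------------------------------------------------------------

def _check_same_topology(src: SurfaceLayer, tgt: SurfaceLayer) -> None:
    if len(src.faces) != len(tgt.faces) or len(src.vertices) != len(tgt.vertices):
        raise MappingError(
            f"topology mismatch between {src.name!r} and {tgt.name!r}: "
            f"{len(src.faces)} vs {len(tgt.faces)} faces"
        )
    for i, (f, g) in enumerate(zip(src.faces, tgt.faces)):
        if f != g:
            raise MappingError(
                f"topology mismatch between {src.name!r} and {tgt.name!r}: "
                f"face {i} differs ({f} vs {g})"
            )


def _map_topological_batch(src, tgt, tri_idx, bary):
    _check_same_topology(src, tgt)
    return tri_idx.copy(), bary.copy(), np.ones(len(tri_idx), dtype=bool)


def _map_normal_batch(src, tgt, tri_idx, bary):
    origins = src.bary_to_xyz(tri_idx, bary)
    normals = _interp_normals(src, tri_idx, bary)
    degenerate = np.linalg.norm(normals, axis=1) == 0
    t_tri, pts, _, hit = intersect_normal_lines(tgt, origins, normals)
    hit &= ~degenerate
    out_bary = np.zeros((len(tri_idx), 3))
    if hit.any():
        out_bary[hit] = _xyz_to_bary(tgt, t_tri[hit], pts[hit])
    t_tri[~hit] = -1
    return t_tri, out_bary, hit


def _map_euclidean_batch(src, tgt, tri_idx, bary):
    pts = src.bary_to_xyz(tri_idx, bary)
    t_tri, cp, _ = closest_point_on_layer(tgt, pts)
    return t_tri, _xyz_to_bary(tgt, t_tri, cp), np.ones(len(tri_idx), dtype=bool)


def _map_random_batch(tgt, n, rng):
    areas = tgt.tri_areas
    total = areas.sum()
    if total <= 0:
        raise MappingError(f"target layer {tgt.name!r} has zero area")
    tri = rng.choice(len(areas), size=n, p=areas / total)
    r1 = np.sqrt(rng.random(n))
    r2 = rng.random(n)
    bary = np.stack([1.0 - r1, r1 * (1.0 - r2), r1 * r2], axis=1)
    return tri, bary, np.ones(n, dtype=bool)


_BATCH = {
    "topological": _map_topological_batch,
    "normal": _map_normal_batch,
    "euclidean": _map_euclidean_batch,
}


def apply_mapping_batch(kind, src, tgt, tri_idx, bary, rng=None):
    """Apply one mapping operator to arrays of surface points."""
    if kind == "random":
        if rng is None:
            raise ValueError("random mapping requires an rng")
        return _map_random_batch(tgt, len(tri_idx), rng)
    return _BATCH[kind](src, tgt, tri_idx, bary)


# ---------------------------------------------------------------------------
# Single-point API
# ---------------------------------------------------------------------------

def _single(layer_tgt, tri, bary, ok):
    if not ok[0]:
        return None
    return SurfacePoint.from_bary(layer_tgt, tri[0], bary[0])


def map_topological(src: SurfaceLayer, tgt: SurfaceLayer, point: SurfacePoint) -> SurfacePoint:
    """Re-anchor a point on a layer with identical face/corner structure."""
    tri, bary, ok = _map_topological_batch(
        src, tgt, np.asarray([point.tri_index]), np.asarray([point.bary])
    )
    return _single(tgt, tri, bary, ok)


def map_normal(src: SurfaceLayer, tgt: SurfaceLayer, point: SurfacePoint) -> SurfacePoint | None:
    """Project along the interpolated surface normal line; ``None`` on miss."""
    tri, bary, ok = _map_normal_batch(
        src, tgt, np.asarray([point.tri_index]), np.asarray([point.bary])
    )
    return _single(tgt, tri, bary, ok)


def map_euclidean(src: SurfaceLayer, tgt: SurfaceLayer, point: SurfacePoint) -> SurfacePoint:
    """Globally closest point on the target surface."""
    tri, bary, ok = _map_euclidean_batch(
        src, tgt, np.asarray([point.tri_index]), np.asarray([point.bary])
    )
    return _single(tgt, tri, bary, ok)


def map_random(
    src: SurfaceLayer, tgt: SurfaceLayer, point: SurfacePoint, rng: np.random.Generator
) -> SurfacePoint:
    """Area-uniform random point on the target, independent of the query."""
    tri, bary, ok = _map_random_batch(tgt, 1, rng)
    return _single(tgt, tri, bary, ok)


def traverse_chain(
    layers: dict,
    steps: list,
    start_layer: str,
    start_point: SurfacePoint,
    rng: np.random.Generator | None = None,
):
    """Apply each step's mapping in order; returns the per-layer point list.

    A normal-mapping miss anywhere aborts with ``None`` — the neuron's
    projection never reaches the synaptic layer.
    """
    pts = [start_point]
    cur_layer = layers[start_layer]
    cur = start_point
    for step in steps:
        tgt = layers[step.target_layer]
        if step.mapping == "random":
            nxt = map_random(cur_layer, tgt, cur, rng)
        else:
            nxt = {
                "topological": map_topological,
                "normal": map_normal,
                "euclidean": map_euclidean,
            }[step.mapping](cur_layer, tgt, cur)
        if nxt is None:
            return None
        pts.append(nxt)
        cur_layer, cur = tgt, nxt
    return pts


def traverse_chain_batch(layers, steps, start_layer, tri_idx, bary, rng=None):
    """Vectorized chain traversal for whole populations.

    Returns ``(per_layer, alive)`` where ``per_layer`` is a list (one entry
    per visited layer, starting layer included) of ``(layer_name, tri, bary)``
    with arrays over the full population, and ``alive`` flags neurons whose
    chain completed.  Entries of dead neurons are -1 / zeros past the miss.
    """
    n = len(tri_idx)
    alive = np.ones(n, dtype=bool)
    cur_tri = np.asarray(tri_idx, dtype=np.intp).copy()
    cur_bary = np.asarray(bary, dtype=float).copy()
    per_layer = [(start_layer, cur_tri.copy(), cur_bary.copy())]
    cur_layer = layers[start_layer]
    for step in steps:
        tgt = layers[step.target_layer]
        nxt_tri = np.full(n, -1, dtype=np.intp)
        nxt_bary = np.zeros((n, 3))
        idx = np.nonzero(alive)[0]
        if len(idx):
            t, b, ok = apply_mapping_batch(
                step.mapping, cur_layer, tgt, cur_tri[idx], cur_bary[idx], rng
            )
            nxt_tri[idx] = np.where(ok, t, -1)
            nxt_bary[idx[ok]] = b[ok]
            alive[idx[~ok]] = False
        per_layer.append((step.target_layer, nxt_tri, nxt_bary))
        cur_layer = tgt
        cur_tri, cur_bary = nxt_tri, nxt_bary
    return per_layer, alive
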