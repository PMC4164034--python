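"""Programmatic surface fixtures with closed-form areas.

Generators for the geometric situations the rest of the package is tested
against: flat sheets, partial cylinders ("tube strips", the classic simple
approximation of an elongated neuronal layer), and cone/frustum strips whose
circumference — the septo-temporal analog — grows from a proximal to a distal
radius.  Plus structural editors: normal offset (a synaptic layer coating a
soma layer), axis mirroring (reversed topographic projections), and midpoint
subdivision (an intermediate layer with a finer mesh).

All generators are deterministic and expose the analytic areas implied by
their parameters, so statistical tests can use closed-form expectations.

Chart conventions: sheets carry an isometric chart (chart units = mm);
tube/cone strips use the unit square with ``u`` circumferential and ``v``
axial.  ``arc_length_at_v`` converts between the two on strips.
"""

from __future__ import annotations

import numpy as np

from .layers import SurfaceLayer

__all__ = [
    "make_sheet",
    "make_tube_strip",
    "make_cone_strip",
    "offset_layer",
    "mirror_layer",
    "subdivided_copy",
    "tube_strip_area",
    "cone_strip_area",
    "cone_band_area",
    "arc_length_at_v",
]


def _grid_quads(nu: int, nv: int):
    """Quad faces of an (nu+1) x (nv+1) vertex grid, corner order CCW."""
    faces = []
    for j in range(nv):
        for i in range(nu):
            a = j * (nu + 1) + i
            faces.append((a, a + 1, a + nu + 2, a + nu + 1))
    return faces


def make_sheet(
    width: float, height: float, nu: int = 8, nv: int = 8, name: str = "sheet"
) -> SurfaceLayer:
    """Planar quad grid in the z=0 plane with an isometric chart (uv in mm)."""
    if width <= 0 or height <= 0 or nu < 1 or nv < 1:
        raise ValueError("sheet dimensions and resolution must be positive")
    us = np.linspace(0.0, width, nu + 1)
    vs = np.linspace(0.0, height, nv + 1)
    uu, vv = np.meshgrid(us, vs)
    verts = np.stack([uu.ravel(), vv.ravel(), np.zeros(uu.size)], axis=1)
    faces = _grid_quads(nu, nv)
    uv = verts[:, :2]
    uv_corners = [uv[list(f)] for f in faces]
    return SurfaceLayer(name=name, vertices=verts, faces=faces, uv_corners=uv_corners)


def _strip(radius_fn, length, arc_fraction, n_arc, n_len, name):
    """Shared builder for tube and cone strips.

    Axis along z (v direction, axial position = v * length); circumferential
    angle = u * arc_fraction * 2*pi.  The chart is the unit square.  A full
    tube (arc_fraction == 1) duplicates the seam vertices so the chart stays
    injective.
    """
    if length <= 0 or not (0 < arc_fraction <= 1) or n_arc < 2 or n_len < 1:
        raise ValueError("invalid strip parameters")
    us = np.linspace(0.0, 1.0, n_arc + 1)
    vs = np.linspace(0.0, 1.0, n_len + 1)
    uu, vv = np.meshgrid(us, vs)
    theta = uu * arc_fraction * 2.0 * np.pi
    r = radius_fn(vv)
    verts = np.stack(
        [r * np.cos(theta), r * np.sin(theta), vv * length], axis=-1
    ).reshape(-1, 3)
    faces = _grid_quads(n_arc, n_len)
    uv = np.stack([uu.ravel(), vv.ravel()], axis=1)
    uv_corners = [uv[list(f)] for f in faces]
    return SurfaceLayer(name=name, vertices=verts, faces=faces, uv_corners=uv_corners)


def make_tube_strip(
    radius: float,
    length: float,
    arc_fraction: float = 0.5,
    n_arc: int = 64,
    n_len: int = 16,
    name: str = "tube_strip",
) -> SurfaceLayer:
    """Partial cylinder: u = circumferential (arc) coordinate, v = axial."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    return _strip(lambda vv: np.full_like(vv, float(radius)), length, arc_fraction,
                  n_arc, n_len, name)


def make_cone_strip(
    r_proximal: float,
    r_distal: float,
    length: float,
    arc_fraction: float = 0.5,
    n_arc: int = 64,
    n_len: int = 16,
    name: str = "cone_strip",
) -> SurfaceLayer:
    """Frustum strip whose circumference grows from proximal to distal end.

    ``u`` runs circumferentially (septo-temporal analog: the arc at the
    proximal end, v=0, is shorter than at the distal end, v=1) and ``v``
    axially (proximal-distal analog).  ``r_proximal == r_distal`` reduces to
    a tube strip.
    """
    if r_proximal <= 0 or r_distal <= 0:
        raise ValueError("radii must be positive")
    rp, rd = float(r_proximal), float(r_distal)
    return _strip(lambda vv: rp + (rd - rp) * vv, length, arc_fraction,
                  n_arc, n_len, name)


def tube_strip_area(radius: float, length: float, arc_fraction: float = 0.5) -> float:
    """Closed-form area of a tube strip."""
    return 2.0 * np.pi * radius * arc_fraction * length


def cone_strip_area(
    r_proximal: float, r_distal: float, length: float, arc_fraction: float = 0.5
) -> float:
    """Closed-form slant area of a cone strip (lateral frustum area)."""
    slant = np.hypot(length, r_distal - r_proximal)
    return np.pi * (r_proximal + r_distal) * arc_fraction * slant


def cone_band_area(
    r_proximal: float,
    r_distal: float,
    length: float,
    v0: float,
    v1: float,
    arc_fraction: float = 0.5,
) -> float:
    """Analytic area of the axial band v in [v0, v1] of a cone strip.

    Bands at the distal end are wider; for thin end bands the distal/proximal
    area ratio approaches ``r_distal / r_proximal``.
    """
    r0 = r_proximal + (r_distal - r_proximal) * v0
    r1 = r_proximal + (r_distal - r_proximal) * v1
    slant = np.hypot(length, r_distal - r_proximal) * (v1 - v0)
    return np.pi * (r0 + r1) * arc_fraction * slant


def arc_length_at_v(
    r_proximal: float, r_distal: float, v, arc_fraction: float = 0.5
):
    """Circumferential (septo-temporal) metric length of the strip at ``v``."""
    r = r_proximal + (r_distal - r_proximal) * np.asarray(v, dtype=float)
    return 2.0 * np.pi * r * arc_fraction


def offset_layer(layer: SurfaceLayer, distance: float, name: str | None = None) -> SurfaceLayer:
    """Displace every vertex along its angle-weighted normal.

    Topology and UV corners are copied verbatim, so a topological mapping
    between the source and the offset copy is valid by construction.  This is
    how a synaptic layer coating a soma layer is generated.
    """
    out = layer.copy(name or f"{layer.name}_offset")
    out.vertices = layer.vertices + distance * layer.vertex_normals
    out._cache.clear()
    return out


def mirror_layer(layer: SurfaceLayer, axis: int, name: str | None = None) -> SurfaceLayer:
    """Negate one coordinate axis (0=x, 1=y, 2=z).

    Topology and UV corners are preserved and face winding is left unchanged,
    so normals flip orientation.  Used to build reversed topographic
    projections (proximal end of the source maps to the distal end of the
    mirrored chart).
    """
    if axis not in (0, 1, 2):
        raise ValueError("axis must be 0, 1 or 2")
    out = layer.copy(name or f"{layer.name}_mirror")
    out.vertices = layer.vertices.copy()
    out.vertices[:, axis] *= -1.0
    out._cache.clear()
    return out


def subdivided_copy(layer: SurfaceLayer, levels: int = 1, name: str | None = None) -> SurfaceLayer:
    """Midpoint subdivision of the triangulated view (faces x4 per level).

    The result is deliberately *not* topologically identical to the source —
    it exercises normal/Euclidean mappings between layers of differing mesh
    structure, the situation where topological transfer is unavailable.
    """
    if levels < 0:
        raise ValueError("levels must be >= 0")
    cur = layer.copy(name or f"{layer.name}_subdiv")
    for _ in range(levels):
        verts = list(cur.vertices)
        tris = cur.tris
        tri_uv = cur.tri_uv
        edge_mid: dict = {}

        def midpoint(i, j):
            key = (min(i, j), max(i, j))
            if key not in edge_mid:
                edge_mid[key] = len(verts)
                verts.append(0.5 * (cur.vertices[i] + cur.vertices[j]))
            return edge_mid[key]

        faces, uv_corners = [], []
        for t in range(len(tris)):
            a, b, c = (int(x) for x in tris[t])
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            ua, ub_, uc = tri_uv[t]
            uab, ubc, uca = 0.5 * (ua + ub_), 0.5 * (ub_ + uc), 0.5 * (uc + ua)
            for f, uvf in (
                ((a, ab, ca), (ua, uab, uca)),
                ((ab, b, bc), (uab, ub_, ubc)),
                ((ca, bc, c), (uca, ubc, uc)),
                ((ab, bc, ca), (uab, ubc, uca)),
            ):
                faces.append(f)
                uv_corners.append(np.asarray(uvf))
        cur = SurfaceLayer(
            name=cur.name, vertices=np.asarray(verts), faces=faces, uv_corners=uv_corners
        )
    return cur
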