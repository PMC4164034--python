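"""Connection lengths along mapping chains, and conduction delays.

Each chain step measures the inter-layer leg of the connection in one of
three base modes:

* ``euclidean`` — straight chord between the point and its image,
* ``normal`` — length along the surface-normal line to its intersection
  with the next layer,
* ``jump`` — distance from the point to its closest point on the next layer
  (a lower bound irrespective of where the image actually landed).

A ``UV`` affix adds the along-surface distance on the layer just reached,
measured by discretizing the straight chart segment from the arrival point
to the origin of the next hop — on the synaptic layer, to the synapse
itself.  That is the term that accounts for neurites growing along a curved
sheet instead of through it.  All lengths are lower-bound estimates: real
arbors meander, these paths do not.

Delays are length times a latency rate (default 4.36 ms/mm, the measured
conduction latency of CA3 axons in rat), optionally jittered by a
multiplicative lognormal factor with mean 1 to emulate developmental
variability in myelination and neurite length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import SurfaceLayer, SurfacePoint, uv_path_lengths
from .mapping import (
    MappingChain,
    _interp_normals,
    closest_point_on_layer,
    intersect_normal_lines,
)
from .sampling import Connectome, ProjectionResult

__all__ = [
    "DelayModel",
    "step_length",
    "connection_length",
    "attach_distances",
    "to_delay",
]

DEFAULT_RATE_MS_PER_MM = 4.36


@dataclass(frozen=True)
class DelayModel:
    """Length-to-delay conversion: ``delay = rate * length * noise``.

    ``rate`` is in ms per mm.  ``jitter_cv`` is the coefficient of variation
    of the multiplicative lognormal noise factor (mean 1); 0 disables noise.
    The lognormal is strictly positive, so delays are never negative.
    """

    rate: float = DEFAULT_RATE_MS_PER_MM
    jitter_cv: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.jitter_cv < 0:
            raise ValueError("jitter_cv must be >= 0")


def to_delay(length_mm, model: DelayModel, rng: np.random.Generator | None = None):
    """Convert path lengths (mm) to conduction delays (ms).

    With ``jitter_cv > 0`` each delay is multiplied by an independent
    lognormal factor with mean 1 and the requested coefficient of variation.
    Scalar in, scalar out; array in, array out.
    """
    scalar = np.isscalar(length_mm)
    length = np.atleast_1d(np.asarray(length_mm, dtype=float))
    if (length < 0).any():
        raise ValueError("lengths must be >= 0")
    delay = model.rate * length
    if model.jitter_cv > 0:
        if rng is None:
            rng = np.random.default_rng(model.seed)
        s2 = np.log1p(model.jitter_cv**2)
        factor = rng.lognormal(mean=-0.5 * s2, sigma=np.sqrt(s2), size=len(length))
        delay = delay * factor
    return float(delay[0]) if scalar else delay


# ---------------------------------------------------------------------------
# Step lengths
# ---------------------------------------------------------------------------

def _base_mode(mode: str) -> str:
    return mode[:-2] if mode.endswith("UV") else mode


def step_length_batch(
    mode: str,
    layer_from: SurfaceLayer,
    layer_to: SurfaceLayer,
    tri_from: np.ndarray,
    bary_from: np.ndarray,
    xyz_to: np.ndarray,
) -> np.ndarray:
    """Vectorized inter-layer leg lengths for one chain step (base mode only)."""
    base = _base_mode(mode)
    xyz_from = layer_from.bary_to_xyz(tri_from, bary_from)
    if base == "euclidean":
        return np.linalg.norm(xyz_to - xyz_from, axis=1)
    if base == "jump":
        _, _, d = closest_point_on_layer(layer_to, xyz_from)
        return d
    if base == "normal":
        normals = _interp_normals(layer_from, tri_from, bary_from)
        _, _, t, hit = intersect_normal_lines(layer_to, xyz_from, normals)
        if not hit.all():
            raise ValueError(
                "normal-mode distance requested for a point whose normal line "
                "misses the target layer"
            )
        return np.abs(t)
    raise ValueError(f"unknown distance mode {mode!r}")


def step_length(
    mode: str,
    from_point: SurfacePoint,
    to_point: SurfacePoint,
    layer_from: SurfaceLayer,
    layer_to: SurfaceLayer,
) -> float:
    """Inter-layer leg length (mm) between a point and its mapped image."""
    return float(
        step_length_batch(
            mode,
            layer_from,
            layer_to,
            np.asarray([from_point.tri_index]),
            np.asarray([from_point.bary]),
            np.asarray([to_point.xyz]),
        )[0]
    )


# ---------------------------------------------------------------------------
# Full connection lengths
# ---------------------------------------------------------------------------

def _side_lengths(
    layers: dict,
    steps: list,
    chain_points: list,      # [(layer_name, tri, bary)] including start layer
    syn_uv: np.ndarray,      # (n_syn, 2) synapse chart positions
    syn_xyz: np.ndarray,
    entry_sel: np.ndarray,   # neuron id per synapse
    max_step: float | None,
) -> np.ndarray:
    """Path length of one side, per synapse (vectorized over synapses)."""
    n_syn = len(entry_sel)
    total = np.zeros(n_syn)
    # Legs before the synaptic layer are per neuron.  The UV affix adds the
    # along-surface distance on the layer just reached, from the arrival
    # point to the origin of the next hop; traversal continues from the
    # arrival point itself, so that term vanishes on intermediate layers and
    # is realized on the synaptic layer (arrival -> synapse) below.
    per_neuron = np.zeros(len(chain_points[0][1]))
    for k, step in enumerate(steps[:-1] if steps else []):
        name_from, tri_f, bary_f = chain_points[k]
        name_to, tri_t, bary_t = chain_points[k + 1]
        lf, lt = layers[name_from], layers[name_to]
        idx = np.nonzero((tri_f >= 0) & (tri_t >= 0))[0]
        if len(idx) == 0:
            continue
        xyz_to = lt.bary_to_xyz(tri_t[idx], bary_t[idx])
        per_neuron[idx] += step_length_batch(
            step.distance_mode, lf, lt, tri_f[idx], bary_f[idx], xyz_to
        )
    total += per_neuron[entry_sel]

    if not steps:
        # Population lives on the synaptic layer itself: the trajectory is
        # the chord from the soma to the synapse.
        sl_name, tri_e, bary_e = chain_points[-1]
        sl = layers[sl_name]
        entry_xyz = sl.bary_to_xyz(tri_e[entry_sel], bary_e[entry_sel])
        total += np.linalg.norm(syn_xyz - entry_xyz, axis=1)
        return total

    # Final hop onto the synaptic layer: the trajectory ends at the synapse.
    last = steps[-1]
    name_from, tri_f, bary_f = chain_points[-2]
    sl_name, tri_e, bary_e = chain_points[-1]
    lf, sl = layers[name_from], layers[sl_name]
    tri_fs, bary_fs = tri_f[entry_sel], bary_f[entry_sel]
    base = _base_mode(last.distance_mode)
    if base == "euclidean" and not last.distance_mode.endswith("UV"):
        # shortest distance straight to the synapse itself
        xyz_from = lf.bary_to_xyz(tri_fs, bary_fs)
        total += np.linalg.norm(syn_xyz - xyz_from, axis=1)
    else:
        entry_xyz = sl.bary_to_xyz(tri_e[entry_sel], bary_e[entry_sel])
        total += step_length_batch(
            last.distance_mode, lf, sl, tri_fs, bary_fs, entry_xyz
        )
        if last.distance_mode.endswith("UV"):
            entry_uv = sl.bary_to_uv(tri_e[entry_sel], bary_e[entry_sel])
            total += uv_path_lengths(sl, entry_uv, syn_uv, max_step)
        else:
            # normal/jump without the UV affix measure only the inter-layer
            # leg; the residual offset to the synapse is the straight chord.
            total += np.linalg.norm(syn_xyz - entry_xyz, axis=1)
    return total


def connection_length(
    chain: MappingChain,
    pre_chain_points: list,
    synapse: SurfacePoint,
    post_chain_points: list,
    max_step: float | None = None,
) -> tuple:
    """(pre_mm, post_mm, total_mm) for one synapse.

    ``pre_chain_points``/``post_chain_points`` are the per-layer point lists
    produced by chain traversal for the two neurons involved.
    """

    def pack(points):
        return [
            (p.layer, np.asarray([p.tri_index]), np.asarray([p.bary]))
            for p in points
        ]

    syn_uv = np.asarray([synapse.uv])
    syn_xyz = np.asarray([synapse.xyz])
    sel = np.zeros(1, dtype=np.intp)
    pre = _side_lengths(chain.layers, chain.pre_steps, pack(pre_chain_points),
                        syn_uv, syn_xyz, sel, max_step)[0]
    post = _side_lengths(chain.layers, chain.post_steps, pack(post_chain_points),
                         syn_uv, syn_xyz, sel, max_step)[0]
    return float(pre), float(post), float(pre + post)


def attach_distances(
    chain: MappingChain,
    conn: Connectome,
    proj: ProjectionResult,
    delay_model: DelayModel | None = None,
    rng: np.random.Generator | None = None,
    max_step: float | None = None,
) -> Connectome:
    """Fill per-synapse path lengths (and delays) into a sampled connectome."""
    conn.pre_mm = _side_lengths(
        chain.layers, chain.pre_steps, proj.pre_layers,
        conn.syn_uv, conn.syn_xyz, conn.pre_id, max_step,
    )
    conn.post_mm = _side_lengths(
        chain.layers, chain.post_steps, proj.post_layers,
        conn.syn_uv, conn.syn_xyz, conn.post_id, max_step,
    )
    conn.total_mm = conn.pre_mm + conn.post_mm
    if delay_model is not None:
        conn.delay_ms = to_delay(conn.total_mm, delay_model, rng)
        conn.provenance["delay_rate_ms_per_mm"] = delay_model.rate
    return conn
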