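"""Synapse generation on the synaptic layer.

Connections are drawn from the product model: the probability of a synapse
at chart position ``z`` between pre-synaptic neuron ``i`` and post-synaptic
neuron ``j`` is proportional to ``w_pre(z | z_i) * w_post(z | z_j)``, where
``z_i, z_j`` are the chart positions at which each neuron's projection
entered the synaptic layer.  Two samplers realize this model:

* :func:`sample_exact` — forms the full discrete joint over (bin, post
  neuron) for every pre-synaptic neuron and samples it directly.  This is
  the reference sampler; cost grows with bins x posts per pre neuron.
* :func:`sample_fast` — the accelerated bin-grid sampler.  The synaptic
  layer's chart is rastered into ``cu x cv`` bins; each post neuron is
  registered in every bin where its kernel weight reaches a fraction ``p0``
  of its peak (weights stored).  Per pre neuron, bins are drawn from the pre
  kernel at bin centers (bins below fraction ``p1`` of the peak skipped)
  multiplied by the bin's total registered post weight (the evidence term of
  Bayes' rule), then the post partner within the bin is drawn proportionally
  to its stored weight.  With zero thresholds this targets exactly the same
  joint as the exact sampler; positive thresholds trade tail mass for speed.

Synapse positions are drawn uniformly within the chosen bin and realized on
the surface through the chart; draws that land off-chart are retried a
bounded number of times and then dropped with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .kernels import KernelSpec, evaluate_kernel
from .layers import SurfaceLayer, points_from_uv
from .mapping import MappingChain, traverse_chain_batch

__all__ = [
    "SamplerConfig",
    "BinGrid",
    "Connectome",
    "ProjectionResult",
    "project_populations",
    "build_bin_grid",
    "sample_exact",
    "sample_fast",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SamplerConfig:
    """Bin-grid sampler settings.

    ``p0`` (post registration) and ``p1`` (pre bin skip) are fractions of
    each neuron's own peak weight over the bin centers; 0 recovers the exact
    discretized model.  ``per_post`` switches the synapse budget from
    outgoing-per-pre to incoming-per-post (roles swapped internally).
    """

    cu: int = 16
    cv: int = 16
    p0: float = 1e-3
    p1: float = 1e-3
    n_synapses_per_pre: int | None = None
    seed: int = 0
    max_retries: int = 10
    per_post: bool = False

    def __post_init__(self):
        if self.cu < 1 or self.cv < 1:
            raise ValueError("bin grid must be at least 1 x 1")
        if not (0 <= self.p0 < 1 and 0 <= self.p1 < 1):
            raise ValueError("thresholds must lie in [0, 1)")


@dataclass
class BinGrid:
    """Raster over the synaptic layer chart with registered post neurons.

    ``weights`` is dense ``(n_bins, m)``: entry ``[b, j]`` is post neuron
    ``j``'s kernel weight at bin ``b``'s center, zeroed where it fell below
    ``p0`` times that neuron's peak.  ``evidence`` is the per-bin total.
    """

    rect: tuple              # (umin, umax, vmin, vmax)
    cu: int
    cv: int
    weights: np.ndarray
    p0: float

    def __post_init__(self):
        self.evidence = self.weights.sum(axis=1)

    @property
    def n_bins(self) -> int:
        return self.cu * self.cv

    def bin_centers(self) -> np.ndarray:
        umin, umax, vmin, vmax = self.rect
        us = umin + (np.arange(self.cu) + 0.5) * (umax - umin) / self.cu
        vs = vmin + (np.arange(self.cv) + 0.5) * (vmax - vmin) / self.cv
        uu, vv = np.meshgrid(us, vs, indexing="ij")
        return np.stack([uu.ravel(), vv.ravel()], axis=1)

    def bin_entries(self, b: int):
        """(post_id, stored weight) pairs registered in bin ``b``."""
        ids = np.nonzero(self.weights[b] > 0)[0]
        return list(zip(ids.tolist(), self.weights[b, ids].tolist()))

    def uniform_in_bin(self, bins: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        umin, umax, vmin, vmax = self.rect
        du = (umax - umin) / self.cu
        dv = (vmax - vmin) / self.cv
        iu, iv = np.divmod(bins, self.cv)
        u = umin + (iu + rng.random(len(bins))) * du
        v = vmin + (iv + rng.random(len(bins))) * dv
        return np.stack([u, v], axis=1)


@dataclass
class ProjectionResult:
    """Both populations carried onto the synaptic layer."""

    pre_layers: list          # [(layer_name, tri, bary)] along the pre chain
    post_layers: list
    pre_alive: np.ndarray
    post_alive: np.ndarray
    pre_entry_uv: np.ndarray  # chart positions on the SL (NaN where dead)
    post_entry_uv: np.ndarray

    @property
    def unconnected_pre(self) -> np.ndarray:
        return np.nonzero(~self.pre_alive)[0]

    @property
    def unconnected_post(self) -> np.ndarray:
        return np.nonzero(~self.post_alive)[0]


@dataclass
class Connectome:
    """The sampled synapse set plus provenance.

    Parallel arrays over synapse records, in sampling order (deterministic
    for a fixed seed): neuron ids, the synapse location on the synaptic
    layer, per-side and total path lengths (mm, filled by the distance
    stage) and conduction delays (ms, filled by the delay stage).
    """

    pre_id: np.ndarray
    post_id: np.ndarray
    syn_tri: np.ndarray
    syn_bary: np.ndarray
    syn_uv: np.ndarray
    syn_xyz: np.ndarray
    bin_index: np.ndarray
    pre_mm: np.ndarray
    post_mm: np.ndarray
    total_mm: np.ndarray
    delay_ms: np.ndarray
    unconnected_pre: np.ndarray
    unconnected_post: np.ndarray
    n_pre: int
    n_post: int
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pre_id)

    @property
    def fill_fraction(self) -> float:
        """alpha in s = alpha * n * m."""
        return len(self) / (self.n_pre * self.n_post) if self.n_pre and self.n_post else 0.0

    def validate(self) -> None:
        for name in ("pre_id", "post_id"):
            ids = getattr(self, name)
            n = self.n_pre if name == "pre_id" else self.n_post
            if len(ids) and (ids.min() < 0 or ids.max() >= n):
                raise ValueError(f"{name} out of range")
        if (self.total_mm < 0).any() or (self.delay_ms < 0).any():
            raise ValueError("negative length or delay")


# ---------------------------------------------------------------------------

def project_populations(chain: MappingChain, rng: np.random.Generator) -> ProjectionResult:
    """Traverse both chains for every neuron; misses become unconnected."""
    pre_pop, post_pop = chain.pre_population, chain.post_population
    pre_layers, pre_alive = traverse_chain_batch(
        chain.layers, chain.pre_steps, pre_pop.layer, pre_pop.tri_index, pre_pop.bary, rng
    )
    post_layers, post_alive = traverse_chain_batch(
        chain.layers, chain.post_steps, post_pop.layer, post_pop.tri_index, post_pop.bary, rng
    )
    sl = chain.synaptic_layer

    def entry_uv(layer_list, alive):
        _, tri, bary = layer_list[-1]
        uv = np.full((len(tri), 2), np.nan)
        if alive.any():
            uv[alive] = sl.bary_to_uv(tri[alive], bary[alive])
        return uv

    return ProjectionResult(
        pre_layers=pre_layers,
        post_layers=post_layers,
        pre_alive=pre_alive,
        post_alive=post_alive,
        pre_entry_uv=entry_uv(pre_layers, pre_alive),
        post_entry_uv=entry_uv(post_layers, post_alive),
    )


def _grid_rect(sl: SurfaceLayer) -> tuple:
    umin, umax, vmin, vmax = sl.uv_bounds
    if umax <= umin or vmax <= vmin:
        raise ValueError("synaptic layer chart has zero extent")
    return (umin, umax, vmin, vmax)


def build_bin_grid(
    sl: SurfaceLayer,
    post_entry_uv: np.ndarray,
    kernel_post: KernelSpec,
    config: SamplerConfig,
) -> BinGrid:
    """Register every post neuron in the bins where its kernel is non-negligible.

    Stored weights are the kernel evaluated at bin centers; entries below
    ``p0`` times the neuron's peak (over the grid) are zeroed.  A warning is
    emitted when the kernel is narrower than about three bins, where the
    bin-center discretization gets coarse.
    """
    rect = _grid_rect(sl)
    n_bins = config.cu * config.cv
    centers = BinGrid(rect, config.cu, config.cv, np.zeros((n_bins, 0)), config.p0).bin_centers()
    m = len(post_entry_uv)
    W = np.zeros((n_bins, m))
    du = (rect[1] - rect[0]) / config.cu
    dv = (rect[3] - rect[2]) / config.cv
    sig = kernel_post.sigma
    if sig[0] < 3 * du or sig[1] < 3 * dv:
        log.warning(
            "post kernel width (%.3g, %.3g) spans fewer than 3 bins (%.3g, %.3g); "
            "consider a finer grid", sig[0], sig[1], du, dv,
        )
    for j in range(m):
        if not np.isfinite(post_entry_uv[j]).all():
            continue  # unconnected post neuron never registers
        w = evaluate_kernel(kernel_post, centers, post_entry_uv[j])
        peak = w.max()
        if peak <= 0:
            continue
        w[w < config.p0 * peak] = 0.0
        W[:, j] = w
    return BinGrid(rect, config.cu, config.cv, W, config.p0)


def _realize_positions(
    sl: SurfaceLayer, grid: BinGrid, bins: np.ndarray,
    rng: np.random.Generator, max_retries: int,
):
    """Uniform within-bin chart positions resolved on the surface.

    Returns (tri, bary, uv, kept_mask); off-chart draws are retried within
    the same bin up to ``max_retries`` times, then the synapse is dropped.
    """
    n = len(bins)
    uv = grid.uniform_in_bin(bins, rng)
    tri, bary, found = points_from_uv(sl, uv)
    tries = 0
    while not found.all() and tries < max_retries:
        idx = np.nonzero(~found)[0]
        uv[idx] = grid.uniform_in_bin(bins[idx], rng)
        t2, b2, f2 = points_from_uv(sl, uv[idx])
        tri[idx], bary[idx], found[idx] = t2, b2, f2
        tries += 1
    if not found.all():
        log.warning("dropped %d synapses whose bins do not overlap the chart",
                    int((~found).sum()))
    return tri, bary, uv, found


def _assemble(chain, config, sl, pre_ids, bins, posts, proj, grid, rng, algorithm):
    order = np.argsort(pre_ids, kind="stable")
    pre_ids, bins, posts = pre_ids[order], bins[order], posts[order]
    tri, bary, uv, kept = _realize_positions(sl, grid, bins, rng, config.max_retries)
    pre_ids, bins, posts = pre_ids[kept], bins[kept], posts[kept]
    tri, bary, uv = tri[kept], bary[kept], uv[kept]
    xyz = sl.bary_to_xyz(tri, bary) if len(tri) else np.zeros((0, 3))
    ns = len(pre_ids)
    conn = Connectome(
        pre_id=pre_ids,
        post_id=posts,
        syn_tri=tri,
        syn_bary=bary,
        syn_uv=uv,
        syn_xyz=xyz,
        bin_index=bins,
        pre_mm=np.full(ns, np.nan),
        post_mm=np.full(ns, np.nan),
        total_mm=np.full(ns, np.nan),
        delay_ms=np.full(ns, np.nan),
        unconnected_pre=proj.unconnected_pre,
        unconnected_post=proj.unconnected_post,
        n_pre=chain.pre_population.size,
        n_post=chain.post_population.size,
        provenance={
            "chain": chain.name,
            "algorithm": algorithm,
            "seed": config.seed,
            "cu": config.cu,
            "cv": config.cv,
            "p0": config.p0,
            "p1": config.p1,
        },
    )
    return conn


def _effective_chain(chain: MappingChain, config: SamplerConfig):
    """Swap pre/post roles for the incoming-budget mode."""
    if not config.per_post:
        return chain, False
    swapped = MappingChain(
        name=chain.name + "[per_post]",
        layers=chain.layers,
        pre_population=chain.post_population,
        post_population=chain.pre_population,
        pre_steps=chain.post_steps,
        post_steps=chain.pre_steps,
        kernel_pre=chain.kernel_post,
        kernel_post=chain.kernel_pre,
        n_synapses_per_pre=chain.n_synapses_per_pre,
    )
    return swapped, True


def _swap_back(conn: Connectome) -> Connectome:
    conn.pre_id, conn.post_id = conn.post_id, conn.pre_id
    conn.n_pre, conn.n_post = conn.n_post, conn.n_pre
    conn.unconnected_pre, conn.unconnected_post = conn.unconnected_post, conn.unconnected_pre
    conn.pre_mm, conn.post_mm = conn.post_mm, conn.pre_mm
    return conn


def sample_exact(
    chain: MappingChain, config: SamplerConfig, rng: np.random.Generator | None = None
) -> Connectome:
    """Reference sampler: draw from the full discrete (bin, post) joint.

    For each connected pre neuron the joint weight over all ``cu x cv`` bins
    and all post neurons is ``w_pre(center_b) * w_post_j(center_b)`` — no
    thresholds.  An all-zero joint (disjoint kernel supports) yields zero
    synapses for that neuron, with a warning.
    """
    chain, swapped = _effective_chain(chain, config)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    proj = project_populations(chain, rng)
    sl = chain.synaptic_layer
    rect = _grid_rect(sl)
    full = SamplerConfig(cu=config.cu, cv=config.cv, p0=0.0, p1=0.0,
                         seed=config.seed, max_retries=config.max_retries)
    grid = build_bin_grid(sl, proj.post_entry_uv, chain.kernel_post, full)
    centers = grid.bin_centers()
    n_syn = config.n_synapses_per_pre or chain.n_synapses_per_pre
    m = chain.post_population.size

    pre_ids, bins, posts = [], [], []
    for i in np.nonzero(proj.pre_alive)[0]:
        w_pre = evaluate_kernel(chain.kernel_pre, centers, proj.pre_entry_uv[i])
        joint = w_pre[:, None] * grid.weights   # (n_bins, m)
        total = joint.sum()
        if total <= 0:
            log.warning("pre neuron %d has an all-zero joint; no synapses", i)
            continue
        flat = rng.choice(joint.size, size=n_syn, p=(joint / total).ravel())
        b, j = np.divmod(flat, m)
        pre_ids.append(np.full(n_syn, i, dtype=np.intp))
        bins.append(b.astype(np.intp))
        posts.append(j.astype(np.intp))
    cat = (lambda xs: np.concatenate(xs) if xs else np.zeros(0, dtype=np.intp))
    conn = _assemble(chain, config, sl, cat(pre_ids), cat(bins), cat(posts),
                     proj, grid, rng, "exact")
    return _swap_back(conn) if swapped else conn


def sample_fast(
    chain: MappingChain,
    config: SamplerConfig,
    rng: np.random.Generator | None = None,
    grid: BinGrid | None = None,
    proj: ProjectionResult | None = None,
) -> Connectome:
    """Accelerated bin-grid sampler.

    Per pre neuron: evaluate the pre kernel at bin centers, skip bins below
    ``p1`` times its peak, weight the remainder by the bin evidence (total
    registered post weight), renormalize and draw bins; within each drawn
    bin draw the post partner proportionally to its stored weight.  Bins
    without registered posts carry zero evidence and are never drawn, so no
    retries are spent on them.
    """
    chain, swapped = _effective_chain(chain, config)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if proj is None:
        proj = project_populations(chain, rng)
    sl = chain.synaptic_layer
    if grid is None:
        grid = build_bin_grid(sl, proj.post_entry_uv, chain.kernel_post, config)
    centers = grid.bin_centers()
    n_syn = config.n_synapses_per_pre or chain.n_synapses_per_pre

    # cumulative post weights per bin for vectorized within-bin draws
    W = grid.weights
    cum = np.cumsum(W, axis=1)
    tot = cum[:, -1]

    pre_ids, bins, posts = [], [], []
    for i in np.nonzero(proj.pre_alive)[0]:
        w_pre = evaluate_kernel(chain.kernel_pre, centers, proj.pre_entry_uv[i])
        peak = w_pre.max()
        if peak <= 0:
            log.warning("pre neuron %d has zero kernel mass on the grid", i)
            continue
        w_pre[w_pre < config.p1 * peak] = 0.0
        bin_w = w_pre * grid.evidence
        total = bin_w.sum()
        if total <= 0:
            log.warning("pre neuron %d finds no admissible bins; no synapses", i)
            continue
        b = rng.choice(grid.n_bins, size=n_syn, p=bin_w / total)
        r = rng.random(n_syn) * tot[b]
        j = np.empty(n_syn, dtype=np.intp)
        for k in range(n_syn):  # searchsorted per drawn bin row
            j[k] = np.searchsorted(cum[b[k]], r[k], side="right")
        pre_ids.append(np.full(n_syn, i, dtype=np.intp))
        bins.append(b.astype(np.intp))
        posts.append(j)
    cat = (lambda xs: np.concatenate(xs) if xs else np.zeros(0, dtype=np.intp))
    conn = _assemble(chain, config, sl, cat(pre_ids), cat(bins), cat(posts),
                     proj, grid, rng, "fast")
    return _swap_back(conn) if swapped else conn
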