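"""Bundled surrogate models for the package's headline analyses.

Three ready-made networks built entirely from the synthetic fixtures:

* :func:`build_spread_models` — a matched cone-strip vs tube-strip pair for
  the connectivity-spread analysis: identical populations, synapse counts
  and (metric) kernels, differing only in layer morphology.  On the cone
  the septo-temporal circumference grows from the proximal to the distal
  end, so a homogeneous areal density puts more neurons per unit of the
  septo-temporal axis distally and an axon of fixed metric reach spans a
  different fraction of the axis depending on where it sits.
* :func:`build_ca_distance_model` — a CA3-to-CA1-like projection between
  two frustum segments sharing one synaptic layer, for comparing
  along-surface (UV) connection lengths against straight chords.
* :func:`build_hippocampal_loop` — a six-population feed-forward loop
  (sEC, DG, CA3, CA1, Sub, dEC) with seven projections, scaled population
  sizes in the experimentally estimated ratios, and literature connection
  weights, used to validate delay-ordered activity propagation.

These builders double as executable documentation of how layers, chains and
kernels compose; all sizes are deliberately desk-scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .distances import DelayModel, attach_distances
from .geometry import (
    arc_length_at_v,
    make_cone_strip,
    make_sheet,
    make_tube_strip,
    offset_layer,
)
from .kernels import KernelSpec
from .layers import place_neurons
from .mapping import MappingChain, MappingStep
from .sampling import SamplerConfig, project_populations, sample_fast
from .spiking import IzhikevichParams, Population

__all__ = [
    "metric_gauss2d",
    "build_spread_models",
    "build_ca_distance_model",
    "build_hippocampal_loop",
    "sample_loop_connectome",
    "loop_connection_arrays",
    "run_spread_comparison",
    "run_distance_comparison",
    "run_loop_simulation",
    "LOOP_WEIGHTS_MV",
    "LOOP_SIZES",
    "LOOP_IN_DEGREE",
    "LOOP_ORDER",
]


def metric_gauss2d(
    sigma_u_mm: float,
    sigma_v_chart: float,
    r_proximal: float,
    r_distal: float,
    arc_fraction: float,
) -> KernelSpec:
    """Gaussian kernel whose septo-temporal reach is fixed in millimetres.

    The strip chart is the unit square with ``u`` circumferential, so a
    metric reach ``sigma_u_mm`` corresponds to a chart width that shrinks as
    the local circumference grows.  The conversion uses the neuron's own
    axial position through the kernel's position-dependence hook.
    """

    def hook(neuron_uv):
        arc = arc_length_at_v(r_proximal, r_distal, neuron_uv[1], arc_fraction)
        return {"sigma": (sigma_u_mm / arc, sigma_v_chart)}

    return KernelSpec(kind="gauss2d", sigma=(0.1, sigma_v_chart), param_fn=hook)


@dataclass
class SpreadModel:
    """One arm of the cone-vs-tube comparison."""

    name: str
    layers: dict
    chain: MappingChain
    sampler: SamplerConfig


# Shared study conditions of the spread comparison.  The tube radius is the
# cone's mean radius, so both strips have near-identical extent; everything
# except the morphology is shared.
_SPREAD = dict(
    r_proximal=0.15,
    r_distal=1.05,
    length=2.0,
    arc_fraction=0.5,
    n_arc=48,
    n_len=24,
    n_pre=2000,
    n_post=2000,
    n_synapses_per_pre=20,
    sigma_u_mm=0.2,
    sigma_v_chart=0.1,
    layer_gap=0.2,
    cu=64,
    cv=32,
)


def build_spread_models(seed: int = 0) -> tuple:
    """(cone_model, tube_model) with identical populations, kernels, counts."""
    p = _SPREAD
    out = []
    for kind in ("cone", "tube"):
        if kind == "cone":
            soma = make_cone_strip(
                p["r_proximal"], p["r_distal"], p["length"], p["arc_fraction"],
                p["n_arc"], p["n_len"], name=f"{kind}_soma",
            )
            rp, rd = p["r_proximal"], p["r_distal"]
        else:
            r_mean = 0.5 * (p["r_proximal"] + p["r_distal"])
            soma = make_tube_strip(
                r_mean, p["length"], p["arc_fraction"], p["n_arc"], p["n_len"],
                name=f"{kind}_soma",
            )
            rp = rd = r_mean
        target = offset_layer(soma, p["layer_gap"], name=f"{kind}_target")
        sl = offset_layer(soma, 0.5 * p["layer_gap"], name=f"{kind}_sl")
        layers = {l.name: l for l in (soma, target, sl)}
        pre = place_neurons(soma, p["n_pre"], seed=seed)
        post = place_neurons(target, p["n_post"], seed=seed + 1)
        kern = metric_gauss2d(
            p["sigma_u_mm"], p["sigma_v_chart"], rp, rd, p["arc_fraction"]
        )
        chain = MappingChain(
            name=f"{kind}_projection",
            layers=layers,
            pre_population=pre,
            post_population=post,
            pre_steps=[MappingStep(sl.name, "euclidean", "euclidean")],
            post_steps=[MappingStep(sl.name, "euclidean", "euclidean")],
            kernel_pre=kern,
            kernel_post=kern,
            n_synapses_per_pre=p["n_synapses_per_pre"],
        )
        sampler = SamplerConfig(cu=p["cu"], cv=p["cv"], seed=seed + 7)
        out.append(SpreadModel(name=kind, layers=layers, chain=chain, sampler=sampler))
    return tuple(out)


@dataclass
class DistanceModel:
    """CA3-to-CA1-like projection set up for distance-mode comparisons."""

    layers: dict
    chain_uv: MappingChain       # euclideanUV distance modes
    chain_straight: MappingChain  # plain euclidean distance modes
    sampler: SamplerConfig


def build_ca_distance_model(seed: int = 0) -> DistanceModel:
    """Two frustum segments (CA3-like, CA1-like) sharing one synaptic layer.

    The pre-side kernel reaches far along the proximal-distal (axial) chart
    axis into the CA1 segment, mimicking axons that run along the curved
    sheet; 250 pre neurons with 22 synapses each give 5500 connections.
    """
    rp, rd, total_len, af = 0.3, 1.1, 4.0, 0.5
    r_mid = rp + (rd - rp) * 0.5
    ca3 = make_cone_strip(rp, r_mid, total_len / 2, af, 48, 16, name="ca3_like")
    ca1 = make_cone_strip(r_mid, rd, total_len / 2, af, 48, 16, name="ca1_like")
    ca1.vertices = ca1.vertices + np.array([0.0, 0.0, total_len / 2])
    ca1._cache.clear()
    full = make_cone_strip(rp, rd, total_len, af, 48, 32, name="ca_sl_base")
    sl = offset_layer(full, 0.15, name="ca_sl")
    layers = {l.name: l for l in (ca3, ca1, sl)}

    pre = place_neurons(ca3, 250, seed=seed)
    post = place_neurons(ca1, 390, seed=seed + 1)
    kernel_pre = KernelSpec(kind="gauss2d", mu=(0.0, 0.30), sigma=(0.03, 0.15))
    kernel_post = KernelSpec(kind="gauss2d", mu=(0.0, 0.0), sigma=(0.03, 0.05))

    def chain(mode):
        return MappingChain(
            name=f"ca3_ca1[{mode}]",
            layers=layers,
            pre_population=pre,
            post_population=post,
            pre_steps=[MappingStep("ca_sl", "euclidean", mode)],
            post_steps=[MappingStep("ca_sl", "euclidean", mode)],
            kernel_pre=kernel_pre,
            kernel_post=kernel_post,
            n_synapses_per_pre=22,
        )

    return DistanceModel(
        layers=layers,
        chain_uv=chain("euclideanUV"),
        chain_straight=chain("euclidean"),
        sampler=SamplerConfig(cu=32, cv=32, seed=seed + 11),
    )


# ---------------------------------------------------------------------------
# Hippocampal loop surrogate
# ---------------------------------------------------------------------------

# Scaled population sizes (experimentally estimated ratios, scaled down).
LOOP_SIZES = {"sEC": 110, "DG": 1200, "CA3": 250, "CA1": 390, "Sub": 285, "dEC": 330}

# Connection weights (mV) of the seven projections.
LOOP_WEIGHTS_MV = {
    ("sEC", "DG"): 9.0,
    ("DG", "CA3"): 5.0,
    ("CA3", "CA3"): 4.0,
    ("CA3", "CA1"): 5.0,
    ("CA1", "Sub"): 4.0,
    ("CA1", "dEC"): 4.0,
    ("Sub", "dEC"): 4.0,
}

# Synapses per post-synaptic neuron (in-degree).  The two output projections
# onto dEC have no literature count in the source table; they reuse the
# CA1->Sub value.  ``interpretation="total"`` instead fixes the projection's
# total synapse count.
LOOP_IN_DEGREE = {
    ("sEC", "DG"): 38,
    ("DG", "CA3"): 15,
    ("CA3", "CA3"): 60,
    ("CA3", "CA1"): 85,
    ("CA1", "Sub"): 15,
    ("CA1", "dEC"): 15,
    ("Sub", "dEC"): 15,
}

LOOP_TOTALS = {
    ("sEC", "DG"): 3520,
    ("DG", "CA3"): 72,
    ("CA3", "CA3"): 6000,
    ("CA3", "CA1"): 5500,
    ("CA1", "Sub"): 4275,
    ("CA1", "dEC"): 4950,
    ("Sub", "dEC"): 4950,
}

LOOP_ORDER = ["sEC", "DG", "CA3", "CA1", "Sub", "dEC"]

# Axial (z) position of each soma sheet in mm.  dEC sits farther from CA1
# than Sub does, mirroring the longer output pathway back to cortex.
_LOOP_Z = {"sEC": 0.0, "DG": 2.0, "CA3": 4.0, "CA1": 6.0, "Sub": 7.5, "dEC": 10.0}


@dataclass
class LoopModel:
    layers: dict
    populations: dict            # name -> NeuronPopulation
    chains: list                 # (pre_name, post_name, MappingChain)
    sampler_seed: int
    delay_model: DelayModel

    def spiking_populations(self):
        return [Population(n, LOOP_SIZES[n], IzhikevichParams()) for n in LOOP_ORDER]


def build_hippocampal_loop(
    seed: int = 0,
    interpretation: str = "in_degree",
    delay_model: DelayModel | None = None,
    synapse_scale: float = 1.0,
) -> LoopModel:
    """Six parallel 1 mm^2 sheets along z with seven sampled projections.

    Each projection runs through its own synaptic layer placed midway
    between the soma sheets (for the recurrent projection, slightly above
    its sheet), using normal mapping and straight-chord distances.
    ``synapse_scale`` multiplies every projection's synapse count, for
    studies that need denser or sparser wiring than the table values.
    """
    if interpretation not in ("in_degree", "total"):
        raise ValueError("interpretation must be 'in_degree' or 'total'")
    layers = {}
    for name, z in _LOOP_Z.items():
        sheet = make_sheet(1.0, 1.0, 8, 8, name=name)
        sheet.vertices = sheet.vertices + np.array([0.0, 0.0, z])
        sheet._cache.clear()
        layers[name] = sheet
    populations = {
        name: place_neurons(layers[name], LOOP_SIZES[name], seed=seed + i)
        for i, name in enumerate(LOOP_ORDER)
    }

    kernel_pre = KernelSpec(kind="gauss2d", sigma=(0.15, 0.15))
    kernel_post = KernelSpec(kind="gauss2d", sigma=(0.10, 0.10))

    chains = []
    for k, (pre_name, post_name) in enumerate(LOOP_WEIGHTS_MV):
        z_pre, z_post = _LOOP_Z[pre_name], _LOOP_Z[post_name]
        z_sl = z_pre + 0.3 if pre_name == post_name else 0.5 * (z_pre + z_post)
        sl = make_sheet(1.0, 1.0, 8, 8, name=f"sl_{pre_name}_{post_name}")
        sl.vertices = sl.vertices + np.array([0.0, 0.0, z_sl])
        sl._cache.clear()
        layers[sl.name] = sl
        n, m = LOOP_SIZES[pre_name], LOOP_SIZES[post_name]
        if interpretation == "in_degree":
            n_syn = max(1, round(synapse_scale * LOOP_IN_DEGREE[(pre_name, post_name)] * m / n))
        else:
            n_syn = max(1, round(synapse_scale * LOOP_TOTALS[(pre_name, post_name)] / n))
        chain = MappingChain(
            name=f"{pre_name}->{post_name}",
            layers=layers,
            pre_population=populations[pre_name],
            post_population=populations[post_name],
            pre_steps=[MappingStep(sl.name, "normal", "euclidean")],
            post_steps=[MappingStep(sl.name, "normal", "euclidean")],
            kernel_pre=kernel_pre,
            kernel_post=kernel_post,
            n_synapses_per_pre=n_syn,
        )
        chains.append((pre_name, post_name, chain))
    return LoopModel(
        layers=layers,
        populations=populations,
        chains=chains,
        sampler_seed=seed + 100,
        delay_model=delay_model or DelayModel(),
    )


def sample_loop_connectome(model: LoopModel, cu: int = 16, cv: int = 16):
    """Sample all seven projections and attach distances and delays.

    Returns ``{(pre_name, post_name): Connectome}``.
    """
    out = {}
    for k, (pre_name, post_name, chain) in enumerate(model.chains):
        cfg = SamplerConfig(cu=cu, cv=cv, seed=model.sampler_seed + k)
        rng = np.random.default_rng(cfg.seed)
        proj = project_populations(chain, rng)
        conn = sample_fast(chain, cfg, rng, proj=proj)
        attach_distances(chain, conn, proj, model.delay_model, rng)
        out[(pre_name, post_name)] = conn
    return out


def run_spread_comparison(seed: int = 0) -> dict:
    """Sample both spread-model arms and quantify the connectivity spread.

    Neurons are ordered along the septo-temporal (u) axis; the spread is the
    standard deviation of normalized index differences, with a group
    jackknife over pre neurons for the uncertainty.  Band-wise spreads are
    taken along the proximal-distal (v) axis, where the cone's circumference
    ratio predicts a monotone trend.
    """
    from .analysis import grouped_std_err, index_differences, order_by_axis, spread_by_band

    out = {}
    for model in build_spread_models(seed=seed):
        rng = np.random.default_rng(model.sampler.seed)
        proj = project_populations(model.chain, rng)
        conn = sample_fast(model.chain, model.sampler, rng, proj=proj)
        orderings = (
            order_by_axis(model.chain.pre_population, 0),
            order_by_axis(model.chain.post_population, 0),
        )
        d = index_differences(conn, orderings)
        std, se = grouped_std_err(d, conn.pre_id, conn.n_pre)
        bands = spread_by_band(
            conn, orderings, 4, band_index=model.chain.pre_population.uv[:, 1]
        )
        out[model.name] = {"std": std, "se": se, "bands": bands, "n": len(conn)}
    c, t = out["cone"], out["tube"]
    out["z"] = (c["std"] - t["std"]) / float(np.hypot(c["se"], t["se"]))
    return out


def run_distance_comparison(seed: int = 0) -> dict:
    """Along-surface vs straight-chord connection lengths on the CA surrogate.

    The same sampled connectome is measured twice — once with UV-affixed
    distance modes, once with straight chords — and the two distributions
    compared with a two-sample KS test.
    """
    import copy

    from .analysis import ks_compare

    m = build_ca_distance_model(seed=seed)
    rng = np.random.default_rng(m.sampler.seed)
    proj = project_populations(m.chain_uv, rng)
    conn = sample_fast(m.chain_uv, m.sampler, rng, proj=proj)
    attach_distances(m.chain_uv, conn, proj)
    uv_total = conn.total_mm.copy()
    conn2 = copy.deepcopy(conn)
    attach_distances(m.chain_straight, conn2, proj)
    straight = conn2.total_mm
    D, p = ks_compare(uv_total, straight)
    return {
        "n": len(conn),
        "uv_total_mm": uv_total,
        "straight_mm": straight,
        "dominance_fraction": float((uv_total >= straight - 1e-9).mean()),
        "ks_D": D,
        "ks_p": p,
    }


def run_loop_simulation(seed: int = 0, T: float = 200.0) -> dict:
    """Sample the loop, convert lengths to delays, simulate, read latencies."""
    from .spiking import StimulusSpec, first_spike_latency, simulate

    model = build_hippocampal_loop(seed=seed)
    connectomes = sample_loop_connectome(model)
    arr = loop_connection_arrays(model, connectomes)
    stim = StimulusSpec("sEC", duration_ms=10.0, amplitude=50.0, rate_per_ms=1.0,
                        seed=seed + 1)
    raster = simulate(model.spiking_populations(), arr, stim, T=T, seed=seed + 2)
    latencies = {n: first_spike_latency(raster, n) for n in LOOP_ORDER}
    return {
        "model": model,
        "connectomes": connectomes,
        "raster": raster,
        "latencies": latencies,
        "n_synapses": int(len(arr)),
    }


def loop_connection_arrays(model: LoopModel, connectomes: dict):
    """Global-id connection list ``(pre_gid, post_gid, weight_mV, delay_ms)``."""
    offsets = {}
    lo = 0
    for name in LOOP_ORDER:
        offsets[name] = lo
        lo += LOOP_SIZES[name]
    rows = []
    for (pre_name, post_name), conn in connectomes.items():
        w = LOOP_WEIGHTS_MV[(pre_name, post_name)]
        rows.append(
            np.stack(
                [
                    conn.pre_id + offsets[pre_name],
                    conn.post_id + offsets[post_name],
                    np.full(len(conn), w),
                    conn.delay_ms,
                ],
                axis=1,
            )
        )
    return np.concatenate(rows, axis=0)
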