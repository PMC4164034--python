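"""Configuration, connectome export/import, simulator-ready artifacts.

The run configuration is a YAML document declaring layers (fixture specs or
OBJ paths), populations, mapping chains with kernels, sampler settings and
the delay model.  A content digest of the configuration is recorded into
every connectome, so exported artifacts identify the exact setup that
produced them.

Export formats are deliberately plain: a fixed-dialect CSV (one row per
synapse), a versioned binary container (NumPy archive) that round-trips the
full record including synapse surface points and provenance, and
simulator-neutral text tables (populations, projections, connection list)
that any spiking simulator — including the bundled one — can ingest.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from .distances import DelayModel
from .geometry import (
    make_cone_strip,
    make_sheet,
    make_tube_strip,
    mirror_layer,
    offset_layer,
    subdivided_copy,
)
from .kernels import KernelSpec
from .layers import SurfaceLayer, place_neurons, read_obj
from .mapping import MappingChain, MappingStep
from .sampling import Connectome, SamplerConfig

__all__ = [
    "RunConfig",
    "load_config",
    "load_density_map",
    "config_digest",
    "export_csv",
    "import_csv",
    "export_binary",
    "import_binary",
    "export_simulator_lists",
    "read_simulator_lists",
]

BINARY_FORMAT_VERSION = 1


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_FIXTURES = {
    "sheet": (make_sheet, ("width", "height", "nu", "nv")),
    "tube_strip": (make_tube_strip, ("radius", "length", "arc_fraction", "n_arc", "n_len")),
    "cone_strip": (
        make_cone_strip,
        ("r_proximal", "r_distal", "length", "arc_fraction", "n_arc", "n_len"),
    ),
}


@dataclass
class RunConfig:
    """Fully resolved run setup built from a configuration document."""

    layers: dict
    populations: dict
    chains: dict
    sampler: SamplerConfig
    delay: DelayModel
    digest: str
    raw: dict = field(repr=False, default_factory=dict)


def config_digest(doc: dict) -> str:
    """Stable content hash of a configuration document."""
    canon = json.dumps(doc, sort_keys=True, default=str).encode()
    return hashlib.sha256(canon).hexdigest()[:16]


def load_density_map(path) -> np.ndarray:
    """Read a density map: single-channel 8/16-bit PNG or a plain-text grid.

    Values are relative weights over the UV unit square (row -> v,
    column -> u); PNGs are flipped vertically so image row 0 (top) maps to
    v = 1, matching the usual image orientation of a chart.
    """
    path = str(path)
    if path.lower().endswith(".png"):
        from PIL import Image

        img = Image.open(path)
        if img.mode not in ("L", "I", "I;16"):
            img = img.convert("L")
        return np.flipud(np.asarray(img, dtype=float))
    return np.atleast_2d(np.loadtxt(path, dtype=float))


def _build_layer(spec: dict, layers: dict) -> SurfaceLayer:
    kind = spec.get("kind", "obj")
    name = spec["name"]
    if kind == "obj":
        return read_obj(spec["path"], name=name)
    if kind in _FIXTURES:
        fn, keys = _FIXTURES[kind]
        kwargs = {k: spec[k] for k in keys if k in spec}
        return fn(name=name, **kwargs)
    if kind in ("offset", "mirror", "subdivided_copy"):
        src = layers.get(spec["source"])
        if src is None:
            raise ConfigError(f"layer {name!r}: unknown source {spec['source']!r}")
        if kind == "offset":
            return offset_layer(src, spec["distance"], name=name)
        if kind == "mirror":
            return mirror_layer(src, spec["axis"], name=name)
        return subdivided_copy(src, spec.get("levels", 1), name=name)
    raise ConfigError(f"layer {name!r}: unknown kind {kind!r}")


def _build_kernel(spec: dict) -> KernelSpec:
    return KernelSpec(
        kind=spec.get("kind", "gauss2d"),
        mu=tuple(spec.get("mu", (0.0, 0.0))),
        sigma=tuple(spec.get("sigma", (0.1, 0.1))),
        axis=int(spec.get("axis", 0)),
    )


def _build_steps(specs: list) -> list:
    return [
        MappingStep(
            target_layer=s["target"],
            mapping=s.get("mapping", "euclidean"),
            distance_mode=s.get("distance", "euclidean"),
        )
        for s in specs or []
    ]


def load_config(source) -> RunConfig:
    """Load a run configuration from a path, file object, or dict."""
    if isinstance(source, dict):
        doc = source
    elif hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError("configuration must be a mapping")
    digest = config_digest(doc)

    layers: dict = {}
    for spec in doc.get("layers", []):
        layer = _build_layer(spec, layers)
        if "density_map_path" in spec:
            layer.density_map = load_density_map(spec["density_map_path"])
            layer.validate()
        elif "density_map" in spec:
            layer.density_map = np.asarray(spec["density_map"], dtype=float)
            layer.validate()
        layers[layer.name] = layer

    populations: dict = {}
    for spec in doc.get("populations", []):
        layer = layers.get(spec["layer"])
        if layer is None:
            raise ConfigError(f"population {spec['name']!r}: unknown layer {spec['layer']!r}")
        populations[spec["name"]] = place_neurons(
            layer, int(spec["n"]), seed=int(spec.get("seed", 0)),
            use_density=bool(spec.get("use_density", False)),
        )

    chains: dict = {}
    for spec in doc.get("chains", []):
        pre = populations.get(spec["pre"])
        post = populations.get(spec["post"])
        if pre is None or post is None:
            raise ConfigError(f"chain {spec['name']!r}: unknown population")
        chains[spec["name"]] = MappingChain(
            name=spec["name"],
            layers=layers,
            pre_population=pre,
            post_population=post,
            pre_steps=_build_steps(spec.get("pre_steps")),
            post_steps=_build_steps(spec.get("post_steps")),
            kernel_pre=_build_kernel(spec.get("kernel_pre", {})),
            kernel_post=_build_kernel(spec.get("kernel_post", {})),
            n_synapses_per_pre=int(spec.get("n_synapses_per_pre", 1)),
        )

    s = doc.get("sampler", {})
    sampler = SamplerConfig(
        cu=int(s.get("cu", 16)),
        cv=int(s.get("cv", 16)),
        p0=float(s.get("p0", 1e-3)),
        p1=float(s.get("p1", 1e-3)),
        seed=int(s.get("seed", 0)),
        per_post=bool(s.get("per_post", False)),
    )
    d = doc.get("delay", {})
    delay = DelayModel(
        rate=float(d.get("rate", 4.36)),
        jitter_cv=float(d.get("jitter_cv", 0.0)),
        seed=d.get("seed"),
    )
    return RunConfig(
        layers=layers, populations=populations, chains=chains,
        sampler=sampler, delay=delay, digest=digest, raw=doc,
    )


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def export_csv(conn: Connectome, path) -> None:
    """Fixed-dialect CSV: 9 significant digits, decimal point, LF endings.

    Row order is the connectome's record order, which is seed-stable, so
    identical seed and configuration produce byte-identical files.
    """
    buf = io.StringIO()
    buf.write("pre_id,post_id,distance_mm,delay_ms\n")
    for i in range(len(conn)):
        buf.write(
            f"{conn.pre_id[i]},{conn.post_id[i]},"
            f"{conn.total_mm[i]:.9g},{conn.delay_ms[i]:.9g}\n"
        )
    with open(path, "w", newline="\n") as fh:
        fh.write(buf.getvalue())


def import_csv(path) -> dict:
    """Read back an exported CSV into plain arrays."""
    data = np.genfromtxt(path, delimiter=",", names=True, dtype=None, encoding="utf-8")
    data = np.atleast_1d(data)
    return {
        "pre_id": data["pre_id"].astype(np.intp) if data.size else np.zeros(0, np.intp),
        "post_id": data["post_id"].astype(np.intp) if data.size else np.zeros(0, np.intp),
        "distance_mm": data["distance_mm"].astype(float) if data.size else np.zeros(0),
        "delay_ms": data["delay_ms"].astype(float) if data.size else np.zeros(0),
    }


# ---------------------------------------------------------------------------
# Versioned binary container
# ---------------------------------------------------------------------------

_ARRAY_FIELDS = (
    "pre_id", "post_id", "syn_tri", "syn_bary", "syn_uv", "syn_xyz",
    "bin_index", "pre_mm", "post_mm", "total_mm", "delay_ms",
    "unconnected_pre", "unconnected_post",
)


def export_binary(conn: Connectome, path) -> None:
    """Lossless, versioned NumPy-archive serialization of a connectome."""
    meta = {
        "format_version": BINARY_FORMAT_VERSION,
        "n_pre": conn.n_pre,
        "n_post": conn.n_post,
        "provenance": conn.provenance,
    }
    arrays = {f: getattr(conn, f) for f in _ARRAY_FIELDS}
    np.savez_compressed(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def import_binary(path) -> Connectome:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        if meta.get("format_version") != BINARY_FORMAT_VERSION:
            raise ConfigError(
                f"unsupported connectome format version {meta.get('format_version')!r}; "
                f"this build reads version {BINARY_FORMAT_VERSION}"
            )
        kwargs = {f: z[f] for f in _ARRAY_FIELDS}
    return Connectome(
        n_pre=meta["n_pre"], n_post=meta["n_post"], provenance=meta["provenance"],
        **kwargs,
    )


# ---------------------------------------------------------------------------
# Simulator-neutral text artifacts
# ---------------------------------------------------------------------------

def export_simulator_lists(
    connectomes: dict,
    population_sizes: dict,
    population_order: list,
    weights_mv: dict,
    neuron_params: dict,
    prefix,
) -> dict:
    """Write population, projection and connection tables.

    ``connectomes`` maps ``(pre_name, post_name)`` to sampled connectomes
    with delays attached.  Global neuron ids are assigned by contiguous
    population blocks in ``population_order``.  Returns the paths written.
    """
    offsets = {}
    lo = 0
    for name in population_order:
        offsets[name] = lo
        lo += population_sizes[name]

    pop_path = f"{prefix}_populations.tsv"
    with open(pop_path, "w", newline="\n") as fh:
        fh.write("name\tsize\tgid_offset\ta\tb\tc_reset\td_jump\n")
        for name in population_order:
            p = neuron_params[name]
            fh.write(
                f"{name}\t{population_sizes[name]}\t{offsets[name]}\t"
                f"{p.a:g}\t{p.b:g}\t{p.c_reset:g}\t{p.d_jump:g}\n"
            )

    proj_path = f"{prefix}_projections.tsv"
    with open(proj_path, "w", newline="\n") as fh:
        fh.write("pre\tpost\tweight_mV\tn_synapses\n")
        for (pre, post), conn in connectomes.items():
            fh.write(f"{pre}\t{post}\t{weights_mv[(pre, post)]:g}\t{len(conn)}\n")

    conn_path = f"{prefix}_connections.tsv"
    with open(conn_path, "w", newline="\n") as fh:
        fh.write("pre_gid\tpost_gid\tweight_mV\tdelay_ms\n")
        for (pre, post), conn in connectomes.items():
            w = weights_mv[(pre, post)]
            for i in range(len(conn)):
                fh.write(
                    f"{conn.pre_id[i] + offsets[pre]}\t"
                    f"{conn.post_id[i] + offsets[post]}\t{w:g}\t"
                    f"{conn.delay_ms[i]:.9g}\n"
                )
    return {"populations": pop_path, "projections": proj_path, "connections": conn_path}


def read_simulator_lists(prefix) -> dict:
    """Read the three tables back into arrays/records."""
    from .spiking import IzhikevichParams, Population

    pops = []
    with open(f"{prefix}_populations.tsv") as fh:
        next(fh)
        for line in fh:
            name, size, _off, a, b, c, d = line.rstrip("\n").split("\t")
            pops.append(
                Population(name, int(size), IzhikevichParams(float(a), float(b), float(c), float(d)))
            )
    conn = np.loadtxt(f"{prefix}_connections.tsv", skiprows=1)
    conn = np.atleast_2d(conn)
    if conn.size == 0:
        conn = conn.reshape(0, 4)
    return {"populations": pops, "connections": conn}
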