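"""Minimal spiking network: Izhikevich neurons with delayed delta synapses.

Just enough simulator to validate that connectomes with distance-derived
conduction delays produce ordered activity propagation through a multi-stage
loop.  Dynamics follow the two-variable quadratic integrate model

    v' = 0.04 v^2 + 5 v + 140 - u + I
    u' = a (b v - u)

integrated by forward Euler (default dt = 0.1 ms) with a spike emitted when
``v >= 30`` mV, after which ``v -> c_reset`` and ``u += d_jump``.  Synapses
are instantaneous voltage increments (weights in mV) delivered through an
event queue quantized to dt; a stimulus injects Poisson-timed current pulses
into one population.  No plasticity, no inhibition, no conductances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "IzhikevichParams",
    "StimulusSpec",
    "Population",
    "SpikeRaster",
    "simulate",
    "first_spike_latency",
]


@dataclass(frozen=True)
class IzhikevichParams:
    """Excitatory regular-spiking defaults: a=0.02, b=0.2, reset -65, jump 8."""

    a: float = 0.02
    b: float = 0.2
    c_reset: float = -65.0
    d_jump: float = 8.0

    def __post_init__(self):
        for f in (self.a, self.b, self.c_reset, self.d_jump):
            if not np.isfinite(f):
                raise ValueError("Izhikevich parameters must be finite")


@dataclass(frozen=True)
class Population:
    """A named block of identical neurons occupying a contiguous gid range."""

    name: str
    size: int
    params: IzhikevichParams = IzhikevichParams()


@dataclass(frozen=True)
class StimulusSpec:
    """Poisson-timed current pulses into one population.

    Each event adds ``amplitude`` (mV) to the target neuron's membrane
    potential at the event time; events arrive independently per neuron at
    ``rate_per_ms`` during the first ``duration_ms`` of the simulation.
    """

    population: str
    duration_ms: float = 10.0
    amplitude: float = 50.0
    rate_per_ms: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.duration_ms < 0 or self.amplitude < 0 or self.rate_per_ms < 0:
            raise ValueError("stimulus parameters must be >= 0")


@dataclass
class SpikeRaster:
    """Spike times (ms) and emitting global ids, plus population gid ranges."""

    times: np.ndarray
    gids: np.ndarray
    pop_ranges: dict   # name -> (gid_lo, gid_hi)

    def population_spikes(self, name: str):
        lo, hi = self.pop_ranges[name]
        sel = (self.gids >= lo) & (self.gids < hi)
        return self.times[sel], self.gids[sel]


def population_offsets(populations) -> dict:
    """Disjoint contiguous gid ranges, in the order populations are given."""
    ranges, lo = {}, 0
    for p in populations:
        ranges[p.name] = (lo, lo + p.size)
        lo += p.size
    return ranges


def simulate(
    populations,
    connections,
    stimulus: StimulusSpec | None = None,
    T: float = 300.0,
    dt: float = 0.1,
    bias_current: float = 0.0,
    seed: int = 0,
) -> SpikeRaster:
    """Run the network for ``T`` ms and return the spike raster.

    ``connections`` is ``(pre_gid, post_gid, weight_mV, delay_ms)`` as four
    arrays or an ``(s, 4)`` array; every delay must be >= dt.  Weight
    delivery uses a ring buffer over the delay horizon, so cost per step is
    linear in the spikes emitted.  Fully reproducible for a fixed seed.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    ranges = population_offsets(populations)
    N = sum(p.size for p in populations)

    a = np.empty(N)
    b = np.empty(N)
    c = np.empty(N)
    d = np.empty(N)
    for p in populations:
        lo, hi = ranges[p.name]
        a[lo:hi], b[lo:hi] = p.params.a, p.params.b
        c[lo:hi], d[lo:hi] = p.params.c_reset, p.params.d_jump

    conn = np.atleast_2d(np.asarray(connections, dtype=float))
    if conn.size == 0:
        conn = conn.reshape(0, 4)
    pre = conn[:, 0].astype(np.intp)
    post = conn[:, 1].astype(np.intp)
    w = conn[:, 2]
    delay_steps = np.round(conn[:, 3] / dt).astype(np.intp)
    if len(delay_steps) and delay_steps.min() < 1:
        raise ValueError("every delay must be >= dt")
    horizon = int(delay_steps.max()) + 1 if len(delay_steps) else 1

    # per-pre adjacency for event delivery
    order = np.argsort(pre, kind="stable")
    pre_s, post_s, w_s, ds_s = pre[order], post[order], w[order], delay_steps[order]
    starts = np.searchsorted(pre_s, np.arange(N + 1))

    rng = np.random.default_rng(seed)
    stim_I = None
    if stimulus is not None:
        lo, hi = ranges[stimulus.population]
        n_steps_stim = int(np.ceil(stimulus.duration_ms / dt))
        p_event = min(stimulus.rate_per_ms * dt, 1.0)
        stim_events = rng.random((n_steps_stim, hi - lo)) < p_event
        stim_I = (lo, hi, stim_events)

    v = np.full(N, -65.0)
    u = b * v
    buffer = np.zeros((horizon, N))
    n_steps = int(np.round(T / dt))
    out_t, out_g = [], []

    for step in range(n_steps):
        slot = step % horizon
        # synaptic events and stimulus pulses are instantaneous voltage
        # increments (mV); the bias current enters the derivative as usual
        v += buffer[slot]
        buffer[slot] = 0.0
        if stim_I is not None and step < len(stim_I[2]):
            lo, hi, ev = stim_I
            v[lo:hi] += stimulus.amplitude * ev[step]
        # two half steps on v for stability at large inputs
        v += 0.5 * dt * (0.04 * v * v + 5.0 * v + 140.0 - u + bias_current)
        v += 0.5 * dt * (0.04 * v * v + 5.0 * v + 140.0 - u + bias_current)
        u += dt * a * (b * v - u)
        fired = np.nonzero(v >= 30.0)[0]
        if len(fired):
            t_now = (step + 1) * dt
            out_t.extend([t_now] * len(fired))
            out_g.extend(fired.tolist())
            v[fired] = c[fired]
            u[fired] += d[fired]
            for g in fired:
                s0, s1 = starts[g], starts[g + 1]
                if s0 == s1:
                    continue
                tgt_slot = (step + ds_s[s0:s1]) % horizon
                np.add.at(buffer, (tgt_slot, post_s[s0:s1]), w_s[s0:s1])
    return SpikeRaster(
        times=np.asarray(out_t), gids=np.asarray(out_g, dtype=np.intp), pop_ranges=ranges
    )


def first_spike_latency(raster: SpikeRaster, population: str):
    """Earliest spike time (ms) in a population, ``None`` if it stays silent."""
    t, _ = raster.population_spikes(population)
    return float(t.min()) if len(t) else None
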