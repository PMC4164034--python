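"""Connectivity kernels: weight functions over synaptic-layer chart space.

A kernel gives, for a neuron whose projection entered the synaptic layer at
chart position ``neuron_uv``, the unnormalized propensity to form a synapse
at chart position ``z``.  It models the reach of the axonal/dendritic arbor
and the density with which synapses are formed.  Built-in kernels evaluate
on the chart displacement ``delta = z - neuron_uv`` with peak weight 1, so
sampler thresholds read directly as fractions of the peak.  Normalization
happens implicitly in the sampler, per neuron, over the sampling domain.

Widths and offsets are in chart units; on non-isometric charts a fixed
chart-unit width corresponds to varying metric reach.  For that case a spec
may carry ``param_fn``, a hook mapping the neuron's own chart position to
parameter overrides (e.g., a metric axonal reach converted to local chart
units), which is how position-dependent kernel shapes are expressed.

New kernels register by name via :func:`register_kernel` and are then
addressable from configuration files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KernelSpec",
    "register_kernel",
    "get_kernel",
    "evaluate_kernel",
    "eval_gauss2d",
    "eval_gauss1d",
]

_REGISTRY: dict = {}


class KernelError(ValueError):
    pass


@dataclass(frozen=True)
class KernelSpec:
    """A named kernel plus its parameters.

    Parameters
    ----------
    kind:
        Registered kernel name (``gauss2d``, ``gauss1d``, or user-defined).
    mu:
        Center offset of the kernel in chart units, relative to the neuron's
        entry point (``(mu_u, mu_v)``).
    sigma:
        Widths ``(sigma_u, sigma_v)`` in chart units; strictly positive.
    axis:
        For 1D kernels, the constrained chart axis (0 = u, 1 = v).
    param_fn:
        Optional hook: ``param_fn(neuron_uv) -> dict`` of parameter
        overrides, evaluated per neuron.
    """

    kind: str = "gauss2d"
    mu: tuple = (0.0, 0.0)
    sigma: tuple = (0.1, 0.1)
    axis: int = 0
    param_fn: object = field(default=None, compare=False)

    def __post_init__(self):
        if self.kind not in _REGISTRY:
            raise KernelError(f"unknown kernel {self.kind!r}; registered: {sorted(_REGISTRY)}")
        if len(self.sigma) != 2 or min(self.sigma) <= 0:
            raise KernelError("sigma must be two strictly positive widths")

    def params_for(self, neuron_uv) -> dict:
        p = {"mu": self.mu, "sigma": self.sigma, "axis": self.axis}
        if self.param_fn is not None:
            p.update(self.param_fn(np.asarray(neuron_uv, dtype=float)))
        return p


def register_kernel(name: str, evaluator) -> None:
    """Register ``evaluator(delta_uv, params) -> weights`` under a new name."""
    if name in _REGISTRY:
        raise KernelError(f"kernel {name!r} already registered")
    _REGISTRY[name] = evaluator


def get_kernel(name: str):
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KernelError(f"unknown kernel {name!r}; registered: {sorted(_REGISTRY)}") from None


def evaluate_kernel(spec: KernelSpec, z_uv: np.ndarray, neuron_uv) -> np.ndarray:
    """Weights at chart points ``z_uv`` for a neuron entering at ``neuron_uv``.

    Finite non-negative for finite inputs; built-ins are translation
    covariant in ``z - neuron_uv``.
    """
    z_uv = np.atleast_2d(np.asarray(z_uv, dtype=float))
    neuron_uv = np.asarray(neuron_uv, dtype=float)
    delta = z_uv - neuron_uv
    params = spec.params_for(neuron_uv)
    w = np.asarray(get_kernel(spec.kind)(delta, params), dtype=float)
    if (w < 0).any():
        raise KernelError(f"kernel {spec.kind!r} returned negative weights")
    return w


def _gauss2d(delta: np.ndarray, params: dict) -> np.ndarray:
    mu = np.asarray(params["mu"], dtype=float)
    su, sv = params["sigma"]
    d = delta - mu
    return np.exp(-(d[:, 0] ** 2 / (2.0 * su**2) + d[:, 1] ** 2 / (2.0 * sv**2)))


def _gauss1d(delta: np.ndarray, params: dict) -> np.ndarray:
    axis = int(params.get("axis", 0))
    mu = np.asarray(params["mu"], dtype=float)[axis]
    s = params["sigma"][axis]
    d = delta[:, axis] - mu
    return np.exp(-(d**2) / (2.0 * s**2))


register_kernel("gauss2d", _gauss2d)
register_kernel("gauss1d", _gauss1d)


def eval_gauss2d(spec: KernelSpec, z_uv, neuron_uv) -> np.ndarray:
    """Anisotropic 2D Gaussian weight, peak 1 at ``delta == mu``."""
    return evaluate_kernel(spec, z_uv, neuron_uv)


def eval_gauss1d(spec: KernelSpec, z_uv, neuron_uv) -> np.ndarray:
    """Gaussian along one chart axis, constant along the other."""
    return evaluate_kernel(spec, z_uv, neuron_uv)
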