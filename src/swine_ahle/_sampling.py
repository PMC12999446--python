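"""PERT sampling primitives shared by the simulation modules."""

from __future__ import annotations

import numpy as np

from .model_inputs import ParameterValue, PertSpec

__all__ = ["sample_pert", "sample_param"]

_LAMBDA = 4.0  # standard PERT shape


def sample_pert(spec: PertSpec, rng: np.random.Generator, size: int | None = None):
    """Draw from the PERT(min, mode, max) distribution (Beta rescaled, lambda=4).

    A degenerate spec (min == max) returns the point mass.  Mean is
    (min + 4*mode + max)/6.
    """
    if spec.is_degenerate:
        return spec.mode if size is None else np.full(size, spec.mode)
    span = spec.maximum - spec.minimum
    alpha = 1.0 + _LAMBDA * (spec.mode - spec.minimum) / span
    beta = 1.0 + _LAMBDA * (spec.maximum - spec.mode) / span
    return spec.minimum + span * rng.beta(alpha, beta, size)


def sample_param(p: ParameterValue, rng: np.random.Generator, size: int | None = None):
    """Sample a ParameterValue: fixed values broadcast, PERTs are drawn."""
    if p.kind == "fixed":
        return p.value if size is None else np.full(size, p.value)
    return sample_pert(p.spec, rng, size)
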