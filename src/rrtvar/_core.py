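"""Shared decoder/estimator arithmetic.

Every variance estimator in the package is built from the same linear
"decoder" of the scrambled sample variance,

    core(s_z^2, zbar) = (s_z^2 - offset - slope * zbar^2) / denom - post_offset,

optionally multiplied by auxiliary-variable adjustment factors.  Both
scrambling models map onto this shape, so the closed-form theory and the
Monte-Carlo engine share one implementation.  All functions here operate
elementwise and accept numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "Decoder",
    "dp_decoder",
    "np_decoder",
    "T1DConstants",
    "T1NConstants",
    "GRatioConstants",
    "core_estimate",
    "ratio_estimate",
    "gratio_estimate",
    "class_estimate",
]


@dataclass(frozen=True)
class Decoder:
    """Linear decoder of the scrambled sample variance."""

    offset: float
    slope: float
    denom: float
    post_offset: float = 0.0

    def __post_init__(self):
        if self.denom <= 0:
            raise InvalidParameterError("decoder denominator must be positive")

    def decode(self, s2_z, zbar):
        return (s2_z - self.offset - self.slope * np.square(zbar)) / self.denom \
            - self.post_offset

    def census_value(self, var_z: float, mean_z: float) -> float:
        """The decoder evaluated at the population point (sigma_z^2, Zbar)."""
        return float(self.decode(var_z, mean_z))

    def encode_variance(self, var_y: float, mean_y: float) -> float:
        """The Var(Z) that makes the census identity hold exactly:
        the inverse of :meth:`census_value` at zbar = mean_y."""
        return (var_y + self.post_offset) * self.denom \
            + self.offset + self.slope * mean_y ** 2


def dp_decoder(params) -> Decoder:
    """Decoder for Z = T*Y + S:  (s_z^2 - var_s - var_t zbar^2)/(var_t + 1)."""
    return Decoder(offset=params.var_s, slope=params.var_t, denom=params.var_t + 1.0)


def np_decoder(params) -> Decoder:
    """Decoder for the combined model; denominator follows ``params.mode``."""
    return Decoder(
        offset=0.0,
        slope=params.multiplier_coefficient,
        denom=params.decoder_denominator,
        post_offset=params.a ** 2 * params.var_s,
    )


@dataclass(frozen=True)
class T1DConstants:
    """Optimizing constants (k1, k2, k3) and generalization exponents
    (lambda1, lambda2) of the two-auxiliary exponential class."""

    k1: float
    k2: float
    k3: float
    lambda1: float
    lambda2: float


@dataclass(frozen=True)
class T1NConstants:
    """Same class under the combined scrambling model: (w1, w2, w3, v1, v2)."""

    w1: float
    w2: float
    w3: float
    v1: float
    v2: float


@dataclass(frozen=True)
class GRatioConstants:
    """Constants of the generalized ratio estimator.  ``exponent`` is the
    power on the adjustment bracket (renamed from the source's g to avoid
    collision with the scrambling mixing weight)."""

    alpha: float = 1.0
    beta: float = 0.0
    omega: float = 1.0
    exponent: float = 1.0


def core_estimate(decoder: Decoder, s2_z, zbar):
    return decoder.decode(s2_z, zbar)


def ratio_estimate(decoder: Decoder, s2_z, zbar, s2_x1, var_x1_pop):
    return decoder.decode(s2_z, zbar) * (var_x1_pop / s2_x1)


def gratio_estimate(decoder, s2_z, zbar, s2_x1, var_x1_pop, c: GRatioConstants):
    known = c.alpha * var_x1_pop + c.beta
    denom = c.omega * (c.alpha * s2_x1 + c.beta) + (1.0 - c.omega) * known
    bracket = (known / denom) ** c.exponent
    return (decoder.decode(s2_z, zbar) + (var_x1_pop - s2_x1)) * bracket


def class_estimate(decoder, s2_z, zbar, s2_x1, s2_x2, var_x1_pop, var_x2_pop,
                   k1, k2, k3, lambda1, lambda2):
    """The generalized exponential two-auxiliary estimator (either model)."""
    lead = (
        k1 * decoder.decode(s2_z, zbar)
        + k2 * (var_x1_pop - s2_x1)
        + k3 * (var_x2_pop - s2_x2)
    )
    adj = np.exp(lambda1 * (var_x1_pop - s2_x1) / (var_x1_pop + s2_x1)) \
        * (var_x2_pop / s2_x2) ** lambda2
    return lead * adj
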