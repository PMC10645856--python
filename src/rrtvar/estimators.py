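"""Point estimators of the population variance of the sensitive variable.

Every estimator consumes one :class:`~rrtvar.population.SampleSummary` of
scrambled responses plus known model/auxiliary parameters.  Negative
variance estimates are returned unmodified (no truncation) so that
empirical MSEs match the unconstrained theory; callers that want
truncation opt in explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._core import (
    GRatioConstants,
    T1DConstants,
    T1NConstants,
    class_estimate,
    core_estimate,
    dp_decoder,
    gratio_estimate,
    np_decoder,
    ratio_estimate,
)
from .errors import DegenerateSampleError, InvalidParameterError
from .population import PopulationMoments, SampleSummary
from .theory import optimum_class_constants

__all__ = [
    "T1DConstants",
    "T1NConstants",
    "GRatioConstants",
    "ClassTemplate",
    "t0_dp",
    "t_ratio_dp",
    "t_gratio_dp",
    "t1d",
    "t_np1",
    "t_np2",
    "t1n",
    "optimum_constants_t1d",
    "optimum_constants_t1n",
    "make_class_estimator",
    "census_summary",
    "ESTIMATOR_TAGS",
]

ESTIMATOR_TAGS = (
    "t0", "ratio", "gratio", "t1D",
    *[f"t1D({i})" for i in range(1, 9)],
    "tNP1", "tNP2", "t1N",
)


def t0_dp(sample: SampleSummary, params) -> float:
    """Basic decoded estimator under Z = T*Y + S:
    (s_z^2 - var_s - var_t zbar^2)/(var_t + 1).  May be negative."""
    return float(core_estimate(dp_decoder(params), sample.s2_z, sample.zbar))


def t_ratio_dp(sample: SampleSummary, params, var_x1_pop: float) -> float:
    """Ratio-adjusted estimator: t0 * sigma_x1^2 / s_x1^2."""
    if sample.s2_x1 <= 0:
        raise DegenerateSampleError("s_x1^2 must be positive for the ratio adjustment")
    return float(ratio_estimate(dp_decoder(params), sample.s2_z, sample.zbar,
                                sample.s2_x1, var_x1_pop))


def t_gratio_dp(sample: SampleSummary, params, var_x1_pop: float,
                constants: GRatioConstants) -> float:
    """Generalized ratio estimator with difference correction and
    power-adjusted bracket."""
    known = constants.alpha * var_x1_pop + constants.beta
    denom = constants.omega * (constants.alpha * sample.s2_x1 + constants.beta) \
        + (1.0 - constants.omega) * known
    if denom == 0:
        raise DegenerateSampleError("generalized-ratio bracket denominator is zero")
    return float(gratio_estimate(dp_decoder(params), sample.s2_z, sample.zbar,
                                 sample.s2_x1, var_x1_pop, constants))


def t1d(sample: SampleSummary, params, var_x1_pop: float, var_x2_pop: float,
        constants: T1DConstants) -> float:
    """Generalized exponential two-auxiliary estimator under Z = T*Y + S."""
    if sample.s2_x1 <= 0 or sample.s2_x2 <= 0:
        raise DegenerateSampleError("auxiliary sample variances must be positive")
    return float(class_estimate(
        dp_decoder(params), sample.s2_z, sample.zbar, sample.s2_x1, sample.s2_x2,
        var_x1_pop, var_x2_pop,
        constants.k1, constants.k2, constants.k3,
        constants.lambda1, constants.lambda2,
    ))


def t_np1(sample: SampleSummary, params) -> float:
    """Basic decoded estimator under the combined model.  May be negative."""
    return float(core_estimate(np_decoder(params), sample.s2_z, sample.zbar))


def t_np2(sample: SampleSummary, params, var_x1_pop: float) -> float:
    """Ratio-adjusted estimator under the combined model."""
    if sample.s2_x1 <= 0:
        raise DegenerateSampleError("s_x1^2 must be positive for the ratio adjustment")
    return float(ratio_estimate(np_decoder(params), sample.s2_z, sample.zbar,
                                sample.s2_x1, var_x1_pop))


def t1n(sample: SampleSummary, params, var_x1_pop: float, var_x2_pop: float,
        constants: T1NConstants) -> float:
    """Generalized exponential two-auxiliary estimator, combined model."""
    if sample.s2_x1 <= 0 or sample.s2_x2 <= 0:
        raise DegenerateSampleError("auxiliary sample variances must be positive")
    return float(class_estimate(
        np_decoder(params), sample.s2_z, sample.zbar, sample.s2_x1, sample.s2_x2,
        var_x1_pop, var_x2_pop,
        constants.w1, constants.w2, constants.w3,
        constants.v1, constants.v2,
    ))


def optimum_constants_t1d(moments: PopulationMoments, params,
                          lambda1: float, lambda2: float, n: int) -> T1DConstants:
    """Closed-form optimum (k1, k2, k3) for given generalization constants,
    computed from true population moments."""
    (k1, k2, k3), _ = optimum_class_constants(
        moments, dp_decoder(params), lambda1, lambda2, n)
    return T1DConstants(k1, k2, k3, lambda1, lambda2)


def optimum_constants_t1n(moments: PopulationMoments, params,
                          v1: float, v2: float, n: int) -> T1NConstants:
    """Closed-form optimum (w1, w2, w3) under the combined model."""
    (w1, w2, w3), _ = optimum_class_constants(
        moments, np_decoder(params), v1, v2, n)
    return T1NConstants(w1, w2, w3, v1, v2)


@dataclass(frozen=True)
class ClassTemplate:
    """One named member of the estimator class: fixed constants hold their
    value, free ones are ``None`` (to be optimized or supplied)."""

    tag: str
    k1: float | None
    k2: float | None
    k3: float | None
    lambda1: float | None
    lambda2: float | None

    @property
    def free(self) -> tuple:
        return tuple(
            name for name in ("k1", "k2", "k3", "lambda1", "lambda2")
            if getattr(self, name) is None
        )

    def resolve(self, **values) -> T1DConstants:
        out = {}
        for name in ("k1", "k2", "k3", "lambda1", "lambda2"):
            fixed = getattr(self, name)
            out[name] = values.get(name, fixed) if fixed is None else fixed
            if out[name] is None:
                raise InvalidParameterError(f"constant {name} left unresolved")
        return T1DConstants(**out)


_CLASS_TABLE = {
    "1D(1)": (None, None, 0.0, 1.0, 0.0),
    "1D(2)": (None, None, 0.0, 0.0, 1.0),
    "1D(3)": (1.0, 0.0, 0.0, 0.0, 1.0),
    "1D(4)": (1.0, None, None, 0.0, 0.0),
    "1D(5)": (1.0, None, 0.0, 1.0, 0.0),
    "1D(6)": (1.0, None, 0.0, 0.0, 1.0),
    "1D(7)": (1.0, 0.0, 0.0, None, 0.0),
    "1D(8)": (1.0, 0.0, 0.0, 0.0, None),
}


def make_class_estimator(tag: str) -> ClassTemplate:
    """Return the named class-member configuration (e.g. ``"1D(3)"``)."""
    key = tag[1:] if tag.startswith("t1D") else tag
    if key not in _CLASS_TABLE:
        raise InvalidParameterError(f"unknown class-estimator tag: {tag}")
    return ClassTemplate(key, *_CLASS_TABLE[key])


def census_summary(params, mean_y: float, var_y: float,
                   var_x1: float, var_x2: float, n: int = 10**6) -> SampleSummary:
    """Parameter-identity sample: the summary whose statistics equal the
    closed-form population moments implied by the model, so that every
    decoding estimator returns ``var_y`` exactly."""
    from .scrambling import DPModelParams

    dec = dp_decoder(params) if isinstance(params, DPModelParams) else np_decoder(params)
    var_z = dec.encode_variance(var_y, mean_y)
    return SampleSummary(n=n, s2_z=var_z, s2_x1=var_x1, s2_x2=var_x2, zbar=mean_y)
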