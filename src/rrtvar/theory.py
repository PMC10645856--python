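"""First-order bias/MSE theory, optimum constants, and the delta-method oracle.

All closed forms are derived from one covariance structure: the sampling
moments (s_z^2, s_x1^2, s_x2^2, zbar) of an SRSWOR draw have, to first
order with theta = 1/n,

    Var(s_z^2)        = theta sigma_z^4 (mu400 - 1)
    Var(s_x1^2)       = theta sigma_x1^4 (mu040 - 1)
    Var(s_x2^2)       = theta sigma_x2^4 (mu004 - 1)
    Var(zbar)         = theta C_z^2 Zbar^2
    Cov(s_z^2, zbar)  = theta sigma_z^2 Zbar mu300 C_z
    Cov(s_x1^2, zbar) = theta sigma_x1^2 Zbar mu120 C_z
    Cov(s_x2^2, zbar) = theta sigma_x2^2 Zbar mu102 C_z
    Cov(s_z^2, s_x1^2)  = theta sigma_z^2 sigma_x1^2 (mu220 - 1)
    Cov(s_z^2, s_x2^2)  = theta sigma_z^2 sigma_x2^2 (mu202 - 1)
    Cov(s_x1^2, s_x2^2) = theta sigma_x1^2 sigma_x2^2 (mu022 - 1)

with standardized moments over (Z, X1, X2).  The generic
:func:`delta_method_mse` oracle assembles exactly this matrix and is the
arbiter for the printed closed forms, several of which carry typographical
defects in the source; those literal variants are retained behind
``strict_paper`` flags where they are well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._core import (
    Decoder,
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
from .errors import (
    CollinearAuxiliaryError,
    DegeneratePopulationError,
    InvalidParameterError,
    RRTVarError,
)
from .population import PopulationMoments

__all__ = [
    "DPTheoryTerms",
    "NPTheoryTerms",
    "mse_t0_theory",
    "mse_tratio_theory",
    "min_mse_tgratio_theory",
    "optimum_gratio_psi",
    "t1d_theory",
    "min_mse_t1d_theory",
    "tnp1_theory",
    "tnp2_theory",
    "t1n_theory",
    "min_mse_t1n_theory",
    "delta_method_mse",
    "efficiency_compare",
    "class_terms",
    "optimum_class_constants",
    "class_mse",
    "class_bias",
]


# ---------------------------------------------------------------------------
# generic building blocks (shared by both scrambling models)
# ---------------------------------------------------------------------------

def _check(moments: PopulationMoments) -> None:
    if moments.var_z <= 0:
        raise DegeneratePopulationError("var_z must be positive")


def _core_var(moments, dec: Decoder, theta: float) -> float:
    """First-order variance of the decoded core estimator."""
    m = moments.mu
    sz2 = moments.var_z
    zbar = moments.mean_z
    cz = moments.cv_z
    return theta / dec.denom ** 2 * (
        sz2 ** 2 * (m[(4, 0, 0)] - 1.0)
        + 4.0 * dec.slope ** 2 * zbar ** 4 * cz ** 2
        - 4.0 * sz2 * dec.slope * zbar ** 2 * m[(3, 0, 0)] * cz
    )


def _cov_x1(moments, dec: Decoder) -> float:
    """Cov(core, delta_x1) / theta."""
    m = moments.mu
    return (
        moments.var_z * (m[(2, 2, 0)] - 1.0)
        - 2.0 * dec.slope * moments.mean_z ** 2 * m[(1, 2, 0)] * moments.cv_z
    ) / dec.denom


def _cov_x2(moments, dec: Decoder) -> float:
    """Cov(core, delta_x2) / theta."""
    m = moments.mu
    return (
        moments.var_z * (m[(2, 0, 2)] - 1.0)
        - 2.0 * dec.slope * moments.mean_z ** 2 * m[(1, 0, 2)] * moments.cv_z
    ) / dec.denom


def _census_residual_sq(moments, dec) -> float:
    """Squared gap between the decoded population value and sigma_y^2.

    Exactly zero when the decoding identity holds (the printed setting);
    retained so the closed forms agree with the delta-method oracle on
    arbitrary realized moments."""
    return (dec.census_value(moments.var_z, moments.mean_z) - moments.var_y) ** 2


def _mse_core(moments, dec, n, strict_paper=False) -> float:
    _check(moments)
    theta = 1.0 / n
    if not strict_paper:
        return _census_residual_sq(moments, dec) + _core_var(moments, dec, theta)
    # literal middle term: 4 slope Zbar^2 C_z^2 (dimensionally inconsistent)
    m = moments.mu
    sz2, zbar, cz = moments.var_z, moments.mean_z, moments.cv_z
    return theta / dec.denom ** 2 * (
        sz2 ** 2 * (m[(4, 0, 0)] - 1.0)
        + 4.0 * dec.slope * zbar ** 2 * cz ** 2
        - 4.0 * sz2 * dec.slope * zbar ** 2 * m[(3, 0, 0)] * cz
    )


def _mse_ratio(moments, dec, n) -> float:
    _check(moments)
    theta = 1.0 / n
    t_star = dec.census_value(moments.var_z, moments.mean_z)
    e2 = moments.mu[(0, 4, 0)] - 1.0
    return (
        _census_residual_sq(moments, dec)
        + _core_var(moments, dec, theta)
        + theta * t_star ** 2 * e2
        - 2.0 * theta * t_star * _cov_x1(moments, dec)
    )


def _min_mse_gratio(moments, dec, n, strict_paper=False) -> float:
    _check(moments)
    theta = 1.0 / n
    e2 = moments.mu[(0, 4, 0)] - 1.0
    if e2 <= 0:
        raise DegeneratePopulationError("mu040 must exceed 1 for a usable auxiliary")
    cov1 = _cov_x1(moments, dec)
    if strict_paper:
        # printed form omits the decoder denominator in the reduction term
        cov1 = cov1 * dec.denom
        return _core_var(moments, dec, theta) - theta * cov1 ** 2 / e2
    return _census_residual_sq(moments, dec) \
        + _core_var(moments, dec, theta) - theta * cov1 ** 2 / e2


def optimum_gratio_psi(moments, dec: Decoder, n: int) -> float:
    """Optimal total coefficient on (s_x1^2 - sigma_x1^2) for the
    generalized ratio estimator (per unit of sigma_x1^2 relative error the
    estimator moves by -psi).  Minimizes the first-order MSE."""
    e2 = moments.mu[(0, 4, 0)] - 1.0
    if e2 <= 0:
        raise DegeneratePopulationError("mu040 must exceed 1")
    return _cov_x1(moments, dec) / e2


def class_terms(moments, dec: Decoder, lambda1: float, lambda2: float, n: int):
    """Quadratic-form coefficients of the generalized class MSE.

    Returns a dict with the intermediates (a1..a7 and helpers).  ``a7``
    equals t*^2 + theta*(a1 - (a2*a4 + a3*a5)/a6); when the census
    identity holds (t* = sigma_y^2) this is the printed denominator of the
    optimum leading constant.
    """
    _check(moments)
    theta = 1.0 / n
    m = moments.mu
    t_star = dec.census_value(moments.var_z, moments.mean_z)
    e2 = m[(0, 4, 0)] - 1.0
    e4 = m[(0, 0, 4)] - 1.0
    e22 = m[(0, 2, 2)] - 1.0
    cov1 = _cov_x1(moments, dec)
    cov2 = _cov_x2(moments, dec)
    l1, l2 = lambda1, lambda2

    a1 = (
        _core_var(moments, dec, theta) / theta
        + t_star ** 2 * (l1 ** 2 / 4.0 * e2 + l2 ** 2 * e4 + l1 * l2 * e22)
        - 2.0 * t_star * (l1 / 2.0 * cov1 + l2 * cov2)
    )
    a2 = t_star * (l1 / 2.0 * e2 + l2 * e22) - cov1
    a3 = cov2 - t_star * (l1 / 2.0 * e22 + l2 * e4)
    a6 = e2 * e4 - e22 ** 2
    if abs(a6) < 1e-12 * max(e2 * e4, 1e-300):
        raise CollinearAuxiliaryError("auxiliary fourth-moment system is singular")
    a4 = a2 * e4 + a3 * e22
    a5 = a2 * e22 + a3 * e2
    residual = a1 - (a2 * a4 + a3 * a5) / a6
    a7 = t_star ** 2 + theta * residual
    return {
        "t_star": t_star, "theta": theta,
        "e2": e2, "e4": e4, "e22": e22,
        "cov1": cov1, "cov2": cov2,
        "a1": a1, "a2": a2, "a3": a3, "a4": a4, "a5": a5, "a6": a6,
        "a7": a7, "residual": residual,
    }


def optimum_class_constants(moments, dec, lambda1, lambda2, n):
    """Closed-form (k1, k2, k3) minimizing the first-order class MSE."""
    t = class_terms(moments, dec, lambda1, lambda2, n)
    var_y = moments.var_y
    k1 = t["t_star"] * var_y / t["a7"] if t["a7"] != 0 else np.nan
    if not np.isfinite(k1):
        raise CollinearAuxiliaryError("optimum leading constant is not finite")
    k2 = -k1 * t["a4"] / (moments.var_x1 * t["a6"])
    k3 = k1 * t["a5"] / (moments.var_x2 * t["a6"])
    return (k1, k2, k3), t


def class_mse(moments, dec, k1, k2, k3, lambda1, lambda2, n) -> float:
    """First-order MSE of the generalized class at arbitrary constants."""
    t = class_terms(moments, dec, lambda1, lambda2, n)
    theta, t_star = t["theta"], t["t_star"]
    sx1, sx2 = moments.var_x1, moments.var_x2
    return (
        (k1 * t_star - moments.var_y) ** 2
        + theta * (
            k1 ** 2 * t["a1"]
            + k2 ** 2 * sx1 ** 2 * t["e2"]
            + k3 ** 2 * sx2 ** 2 * t["e4"]
            + 2.0 * k1 * k2 * sx1 * t["a2"]
            - 2.0 * k1 * k3 * sx2 * t["a3"]
            + 2.0 * k2 * k3 * sx1 * sx2 * t["e22"]
        )
    )


def class_bias(moments, dec, k1, k2, k3, lambda1, lambda2, n) -> float:
    """First-order bias of the generalized class."""
    t = class_terms(moments, dec, lambda1, lambda2, n)
    theta, t_star = t["theta"], t["t_star"]
    l1, l2 = lambda1, lambda2
    core_bias = -dec.slope * moments.mean_z ** 2 * moments.cv_z ** 2 / dec.denom
    adj_quad = (l1 / 4.0 + l1 ** 2 / 8.0) * t["e2"] \
        + l2 * (l2 + 1.0) / 2.0 * t["e4"] + l1 * l2 / 2.0 * t["e22"]
    return (
        (k1 * t_star - moments.var_y)
        + k1 * theta * (core_bias - l1 / 2.0 * t["cov1"] - l2 * t["cov2"])
        + k1 * t_star * theta * adj_quad
        + k2 * moments.var_x1 * theta * (l1 / 2.0 * t["e2"] + l2 * t["e22"])
        + k3 * moments.var_x2 * theta * (l1 / 2.0 * t["e22"] + l2 * t["e4"])
    )


def _min_mse_class(moments, dec, lambda1, lambda2, n, strict_paper=False) -> float:
    t = class_terms(moments, dec, lambda1, lambda2, n)
    var_y = moments.var_y
    if strict_paper:
        # literal printed form: sigma_y^6 (1 - 1/A7)
        return var_y ** 3 * (1.0 - 1.0 / t["a7"])
    return var_y ** 2 - (t["t_star"] * var_y) ** 2 / t["a7"]


# ---------------------------------------------------------------------------
# model-facing wrappers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DPTheoryTerms:
    """Intermediates of the class MSE under the multiplicative-additive model."""

    a1: float
    a2: float
    a3: float
    a4: float
    a5: float
    a6: float
    a7: float


@dataclass(frozen=True)
class NPTheoryTerms:
    """Intermediates of the class MSE under the combined model.

    Slot mapping (documented because the source mixes symbol families):
    d1 = per-theta variance of the decoded core; d2/d3 = per-theta
    covariances of the core with the two auxiliary relative errors;
    d4 = residual variance term after the auxiliary optimization;
    b1..b3 mirror a1..a3 of the other model, b4/b6 the combined
    numerators, b5/b7 the (variance-scaled) determinant, b8 the residual
    entering the optimum leading constant.
    """

    d1: float
    d2: float
    d3: float
    d4: float
    b1: float
    b2: float
    b3: float
    b4: float
    b5: float
    b6: float
    b7: float
    b8: float


def mse_t0_theory(moments, params, n: int, strict_paper: bool = False) -> float:
    """First-order MSE of the basic decoded estimator under Z = T*Y + S."""
    return _mse_core(moments, dp_decoder(params), n, strict_paper)


def mse_tratio_theory(moments, params, n: int) -> float:
    """First-order MSE of the ratio-adjusted estimator under Z = T*Y + S."""
    return _mse_ratio(moments, dp_decoder(params), n)


def min_mse_tgratio_theory(moments, params, n: int, strict_paper: bool = False) -> float:
    """Minimum first-order MSE of the generalized ratio estimator."""
    return _min_mse_gratio(moments, dp_decoder(params), n, strict_paper)


def t1d_theory(moments, params, constants: T1DConstants, n: int,
               strict_paper: bool = False):
    """(bias, mse, min_mse) of the generalized class under Z = T*Y + S."""
    dec = dp_decoder(params)
    bias = class_bias(moments, dec, constants.k1, constants.k2, constants.k3,
                      constants.lambda1, constants.lambda2, n)
    mse = class_mse(moments, dec, constants.k1, constants.k2, constants.k3,
                    constants.lambda1, constants.lambda2, n)
    min_mse = _min_mse_class(moments, dec, constants.lambda1, constants.lambda2,
                             n, strict_paper)
    return bias, mse, min_mse


def min_mse_t1d_theory(moments, params, lambda1, lambda2, n,
                       strict_paper: bool = False) -> float:
    return _min_mse_class(moments, dp_decoder(params), lambda1, lambda2, n,
                          strict_paper)


def dp_theory_terms(moments, params, lambda1, lambda2, n) -> DPTheoryTerms:
    t = class_terms(moments, dp_decoder(params), lambda1, lambda2, n)
    return DPTheoryTerms(*(t[k] for k in ("a1", "a2", "a3", "a4", "a5", "a6", "a7")))


def tnp1_theory(moments, params, n: int, strict_paper: bool = False):
    """(bias, mse) of the basic decoded estimator under the combined model."""
    dec = np_decoder(params)
    theta = 1.0 / n
    bias = -theta * dec.slope * moments.mean_z ** 2 * moments.cv_z ** 2 / dec.denom
    mse = _mse_core(moments, dec, n, strict_paper)
    return bias, mse


def tnp2_theory(moments, params, n: int):
    """(bias, mse) of the ratio-adjusted estimator under the combined model."""
    dec = np_decoder(params)
    theta = 1.0 / n
    t_star = dec.census_value(moments.var_z, moments.mean_z)
    e2 = moments.mu[(0, 4, 0)] - 1.0
    bias = theta * (
        -dec.slope * moments.mean_z ** 2 * moments.cv_z ** 2 / dec.denom
        + t_star * e2 - _cov_x1(moments, dec)
    )
    return bias, _mse_ratio(moments, dec, n)


def t1n_theory(moments, params, constants: T1NConstants, n: int,
               strict_paper: bool = False):
    """(bias, mse, min_mse) of the generalized class under the combined model."""
    dec = np_decoder(params)
    bias = class_bias(moments, dec, constants.w1, constants.w2, constants.w3,
                      constants.v1, constants.v2, n)
    mse = class_mse(moments, dec, constants.w1, constants.w2, constants.w3,
                    constants.v1, constants.v2, n)
    min_mse = _min_mse_class(moments, dec, constants.v1, constants.v2, n,
                             strict_paper)
    return bias, mse, min_mse


def min_mse_t1n_theory(moments, params, v1, v2, n, strict_paper=False) -> float:
    return _min_mse_class(moments, np_decoder(params), v1, v2, n, strict_paper)


def np_theory_terms(moments, params, v1, v2, n) -> NPTheoryTerms:
    dec = np_decoder(params)
    t = class_terms(moments, dec, v1, v2, n)
    d1 = _core_var(moments, dec, 1.0)
    d2 = t["cov1"]
    d3 = t["cov2"]
    return NPTheoryTerms(
        d1=d1, d2=d2, d3=d3, d4=t["residual"],
        b1=t["a1"], b2=t["a2"], b3=t["a3"], b4=t["a4"],
        b5=moments.var_x1 * t["a6"], b6=t["a5"],
        b7=moments.var_x2 * t["a6"], b8=t["residual"],
    )


# ---------------------------------------------------------------------------
# the delta-method oracle
# ---------------------------------------------------------------------------

def _moment_covariance(moments: PopulationMoments, n: int) -> np.ndarray:
    theta = 1.0 / n
    m = moments.mu
    sz2, sx1, sx2 = moments.var_z, moments.var_x1, moments.var_x2
    zbar, cz = moments.mean_z, moments.cv_z
    c = np.empty((4, 4))
    c[0, 0] = sz2 ** 2 * (m[(4, 0, 0)] - 1.0)
    c[1, 1] = sx1 ** 2 * (m[(0, 4, 0)] - 1.0)
    c[2, 2] = sx2 ** 2 * (m[(0, 0, 4)] - 1.0)
    c[3, 3] = cz ** 2 * zbar ** 2
    c[0, 1] = c[1, 0] = sz2 * sx1 * (m[(2, 2, 0)] - 1.0)
    c[0, 2] = c[2, 0] = sz2 * sx2 * (m[(2, 0, 2)] - 1.0)
    c[1, 2] = c[2, 1] = sx1 * sx2 * (m[(0, 2, 2)] - 1.0)
    c[0, 3] = c[3, 0] = sz2 * zbar * m[(3, 0, 0)] * cz
    c[1, 3] = c[3, 1] = sx1 * zbar * m[(1, 2, 0)] * cz
    c[2, 3] = c[3, 2] = sx2 * zbar * m[(1, 0, 2)] * cz
    return theta * c


def delta_method_mse(estimator, moments: PopulationMoments, n: int) -> float:
    """Generic first-order MSE of ``estimator(s_z2, s_x12, s_x22, zbar)``.

    Returns (t(mu*) - sigma_y^2)^2 + grad' C grad with a central-difference
    gradient at the population point and C the 4x4 covariance assembled
    from the standardized-moment expectation table.
    """
    point = np.array([moments.var_z, moments.var_x1, moments.var_x2,
                      moments.mean_z], dtype=float)
    cov = _moment_covariance(moments, n)
    grad = np.empty(4)
    for i in range(4):
        h = max(1e-6 * abs(point[i]), 1e-9)
        hi, lo = point.copy(), point.copy()
        hi[i] += h
        lo[i] -= h
        grad[i] = (estimator(*hi) - estimator(*lo)) / (2.0 * h)
    if not np.all(np.isfinite(grad)):
        raise RRTVarError("non-finite gradient in delta-method expansion")
    bias0 = float(estimator(*point)) - moments.var_y
    return bias0 ** 2 + float(grad @ cov @ grad)


# ---------------------------------------------------------------------------
# efficiency comparison
# ---------------------------------------------------------------------------

def _dp_mse_by_tag(tag, moments, params, n, lambda1, lambda2):
    from .estimators import make_class_estimator  # local import, no cycle

    if tag == "t0":
        return mse_t0_theory(moments, params, n)
    if tag == "ratio":
        return mse_tratio_theory(moments, params, n)
    if tag == "gratio":
        return min_mse_tgratio_theory(moments, params, n)
    if tag == "t1D":
        return min_mse_t1d_theory(moments, params, lambda1, lambda2, n)
    if tag.startswith("t1D("):
        tpl = make_class_estimator(tag)
        dec = dp_decoder(params)
        l1 = tpl.lambda1 if tpl.lambda1 is not None else lambda1
        l2 = tpl.lambda2 if tpl.lambda2 is not None else lambda2
        (k1o, k2o, k3o), _ = optimum_class_constants(moments, dec, l1, l2, n)
        k1 = tpl.k1 if tpl.k1 is not None else k1o
        k2 = tpl.k2 if tpl.k2 is not None else k2o
        k3 = tpl.k3 if tpl.k3 is not None else k3o
        if tpl.k1 is not None:
            # with k1 pinned, re-solve the (k2, k3) normal equations for the
            # members that keep them free
            t = class_terms(moments, dec, l1, l2, n)
            if tpl.k2 is None and tpl.k3 is None:
                k2 = -k1 * t["a4"] / (moments.var_x1 * t["a6"])
                k3 = k1 * t["a5"] / (moments.var_x2 * t["a6"])
            elif tpl.k2 is None:
                k2 = (-k1 * t["a2"] - k3 * moments.var_x2 * t["e22"]) / \
                    (moments.var_x1 * t["e2"])
            elif tpl.k3 is None:
                k3 = (k1 * t["a3"] - k2 * moments.var_x1 * t["e22"]) / \
                    (moments.var_x2 * t["e4"])
        return class_mse(moments, dec, k1, k2, k3, l1, l2, n)
    raise InvalidParameterError(f"unknown estimator tag for this model: {tag}")


def _np_mse_by_tag(tag, moments, params, n, v1, v2):
    if tag == "tNP1":
        return tnp1_theory(moments, params, n)[1]
    if tag == "tNP2":
        return tnp2_theory(moments, params, n)[1]
    if tag == "t1N":
        return min_mse_t1n_theory(moments, params, v1, v2, n)
    raise InvalidParameterError(f"unknown estimator tag for this model: {tag}")


def efficiency_compare(moments, params, n, estimator_tags,
                       lambda1: float = 1.0, lambda2: float = 1.0) -> pd.DataFrame:
    """Tabulate theoretical MSEs against the basic estimator of the model.

    Efficiency conditions are decided by direct evaluation of the MSE
    expressions (difference > 0 <=> the candidate is better), which is
    equivalent to the printed inequality chains.
    """
    from .scrambling import DPModelParams

    is_dp = isinstance(params, DPModelParams)
    base_tag = "t0" if is_dp else "tNP1"
    fn = _dp_mse_by_tag if is_dp else _np_mse_by_tag
    base = fn(base_tag, moments, params, n, lambda1, lambda2)
    rows = []
    for tag in estimator_tags:
        mse = fn(tag, moments, params, n, lambda1, lambda2)
        rows.append({
            "tag": tag,
            "mse": mse,
            "mse_minus_baseline": mse - base,
            "better_than_baseline": bool(mse < base),
        })
    return pd.DataFrame(rows)


# convenience callables for the oracle ---------------------------------------

def core_callable(dec: Decoder):
    return lambda s2z, s2x1, s2x2, zbar: core_estimate(dec, s2z, zbar)


def ratio_callable(dec: Decoder, var_x1_pop: float):
    return lambda s2z, s2x1, s2x2, zbar: ratio_estimate(dec, s2z, zbar, s2x1,
                                                        var_x1_pop)


def gratio_callable(dec: Decoder, var_x1_pop: float, constants: GRatioConstants):
    return lambda s2z, s2x1, s2x2, zbar: gratio_estimate(
        dec, s2z, zbar, s2x1, var_x1_pop, constants)


def class_callable(dec: Decoder, var_x1_pop, var_x2_pop, k1, k2, k3, l1, l2):
    return lambda s2z, s2x1, s2x2, zbar: class_estimate(
        dec, s2z, zbar, s2x1, s2x2, var_x1_pop, var_x2_pop, k1, k2, k3, l1, l2)
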