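"""Scrambled-response models and privacy-protection measures.

Two models are implemented:

* the multiplicative-plus-additive model ``Z = T*Y + S`` with a mean-1
  multiplier T (written R in the privacy section; one parameter object
  serves both symbols), and
* the combined model ``Z = g*(Y + a*S) + (1 - g)*R*(Y + a*S)`` that mixes
  additive and multiplicative perturbation through the mixing weight g.

Privacy is measured by Delta = E(Z - Y)^2: larger means the reported value
sits further from the true one on average.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "DistributionSpec",
    "DPModelParams",
    "NPModelParams",
    "PrivacyResult",
    "scramble_dp",
    "scramble_proposed",
    "privacy_dp",
    "privacy_proposed",
    "privacy_mc",
    "privacy_gain_condition",
]


@dataclass(frozen=True)
class DistributionSpec:
    """Serializable spec of a scrambling distribution: {family, mean, sd}."""

    family: str = "normal"
    mean: float = 0.0
    sd: float = 1.0

    def draw(self, rng: np.random.Generator, size) -> np.ndarray:
        if self.family == "normal":
            return rng.normal(self.mean, self.sd, size)
        if self.family == "uniform":
            # uniform with the requested mean and sd
            half = self.sd * np.sqrt(3.0)
            return rng.uniform(self.mean - half, self.mean + half, size)
        if self.family == "degenerate":
            return np.full(size, self.mean)
        raise InvalidParameterError(f"unknown distribution family: {self.family}")

    @property
    def var(self) -> float:
        return self.sd ** 2


def _spec(dist, default_mean, var):
    if dist is not None:
        return dist
    sd = float(np.sqrt(var))
    return DistributionSpec("normal", default_mean, sd) if sd > 0 else \
        DistributionSpec("degenerate", default_mean, 0.0)


@dataclass(frozen=True)
class DPModelParams:
    """Parameters of the Z = T*Y + S model.

    T has mean 1 and variance ``var_t``; S has mean 0 and variance
    ``var_s``.  The decoding identity requires those means; pass
    ``allow_off_center=True`` to override (e.g. for a constant shift).
    """

    var_s: float = 0.5
    var_t: float = 0.5
    s_dist: DistributionSpec | None = None
    t_dist: DistributionSpec | None = None
    allow_off_center: bool = False

    def __post_init__(self):
        if self.var_s < 0 or self.var_t < 0:
            raise InvalidParameterError("variances must be nonnegative")
        object.__setattr__(self, "s_dist", _spec(self.s_dist, 0.0, self.var_s))
        object.__setattr__(self, "t_dist", _spec(self.t_dist, 1.0, self.var_t))
        if not self.allow_off_center:
            if self.s_dist.mean != 0.0 or self.t_dist.mean != 1.0:
                raise InvalidParameterError(
                    "decoding requires mean(S) = 0 and mean(T) = 1 "
                    "(set allow_off_center=True to override)"
                )

    @property
    def var_r(self) -> float:
        """Alias: the multiplier variance under its other symbol."""
        return self.var_t


@dataclass(frozen=True)
class NPModelParams:
    """Parameters of the combined model Z = g*(Y+aS) + (1-g)*R*(Y+aS).

    ``G`` is the printed decoding denominator g^2 + (1-g)^2 (var_r + 1).
    The literal simulation of the model has Var(Z) governed by
    1 + (1-g)^2 var_r instead (the printed form drops the covariance
    between the two mixture components); ``decoder_denominator`` exposes
    both readings via ``mode``.
    """

    g: float = 0.5
    a: float = 1.0
    var_r: float = 0.5
    var_s: float = 0.5
    mode: str = "paper"
    r_dist: DistributionSpec | None = None
    s_dist: DistributionSpec | None = None

    def __post_init__(self):
        if not 0.0 <= self.g <= 1.0:
            raise InvalidParameterError("g must lie in [0, 1]")
        if self.a < 0 or self.var_r < 0 or self.var_s < 0:
            raise InvalidParameterError("a and variances must be nonnegative")
        if self.mode not in ("paper", "consistent"):
            raise InvalidParameterError("mode must be 'paper' or 'consistent'")
        object.__setattr__(self, "r_dist", _spec(self.r_dist, 1.0, self.var_r))
        object.__setattr__(self, "s_dist", _spec(self.s_dist, 0.0, self.var_s))

    @property
    def G(self) -> float:
        """Printed decoding denominator g^2 + (1-g)^2 (var_r + 1)."""
        return self.g ** 2 + (1.0 - self.g) ** 2 * (self.var_r + 1.0)

    @property
    def decoder_denominator(self) -> float:
        if self.mode == "paper":
            return self.G
        return 1.0 + (1.0 - self.g) ** 2 * self.var_r

    @property
    def multiplier_coefficient(self) -> float:
        """Coefficient of zbar^2 inside the decoder: (1-g)^2 var_r."""
        return (1.0 - self.g) ** 2 * self.var_r


@dataclass(frozen=True)
class PrivacyResult:
    """Privacy level Delta = E(Z - Y)^2 with the ingredients that built it."""

    delta: float
    model_tag: str
    components: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.delta < 0:
            raise InvalidParameterError("privacy level cannot be negative")


def scramble_dp(y, params: DPModelParams, seed) -> np.ndarray:
    """Scramble Y as Z_i = T_i * Y_i + S_i with independent per-unit draws."""
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    t = params.t_dist.draw(rng, y.shape)
    s = params.s_dist.draw(rng, y.shape)
    return t * y + s


def scramble_proposed(y, params: NPModelParams, seed) -> np.ndarray:
    """Scramble Y as Z_i = g (Y_i + a S_i) + (1-g) R_i (Y_i + a S_i)."""
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    r = params.r_dist.draw(rng, y.shape)
    s = params.s_dist.draw(rng, y.shape)
    w = y + params.a * s
    return params.g * w + (1.0 - params.g) * r * w


def privacy_dp(mean_y: float, var_y: float, var_r: float, var_s: float) -> PrivacyResult:
    """Closed-form privacy of Z = R*Y + S: var_r (mu_Y^2 + var_y) + var_s."""
    if var_y < 0 or var_r < 0 or var_s < 0:
        raise InvalidParameterError("variances must be nonnegative")
    delta = var_r * (mean_y ** 2 + var_y) + var_s
    return PrivacyResult(delta, "dp", {
        "mean_y": mean_y, "var_y": var_y, "var_r": var_r, "var_s": var_s,
    })


def privacy_proposed(
    mean_y: float, var_y: float, a: float, g: float, var_r: float, var_s: float
) -> PrivacyResult:
    """Closed-form privacy of the combined model:
    (mu_Y^2 + var_y + a^2 var_s)(1 + (1-g)^2 var_r) - (mu_Y^2 + var_y).
    """
    if not 0.0 <= g <= 1.0:
        raise InvalidParameterError("g must lie in [0, 1]")
    if var_y < 0 or var_r < 0 or var_s < 0 or a < 0:
        raise InvalidParameterError("a and variances must be nonnegative")
    m = mean_y ** 2 + var_y
    delta = (m + a ** 2 * var_s) * (1.0 + (1.0 - g) ** 2 * var_r) - m
    return PrivacyResult(delta, "proposed", {
        "mean_y": mean_y, "var_y": var_y, "a": a, "g": g,
        "var_r": var_r, "var_s": var_s,
    })


def privacy_mc(z, y) -> float:
    """Empirical privacy: mean of (Z_i - Y_i)^2."""
    z = np.asarray(z, dtype=float)
    y = np.asarray(y, dtype=float)
    if z.shape != y.shape or z.ndim != 1 or z.size < 1:
        raise InvalidInputError("z and y must be equal-length vectors")
    return float(np.mean((z - y) ** 2))


def privacy_gain_condition(mean_y, var_y, a, g, var_r, var_s):
    """Difference Delta_proposed - Delta_dp and whether the proposed model
    is the more private one.

    The sign agrees with the expanded comparison form
    (mu_Y^2 + var_y) var_r g (g - 2) - var_s [1 - a^2 (1 + (1-g)^2 var_r)].
    """
    d_pn = privacy_proposed(mean_y, var_y, a, g, var_r, var_s).delta
    d_d = privacy_dp(mean_y, var_y, var_r, var_s).delta
    diff = d_pn - d_d
    return diff, diff > 0


def privacy_gain_expanded(mean_y, var_y, a, g, var_r, var_s) -> float:
    """The expanded algebraic form of Delta_proposed - Delta_dp
    (used as an independent cross-check of the two closed forms)."""
    m = mean_y ** 2 + var_y
    return m * var_r * g * (g - 2.0) - var_s * (
        1.0 - a ** 2 * (1.0 + (1.0 - g) ** 2 * var_r)
    )
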