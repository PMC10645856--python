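"""Synthetic finite populations, their moments, and SRSWOR sampling.

A finite population holds the triple (Y, X1, X2): the sensitive study
variable and two non-sensitive auxiliaries.  All downstream theory is
driven by central cross-moments with divisor ``N - 1`` and by the
standardized moments derived from them, computed over the *scrambled*
response Z in the first slot (configurable to Y for auditing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegeneratePopulationError,
    InvalidInputError,
    InvalidParameterError,
)

__all__ = [
    "FinitePopulation",
    "PopulationMoments",
    "SampleSummary",
    "MOMENT_TRIPLES",
    "example_survey_population",
    "generate_population",
    "eta_moment",
    "mu_moment",
    "compute_population_moments",
    "draw_srswor",
    "summarize_sample",
]

#: standardized-moment triples consumed by the closed-form theory
MOMENT_TRIPLES = (
    (4, 0, 0), (0, 4, 0), (0, 0, 4),
    (2, 2, 0), (2, 0, 2), (0, 2, 2),
    (3, 0, 0), (1, 2, 0), (1, 0, 2),
)


@dataclass(frozen=True)
class FinitePopulation:
    """The N x 3 truth (Y, X1, X2) from which everything is sampled."""

    y_values: np.ndarray
    x1_values: np.ndarray
    x2_values: np.ndarray

    def __post_init__(self):
        y = np.asarray(self.y_values, dtype=float)
        x1 = np.asarray(self.x1_values, dtype=float)
        x2 = np.asarray(self.x2_values, dtype=float)
        object.__setattr__(self, "y_values", y)
        object.__setattr__(self, "x1_values", x1)
        object.__setattr__(self, "x2_values", x2)
        if not (y.shape == x1.shape == x2.shape) or y.ndim != 1:
            raise InvalidInputError("Y, X1, X2 must be 1-d vectors of equal length")
        if y.size < 4:
            raise InvalidInputError("population size must be at least 4")
        for name, v in (("Y", y), ("X1", x1), ("X2", x2)):
            if np.var(v, ddof=1) <= 0.0:
                raise DegeneratePopulationError(f"{name} has zero population variance")

    @property
    def size(self) -> int:
        return self.y_values.size

    @property
    def mean_y(self) -> float:
        return float(np.mean(self.y_values))

    @property
    def var_y(self) -> float:
        """Finite-population variance of Y (divisor N - 1): the estimand."""
        return float(np.var(self.y_values, ddof=1))

    @property
    def var_x1(self) -> float:
        return float(np.var(self.x1_values, ddof=1))

    @property
    def var_x2(self) -> float:
        return float(np.var(self.x2_values, ddof=1))

    def to_csv(self, path) -> None:
        """Export as a delimited table with header Y,X1,X2."""
        pd.DataFrame(
            {"Y": self.y_values, "X1": self.x1_values, "X2": self.x2_values}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FinitePopulation":
        df = pd.read_csv(path)
        missing = {"Y", "X1", "X2"} - set(df.columns)
        if missing:
            raise InvalidInputError(f"population table missing columns: {sorted(missing)}")
        return cls(df["Y"].to_numpy(float), df["X1"].to_numpy(float), df["X2"].to_numpy(float))


@dataclass
class PopulationMoments:
    """All means, variances and standardized moments the theory consumes.

    Moment triples (r, s, a) are taken over (Z, X1, X2) by default: the
    first index always refers to the scrambled response.  ``mu`` holds the
    standardized moments and ``eta`` the raw central cross-moments.
    """

    mean_z: float
    var_z: float
    var_y: float
    var_x1: float
    var_x2: float
    mean_y: float
    mu: dict = field(default_factory=dict)
    eta: dict = field(default_factory=dict)
    theta: float | None = None

    @property
    def cv_z(self) -> float:
        """Coefficient of variation of Z (sqrt(var_z)/mean_z)."""
        return float(np.sqrt(self.var_z) / self.mean_z)

    def with_theta(self, n: int) -> "PopulationMoments":
        """Return a copy with theta = 1/n attached (no fpc, as printed)."""
        out = PopulationMoments(
            self.mean_z, self.var_z, self.var_y, self.var_x1, self.var_x2,
            self.mean_y, dict(self.mu), dict(self.eta), theta=1.0 / n,
        )
        return out


@dataclass(frozen=True)
class SampleSummary:
    """Sample moments of one SRSWOR draw of scrambled responses."""

    n: int
    s2_z: float
    s2_x1: float
    s2_x2: float
    zbar: float

    def __post_init__(self):
        if self.n < 2:
            raise InvalidInputError("sample size must be at least 2")
        for f in ("s2_z", "s2_x1", "s2_x2"):
            if getattr(self, f) < 0:
                raise InvalidInputError(f"{f} must be nonnegative")

    @property
    def theta(self) -> float:
        return 1.0 / self.n


def example_survey_population(seed: int = 90) -> FinitePopulation:
    """Synthetic 90-unit demonstration population mimicking the published
    GPA-survey summary characteristics (auxiliaries with means 27.61 and
    19.88, standard deviations 8.66 and 18.83; a 0-4 bounded study
    variable).  The real survey data are not public; this fixture is for
    demonstration only and reproduces summary statistics, not microdata."""
    rng = np.random.default_rng(seed)
    y = np.clip(rng.normal(3.0, 0.6, 90), 0.0, 4.0)
    x1 = 27.61 + 8.66 * ((y - 3.0) / 0.6 * 0.4
                         + np.sqrt(1 - 0.4 ** 2) * rng.standard_normal(90))
    x2 = np.abs(19.88 + 18.83 * ((y - 3.0) / 0.6 * 0.3
                                 + np.sqrt(1 - 0.3 ** 2) * rng.standard_normal(90)))
    return FinitePopulation(y, x1, x2)


def generate_population(cov, means, size: int, seed: int) -> FinitePopulation:
    """Draw a trivariate-normal finite population of N units.

    Parameters
    ----------
    cov : (3, 3) array_like
        Symmetric positive-definite covariance of (Y, X1, X2).
    means : length-3 sequence
        Mean vector of (Y, X1, X2).
    size : int
        Population size N (>= 10).
    seed : int
        Seed for the generator; same arguments => bit-identical output.
    """
    cov = np.asarray(cov, dtype=float)
    means = np.asarray(means, dtype=float)
    if cov.shape != (3, 3) or means.shape != (3,):
        raise InvalidParameterError("cov must be 3x3 and means length 3")
    if not np.allclose(cov, cov.T):
        raise InvalidParameterError("covariance matrix must be symmetric")
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise InvalidParameterError("covariance matrix must be positive definite") from exc
    if size < 10:
        raise InvalidParameterError("population size must be at least 10")
    rng = np.random.default_rng(seed)
    draws = means + rng.standard_normal((size, 3)) @ chol.T
    return FinitePopulation(draws[:, 0], draws[:, 1], draws[:, 2])


def eta_moment(values_y, values_x1, values_x2, r: int, s: int, a: int) -> float:
    """Central cross-moment with divisor N - 1:
    (1/(N-1)) * sum (Yi - Ybar)^r (X1i - X1bar)^s (X2i - X2bar)^a.
    """
    y = np.asarray(values_y, dtype=float)
    x1 = np.asarray(values_x1, dtype=float)
    x2 = np.asarray(values_x2, dtype=float)
    if not (y.shape == x1.shape == x2.shape) or y.ndim != 1 or y.size < 2:
        raise InvalidInputError("vectors must share a common length >= 2")
    if min(r, s, a) < 0:
        raise InvalidInputError("moment orders must be nonnegative")
    dy = y - y.mean() if r else 1.0
    d1 = x1 - x1.mean() if s else 1.0
    d2 = x2 - x2.mean() if a else 1.0
    term = np.ones_like(y)
    if r:
        term = term * dy ** r
    if s:
        term = term * d1 ** s
    if a:
        term = term * d2 ** a
    return float(term.sum() / (y.size - 1))


def mu_moment(moments: PopulationMoments, r: int, s: int, a: int) -> float:
    """Standardized moment mu_rsa = eta_rsa / (eta200^{r/2} eta020^{s/2} eta002^{a/2})."""
    e200 = moments.eta[(2, 0, 0)]
    e020 = moments.eta[(0, 2, 0)]
    e002 = moments.eta[(0, 0, 2)]
    if min(e200, e020, e002) <= 0:
        raise DegeneratePopulationError("all marginal variances must be positive")
    return float(
        moments.eta[(r, s, a)]
        / (e200 ** (r / 2) * e020 ** (s / 2) * e002 ** (a / 2))
    )


def compute_population_moments(
    pop: FinitePopulation, z_values, first_axis: str = "z"
) -> PopulationMoments:
    """Compute every moment needed by the closed-form theory.

    ``z_values`` are the scrambled responses for all N units.  Moment
    triples are over (Z, X1, X2) when ``first_axis == "z"`` (the default,
    forced by the error-term expectation table) or over (Y, X1, X2) when
    ``first_axis == "y"``.
    """
    z = np.asarray(z_values, dtype=float)
    if z.shape != pop.y_values.shape:
        raise InvalidInputError("z_values must have the population length")
    if first_axis not in ("z", "y"):
        raise InvalidParameterError("first_axis must be 'z' or 'y'")
    first = z if first_axis == "z" else pop.y_values

    moments = PopulationMoments(
        mean_z=float(z.mean()),
        var_z=float(np.var(z, ddof=1)),
        var_y=pop.var_y,
        var_x1=pop.var_x1,
        var_x2=pop.var_x2,
        mean_y=pop.mean_y,
    )
    triples = set(MOMENT_TRIPLES) | {(2, 0, 0), (0, 2, 0), (0, 0, 2)}
    for (r, s, a) in triples:
        moments.eta[(r, s, a)] = eta_moment(first, pop.x1_values, pop.x2_values, r, s, a)
    for (r, s, a) in triples:
        moments.mu[(r, s, a)] = mu_moment(moments, r, s, a)
    return moments


def draw_srswor(pop_size: int, n: int, seed) -> np.ndarray:
    """Draw n distinct unit indices uniformly from {0, ..., N-1} (SRSWOR)."""
    if n < 2 or n > pop_size:
        raise InvalidParameterError("need 2 <= n <= N for SRSWOR")
    rng = np.random.default_rng(seed)
    return rng.choice(pop_size, size=n, replace=False, shuffle=False)


def summarize_sample(z, x1, x2) -> SampleSummary:
    """Sample variances (divisor n - 1) and mean of the scrambled responses."""
    z = np.asarray(z, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if not (z.shape == x1.shape == x2.shape) or z.ndim != 1 or z.size < 2:
        raise InvalidInputError("sample vectors must share a common length >= 2")
    return SampleSummary(
        n=z.size,
        s2_z=float(np.var(z, ddof=1)),
        s2_x1=float(np.var(x1, ddof=1)),
        s2_x2=float(np.var(x2, ddof=1)),
        zbar=float(z.mean()),
    )
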