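"""Monte-Carlo engine: repeated SRSWOR samples, empirical Mean/MSE per
estimator, percent relative efficiency, and the unified
privacy-efficiency measure.

Design choices (documented, since the source is silent):

* The finite population (Y, X1, X2) is fixed for a whole run; scrambling
  noise is redrawn independently for the sampled units in every
  replication (each respondent scrambles at response time).
* The estimand is the realized finite-population variance of Y
  (divisor N - 1), not the superpopulation variance.
* "Design" moments used for optimum constants and theory values are
  population moments of (Z, X1, X2) averaged over ``moment_reps``
  independent full-population scramblings.
* The unified measure is MSE / Delta (matching the tabulated values; the
  printed x100 variant is available via ``times_100=True``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._core import GRatioConstants, dp_decoder, np_decoder
from .errors import IncompleteResultsError, InvalidParameterError
from .population import (
    FinitePopulation,
    PopulationMoments,
    eta_moment,
    generate_population,
    MOMENT_TRIPLES,
)
from .scrambling import DPModelParams, NPModelParams, privacy_dp, privacy_proposed
from .theory import optimum_class_constants, optimum_gratio_psi

__all__ = [
    "POPULATION_I_COV",
    "POPULATION_II_COV",
    "SimulationConfig",
    "SimulationResult",
    "run_monte_carlo",
    "pre",
    "unified_measure",
    "build_table",
]

#: covariance matrices of the two benchmark populations
POPULATION_I_COV = np.array([[10.0, 3.0, 2.9], [3.0, 2.0, 1.1], [2.9, 1.1, 2.0]])
POPULATION_II_COV = np.array([[6.0, 3.0, 2.9], [3.0, 2.0, 1.1], [2.9, 1.1, 2.0]])

_DP_ESTIMATORS = ("t0", "ratio", "gratio", "t1D")
_NP_ESTIMATORS = ("tNP1", "tNP2", "t1N")


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of one Monte-Carlo study."""

    cov: np.ndarray = field(default_factory=lambda: POPULATION_I_COV.copy())
    means: tuple = (3.0, 3.0, 3.0)
    pop_size: int = 100_000
    model: str = "dp"                      # "dp" or "np"
    var_t: float = 0.5                     # DP multiplier variance
    g: float = 0.5                         # combined-model mixing weight
    a: float = 1.0
    var_r: float = 0.5
    np_mode: str = "consistent"            # decoder mode used in simulation
    sample_sizes: tuple = (200, 300, 500)
    var_s_values: tuple = (0.2, 0.5, 1.0)
    estimators: tuple | None = None
    replications: int = 10_000
    seed: int = 2023
    lambda1: float = 1.0
    lambda2: float = 1.0
    moment_reps: int = 8
    truncate_negative: bool = False
    batch_size: int = 512

    def __post_init__(self):
        if self.model not in ("dp", "np"):
            raise InvalidParameterError("model must be 'dp' or 'np'")
        if self.replications < 100:
            raise InvalidParameterError("need at least 100 replications")
        if max(self.sample_sizes) >= self.pop_size:
            raise InvalidParameterError("every sample size must be < pop_size")
        if self.estimators is None:
            tags = _DP_ESTIMATORS if self.model == "dp" else _NP_ESTIMATORS
            object.__setattr__(self, "estimators", tags)

    def model_params(self, var_s: float):
        if self.model == "dp":
            return DPModelParams(var_s=var_s, var_t=self.var_t)
        return NPModelParams(g=self.g, a=self.a, var_r=self.var_r,
                             var_s=var_s, mode=self.np_mode)

    def privacy_level(self, var_s: float, mean_y: float, var_y: float) -> float:
        if self.model == "dp":
            return privacy_dp(mean_y, var_y, self.var_t, var_s).delta
        return privacy_proposed(mean_y, var_y, self.a, self.g,
                                self.var_r, var_s).delta


@dataclass(frozen=True)
class SimulationResult:
    """One (estimator, n, var_s) cell of the results grid."""

    estimator: str
    n: int
    var_s: float
    mean_estimate: float
    empirical_mse: float
    pre: float
    vartheta: float
    mc_standard_error: float
    theory_mse: float
    negative_count: int
    failure_count: int


def _scramble_batch(y, cfg: SimulationConfig, var_s: float, rng) -> np.ndarray:
    if cfg.model == "dp":
        t = rng.normal(1.0, np.sqrt(cfg.var_t), y.shape)
        s = rng.normal(0.0, np.sqrt(var_s), y.shape)
        return t * y + s
    r = rng.normal(1.0, np.sqrt(cfg.var_r), y.shape)
    s = rng.normal(0.0, np.sqrt(var_s), y.shape)
    w = y + cfg.a * s
    return cfg.g * w + (1.0 - cfg.g) * r * w


def _design_moments(pop: FinitePopulation, cfg: SimulationConfig, var_s: float,
                    rng) -> PopulationMoments:
    """Population moments of (Z, X1, X2) averaged over independent
    full-population scramblings (expectation over response noise)."""
    triples = set(MOMENT_TRIPLES) | {(2, 0, 0), (0, 2, 0), (0, 0, 2)}
    eta_acc = {t: 0.0 for t in triples}
    mean_acc = var_acc = 0.0
    for _ in range(cfg.moment_reps):
        z = _scramble_batch(pop.y_values, cfg, var_s, rng)
        mean_acc += z.mean()
        var_acc += np.var(z, ddof=1)
        for t in triples:
            eta_acc[t] += eta_moment(z, pop.x1_values, pop.x2_values, *t)
    k = cfg.moment_reps
    moments = PopulationMoments(
        mean_z=mean_acc / k, var_z=var_acc / k,
        var_y=pop.var_y, var_x1=pop.var_x1, var_x2=pop.var_x2,
        mean_y=pop.mean_y,
    )
    e200 = eta_acc[(2, 0, 0)] / k
    e020 = eta_acc[(0, 2, 0)] / k
    e002 = eta_acc[(0, 0, 2)] / k
    for t in triples:
        moments.eta[t] = eta_acc[t] / k
        r, s, a = t
        moments.mu[t] = moments.eta[t] / (
            e200 ** (r / 2) * e020 ** (s / 2) * e002 ** (a / 2))
    return moments


def _cell_estimators(cfg, params, moments, n):
    """Build vectorized estimator callables (s2_z, s2_x1, s2_x2, zbar) -> array
    for one grid cell, with constants optimized from the design moments."""
    from .theory import (
        min_mse_t1d_theory, min_mse_t1n_theory, mse_t0_theory,
        mse_tratio_theory, min_mse_tgratio_theory, tnp1_theory, tnp2_theory,
    )

    var_x1, var_x2 = moments.var_x1, moments.var_x2
    out = {}
    theory = {}
    if cfg.model == "dp":
        dec = dp_decoder(params)
        (k1, k2, k3), _ = optimum_class_constants(
            moments, dec, cfg.lambda1, cfg.lambda2, n)
        psi = optimum_gratio_psi(moments, dec, n)
        t_star = dec.census_value(moments.var_z, moments.mean_z)
        # alpha=1, beta=0, exponent=1; omega chosen so the linearized
        # coefficient on delta_x1 equals the optimal psi
        omega = (psi - var_x1) / t_star
        grc = GRatioConstants(alpha=1.0, beta=0.0, omega=omega, exponent=1.0)
        for tag in cfg.estimators:
            if tag == "t0":
                out[tag] = lambda sz, s1, s2, zb: dec.decode(sz, zb)
                theory[tag] = mse_t0_theory(moments, params, n)
            elif tag == "ratio":
                out[tag] = lambda sz, s1, s2, zb: dec.decode(sz, zb) * (var_x1 / s1)
                theory[tag] = mse_tratio_theory(moments, params, n)
            elif tag == "gratio":
                def _gratio(sz, s1, s2, zb, _g=grc):
                    denom = _g.omega * s1 + (1.0 - _g.omega) * var_x1
                    return (dec.decode(sz, zb) + (var_x1 - s1)) * \
                        (var_x1 / denom) ** _g.exponent
                out[tag] = _gratio
                theory[tag] = min_mse_tgratio_theory(moments, params, n)
            elif tag == "t1D":
                def _t1d(sz, s1, s2, zb, k1=k1, k2=k2, k3=k3):
                    lead = k1 * dec.decode(sz, zb) + k2 * (var_x1 - s1) \
                        + k3 * (var_x2 - s2)
                    adj = np.exp(cfg.lambda1 * (var_x1 - s1) / (var_x1 + s1)) \
                        * (var_x2 / s2) ** cfg.lambda2
                    return lead * adj
                out[tag] = _t1d
                theory[tag] = min_mse_t1d_theory(moments, params,
                                                 cfg.lambda1, cfg.lambda2, n)
            else:
                raise InvalidParameterError(f"estimator {tag} not valid for dp model")
    else:
        dec = np_decoder(params)
        (w1, w2, w3), _ = optimum_class_constants(
            moments, dec, cfg.lambda1, cfg.lambda2, n)
        for tag in cfg.estimators:
            if tag == "tNP1":
                out[tag] = lambda sz, s1, s2, zb: dec.decode(sz, zb)
                theory[tag] = tnp1_theory(moments, params, n)[1]
            elif tag == "tNP2":
                out[tag] = lambda sz, s1, s2, zb: dec.decode(sz, zb) * (var_x1 / s1)
                theory[tag] = tnp2_theory(moments, params, n)[1]
            elif tag == "t1N":
                def _t1n(sz, s1, s2, zb, w1=w1, w2=w2, w3=w3):
                    lead = w1 * dec.decode(sz, zb) + w2 * (var_x1 - s1) \
                        + w3 * (var_x2 - s2)
                    adj = np.exp(cfg.lambda1 * (var_x1 - s1) / (var_x1 + s1)) \
                        * (var_x2 / s2) ** cfg.lambda2
                    return lead * adj
                out[tag] = _t1n
                theory[tag] = min_mse_t1n_theory(moments, params,
                                                 cfg.lambda1, cfg.lambda2, n)
            else:
                raise InvalidParameterError(f"estimator {tag} not valid for np model")
    return out, theory


def run_monte_carlo(config: SimulationConfig,
                    population: FinitePopulation | None = None) -> list[SimulationResult]:
    """Run the full (var_s x n) grid and return one result row per
    estimator and cell.  Deterministic for a fixed root seed."""
    root = np.random.SeedSequence(config.seed)
    pop_ss, mom_ss, mc_ss = root.spawn(3)
    if population is None:
        pop_seed = int(pop_ss.generate_state(1)[0])
        population = generate_population(config.cov, config.means,
                                         config.pop_size, pop_seed)
    y, x1, x2 = population.y_values, population.x1_values, population.x2_values
    n_pop = population.size
    sigma_y2 = population.var_y

    mom_rngs = {v: np.random.default_rng(ss)
                for v, ss in zip(config.var_s_values,
                                 mom_ss.spawn(len(config.var_s_values)))}
    cell_seeds = {}
    cells = [(vs, n) for vs in config.var_s_values for n in config.sample_sizes]
    for (vs, n), ss in zip(cells, mc_ss.spawn(len(cells))):
        cell_seeds[(vs, n)] = ss

    results: list[SimulationResult] = []
    base_tag = "t0" if config.model == "dp" else "tNP1"

    for var_s in config.var_s_values:
        params = config.model_params(var_s)
        moments_by_vs = _design_moments(population, config, var_s, mom_rngs[var_s])
        delta = config.privacy_level(var_s, population.mean_y, sigma_y2)
        for n in config.sample_sizes:
            moments = moments_by_vs.with_theta(n)
            estimators, theory = _cell_estimators(config, params, moments, n)
            rng = np.random.default_rng(cell_seeds[(var_s, n)])
            reps = config.replications
            estimates = {tag: np.empty(reps) for tag in estimators}
            failures = {tag: 0 for tag in estimators}
            done = 0
            while done < reps:
                b = min(config.batch_size, reps - done)
                idx = np.empty((b, n), dtype=np.int64)
                for j in range(b):
                    idx[j] = rng.choice(n_pop, size=n, replace=False, shuffle=False)
                ys = y[idx]
                z = _scramble_batch(ys, config, var_s, rng)
                s2_z = np.var(z, axis=1, ddof=1)
                s2_x1 = np.var(x1[idx], axis=1, ddof=1)
                s2_x2 = np.var(x2[idx], axis=1, ddof=1)
                zbar = z.mean(axis=1)
                for tag, fn in estimators.items():
                    with np.errstate(all="ignore"):
                        vals = np.asarray(fn(s2_z, s2_x1, s2_x2, zbar), dtype=float)
                    bad = ~np.isfinite(vals)
                    if bad.any():
                        failures[tag] += int(bad.sum())
                        vals = np.where(bad, np.nan, vals)
                    estimates[tag][done:done + b] = vals
                done += b

            mse_by_tag = {}
            for tag in estimators:
                vals = estimates[tag]
                if config.truncate_negative:
                    vals = np.maximum(vals, 0.0)
                sq = (vals - sigma_y2) ** 2
                mse_by_tag[tag] = float(np.nanmean(sq))
            for tag in estimators:
                vals = estimates[tag]
                if config.truncate_negative:
                    vals = np.maximum(vals, 0.0)
                sq = (vals - sigma_y2) ** 2
                mse = mse_by_tag[tag]
                results.append(SimulationResult(
                    estimator=tag, n=n, var_s=var_s,
                    mean_estimate=float(np.nanmean(vals)),
                    empirical_mse=mse,
                    pre=pre(mse_by_tag.get(base_tag, mse), mse),
                    vartheta=unified_measure(mse, delta),
                    mc_standard_error=float(np.nanstd(sq) / np.sqrt(reps)),
                    theory_mse=theory[tag],
                    negative_count=int(np.sum(vals < 0)),
                    failure_count=failures[tag],
                ))
    return results


def pre(mse_baseline: float, mse_candidate: float) -> float:
    """Percent relative efficiency: 100 * MSE(baseline) / MSE(candidate)."""
    if mse_candidate <= 0:
        raise InvalidParameterError("candidate MSE must be positive")
    return 100.0 * (mse_baseline / mse_candidate)


def unified_measure(mse: float, delta: float, times_100: bool = False) -> float:
    """Joint efficiency-privacy score MSE / Delta (smaller is better).

    The tabulated values use the plain ratio; ``times_100=True`` applies
    the printed x100 scaling instead."""
    if delta <= 0:
        raise InvalidParameterError("privacy level must be positive")
    value = mse / delta
    return 100.0 * value if times_100 else value


def results_frame(results) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in results])


_LAYOUTS = {
    "table4": _DP_ESTIMATORS,
    "table5": _DP_ESTIMATORS,
    "table6": _NP_ESTIMATORS,
}


def build_table(results, layout: str = "table4",
                var_s_values=None, sample_sizes=None, estimators=None) -> pd.DataFrame:
    """Assemble result rows into the published table shape: grouped by
    Var(S) then n, columns Mean/MSE/PRE/vartheta rounded to 4/4/2/4
    decimals.  Raises if any requested grid cell is missing."""
    if layout not in _LAYOUTS:
        raise InvalidParameterError(f"unknown layout: {layout}")
    df = results_frame(results)
    if estimators is None:
        estimators = [t for t in _LAYOUTS[layout] if t in set(df["estimator"])] \
            or sorted(set(df["estimator"]))
    if var_s_values is None:
        var_s_values = sorted(set(df["var_s"]))
    if sample_sizes is None:
        sample_sizes = sorted(set(df["n"]))

    have = set(zip(df["var_s"], df["n"], df["estimator"]))
    missing = [(vs, n, e) for vs in var_s_values for n in sample_sizes
               for e in estimators if (vs, n, e) not in have]
    if missing:
        raise IncompleteResultsError(missing)

    rows = []
    lookup = {(r.var_s, r.n, r.estimator): r for r in results}
    for vs in var_s_values:
        for n in sample_sizes:
            for e in estimators:
                r = lookup[(vs, n, e)]
                rows.append({
                    "Var(S)": vs, "n": n, "Estimator": e,
                    "Mean": round(r.mean_estimate, 4),
                    "MSE": round(r.empirical_mse, 4),
                    "PRE": round(r.pre, 2),
                    "vartheta": round(r.vartheta, 4),
                })
    return pd.DataFrame(rows)
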