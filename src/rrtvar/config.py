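"""TOML configuration for the CLI.

A config document mirrors :class:`~rrtvar.simulation.SimulationConfig`::

    [population]
    cov = [[10.0, 3.0, 2.9], [3.0, 2.0, 1.1], [2.9, 1.1, 2.0]]
    means = [3.0, 3.0, 3.0]
    size = 100000

    [model]
    kind = "dp"          # or "np"
    var_t = 0.5          # dp multiplier variance
    # g = 0.5; a = 1.0; var_r = 0.5; mode = "consistent"   (np model)

    [simulation]
    sample_sizes = [200, 300, 500]
    var_s = [0.2, 0.5, 1.0]
    replications = 10000
    seed = 2023
"""

from __future__ import annotations

import tomllib

import numpy as np

from .errors import InvalidParameterError
from .simulation import SimulationConfig

__all__ = ["load_config", "parse_config"]


def parse_config(doc: dict) -> SimulationConfig:
    pop = doc.get("population", {})
    model = doc.get("model", {})
    sim = doc.get("simulation", {})

    kind = model.get("kind", "dp")
    if kind not in ("dp", "np"):
        raise InvalidParameterError(f"model.kind must be 'dp' or 'np', got {kind!r}")

    kwargs = dict(
        model=kind,
        var_t=float(model.get("var_t", 0.5)),
        g=float(model.get("g", 0.5)),
        a=float(model.get("a", 1.0)),
        var_r=float(model.get("var_r", 0.5)),
        np_mode=model.get("mode", "consistent"),
        sample_sizes=tuple(int(n) for n in sim.get("sample_sizes", (200, 300, 500))),
        var_s_values=tuple(float(v) for v in sim.get("var_s", (0.2, 0.5, 1.0))),
        replications=int(sim.get("replications", 10_000)),
        seed=int(sim.get("seed", 2023)),
        lambda1=float(sim.get("lambda1", 1.0)),
        lambda2=float(sim.get("lambda2", 1.0)),
        moment_reps=int(sim.get("moment_reps", 8)),
        truncate_negative=bool(sim.get("truncate_negative", False)),
    )
    if "cov" in pop:
        kwargs["cov"] = np.asarray(pop["cov"], dtype=float)
    if "means" in pop:
        kwargs["means"] = tuple(float(m) for m in pop["means"])
    if "size" in pop:
        kwargs["pop_size"] = int(pop["size"])
    if "estimators" in sim:
        kwargs["estimators"] = tuple(sim["estimators"])
    return SimulationConfig(**kwargs)


def load_config(path) -> SimulationConfig:
    with open(path, "rb") as fh:
        return parse_config(tomllib.load(fh))
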