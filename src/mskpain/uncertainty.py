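"""Deterministic and probabilistic sensitivity analysis.

One-way analysis re-evaluates the full pipeline at low/base/high values of
a single parameter, ceteris paribus. The probabilistic analysis (PSA)
jointly redraws every uncertain parameter from its assigned distribution —
beta for proportions, gamma for costs and counts, Dirichlet for severity
splits, the pooled empirical elicitation densities for transitions — and
propagates each draw through the whole model. Outcome uncertainty is
summarised by equal-tailed percentile Bayesian credibility intervals (BCI)
computed with linear interpolation between order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Mapping

import numpy as np

from .elicitation import PooledDensity, elicited_mean, sample_transition_prob

__all__ = [
    "Distribution",
    "beta_from_mean_sd",
    "gamma_from_mean_sd",
    "PSAConfig",
    "PSAResult",
    "bci",
    "run_psa",
    "one_way_sa",
]

_FAMILIES = ("beta", "gamma", "dirichlet", "empirical_pooled", "fixed")


@dataclass(frozen=True)
class Distribution:
    """A parameter's PSA sampling distribution.

    params by family: beta -> {a, b}; gamma -> {shape, scale};
    dirichlet -> {alpha: sequence}; empirical_pooled -> {density:
    PooledDensity}; fixed -> {value} (scalar or vector).
    """

    family: str
    params: Mapping[str, Any]

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected {_FAMILIES}")
        object.__setattr__(self, "params", dict(self.params))

    def mean(self):
        p = self.params
        if self.family == "beta":
            return p["a"] / (p["a"] + p["b"])
        if self.family == "gamma":
            return p["shape"] * p["scale"]
        if self.family == "dirichlet":
            alpha = np.asarray(p["alpha"], dtype=float)
            return alpha / alpha.sum()
        if self.family == "empirical_pooled":
            return elicited_mean(p["density"])
        value = p["value"]
        return np.asarray(value, dtype=float) if np.ndim(value) else float(value)

    def sample(self, rng: np.random.Generator, size: int):
        """Vector of ``size`` draws (rows, for vector-valued parameters)."""
        p = self.params
        if self.family == "beta":
            return rng.beta(p["a"], p["b"], size=size)
        if self.family == "gamma":
            if p["scale"] == 0 or p["shape"] == 0:
                return np.full(size, self.mean())
            return rng.gamma(p["shape"], p["scale"], size=size)
        if self.family == "dirichlet":
            return rng.dirichlet(np.asarray(p["alpha"], dtype=float), size=size)
        if self.family == "empirical_pooled":
            return sample_transition_prob(p["density"], rng, size=size)
        return np.broadcast_to(self.mean(), (size,) + np.shape(self.mean())).copy()


def beta_from_mean_sd(mean: float, sd: float) -> Distribution:
    """Moment-matched beta; degenerate means collapse to a fixed value.

    If the requested variance is infeasible (>= m(1-m)) it is shrunk to half
    the feasible maximum so the match stays proper.
    """
    if not 0.0 <= mean <= 1.0:
        raise ValueError("mean of a proportion must lie in [0, 1]")
    if sd <= 0 or mean in (0.0, 1.0):
        return Distribution("fixed", {"value": mean})
    var = sd * sd
    vmax = mean * (1.0 - mean)
    if var >= vmax:
        var = vmax / 2.0
    nu = vmax / var - 1.0
    return Distribution("beta", {"a": mean * nu, "b": (1.0 - mean) * nu})


def gamma_from_mean_sd(mean: float, sd: float) -> Distribution:
    if mean < 0:
        raise ValueError("gamma mean must be non-negative")
    if sd <= 0 or mean == 0:
        return Distribution("fixed", {"value": mean})
    shape = (mean / sd) ** 2
    return Distribution("gamma", {"shape": shape, "scale": sd * sd / mean})


@dataclass(frozen=True)
class PSAConfig:
    n_iterations: int = 5000
    credibility_level: float = 0.95
    seed: int = 0
    distribution_map: Mapping[str, Distribution] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not 0.0 < self.credibility_level < 1.0:
            raise ValueError("credibility_level must lie in (0, 1)")
        object.__setattr__(self, "distribution_map", dict(self.distribution_map))


@dataclass(frozen=True)
class PSAResult:
    """Monte Carlo samples of one outcome with its point estimate and BCI.

    ``point_estimate`` is the model evaluated at the parameter means;
    ``mean_of_samples`` is the Monte Carlo average — both are reported
    because published tables do not always say which one they print.
    """

    outcome_label: str
    point_estimate: float
    samples: np.ndarray
    bci_low: float
    bci_high: float
    mean_of_samples: float


def bci(samples, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed percentile credibility interval.

    Percentiles use linear interpolation between order statistics (the
    numpy default), so e.g. samples 1..100 at level 0.95 give
    (3.475, 97.525).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("bci requires at least one sample")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    tail = 100.0 * (1.0 - level) / 2.0
    low, high = np.percentile(samples, [tail, 100.0 - tail])
    return float(low), float(high)


def run_psa(
    model_fn: Callable[[Mapping[str, Any]], Mapping[str, float]],
    config: PSAConfig,
) -> dict[str, PSAResult]:
    """Monte Carlo PSA: jointly redraw all parameters, re-run the model.

    Parameters are sampled independently (no correlation structure is
    specified) in sorted-name order from one seeded generator, so a fixed
    seed reproduces the analysis exactly. The point estimate is the model
    at the parameter means.
    """
    dists = config.distribution_map
    if not dists:
        raise ValueError("distribution_map is empty; nothing to sample")
    names = sorted(dists)
    rng = np.random.default_rng(config.seed)
    draws = {name: dists[name].sample(rng, config.n_iterations) for name in names}

    point_outcomes = model_fn({name: dists[name].mean() for name in names})
    labels = list(point_outcomes)
    samples = {label: np.empty(config.n_iterations) for label in labels}
    for i in range(config.n_iterations):
        params = {name: draws[name][i] for name in names}
        outcomes = model_fn(params)
        for label in labels:
            samples[label][i] = outcomes[label]

    results: dict[str, PSAResult] = {}
    for label in labels:
        lo, hi = bci(samples[label], config.credibility_level)
        results[label] = PSAResult(
            outcome_label=label,
            point_estimate=float(point_outcomes[label]),
            samples=samples[label],
            bci_low=lo,
            bci_high=hi,
            mean_of_samples=float(samples[label].mean()),
        )
    return results


def one_way_sa(
    model_fn: Callable[[Mapping[str, Any]], Mapping[str, float]],
    base_params: Mapping[str, Any],
    parameter_id: str,
    low,
    high,
) -> dict[str, tuple[float, float, float]]:
    """One-way deterministic sensitivity: outcomes at (low, base, high).

    Only ``parameter_id`` moves; every other parameter stays at base.
    Returns outcome -> (at low, at base, at high), the rows of a tornado
    table.
    """
    if parameter_id not in base_params:
        raise KeyError(f"unknown parameter {parameter_id!r}")
    results = []
    for value in (low, base_params[parameter_id], high):
        params = dict(base_params)
        params[parameter_id] = value
        results.append(model_fn(params))
    return {
        label: (results[0][label], results[1][label], results[2][label])
        for label in results[1]
    }
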