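"""Benchmark observation datasets: standard simulations at exact parameters.

The "experimental" data for the bundled benchmarks are noise-free standard
simulations generated from the printed exact parameter sets, sampled at the
measurement time points.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .ode_models import (
    ERK_TIME_SPAN,
    G1S_TIMES,
    ODEModel,
    TimeSeries,
    ValidationError,
    erk_model,
    g1s_model,
    simulate,
)

__all__ = [
    "BenchmarkDataset",
    "BenchmarkRecipe",
    "make_standard_dataset",
    "list_benchmarks",
    "load_benchmark",
]


@dataclass
class BenchmarkDataset:
    """A generated observation set with its provenance."""

    model_name: str
    measurement_times: np.ndarray
    observations: TimeSeries
    exact_params: np.ndarray
    rtol: float
    atol: float


@dataclass(frozen=True)
class BenchmarkRecipe:
    """Recipe for regenerating a bundled benchmark dataset."""

    model_factory: Callable[[], ODEModel]
    measurement_times: tuple[float, ...]
    robustness_mu: float
    description: str


def make_standard_dataset(
    model: ODEModel,
    times: np.ndarray,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    noise_sd: float = 0.0,
    noise_seed: int | None = None,
) -> BenchmarkDataset:
    """Simulate at the model's exact parameters and sample at ``times``.

    Generation is deterministic: identical settings give bit-identical data.
    ``noise_sd`` optionally adds seeded multiplicative Gaussian measurement
    noise (off by default; the benchmarks are noise-free).
    """
    if model.exact_params is None:
        raise ValidationError(f"model {model.name!r} has no exact parameters")
    times = np.asarray(times, dtype=float)
    obs = simulate(model, model.exact_params, times, rtol=rtol, atol=atol)
    if noise_sd > 0.0:
        rng = np.random.default_rng(noise_seed)
        noisy = obs.values * (1.0 + noise_sd * rng.standard_normal(obs.values.shape))
        obs = TimeSeries(obs.times, noisy, obs.component_names)
    return BenchmarkDataset(
        model_name=model.name,
        measurement_times=times,
        observations=obs,
        exact_params=model.exact_params.copy(),
        rtol=rtol,
        atol=atol,
    )


# ERK measurement grid: the source experimental series is not reproduced
# here; 7 uniform points over the simulated window stand in for it.
_ERK_TIMES = tuple(np.linspace(ERK_TIME_SPAN[0], ERK_TIME_SPAN[1], 7))

_RECIPES: dict[str, BenchmarkRecipe] = {
    "erk": BenchmarkRecipe(
        model_factory=erk_model,
        measurement_times=_ERK_TIMES,
        robustness_mu=0.2,
        description="distributive ERK activation by MEKpp (6 species, 6 rates)",
    ),
    "g1s": BenchmarkRecipe(
        model_factory=g1s_model,
        measurement_times=G1S_TIMES,
        robustness_mu=0.2,
        description="pRB / E2F1 G1/S transition module (2 species, 10 parameters)",
    ),
}


def list_benchmarks() -> dict[str, BenchmarkRecipe]:
    """Catalogue of the bundled benchmark recipes."""
    return dict(_RECIPES)


def load_benchmark(name: str, **kwargs) -> BenchmarkDataset:
    """Generate a bundled benchmark dataset by name."""
    try:
        recipe = _RECIPES[name]
    except KeyError:
        raise ValidationError(f"unknown benchmark {name!r}; one of {sorted(_RECIPES)}") from None
    return make_standard_dataset(
        recipe.model_factory(), np.asarray(recipe.measurement_times), **kwargs
    )
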