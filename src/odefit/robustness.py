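"""Monte-Carlo robustness analysis of fitted models.

Parameters are perturbed multiplicatively with independent Gaussian noise,
``theta_i -> theta_i * (1 + mu * N(0, 1))``, the model is re-simulated, and
the relative deviation of the perturbed trajectory from the unperturbed one
is averaged over the perturbation ensemble (a uniform Monte-Carlo estimate
of the probability-weighted robustness integral).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .ode_models import ODEModel, SimulationFailure, ValidationError, simulate, try_simulate

__all__ = [
    "PerturbationConfig",
    "RobustnessReport",
    "perturb_parameters",
    "parameter_variation",
    "robustness_analysis",
    "robustness_compare",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PerturbationConfig:
    """Perturbation-ensemble settings (strength, size, seed)."""

    mu: float = 0.2
    n_perturbations: int = 5000
    seed: int | None = None
    resample_on_invalid: bool = True

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValidationError("mu must be >= 0")
        if self.n_perturbations < 1:
            raise ValidationError("n_perturbations must be >= 1")


@dataclass
class RobustnessReport:
    """Ensemble summaries of simulation deviation and parameter variation."""

    mean_sim_error: float
    std_sim_error: float
    mean_variation: float
    std_variation: float
    n_failed: int
    n_perturbations: int
    mu: float


def perturb_parameters(
    theta: np.ndarray,
    config: PerturbationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One multiplicative-Gaussian perturbation of ``theta``.

    With ``resample_on_invalid``, coordinates driven nonpositive are redrawn
    (up to 100 attempts each, then left at the final draw and logged).
    """
    theta = np.asarray(theta, dtype=float)
    perturbed = theta * (1.0 + config.mu * rng.standard_normal(theta.size))
    if config.resample_on_invalid:
        for _ in range(100):
            bad = perturbed <= 0
            if not np.any(bad):
                break
            perturbed[bad] = theta[bad] * (
                1.0 + config.mu * rng.standard_normal(int(np.sum(bad)))
            )
        else:
            logger.warning("perturbation resampling exhausted 100 attempts")
    return perturbed


def parameter_variation(perturbed: np.ndarray, theta: np.ndarray) -> float:
    """Variation of a perturbed set: mean relative parameter deviation."""
    return float(np.mean(np.abs(perturbed - theta) / theta))


def _trajectory_deviation(
    perturbed_values: np.ndarray, reference_values: np.ndarray, zero_tol: float
) -> float:
    """Mean relative deviation over components and time points."""
    mask = np.abs(reference_values) > zero_tol
    rel = np.abs(perturbed_values[mask] - reference_values[mask]) / np.abs(
        reference_values[mask]
    )
    return float(np.mean(rel))


def robustness_analysis(
    model: ODEModel,
    theta: np.ndarray,
    obs_times: np.ndarray,
    config: PerturbationConfig,
    *,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    zero_tol: float = 1e-12,
) -> RobustnessReport:
    """Perturb ``theta`` ``n_perturbations`` times, re-simulate, summarise.

    Failed (blown-up) perturbed simulations are excluded from the means and
    counted in ``n_failed``.  The unperturbed simulation must succeed.
    """
    theta = np.asarray(theta, dtype=float)
    obs_times = np.asarray(obs_times, dtype=float)
    reference = simulate(model, theta, obs_times, rtol=rtol, atol=atol)  # may raise
    rng = np.random.default_rng(config.seed)
    sim_errors: list[float] = []
    variations: list[float] = []
    n_failed = 0
    for _ in range(config.n_perturbations):
        perturbed = perturb_parameters(theta, config, rng)
        variations.append(parameter_variation(perturbed, theta))
        result = try_simulate(model, perturbed, obs_times, rtol=rtol, atol=atol)
        if isinstance(result, SimulationFailure):
            n_failed += 1
            continue
        sim_errors.append(
            _trajectory_deviation(result.values, reference.values, zero_tol)
        )
    if n_failed:
        logger.info(
            "robustness: %d/%d perturbed simulations failed and were excluded",
            n_failed,
            config.n_perturbations,
        )
    err = np.asarray(sim_errors)
    var = np.asarray(variations)
    return RobustnessReport(
        mean_sim_error=float(np.mean(err)) if err.size else float("nan"),
        std_sim_error=float(np.std(err, ddof=1)) if err.size > 1 else 0.0,
        mean_variation=float(np.mean(var)),
        std_variation=float(np.std(var, ddof=1)) if var.size > 1 else 0.0,
        n_failed=n_failed,
        n_perturbations=config.n_perturbations,
        mu=config.mu,
    )


def robustness_compare(
    reports_by_criterion: dict[str, list[RobustnessReport]],
) -> list[dict[str, float | str]]:
    """Average per-criterion reports and rank by mean simulation error.

    Each criterion contributes the reports of its top estimate sets; rows
    are returned sorted ascending by averaged mean simulation error (most
    robust first).
    """
    if not reports_by_criterion:
        raise ValidationError("no criterion reports supplied")
    rows = []
    for cid, reports in reports_by_criterion.items():
        if not reports:
            raise ValidationError(f"criterion {cid!r} contributed no reports")
        rows.append(
            {
                "criterion": cid,
                "mean_sim_error": float(np.mean([r.mean_sim_error for r in reports])),
                "std_sim_error": float(np.mean([r.std_sim_error for r in reports])),
                "mean_variation": float(np.mean([r.mean_variation for r in reports])),
                "std_variation": float(np.mean([r.std_variation for r in reports])),
                "n_failed": int(np.sum([r.n_failed for r in reports])),
            }
        )
    rows.sort(key=lambda r: r["mean_sim_error"])
    for rank, row in enumerate(rows, start=1):
        row["rank"] = rank
    return rows
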