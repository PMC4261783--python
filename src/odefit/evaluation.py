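"""Accuracy scoring of parameter estimates against the reference vector."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inference import EstimateSet
from .ode_models import ValidationError

__all__ = ["AccuracyReport", "accuracy", "select_top_k", "km_factor_errors"]


@dataclass
class AccuracyReport:
    """Mean/STD of per-set relative estimation errors and scaled means.

    The per-set error of an estimate is the mean over parameters of
    ``|theta_est - theta*| / theta*``; ``mean_error`` averages it over the
    sets, ``std_error`` is the sample STD over the per-set errors, and
    ``per_param_scaled_mean`` is the across-set average estimate of each
    parameter divided by its exact value (1 = perfect).
    """

    criterion_id: str
    mean_error: float
    std_error: float
    per_set_errors: np.ndarray
    per_param_scaled_mean: np.ndarray


def per_set_relative_error(params: np.ndarray, exact: np.ndarray) -> float:
    """Mean over parameters of the relative deviation from ``exact``."""
    return float(np.mean(np.abs(params - exact) / exact))


def accuracy(estimates: EstimateSet, exact: np.ndarray) -> AccuracyReport:
    """Score an estimate set (typically the top-10) against exact parameters."""
    exact = np.asarray(exact, dtype=float)
    if np.any(exact == 0):
        raise ValidationError("exact parameters must be nonzero for relative errors")
    if len(estimates) < 1:
        raise ValidationError("estimate set is empty")
    mat = estimates.params_matrix  # (k, m)
    errors = np.array([per_set_relative_error(row, exact) for row in mat])
    ddof = 1 if errors.size > 1 else 0
    return AccuracyReport(
        criterion_id=estimates.records[0].criterion_id,
        mean_error=float(np.mean(errors)),
        std_error=float(np.std(errors, ddof=ddof)),
        per_set_errors=errors,
        per_param_scaled_mean=np.mean(mat, axis=0) / exact,
    )


def select_top_k(estimates: EstimateSet, k: int) -> EstimateSet:
    """The ``k`` lowest-fitness records (ascending order preserved)."""
    return estimates.top(k)


def km_factor_errors(
    estimates: EstimateSet,
    exact: np.ndarray,
    factor_map: list[tuple[int, int, int]],
) -> dict[str, np.ndarray | float]:
    """Relative errors of the activation-step Michaelis factors.

    Each entry of ``factor_map`` is an index triple ``(i_on, i_off, i_cat)``
    into the parameter vector; the step factor is
    ``K_m = (theta_off + theta_cat) / theta_on``.  Returns per-set mean
    relative factor errors plus their mean/STD, mirroring :func:`accuracy`.
    """
    exact = np.asarray(exact, dtype=float)
    for triple in factor_map:
        if len(triple) != 3 or any(not 0 <= i < exact.size for i in triple):
            raise ValidationError(f"malformed factor_map triple {triple!r}")

    def factors(theta: np.ndarray) -> np.ndarray:
        return np.array(
            [(theta[i_off] + theta[i_cat]) / theta[i_on] for i_on, i_off, i_cat in factor_map]
        )

    exact_f = factors(exact)
    if np.any(exact_f == 0):
        raise ValidationError("exact factors must be nonzero")
    per_set = np.array(
        [float(np.mean(np.abs(factors(row) - exact_f) / exact_f)) for row in estimates.params_matrix]
    )
    ddof = 1 if per_set.size > 1 else 0
    return {
        "per_set_errors": per_set,
        "mean_error": float(np.mean(per_set)),
        "std_error": float(np.std(per_set, ddof=ddof)),
    }
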