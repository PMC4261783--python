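"""The 16 discrete/continuous least-squares fitness criteria.

Eight discrete criteria compare simulation and observation at the
measurement time points (values, spline slopes, spline curvatures, and a
max-curvature-mismatch term), in absolute or relative form.  Eight
continuous counterparts integrate the squared pointwise mismatch of the
spline representations over the whole observation window with composite
Simpson quadrature, the max terms using the sampled-maximum rule (maximum
over the quadrature grid).

Term numbering (used in criterion compositions):

====  ===========================================================
term  definition
====  ===========================================================
2     sum_ij (sim_ij - obs_ij)^2
3     sum_ij ((sim_ij - obs_ij) / obs_ij)^2
4,5   as 2,3 with first spline derivatives at the knots
6,7   as 2,3 with second spline derivatives at the knots
8     max_j sum_i (sim''_ij - obs''_ij)^2
9     max_j sum_i ((sim''_ij - obs''_ij) / obs''_ij)^2
10    int_a^b sum_i (S_i - O_i)^2 dt
11    int_a^b sum_i ((S_i - O_i) / O_i)^2 dt
12-15 as 10,11 with first / second derivatives
16    max_t sum_i (S''_i - O''_i)^2     (sampled maximum)
17    max_t sum_i ((S''_i - O''_i) / O''_i)^2
====  ===========================================================

Relative terms are evaluated only over entries whose denominator is bounded
away from zero; by default a zero denominator raises a division-guard
error, while the run-time evaluator masks such entries out and logs the
exclusion (benchmark observations contain structural zeros at t = 0).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .interpolation import ContinuousTrajectory, fit_spline
from .ode_models import SimulationFailure, TimeSeries, ValidationError

__all__ = [
    "ALL_CRITERIA",
    "CRITERION_COMPONENTS",
    "CriterionSpec",
    "CriterionSettings",
    "CriterionEvaluator",
    "DivisionGuardError",
    "FitnessValue",
    "FAILED_FITNESS",
    "composite_simpson",
    "continuous_error",
    "discrete_value_error",
    "discrete_derivative_error",
    "roughness_penalty",
    "evaluate_criterion",
]

logger = logging.getLogger(__name__)

#: Table of criterion compositions: criterion id -> term numbers.
CRITERION_COMPONENTS: dict[str, tuple[int, ...]] = {
    "DAE1": (2,),
    "DAE2": (2, 4),
    "DAE3": (2, 4, 6),
    "DAE4": (2, 4, 8),
    "DRE1": (3,),
    "DRE2": (3, 5),
    "DRE3": (3, 5, 7),
    "DRE4": (3, 5, 9),
    "CAE1": (10,),
    "CAE2": (10, 12),
    "CAE3": (10, 12, 14),
    "CAE4": (10, 12, 16),
    "CRE1": (11,),
    "CRE2": (11, 13),
    "CRE3": (11, 13, 15),
    "CRE4": (11, 13, 17),
}

ALL_CRITERIA = tuple(CRITERION_COMPONENTS)


class DivisionGuardError(ValueError):
    """Raised when a relative criterion meets a (near-)zero denominator."""

    def __init__(self, term: int, locations: list[tuple[int, int]]):
        self.term = term
        self.locations = locations
        super().__init__(
            f"relative term {term}: denominator ~0 at (component, point) {locations[:5]}"
            + ("..." if len(locations) > 5 else "")
        )


@dataclass(frozen=True)
class CriterionSpec:
    """One of the 16 fitness functions, decomposed into its error terms."""

    id: str
    mode: str  # "discrete" | "continuous"
    error_kind: str  # "absolute" | "relative"
    components: tuple[int, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.id not in CRITERION_COMPONENTS:
            raise ValidationError(f"unknown criterion id {self.id!r}")
        if self.components != CRITERION_COMPONENTS[self.id]:
            raise ValidationError(
                f"components {self.components} do not match the table entry "
                f"{CRITERION_COMPONENTS[self.id]} for {self.id}"
            )
        if len(self.weights) != len(self.components):
            raise ValidationError("weights length must equal components length")
        if any(w < 0 for w in self.weights):
            raise ValidationError("weights must be nonnegative")

    @classmethod
    def from_id(cls, cid: str, weights: tuple[float, ...] | None = None) -> "CriterionSpec":
        cid = cid.upper()
        if cid not in CRITERION_COMPONENTS:
            raise ValidationError(f"unknown criterion id {cid!r}; one of {ALL_CRITERIA}")
        comps = CRITERION_COMPONENTS[cid]
        if weights is None:
            weights = (1.0,) * len(comps)
        mode = "discrete" if cid.startswith("D") else "continuous"
        kind = "absolute" if cid[1] == "A" else "relative"
        return cls(cid, mode, kind, comps, tuple(float(w) for w in weights))


@dataclass
class FitnessValue:
    """Scalar fitness with its per-term decomposition."""

    total: float
    per_term: dict[int, float] = field(default_factory=dict)
    failed: bool = False


FAILED_FITNESS = FitnessValue(total=math.inf, per_term={}, failed=True)


@dataclass(frozen=True)
class CriterionSettings:
    """Numerical settings shared by criterion evaluations.

    ``n_panels`` is the (even) number of Simpson subintervals.
    ``solution_grid`` controls where the numerical solution is sampled
    before splining for the continuous criteria: ``None`` (default) uses the
    measurement knots — the same grid the observation spline is built on —
    while an integer uses that many uniform points.  A dense solution grid
    makes the criterion compare the near-exact solution against the
    knot-splined observation, whose interpolation error then dominates and
    biases the fit; matching grids keeps the comparison symmetric.
    """

    n_panels: int = 400
    zero_tol: float = 1e-12
    boundary: str = "natural"
    solution_grid: int | None = None

    def __post_init__(self) -> None:
        if self.n_panels < 2 or self.n_panels % 2 != 0:
            raise ValidationError("n_panels must be an even integer >= 2")


def composite_simpson(y: np.ndarray, h: float) -> float:
    """Composite Simpson quadrature of samples ``y`` on a uniform grid.

    ``y`` must have an odd number of samples (an even number of panels).
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[-1] - 1
    if n < 2 or n % 2 != 0:
        raise ValidationError("composite Simpson needs an even number of panels >= 2")
    w = np.ones(n + 1)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    return float(np.sum(y * w, axis=-1).sum() * h / 3.0)


def _squared_mismatch(
    sim: np.ndarray,
    obs: np.ndarray,
    kind: str,
    term: int,
    zero_tol: float,
    mask_zeros: bool,
) -> np.ndarray:
    """Pointwise squared (relative) mismatch; masked entries contribute 0."""
    diff = sim - obs
    if kind == "absolute":
        return diff * diff
    denom_ok = np.abs(obs) > zero_tol
    if not np.all(denom_ok):
        if not mask_zeros:
            locs = [tuple(int(v) for v in ij) for ij in np.argwhere(~denom_ok)]
            raise DivisionGuardError(term, locs)
        logger.debug(
            "relative term %d: excluding %d near-zero-denominator entries",
            term,
            int(np.sum(~denom_ok)),
        )
    out = np.zeros_like(diff)
    np.divide(diff, obs, out=out, where=denom_ok)
    return out * out


def discrete_value_error(
    sim: TimeSeries,
    obs: TimeSeries,
    kind: str = "absolute",
    *,
    zero_tol: float = 1e-12,
    mask_zeros: bool = False,
) -> float:
    """Terms 2 / 3: summed squared (relative) value mismatch at the knots."""
    _check_grids(sim, obs)
    term = 2 if kind == "absolute" else 3
    sq = _squared_mismatch(sim.values, obs.values, kind, term, zero_tol, mask_zeros)
    return float(np.sum(sq))


def discrete_derivative_error(
    sim: TimeSeries,
    obs: TimeSeries,
    order: int,
    kind: str = "absolute",
    *,
    boundary: str = "natural",
    zero_tol: float = 1e-12,
    mask_zeros: bool = False,
) -> float:
    """Terms 4-7: squared mismatch of spline derivatives at the knots.

    Both series are splined on the shared knot grid; derivatives of ``order``
    (1 or 2) are taken from the splines.
    """
    _check_grids(sim, obs)
    if order not in (1, 2):
        raise ValidationError("order must be 1 or 2")
    term = {(1, "absolute"): 4, (1, "relative"): 5, (2, "absolute"): 6, (2, "relative"): 7}[
        (order, kind)
    ]
    sim_d = fit_spline(sim, boundary)(sim.times, order)
    obs_d = fit_spline(obs, boundary)(obs.times, order)
    sq = _squared_mismatch(sim_d, obs_d, kind, term, zero_tol, mask_zeros)
    return float(np.sum(sq))


def roughness_penalty(
    sim: TimeSeries | ContinuousTrajectory,
    obs: TimeSeries | ContinuousTrajectory,
    kind: str = "absolute",
    mode: str = "discrete",
    *,
    n_panels: int = 400,
    boundary: str = "natural",
    zero_tol: float = 1e-12,
    mask_zeros: bool = False,
) -> float:
    """Terms 8 / 9 (discrete) and 16 / 17 (continuous): max curvature mismatch.

    The maximal value over the window is taken at the sampling points: the
    measurement knots in discrete mode, the Simpson grid in continuous mode.
    """
    if mode == "discrete":
        if not isinstance(sim, TimeSeries) or not isinstance(obs, TimeSeries):
            raise ValidationError("discrete roughness needs TimeSeries inputs")
        _check_grids(sim, obs)
        term = 8 if kind == "absolute" else 9
        sim_d2 = fit_spline(sim, boundary)(sim.times, 2)
        obs_d2 = fit_spline(obs, boundary)(obs.times, 2)
    elif mode == "continuous":
        sim_traj = sim if isinstance(sim, ContinuousTrajectory) else fit_spline(sim, boundary)
        obs_traj = obs if isinstance(obs, ContinuousTrajectory) else fit_spline(obs, boundary)
        term = 16 if kind == "absolute" else 17
        a, b = _shared_span(sim_traj, obs_traj)
        grid = np.linspace(a, b, n_panels + 1)
        sim_d2 = sim_traj(grid, 2)
        obs_d2 = obs_traj(grid, 2)
    else:
        raise ValidationError("mode must be 'discrete' or 'continuous'")
    sq = _squared_mismatch(sim_d2, obs_d2, kind, term, zero_tol, mask_zeros)
    return float(np.max(np.sum(sq, axis=0)))


def continuous_error(
    sim_traj: ContinuousTrajectory,
    obs_traj: ContinuousTrajectory,
    order: int = 0,
    kind: str = "absolute",
    n_panels: int = 400,
    *,
    zero_tol: float = 1e-12,
    mask_zeros: bool = False,
) -> float:
    """Terms 10-15: Simpson integral of the squared (relative) mismatch of
    order-th derivatives over the shared span."""
    if order not in (0, 1, 2):
        raise ValidationError("order must be 0, 1 or 2")
    term = {
        (0, "absolute"): 10,
        (0, "relative"): 11,
        (1, "absolute"): 12,
        (1, "relative"): 13,
        (2, "absolute"): 14,
        (2, "relative"): 15,
    }[(order, kind)]
    a, b = _shared_span(sim_traj, obs_traj)
    grid = np.linspace(a, b, n_panels + 1)
    sq = _squared_mismatch(
        sim_traj(grid, order), obs_traj(grid, order), kind, term, zero_tol, mask_zeros
    )
    return composite_simpson(np.sum(sq, axis=0), (b - a) / n_panels)


def _check_grids(sim: TimeSeries, obs: TimeSeries) -> None:
    if sim.component_names != obs.component_names:
        raise ValidationError("sim and obs must share the same components")
    if sim.times.shape != obs.times.shape or not np.allclose(
        sim.times, obs.times, rtol=1e-9, atol=1e-12
    ):
        raise ValidationError("sim and obs must share an identical time grid")


def _shared_span(
    sim_traj: ContinuousTrajectory, obs_traj: ContinuousTrajectory
) -> tuple[float, float]:
    a1, b1 = sim_traj.span
    a2, b2 = obs_traj.span
    if not (math.isclose(a1, a2, abs_tol=1e-9) and math.isclose(b1, b2, abs_tol=1e-9)):
        raise ValidationError(f"trajectory spans differ: [{a1}, {b1}] vs [{a2}, {b2}]")
    return a1, b1


class CriterionEvaluator:
    """Evaluates one criterion repeatedly against a fixed observation set.

    The observation spline and its derivatives are computed once; each call
    to :meth:`evaluate` only has to process the new simulation.  Relative
    terms mask out observation entries with (near-)zero denominators, which
    is logged once per evaluator.
    """

    def __init__(
        self,
        spec: CriterionSpec,
        obs: TimeSeries,
        settings: CriterionSettings | None = None,
    ):
        self.spec = spec
        self.obs = obs
        self.settings = settings or CriterionSettings()
        st = self.settings
        self.obs_traj = fit_spline(obs, st.boundary)
        self._knots = obs.times
        self._obs_knot = {
            0: obs.values,
            1: self.obs_traj(self._knots, 1),
            2: self.obs_traj(self._knots, 2),
        }
        a, b = self.obs_traj.span
        self._span = (a, b)
        if spec.mode == "continuous":
            self._grid = np.linspace(a, b, st.n_panels + 1)
            self._h = (b - a) / st.n_panels
            self._obs_grid = {k: self.obs_traj(self._grid, k) for k in (0, 1, 2)}

    def evaluate(self, sim: TimeSeries | SimulationFailure) -> FitnessValue:
        if isinstance(sim, SimulationFailure):
            return FitnessValue(total=math.inf, per_term={}, failed=True)
        st = self.settings
        per_term: dict[int, float] = {}
        if self.spec.mode == "discrete":
            sim_k = sim.restrict(self._knots)
            need_deriv = any(t in (4, 5, 6, 7, 8, 9) for t in self.spec.components)
            sim_traj = fit_spline(sim_k, st.boundary) if need_deriv else None
            for term in self.spec.components:
                if term in (2, 3):
                    sim_v, obs_v = sim_k.values, self._obs_knot[0]
                elif term in (4, 5):
                    sim_v, obs_v = sim_traj(self._knots, 1), self._obs_knot[1]
                else:  # 6..9
                    sim_v, obs_v = sim_traj(self._knots, 2), self._obs_knot[2]
                kind = "absolute" if term % 2 == 0 else "relative"
                sq = _squared_mismatch(sim_v, obs_v, kind, term, st.zero_tol, True)
                if term in (8, 9):
                    per_term[term] = float(np.max(np.sum(sq, axis=0)))
                else:
                    per_term[term] = float(np.sum(sq))
        else:
            sim_traj = fit_spline(sim, st.boundary)
            if not np.allclose(sim_traj.span, self._span, atol=1e-9):
                raise ValidationError("simulation span must cover the observation span")
            for term in self.spec.components:
                order = {10: 0, 11: 0, 12: 1, 13: 1}.get(term, 2)
                kind = "absolute" if term % 2 == 0 else "relative"
                sq = _squared_mismatch(
                    sim_traj(self._grid, order),
                    self._obs_grid[order],
                    kind,
                    term,
                    st.zero_tol,
                    True,
                )
                summed = np.sum(sq, axis=0)
                if term in (16, 17):
                    per_term[term] = float(np.max(summed))
                else:
                    per_term[term] = composite_simpson(summed, self._h)
        total = float(sum(w * per_term[t] for w, t in zip(self.spec.weights, self.spec.components)))
        return FitnessValue(total=total, per_term=per_term)


def evaluate_criterion(
    spec: CriterionSpec | str,
    sim: TimeSeries | SimulationFailure,
    obs: TimeSeries,
    settings: CriterionSettings | None = None,
) -> FitnessValue:
    """One-shot evaluation of criterion ``spec`` for ``sim`` against ``obs``."""
    if isinstance(spec, str):
        spec = CriterionSpec.from_id(spec)
    return CriterionEvaluator(spec, obs, settings).evaluate(sim)
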