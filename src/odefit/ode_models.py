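"""ODE model contracts, bundled benchmark models, and stiff simulation.

A model is a named dynamical system ``dX/dt = f(X, theta, t)`` together with
the metadata needed for inference: parameter bounds for the search, an
optional reference parameter vector, and optional conservation relations
used for consistency checks.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import odeint

__all__ = [
    "ODEModel",
    "TimeSeries",
    "SimulationError",
    "SimulationFailure",
    "simulate",
    "try_simulate",
    "erk_model",
    "g1s_model",
    "get_model",
    "register_model",
]


class ValidationError(ValueError):
    """Raised when a domain object violates its construction contract."""


class SimulationError(RuntimeError):
    """Raised when the ODE integrator fails to produce a finite trajectory."""

    def __init__(self, message: str, params: np.ndarray | None = None):
        super().__init__(message)
        self.params = None if params is None else np.asarray(params, dtype=float)


@dataclass(frozen=True)
class SimulationFailure:
    """Flagged non-fatal failure outcome: carries the offending parameters.

    Consumers (the genetic algorithm, the robustness sampler) treat this as
    worst-possible fitness instead of crashing.
    """

    params: np.ndarray
    message: str


@dataclass
class TimeSeries:
    """Discrete trajectory: strictly increasing times, one row per component."""

    times: np.ndarray
    values: np.ndarray
    component_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.component_names = tuple(self.component_names)
        if self.times.ndim != 1:
            raise ValidationError("times must be one-dimensional")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValidationError("times must be strictly increasing")
        if self.values.shape != (len(self.component_names), self.times.size):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.component_names)} components, {self.times.size} times)"
            )
        if not np.all(np.isfinite(self.times)) or not np.all(np.isfinite(self.values)):
            raise ValidationError("times and values must be finite (no missing data)")

    @property
    def n_components(self) -> int:
        return len(self.component_names)

    @property
    def n_times(self) -> int:
        return self.times.size

    def restrict(self, times: np.ndarray, rtol: float = 1e-9, atol: float = 1e-9) -> "TimeSeries":
        """Return the sub-series at the requested times (must be present)."""
        times = np.asarray(times, dtype=float)
        idx = np.searchsorted(self.times, times)
        idx = np.clip(idx, 0, self.times.size - 1)
        # searchsorted returns the left insertion point; the match may sit on
        # either side of it
        left = np.clip(idx - 1, 0, self.times.size - 1)
        use_left = np.abs(self.times[left] - times) < np.abs(self.times[idx] - times)
        idx = np.where(use_left, left, idx)
        if not np.allclose(self.times[idx], times, rtol=rtol, atol=atol):
            missing = times[~np.isclose(self.times[idx], times, rtol=rtol, atol=atol)]
            raise ValidationError(f"times not present in series: {missing}")
        return TimeSeries(self.times[idx], self.values[:, idx], self.component_names)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TimeSeries):
            return NotImplemented
        return (
            self.component_names == other.component_names
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.values, other.values)
        )


@dataclass(frozen=True)
class ODEModel:
    """A named ODE system with inference metadata.

    ``rhs(state, params, t)`` returns the derivative vector.  ``wmax`` is the
    per-parameter upper search bound (the lower bound is always 0);
    ``exact_params`` is the reference vector used to generate benchmark
    observations; ``conserved_sums`` lists index sets whose component sum is
    invariant along trajectories.
    """

    name: str
    state_names: tuple[str, ...]
    param_names: tuple[str, ...]
    rhs: Callable[[np.ndarray, np.ndarray, float], Sequence[float]]
    default_initial_state: np.ndarray
    wmax: np.ndarray
    exact_params: np.ndarray | None = None
    conserved_sums: tuple[tuple[int, ...], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "state_names", tuple(self.state_names))
        object.__setattr__(self, "param_names", tuple(self.param_names))
        init = np.asarray(self.default_initial_state, dtype=float)
        object.__setattr__(self, "default_initial_state", init)
        wmax = np.broadcast_to(
            np.asarray(self.wmax, dtype=float), (len(self.param_names),)
        ).copy()
        object.__setattr__(self, "wmax", wmax)
        if self.exact_params is not None:
            object.__setattr__(
                self, "exact_params", np.asarray(self.exact_params, dtype=float)
            )
        if len(self.state_names) != init.size:
            raise ValidationError("state_names and default_initial_state length mismatch")
        if self.exact_params is not None and self.exact_params.size != len(self.param_names):
            raise ValidationError("exact_params length does not match param_names")
        if not np.all(wmax > 0):
            raise ValidationError("all wmax entries must be positive")

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def with_initial_state(self, state: Sequence[float]) -> "ODEModel":
        return replace(self, default_initial_state=np.asarray(state, dtype=float))


def simulate(
    model: ODEModel,
    params: Sequence[float],
    times: Sequence[float],
    *,
    initial_state: Sequence[float] | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    max_steps: int = 100_000,
) -> TimeSeries:
    """Integrate ``model`` at ``params`` and sample exactly at ``times``.

    Uses LSODA (adaptive stiff/non-stiff implicit multistep) so that stiff
    parameter regions encountered during search do not stall the run.

    Raises :class:`SimulationError` when the integrator fails or produces
    non-finite states.
    """
    params = np.asarray(params, dtype=float)
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or (times.size >= 2 and not np.all(np.diff(times) > 0)):
        raise ValidationError("times must be a strictly increasing 1-D vector")
    y0 = (
        model.default_initial_state
        if initial_state is None
        else np.asarray(initial_state, dtype=float)
    )
    if times.size == 1:
        return TimeSeries(times, y0[:, None].copy(), model.state_names)

    def fun(y: np.ndarray, t: float) -> Sequence[float]:
        return model.rhs(y, params, t)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        y, info = odeint(
            fun,
            y0,
            times,
            rtol=rtol,
            atol=atol,
            mxstep=max_steps,
            full_output=True,
            printmessg=False,
        )
    if info["message"] != "Integration successful." or not np.all(np.isfinite(y)):
        raise SimulationError(
            f"integration failed for model {model.name!r}: {info['message']}",
            params=params,
        )
    return TimeSeries(times, y.T.copy(), model.state_names)


def try_simulate(
    model: ODEModel,
    params: Sequence[float],
    times: Sequence[float],
    **kwargs,
) -> TimeSeries | SimulationFailure:
    """Like :func:`simulate` but returns a flagged failure instead of raising."""
    try:
        return simulate(model, params, times, **kwargs)
    except SimulationError as err:
        return SimulationFailure(np.asarray(params, dtype=float), str(err))


# ---------------------------------------------------------------------------
# Bundled benchmark models
# ---------------------------------------------------------------------------


def _erk_rhs(y, p, t):
    # Distributive two-collision activation of ERK by MEKpp:
    #   M + E   <->[a1,d1] M.E   ->[k1] M + Ep
    #   M + Ep  <->[a2,d2] M.Ep  ->[k2] M + Epp
    m, e, c1, ep, c2, epp = y
    a1, d1, k1, a2, d2, k2 = p
    v_bind1 = a1 * m * e
    v_rel1 = d1 * c1
    v_cat1 = k1 * c1
    v_bind2 = a2 * m * ep
    v_rel2 = d2 * c2
    v_cat2 = k2 * c2
    return (
        -v_bind1 + v_rel1 + v_cat1 - v_bind2 + v_rel2 + v_cat2,  # [M]
        -v_bind1 + v_rel1,  # [E]
        v_bind1 - v_rel1 - v_cat1,  # [M.E]
        v_cat1 - v_bind2 + v_rel2,  # [Ep]
        v_bind2 - v_rel2 - v_cat2,  # [M.Ep]
        v_cat2,  # [Epp]
    )


#: Reference rate constants for the ERK activation module, ordered
#: (a1, d1, k1, a2, d2, k2).  Chosen so that the 0.165 uM kinase pool
#: converts the 5 uM substrate over a ~10 time-unit window.
ERK_EXACT_PARAMS = (30.0, 40.0, 15.0, 30.0, 40.0, 15.0)

#: Default observation window for the ERK module benchmark.
ERK_TIME_SPAN = (0.0, 9.0)


def erk_model() -> ODEModel:
    """Six-species mass-action model of distributive ERK activation by MEKpp.

    States are ordered ``[M], [E], [M.E], [Ep], [M.Ep], [Epp]`` with initial
    condition ``[0.165, 5, 0, 0, 0, 0]``.  The total-MEK and total-ERK pools
    are conserved.  All six rate constants share the search bound Wmax = 300.
    """
    return ODEModel(
        name="erk",
        state_names=("MEKpp", "ERK", "MEKpp_ERK", "ERKp", "MEKpp_ERKp", "ERKpp"),
        param_names=("a1", "d1", "k1", "a2", "d2", "k2"),
        rhs=_erk_rhs,
        default_initial_state=(0.165, 5.0, 0.0, 0.0, 0.0, 0.0),
        wmax=300.0,
        exact_params=ERK_EXACT_PARAMS,
        conserved_sums=((0, 2, 4), (1, 2, 3, 4, 5)),
    )


def _g1s_rhs(y, p, t):
    prb, e2f1 = y
    k1, kn1, j11, phi_prb, kp, k2, a, kn2, j12, phi_e2f1 = p
    d_prb = k1 * (e2f1 / (kn1 + e2f1)) * (j11 / (j11 + prb)) - phi_prb * prb
    d_e2f1 = (
        kp
        + k2 * ((a * a + e2f1 * e2f1) / (kn2 * kn2 + e2f1 * e2f1)) * (j12 / (j12 + prb))
        - phi_e2f1 * e2f1
    )
    return (d_prb, d_e2f1)


#: Reference parameters of the G1/S transition module, ordered
#: (k1, Kn1, J11, phi_pRB, kp, k2, a, Kn2, J12, phi_E2F1).
G1S_EXACT_PARAMS = (1.0, 0.5, 0.5, 0.005, 0.05, 1.6, 0.04, 4.0, 5.0, 0.1)

#: Measurement grid of the G1/S benchmark.
G1S_TIMES = (0.0, 50.0, 100.0, 150.0, 200.0, 250.0, 300.0)


def g1s_model() -> ODEModel:
    """Two-species pRB / E2F1 model of the G1/S transition.

    E2F1 activates its own transcription and that of its inhibitor pRB; pRB
    represses both productions.  Ten parameters, all with search bound
    Wmax = 5, initial state [pRB, E2F1] = [1, 5].
    """
    return ODEModel(
        name="g1s",
        state_names=("pRB", "E2F1"),
        param_names=(
            "k1",
            "Kn1",
            "J11",
            "phi_pRB",
            "kp",
            "k2",
            "a",
            "Kn2",
            "J12",
            "phi_E2F1",
        ),
        rhs=_g1s_rhs,
        default_initial_state=(1.0, 5.0),
        wmax=5.0,
        exact_params=G1S_EXACT_PARAMS,
    )


_MODEL_REGISTRY: dict[str, Callable[[], ODEModel]] = {
    "erk": erk_model,
    "g1s": g1s_model,
}


def register_model(name: str, factory: Callable[[], ODEModel]) -> None:
    """Register a plugin model factory under ``name`` for CLI lookup."""
    _MODEL_REGISTRY[name] = factory


def get_model(name: str) -> ODEModel:
    try:
        return _MODEL_REGISTRY[name]()
    except KeyError:
        raise ValidationError(
            f"unknown model {name!r}; available: {sorted(_MODEL_REGISTRY)}"
        ) from None
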