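"""Piecewise-cubic spline interpolation with selectable boundary conditions.

The spline is assembled from the second-derivative ("moment") formulation:
with knots t_1 < ... < t_m, values y_i and moments M_i = S''(t_i), each
interval carries the cubic

    s_i(t) = a_i + b_i (t - t_i) + c_i (t - t_i)^2 + d_i (t - t_i)^3

and the interior C2-continuity conditions form a tridiagonal system in the
moments.  Three boundary closures are supported:

* ``natural``      : M_1 = M_m = 0
* ``parabolic``    : M_1 = M_2 and M_{m-1} = M_m
* ``cubic_runout`` : M_1 = 2 M_2 - M_3 and M_m = 2 M_{m-1} - M_{m-2}
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PPoly
from scipy.linalg import solve_banded

from .ode_models import TimeSeries, ValidationError

__all__ = [
    "BOUNDARY_KINDS",
    "ContinuousTrajectory",
    "ExtrapolationError",
    "TooFewKnotsError",
    "fit_spline",
    "spline_moments",
    "eval_trajectory",
]

BOUNDARY_KINDS = ("natural", "parabolic", "cubic_runout")

_MIN_KNOTS = {"natural": 3, "parabolic": 3, "cubic_runout": 4}


class TooFewKnotsError(ValidationError):
    """Raised when the knot count is below the minimum for the boundary kind."""


class ExtrapolationError(ValueError):
    """Raised when a trajectory is evaluated outside its span."""


def spline_moments(times: np.ndarray, values: np.ndarray, boundary: str = "natural") -> np.ndarray:
    """Solve the tridiagonal moment system; returns M with shape of ``values``.

    ``values`` has one row per component, one column per knot.
    """
    times = np.asarray(times, dtype=float)
    values = np.atleast_2d(np.asarray(values, dtype=float))
    m = times.size
    if boundary not in _MIN_KNOTS:
        raise ValidationError(f"unknown boundary kind {boundary!r}; one of {BOUNDARY_KINDS}")
    if m < _MIN_KNOTS[boundary]:
        raise TooFewKnotsError(
            f"{boundary} spline needs at least {_MIN_KNOTS[boundary]} knots, got {m}"
        )
    if not np.all(np.diff(times) > 0):
        raise ValidationError("knot times must be strictly increasing (no duplicates)")

    h = np.diff(times)  # (m-1,)
    # banded matrix rows: ab[u + i - j, j] = A[i, j]; bandwidths (2, 2) cover
    # the three-term runout boundary rows
    ab = np.zeros((5, m))
    rhs = np.zeros((m, values.shape[0]))

    def set_entry(i: int, j: int, v: float) -> None:
        ab[2 + i - j, j] = v

    for i in range(1, m - 1):
        set_entry(i, i - 1, h[i - 1] / 6.0)
        set_entry(i, i, (h[i - 1] + h[i]) / 3.0)
        set_entry(i, i + 1, h[i] / 6.0)
    slopes = np.diff(values, axis=1) / h  # (n_comp, m-1)
    rhs[1 : m - 1, :] = (slopes[:, 1:] - slopes[:, :-1]).T

    if boundary == "natural":
        set_entry(0, 0, 1.0)
        set_entry(m - 1, m - 1, 1.0)
    elif boundary == "parabolic":
        set_entry(0, 0, 1.0)
        set_entry(0, 1, -1.0)
        set_entry(m - 1, m - 1, 1.0)
        set_entry(m - 1, m - 2, -1.0)
    else:  # cubic_runout
        set_entry(0, 0, 1.0)
        set_entry(0, 1, -2.0)
        set_entry(0, 2, 1.0)
        set_entry(m - 1, m - 1, 1.0)
        set_entry(m - 1, m - 2, -2.0)
        set_entry(m - 1, m - 3, 1.0)

    moments = solve_banded((2, 2), ab, rhs)  # (m, n_comp)
    return moments.T


@dataclass
class ContinuousTrajectory:
    """Piecewise-cubic representation evaluable for value and derivatives.

    ``coefficients`` has shape (n_components, n_intervals, 4) holding
    (a_i, b_i, c_i, d_i) per interval in the local variable t - t_i.
    """

    knots: np.ndarray
    coefficients: np.ndarray
    boundary: str
    component_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.component_names = tuple(self.component_names)
        # PPoly wants coefficients highest-order first: (4, n_int, n_comp)
        c = np.transpose(self.coefficients[:, :, ::-1], (2, 1, 0))
        self._ppoly = PPoly(c, self.knots, extrapolate=False)
        self._dppoly = self._ppoly.derivative(1)
        self._ddppoly = self._ppoly.derivative(2)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.knots[0]), float(self.knots[-1])

    def __call__(self, t, order: int = 0) -> np.ndarray:
        """Evaluate S, S' or S'' at ``t``; shape (n_components,) or (n, n_components)."""
        t = np.asarray(t, dtype=float)
        a, b = self.span
        tol = 1e-12 * max(abs(a), abs(b), 1.0)
        if np.any(t < a - tol) or np.any(t > b + tol):
            raise ExtrapolationError(
                f"evaluation time outside span [{a}, {b}] (no extrapolation)"
            )
        tc = np.clip(t, a, b)
        if order == 0:
            out = self._ppoly(tc)
        elif order == 1:
            out = self._dppoly(tc)
        elif order == 2:
            out = self._ddppoly(tc)
        else:
            raise ValidationError("order must be 0, 1 or 2")
        out = np.asarray(out)
        # scalar t -> (n_comp,); vector t -> (n_comp, n_t) matching TimeSeries
        return out if t.ndim == 0 else out.T


def fit_spline(series: TimeSeries, boundary: str = "natural") -> ContinuousTrajectory:
    """Fit a per-component cubic spline through ``series`` on its knot grid."""
    times = series.times
    values = series.values
    moments = spline_moments(times, values, boundary)  # (n_comp, m)
    h = np.diff(times)  # (m-1,)
    y = values
    a = y[:, :-1]
    c = moments[:, :-1] / 2.0
    d = np.diff(moments, axis=1) / (6.0 * h)
    b = np.diff(y, axis=1) / h - h * (2.0 * moments[:, :-1] + moments[:, 1:]) / 6.0
    coeffs = np.stack([a, b, c, d], axis=-1)  # (n_comp, m-1, 4)
    return ContinuousTrajectory(times, coeffs, boundary, series.component_names)


def eval_trajectory(traj: ContinuousTrajectory, t, order: int = 0) -> np.ndarray:
    """Functional alias for :meth:`ContinuousTrajectory.__call__`."""
    return traj(t, order)
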