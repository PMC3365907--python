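"""Adaptive Taylor-series integration with dense output and event location.

The integrator advances a polynomial vector field by recomputing, at every
step, the solution's Taylor coefficients through a fixed order (default 15)
via the series recurrences in :mod:`hrsweep._kernels`, then choosing the
step from a two-term tail estimate against an absolute tolerance (default
1e-12).  Each accepted step is kept as a :class:`TaylorSegment`, so the
returned :class:`Trajectory` is a piecewise power series: it can be
evaluated anywhere in its span (dense output) and events — voltage maxima,
plane crossings — are located as polynomial roots of the stored series
rather than by sampling.

The first variational system (tangent flow ``dM/dt = J(x(t)) M``) is a
polynomial field over the joint state+tangent variables and is integrated
by the same machinery (:func:`integrate_variational`), which is what the
Lyapunov-spectrum computation builds on.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from . import _kernels
from .model import HRParams, hr_field
from .polyfield import PolynomialField

__all__ = [
    "IntegratorOptions",
    "TaylorSegment",
    "Trajectory",
    "EventSpec",
    "DivergenceError",
    "taylor_coefficients",
    "select_step",
    "integrate",
    "integrate_endpoint",
    "dense_eval",
    "locate_events",
    "integrate_variational",
]

_EMPTY_F = np.empty(0, dtype=np.float64)
_EMPTY_I = np.empty(0, dtype=np.int64)
_EMPTY_OFF = np.zeros(1, dtype=np.int64)


class DivergenceError(RuntimeError):
    """Trajectory blew up (non-finite coefficients) before ``t_end``."""

    def __init__(self, t_reached: float):
        super().__init__(f"solution became non-finite near t = {t_reached:g}")
        self.t_reached = t_reached


@dataclasses.dataclass(frozen=True)
class IntegratorOptions:
    """Tunables of the Taylor method.

    ``order`` is the truncation order of the series, ``tol`` the absolute
    local-error tolerance used by the step-size rule, ``max_step`` a cap on
    the step, and ``safety`` the usual safety factor in (0, 1].
    """

    order: int = 15
    tol: float = 1e-12
    max_step: float = 10.0
    safety: float = 0.9

    def __post_init__(self) -> None:
        if self.order < 2:
            raise ValueError("order must be >= 2")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_step <= 0:
            raise ValueError("max_step must be positive")
        if not 0 < self.safety <= 1:
            raise ValueError("safety must lie in (0, 1]")


@dataclasses.dataclass(frozen=True)
class TaylorSegment:
    """One accepted step: ``x_v(t) = sum_j coeffs[v, j] (t - t_start)^j``."""

    t_start: float
    h: float
    coeffs: np.ndarray  # (nvars, order+1)

    def eval(self, t: float) -> np.ndarray:
        tau = t - self.t_start
        return _horner(self.coeffs, tau)


def _horner(coeffs: np.ndarray, tau: float) -> np.ndarray:
    r = coeffs[:, -1].copy()
    for j in range(coeffs.shape[1] - 2, -1, -1):
        r = r * tau + coeffs[:, j]
    return r


class Trajectory:
    """Piecewise power-series solution over ``[t0, t_end]``."""

    def __init__(self, ts: np.ndarray, hs: np.ndarray, coeffs: np.ndarray):
        if len(ts) == 0:
            raise ValueError("trajectory needs at least one segment")
        self.ts = ts
        self.hs = hs
        self.coeffs = coeffs
        self.t0 = float(ts[0])
        self.t_end = float(ts[-1] + hs[-1])
        self.nvars = coeffs.shape[1]

    def __len__(self) -> int:
        return len(self.ts)

    def segment(self, i: int) -> TaylorSegment:
        return TaylorSegment(float(self.ts[i]), float(self.hs[i]), self.coeffs[i])

    def segment_index(self, t: float) -> int:
        if not self.t0 <= t <= self.t_end * (1 + 1e-15) + 1e-300:
            raise ValueError(f"t={t} outside trajectory span [{self.t0}, {self.t_end}]")
        i = int(np.searchsorted(self.ts, t, side="right")) - 1
        return max(i, 0)

    def eval(self, t: float) -> np.ndarray:
        """Dense output: Horner evaluation of the covering segment."""
        i = self.segment_index(t)
        return _horner(self.coeffs[i], t - self.ts[i])

    __call__ = eval

    def sample(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        """States at ``n`` equispaced times spanning the trajectory."""
        t = np.linspace(self.t0, self.t_end, n)
        out = np.empty((n, self.nvars))
        for i, ti in enumerate(t):
            out[i] = self.eval(ti)
        return t, out

    def knot_states(self) -> np.ndarray:
        """States at all segment start times (series coefficient 0)."""
        return self.coeffs[:, :, 0]

    @property
    def endpoint(self) -> np.ndarray:
        return _horner(self.coeffs[-1], self.hs[-1])

    def restrict(self, t_lo: float, t_hi: float) -> "Trajectory":
        """Sub-trajectory of the segments overlapping ``[t_lo, t_hi]``."""
        i0 = self.segment_index(max(t_lo, self.t0))
        i1 = self.segment_index(min(t_hi, self.t_end)) + 1
        return Trajectory(self.ts[i0:i1], self.hs[i0:i1], self.coeffs[i0:i1])

    def integral(self, var: int, t_lo: float, t_hi: float) -> float:
        """Exact integral of one variable's piecewise series over [t_lo, t_hi]."""
        if not (self.t0 <= t_lo <= t_hi <= self.t_end + 1e-12):
            raise ValueError("integration range outside trajectory span")

        def prim(i: int, tau: float) -> float:
            c = self.coeffs[i, var]
            r = 0.0
            for j in range(len(c) - 1, -1, -1):
                r = r * tau + c[j] / (j + 1)
            return r * tau

        i0 = self.segment_index(t_lo)
        i1 = self.segment_index(min(t_hi, self.t_end))
        if i0 == i1:
            return prim(i0, t_hi - self.ts[i0]) - prim(i0, t_lo - self.ts[i0])
        total = prim(i0, self.hs[i0]) - prim(i0, t_lo - self.ts[i0])
        for i in range(i0 + 1, i1):
            total += prim(i, self.hs[i])
        total += prim(i1, t_hi - self.ts[i1])
        return total

    def to_columns(self, n: int = 1000) -> np.ndarray:
        """Columnar (t, x_1, ..., x_nv) sampling for text export."""
        t, states = self.sample(n)
        return np.column_stack([t, states])

    def write_text(self, path, n: int = 1000, names: Sequence[str] = ("x", "y", "z")) -> None:
        cols = self.to_columns(n)
        header = "t " + " ".join(names[: self.nvars])
        np.savetxt(path, cols, header=header)

    def save(self, path) -> None:
        """Persist the segment arrays (portable .npz container)."""
        np.savez_compressed(path, ts=self.ts, hs=self.hs, coeffs=self.coeffs)

    @classmethod
    def load(cls, path) -> "Trajectory":
        with np.load(path) as data:
            return cls(data["ts"].copy(), data["hs"].copy(), data["coeffs"].copy())


@dataclasses.dataclass(frozen=True)
class EventSpec:
    """An event expressible as a polynomial condition on the stored series.

    ``kind`` is "extremum" (roots of a variable's derivative series) or
    "crossing" (a variable passing a level).  ``direction`` selects maxima
    (-1) vs minima (+1) for extrema, or falling (-1) vs rising (+1)
    crossings; 0 keeps both.
    """

    kind: str = "extremum"
    var: int = 0
    level: float = 0.0
    direction: int = -1

    def __post_init__(self) -> None:
        if self.kind not in ("extremum", "crossing"):
            raise ValueError("kind must be 'extremum' or 'crossing'")

    @classmethod
    def maximum(cls, var: int = 0) -> "EventSpec":
        """Local maxima of a variable (e.g. voltage maxima for spikes)."""
        return cls(kind="extremum", var=var, direction=-1)

    @classmethod
    def minimum(cls, var: int = 0) -> "EventSpec":
        return cls(kind="extremum", var=var, direction=+1)

    @classmethod
    def crossing(cls, var: int, level: float, direction: int = 0) -> "EventSpec":
        """Crossings of the plane ``x[var] == level`` (a Poincare section)."""
        return cls(kind="crossing", var=var, level=level, direction=direction)


def _as_field(system: HRParams | PolynomialField) -> PolynomialField:
    if isinstance(system, PolynomialField):
        return system
    if isinstance(system, HRParams):
        return hr_field(system)
    raise TypeError("system must be HRParams or PolynomialField")


def taylor_coefficients(
    state: Sequence[float], system: HRParams | PolynomialField, n: int
) -> np.ndarray:
    """Normalized solution-series coefficients through ``state``, orders 0..n.

    Computed by the series recurrence (convolutions for the polynomial
    terms); row ``v`` holds the coefficients of variable ``v``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    field = _as_field(system)
    x = np.asarray(state, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("state must be finite")
    work = np.zeros((max(len(field.tcoef), 1), field.maxfac, n + 1))
    return _kernels.series_coeffs(
        x, n, field.tcoef, field.ttarget, field.fac_idx, field.fac_off, work
    )


def select_step(coeffs: np.ndarray, opts: IntegratorOptions = IntegratorOptions()) -> float:
    """Step size from the two-term tail estimate of the given series."""
    c = np.atleast_2d(np.asarray(coeffs, dtype=np.float64))
    return float(_kernels.select_step(c, opts.tol, opts.safety, opts.max_step))


def _run(field, ic, t0, t_end, opts, store, quad_terms=None):
    x = np.asarray(ic, dtype=np.float64)
    if x.shape != (field.nvars,):
        raise ValueError(f"initial state must have shape ({field.nvars},)")
    if quad_terms is None:
        qcoef, qidx, qoff = _EMPTY_F, _EMPTY_I, _EMPTY_OFF
    else:
        qcoef, qidx, qoff = quad_terms
    status, nseg, ts, hs, coeffs, state, t, qint = _kernels.integrate_kernel(
        x,
        t0,
        t_end,
        opts.order,
        opts.tol,
        opts.safety,
        opts.max_step,
        field.tcoef,
        field.ttarget,
        field.fac_idx,
        field.fac_off,
        field.maxfac,
        store,
        qcoef,
        qidx,
        qoff,
    )
    if status == _kernels.STATUS_BLOWUP:
        raise DivergenceError(t)
    if status == _kernels.STATUS_STALL:
        raise DivergenceError(t)
    return ts, hs, coeffs, state, qint


def integrate(
    ic: Sequence[float],
    system: HRParams | PolynomialField,
    t_end: float,
    opts: IntegratorOptions = IntegratorOptions(),
    t0: float = 0.0,
) -> Trajectory:
    """Integrate over ``[t0, t_end]`` keeping every segment (dense output)."""
    if t_end <= t0:
        raise ValueError("t_end must exceed t0")
    field = _as_field(system)
    ts, hs, coeffs, _state, _q = _run(field, ic, t0, t_end, opts, store=True)
    return Trajectory(ts, hs, coeffs)


def integrate_endpoint(
    ic: Sequence[float],
    system: HRParams | PolynomialField,
    t_end: float,
    opts: IntegratorOptions = IntegratorOptions(),
    t0: float = 0.0,
    quad_terms=None,
) -> tuple[np.ndarray, float]:
    """Endpoint state only (no stored segments), with optional quadrature.

    ``quad_terms`` is a flat-array encoding (coef, fac_idx, fac_off) of a
    scalar polynomial q(x); the second return value is the accumulated
    integral of q along the solution, computed segment-exactly from the
    series.  Used for the Jacobian-trace quadrature in the Lyapunov
    sum-rule diagnostic.
    """
    field = _as_field(system)
    _ts, _hs, _coeffs, state, qint = _run(
        field, ic, t0, t_end, opts, store=False, quad_terms=quad_terms
    )
    return state, qint


def dense_eval(traj: Trajectory, t: float) -> np.ndarray:
    """Evaluate the trajectory's covering segment at time ``t``."""
    return traj.eval(t)


def locate_events(traj: Trajectory, ev: EventSpec) -> tuple[np.ndarray, np.ndarray]:
    """All event roots on the trajectory, in time order.

    Roots are bracketed by sign changes of the event polynomial at
    Chebyshev-spaced samples on each segment and refined by safeguarded
    Newton iteration; extremum events are filtered by the sign of the
    second-derivative series.  Returns (times, values-of-the-variable).
    """
    mode = 0 if ev.kind == "extremum" else 1
    max_events = 4 * len(traj) + 16
    n, t, v = _kernels.locate_kernel(
        traj.ts, traj.hs, traj.coeffs, mode, ev.var, ev.level, ev.direction, max_events
    )
    return t, v


def event_states(traj: Trajectory, times: np.ndarray) -> np.ndarray:
    """Full states at the given event times (dense evaluation)."""
    out = np.empty((len(times), traj.nvars))
    for i, t in enumerate(times):
        out[i] = traj.eval(min(max(t, traj.t0), traj.t_end))
    return out


def variational_field(system: HRParams | PolynomialField) -> PolynomialField:
    """Joint state+tangent polynomial field (cached per base field)."""
    return _as_field(system).variational()


def integrate_variational(
    ic: Sequence[float],
    basis: np.ndarray,
    system: HRParams | PolynomialField,
    t_end: float,
    opts: IntegratorOptions = IntegratorOptions(),
) -> tuple[Trajectory, np.ndarray]:
    """Jointly integrate the state and the tangent matrix ``dM/dt = J M``.

    Returns the extended trajectory (state variables first, then the
    row-major tangent entries) and the evolved matrix at ``t_end``.
    At ``t_end == 0`` the basis is returned unchanged.
    """
    field = _as_field(system)
    n = field.nvars
    basis = np.asarray(basis, dtype=np.float64)
    if basis.shape != (n, n):
        raise ValueError(f"basis must be {n}x{n}")
    if abs(np.linalg.det(basis)) < 1e-300:
        raise ValueError("basis must be nonsingular")
    if t_end == 0:
        empty = np.concatenate([np.asarray(ic, float), basis.ravel()])
        seg = np.zeros((1, n + n * n, opts.order + 1))
        seg[0, :, 0] = empty
        return Trajectory(np.array([0.0]), np.array([0.0]), seg), basis.copy()
    ext = field.variational()
    ic_ext = np.concatenate([np.asarray(ic, dtype=np.float64), basis.ravel()])
    traj = integrate(ic_ext, ext, t_end, opts)
    final = traj.endpoint
    return traj, final[n:].reshape(n, n)
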