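"""Slow-fast dissection of the frozen-z fast subsystem.

With the slow gating variable ``z`` frozen as a parameter, the fast
``(x, y)`` subsystem's limiting sets organize the bursting geometry of the
full model:

- ``Meq``, the Z-shaped branch of fast equilibria (roots of the cubic
  ``a x^3 + (d - b) x^2 - (c + I - z) = 0`` with ``y = c - d x^2``), whose
  lower branch is the hyperpolarized quiescent state and whose middle
  branch is a saddle;
- the fold points (saddle-node bifurcations) where ``z(x)`` along the
  branch is stationary, at ``x = 0`` and ``x = -2(d - b)/(3a)``;
- Andronov-Hopf points on the depolarized branch where the fast Jacobian
  trace vanishes;
- ``Mlc``, the manifold of stable fast limit cycles (tonic-spiking
  manifold), sampled here by direct convergence to the cycle at each
  ``z``, with the per-cycle time average <x> that organizes where the slow
  nullcline pins a tonic-spiking orbit;
- the homoclinic edge terminating ``Mlc``, found operationally by
  bisection on ``z`` between "cycle with finite period" and "no cycle /
  period beyond a cap" (the true homoclinic period is infinite).

A hysteresis loop between the lower fold and the homoclinic edge, cut by
the slow nullcline through the saddle branch, is what makes the full model
a square-wave burster; :func:`burster_condition` checks exactly that.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .model import HRParams, fast_field, rhs, slow_nullcline_z
from .taylor import (
    DivergenceError,
    EventSpec,
    IntegratorOptions,
    integrate,
    integrate_endpoint,
    locate_events,
)

__all__ = [
    "EquilibriumPoint",
    "FoldSet",
    "HopfPoint",
    "LimitCyclePoint",
    "HomoclinicEstimate",
    "DissectionSummary",
    "fast_equilibria_at_z",
    "find_folds",
    "find_fast_hopf",
    "limit_cycle_branch",
    "estimate_homoclinic_z",
    "burster_condition",
]

STABLE = "stable"
SADDLE = "saddle"
UNSTABLE = "unstable"


@dataclasses.dataclass(frozen=True)
class EquilibriumPoint:
    """A fast-subsystem equilibrium at frozen ``z`` with its 2x2 spectrum."""

    z: float
    x: float
    y: float
    eigenvalues: tuple[complex, complex]
    stability: str  # "stable node/focus", "saddle", "unstable node/focus"


@dataclasses.dataclass(frozen=True)
class FoldSet:
    """Fold (saddle-node) points of the equilibrium branch ``Meq``."""

    points: tuple[tuple[float, float], ...]  # (z, x), sorted by z
    degenerate: bool  # d == b: the two stationary points merge

    @property
    def z_values(self) -> tuple[float, ...]:
        return tuple(z for z, _x in self.points)


@dataclasses.dataclass(frozen=True)
class HopfPoint:
    z: float
    x: float
    omega: float  # imaginary part of the eigenvalue pair at the point


@dataclasses.dataclass(frozen=True)
class LimitCyclePoint:
    """One sample of the spiking manifold ``Mlc`` at frozen ``z``."""

    z: float
    period: float
    x_min: float
    x_max: float
    x_avg: float  # time average of x over one period
    converged: bool


@dataclasses.dataclass(frozen=True)
class HomoclinicEstimate:
    z_lo: float  # cycle still exists here
    z_hi: float  # no cycle / period beyond the cap here
    z: float  # bracket midpoint

    @property
    def width(self) -> float:
        return self.z_hi - self.z_lo


@dataclasses.dataclass(frozen=True)
class DissectionSummary:
    fold_z: tuple[float, ...]
    hopf_z: tuple[float, ...]
    homoclinic: HomoclinicEstimate | None
    equilibrium: tuple[float, float, float]  # full-system equilibrium (x, y, z)
    equilibrium_branch: str
    is_burster: bool | None  # None when undetermined
    reason: str


def _fast_jacobian(x: float, p: HRParams) -> np.ndarray:
    return np.array([[-3.0 * p.a * x**2 + 2.0 * p.b * x, 1.0], [-2.0 * p.d * x, -1.0]])


def _classify(eig: np.ndarray) -> str:
    re = eig.real
    if re[0] * re[1] < 0 and abs(eig[0].imag) < 1e-12:
        return SADDLE
    if np.all(re < 0):
        return STABLE
    return UNSTABLE


def fast_equilibria_at_z(z: float, p: HRParams) -> list[EquilibriumPoint]:
    """Real fast equilibria at frozen ``z``, with eigenvalues and stability.

    Roots of ``a x^3 + (d - b) x^2 - (c + I - z) = 0``; ``y = c - d x^2``
    holds exactly on the branch.  Sorted by ``x`` ascending.
    """
    roots = np.roots([p.a, p.d - p.b, 0.0, -(p.c + p.I - z)])
    out: list[EquilibriumPoint] = []
    for r in sorted(roots, key=lambda v: v.real):
        if abs(r.imag) > 1e-9 * (1 + abs(r)):
            continue
        x = float(r.real)
        eig = np.linalg.eigvals(_fast_jacobian(x, p))
        out.append(
            EquilibriumPoint(
                z=float(z),
                x=x,
                y=float(p.c - p.d * x**2),
                eigenvalues=(complex(eig[0]), complex(eig[1])),
                stability=_classify(eig),
            )
        )
    return out


def _branch_z(x: float, p: HRParams) -> float:
    """z along the equilibrium branch as a function of x."""
    return p.c + p.I - p.a * x**3 - (p.d - p.b) * x**2


def find_folds(p: HRParams) -> FoldSet:
    """Stationary points of ``z(x)`` along ``Meq`` (saddle-node points).

    Closed form: ``x = 0`` and ``x = -2(d - b)/(3a)``; the two merge into a
    degenerate inflection when ``d == b``.
    """
    x1 = 0.0
    if p.d == p.b:
        return FoldSet(points=((_branch_z(x1, p), x1),), degenerate=True)
    x2 = -2.0 * (p.d - p.b) / (3.0 * p.a)
    pts = sorted(((float(_branch_z(x, p)), float(x)) for x in (x1, x2)))
    return FoldSet(points=tuple(pts), degenerate=False)


def find_fast_hopf(p: HRParams) -> list[HopfPoint]:
    """Zero-trace points of the fast Jacobian with positive determinant.

    Candidates solve ``-3a x^2 + 2b x - 1 = 0``; only those with complex
    (determinant > trace^2/4 = 0) eigenvalues qualify as Andronov-Hopf
    points.  Empty when ``b^2 <= 3a``.
    """
    disc = p.b**2 - 3.0 * p.a
    if disc <= 0:
        return []
    out = []
    for x in ((p.b + np.sqrt(disc)) / (3.0 * p.a), (p.b - np.sqrt(disc)) / (3.0 * p.a)):
        det = float(np.linalg.det(_fast_jacobian(x, p)))
        if det > 0:
            out.append(HopfPoint(z=float(_branch_z(x, p)), x=float(x), omega=float(np.sqrt(det))))
    return out


def _converge_cycle(
    z: float,
    p: HRParams,
    start: np.ndarray,
    opts: IntegratorOptions,
    period_cap: float,
    settle_tol: float = 1e-9,
    max_time: float | None = None,
):
    """Converge the fast subsystem to its stable limit cycle at frozen z.

    Returns (status, period, x_min, x_max, x_avg, end_state); status is
    "cycle", "equilibrium" or "no_cycle" (period beyond the cap or no
    recurrence within the time budget).
    """
    field = fast_field(p, z)
    if max_time is None:
        max_time = 6.0 * period_cap
    st = np.asarray(start, dtype=np.float64)
    t_done = 0.0
    chunk = max(period_cap / 2, 100.0)
    last_max_state = None
    converged = False
    while t_done < max_time and not converged:
        try:
            traj = integrate(st, field, chunk, opts)
        except DivergenceError:
            return "no_cycle", np.nan, np.nan, np.nan, np.nan, st
        st = traj.endpoint
        t_done += chunk
        v = field.rhs(st)
        if np.linalg.norm(v) < 1e-8:
            return "equilibrium", np.nan, np.nan, np.nan, np.nan, st
        tmax, vmax = locate_events(traj, EventSpec.maximum(0))
        if len(tmax) == 0:
            continue
        states = np.array([traj.eval(t) for t in tmax])
        for i in range(len(tmax)):
            if last_max_state is not None:
                if np.max(np.abs(states[i] - last_max_state)) < settle_tol:
                    converged = True
            last_max_state = states[i]
        if len(tmax) >= 2 and np.max(np.diff(tmax)) > period_cap:
            return "no_cycle", np.nan, np.nan, np.nan, np.nan, st
    if not converged:
        return "no_cycle", np.nan, np.nan, np.nan, np.nan, st
    # measure one period from the converged state
    traj = integrate(st, field, min(2.5 * period_cap, max_time), opts)
    tmax, _ = locate_events(traj, EventSpec.maximum(0))
    if len(tmax) < 2:
        return "no_cycle", np.nan, np.nan, np.nan, np.nan, traj.endpoint
    t1, t2 = float(tmax[0]), float(tmax[1])
    period = t2 - t1
    if period > period_cap:
        return "no_cycle", np.nan, np.nan, np.nan, np.nan, traj.endpoint
    one = traj.restrict(t1, t2)
    tmin, vmin = locate_events(one, EventSpec.minimum(0))
    knots = one.knot_states()[:, 0]
    x_lo = float(min(knots.min(), vmin.min() if len(vmin) else np.inf))
    x_hi = float(max(knots.max(), traj.eval(t1)[0]))
    x_avg = traj.integral(0, t1, t2) / period
    return "cycle", period, x_lo, x_hi, float(x_avg), traj.endpoint


def limit_cycle_branch(
    z_range: tuple[float, float],
    p: HRParams,
    n_samples: int = 20,
    opts: IntegratorOptions = IntegratorOptions(),
    period_cap: float = 1.0e3,
    ic: tuple[float, float] | None = None,
) -> list[LimitCyclePoint]:
    """Sample the spiking manifold ``Mlc`` over a ``z`` interval.

    Each sample converges the fast flow to the stable cycle (warm-started
    from the neighboring sample), then reports period, x-extrema and the
    per-period time average <x> by exact series quadrature.  Samples where
    no cycle is reached within budget are flagged ``converged=False``.
    """
    z_lo, z_hi = z_range
    zs = np.linspace(z_lo, z_hi, n_samples)
    start = np.array(ic if ic is not None else (0.0, p.c), dtype=np.float64)
    out: list[LimitCyclePoint] = []
    for z in zs:
        status, period, x_lo, x_hi, x_avg, end = _converge_cycle(
            float(z), p, start, opts, period_cap
        )
        if status == "cycle":
            out.append(LimitCyclePoint(float(z), period, x_lo, x_hi, x_avg, True))
            start = end
        else:
            out.append(
                LimitCyclePoint(float(z), np.nan, np.nan, np.nan, np.nan, False)
            )
    return out


def estimate_homoclinic_z(
    p: HRParams,
    period_cap: float = 1.0e3,
    z_range: tuple[float, float] | None = None,
    tol: float = 1e-6,
    opts: IntegratorOptions = IntegratorOptions(),
) -> HomoclinicEstimate | None:
    """Bisect on ``z`` for the edge where the fast limit cycle terminates.

    The cycle period diverges (logarithmically in parameter distance) at
    the homoclinic connection, so the edge is defined operationally by the
    period exceeding ``period_cap``.  Default search range: between the
    two folds of ``Meq``.  Returns None when no cycle/no-cycle sign change
    is found in the range.
    """
    if z_range is None:
        folds = find_folds(p)
        if folds.degenerate:
            return None
        z_range = (folds.points[0][0], folds.points[1][0])
    z_lo, z_hi = z_range

    state = {"lo": None}

    def has_cycle(z: float) -> bool:
        start = state["lo"] if state["lo"] is not None else np.array([0.0, p.c])
        status, period, *_rest, end = _converge_cycle(z, p, start, opts, period_cap)
        if status == "cycle":
            state["lo"] = end
            return True
        return False

    if not has_cycle(z_lo):
        return None
    if has_cycle(z_hi):
        return None
    while z_hi - z_lo > tol:
        mid = 0.5 * (z_lo + z_hi)
        if has_cycle(mid):
            z_lo = mid
        else:
            z_hi = mid
    return HomoclinicEstimate(z_lo=z_lo, z_hi=z_hi, z=0.5 * (z_lo + z_hi))


def full_system_equilibria(p: HRParams) -> list[tuple[float, float, float]]:
    """Equilibria of the full model: the branch cubic with z on the slow
    nullcline, ``-a x^3 + (b - d) x^2 - s x + (c + I + s x0) = 0``."""
    roots = np.roots([-p.a, p.b - p.d, -p.s, p.c + p.I + p.s * p.x0])
    out = []
    for r in roots:
        if abs(r.imag) < 1e-9 * (1 + abs(r)):
            x = float(r.real)
            out.append((x, float(p.c - p.d * x**2), float(slow_nullcline_z(x, p))))
    return out


def burster_condition(
    p: HRParams,
    period_cap: float = 1.0e3,
    opts: IntegratorOptions = IntegratorOptions(),
) -> DissectionSummary:
    """Does the slow nullcline cut ``Meq`` inside the hysteresis loop?

    The model bursts when its full-system equilibrium falls on the middle
    (saddle) branch of ``Meq`` with its ``z`` between the homoclinic edge
    and the fold bounding the depolarized branch: then neither manifold
    can hold the phase point and it cycles between them.
    """
    folds = find_folds(p)
    hopfs = find_fast_hopf(p)
    hom = estimate_homoclinic_z(p, period_cap=period_cap, opts=opts)
    eqs = full_system_equilibria(p)
    # the physiologically relevant equilibrium: the one on/nearest the branch
    eq = min(eqs, key=lambda e: e[0])
    if len(eqs) > 1:
        # pick the equilibrium whose local fast spectrum is saddle if any
        for cand in eqs:
            if _classify(np.linalg.eigvals(_fast_jacobian(cand[0], p))) == SADDLE:
                eq = cand
                break
    x_eq, _y_eq, z_eq = eq
    branch = _classify(np.linalg.eigvals(_fast_jacobian(x_eq, p)))
    if hom is None:
        return DissectionSummary(
            fold_z=folds.z_values,
            hopf_z=tuple(h.z for h in hopfs),
            homoclinic=None,
            equilibrium=eq,
            equilibrium_branch=branch,
            is_burster=None,
            reason="homoclinic edge not found in the fold interval",
        )
    z_top = max(folds.z_values)
    inside = branch == SADDLE and hom.z < z_eq < z_top
    reason = (
        f"equilibrium z={z_eq:.4f} on {branch} branch; hysteresis window "
        f"({hom.z:.4f}, {z_top:.4f})"
    )
    return DissectionSummary(
        fold_z=folds.z_values,
        hopf_z=tuple(h.z for h in hopfs),
        homoclinic=hom,
        equilibrium=eq,
        equilibrium_branch=branch,
        is_burster=bool(inside),
        reason=reason,
    )
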