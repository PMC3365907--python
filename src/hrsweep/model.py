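"""The Hindmarsh-Rose bursting-neuron model.

The model is the three-dimensional phenomenological system

    x' = y - a*x^3 + b*x^2 - z + I
    y' = c - d*x^2 - y
    z' = eps * (s*(x - x0) - z)

where ``x`` plays the role of the membrane potential, ``y`` a fast gating
variable and ``z`` a slow gating variable whose rate ``eps`` (0 < eps << 1)
makes the system slow-fast.  ``I`` is the applied current, ``b`` an
intrinsic bifurcation parameter shaping the fast subsystem, and ``x0``
shifts the slow nullcline, delaying or advancing activation of the slow
current.  All quantities are dimensionless; time is the model's intrinsic
unit.

Freezing ``z`` decouples the fast ``(x, y)`` subsystem, which is the basis
of the slow-fast dissection in :mod:`hrsweep.slowfast`.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

from .polyfield import PolynomialField

__all__ = [
    "HRParams",
    "PRESETS",
    "preset",
    "rhs",
    "jacobian",
    "fast_rhs",
    "slow_nullcline_z",
    "hr_field",
    "fast_field",
]


@dataclasses.dataclass(frozen=True)
class HRParams:
    """Parameter record for the Hindmarsh-Rose system (dimensionless)."""

    a: float = 1.0
    b: float = 2.7
    c: float = 1.0
    d: float = 5.0
    s: float = 4.0
    x0: float = -1.6
    eps: float = 0.01
    I: float = 4.0

    def __post_init__(self) -> None:
        vals = dataclasses.astuple(self)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("HRParams fields must be finite")
        if self.eps <= 0:
            raise ValueError("eps must be positive (slow-fast regime: 0 < eps << 1)")

    def replace(self, **kw) -> "HRParams":
        return dataclasses.replace(self, **kw)

    def asdict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


#: Named parameter presets.  "square_wave" and "plateau" are the two classic
#: bursting topologies of the model at I=4 (fold/homoclinic at b=2.7,
#: fold/Hopf at b=2.52).  "x0_scan" is the regime used for the slow-offset
#: screens (b=3, c=-3, I=3.5); note its c differs in sign from the classic
#: presets — both conventions appear in the literature on this model, so
#: both are expressible here.
PRESETS: dict[str, HRParams] = {
    "default": HRParams(),
    "square_wave": HRParams(b=2.7, I=4.0),
    "plateau": HRParams(b=2.52, I=4.0),
    "x0_scan": HRParams(b=3.0, c=-3.0, I=3.5),
}


def preset(name: str) -> HRParams:
    """Return a named parameter preset (see :data:`PRESETS`)."""
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None


def _check_finite(state: Sequence[float]) -> np.ndarray:
    arr = np.asarray(state, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("state must be finite")
    return arr


def rhs(state: Sequence[float], p: HRParams) -> np.ndarray:
    """Vector field ``(x', y', z')`` at ``state = (x, y, z)``."""
    x, y, z = _check_finite(state)
    return np.array(
        [
            y - p.a * x**3 + p.b * x**2 - z + p.I,
            p.c - p.d * x**2 - y,
            p.eps * (p.s * (x - p.x0) - z),
        ]
    )


def jacobian(state: Sequence[float], p: HRParams) -> np.ndarray:
    """Analytic Jacobian of :func:`rhs`; its trace is the divergence."""
    x, _y, _z = _check_finite(state)
    return np.array(
        [
            [-3.0 * p.a * x**2 + 2.0 * p.b * x, 1.0, -1.0],
            [-2.0 * p.d * x, -1.0, 0.0],
            [p.eps * p.s, 0.0, -p.eps],
        ]
    )


def fast_rhs(fs: Sequence[float], z: float, p: HRParams) -> np.ndarray:
    """Frozen-``z`` fast subsystem ``(x', y')`` at ``fs = (x, y)``."""
    x, y = _check_finite(fs)
    return np.array(
        [
            y - p.a * x**3 + p.b * x**2 - z + p.I,
            p.c - p.d * x**2 - y,
        ]
    )


def slow_nullcline_z(x: float, p: HRParams) -> float:
    """The slow nullcline ``z' = 0``, i.e. ``z = s*(x - x0)``."""
    return p.s * (x - p.x0)


def hr_field(p: HRParams) -> PolynomialField:
    """The model as a polynomial term list for the Taylor integrator."""
    return PolynomialField(
        3,
        [
            (0, 1.0, {1: 1}),
            (0, -p.a, {0: 3}),
            (0, p.b, {0: 2}),
            (0, -1.0, {2: 1}),
            (0, p.I, None),
            (1, p.c, None),
            (1, -p.d, {0: 2}),
            (1, -1.0, {1: 1}),
            (2, p.eps * p.s, {0: 1}),
            (2, -p.eps * p.s * p.x0, None),
            (2, -p.eps, {2: 1}),
        ],
    )


def fast_field(p: HRParams, z: float) -> PolynomialField:
    """The frozen-``z`` fast subsystem as a two-variable polynomial field."""
    return PolynomialField(
        2,
        [
            (0, 1.0, {1: 1}),
            (0, -p.a, {0: 3}),
            (0, p.b, {0: 2}),
            (0, p.I - z, None),
            (1, p.c, None),
            (1, -p.d, {0: 2}),
            (1, -1.0, {1: 1}),
        ],
    )
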