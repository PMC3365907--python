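"""Polynomial vector fields represented as explicit monomial term lists.

Autonomous systems dx_i/dt = f_i(x) with polynomial right-hand sides are
the natural habitat of the Taylor-series integrator: the solution's series
coefficients follow from products of the state's series, order by order,
without symbolic or numerical differentiation.  A field is stored as a flat
list of monomial terms (target variable, real coefficient, variable powers),
which the integrator kernels consume as plain integer/float arrays.

The representation also supports exact term-wise differentiation, which is
how the first variational system (tangent flow) is constructed: the tangent
matrix entries become additional polynomial variables, so the joint
state+tangent system is again a polynomial field and runs through the same
integrator.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = ["PolynomialField"]

TermSpec = tuple[int, float, Mapping[int, int] | None]


class PolynomialField:
    """A polynomial vector field ``dx/dt = f(x)`` over ``nvars`` variables.

    Parameters
    ----------
    nvars:
        Dimension of the state space.
    terms:
        Iterable of ``(target, coeff, powers)`` where ``powers`` maps
        variable index to a positive integer exponent (``None`` or ``{}``
        for a constant term).
    """

    def __init__(self, nvars: int, terms: Iterable[TermSpec]):
        self.nvars = int(nvars)
        norm: list[tuple[int, float, tuple[tuple[int, int], ...]]] = []
        for target, coeff, powers in terms:
            if not 0 <= target < self.nvars:
                raise ValueError(f"term target {target} out of range")
            pws = tuple(sorted((int(v), int(e)) for v, e in (powers or {}).items() if e))
            for v, e in pws:
                if not 0 <= v < self.nvars:
                    raise ValueError(f"term variable {v} out of range")
                if e < 0:
                    raise ValueError("negative exponents are not polynomial")
            norm.append((int(target), float(coeff), pws))
        self.terms = tuple(norm)
        self._build_arrays()

    def _build_arrays(self) -> None:
        coef, targ, fac_idx, fac_off = [], [], [], [0]
        for target, coeff, pws in self.terms:
            coef.append(coeff)
            targ.append(target)
            for v, e in pws:
                fac_idx.extend([v] * e)
            fac_off.append(len(fac_idx))
        self.tcoef = np.asarray(coef, dtype=np.float64)
        self.ttarget = np.asarray(targ, dtype=np.int64)
        self.fac_idx = np.asarray(fac_idx, dtype=np.int64)
        self.fac_off = np.asarray(fac_off, dtype=np.int64)
        self.maxfac = int(max((b - a for a, b in zip(self.fac_off, self.fac_off[1:])), default=0))
        self.maxfac = max(self.maxfac, 1)

    # -- evaluation ----------------------------------------------------

    def rhs(self, state: Sequence[float]) -> np.ndarray:
        """Evaluate ``f(state)`` directly from the term list."""
        x = np.asarray(state, dtype=np.float64)
        if x.shape != (self.nvars,):
            raise ValueError(f"state must have shape ({self.nvars},)")
        out = np.zeros(self.nvars)
        for target, coeff, pws in self.terms:
            v = coeff
            for var, e in pws:
                v *= x[var] ** e
            out[target] += v
        return out

    def jacobian(self, state: Sequence[float]) -> np.ndarray:
        """Evaluate the Jacobian matrix of ``f`` at ``state``."""
        x = np.asarray(state, dtype=np.float64)
        J = np.zeros((self.nvars, self.nvars))
        for target, coeff, pws in self.terms:
            for var, e in pws:
                v = coeff * e * x[var] ** (e - 1)
                for ovar, oe in pws:
                    if ovar != var:
                        v *= x[ovar] ** oe
                J[target, var] += v
        return J

    # -- calculus on terms ---------------------------------------------

    def jacobian_terms(self) -> dict[tuple[int, int], list[tuple[float, tuple[tuple[int, int], ...]]]]:
        """Polynomial terms of each Jacobian entry ``(i, j) -> df_i/dx_j``."""
        out: dict[tuple[int, int], list[tuple[float, tuple[tuple[int, int], ...]]]] = {}
        for target, coeff, pws in self.terms:
            for var, e in pws:
                dpws = tuple(
                    (v, ee - 1 if v == var else ee) for v, ee in pws if not (v == var and ee == 1)
                )
                dpws = tuple((v, ee) for v, ee in dpws if ee)
                out.setdefault((target, var), []).append((coeff * e, dpws))
        return out

    def trace_terms(self) -> list[tuple[float, tuple[tuple[int, int], ...]]]:
        """Polynomial terms of the divergence ``sum_i df_i/dx_i``."""
        jt = self.jacobian_terms()
        out: list[tuple[float, tuple[tuple[int, int], ...]]] = []
        for i in range(self.nvars):
            out.extend(jt.get((i, i), []))
        return out

    def variational(self) -> "PolynomialField":
        """Extend the field with the tangent flow ``dM/dt = J(x) M``.

        Variables ``0..n-1`` are the state; variable ``n + i*n + k`` is the
        tangent-matrix entry ``M[i, k]``.  The result is a polynomial field
        over ``n + n**2`` variables and integrates with the same kernels.
        """
        n = self.nvars
        terms: list[TermSpec] = [(t, c, dict(p)) for t, c, p in self.terms]
        jt = self.jacobian_terms()
        for (i, j), entry in jt.items():
            for k in range(n):
                mjk = n + j * n + k
                mik_target = n + i * n + k
                for coeff, pws in entry:
                    powers = dict(pws)
                    powers[mjk] = powers.get(mjk, 0) + 1
                    terms.append((mik_target, coeff, powers))
        return PolynomialField(n + n * n, terms)

    def __repr__(self) -> str:  # pragma: no cover
        return f"PolynomialField(nvars={self.nvars}, nterms={len(self.terms)})"
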