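"""Full Lyapunov-exponent spectra via variational equations.

The classical reorthonormalization algorithm: integrate the tangent flow
``dM/dt = J(x(t)) M`` from the identity matrix alongside the state, and at
fixed intervals apply Gram-Schmidt orthonormalization to the propagated
vectors, accumulating the logarithms of their growth factors.  The k-th
exponent is the time average of the k-th log growth; the leading vector
tracks the most expanding direction, and the nested subspaces spanned by
the first k vectors measure the growth of k-volumes.

Diagnostics: the running-average history of each exponent, and the sum
rule |sum(lambda) - <trace J>| (the tangent determinant grows exactly like
exp(integral of the divergence), so the spectrum sum must match the
time-averaged Jacobian trace; the trace integral is accumulated
segment-exactly from the Taylor series, independently of the tangent
flow).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .model import HRParams
from .polyfield import PolynomialField
from .taylor import IntegratorOptions, _as_field, integrate_endpoint

__all__ = [
    "LyapunovOptions",
    "LyapunovResult",
    "gram_schmidt",
    "lyapunov_spectrum",
]


@dataclasses.dataclass(frozen=True)
class LyapunovOptions:
    """Settings of the spectrum computation.

    ``transient`` is discarded before exponent accumulation starts;
    ``total`` is the final integration time; ``interval`` the time between
    Gram-Schmidt reorthonormalizations; ``record_every`` how many intervals
    pass between convergence-history samples.
    """

    transient: float = 1.0e3
    total: float = 1.0e5
    interval: float = 1.0
    record_every: int = 100
    integrator: IntegratorOptions = IntegratorOptions()

    def __post_init__(self) -> None:
        if not self.total > self.transient > 0:
            raise ValueError("need total > transient > 0")
        if self.interval <= 0:
            raise ValueError("renormalization interval must be positive")


@dataclasses.dataclass(frozen=True)
class LyapunovResult:
    """Ordered spectrum with convergence history and sum-rule residual."""

    exponents: np.ndarray  # sorted descending, per unit model time
    history_t: np.ndarray  # elapsed averaging time at each history sample
    history: np.ndarray  # (len(history_t), n) running-average exponents
    sum_residual: float  # |sum(lambda) - time-averaged trace J|
    trace_average: float
    total_time: float

    @property
    def lambda1(self) -> float:
        return float(self.exponents[0])


def gram_schmidt(vectors: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Classical Gram-Schmidt on the rows of ``vectors``.

    Returns the orthonormal basis (spanning the same nested subspaces) and
    the pre-normalization growth norms.  Raises on rank deficiency.
    """
    V = np.asarray(vectors, dtype=np.float64)
    n, m = V.shape
    Q = np.empty_like(V)
    norms = np.empty(n)
    for i in range(n):
        v = V[i].copy()
        for j in range(i):
            v -= (Q[j] @ V[i]) * Q[j]
        norms[i] = np.linalg.norm(v)
        if norms[i] < 1e-300 or not np.isfinite(norms[i]):
            raise np.linalg.LinAlgError(f"rank-deficient basis at vector {i}")
        Q[i] = v / norms[i]
    return Q, norms


def _trace_quad_arrays(field: PolynomialField):
    """Flat-array encoding of the divergence polynomial for quadrature."""
    terms = field.trace_terms()
    coef, fac_idx, fac_off = [], [], [0]
    for c, pws in terms:
        coef.append(c)
        for v, e in pws:
            fac_idx.extend([v] * e)
        fac_off.append(len(fac_idx))
    return (
        np.asarray(coef, dtype=np.float64),
        np.asarray(fac_idx, dtype=np.int64),
        np.asarray(fac_off, dtype=np.int64),
    )


def lyapunov_spectrum(
    system: HRParams | PolynomialField,
    ic,
    opts: LyapunovOptions = LyapunovOptions(),
) -> LyapunovResult:
    """Lyapunov spectrum along the trajectory through ``ic``.

    After discarding the transient, the joint state+tangent system is
    integrated over successive renormalization intervals starting from the
    identity basis; each interval ends with a Gram-Schmidt step whose log
    growth factors accumulate into the exponents.
    """
    field = _as_field(system)
    n = field.nvars
    ext = field.variational()
    quad = _trace_quad_arrays(field)
    # the divergence lives on the state variables, shared with the extended field
    state, _ = integrate_endpoint(
        np.asarray(ic, dtype=np.float64), field, opts.transient, opts.integrator
    )
    nsteps = max(int(round((opts.total - opts.transient) / opts.interval)), 1)
    logs = np.zeros(n)
    trace_int = 0.0
    elapsed = 0.0
    hist_t: list[float] = []
    hist: list[np.ndarray] = []
    y = np.concatenate([state, np.eye(n).ravel()])
    for k in range(nsteps):
        y, qint = integrate_endpoint(y, ext, opts.interval, opts.integrator, quad_terms=quad)
        trace_int += qint
        elapsed += opts.interval
        M = y[n:].reshape(n, n)
        Q, norms = gram_schmidt(M.T)  # columns of M are the propagated vectors
        logs += np.log(norms)
        y[n:] = Q.T.ravel()
        if (k + 1) % opts.record_every == 0 or k == nsteps - 1:
            hist_t.append(elapsed)
            hist.append(np.sort(logs / elapsed)[::-1])
    exponents = np.sort(logs / elapsed)[::-1]
    trace_avg = trace_int / elapsed
    return LyapunovResult(
        exponents=exponents,
        history_t=np.asarray(hist_t),
        history=np.asarray(hist),
        sum_residual=float(abs(logs.sum() / elapsed - trace_avg)),
        trace_average=float(trace_avg),
        total_time=elapsed,
    )
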