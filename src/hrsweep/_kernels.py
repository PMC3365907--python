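"""JIT-compiled numerical kernels for the Taylor-series integrator.

Everything here works on the flat array encoding of a polynomial vector
field produced by :class:`hrsweep.polyfield.PolynomialField`:

- ``tcoef[t]``   real coefficient of monomial term ``t``
- ``ttarget[t]`` index of the equation the term belongs to
- ``fac_idx``    flattened list of variable factors (variable index repeated
  by its exponent), ``fac_off[t]:fac_off[t+1]`` delimiting term ``t``

Solution series are built order by order: if the state series ``c[v, :]``
is known through order ``k`` then the k-th series coefficient of every
monomial follows by incremental convolution of its factor chain, giving the
k-th derivative coefficient of the field and hence ``c[v, k+1]``.  Each
partial product only ever needs its newest coefficient, so the per-step
cost is O(order^2) per factor.

Status codes returned by the integration kernels:
0 = reached t_end; 1 = non-finite state/coefficients (blow-up);
2 = step size underflow (stall).
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_BLOWUP = 1
STATUS_STALL = 2


@njit(cache=True)
def series_coeffs(state, order, tcoef, ttarget, fac_idx, fac_off, work):
    """Taylor coefficients of the solution through ``state``, orders 0..order.

    ``work`` is scratch of shape (nterms, maxfac, order+1), reused across
    calls.  Returns ``c`` with ``c[v, j]`` multiplying ``(t - t0)**j``.
    """
    nv = state.shape[0]
    nt = tcoef.shape[0]
    c = np.zeros((nv, order + 1))
    for v in range(nv):
        c[v, 0] = state[v]
    for k in range(order):
        f = np.zeros(nv)
        for t in range(nt):
            lo = fac_off[t]
            hi = fac_off[t + 1]
            nf = hi - lo
            if nf == 0:
                if k == 0:
                    f[ttarget[t]] += tcoef[t]
                continue
            work[t, 0, k] = c[fac_idx[lo], k]
            for j in range(1, nf):
                fv = fac_idx[lo + j]
                s = 0.0
                for i in range(k + 1):
                    s += work[t, j - 1, i] * c[fv, k - i]
                work[t, j, k] = s
            f[ttarget[t]] += tcoef[t] * work[t, nf - 1, k]
        kp1 = k + 1
        for v in range(nv):
            c[v, kp1] = f[v] / kp1
    return c


@njit(cache=True)
def select_step(c, tol, safety, max_step):
    """Step from the two highest-order coefficient norms (tail estimate)."""
    order = c.shape[1] - 1
    nv = c.shape[0]
    h = max_step
    for j in range(order - 1, order + 1):
        m = 0.0
        for v in range(nv):
            a = abs(c[v, j])
            if a > m:
                m = a
        if m > 0.0:
            hj = safety * (tol / m) ** (1.0 / j)
            if hj < h:
                h = hj
    return h


@njit(cache=True, inline="always")
def eval_series(c, v, tau):
    """Horner evaluation of variable ``v``'s series at local time ``tau``."""
    order = c.shape[1] - 1
    r = c[v, order]
    for j in range(order - 1, -1, -1):
        r = r * tau + c[v, j]
    return r


@njit(cache=True)
def _poly_eval(p, np_, tau):
    r = p[np_ - 1]
    for j in range(np_ - 2, -1, -1):
        r = r * tau + p[j]
    return r


@njit(cache=True)
def _quad_series(c, order, qcoef, qfac_idx, qfac_off):
    """Series of the scalar polynomial q(state) along the segment."""
    q = np.zeros(order + 1)
    prev = np.empty(order + 1)
    cur = np.empty(order + 1)
    nq = qcoef.shape[0]
    for t in range(nq):
        lo = qfac_off[t]
        hi = qfac_off[t + 1]
        nf = hi - lo
        if nf == 0:
            q[0] += qcoef[t]
            continue
        for k in range(order + 1):
            prev[k] = c[qfac_idx[lo], k]
        for j in range(1, nf):
            fv = qfac_idx[lo + j]
            for k in range(order + 1):
                s = 0.0
                for i in range(k + 1):
                    s += prev[i] * c[fv, k - i]
                cur[k] = s
            for k in range(order + 1):
                prev[k] = cur[k]
        for k in range(order + 1):
            q[k] += qcoef[t] * prev[k]
    return q


@njit(cache=True)
def integrate_kernel(
    state0,
    t0,
    t_end,
    order,
    tol,
    safety,
    max_step,
    tcoef,
    ttarget,
    fac_idx,
    fac_off,
    maxfac,
    store,
    qcoef,
    qfac_idx,
    qfac_off,
):
    """Advance from ``(t0, state0)`` to ``t_end``.

    Returns (status, nseg, ts, hs, coeffs, final_state, t_reached, qint)
    where ``qint`` accumulates the time integral of the optional scalar
    polynomial ``q(state)`` (empty ``qcoef`` disables it).  With
    ``store=False`` the segment arrays stay empty.
    """
    nv = state0.shape[0]
    nt = tcoef.shape[0]
    work = np.zeros((nt, maxfac, order + 1))
    cap = 4096 if store else 1
    ts = np.empty(cap)
    hs = np.empty(cap)
    coeffs = np.empty((cap, nv, order + 1))
    nseg = 0
    state = state0.copy()
    t = t0
    qint = 0.0
    status = STATUS_OK
    nq = qcoef.shape[0]
    while t < t_end:
        c = series_coeffs(state, order, tcoef, ttarget, fac_idx, fac_off, work)
        finite = True
        for v in range(nv):
            for j in range(order + 1):
                if not np.isfinite(c[v, j]):
                    finite = False
        if not finite:
            status = STATUS_BLOWUP
            break
        h = select_step(c, tol, safety, max_step)
        if t + h > t_end:
            h = t_end - t
        if t + h <= t:
            status = STATUS_STALL
            break
        if store:
            if nseg >= cap:
                new_cap = cap * 2
                ts2 = np.empty(new_cap)
                hs2 = np.empty(new_cap)
                coeffs2 = np.empty((new_cap, nv, order + 1))
                ts2[:cap] = ts
                hs2[:cap] = hs
                coeffs2[:cap] = coeffs
                ts = ts2
                hs = hs2
                coeffs = coeffs2
                cap = new_cap
            ts[nseg] = t
            hs[nseg] = h
            coeffs[nseg] = c
            nseg += 1
        if nq > 0:
            q = _quad_series(c, order, qcoef, qfac_idx, qfac_off)
            hp = h
            for j in range(order + 1):
                qint += q[j] * hp / (j + 1)
                hp *= h
        for v in range(nv):
            state[v] = eval_series(c, v, h)
        t = t + h
    return status, nseg, ts[:nseg], hs[:nseg], coeffs[:nseg], state, t, qint


@njit(cache=True)
def _refine_root(p, np_, a, b, fa, fb):
    """Safeguarded Newton/bisection root of polynomial ``p`` on [a, b]."""
    x = 0.5 * (a + b)
    for _ in range(80):
        f = _poly_eval(p, np_, x)
        if f == 0.0:
            return x
        # derivative
        fp = 0.0
        for j in range(np_ - 1, 0, -1):
            fp = fp * x + j * p[j]
        took_newton = False
        if fp != 0.0:
            xn = x - f / fp
            if a < xn < b:
                took_newton = True
        if (fa < 0.0) == (f < 0.0):
            a = x
            fa = f
        else:
            b = x
            fb = f
        if took_newton:
            x = xn
        else:
            x = 0.5 * (a + b)
        if b - a < 1e-14 * (abs(a) + abs(b) + 1e-3):
            break
    return 0.5 * (a + b)


@njit(cache=True)
def locate_kernel(ts, hs, coeffs, mode, var, level, direction, max_events):
    """Locate event roots on every segment of a stored trajectory.

    mode 0: extrema of variable ``var`` (roots of its derivative series);
            direction -1 keeps maxima (2nd derivative < 0), +1 minima,
            0 any extremum.
    mode 1: crossings of ``x[var] == level``; direction +1 rising,
            -1 falling, 0 any.

    Returns (n, times, values) with ``values`` the variable's value at the
    event.
    """
    nseg = ts.shape[0]
    order = coeffs.shape[2] - 1
    out_t = np.empty(max_events)
    out_v = np.empty(max_events)
    n = 0
    npts = order + 2
    p = np.empty(order + 1)
    for si in range(nseg):
        h = hs[si]
        c = coeffs[si]
        if mode == 0:
            np_ = order
            for j in range(order):
                p[j] = (j + 1) * c[var, j + 1]
        else:
            np_ = order + 1
            for j in range(order + 1):
                p[j] = c[var, j]
            p[0] -= level
        # Chebyshev-extrema sampling nodes on [0, h], endpoints included
        prev_tau = 0.0
        prev_f = _poly_eval(p, np_, 0.0)
        for i in range(1, npts):
            tau = h * 0.5 * (1.0 - np.cos(np.pi * i / (npts - 1)))
            f = _poly_eval(p, np_, tau)
            root = np.nan
            if prev_f == 0.0 and si == 0 and i == 1:
                root = prev_tau
            elif (prev_f < 0.0) != (f < 0.0) and prev_f != 0.0:
                if f == 0.0:
                    root = tau
                else:
                    root = _refine_root(p, np_, prev_tau, tau, prev_f, f)
            if root == root:  # not NaN
                keep = True
                if mode == 0:
                    # second-derivative series at the root
                    d2 = 0.0
                    for j in range(np_ - 1, 0, -1):
                        d2 = d2 * root + j * p[j]
                    if direction < 0 and not (d2 < 0.0):
                        keep = False
                    elif direction > 0 and not (d2 > 0.0):
                        keep = False
                else:
                    d1 = 0.0
                    for j in range(np_ - 1, 0, -1):
                        d1 = d1 * root + j * p[j]
                    if direction > 0 and not (d1 > 0.0):
                        keep = False
                    elif direction < 0 and not (d1 < 0.0):
                        keep = False
                if keep and n < max_events:
                    tev = ts[si] + root
                    # drop duplicate from adjoining segment knot
                    if n > 0 and tev - out_t[n - 1] < 1e-9 * (1.0 + abs(tev)):
                        pass
                    else:
                        out_t[n] = tev
                        out_v[n] = eval_series(c, var, root)
                        n += 1
            prev_tau = tau
            prev_f = f
    return n, out_t[:n], out_v[:n]
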