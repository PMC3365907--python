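"""Shared fixtures: cached simulations and synthetic trajectory builders."""

from __future__ import annotations

import numpy as np
import pytest

from hrsweep.model import HRParams, preset
from hrsweep.taylor import IntegratorOptions, Trajectory, integrate, integrate_endpoint


def make_trajectory_from_function(f, t0: float, t1: float, nseg: int = 400, order: int = 9) -> Trajectory:
    """Synthetic single-variable trajectory fitted to an analytic signal.

    Builds piecewise power-series segments by least-squares polynomial fit
    of ``f`` on each segment — a stand-in for an integrated trajectory, so
    the event/metric machinery can be exercised on constructed waveforms
    with known spikes and gaps.
    """
    ts = np.linspace(t0, t1, nseg + 1)
    hs = np.diff(ts)
    coeffs = np.zeros((nseg, 1, order + 1))
    for i in range(nseg):
        tau = np.linspace(0.0, hs[i], 3 * (order + 1))
        vals = f(ts[i] + tau)
        # power-basis fit on the local segment coordinate
        V = np.vander(tau, order + 1, increasing=True)
        c, *_ = np.linalg.lstsq(V, vals, rcond=None)
        coeffs[i, 0] = c
    return Trajectory(ts[:-1], hs, coeffs)


def gaussian_bumps(centers, amplitudes, width: float = 0.15, baseline: float = -1.5):
    centers = np.asarray(centers, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)

    def f(t):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.full(t.shape, baseline)
        for c, a in zip(centers, amplitudes):
            out = out + a * np.exp(-((t - c) ** 2) / (2 * width**2))
        return out

    return f


@pytest.fixture(scope="session")
def square_wave_traj():
    """Post-transient square-wave bursting trajectory (b=2.7, I=4)."""
    p = preset("square_wave")
    st, _ = integrate_endpoint(np.zeros(3), p, 1000.0)
    return integrate(st, p, 4000.0, t0=1000.0), p, (1000.0, 4000.0)


@pytest.fixture(scope="session")
def plateau_traj():
    """Post-transient plateau-like bursting trajectory (b=2.52, I=4)."""
    p = preset("plateau")
    st, _ = integrate_endpoint(np.zeros(3), p, 1000.0)
    return integrate(st, p, 4000.0, t0=1000.0), p, (1000.0, 4000.0)


@pytest.fixture(scope="session")
def default_opts():
    return IntegratorOptions()
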