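# hrsweep

A parameter-sweeping toolkit for slow–fast bursting neuron models, built
around the Hindmarsh–Rose system

```
x' = y − a·x³ + b·x² − z + I
y' = c − d·x² − y
z' = ε·(s·(x − x0) − z),        0 < ε ≪ 1
```

where `x` is the membrane potential, `y` a fast gating variable, `z` a slow
gating variable, `I` the applied current, `b` an intrinsic parameter shaping
the fast subsystem, and `x0` the offset that positions the slow nullcline
`z = s(x − x0)`.

The package is aimed at computational neuroscientists and dynamicists who
want to screen a neuron model's activity regimes — quiescence, tonic
spiking, regular and chaotic bursting — over one or two parameters, using
both *neuroscience-native* temporal metrics read off the voltage trace and
*calculus-based* Lyapunov spectra, and to explain what they find with a
slow–fast dissection of the fast subsystem.

## What's inside

- **`hrsweep.taylor`** — adaptive Taylor-series integrator (default order
  15, tolerance 1e−12) for polynomial vector fields. Every accepted step is
  kept as a power-series segment, so the solution has exact dense output
  and events (voltage maxima, plane crossings) are located as polynomial
  roots rather than by sampling. The variational equations
  `dM/dt = J(x(t))·M` integrate through the same machinery.
- **`hrsweep.metrics`** — spike detection, burst partitioning, spike counts
  per burst (SN), duty cycle (DC = mean burst duration / mean burst
  period), interspike-interval (ISI) statistics, activity classification,
  and the square-wave (fold/homoclinic) vs plateau-like (fold/Hopf) burst
  topology classifier.
- **`hrsweep.lyapunov`** — full Lyapunov spectra by tangent-flow
  integration with periodic Gram–Schmidt reorthonormalization, with a
  running-average convergence history and an independent sum-rule check
  (Σλ vs the time-averaged Jacobian trace).
- **`hrsweep.sweep`** — 1D/2D parameter sweeps with warm-started
  ("inherit") or fixed initial conditions, spike-adding boundary detection,
  multistability scans over deterministic initial-condition lattices, and
  text/JSON grid persistence.
- **`hrsweep.slowfast`** — the frozen-`z` fast subsystem: the Z-shaped
  equilibrium branch `Meq` with stability, closed-form fold points, fast
  Andronov–Hopf points, the spiking manifold `Mlc` sampled with per-cycle
  `⟨x⟩` averages, the homoclinic edge by bisection, and the geometric
  burster condition (slow nullcline cutting the saddle branch inside the
  hysteresis loop).

## Worked example

```python
import numpy as np
from hrsweep import preset, integrate, integrate_endpoint, analyze_trajectory
from hrsweep.lyapunov import lyapunov_spectrum, LyapunovOptions
from hrsweep.slowfast import burster_condition

p = preset("square_wave")            # b=2.7, I=4: classic square-wave burster
st, _ = integrate_endpoint(np.zeros(3), p, 1000.0)          # settle transient
traj = integrate(st, p, 5000.0, t0=1000.0)                  # dense trajectory
rec = analyze_trajectory(traj, (1000.0, 5000.0))
print(rec.activity.primary, rec.activity.topology)
print("spikes per burst:", int(rec.metrics.sn[0]), " duty cycle:", round(rec.metrics.dc, 3))

lam = lyapunov_spectrum(p, np.zeros(3), LyapunovOptions(total=2.1e4))
print("lyapunov spectrum:", np.round(lam.exponents, 5))

print("burster?", burster_condition(p).is_burster)
```

prints

```
bursting_regular square_wave
spikes per burst: 11  duty cycle: 0.754
lyapunov spectrum: [-8.00000e-05 -5.63000e-03 -8.16687e+00]
burster? True
```

The orbit bursts with 11 spikes per burst and is active ~75% of each burst
period; its leading Lyapunov exponent is zero to within the averaging error
(the signature of a stable periodic orbit) with λ₂ < 0; and the slow–fast
dissection confirms the geometry: the slow nullcline cuts the saddle branch
of `Meq` between the homoclinic edge (z ≈ 4.099) and the upper fold (z = 5),
so the model is a burster.

The same pipeline drives the command line:

```
hrsweep classify --preset square_wave
hrsweep lyapunov --preset plateau --total 20000
hrsweep sweep2d --preset x0_scan --axis I:3.2:3.8:40 --axis x0:-1.2:-0.5:40 --out grid.csv
hrsweep dissect --preset square_wave
```

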