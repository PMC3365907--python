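# Methods

## Model and conventions

The Hindmarsh–Rose system is integrated as written, in dimensionless
variables with time in the model's intrinsic unit. The default parameter
set is a=1, c=1, d=5, s=4, x0=−1.6, ε=0.01, I=4, with `b` the principal
fast-subsystem parameter. Three named presets cover the regimes the
package is exercised on: `square_wave` (b=2.7, I=4), `plateau` (b=2.52,
I=4), and `x0_scan` (b=3, c=−3, I=3.5), the regime used for slow-offset
screens. The sign of `c` differs between the first two presets and the
third; both conventions circulate for this model, and the parameter record
accepts either. ε must be positive: the slow–fast structure is the point
of the model, and a frozen slow variable is expressed by the dissection
tools rather than by ε=0.

## Taylor-series integration

The integrator handles any polynomial vector field given as a monomial
term list. At each step the solution's Taylor coefficients through order
n (default 15) are generated by the series recurrence: once the state
series is known through order k, the k-th series coefficient of each
monomial follows by incremental convolution of its factor chain, and
coefficient k+1 of each variable is the corresponding field coefficient
divided by k+1. No symbolic differentiation or finite differencing is
involved; cost per step is O(n² · total factor count).

The step size is `h = safety · min_{j∈{n−1,n}} (tol/‖c_j‖∞)^{1/j}` with
safety 0.9 and absolute tolerance 1e−12 by default, capped by a maximum
step (default 10). Taking the minimum over the last *two* orders is the
standard tail estimate; it is robust to an accidentally small top
coefficient (odd/even effects). Steps are never rejected: the tail
estimate is conservative enough that local error stays within an order of
magnitude of the tolerance, which the test suite verifies against refined
re-integration.

Each accepted step is stored as a power-series segment, so the trajectory
is a piecewise polynomial: dense evaluation is Horner's rule, integrals of
a variable over any sub-interval are exact term-wise primitives, and
events are roots of segment polynomials. Event location samples the event
polynomial (a variable's derivative series for extrema, the shifted series
for level crossings) at Chebyshev-spaced nodes per segment, brackets sign
changes, and polishes each root with safeguarded Newton iteration;
extremum events are filtered by the sign of the second-derivative series.
Double roots are deliberately not chased — a grazing contact with zero
prominence is not a spike.

The variational (tangent-flow) system is built symbolically at the
term-list level: tangent-matrix entries become additional polynomial
variables, so the joint system integrates through the same kernels at
order-15/1e−12 accuracy. The kernels are JIT-compiled with numba; that is
what makes thousand-cell sweeps with per-cell spectra a desk-scale
computation.

## Spike and burst metrics

All thresholds are relative to the voltage range measured on the analysis
window, so the pipeline adapts to orbit amplitude:

- spike threshold θ at 30% of range above the minimum (configurable);
- quiescence level θ_q at 10% of range; a dwell below θ_q longer than 5
  time units separates bursts (interburst gaps in the regimes studied are
  ≳35 time units, intra-burst dips never reach θ_q, so the rule has a wide
  safety margin);
- extrema must rise above the interpolated minima floor by 1e−4 of the
  range (prominence filter against numerical ripple);
- a window whose voltage range is below 0.05 counts as settled to
  equilibrium.

Bursts run from the upward θ_q crossing preceding their first spike to the
downward crossing after the last; periods are measured onset-to-onset, and
bursts not bracketed by two qualifying dwells (window edges) are excluded
from the statistics. DC = mean burst duration / mean burst period. The
"distinct ISI" count merges interspike intervals within a relative
tolerance of 1e−3 of their class representative, over the whole window.

Classification order: quiescence (no spikes), chaos (more than 25 distinct
ISIs in the window, or spike-count deviation persisting in both halves of
the burst sequence), tonic spiking (one spike per train — the "round"
orbit of this model dips below θ_q every period, so single-spike trains,
not absence of dwells, is the operative signature), else regular bursting.
Chaos is tested before tonicity so that irregular single-spike trains are
not mislabeled.

Burst topology: square-wave (fold/homoclinic) bursts end with their
largest ISI — the orbit slows logarithmically near the fast-subsystem
saddle — with spike amplitudes inside a 20%-of-range band around the burst
median; plateau-like (fold/Hopf) bursts end in a ring-down, maxima
decaying out of the amplitude band while the minima floor rises toward the
depolarized equilibrium. Votes are taken per burst and the majority wins.

### The short-spike convention

Near a spike-deletion the disappearing spike lingers as a shrinking
sub-threshold oscillation after the saddle passage. Whether it counts
toward SN is a threshold choice: with the default 30% threshold the SC
boundary trails the dynamical transition (where λ₂ peaks and the terminal
ISI is maximal) by Δb ≈ 0.01 on the I=2.4 cut; counting only large spikes
(fraction 0.5) puts the SC step within one grid cell of the λ₂ peak. The
spike-adding analyses therefore use the large-spike threshold, and the
threshold is exposed everywhere.

## Lyapunov spectra

Classical tangent-space reorthonormalization: integrate state + tangent
basis from the identity, apply Gram–Schmidt every 1.0 time units (the
spike period is O(10), so growth factors stay far from overflow; halving
the interval moves the exponents by ~1e−8 in practice), accumulate log
growth factors, and divide by elapsed time. Defaults: transient 1e3
discarded, total time 1e5; sweeps use a fast mode (1e4, recorded in the
per-cell metadata) whose λ₂ resolution is sufficient for boundary
annotation. The sum rule |Σλ − ⟨trace J⟩| is reported on every run, with
the trace average accumulated by exact series quadrature along the
trajectory — an independent path from the tangent flow, typically agreeing
to 1e−7.

## Sweeps and multistability

Sweeps traverse the lattice in axis order (2D: row-major, second axis
fastest). The inherit policy warm-starts each cell from the previous
cell's final state and resets at each row start, making the traversal part
of the reproducibility contract; in monostable regions it is
indistinguishable from fixed initial conditions (tested), while in
bistable regions it deliberately tracks one attractor branch —
multistability is probed separately by `scan_attractors` over a
deterministic initial-condition lattice placed on the fast nullcline
`y = c − d·x²` around the full-system equilibrium's z. Attractor
signatures are (period to 1e−3 relative tolerance via return times over
voltage maxima, spikes per period, maxima per period); non-convergent
starts are flagged and excluded. Failed cells (divergence) stay in the
grid, flagged, so record count always equals the lattice size.

Default per-cell budgets are transient 1e3 and window 1e4; the band-
structure scans use transient 500 and window 1500 (several burst periods
at those parameters), which resolves SN per cell at a fraction of the
cost. Axis ranges for the published-regime scans (b ∈ [2.5, 3.1] at I=2.4;
x0 ∈ [−1.2, −0.5] × I ∈ [3.2, 3.8]) are this package's documented choices
around the cited points, not claimed reproductions of any figure's exact
frame.

## Slow–fast dissection

Fast equilibria are roots of `a·x³ + (d−b)·x² − (c+I−z) = 0` with
`y = c − d·x²`; folds are the closed-form stationary points of z(x) at
x = 0 and x = −2(d−b)/(3a) (degenerate when d = b); fast Hopf candidates
zero the 2×2 trace and are kept where the determinant is positive. The
spiking manifold `Mlc` is sampled by brute-force convergence to the stable
cycle at each frozen z (return-map settling at 1e−9, warm-started from the
neighboring sample), with `⟨x⟩` computed by exact series quadrature over
one period. The homoclinic edge is defined operationally by bisection
between "cycle converged with period < 1e3" and "no cycle", to a bracket
of 1e−6 in z. The cycle period grows only logarithmically toward the
connection (≈11 at 1e−4 from the edge, vs ≈7 mid-branch at the square-wave
preset), so the edge manifests as a sharp disappearance rather than a
numerically visible period blow-up; the period cap is a formal guard.

The burster condition follows the geometry: the model bursts when its
full-system equilibrium (the branch cubic intersected with the slow
nullcline) sits on the saddle branch of `Meq` with z between the
homoclinic edge and the upper fold — then neither manifold retains the
phase point and it cycles between them. The verdict is cross-checked
against simulated activity classes in the tests.

## What the tests do and do not show

All inputs are generated by the simulator itself or by closed-form fields
(exponential, harmonic, diagonal-linear), so the suite validates the
numerics and the metric definitions on clean, noise-free model output.
The classifiers carry no noise handling and assume the windowed extrema
are resolved by the integrator's tolerance; applying them to experimental
voltage traces would at minimum require revisiting the prominence filter
and the range-relative thresholds. Desk-scale problem sizes (windows of a
few thousand time units, Lyapunov horizons of 1e4–2e4, grids up to 60×60)
are the package's defaults for its own verification; all are plain options
and scale up linearly.

## Known limitations

- Unstable limit-cycle branches and two-parameter continuation of the
  fold/Hopf/homoclinic loci are out of scope; the dissection covers the
  stable structures a brute-force sweep can reach.
- The chaos rule is windowed and threshold-based; near regime boundaries
  (spike-adding, boundary crises) finite windows can blur the label, and
  λ₁ is the sharper instrument there.
- The tangency mechanism converting square-wave into plateau-like bursting
  is detected only through its observable consequence (the topology
  classifier), not as a geometric tangency of `Mlc` to the saddle branch.
- Event location guards against double roots by bracketing, but a
  perfectly grazing extremum (zero prominence) is by design not an event.
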