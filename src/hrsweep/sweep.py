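"""1D/2D parameter sweeps of activity metrics, and attractor scans.

A sweep evaluates, on a lattice over one or two model parameters, the
spike-count (SN), duty-cycle (DC), ISI and classification metrics — and
optionally the Lyapunov spectrum — of the orbit at each cell.  Cells are
visited in axis order (2D: row-major, second axis fastest) and, with the
"inherit" initial-condition policy, each cell starts from the previous
cell's final state, which keeps the orbit on the attractor across small
parameter increments; inheritance resets at the start of every row so the
traversal is reproducible.  Failed cells (divergence) are flagged and the
grid stays complete.

Spike-adding boundaries are read off the SN field as unit steps between
axis neighbors, annotated with the second Lyapunov exponent when it was
recorded (the exponent's local rise to zero accompanies each spike-adding
transition).  :func:`scan_attractors` probes multistability by converging
a deterministic set of initial conditions and merging the resulting
periodic-orbit signatures (period + spikes per period).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .lyapunov import LyapunovOptions, lyapunov_spectrum
from .metrics import (
    DEFAULT_CRITERIA,
    QUIESCENCE,
    UNDETERMINED,
    ClassificationCriteria,
    analyze_trajectory,
)
from .model import HRParams
from .taylor import (
    DivergenceError,
    EventSpec,
    IntegratorOptions,
    event_states,
    integrate,
    integrate_endpoint,
    locate_events,
)

__all__ = [
    "Axis",
    "SweepSpec",
    "CellRecord",
    "SweepGrid",
    "sweep_1d",
    "sweep_2d",
    "detect_spike_adding_boundaries",
    "scan_attractors",
    "ic_lattice",
    "AttractorSignature",
    "AttractorScan",
    "write_grid",
    "read_grid",
]

_PARAM_NAMES = ("a", "b", "c", "d", "s", "x0", "eps", "I")


@dataclasses.dataclass(frozen=True)
class Axis:
    """One sweep axis over a named model parameter."""

    name: str
    lo: float
    hi: float
    count: int
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.name not in _PARAM_NAMES:
            raise ValueError(f"unknown parameter {self.name!r}")
        if self.count < 2:
            raise ValueError("axis count must be >= 2")
        if not self.lo < self.hi:
            raise ValueError("need lo < hi")
        if self.scale not in ("linear", "log"):
            raise ValueError("scale must be 'linear' or 'log'")
        if self.scale == "log" and self.lo <= 0:
            raise ValueError("log axis needs positive bounds")

    def values(self) -> np.ndarray:
        if self.scale == "log":
            return np.geomspace(self.lo, self.hi, self.count)
        return np.linspace(self.lo, self.hi, self.count)


@dataclasses.dataclass(frozen=True)
class SweepSpec:
    """Everything needed to reproduce a sweep.

    ``transient`` and ``window`` are the per-cell time budget (discarded
    settling time and metrics window); ``lyapunov`` turns on per-cell
    spectra over ``lyap_total`` time units.  ``ic_policy`` is "inherit"
    (warm-start from the previous cell) or "fixed" (every cell starts at
    ``ic``).
    """

    axes: tuple[Axis, ...]
    params: HRParams = HRParams()
    ic: tuple[float, float, float] = (0.0, 0.0, 0.0)
    ic_policy: str = "inherit"
    transient: float = 1.0e3
    window: float = 1.0e4
    lyapunov: bool = False
    lyap_total: float = 1.0e4
    lyap_interval: float = 1.0
    keep_isis: bool = False
    criteria: ClassificationCriteria = DEFAULT_CRITERIA
    integrator: IntegratorOptions = IntegratorOptions()

    def __post_init__(self) -> None:
        if len(self.axes) not in (1, 2):
            raise ValueError("one or two axes required")
        names = [a.name for a in self.axes]
        if len(set(names)) != len(names):
            raise ValueError("axis names must be distinct")
        if self.ic_policy not in ("inherit", "fixed"):
            raise ValueError("ic_policy must be 'inherit' or 'fixed'")

    @property
    def n_cells(self) -> int:
        """Cell count of the lattice — enumerable without running."""
        n = 1
        for a in self.axes:
            n *= a.count
        return n

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(a.count for a in self.axes)


@dataclasses.dataclass
class CellRecord:
    """Metrics recorded at one lattice cell."""

    index: tuple[int, ...]
    coords: dict[str, float]
    activity: str = UNDETERMINED
    topology: str = UNDETERMINED
    sn_mode: int | None = None
    sn_mean: float | None = None
    sn_dev: int | None = None
    dc: float | None = None
    n_spikes: int = 0
    n_distinct_isi: int = 0
    lam: tuple[float, ...] | None = None
    isis: np.ndarray | None = None
    failed: bool = False
    note: str = ""

    def __eq__(self, other) -> bool:  # field-for-field, array-aware
        if not isinstance(other, CellRecord):
            return NotImplemented
        for f in dataclasses.fields(self):
            a, b = getattr(self, f.name), getattr(other, f.name)
            if isinstance(a, np.ndarray) or isinstance(b, np.ndarray):
                if a is None or b is None or not np.array_equal(a, b):
                    return False
            elif a != b:
                return False
        return True


@dataclasses.dataclass
class SweepGrid:
    """Complete sweep output: spec, per-cell records, metadata."""

    spec: SweepSpec
    records: list[CellRecord]
    meta: dict

    @property
    def shape(self) -> tuple[int, ...]:
        return self.spec.shape

    def field(self, name: str) -> np.ndarray:
        """A per-cell scalar reshaped to the lattice shape."""
        vals = [getattr(r, name) for r in self.records]
        arr = np.array(
            [np.nan if v is None else v for v in vals],
            dtype=float if name not in ("activity", "topology", "note") else object,
        )
        return arr.reshape(self.shape)

    def sn_map(self) -> np.ndarray:
        return self.field("sn_mode")

    def __eq__(self, other) -> bool:
        if not isinstance(other, SweepGrid):
            return NotImplemented
        return self.spec == other.spec and self.records == other.records


def _sn_mode(sn: np.ndarray) -> int | None:
    if len(sn) == 0:
        return None
    vals, counts = np.unique(sn, return_counts=True)
    return int(vals[np.argmax(counts)])


def _evaluate_cell(
    index: tuple[int, ...], coords: dict[str, float], p: HRParams, ic, spec: SweepSpec
):
    rec = CellRecord(index=index, coords=dict(coords))
    try:
        st, _ = integrate_endpoint(
            np.asarray(ic, dtype=np.float64), p, spec.transient, spec.integrator
        )
        traj = integrate(st, p, spec.transient + spec.window, spec.integrator, t0=spec.transient)
    except DivergenceError as err:
        rec.failed = True
        rec.note = str(err)
        return rec, None
    res = analyze_trajectory(traj, (spec.transient, spec.transient + spec.window), spec.criteria)
    m = res.metrics
    rec.activity = res.activity.primary
    rec.topology = res.activity.topology
    rec.sn_mode = _sn_mode(m.sn)
    rec.sn_mean = float(np.mean(m.sn)) if len(m.sn) else None
    rec.sn_dev = m.sn_deviation if len(m.sn) else None
    rec.dc = m.dc
    rec.n_spikes = m.n_spikes
    rec.n_distinct_isi = m.n_distinct_isi
    if spec.keep_isis:
        rec.isis = m.isis_all.copy()
    if spec.lyapunov:
        lopts = LyapunovOptions(
            transient=spec.lyap_interval,
            total=spec.lyap_total,
            interval=spec.lyap_interval,
            integrator=spec.integrator,
        )
        try:
            lres = lyapunov_spectrum(p, traj.endpoint, lopts)
            rec.lam = tuple(float(v) for v in lres.exponents)
        except (DivergenceError, np.linalg.LinAlgError) as err:
            rec.note = f"lyapunov failed: {err}"
    return rec, traj.endpoint


def sweep_1d(spec: SweepSpec) -> list[CellRecord]:
    """Evaluate a one-axis sweep in axis order."""
    if len(spec.axes) != 1:
        raise ValueError("sweep_1d requires exactly one axis")
    axis = spec.axes[0]
    records: list[CellRecord] = []
    ic = np.asarray(spec.ic, dtype=np.float64)
    for i, v in enumerate(axis.values()):
        p = spec.params.replace(**{axis.name: float(v)})
        rec, final = _evaluate_cell((i,), {axis.name: float(v)}, p, ic, spec)
        records.append(rec)
        if spec.ic_policy == "inherit" and final is not None:
            ic = final
        elif spec.ic_policy == "fixed" or final is None:
            ic = np.asarray(spec.ic, dtype=np.float64)
    return records


def sweep_2d(spec: SweepSpec) -> SweepGrid:
    """Evaluate a two-axis sweep row-major (second axis fastest).

    With the inherit policy the warm start resets to ``spec.ic`` at the
    start of each row, making the traversal order part of the contract.
    """
    if len(spec.axes) != 2:
        raise ValueError("sweep_2d requires exactly two axes")
    ax0, ax1 = spec.axes
    records: list[CellRecord] = []
    for i, v0 in enumerate(ax0.values()):
        ic = np.asarray(spec.ic, dtype=np.float64)
        for j, v1 in enumerate(ax1.values()):
            p = spec.params.replace(**{ax0.name: float(v0), ax1.name: float(v1)})
            rec, final = _evaluate_cell(
                (i, j), {ax0.name: float(v0), ax1.name: float(v1)}, p, ic, spec
            )
            records.append(rec)
            if spec.ic_policy == "inherit" and final is not None:
                ic = final
            elif spec.ic_policy == "fixed" or final is None:
                ic = np.asarray(spec.ic, dtype=np.float64)
    meta = {
        "traversal": "row-major, second axis fastest; inherit resets per row",
        "n_cells": spec.n_cells,
    }
    return SweepGrid(spec=spec, records=records, meta=meta)


def detect_spike_adding_boundaries(
    data: SweepGrid | Sequence[CellRecord],
) -> list[dict]:
    """Cells whose SN differs from an axis neighbor by exactly one.

    Each boundary is reported once, keyed by the lower-index cell of the
    pair, with the neighbor index, the SN step, and the second Lyapunov
    exponents of the pair when recorded.
    """
    if isinstance(data, SweepGrid):
        records = data.records
        shape = data.shape
    else:
        records = list(data)
        shape = (len(records),)
    sn = np.array(
        [np.nan if r.sn_mode is None else r.sn_mode for r in records], dtype=float
    ).reshape(shape)
    lam2 = np.array(
        [np.nan if r.lam is None else r.lam[1] for r in records], dtype=float
    ).reshape(shape)
    out: list[dict] = []
    grid = np.arange(int(np.prod(shape))).reshape(shape)
    for axis in range(len(shape)):
        a = np.moveaxis(sn, axis, 0)
        l2 = np.moveaxis(lam2, axis, 0)
        idx = np.moveaxis(grid, axis, 0)
        diff = a[1:] - a[:-1]
        hits = np.argwhere(np.abs(diff) == 1)
        for h in hits:
            i = (int(h[0]),) + tuple(int(x) for x in h[1:])
            j = (int(h[0]) + 1,) + tuple(int(x) for x in h[1:])
            out.append(
                {
                    "cell": records[int(idx[i])].index,
                    "neighbor": records[int(idx[j])].index,
                    "axis": axis,
                    "dsn": int(diff[i]),
                    "lam2_pair": (float(l2[i]), float(l2[j])),
                }
            )
    return out


# ---------------------------------------------------------------------------
# attractor scanning (multistability)


@dataclasses.dataclass(frozen=True)
class AttractorSignature:
    """Period, spike count per period and label of a converged attractor."""

    period: float
    spikes_per_period: int
    maxima_per_period: int
    label: str

    def matches(self, other: "AttractorSignature", rtol: float) -> bool:
        if self.label != other.label:
            return False
        if self.label == QUIESCENCE:
            return True
        if self.spikes_per_period != other.spikes_per_period:
            return False
        if self.maxima_per_period != other.maxima_per_period:
            return False
        ref = max(abs(self.period), 1e-12)
        return abs(self.period - other.period) <= rtol * ref


@dataclasses.dataclass
class AttractorScan:
    signatures: list[AttractorSignature]
    n_flagged: int  # non-convergent initial conditions, excluded

    @property
    def n_distinct(self) -> int:
        return len(self.signatures)


def _orbit_signature(
    p: HRParams,
    ic,
    transient: float,
    window: float,
    opts: IntegratorOptions,
    criteria: ClassificationCriteria,
    period_rtol: float,
):
    st, _ = integrate_endpoint(np.asarray(ic, dtype=np.float64), p, transient, opts)
    traj = integrate(st, p, transient + window, opts, t0=transient)
    tmax, vmax = locate_events(traj, EventSpec.maximum(0))
    if len(tmax) < 4:
        return AttractorSignature(0.0, 0, 0, QUIESCENCE)
    states = event_states(traj, tmax)
    scale = float(np.max(np.abs(states))) + 1.0
    atol = 1e-4 * scale
    nmax = len(tmax)
    knots = traj.knot_states()[:, 0]
    rng_lo = min(knots.min(), states[:, 0].min())
    rng_hi = max(knots.max(), states[:, 0].max())
    theta = rng_lo + criteria.spike_fraction * (rng_hi - rng_lo)
    for m in range(1, nmax // 3 + 1):
        k = min(8, nmax - m)
        d = states[nmax - k :] - states[nmax - k - m : nmax - m]
        if np.max(np.abs(d)) < atol:
            rets = tmax[nmax - k :] - tmax[nmax - k - m : nmax - m]
            period = float(np.mean(rets))
            if np.max(np.abs(rets - period)) > period_rtol * period:
                continue
            spikes = int(np.sum(vmax[nmax - m :] > theta))
            return AttractorSignature(period, spikes, m, "periodic")
    return None  # non-convergent within the window


def ic_lattice(p: HRParams, nx: int = 5, nz: int = 4, dz: float = 1.0) -> list[tuple[float, float, float]]:
    """Deterministic initial-condition lattice for multistability probing.

    Points sit on the fast nullcline ``y = c - d x^2`` over a grid of
    membrane potentials, with ``z`` spanning a band of width ``2*dz``
    around the full-system equilibrium's slow-variable value — the region
    the competing attractors share.
    """
    coeffs = [-p.a, p.b - p.d, -p.s, p.c + p.I + p.s * p.x0]
    roots = np.roots(coeffs)
    xeq = roots[np.isreal(roots)].real
    z0 = float(np.median(p.s * (xeq - p.x0)))
    out = []
    for x in np.linspace(-1.6, 1.6, nx):
        for z in np.linspace(z0 - dz, z0 + dz, nz):
            out.append((float(x), float(p.c - p.d * x * x), float(z)))
    return out


def scan_attractors(
    p: HRParams,
    ic_set: Iterable[Sequence[float]],
    transient: float = 2.0e3,
    window: float = 2.0e3,
    opts: IntegratorOptions = IntegratorOptions(),
    criteria: ClassificationCriteria = DEFAULT_CRITERIA,
    period_rtol: float = 1e-3,
) -> AttractorScan:
    """Distinct attractor signatures reached from a deterministic IC set.

    Each initial condition is settled past the transient, the orbit's
    minimal return structure over the voltage maxima is extracted (period
    to the given relative tolerance, spikes per period), and equal
    signatures merge.  Non-convergent runs are flagged and excluded.
    """
    signatures: list[AttractorSignature] = []
    flagged = 0
    for ic in ic_set:
        try:
            sig = _orbit_signature(p, ic, transient, window, opts, criteria, period_rtol)
        except DivergenceError:
            sig = None
        if sig is None:
            flagged += 1
            continue
        if not any(sig.matches(s, period_rtol) for s in signatures):
            signatures.append(sig)
    return AttractorScan(signatures=signatures, n_flagged=flagged)


# ---------------------------------------------------------------------------
# grid persistence: columnar text + JSON metadata sidecar

_CSV_COLS = [
    "activity",
    "topology",
    "sn_mode",
    "sn_mean",
    "sn_dev",
    "dc",
    "n_spikes",
    "n_distinct_isi",
    "failed",
    "note",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_grid(grid: SweepGrid, path: str | Path) -> None:
    """One row per cell (indices, axis values, metrics) + JSON sidecar."""
    path = Path(path)
    rows = []
    nax = len(grid.spec.axes)
    for r in grid.records:
        row: dict = {}
        for k in range(nax):
            row[f"i{k}"] = r.index[k]
        for name, v in r.coords.items():
            row[name] = repr(v)
        for col in _CSV_COLS:
            row[col] = getattr(r, col)
        if r.lam is not None:
            for k, v in enumerate(r.lam):
                row[f"lam{k + 1}"] = repr(float(v))
        if r.isis is not None:
            row["isis"] = ";".join(repr(float(v)) for v in r.isis)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    meta = {
        "axes": [dataclasses.asdict(a) for a in grid.spec.axes],
        "params": grid.spec.params.asdict(),
        "ic": list(grid.spec.ic),
        "ic_policy": grid.spec.ic_policy,
        "transient": grid.spec.transient,
        "window": grid.spec.window,
        "lyapunov": grid.spec.lyapunov,
        "lyap_total": grid.spec.lyap_total,
        "lyap_interval": grid.spec.lyap_interval,
        "keep_isis": grid.spec.keep_isis,
        "criteria": dataclasses.asdict(grid.spec.criteria),
        "integrator": dataclasses.asdict(grid.spec.integrator),
        "meta": grid.meta,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_grid(path: str | Path) -> SweepGrid:
    """Rebuild a grid written by :func:`write_grid`; sidecar is mandatory."""
    path = Path(path)
    side = _sidecar(path)
    if not side.exists():
        raise FileNotFoundError(
            f"metadata sidecar {side} is missing; refusing to guess the sweep spec"
        )
    meta = json.loads(side.read_text())
    spec = SweepSpec(
        axes=tuple(Axis(**a) for a in meta["axes"]),
        params=HRParams(**meta["params"]),
        ic=tuple(meta["ic"]),
        ic_policy=meta["ic_policy"],
        transient=meta["transient"],
        window=meta["window"],
        lyapunov=meta["lyapunov"],
        lyap_total=meta["lyap_total"],
        lyap_interval=meta["lyap_interval"],
        keep_isis=meta["keep_isis"],
        criteria=ClassificationCriteria(**meta["criteria"]),
        integrator=IntegratorOptions(**meta["integrator"]),
    )
    try:
        df = pd.read_csv(path, keep_default_na=False)
    except Exception as err:
        raise ValueError(f"malformed grid file {path}: {err}") from None
    nax = len(spec.axes)
    records: list[CellRecord] = []
    for _, row in df.iterrows():
        index = tuple(int(row[f"i{k}"]) for k in range(nax))
        coords = {a.name: float(row[a.name]) for a in spec.axes}
        lam = None
        if "lam1" in df.columns and row.get("lam1", "") != "":
            lam = tuple(float(row[f"lam{k + 1}"]) for k in range(3))
        isis = None
        if "isis" in df.columns:
            cell = row["isis"]
            if isinstance(cell, str) and cell:
                isis = np.array([float(v) for v in cell.split(";")])
            elif spec.keep_isis:
                isis = np.empty(0)
        records.append(
            CellRecord(
                index=index,
                coords=coords,
                activity=str(row["activity"]),
                topology=str(row["topology"]),
                sn_mode=None if row["sn_mode"] == "" else int(float(row["sn_mode"])),
                sn_mean=None if row["sn_mean"] == "" else float(row["sn_mean"]),
                sn_dev=None if row["sn_dev"] == "" else int(float(row["sn_dev"])),
                dc=None if row["dc"] == "" else float(row["dc"]),
                n_spikes=int(row["n_spikes"]),
                n_distinct_isi=int(row["n_distinct_isi"]),
                lam=lam,
                isis=isis,
                failed=bool(row["failed"]) if not isinstance(row["failed"], str) else row["failed"] == "True",
                note=str(row["note"]) if row["note"] != "" else "",
            )
        )
    expected = spec.n_cells
    if len(records) != expected:
        raise ValueError(
            f"grid file {path} has {len(records)} rows, spec promises {expected}"
        )
    return SweepGrid(spec=spec, records=records, meta=meta.get("meta", {}))
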