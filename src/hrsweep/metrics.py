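"""Neuroscience-native temporal metrics from dense voltage trajectories.

The pipeline mirrors what an experimentalist extracts from a voltage trace:

1. :func:`detect_spikes` — voltage maxima above an amplitude threshold
   (a fraction of the window's voltage range), located as series roots, not
   by sampling;
2. :func:`partition_bursts` — group spikes into bursts separated by
   quiescent dwells below a hyperpolarized level;
3. :func:`compute_metrics` — per-burst spike counts (SN), spike-count
   deviation, duty cycle DC = mean burst duration / mean burst period,
   interspike-interval (ISI) sequences and the number of distinct ISIs;
4. :func:`classify_activity` — quiescence / tonic spiking / regular or
   chaotic bursting, with chaos flagged by spike-count variability or by
   more than a preset number (default 25) of unlike ISIs;
5. :func:`classify_burst_topology` — square-wave (fold/homoclinic)
   bursting, whose terminal ISIs grow as the orbit slows near the saddle,
   vs plateau-like (fold/Hopf) bursting, whose terminal spike amplitudes
   ring down around the depolarized equilibrium.

Conventions chosen where the underlying definitions are qualitative: a
voltage trace whose windowed range is tiny (< 0.05) is quiescent; a regime
whose bursts all carry exactly one spike is tonic spiking (the "round"
periodic orbit); the chaos test is applied to the whole analysis window.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .taylor import EventSpec, Trajectory, locate_events

__all__ = [
    "ClassificationCriteria",
    "SpikeTrain",
    "Burst",
    "BurstPartition",
    "BurstMetrics",
    "ActivityClass",
    "detect_spikes",
    "partition_bursts",
    "compute_metrics",
    "classify_activity",
    "classify_burst_topology",
    "isi_bifurcation_record",
    "distinct_isi_count",
    "analyze_trajectory",
]

#: Activity labels
QUIESCENCE = "quiescence"
TONIC = "tonic_spiking"
BURST_REGULAR = "bursting_regular"
BURST_CHAOTIC = "bursting_chaotic"
UNDETERMINED = "undetermined"

SQUARE_WAVE = "square_wave"
PLATEAU = "plateau_like"


@dataclasses.dataclass(frozen=True)
class ClassificationCriteria:
    """Thresholds of the spike/burst/chaos classifiers.

    ``chaos_spike_limit``: more distinct ISIs than this in the analysis
    window flags chaotic bursting.  ``spike_fraction`` places the spike
    threshold at that fraction of the window's voltage range above its
    minimum; ``quiescence_fraction`` likewise for the quiescent dwell
    level.  ``quiescence_dwell`` is the minimum time below the dwell level
    that separates bursts.  ``isi_rel_tol`` is the relative tolerance under
    which two ISIs count as alike.  ``amplitude_band`` (fraction of range)
    is the spike-amplitude uniformity band used by the burst-topology
    classifier, and ``flat_range`` the windowed voltage range below which a
    trace counts as settled to equilibrium.
    """

    chaos_spike_limit: int = 25
    isi_rel_tol: float = 1e-3
    spike_fraction: float = 0.3
    quiescence_fraction: float = 0.1
    quiescence_dwell: float = 5.0
    min_bursts: int = 3
    amplitude_band: float = 0.2
    flat_range: float = 0.05
    min_prominence: float = 1e-4  # fraction of range an extremum must rise

    def __post_init__(self) -> None:
        if self.chaos_spike_limit <= 0 or self.isi_rel_tol <= 0 or self.quiescence_dwell <= 0:
            raise ValueError("classification limits must be positive")
        if not 0 < self.spike_fraction < 1 or not 0 < self.quiescence_fraction < 1:
            raise ValueError("threshold fractions must lie in (0, 1)")


DEFAULT_CRITERIA = ClassificationCriteria()


@dataclasses.dataclass(frozen=True)
class SpikeTrain:
    """Spike events (times and voltage maxima) in an analysis window."""

    times: np.ndarray
    values: np.ndarray
    threshold: float
    x_min: float
    x_max: float
    window: tuple[float, float]
    all_max_times: np.ndarray
    all_max_values: np.ndarray

    def __len__(self) -> int:
        return len(self.times)

    @property
    def x_range(self) -> float:
        return self.x_max - self.x_min


@dataclasses.dataclass(frozen=True)
class Burst:
    """One burst: its spikes and active-phase boundaries.

    ``t_on``/``t_off`` are the dwell-level crossings bracketing the active
    phase; ``t_next_on`` is the next burst's onset (period = onset to
    onset), None for the last burst in the window.
    """

    spike_times: np.ndarray
    spike_values: np.ndarray
    t_on: float
    t_off: float
    t_next_on: float | None

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)

    @property
    def duration(self) -> float:
        return self.t_off - self.t_on

    @property
    def period(self) -> float | None:
        return None if self.t_next_on is None else self.t_next_on - self.t_on

    @property
    def isis(self) -> np.ndarray:
        return np.diff(self.spike_times)


@dataclasses.dataclass(frozen=True)
class BurstPartition:
    """Bursts in the window, plus the raw dwell/threshold context."""

    bursts: tuple[Burst, ...]
    tonic: bool  # no separating quiescent dwell found
    window: tuple[float, float]
    theta_q: float
    spikes: SpikeTrain
    n_edge_spikes: int  # spikes in partial bursts at the window edges

    @property
    def n_bursts(self) -> int:
        return len(self.bursts)


@dataclasses.dataclass(frozen=True)
class BurstMetrics:
    """Spike-count, duty-cycle and ISI statistics of a burst partition."""

    sn: np.ndarray  # spikes per burst
    sn_deviation: int  # max - min of sn
    dc: float | None  # duty cycle, None when periods are unavailable
    durations: np.ndarray
    periods: np.ndarray
    isis_per_burst: tuple[np.ndarray, ...]
    isis_all: np.ndarray  # consecutive spike-time differences, whole window
    n_distinct_isi: int
    n_spikes: int
    tonic: bool
    insufficient: bool
    x_range: float


@dataclasses.dataclass(frozen=True)
class ActivityClass:
    primary: str
    topology: str = UNDETERMINED
    reason: str = ""


def _window_events(traj: Trajectory, window: tuple[float, float], spec: EventSpec):
    t_lo, t_hi = window
    sub = traj.restrict(t_lo, t_hi)
    t, v = locate_events(sub, spec)
    keep = (t >= t_lo) & (t <= t_hi)
    return t[keep], v[keep]


def detect_spikes(
    traj: Trajectory,
    window: tuple[float, float] | None = None,
    criteria: ClassificationCriteria = DEFAULT_CRITERIA,
    var: int = 0,
) -> SpikeTrain:
    """Voltage maxima above the window-relative spike threshold.

    The threshold is ``x_min + spike_fraction * (x_max - x_min)`` with the
    extremes measured on the window (segment knots plus located extrema),
    so it adapts to the orbit's amplitude rather than to absolute units.
    """
    if window is None:
        window = (traj.t0, traj.t_end)
    t_lo, t_hi = window
    if t_hi <= t_lo:
        e = np.empty(0)
        return SpikeTrain(e, e, np.nan, np.nan, np.nan, window, e, e)
    tmax, vmax = _window_events(traj, window, EventSpec.maximum(var))
    tmin, vmin = _window_events(traj, window, EventSpec.minimum(var))
    sub = traj.restrict(t_lo, t_hi)
    knots = sub.knot_states()[:, var]
    lo_candidates = [knots.min()] + ([vmin.min()] if len(vmin) else [])
    hi_candidates = [knots.max()] + ([vmax.max()] if len(vmax) else [])
    x_min = float(min(lo_candidates))
    x_max = float(max(hi_candidates))
    x_range = x_max - x_min
    if x_range < criteria.flat_range:
        # settled to equilibrium: no suprathreshold activity by definition
        e = np.empty(0)
        return SpikeTrain(e, e, x_max, x_min, x_max, window, e, e)
    # prominence filter: a genuine extremum must rise above its flanking
    # minima by a fraction of the range (guards against numerical ripple)
    if len(tmin):
        floor = np.interp(tmax, tmin, vmin)
        keep = (vmax - floor) > criteria.min_prominence * x_range
        tmax, vmax = tmax[keep], vmax[keep]
    threshold = x_min + criteria.spike_fraction * x_range
    above = vmax > threshold
    return SpikeTrain(
        tmax[above], vmax[above], threshold, x_min, x_max, window, tmax, vmax
    )


def partition_bursts(
    spikes: SpikeTrain,
    traj: Trajectory,
    criteria: ClassificationCriteria = DEFAULT_CRITERIA,
    var: int = 0,
) -> BurstPartition:
    """Group spikes into bursts separated by sub-``theta_q`` quiescent dwells.

    ``theta_q`` sits at ``quiescence_fraction`` of the voltage range; a
    dwell below it longer than ``quiescence_dwell`` separates bursts.  The
    active phase runs from the upward crossing preceding the first spike to
    the downward crossing after the last; periods are onset-to-onset.
    Bursts not bracketed by two dwells (window edges) are excluded and
    counted in ``n_edge_spikes``.
    """
    window = spikes.window
    t_lo, t_hi = window
    theta_q = spikes.x_min + criteria.quiescence_fraction * spikes.x_range
    tf, _ = _window_events(traj, window, EventSpec.crossing(var, theta_q, -1))
    tr, _ = _window_events(traj, window, EventSpec.crossing(var, theta_q, +1))

    below_at_start = traj.eval(t_lo)[var] < theta_q
    # assemble below-theta_q intervals (fall, rise); edge intervals allowed
    intervals: list[tuple[float, float, bool]] = []  # (start, end, interior)
    fi = ri = 0
    cur_start = t_lo if below_at_start else None
    edge_open = below_at_start
    while fi < len(tf) or ri < len(tr):
        take_fall = ri >= len(tr) or (fi < len(tf) and tf[fi] < tr[ri])
        if take_fall:
            if cur_start is None:
                cur_start = tf[fi]
                edge_open = False
            fi += 1
        else:
            if cur_start is not None:
                intervals.append((cur_start, tr[ri], not edge_open))
                cur_start = None
                edge_open = False
            ri += 1
    if cur_start is not None:
        intervals.append((cur_start, t_hi, False))

    separators = [iv for iv in intervals if iv[1] - iv[0] > criteria.quiescence_dwell]

    st = spikes.times
    if not separators:
        # no quiescent dwell at all: tonic pseudo-burst spanning the window
        burst = Burst(st, spikes.values, t_lo, t_hi, None)
        return BurstPartition((burst,) if len(st) else (), True, window, theta_q, spikes, 0)

    bursts: list[Burst] = []
    onsets: list[float] = []
    for k in range(len(separators) - 1):
        on = separators[k][1]
        off = separators[k + 1][0]
        mask = (st >= on) & (st <= off)
        if mask.any():
            bursts.append(Burst(st[mask], spikes.values[mask], on, off, None))
            onsets.append(on)
    # attach next-onset for periods
    full: list[Burst] = []
    for i, b in enumerate(bursts):
        nxt = bursts[i + 1].t_on if i + 1 < len(bursts) else None
        full.append(dataclasses.replace(b, t_next_on=nxt))
    n_edge = len(st) - sum(b.n_spikes for b in full)
    return BurstPartition(tuple(full), False, window, theta_q, spikes, n_edge)


def distinct_isi_count(isis: np.ndarray, rel_tol: float) -> int:
    """Number of ISI equivalence classes under a relative tolerance.

    Sorted ISIs are merged into a class while each consecutive gap stays
    within ``rel_tol`` of the class representative (its first member).
    """
    if len(isis) == 0:
        return 0
    s = np.sort(isis)
    n = 1
    rep = s[0]
    for v in s[1:]:
        if v - rep > rel_tol * max(rep, 1e-300):
            n += 1
            rep = v
    return n


def compute_metrics(
    partition: BurstPartition,
    criteria: ClassificationCriteria = DEFAULT_CRITERIA,
) -> BurstMetrics:
    """SN sequence, deviation, duty cycle and ISI statistics."""
    bursts = partition.bursts
    spikes = partition.spikes
    sn = np.array([b.n_spikes for b in bursts], dtype=int)
    durations = np.array([b.duration for b in bursts])
    periods = np.array([b.period for b in bursts if b.period is not None])
    isis_all = np.diff(spikes.times)
    insufficient = (not partition.tonic) and (len(bursts) < 2 or len(periods) < 1)
    dc: float | None
    if partition.tonic:
        dc = None
        insufficient = len(spikes) < 2
    elif insufficient or len(periods) == 0:
        dc = None
    else:
        dur_with_period = np.array(
            [b.duration for b in bursts if b.period is not None]
        )
        dc = float(np.mean(dur_with_period) / np.mean(periods))
    return BurstMetrics(
        sn=sn,
        sn_deviation=int(sn.max() - sn.min()) if len(sn) else 0,
        dc=dc,
        durations=durations,
        periods=periods,
        isis_per_burst=tuple(b.isis for b in bursts),
        isis_all=isis_all,
        n_distinct_isi=distinct_isi_count(isis_all, criteria.isi_rel_tol),
        n_spikes=len(spikes),
        tonic=partition.tonic,
        insufficient=insufficient,
        x_range=spikes.x_range,
    )


def classify_activity(
    metrics: BurstMetrics,
    criteria: ClassificationCriteria = DEFAULT_CRITERIA,
) -> ActivityClass:
    """Primary activity class from windowed metrics.

    Order of tests: quiescence (no spikes, or a settled flat trace), then
    chaos (distinct-ISI count over the window, or persistent spike-count
    deviation), then tonic spiking (one spike per train), then regular
    bursting.  The chaos test precedes the tonic test so that irregular
    single-spike trains are not mistaken for tonic spiking.
    """
    if metrics.n_spikes == 0 or (np.isfinite(metrics.x_range) and metrics.x_range < criteria.flat_range):
        return ActivityClass(QUIESCENCE, reason="no suprathreshold spikes")
    if metrics.n_distinct_isi > criteria.chaos_spike_limit:
        return ActivityClass(
            BURST_CHAOTIC,
            reason=f"{metrics.n_distinct_isi} distinct ISIs > {criteria.chaos_spike_limit}",
        )
    if len(metrics.sn) >= criteria.min_bursts and metrics.sn_deviation > 0:
        half = len(metrics.sn) // 2
        if np.ptp(metrics.sn[:half]) > 0 and np.ptp(metrics.sn[half:]) > 0:
            return ActivityClass(
                BURST_CHAOTIC, reason=f"persistent spike-count deviation {metrics.sn_deviation}"
            )
    if metrics.insufficient:
        return ActivityClass(UNDETERMINED, reason="fewer than 2 complete bursts in window")
    if metrics.tonic or (len(metrics.sn) > 0 and metrics.sn.max() == 1):
        return ActivityClass(TONIC, reason="single spike per train")
    return ActivityClass(BURST_REGULAR)


def _burst_topology_vote(
    amps: np.ndarray,
    isis: np.ndarray,
    mins_between: np.ndarray,
    x_range: float,
    criteria: ClassificationCriteria,
) -> str:
    """Topology vote for one burst from its maxima amplitudes and ISIs."""
    if len(amps) < 4 or len(isis) < 3:
        return UNDETERMINED
    band = criteria.amplitude_band * x_range
    med = float(np.median(amps))
    # plateau: a terminal ring-down — maxima fall out of the amplitude band
    # and keep decaying while the minima floor rises toward them
    low = np.where(amps < med - band)[0]
    if len(low) >= 1:
        i0 = int(low[0])
        tail = amps[i0 - 1 :] if i0 > 0 else amps
        tail_mins = mins_between[max(i0 - 1, 0) :]
        if (
            len(tail) >= 3
            and np.all(np.diff(tail) < 0)
            and (len(tail_mins) < 2 or np.all(np.diff(tail_mins) > 0))
        ):
            return PLATEAU
        return UNDETERMINED
    # square wave: terminal ISI is the burst's largest, amplitudes in band
    if isis[-1] >= np.max(isis) * (1 - 1e-9) and np.min(amps) >= med - band:
        return SQUARE_WAVE
    return UNDETERMINED


def classify_burst_topology(
    partition: BurstPartition,
    traj: Trajectory,
    criteria: ClassificationCriteria = DEFAULT_CRITERIA,
    var: int = 0,
) -> str:
    """Square-wave vs plateau-like burst termination.

    Square-wave (fold/homoclinic) bursts end with their largest interspike
    interval — the orbit slows logarithmically near the fast-subsystem
    saddle — while spike amplitudes stay within a band of the burst median.
    Plateau-like (fold/Hopf) bursts end with spike amplitudes decaying
    monotonically toward the depolarized equilibrium (minima rising, maxima
    falling) before the orbit drops to the hyperpolarized branch.  Votes
    are taken per burst over all voltage maxima (sub-threshold ones
    included) and the majority label wins.
    """
    if not partition.bursts or partition.tonic:
        return UNDETERMINED
    spikes = partition.spikes
    tmax, vmax = spikes.all_max_times, spikes.all_max_values
    tmin, vmin = _window_events(traj, partition.window, EventSpec.minimum(var))
    votes: list[str] = []
    for b in partition.bursts:
        m = (tmax >= b.t_on) & (tmax <= b.t_off)
        amps = vmax[m]
        bt = tmax[m]
        if len(bt) < 2:
            continue
        mm = (tmin > bt[0]) & (tmin < bt[-1])
        votes.append(
            _burst_topology_vote(amps, np.diff(bt), vmin[mm], spikes.x_range, criteria)
        )
    if not votes:
        return UNDETERMINED
    counts = {lab: votes.count(lab) for lab in set(votes)}
    best = max(counts, key=counts.get)
    if best == UNDETERMINED or counts[best] <= len(votes) / 2:
        return UNDETERMINED
    return best


def isi_bifurcation_record(metrics: BurstMetrics) -> np.ndarray:
    """Flat ISI multiset of the window, for ISI bifurcation diagrams."""
    return metrics.isis_all.copy()


@dataclasses.dataclass(frozen=True)
class ActivityRecord:
    """Bundle of everything the analyzers extract from one trajectory."""

    activity: ActivityClass
    metrics: BurstMetrics
    partition: BurstPartition
    spikes: SpikeTrain


def analyze_trajectory(
    traj: Trajectory,
    window: tuple[float, float] | None = None,
    criteria: ClassificationCriteria = DEFAULT_CRITERIA,
) -> ActivityRecord:
    """Run the full metric/classification pipeline on one trajectory."""
    spikes = detect_spikes(traj, window, criteria)
    partition = partition_bursts(spikes, traj, criteria)
    metrics = compute_metrics(partition, criteria)
    activity = classify_activity(metrics, criteria)
    if activity.primary in (BURST_REGULAR, BURST_CHAOTIC):
        topology = classify_burst_topology(partition, traj, criteria)
        activity = dataclasses.replace(activity, topology=topology)
    return ActivityRecord(activity, metrics, partition, spikes)
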