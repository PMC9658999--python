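"""Event-anchored alignment and averaging of single-cell cell-cycle traces.

A trace is anchored at three annotated events — karyokinesis (K), budding
(B), and the next karyokinesis — splitting each cycle into G1 (K to B) and
S/G2/M (B to K).  Cycles of different lengths are made comparable by linear
interpolation of each phase onto a fixed number of equidistant points
(80 in total by default), with the per-phase point counts allocated in
proportion to the population-average phase durations, and then averaged on
a common relative-time axis from 0 to 1 with 95% confidence bands.

Also provides phase/volume metrics at the events, per-cell cross-correlation
lag analysis between two readouts, and the Mann-Whitney test with
rank-biserial effect size used for comparing N/C-ratio distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

__all__ = [
    "KARYOKINESIS",
    "BUDDING",
    "CellTrace",
    "CycleSegment",
    "AlignedCycle",
    "GroupAverage",
    "DegenerateCycleError",
    "split_cycles",
    "allocate_points",
    "interpolate_cycle",
    "normalize_cycle",
    "average_cycles",
    "align_traces",
    "phase_metrics",
    "cross_correlation",
    "mean_cross_correlation",
    "mann_whitney_rb",
    "traces_to_matrix",
]

KARYOKINESIS = "karyokinesis"
BUDDING = "budding"
_EVENT_TYPES = (KARYOKINESIS, BUDDING)


class DegenerateCycleError(ValueError):
    """Raised when a cycle cannot be normalized (constant values / zero mean)."""


@dataclass
class CellTrace:
    """One cell's sampled readout over time with annotated cycle events.

    times are minutes (strictly increasing); values the readout (N/C ratio
    or abundance, a.u.); volumes the total (mother plus bud) volume in fL;
    bud_volumes an optional separate bud-volume series; events a list of
    (type, time) with type in {karyokinesis, budding}.
    """

    cell_id: str
    times: np.ndarray
    values: np.ndarray
    volumes: np.ndarray | None = None
    bud_volumes: np.ndarray | None = None
    events: list = field(default_factory=list)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError(f"cell {self.cell_id}: times/values must be equal-length 1-D")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"cell {self.cell_id}: times must be strictly increasing")
        for arr_name in ("volumes", "bud_volumes"):
            arr = getattr(self, arr_name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != self.times.shape:
                    raise ValueError(f"cell {self.cell_id}: {arr_name} length mismatch")
                setattr(self, arr_name, arr)
        self.events = sorted(self.events, key=lambda e: e[1])
        for etype, _ in self.events:
            if etype not in _EVENT_TYPES:
                raise ValueError(f"cell {self.cell_id}: unknown event type {etype!r}")

    def event_times(self, etype: str) -> np.ndarray:
        return np.array([t for e, t in self.events if e == etype], dtype=float)


@dataclass(frozen=True)
class CycleSegment:
    """One complete K -> B -> K cycle within a parent trace."""

    trace: CellTrace
    t_start: float  # first karyokinesis
    t_bud: float
    t_end: float  # next karyokinesis

    @property
    def g1_duration(self) -> float:
        return self.t_bud - self.t_start

    @property
    def sg2m_duration(self) -> float:
        return self.t_end - self.t_bud


@dataclass
class AlignedCycle:
    """One cycle resampled onto a fixed-length relative-time grid.

    rel_time runs from 0 (first karyokinesis) to 1 (next karyokinesis);
    boundary_index is the index of the budding point.
    """

    rel_time: np.ndarray
    values: np.ndarray
    boundary_index: int
    g1_duration: float
    sg2m_duration: float
    abs_times: np.ndarray | None = None
    cell_id: str = ""


@dataclass
class GroupAverage:
    """Pointwise mean of aligned cycles with 95% confidence band half-widths."""

    rel_time: np.ndarray
    mean: np.ndarray
    ci_half_width: np.ndarray
    n_cycles: int


def _check_alternating(events, cell_id: str):
    types = [e for e, _ in events]
    for a, b in zip(types, types[1:]):
        if a == b:
            raise ValueError(
                f"cell {cell_id}: events must alternate karyokinesis/budding, "
                f"got consecutive {a!r}"
            )


def split_cycles(trace: CellTrace) -> list[CycleSegment]:
    """Split a trace into complete K->B->K segments.

    Incomplete leading/trailing portions are dropped; consecutive segments
    share their boundary karyokinesis.  Non-alternating events reject the
    whole trace.
    """
    _check_alternating(trace.events, trace.cell_id)
    segments = []
    events = trace.events
    for i in range(len(events) - 2):
        e0, e1, e2 = events[i], events[i + 1], events[i + 2]
        if e0[0] == KARYOKINESIS and e1[0] == BUDDING and e2[0] == KARYOKINESIS:
            segments.append(
                CycleSegment(trace=trace, t_start=e0[1], t_bud=e1[1], t_end=e2[1])
            )
    if not segments:
        warnings.warn(
            f"cell {trace.cell_id}: no complete karyokinesis-budding-karyokinesis "
            "cycle found",
            stacklevel=2,
        )
    return segments


def allocate_points(mean_g1: float, mean_sg2m: float, n_total: int = 80):
    """Split n_total interpolation points between the phases in proportion to
    the average phase durations (nearest integer, ties rounded up)."""
    if mean_g1 <= 0 or mean_sg2m <= 0:
        raise ValueError("mean phase durations must be positive")
    if n_total < 4:
        raise ValueError("need at least 4 interpolation points")
    n_g1 = int(np.floor(n_total * mean_g1 / (mean_g1 + mean_sg2m) + 0.5))
    n_sg2m = n_total - n_g1
    if n_g1 < 2 or n_sg2m < 2:
        raise ValueError(
            f"point allocation ({n_g1}, {n_sg2m}) leaves a phase with fewer than "
            "2 points; increase n_total or check the phase durations"
        )
    return n_g1, n_sg2m


def interpolate_cycle(segment: CycleSegment, n_g1: int, n_sg2m: int) -> AlignedCycle:
    """Linearly resample one cycle onto n_g1 + n_sg2m equidistant points.

    G1 is sampled on [K1, B) (half-open, so the budding sample is not
    duplicated across phases) and S/G2/M on [B, K2] (closed); values come
    from linear interpolation of the raw trace.
    """
    tr = segment.trace
    if segment.t_start < tr.times[0] or segment.t_end > tr.times[-1]:
        raise ValueError(
            f"cell {tr.cell_id}: cycle events outside the sampled time range"
        )
    in_g1 = np.count_nonzero((tr.times >= segment.t_start) & (tr.times < segment.t_bud))
    in_s = np.count_nonzero((tr.times >= segment.t_bud) & (tr.times <= segment.t_end))
    if in_g1 < 2 or in_s < 2:
        raise ValueError(
            f"cell {tr.cell_id}: a cycle phase contains fewer than 2 raw samples"
        )
    g1_times = segment.t_start + np.arange(n_g1) * (segment.g1_duration / n_g1)
    s_times = segment.t_bud + np.arange(n_sg2m) * (
        segment.sg2m_duration / (n_sg2m - 1)
    )
    query = np.concatenate([g1_times, s_times])
    values = np.interp(query, tr.times, tr.values)
    n_total = n_g1 + n_sg2m
    return AlignedCycle(
        rel_time=np.arange(n_total) / (n_total - 1),
        values=values,
        boundary_index=n_g1,
        g1_duration=segment.g1_duration,
        sg2m_duration=segment.sg2m_duration,
        abs_times=query,
        cell_id=tr.cell_id,
    )


def normalize_cycle(aligned: AlignedCycle, mode: str = "none") -> AlignedCycle:
    """Per-cycle normalization matching the plotting conventions:
    minmax_sym maps [min, max] to [-1, 1]; minmax01 to [0, 1]; mean divides
    by the cycle mean; none is the identity."""
    v = aligned.values
    if mode == "none":
        return aligned
    if mode in ("minmax_sym", "minmax01"):
        lo, hi = float(v.min()), float(v.max())
        if hi == lo:
            raise DegenerateCycleError(
                f"cell {aligned.cell_id}: constant cycle cannot be min-max normalized"
            )
        unit = (v - lo) / (hi - lo)
        out = 2.0 * unit - 1.0 if mode == "minmax_sym" else unit
    elif mode == "mean":
        m = float(v.mean())
        if m == 0.0:
            raise DegenerateCycleError(
                f"cell {aligned.cell_id}: zero-mean cycle cannot be mean-normalized"
            )
        out = v / m
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return replace(aligned, values=out)


def average_cycles(cycles, normalize_mode: str = "none") -> GroupAverage:
    """Pointwise average of aligned cycles with 95% confidence bands.

    Normalization (if any) is applied per cycle before averaging; the band
    half-width is 1.96 * sd / sqrt(n) per grid point.  Cycles that cannot
    be normalized are excluded with a warning.
    """
    cycles = list(cycles)
    if len(cycles) < 2:
        raise ValueError("need at least 2 cycles to average")
    lengths = {len(c.values) for c in cycles}
    if len(lengths) != 1:
        raise ValueError(f"mixed aligned-cycle lengths {sorted(lengths)}")
    used = []
    for c in cycles:
        try:
            used.append(normalize_cycle(c, normalize_mode))
        except DegenerateCycleError as err:
            warnings.warn(f"excluding degenerate cycle: {err}", stacklevel=2)
    if len(used) < 2:
        raise ValueError("fewer than 2 cycles left after normalization")
    mat = np.stack([c.values for c in used])
    n = mat.shape[0]
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    return GroupAverage(
        rel_time=used[0].rel_time.copy(),
        mean=mean,
        ci_half_width=1.96 * sd / np.sqrt(n),
        n_cycles=n,
    )


def align_traces(traces, n_total: int = 80):
    """Split, allocate and interpolate a set of traces in one go.

    The mean phase durations used for point allocation are computed from the
    analyzed cycle set itself.  Returns the list of AlignedCycle.
    """
    segments = []
    for tr in traces:
        segments.extend(split_cycles(tr))
    if not segments:
        raise ValueError("no complete cycles in the trace set")
    mean_g1 = float(np.mean([s.g1_duration for s in segments]))
    mean_sg2m = float(np.mean([s.sg2m_duration for s in segments]))
    n_g1, n_sg2m = allocate_points(mean_g1, mean_sg2m, n_total)
    return [interpolate_cycle(s, n_g1, n_sg2m) for s in segments]


def _volume_at_or_after(times, series, t_event):
    """Series value at the first frame at/after the event time."""
    if series is None:
        return np.nan
    idx = int(np.searchsorted(times, t_event, side="left"))
    if idx >= len(times):
        return np.nan
    return float(series[idx])


def phase_metrics(trace: CellTrace):
    """Per-cycle phase durations and volumes at the cycle events.

    G1 is karyokinesis to budding, S/G2/M budding to the next karyokinesis.
    Volumes are read at the first frame at/after the event (the frame where
    the event first becomes detectable); the bud volume at karyokinesis
    requires the optional bud-volume series and is NaN otherwise.
    """
    out = []
    for seg in split_cycles(trace):
        out.append(
            {
                "cell_id": trace.cell_id,
                "g1_duration": seg.g1_duration,
                "sg2m_duration": seg.sg2m_duration,
                "volume_at_budding": _volume_at_or_after(
                    trace.times, trace.volumes, seg.t_bud
                ),
                "bud_volume_at_karyokinesis": _volume_at_or_after(
                    trace.times, trace.bud_volumes, seg.t_end
                ),
            }
        )
    return out


def cross_correlation(a, b, max_lag: int, min_overlap: int = 10):
    """Pearson cross-correlation of two equally sampled series at integer
    frame lags in [-max_lag, max_lag].

    At lag k the pairs are (a[i], b[i+k]); a maximum at negative lag means
    b's features precede a's.  Lags with overlap below `min_overlap` are
    returned as NaN with a warning.  Returns (lags, cc).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be equal-length 1-D arrays")
    n = len(a)
    lags = np.arange(-max_lag, max_lag + 1)
    cc = np.full(len(lags), np.nan)
    skipped = []
    for j, k in enumerate(lags):
        if k >= 0:
            x, y = a[: n - k], b[k:]
        else:
            x, y = a[-k:], b[: n + k]
        if len(x) < min_overlap:
            skipped.append(int(k))
            continue
        xm = x - x.mean()
        ym = y - y.mean()
        denom = np.sqrt((xm @ xm) * (ym @ ym))
        if denom == 0:
            skipped.append(int(k))
            continue
        cc[j] = float(xm @ ym / denom)
    if skipped:
        warnings.warn(f"lags {skipped} omitted (insufficient overlap)", stacklevel=2)
    return lags, cc


def mean_cross_correlation(pairs, max_lag: int, min_overlap: int = 10):
    """Population cross-correlation: mean over per-cell curves (NaN-aware).

    `pairs` is an iterable of (series_a, series_b) per cell.  Returns
    (lags, mean_cc, lag_at_max).
    """
    curves = []
    lags = None
    for a, b in pairs:
        lags, cc = cross_correlation(a, b, max_lag, min_overlap)
        curves.append(cc)
    if not curves:
        raise ValueError("no cell pairs supplied")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_cc = np.nanmean(np.stack(curves), axis=0)
    if np.all(np.isnan(mean_cc)):
        raise ValueError("no lag had sufficient overlap in any cell")
    lag_at_max = int(lags[int(np.nanargmax(mean_cc))])
    return lags, mean_cc, lag_at_max


def mann_whitney_rb(sample_x, sample_y):
    """Two-tailed Mann-Whitney U test with rank-biserial effect size.

    U uses midranks for ties; P is exact when n1*n2 <= 400 and there are no
    cross-sample ties, otherwise the normal approximation with tie
    correction.  The effect size r = |1 - 2U/(n1*n2)| is reported as a
    magnitude in [0, 1].  Returns (U, P, r).
    """
    x = np.asarray(sample_x, dtype=float)
    y = np.asarray(sample_y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each sample needs at least 3 values")
    n1, n2 = len(x), len(y)
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        return n1 * n2 / 2.0, 1.0, 0.0
    has_ties = len(np.unique(np.concatenate([x, y]))) < n1 + n2
    method = "exact" if (n1 * n2 <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    U = float(res.statistic)
    r = abs(1.0 - 2.0 * U / (n1 * n2))
    return U, float(res.pvalue), r


def traces_to_matrix(traces) -> np.ndarray:
    """Stack traces sharing one time grid into an (M, T) array."""
    traces = list(traces)
    t0 = traces[0].times
    for tr in traces[1:]:
        if tr.times.shape != t0.shape or not np.allclose(tr.times, t0):
            raise ValueError("traces are not on a shared time grid")
    return np.stack([tr.values for tr in traces])
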