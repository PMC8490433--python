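"""Event idealization: from a current trace to a table of blockade events.

A docked sensing strand produces a static blockage level I_p; reversible
binding of a mobile analyte switches the current to a bound level I_b.  This
module estimates I_p from the all-points histogram (Gaussian fit of the
dominant mode, or of >= 500 static-blockage segment means), detects the
"further pore blockage" excursions by half-amplitude threshold crossing with
hysteresis, and annotates each event with its blockage amplitude
dI = I_b - I_p, dwell time t_off, inter-event interval t_on and level noise.
Multi-level events (e.g. protonation intermediates switching between I_b1
and I_b2) can additionally be segmented into sub-levels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats

from .errors import (
    AmbiguousBaselineError,
    ConfigurationError,
    DetectionError,
    InsufficientDataError,
    SublevelCollapseWarning,
)
from .simulate import RELOAD_STATE, SimulatedTrace

__all__ = [
    "BaselineEstimate",
    "DetectionSettings",
    "SubLevel",
    "EventRecord",
    "EventTable",
    "estimate_baseline",
    "baseline_from_segment_means",
    "detect_events",
    "annotate_events",
    "cycle_windows",
    "idealize_sublevels",
]


@dataclass(frozen=True)
class BaselineEstimate:
    """Gaussian-fitted static blockage level."""

    mean_Ip: float
    sd_Ip: float
    n_segments: int = 1
    method: str = "histogram"

    def __post_init__(self) -> None:
        if self.sd_Ip < 0:
            raise ConfigurationError("baseline SD must be >= 0")
        if self.n_segments < 1:
            raise ConfigurationError("n_segments must be >= 1")


@dataclass(frozen=True)
class DetectionSettings:
    """Threshold-crossing detection parameters.

    Events are entered when the signal crosses ``enter_frac`` of the nominal
    amplitude away from baseline and exited when it returns within
    ``exit_frac`` (hysteresis).  Events shorter than ``min_duration_s``
    (default 3 samples at 25 kHz) are discarded.  ``threshold_sd_mult`` is
    the minimum acceptable ratio of half-amplitude to baseline noise.
    """

    enter_frac: float = 0.5
    exit_frac: float = 0.25
    min_duration_s: float = 1.2e-4
    threshold_sd_mult: float = 3.0
    compensate_filter_delay: bool = True
    guard_time_constants: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.exit_frac < self.enter_frac <= 1):
            raise ConfigurationError("need 0 < exit_frac < enter_frac <= 1")
        if self.min_duration_s < 0:
            raise ConfigurationError("min_duration_s must be >= 0")


@dataclass(frozen=True)
class SubLevel:
    level: int
    t_start: float
    t_end: float
    mean: float


@dataclass(frozen=True)
class EventRecord:
    """One blockade event, in 0-based half-open sample coordinates."""

    start: int
    end: int
    t_off: float
    t_on: float  # NaN for the first event of a cycle
    cycle: int = 0
    delta_I: float = math.nan
    level_sd: float = math.nan
    mean_level: float = math.nan
    label: str | None = None
    sublevels: tuple[SubLevel, ...] | None = None
    transition_counts: pd.DataFrame | None = None
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ConfigurationError("event must have start < end")
        if not self.t_off > 0:
            raise ConfigurationError("t_off must be > 0")


@dataclass
class EventTable:
    """Time-ordered, non-overlapping events plus provenance."""

    events: list[EventRecord]
    baseline: BaselineEstimate | None = None
    sampling_rate: float = 25_000.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        prev_end: dict[int, int] = {}
        prev_all = -1
        for ev in self.events:
            if ev.start < prev_end.get(ev.cycle, -1) or ev.start < prev_all:
                raise ConfigurationError("events overlap or are out of order")
            prev_end[ev.cycle] = ev.end
            prev_all = ev.end

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __getitem__(self, i: int) -> EventRecord:
        return self.events[i]

    def to_dataframe(self) -> pd.DataFrame:
        fs = self.sampling_rate
        rows = [
            {
                "event_id": i,
                "cycle": ev.cycle,
                "start_s": ev.start / fs,
                "end_s": ev.end / fs,
                "t_off_s": ev.t_off,
                "t_on_s": ev.t_on,
                "delta_I_pA": ev.delta_I,
                "level_sd_pA": ev.level_sd,
                "label": "" if ev.label is None else ev.label,
            }
            for i, ev in enumerate(self.events)
        ]
        cols = [
            "event_id",
            "cycle",
            "start_s",
            "end_s",
            "t_off_s",
            "t_on_s",
            "delta_I_pA",
            "level_sd_pA",
            "label",
        ]
        return pd.DataFrame(rows, columns=cols)

    def dwell_times(self) -> np.ndarray:
        return np.array([ev.t_off for ev in self.events])

    def interevent_intervals(self) -> np.ndarray:
        vals = np.array([ev.t_on for ev in self.events])
        return vals[np.isfinite(vals)]


def _gaussian(x, amp, mu, sd):
    return amp * np.exp(-0.5 * ((x - mu) / sd) ** 2)


def estimate_baseline(
    trace: SimulatedTrace | np.ndarray,
    *,
    bins: int = 256,
    min_baseline_samples: int = 1000,
    mode_tie_ratio: float = 0.8,
) -> BaselineEstimate:
    """Estimate I_p from the all-points histogram of a trace.

    The dominant histogram mode is fitted with a Gaussian; the fit centre
    gives the mean blockage level and the fit width its SD.  If a second,
    well-separated mode rivals the dominant one (height ratio above
    ``mode_tie_ratio``) the estimate is ambiguous and the level must be
    chosen manually.
    """
    samples = np.asarray(getattr(trace, "samples", trace), dtype=float)
    if samples.size < min_baseline_samples:
        raise InsufficientDataError(
            f"need >= {min_baseline_samples} samples for a baseline estimate"
        )
    counts, edges = np.histogram(samples, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    peak = int(np.argmax(counts))

    # rival-mode check: a second prominent mode of comparable height to the
    # dominant one signals a bimodal tie
    smooth = np.convolve(counts.astype(float), np.ones(5) / 5.0, mode="same")
    peaks, _ = signal.find_peaks(smooth, prominence=0.25 * smooth.max())
    if peaks.size >= 2:
        heights = np.sort(smooth[peaks])[::-1]
        if heights[1] >= mode_tie_ratio * heights[0]:
            raise AmbiguousBaselineError(
                "all-points histogram is bimodal; choose the blockage level manually"
            )

    mode_center = centers[peak]
    bin_width = edges[1] - edges[0]
    near = samples[np.abs(samples - mode_center) <= bin_width]
    if near.size and float(np.std(near)) < 1e-9:
        # (near-)noiseless trace: the mode is a delta function
        return BaselineEstimate(float(np.mean(near)), 0.0, 1, "histogram")

    # rough width from the half-height extent of the dominant mode
    half = counts[peak] / 2.0
    lo_edge = peak
    while lo_edge > 0 and counts[lo_edge - 1] >= half:
        lo_edge -= 1
    hi_edge = peak
    while hi_edge < len(counts) - 1 and counts[hi_edge + 1] >= half:
        hi_edge += 1
    fwhm = (hi_edge - lo_edge + 1) * bin_width
    rough_sd = max(fwhm / 2.355, bin_width)
    window = np.abs(centers - mode_center) <= 5 * rough_sd
    x, y = centers[window], counts[window].astype(float)
    try:
        popt, _ = optimize.curve_fit(
            _gaussian, x, y, p0=[counts[peak], mode_center, rough_sd], maxfev=10_000
        )
        mu, sd = float(popt[1]), abs(float(popt[2]))
    except RuntimeError:
        sel = np.abs(samples - mode_center) <= 4 * rough_sd
        mu, sd = float(np.mean(samples[sel])), float(np.std(samples[sel]))
    return BaselineEstimate(mu, sd, 1, "histogram")


def baseline_from_segment_means(means: Sequence[float]) -> BaselineEstimate:
    """Gaussian fit of static-blockage segment means (>= 500 recommended).

    Mirrors the static pore-blockage protocol: the mean blockage level of
    each capture cycle is collected and the set is fitted to a Gaussian
    whose central position gives the mean I_p.
    """
    vals = np.asarray(means, dtype=float)
    if vals.size < 2:
        raise InsufficientDataError("need >= 2 segment means")
    mu, sd = stats.norm.fit(vals)
    return BaselineEstimate(float(mu), float(sd), int(vals.size), "segment-means")


def cycle_windows(trace: SimulatedTrace) -> list[tuple[int, int, int]]:
    """(start, end, cycle) sample windows excluding reload dead time."""
    n = trace.samples.size
    fs = trace.sampling_rate
    if trace.truth is None:
        return [(0, n, 0)]
    windows: list[tuple[int, int, int]] = []
    cur_cycle, cur_start = None, None
    for seg in trace.truth.segments:
        if seg.state == RELOAD_STATE:
            continue
        if cur_cycle != seg.cycle:
            if cur_cycle is not None:
                windows.append((cur_start, min(int(round(prev_end * fs)), n), cur_cycle))
            cur_cycle, cur_start = seg.cycle, int(round(seg.t_start * fs))
        prev_end = seg.t_end
    if cur_cycle is not None:
        windows.append((cur_start, min(int(round(prev_end * fs)), n), cur_cycle))
    return windows


def detect_events(
    trace: SimulatedTrace,
    baseline: BaselineEstimate,
    nominal_delta_I: float,
    settings: DetectionSettings | None = None,
    *,
    annotate: bool = True,
) -> EventTable:
    """Half-amplitude threshold detection with hysteresis.

    The event is entered when the current crosses ``baseline +
    enter_frac * nominal_delta_I`` (in the direction of the excursion) and
    exited when it recrosses ``exit_frac``.  Events shorter than
    ``min_duration_s`` are discarded; ``t_on`` is the gap to the previous
    event within the same cycle.  When the trace records that a causal
    analog filter was applied, boundaries are shifted back by the filter's
    group delay.
    """
    settings = settings or DetectionSettings()
    if nominal_delta_I == 0:
        raise ConfigurationError("nominal_delta_I must be nonzero")
    half = abs(nominal_delta_I) * settings.enter_frac
    if baseline.sd_Ip > 0 and half < settings.threshold_sd_mult * baseline.sd_Ip:
        raise DetectionError(
            f"detection threshold {half:.3g} pA lies inside the baseline noise band "
            f"({settings.threshold_sd_mult} x sd_Ip = "
            f"{settings.threshold_sd_mult * baseline.sd_Ip:.3g} pA)"
        )

    fs = trace.sampling_rate
    # normalize so the excursion is positive with unit nominal amplitude
    s = (trace.samples - baseline.mean_Ip) / nominal_delta_I
    min_samples = max(1, int(round(settings.min_duration_s * fs)))
    delay = 0
    if settings.compensate_filter_delay and trace.filter_applied:
        delay = int(round(trace.acquisition.group_delay_samples()))

    records: list[EventRecord] = []
    for w_start, w_end, cycle in cycle_windows(trace):
        sw = s[w_start:w_end]
        if sw.size == 0:
            continue
        above = sw >= settings.enter_frac
        below = sw < settings.exit_frac
        enters = np.flatnonzero(above[1:] & ~above[:-1]) + 1
        if above[0]:
            enters = np.concatenate(([0], enters))
        below_idx = np.flatnonzero(below)
        prev_end_local = None
        pos = -1
        for e in enters:
            if e <= pos:
                continue
            k = np.searchsorted(below_idx, e)
            x_end = int(below_idx[k]) if k < below_idx.size else sw.size
            pos = x_end
            start, end = int(e), int(x_end)
            if end - start < min_samples:
                continue
            g_start = max(w_start, w_start + start - delay)
            g_end = max(g_start + 1, w_start + end - delay)
            t_on = math.nan if prev_end_local is None else (start - prev_end_local) / fs
            records.append(
                EventRecord(
                    start=g_start,
                    end=g_end,
                    t_off=(end - start) / fs,
                    t_on=t_on,
                    cycle=cycle,
                )
            )
            prev_end_local = end

    table = EventTable(
        events=records,
        baseline=baseline,
        sampling_rate=fs,
        provenance={
            "nominal_delta_I_pA": nominal_delta_I,
            "enter_frac": settings.enter_frac,
            "exit_frac": settings.exit_frac,
            "min_duration_s": settings.min_duration_s,
            "filter_delay_samples": delay,
        },
    )
    if annotate:
        table = annotate_events(trace, table, settings=settings)
    return table


def _guard_samples(trace: SimulatedTrace, settings: DetectionSettings) -> int:
    corner = trace.acquisition.analog_corner
    if not trace.filter_applied or corner is None:
        return 1
    tau = 1.0 / (2 * math.pi * corner)
    return max(1, int(math.ceil(settings.guard_time_constants * tau * trace.sampling_rate)))


def annotate_events(
    trace: SimulatedTrace,
    table: EventTable,
    settings: DetectionSettings | None = None,
) -> EventTable:
    """Fill per-event amplitude and level-noise statistics.

    ``delta_I`` = (event mean level) - I_p, so positive-going events (bound
    level above baseline) get delta_I > 0 and negative-going events get
    delta_I < 0.  One analog-filter time constant is trimmed from each event
    edge before computing level statistics; events too short for the guard
    bands use the full window and are flagged.
    """
    settings = settings or DetectionSettings()
    if table.baseline is None:
        raise ConfigurationError("event table has no baseline estimate")
    guard = _guard_samples(trace, settings)
    mean_ip = table.baseline.mean_Ip
    out: list[EventRecord] = []
    for ev in table.events:
        lo, hi = ev.start + guard, ev.end - guard
        flags = set(ev.flags)
        if hi - lo < 2:
            lo, hi = ev.start, ev.end
            flags.add("short_for_guard")
        window = trace.samples[lo:hi]
        mean_level = float(np.mean(window))
        out.append(
            replace(
                ev,
                delta_I=mean_level - mean_ip,
                level_sd=float(np.std(window)),
                mean_level=mean_level,
                flags=frozenset(flags),
            )
        )
    return EventTable(out, table.baseline, table.sampling_rate, dict(table.provenance))


def idealize_sublevels(
    trace: SimulatedTrace,
    event: EventRecord,
    n_levels: int,
    baseline: BaselineEstimate,
    *,
    median_kernel: int = 5,
    min_run_samples: int = 3,
    separation_sd_mult: float = 2.0,
    seed: int = 0,
) -> EventRecord:
    """Segment an event's bound region into discrete sub-levels.

    The bound-region samples are median filtered and clustered into
    ``n_levels`` candidate levels (k-means); adjacent levels closer than
    ``separation_sd_mult`` times the within-level noise are merged (with a
    warning).  Samples are then assigned by mid-level thresholds and runs
    shorter than ``min_run_samples`` absorbed into their neighbours.  The
    transition-count matrix includes entry from and exit to the baseline.
    """
    if n_levels not in (1, 2, 3):
        raise ConfigurationError("n_levels must be 1, 2 or 3")
    window = trace.samples[event.start : event.end]
    if window.size < 2 * min_run_samples:
        raise InsufficientDataError("event too short for sub-level segmentation")
    filt = signal.medfilt(window, kernel_size=min(median_kernel, 2 * (window.size // 2) - 1))

    from sklearn.cluster import KMeans

    k = min(n_levels, window.size)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(filt.reshape(-1, 1))
    centers = np.sort(km.cluster_centers_.ravel())

    # robust within-level noise from first differences of the raw window
    # (median |diff| of white noise = 0.9539 sigma; jumps barely move it)
    level_noise = float(np.median(np.abs(np.diff(window))) / 0.9539)

    merged = [centers[0]]
    collapsed = False
    for c in centers[1:]:
        if c - merged[-1] < separation_sd_mult * max(level_noise, 1e-12):
            merged[-1] = 0.5 * (merged[-1] + c)
            collapsed = True
        else:
            merged.append(c)
    centers = np.array(merged)
    if collapsed:
        warnings.warn(
            f"requested {n_levels} sub-levels not supported by the data; "
            f"collapsed to {len(centers)}",
            SublevelCollapseWarning,
            stacklevel=2,
        )

    thresholds = 0.5 * (centers[:-1] + centers[1:])
    labels = np.searchsorted(thresholds, filt)

    # absorb short runs into the previous level
    runs: list[list[int]] = []  # [label, start, end)
    for i, lab in enumerate(labels):
        if runs and runs[-1][0] == lab:
            runs[-1][2] = i + 1
        else:
            runs.append([int(lab), i, i + 1])
    cleaned: list[list[int]] = []
    for run in runs:
        if cleaned and (run[2] - run[1]) < min_run_samples:
            cleaned[-1][2] = run[2]
        elif cleaned and cleaned[-1][0] == run[0]:
            cleaned[-1][2] = run[2]
        else:
            cleaned.append(run)
    # re-merge neighbours equalized by the absorption pass
    final: list[list[int]] = []
    for run in cleaned:
        if final and final[-1][0] == run[0]:
            final[-1][2] = run[2]
        else:
            final.append(run)

    fs = trace.sampling_rate
    t0 = event.start / fs
    subs = tuple(
        SubLevel(
            level=run[0] + 1,
            t_start=t0 + run[1] / fs,
            t_end=t0 + run[2] / fs,
            mean=float(np.mean(window[run[1] : run[2]])),
        )
        for run in final
    )

    names = ["I_p"] + [f"I_b{j + 1}" for j in range(len(centers))]
    counts = pd.DataFrame(0, index=names, columns=names, dtype=int)
    seq = ["I_p"] + [f"I_b{run[0] + 1}" for run in final] + ["I_p"]
    for a, b in zip(seq[:-1], seq[1:]):
        counts.loc[a, b] += 1
    return replace(event, sublevels=subs, transition_counts=counts)
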