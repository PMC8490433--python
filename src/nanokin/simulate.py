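"""Ground-truth-annotated synthetic current traces.

The generator is split in two: :func:`sample_state_path` draws a
continuous-time Markov (Gillespie) path through a :class:`~nanokin.schemes.
KineticScheme`, and :func:`render_trace` turns a path into a sampled current
record with baseline white noise, state-dependent extra noise (broadband or
secondary telegraph flicker) and an emulation of the analog acquisition
filter.  Every downstream stage (idealization, kinetics, classification) can
therefore be tested against exact ground truth.

Higher-level drivers build on those two: concentration titrations, runs with
an irreversible (absorbing) reaction and voltage-reload cycles, and
multi-analyte mixtures with per-event class labels.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SingleCycleWarning
from .schemes import AcquisitionSettings, KineticScheme, NoiseModel

__all__ = [
    "RELOAD_STATE",
    "PathSegment",
    "GroundTruthPath",
    "SimulatedTrace",
    "sample_state_path",
    "render_trace",
    "simulate_trace",
    "simulate_concentration_series",
    "simulate_irreversible_run",
    "simulate_mixture",
]

#: Reserved state name for the dead time between voltage-reload cycles.
RELOAD_STATE = "_reload"


@dataclass(frozen=True)
class PathSegment:
    state: str
    t_start: float
    t_end: float
    cycle: int = 0

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class GroundTruthPath:
    """Contiguous, non-overlapping state intervals covering [0, duration]."""

    segments: tuple[PathSegment, ...]

    def __post_init__(self) -> None:
        segs = tuple(self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ConfigurationError("path has no segments")
        t = segs[0].t_start
        if abs(t) > 1e-12:
            raise ConfigurationError("path must start at t = 0")
        for seg in segs:
            if seg.t_end < seg.t_start:
                raise ConfigurationError("segment with negative duration")
            if abs(seg.t_start - t) > 1e-9:
                raise ConfigurationError("path segments are not contiguous")
            t = seg.t_end

    @property
    def duration(self) -> float:
        return self.segments[-1].t_end

    @property
    def n_cycles(self) -> int:
        return max(s.cycle for s in self.segments) + 1

    def state_indices(self, sampling_rate: float, n_samples: int) -> np.ndarray:
        """Index into ``self.states`` of the state occupied at each sample.

        Sample ``i`` reads the state at time ``i / sampling_rate`` (intervals
        are half-open on the right).
        """
        ends = np.array([s.t_end for s in self.segments])
        times = np.arange(n_samples) / sampling_rate
        idx = np.searchsorted(ends, times, side="right")
        return np.minimum(idx, len(self.segments) - 1)

    def events(self, baseline_state: str, exclude: frozenset[str] = frozenset()) -> list[PathSegment]:
        """Segments that are binding events (not baseline/reload/excluded)."""
        skip = {baseline_state, RELOAD_STATE} | set(exclude)
        return [s for s in self.segments if s.state not in skip]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "state": [s.state for s in self.segments],
                "t_start_s": [s.t_start for s in self.segments],
                "t_end_s": [s.t_end for s in self.segments],
                "cycle": [s.cycle for s in self.segments],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GroundTruthPath":
        segs = tuple(
            PathSegment(str(r.state), float(r.t_start_s), float(r.t_end_s), int(r.cycle))
            for r in df.itertuples()
        )
        return cls(segs)


@dataclass
class SimulatedTrace:
    """A sampled current record plus its provenance.

    ``samples`` are in pA; ``truth`` is the generating state path when the
    trace is synthetic.  ``filter_applied`` records whether the analog-filter
    emulation ran, so detection can compensate its group delay.
    """

    samples: np.ndarray
    acquisition: AcquisitionSettings
    truth: GroundTruthPath | None = None
    state_means: dict[str, float] = field(default_factory=dict)
    concentration: float = 0.0
    temperature: float = 294.15
    voltage: float = 180.0
    seed: int | None = None
    filter_applied: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ConfigurationError("trace samples must be one-dimensional")

    @property
    def sampling_rate(self) -> float:
        return self.acquisition.sampling_rate

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate


def _spawn_seeds(seed, n: int) -> list[np.random.SeedSequence]:
    if isinstance(seed, np.random.SeedSequence):
        return seed.spawn(n)
    return np.random.SeedSequence(seed).spawn(n)


def sample_state_path(
    scheme: KineticScheme,
    concentration: float,
    duration: float,
    seed=None,
    *,
    start_state: str | None = None,
    cycle: int = 0,
) -> GroundTruthPath:
    """Draw one continuous-time Markov path through the scheme.

    Dwell times in each state are exponential with that state's total exit
    rate; concentration-coupled rates are scaled by ``concentration`` (mol/L).
    The path ends at ``duration`` or, on entering an absorbing state, stays
    there for the remaining time.
    """
    if duration <= 0:
        raise ConfigurationError("duration must be > 0")
    if concentration < 0:
        raise ConfigurationError("concentration must be >= 0")
    rng = np.random.default_rng(seed)
    state = start_state if start_state is not None else scheme.baseline_state
    if state not in scheme.states:
        raise ConfigurationError(f"unknown start state {state!r}")

    segments: list[PathSegment] = []
    t = 0.0
    end = duration
    while t < end:
        exits = scheme.exit_rates(state, concentration)
        total = sum(r for _, r in exits)
        if state in scheme.absorbing_states or total <= 0.0:
            segments.append(PathSegment(state, t, end, cycle))
            break
        dwell = rng.exponential(1.0 / total)
        t_next = min(t + dwell, end)
        segments.append(PathSegment(state, t, t_next, cycle))
        if t_next >= end:
            break
        targets, rates = zip(*exits)
        probs = np.array(rates) / total
        state = targets[rng.choice(len(targets), p=probs)]
        t = t_next
    return GroundTruthPath(tuple(segments))


def _telegraph_wave(
    n: int, sampling_rate: float, amplitude: float, rate_up: float, rate_down: float, rng
) -> np.ndarray:
    """Zero-mean two-level flicker of peak-to-peak ``amplitude`` over n samples."""
    out = np.empty(n)
    half = amplitude / 2.0
    up = rng.random() < 0.5
    i = 0
    while i < n:
        rate = rate_down if up else rate_up  # exit rate of the current level
        if rate <= 0:
            out[i:] = half if up else -half
            break
        dwell = rng.exponential(1.0 / rate)
        j = min(n, i + max(1, int(round(dwell * sampling_rate))))
        out[i:j] = half if up else -half
        up = not up
        i = j
    return out


def render_trace(
    path: GroundTruthPath,
    scheme: KineticScheme | Mapping[str, float],
    noise: NoiseModel,
    acq: AcquisitionSettings,
    seed=None,
    *,
    apply_filter: bool | None = None,
    concentration: float = 0.0,
    temperature: float = 294.15,
    voltage: float = 180.0,
) -> SimulatedTrace:
    """Render a state path into a sampled, noisy, filtered current trace.

    Per-sample current = occupying state's mean + baseline white noise +
    state-specific extra noise, then passed through the analog-filter
    emulation (unless disabled).  With all noise terms zero and the filter
    off, the output is exactly the piecewise-constant state-mean signal.
    """
    means_map = dict(scheme.states) if isinstance(scheme, KineticScheme) else dict(scheme)
    if RELOAD_STATE not in means_map:
        if isinstance(scheme, KineticScheme) and scheme.open_pore_state is not None:
            means_map[RELOAD_STATE] = means_map[scheme.open_pore_state]
        else:
            base = (
                means_map[scheme.baseline_state]
                if isinstance(scheme, KineticScheme)
                else next(iter(means_map.values()))
            )
            means_map[RELOAD_STATE] = base

    n = int(round(path.duration * acq.sampling_rate))
    if n <= 0:
        raise ConfigurationError("path too short for the sampling rate")
    idx = path.state_indices(acq.sampling_rate, n)
    seg_states = [s.state for s in path.segments]
    for st in seg_states:
        if st not in means_map:
            raise ConfigurationError(f"no mean current configured for state {st!r}")
    seg_means = np.array([means_map[s] for s in seg_states])
    current = seg_means[idx]

    rng = np.random.default_rng(seed)
    if noise.baseline_sd > 0:
        current = current + rng.normal(0.0, noise.baseline_sd, n)
    for state_name, extra in noise.state_noise.items():
        in_state = np.array([s == state_name for s in seg_states])[idx]
        n_in = int(in_state.sum())
        if n_in == 0:
            continue
        if extra.broadband_sd > 0:
            current[in_state] += rng.normal(0.0, extra.broadband_sd, n_in)
        if extra.telegraph is not None and extra.telegraph.amplitude > 0:
            for k, seg in enumerate(path.segments):
                if seg.state != state_name:
                    continue
                sel = np.flatnonzero(idx == k)
                if sel.size == 0:
                    continue
                current[sel] += _telegraph_wave(
                    sel.size,
                    acq.sampling_rate,
                    extra.telegraph.amplitude,
                    extra.telegraph.rate_up,
                    extra.telegraph.rate_down,
                    rng,
                )

    use_filter = acq.analog_corner is not None if apply_filter is None else apply_filter
    if use_filter and acq.analog_corner is None:
        raise ConfigurationError("cannot apply filter: no analog corner configured")
    if use_filter:
        from scipy import signal

        sos = acq.filter_sos()
        zi = signal.sosfilt_zi(sos) * current[0]
        current, _ = signal.sosfilt(sos, current, zi=zi)

    return SimulatedTrace(
        samples=current,
        acquisition=acq,
        truth=path,
        state_means=means_map,
        concentration=concentration,
        temperature=temperature,
        voltage=voltage,
        seed=seed if isinstance(seed, int) else None,
        filter_applied=bool(use_filter),
    )


def simulate_trace(
    scheme: KineticScheme,
    concentration: float,
    noise: NoiseModel,
    acq: AcquisitionSettings,
    seed=None,
    *,
    apply_filter: bool | None = None,
    temperature: float = 294.15,
    voltage: float = 180.0,
) -> SimulatedTrace:
    """Sample a path and render it, with sub-seeds derived from ``seed``."""
    s_path, s_noise = _spawn_seeds(seed, 2)
    path = sample_state_path(scheme, concentration, acq.duration, s_path)
    trace = render_trace(
        path,
        scheme,
        noise,
        acq,
        s_noise,
        apply_filter=apply_filter,
        concentration=concentration,
        temperature=temperature,
        voltage=voltage,
    )
    trace.seed = seed if isinstance(seed, int) else None
    return trace


def simulate_concentration_series(
    scheme: KineticScheme,
    concentrations: Sequence[float],
    noise: NoiseModel,
    acq: AcquisitionSettings,
    seed=None,
    *,
    apply_filter: bool | None = None,
) -> list[SimulatedTrace]:
    """One trace per concentration; per-trace seeds derived from the master.

    Repeated calls with the same master seed and configuration produce
    bit-identical traces.
    """
    if len(concentrations) == 0:
        raise ConfigurationError("concentration list is empty")
    if len(concentrations) > 1 and len(set(concentrations)) < 2:
        raise ConfigurationError("need at least 2 distinct concentrations")
    subseeds = _spawn_seeds(seed, len(concentrations))
    return [
        simulate_trace(scheme, c, noise, acq, ss, apply_filter=apply_filter)
        for c, ss in zip(concentrations, subseeds)
    ]


def simulate_irreversible_run(
    scheme: KineticScheme,
    concentration: float,
    noise: NoiseModel,
    acq: AcquisitionSettings,
    seed=None,
    *,
    reload_times: Sequence[float] | None = None,
    reload_on_absorption: bool = False,
    detection_delay: float = 1.0,
    dead_time: float = 1.0,
    apply_filter: bool | None = None,
) -> SimulatedTrace:
    """Simulate an irreversible reaction with voltage-reload cycles.

    After the path enters an absorbing state (e.g. oxidative loss of the
    reactive group) no further events occur until the next reload.  A reload
    ejects and recaptures the sensing strand: the path restarts in the
    baseline state, the cycle index increments, and a fixed ``dead_time``
    (default 1 s) of open-pore/reload signal separates the cycles.

    ``reload_times`` gives a fixed schedule (k reload times -> k+1 cycles);
    alternatively ``reload_on_absorption`` reloads ``detection_delay``
    seconds after each absorption.
    """
    reachable_absorbing = any(
        e.target in scheme.absorbing_states and e.rate > 0 for e in scheme.rates
    )
    if not scheme.absorbing_states or not reachable_absorbing:
        raise ConfigurationError("scheme has no reachable absorbing state")
    if reload_times is None and not reload_on_absorption:
        warnings.warn(
            "no reload schedule or rule given; simulating a single cycle",
            SingleCycleWarning,
            stacklevel=2,
        )

    duration = acq.duration
    rng_path, rng_noise = _spawn_seeds(seed, 2)
    rng = np.random.default_rng(rng_path)
    segments: list[PathSegment] = []

    def run_cycle(t0: float, t1: float, cycle: int) -> float | None:
        """Simulate one cycle on [t0, t1); return absorption time or None."""
        t = t0
        state = scheme.baseline_state
        absorbed_at = None
        while t < t1:
            exits = scheme.exit_rates(state, concentration)
            total = sum(r for _, r in exits)
            if state in scheme.absorbing_states or total <= 0.0:
                if state in scheme.absorbing_states and absorbed_at is None:
                    absorbed_at = t
                segments.append(PathSegment(state, t, t1, cycle))
                break
            dwell = rng.exponential(1.0 / total)
            t_next = min(t + dwell, t1)
            segments.append(PathSegment(state, t, t_next, cycle))
            if t_next >= t1:
                break
            targets, rates = zip(*exits)
            state = targets[rng.choice(len(targets), p=np.array(rates) / total)]
            t = t_next
        return absorbed_at

    if reload_on_absorption and reload_times is None:
        t = 0.0
        cycle = 0
        while t < duration:
            absorbed_at = run_cycle(t, duration, cycle)
            if absorbed_at is None:
                break
            reload_at = min(absorbed_at + detection_delay, duration)
            # truncate the trailing absorbed segment at the reload moment
            last = segments[-1]
            segments[-1] = PathSegment(last.state, last.t_start, reload_at, cycle)
            if reload_at >= duration:
                break
            gap_end = min(reload_at + dead_time, duration)
            cycle += 1
            segments.append(PathSegment(RELOAD_STATE, reload_at, gap_end, cycle))
            t = gap_end
    else:
        times = sorted(t for t in (reload_times or []) if 0 < t < duration)
        t = 0.0
        for cycle, r in enumerate(times):
            if r <= t:
                continue
            run_cycle(t, r, cycle)
            gap_end = min(r + dead_time, duration)
            segments.append(PathSegment(RELOAD_STATE, r, gap_end, cycle + 1))
            t = gap_end
            if t >= duration:
                break
        if t < duration:
            run_cycle(t, duration, len(times))

    path = GroundTruthPath(tuple(segments))
    trace = render_trace(
        path,
        scheme,
        noise,
        acq,
        rng_noise,
        apply_filter=apply_filter,
        concentration=concentration,
    )
    trace.seed = seed if isinstance(seed, int) else None
    return trace


def _two_state_parts(scheme: KineticScheme) -> tuple[float, str, float, float]:
    """Extract (k_on, bound state, bound mean, k_off) from a two-state scheme."""
    on = [e for e in scheme.rates if e.source == scheme.baseline_state and e.concentration_coupled]
    if len(on) != 1:
        raise ConfigurationError("mixture component must have exactly one association rate")
    bound = on[0].target
    off = [e for e in scheme.rates if e.source == bound and e.target == scheme.baseline_state]
    if len(off) != 1:
        raise ConfigurationError("mixture component must have exactly one dissociation rate")
    return on[0].rate, bound, scheme.states[bound], off[0].rate


def simulate_mixture(
    schemes: Mapping[str, KineticScheme],
    proportions: Mapping[str, float],
    concentration: float,
    noise: NoiseModel,
    acq: AcquisitionSettings,
    seed=None,
    *,
    apply_filter: bool | None = None,
) -> tuple[SimulatedTrace, list[str]]:
    """Simulate a multi-analyte mixture sharing one baseline level.

    Each binding event's class is drawn independently from ``proportions``;
    the waiting time between events follows the proportion-weighted total
    association rate.  Ground-truth event states are named ``bound:<label>``
    and the per-event label list is returned alongside the trace, so a
    classifier can be scored against truth.

    Per-class noise signatures are configured on the shared ``noise`` model
    under the ``bound:<label>`` state names.
    """
    labels = list(schemes)
    if not labels:
        raise ConfigurationError("no mixture components")
    if set(proportions) != set(labels):
        raise ConfigurationError("proportions must cover exactly the scheme labels")
    p = np.array([proportions[lbl] for lbl in labels], dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ConfigurationError("proportions must be >= 0 and sum to 1")

    parts = {lbl: _two_state_parts(schemes[lbl]) for lbl in labels}
    baselines = {lbl: schemes[lbl].states[schemes[lbl].baseline_state] for lbl in labels}
    if len(set(baselines.values())) != 1:
        raise ConfigurationError("mixture components must share the baseline level")
    i_p = next(iter(baselines.values()))

    total_on = concentration * float(sum(proportions[lbl] * parts[lbl][0] for lbl in labels))
    rng_path, rng_noise = _spawn_seeds(seed, 2)
    rng = np.random.default_rng(rng_path)

    segments: list[PathSegment] = []
    event_labels: list[str] = []
    duration = acq.duration
    t = 0.0
    while t < duration:
        if total_on <= 0:
            segments.append(PathSegment("baseline", t, duration))
            break
        wait = rng.exponential(1.0 / total_on)
        t_on_end = min(t + wait, duration)
        segments.append(PathSegment("baseline", t, t_on_end))
        if t_on_end >= duration:
            break
        lbl = labels[rng.choice(len(labels), p=p)]
        k_off = parts[lbl][3]
        dwell = rng.exponential(1.0 / k_off) if k_off > 0 else duration
        t_off_end = min(t_on_end + dwell, duration)
        segments.append(PathSegment(f"bound:{lbl}", t_on_end, t_off_end))
        event_labels.append(lbl)
        t = t_off_end

    means = {"baseline": i_p}
    for lbl in labels:
        means[f"bound:{lbl}"] = parts[lbl][2]
    path = GroundTruthPath(tuple(segments))
    trace = render_trace(
        path, means, noise, acq, rng_noise, apply_filter=apply_filter, concentration=concentration
    )
    trace.seed = seed if isinstance(seed, int) else None
    return trace, event_labels
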