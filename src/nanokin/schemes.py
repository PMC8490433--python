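"""Kinetic schemes, noise models and acquisition settings.

A :class:`KineticScheme` is a continuous-time Markov chain over named
conductance states.  Each state carries a mean residual current (pA); each
directed rate entry carries a base rate in s^-1 that is optionally scaled by
the mobile-analyte concentration at simulation time (a "concentration
coupled" rate, i.e. a pseudo-first-order association step).  One state is
designated the event baseline — the static blockage level I_p of a docked
sensing strand — and states may be absorbing (irreversible chemistry, e.g.
oxidative loss of the reactive group).

The canonical instance is the two-state telegraph model of reversible
single-site binding::

    baseline --(k_on * c)--> bound      # bimolecular association
    bound    --(k_off)-----> baseline   # unimolecular dissociation

with equilibrium binding constant K_b = k_on / k_off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .errors import ConfigurationError

__all__ = [
    "RateEntry",
    "KineticScheme",
    "TelegraphNoise",
    "StateNoise",
    "NoiseModel",
    "AcquisitionSettings",
    "two_state_scheme",
    "three_level_scheme",
]


@dataclass(frozen=True)
class RateEntry:
    """One directed transition of the Markov chain.

    ``rate`` is in s^-1; if ``concentration_coupled`` the effective rate is
    ``rate * concentration`` with concentration in mol/L, so ``rate`` is then
    a second-order constant in M^-1 s^-1.
    """

    source: str
    target: str
    rate: float
    concentration_coupled: bool = False


@dataclass(frozen=True)
class KineticScheme:
    """Named conductance states plus transition rates.

    Parameters
    ----------
    states
        Mapping state name -> mean residual current in pA.
    rates
        Directed :class:`RateEntry` list.
    baseline_state
        The event baseline (static blockage level I_p).
    absorbing_states
        States with no exit; entering one ends all switching.
    open_pore_state
        Optional designated open-pore state (I_0); informational.
    """

    states: dict[str, float]
    rates: tuple[RateEntry, ...]
    baseline_state: str
    absorbing_states: frozenset[str] = frozenset()
    open_pore_state: str | None = None

    def __post_init__(self) -> None:
        if not self.states:
            raise ConfigurationError("scheme has no states")
        for name, mean in self.states.items():
            if not math.isfinite(mean):
                raise ConfigurationError(f"state {name!r} has non-finite mean current")
        if self.baseline_state not in self.states:
            raise ConfigurationError(
                f"baseline state {self.baseline_state!r} not among states"
            )
        if self.open_pore_state is not None and self.open_pore_state not in self.states:
            raise ConfigurationError(
                f"open-pore state {self.open_pore_state!r} not among states"
            )
        object.__setattr__(self, "rates", tuple(self.rates))
        object.__setattr__(self, "absorbing_states", frozenset(self.absorbing_states))
        for entry in self.rates:
            if entry.source not in self.states or entry.target not in self.states:
                raise ConfigurationError(
                    f"rate {entry.source!r}->{entry.target!r} references unknown state"
                )
            if not (entry.rate >= 0.0) or not math.isfinite(entry.rate):
                raise ConfigurationError(
                    f"rate {entry.source!r}->{entry.target!r} must be finite and >= 0"
                )
            if entry.source in self.absorbing_states and entry.rate > 0:
                raise ConfigurationError(
                    f"absorbing state {entry.source!r} has a nonzero exit rate"
                )
        for name in self.absorbing_states:
            if name not in self.states:
                raise ConfigurationError(f"absorbing state {name!r} not among states")

    # -- queries -----------------------------------------------------------

    def exit_rates(self, state: str, concentration: float) -> list[tuple[str, float]]:
        """Effective (target, rate) pairs out of ``state`` at a concentration."""
        if state not in self.states:
            raise ConfigurationError(f"unknown state {state!r}")
        if concentration < 0:
            raise ConfigurationError("concentration must be >= 0")
        out = []
        for e in self.rates:
            if e.source != state:
                continue
            r = e.rate * concentration if e.concentration_coupled else e.rate
            if r > 0:
                out.append((e.target, r))
        return out

    def mean_current(self, state: str) -> float:
        return self.states[state]

    def with_rate_scale(self, factor: float) -> "KineticScheme":
        """Scheme with every rate multiplied by ``factor`` (voltage-style hook)."""
        if factor < 0:
            raise ConfigurationError("rate scale factor must be >= 0")
        scaled = tuple(replace(e, rate=e.rate * factor) for e in self.rates)
        return replace(self, rates=scaled)


def two_state_scheme(
    i_p: float,
    i_b: float,
    k_on: float,
    k_off: float,
    *,
    bound_state: str = "bound",
    k_absorb: float = 0.0,
    absorbed_state: str = "terminated",
    absorbed_current: float | None = None,
) -> KineticScheme:
    """Reversible single-site binding, optionally with irreversible loss.

    ``k_on`` is the bimolecular association constant (M^-1 s^-1, applied as
    ``k_on * c``); ``k_off`` the unimolecular dissociation rate (s^-1).  If
    ``k_absorb`` > 0 an absorbing state is reachable from the bound state
    (e.g. oxidation of the reactive group), after which the trace returns to
    a quiet baseline at ``absorbed_current`` (defaults to I_p, matching the
    fluctuation-free post-reaction baseline).
    """
    states = {"baseline": i_p, bound_state: i_b}
    rates = [
        RateEntry("baseline", bound_state, k_on, concentration_coupled=True),
        RateEntry(bound_state, "baseline", k_off),
    ]
    absorbing: frozenset[str] = frozenset()
    if k_absorb > 0:
        states[absorbed_state] = i_p if absorbed_current is None else absorbed_current
        rates.append(RateEntry(bound_state, absorbed_state, k_absorb))
        absorbing = frozenset({absorbed_state})
    return KineticScheme(
        states=states,
        rates=tuple(rates),
        baseline_state="baseline",
        absorbing_states=absorbing,
    )


def three_level_scheme(
    i_p: float,
    i_b1: float,
    i_b2: float,
    *,
    k_on1: float,
    k_off1: float,
    k_on2: float = 0.0,
    k_off2: float = 0.0,
    k_12: float = 0.0,
    k_21: float = 0.0,
) -> KineticScheme:
    """Baseline plus two bound sub-levels with dynamic switching.

    Models a bound adduct that interconverts between two conductance levels
    (e.g. protonated/deprotonated forms of a bound polyol): I_p <-> I_b1,
    optionally I_p <-> I_b2, and I_b1 <-> I_b2 exchange.
    """
    states = {"baseline": i_p, "bound1": i_b1, "bound2": i_b2}
    rates = [
        RateEntry("baseline", "bound1", k_on1, concentration_coupled=True),
        RateEntry("bound1", "baseline", k_off1),
    ]
    if k_on2 > 0:
        rates.append(RateEntry("baseline", "bound2", k_on2, concentration_coupled=True))
    if k_off2 > 0:
        rates.append(RateEntry("bound2", "baseline", k_off2))
    if k_12 > 0:
        rates.append(RateEntry("bound1", "bound2", k_12))
    if k_21 > 0:
        rates.append(RateEntry("bound2", "bound1", k_21))
    return KineticScheme(states=states, rates=tuple(rates), baseline_state="baseline")


@dataclass(frozen=True)
class TelegraphNoise:
    """Secondary two-level flicker superimposed on a state's mean current.

    A zero-mean square-wave of peak-to-peak ``amplitude`` pA whose up/down
    dwell times are exponential with ``rate_up``/``rate_down`` (s^-1).
    """

    amplitude: float
    rate_up: float
    rate_down: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ConfigurationError("telegraph amplitude must be >= 0")
        if self.rate_up < 0 or self.rate_down < 0:
            raise ConfigurationError("telegraph rates must be >= 0")


@dataclass(frozen=True)
class StateNoise:
    """Extra noise carried by one conductance state."""

    broadband_sd: float = 0.0
    telegraph: TelegraphNoise | None = None

    def __post_init__(self) -> None:
        if self.broadband_sd < 0:
            raise ConfigurationError("broadband SD must be >= 0")


@dataclass(frozen=True)
class NoiseModel:
    """White baseline noise plus per-state extra components.

    ``baseline_sd`` is the white-noise SD (pA) of the recording before any
    acquisition filtering; ``state_noise`` maps state names to extra
    broadband or secondary-telegraph components that switch on only while
    that state is occupied (the characteristic bound-state fluctuations).
    """

    baseline_sd: float = 0.0
    state_noise: dict[str, StateNoise] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.baseline_sd < 0:
            raise ConfigurationError("baseline SD must be >= 0")


@dataclass(frozen=True)
class AcquisitionSettings:
    """Digitisation and analog-filter emulation parameters.

    Defaults follow a patch-clamp acquisition chain: 25 kHz sampling with a
    4-pole low-pass Bessel filter at a 1 kHz corner.  ``analog_corner=None``
    disables the filter emulation.
    """

    sampling_rate: float = 25_000.0
    analog_corner: float | None = 1_000.0
    analog_filter_order: int = 4
    analog_filter_type: str = "bessel"
    duration: float = 1.0
    voltage_protocol: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling rate must be > 0")
        if self.duration <= 0:
            raise ConfigurationError("duration must be > 0")
        if self.analog_corner is not None:
            if not (0 < self.analog_corner < self.sampling_rate / 2):
                raise ConfigurationError(
                    "analog corner must lie in (0, sampling_rate/2)"
                )
        if self.analog_filter_order < 1:
            raise ConfigurationError("filter order must be >= 1")
        if self.analog_filter_type not in ("bessel", "butter"):
            raise ConfigurationError("filter type must be 'bessel' or 'butter'")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))

    def filter_sos(self):
        """Second-order sections of the analog-filter emulation, or None."""
        if self.analog_corner is None:
            return None
        from scipy import signal

        design = signal.bessel if self.analog_filter_type == "bessel" else signal.butter
        kwargs = {"norm": "mag"} if self.analog_filter_type == "bessel" else {}
        return design(
            self.analog_filter_order,
            self.analog_corner,
            btype="low",
            fs=self.sampling_rate,
            output="sos",
            **kwargs,
        )

    def group_delay_samples(self) -> float:
        """Low-frequency group delay of the causal analog filter, in samples."""
        sos = self.filter_sos()
        if sos is None:
            return 0.0
        import numpy as np
        from scipy import signal

        b, a = signal.sos2tf(sos)
        w = np.array([1e-4])
        _, gd = signal.group_delay((b, a), w=w)
        return float(gd[0])
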