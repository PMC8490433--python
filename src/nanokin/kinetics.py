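"""Binding kinetics from event tables.

The reversible single-site model behind all estimates::

    1 / tau_on  = k_on * c        (single-step bimolecular association)
    1 / tau_off = k_off           (unimolecular dissociation)
    K_b         = k_on / k_off    (equilibrium binding constant)

tau_on and tau_off are the mean inter-event interval and mean dwell time.
Dwell means are estimated by left-truncated exponential maximum likelihood
(tau = sample mean - t_min, the truncation point set by the detector's
minimum event duration); a histogram least-squares route is kept for parity
with conventional time-histogram fitting.  k_on is the slope of 1/tau_on
against concentration (weighted least squares), k_off the mean of 1/tau_off
across conditions, with a concentration-independence diagnostic.

Everything is also available through statsmodels-style model objects:
:class:`ExponentialDwellModel`, :class:`BindingKineticsModel` and
:class:`ArrheniusModel`, whose ``fit()`` methods return Results objects with
estimates, standard errors and a ``summary()`` table.

Units are mol/L, seconds and kelvin throughout; convert at the boundary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigurationError, InsufficientDataError, NegativeSlopeWarning

__all__ = [
    "GAS_CONSTANT",
    "DwellSet",
    "ExponentialFit",
    "KonEstimate",
    "KoffEstimate",
    "RateConstants",
    "ArrheniusFit",
    "LodEstimate",
    "fit_exponential_mle",
    "fit_exponential_histogram",
    "estimate_kon",
    "estimate_koff",
    "compute_Kb",
    "fit_arrhenius",
    "compute_lod",
    "ExponentialDwellModel",
    "ExponentialDwellResults",
    "BindingKineticsModel",
    "BindingKineticsResults",
    "ArrheniusModel",
    "ArrheniusResults",
]

GAS_CONSTANT = 8.314462618  # J / (mol K)


@dataclass(frozen=True)
class DwellSet:
    """Durations of one kind (dwell ``t_off`` or interval ``t_on``).

    ``t_min`` is the left-truncation point: no duration below it can have
    been observed (detector minimum event duration).
    """

    values: np.ndarray
    kind: str
    t_min: float = 0.0
    concentration: float = math.nan
    temperature: float = math.nan

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if self.kind not in ("t_off", "t_on"):
            raise ConfigurationError("kind must be 't_off' or 't_on'")
        if self.t_min < 0:
            raise ConfigurationError("t_min must be >= 0")
        if vals.size and np.any(vals < self.t_min):
            raise ConfigurationError("durations below the truncation point t_min")

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class ExponentialFit:
    """Fitted exponential time constant with its standard error."""

    tau: float
    se_tau: float
    n: int
    method: str = "mle"

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ConfigurationError("tau must be > 0")
        if self.se_tau < 0:
            raise ConfigurationError("se_tau must be >= 0")

    @property
    def rate(self) -> float:
        return 1.0 / self.tau

    @property
    def se_rate(self) -> float:
        return self.se_tau / self.tau**2


def _as_dwellset(dwells, kind="t_off", t_min=0.0) -> DwellSet:
    if isinstance(dwells, DwellSet):
        return dwells
    return DwellSet(np.asarray(dwells, dtype=float), kind, t_min)


def fit_exponential_mle(dwells, *, t_min: float | None = None) -> ExponentialFit:
    """Left-truncated exponential MLE of the mean dwell.

    For exponential data observed only above ``t_min`` the maximum-likelihood
    estimate is ``tau = mean(values) - t_min`` with SE ``tau / sqrt(n)``.
    """
    ds = _as_dwellset(dwells, t_min=t_min or 0.0)
    if t_min is not None and not isinstance(dwells, DwellSet):
        ds = DwellSet(ds.values, ds.kind, t_min)
    if ds.n < 5:
        raise InsufficientDataError(f"need >= 5 dwell times, got {ds.n}")
    tau = float(np.mean(ds.values)) - ds.t_min
    if tau <= 0:
        raise InsufficientDataError("mean dwell does not exceed the truncation point")
    return ExponentialFit(tau=tau, se_tau=tau / math.sqrt(ds.n), n=ds.n, method="mle")


def fit_exponential_histogram(
    dwells,
    n_bins: int = 30,
    *,
    binning: str = "linear",
) -> ExponentialFit:
    """Least-squares fit of an exponential density to a dwell-time histogram.

    Kept for parity with conventional time-histogram analysis; the MLE route
    is preferred, especially at small n.
    """
    ds = _as_dwellset(dwells)
    if ds.n < 30:
        raise InsufficientDataError(f"need >= 30 dwell times for a histogram fit, got {ds.n}")
    vals = ds.values
    lo, hi = float(vals.min()), float(vals.max())
    if not hi > lo:
        raise ConfigurationError("all dwell times fall in a single bin")
    if binning == "log":
        edges = np.geomspace(max(lo, 1e-12), hi, n_bins + 1)
    elif binning == "linear":
        edges = np.linspace(lo, hi, n_bins + 1)
    else:
        raise ConfigurationError("binning must be 'linear' or 'log'")
    counts, edges = np.histogram(vals, bins=edges)
    if np.count_nonzero(counts) < 2:
        raise ConfigurationError("all dwell times fall in a single bin")
    widths = np.diff(edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    density = counts / widths

    def model(t, amp, tau):
        return amp * np.exp(-t / tau)

    tau0 = max(float(np.mean(vals)) - ds.t_min, 1e-9)
    popt, pcov = optimize.curve_fit(
        model, centers, density, p0=[density.max() or 1.0, tau0], maxfev=10_000
    )
    tau = abs(float(popt[1]))
    se = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else tau / math.sqrt(ds.n)
    return ExponentialFit(tau=tau, se_tau=se, n=ds.n, method="histogram")


@dataclass(frozen=True)
class KonEstimate:
    """Association rate constant from the 1/tau_on titration line."""

    k_on: float  # M^-1 s^-1
    se: float
    intercept: float  # s^-1, diagnostic; ~0 for a single-step model
    se_intercept: float
    n_points: int
    flagged: bool = False


@dataclass(frozen=True)
class KoffEstimate:
    """Dissociation rate constant (mean of 1/tau_off) with diagnostics."""

    k_off: float  # s^-1
    se: float
    n_conditions: int
    conc_slope: float = math.nan  # d(1/tau_off)/dc, should be ~0
    conc_slope_se: float = math.nan
    conc_slope_pvalue: float = math.nan


@dataclass(frozen=True)
class RateConstants:
    """k_on, k_off and K_b = k_on/k_off with propagated uncertainties."""

    k_on: float
    se_k_on: float
    k_off: float
    se_k_off: float
    K_b: float
    se_K_b: float
    intercept: float = math.nan
    se_intercept: float = math.nan

    def __post_init__(self) -> None:
        if self.k_off > 0 and self.k_on > 0:
            if not math.isclose(self.K_b, self.k_on / self.k_off, rel_tol=1e-9):
                raise ConfigurationError("K_b must equal k_on / k_off")


def estimate_kon(
    series: Sequence[tuple[float, ExponentialFit]],
    *,
    force_origin: bool = False,
) -> KonEstimate:
    """Weighted least-squares slope of 1/tau_on against concentration.

    ``series`` pairs each concentration (mol/L) with the fitted tau_on.
    Weights come from the propagated SEs of 1/tau_on; a free intercept is
    reported as a diagnostic (it should be ~0 under the single-step
    bimolecular model) unless ``force_origin``.
    """
    if len(series) < 3 and not force_origin:
        raise InsufficientDataError("need >= 3 concentrations for the titration fit")
    if len(series) < 2 and force_origin:
        raise InsufficientDataError("need >= 2 points")
    c = np.array([p[0] for p in series], dtype=float)
    if np.any(c < 0):
        raise ConfigurationError("concentrations must be >= 0")
    rates = np.array([p[1].rate for p in series])
    ses = np.array([p[1].se_rate for p in series])
    w = 1.0 / ses**2 if np.all(ses > 0) else np.ones_like(rates)

    import statsmodels.api as sm

    X = c.reshape(-1, 1) if force_origin else sm.add_constant(c)
    res = sm.WLS(rates, X, weights=w).fit()
    if force_origin:
        slope, se_slope = float(res.params[0]), float(res.bse[0])
        intercept, se_intercept = 0.0, 0.0
    else:
        intercept, slope = (float(v) for v in res.params)
        se_intercept, se_slope = (float(v) for v in res.bse)
    flagged = slope <= 0
    if flagged:
        warnings.warn(
            "association titration produced a non-positive slope",
            NegativeSlopeWarning,
            stacklevel=2,
        )
    return KonEstimate(slope, se_slope, intercept, se_intercept, len(series), flagged)


def estimate_koff(
    fits: Sequence[ExponentialFit],
    concentrations: Sequence[float] | None = None,
) -> KoffEstimate:
    """Mean of 1/tau_off across conditions, with SE by propagation.

    If concentrations are supplied, an OLS slope of 1/tau_off against c is
    reported as a diagnostic: the unimolecular dissociation model predicts
    no concentration dependence.
    """
    if len(fits) == 0:
        raise InsufficientDataError("no dwell fits supplied")
    rates = np.array([f.rate for f in fits])
    ses = np.array([f.se_rate for f in fits])
    k_off = float(np.mean(rates))
    se = float(np.sqrt(np.sum(ses**2)) / len(fits))

    slope = slope_se = pval = math.nan
    if concentrations is not None and len(concentrations) == len(fits) and len(fits) >= 3:
        c = np.asarray(concentrations, dtype=float)
        lr = stats.linregress(c, rates)
        slope, slope_se, pval = float(lr.slope), float(lr.stderr), float(lr.pvalue)
    return KoffEstimate(k_off, se, len(fits), slope, slope_se, pval)


def compute_Kb(
    k_on: float,
    k_off: float,
    se_k_on: float = 0.0,
    se_k_off: float = 0.0,
) -> tuple[float, float]:
    """Equilibrium binding constant K_b = k_on / k_off with propagated SE."""
    if k_off <= 0:
        raise ConfigurationError(
            "k_off must be > 0 (irreversible regime has no equilibrium constant)"
        )
    kb = k_on / k_off
    rel = 0.0
    if k_on > 0:
        rel = math.sqrt((se_k_on / k_on) ** 2 + (se_k_off / k_off) ** 2)
    return kb, abs(kb) * rel


@dataclass(frozen=True)
class ArrheniusFit:
    """ln k = ln A - Ea / (R T)."""

    activation_energy: float  # kJ/mol
    se_activation_energy: float
    ln_prefactor: float
    se_ln_prefactor: float
    r_squared: float
    n: int

    def predict(self, temperature) -> np.ndarray:
        T = np.asarray(temperature, dtype=float)
        ea = self.activation_energy * 1e3
        return np.exp(self.ln_prefactor - ea / (GAS_CONSTANT * T))


def fit_arrhenius(
    temperatures: Sequence[float],
    rates: Sequence[float],
) -> ArrheniusFit:
    """OLS of ln k against 1/T; Ea = -slope * R (reported in kJ/mol)."""
    T = np.asarray(temperatures, dtype=float)
    k = np.asarray(rates, dtype=float)
    if T.size != k.size:
        raise ConfigurationError("temperatures and rates differ in length")
    if T.size < 3:
        raise InsufficientDataError("need >= 3 temperatures")
    if np.any(T <= 0):
        raise ConfigurationError("temperatures must be > 0 K")
    if T.max() - T.min() < 5.0:
        raise InsufficientDataError("temperatures must span >= 5 K")
    if np.any(k <= 0):
        raise ConfigurationError("rates must be > 0 for an Arrhenius fit")
    lr = stats.linregress(1.0 / T, np.log(k))
    ea = -float(lr.slope) * GAS_CONSTANT / 1e3
    se_ea = float(lr.stderr) * GAS_CONSTANT / 1e3
    return ArrheniusFit(
        activation_energy=ea,
        se_activation_energy=se_ea,
        ln_prefactor=float(lr.intercept),
        se_ln_prefactor=float(lr.intercept_stderr),
        r_squared=float(lr.rvalue) ** 2,
        n=int(T.size),
    )


@dataclass(frozen=True)
class LodEstimate:
    """Limit of detection: concentration giving >= n_min events in t_obs."""

    lod: float  # mol/L
    n_min: int = 5
    t_obs: float = 600.0
    criterion: str = "expected"


def compute_lod(
    k_on: float,
    n_min: int = 5,
    t_obs: float = 600.0,
    *,
    criterion: str = "expected",
    prob: float = 0.95,
) -> LodEstimate:
    """Concentration needed to see at least ``n_min`` events in ``t_obs``.

    ``criterion='expected'`` uses the expected-count definition
    ``lod = n_min / (k_on * t_obs)`` (the unbound fraction is ~1 at such low
    concentrations).  ``criterion='poisson'`` instead finds the concentration
    at which a Poisson count reaches >= n_min with probability ``prob``.
    """
    if k_on <= 0:
        raise ConfigurationError("k_on must be > 0")
    if n_min < 1 or t_obs <= 0:
        raise ConfigurationError("need n_min >= 1 and t_obs > 0")
    if criterion == "expected":
        lod = n_min / (k_on * t_obs)
    elif criterion == "poisson":
        def deficit(lam):
            return stats.poisson.sf(n_min - 1, lam) - prob

        lam = optimize.brentq(deficit, 1e-9, 1e6)
        lod = lam / (k_on * t_obs)
    else:
        raise ConfigurationError("criterion must be 'expected' or 'poisson'")
    return LodEstimate(lod=float(lod), n_min=n_min, t_obs=t_obs, criterion=criterion)


# ---------------------------------------------------------------------------
# Model / Results layer
# ---------------------------------------------------------------------------


class ExponentialDwellModel:
    """Exponential dwell-time model for one experimental condition.

    Parameters
    ----------
    values
        Observed durations in seconds (dwells or inter-event intervals).
    kind
        ``"t_off"`` (dwell) or ``"t_on"`` (interval).
    t_min
        Left-truncation point (detector minimum duration), seconds.
    """

    def __init__(self, values, kind: str = "t_off", t_min: float = 0.0, **meta):
        self.data = DwellSet(np.asarray(values, dtype=float), kind, t_min, **meta)

    def fit(self, method: str = "mle", **kwargs) -> "ExponentialDwellResults":
        if method == "mle":
            f = fit_exponential_mle(self.data)
        elif method == "histogram":
            f = fit_exponential_histogram(self.data, **kwargs)
        else:
            raise ConfigurationError("method must be 'mle' or 'histogram'")
        return ExponentialDwellResults(self, f)


@dataclass
class ExponentialDwellResults:
    model: ExponentialDwellModel
    fit: ExponentialFit

    @property
    def tau(self) -> float:
        return self.fit.tau

    @property
    def bse(self) -> float:
        return self.fit.se_tau

    @property
    def rate(self) -> float:
        return self.fit.rate

    def summary(self) -> str:
        d = self.model.data
        lines = [
            "Exponential dwell fit",
            "=" * 44,
            f"kind        : {d.kind}",
            f"method      : {self.fit.method}",
            f"n           : {self.fit.n}",
            f"t_min [s]   : {d.t_min:.6g}",
            f"tau [s]     : {self.fit.tau:.6g} +/- {self.fit.se_tau:.3g}",
            f"rate [1/s]  : {self.fit.rate:.6g}",
        ]
        return "\n".join(lines)


class BindingKineticsModel:
    """Two-state binding kinetics fitted to a concentration titration.

    Built from per-concentration dwell/interval sets (or directly from
    idealized event tables); ``fit()`` estimates k_on from the 1/tau_on
    slope, k_off from the mean 1/tau_off, and K_b = k_on/k_off, each with
    standard errors.
    """

    def __init__(
        self,
        t_on_sets: Sequence[DwellSet],
        t_off_sets: Sequence[DwellSet],
    ):
        if len(t_on_sets) != len(t_off_sets) or len(t_on_sets) == 0:
            raise ConfigurationError("need matching, nonempty t_on and t_off sets")
        for s in t_on_sets:
            if s.kind != "t_on" or not math.isfinite(s.concentration):
                raise ConfigurationError("t_on sets must have kind 't_on' and a concentration")
        for s in t_off_sets:
            if s.kind != "t_off" or not math.isfinite(s.concentration):
                raise ConfigurationError("t_off sets must have kind 't_off' and a concentration")
        self.t_on_sets = list(t_on_sets)
        self.t_off_sets = list(t_off_sets)

    @classmethod
    def from_event_tables(
        cls,
        tables: Iterable,
        concentrations: Sequence[float],
        *,
        t_min_off: float | None = None,
    ) -> "BindingKineticsModel":
        """Build the model from idealized event tables, one per concentration.

        ``t_min_off`` defaults to each table's detection minimum duration
        (recorded in its provenance), which is the dwell truncation point.
        """
        t_on_sets, t_off_sets = [], []
        for table, c in zip(tables, concentrations):
            tmin = t_min_off
            if tmin is None:
                tmin = float(table.provenance.get("min_duration_s", 0.0))
            t_off_sets.append(DwellSet(table.dwell_times(), "t_off", tmin, concentration=c))
            t_on_sets.append(DwellSet(table.interevent_intervals(), "t_on", 0.0, concentration=c))
        return cls(t_on_sets, t_off_sets)

    def fit(
        self,
        *,
        dwell_method: str = "mle",
        force_origin: bool = False,
    ) -> "BindingKineticsResults":
        fitter = fit_exponential_mle if dwell_method == "mle" else fit_exponential_histogram
        on_fits = [(s.concentration, fitter(s)) for s in self.t_on_sets]
        off_fits = [fitter(s) for s in self.t_off_sets]
        off_concs = [s.concentration for s in self.t_off_sets]

        kon = estimate_kon(on_fits, force_origin=force_origin)
        koff = estimate_koff(off_fits, off_concs)
        kb, se_kb = compute_Kb(kon.k_on, koff.k_off, kon.se, koff.se)
        rc = RateConstants(
            k_on=kon.k_on,
            se_k_on=kon.se,
            k_off=koff.k_off,
            se_k_off=koff.se,
            K_b=kb,
            se_K_b=se_kb,
            intercept=kon.intercept,
            se_intercept=kon.se_intercept,
        )
        per_cond = pd.DataFrame(
            {
                "concentration_molar": [c for c, _ in on_fits],
                "tau_on_s": [f.tau for _, f in on_fits],
                "se_tau_on_s": [f.se_tau for _, f in on_fits],
                "n_on": [f.n for _, f in on_fits],
                "tau_off_s": [f.tau for f in off_fits],
                "se_tau_off_s": [f.se_tau for f in off_fits],
                "n_off": [f.n for f in off_fits],
            }
        )
        return BindingKineticsResults(self, rc, kon, koff, per_cond)


@dataclass
class BindingKineticsResults:
    """Rate constants, their uncertainties and per-condition diagnostics."""

    model: BindingKineticsModel
    rate_constants: RateConstants
    kon_estimate: KonEstimate
    koff_estimate: KoffEstimate
    per_condition: pd.DataFrame

    @property
    def params(self) -> pd.Series:
        rc = self.rate_constants
        return pd.Series({"k_on": rc.k_on, "k_off": rc.k_off, "K_b": rc.K_b})

    @property
    def bse(self) -> pd.Series:
        rc = self.rate_constants
        return pd.Series({"k_on": rc.se_k_on, "k_off": rc.se_k_off, "K_b": rc.se_K_b})

    def lod(self, n_min: int = 5, t_obs: float = 600.0, **kw) -> LodEstimate:
        return compute_lod(self.rate_constants.k_on, n_min, t_obs, **kw)

    def occupancy(self, concentration: float) -> float:
        """Equilibrium bound fraction c*K_b / (1 + c*K_b)."""
        x = concentration * self.rate_constants.K_b
        return x / (1.0 + x)

    def summary(self) -> str:
        rc = self.rate_constants
        ko = self.koff_estimate
        lines = [
            "Two-state binding kinetics",
            "=" * 60,
            f"conditions            : {len(self.per_condition)}",
            f"k_on  [1/(M s)]       : {rc.k_on:.6g} +/- {rc.se_k_on:.3g}",
            f"k_off [1/s]           : {rc.k_off:.6g} +/- {rc.se_k_off:.3g}",
            f"K_b   [1/M]           : {rc.K_b:.6g} +/- {rc.se_K_b:.3g}",
            f"titration intercept   : {rc.intercept:.4g} +/- {rc.se_intercept:.3g} 1/s",
        ]
        if math.isfinite(ko.conc_slope):
            lines.append(
                f"1/tau_off vs c slope  : {ko.conc_slope:.4g} "
                f"(p = {ko.conc_slope_pvalue:.3g}; ~0 expected)"
            )
        lines.append("")
        lines.append(self.per_condition.to_string(index=False))
        return "\n".join(lines)


class ArrheniusModel:
    """Temperature dependence of a rate constant, ln k = ln A - Ea/(RT)."""

    def __init__(self, temperatures, rates):
        self.temperatures = np.asarray(temperatures, dtype=float)
        self.rates = np.asarray(rates, dtype=float)

    def fit(self) -> "ArrheniusResults":
        return ArrheniusResults(self, fit_arrhenius(self.temperatures, self.rates))


@dataclass
class ArrheniusResults:
    model: ArrheniusModel
    fit: ArrheniusFit

    @property
    def activation_energy(self) -> float:
        return self.fit.activation_energy

    def predict(self, temperature):
        return self.fit.predict(temperature)

    def summary(self) -> str:
        f = self.fit
        return "\n".join(
            [
                "Arrhenius fit",
                "=" * 44,
                f"n temperatures   : {f.n}",
                f"Ea [kJ/mol]      : {f.activation_energy:.6g} +/- {f.se_activation_energy:.3g}",
                f"ln A             : {f.ln_prefactor:.6g} +/- {f.se_ln_prefactor:.3g}",
                f"R^2              : {f.r_squared:.6f}",
            ]
        )
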