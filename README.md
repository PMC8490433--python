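# nanokin

Analysis toolkit for **single-molecule nanopore stochastic sensing**: the
experiment in which a reactive group tethered inside a protein nanopore
(MspA-style) binds mobile analytes one molecule at a time, and each binding
event appears as a discrete, telegraph-like excursion of the ionic current.
`nanokin` is aimed at single-channel electrophysiologists and method
developers who need a reproducible, fully testable path from raw current
traces to binding kinetics and analyte identification — including a
simulator that generates traces with exact ground truth, so every stage of
the analysis can be validated without instrument data.

## The model

With the sensing strand docked, the pore sits at a static blockage level
$I_p$; binding of a mobile reactant switches the current to a bound level
$I_b$. Events are described by the blockage amplitude
$\Delta I = I_b - I_p$, the dwell time $t_\mathrm{off}$ and the inter-event
interval $t_\mathrm{on}$. Reversible single-site binding follows a
two-state Markov scheme whose mean times obey

$$1/\tau_\mathrm{on} = k_\mathrm{on}\,c, \qquad
  1/\tau_\mathrm{off} = k_\mathrm{off}, \qquad
  K_b = k_\mathrm{on}/k_\mathrm{off},$$

i.e. a single-step bimolecular association (slope of $1/\tau_\mathrm{on}$
against concentration $c$) and a concentration-independent unimolecular
dissociation. The package provides:

- **`nanokin.simulate`** — Gillespie simulation of arbitrary kinetic
  schemes (two-state, multi-level intermediates, absorbing states for
  irreversible chemistry with voltage-reload cycles, labelled mixtures),
  rendered into sampled traces with baseline white noise, per-state extra
  noise (broadband or secondary telegraph flicker) and an emulation of the
  analog acquisition filter (default 4-pole Bessel, 1 kHz, at 25 kHz
  sampling).
- **`nanokin.idealize`** — all-points-histogram baseline fitting,
  half-amplitude threshold detection with hysteresis, per-event
  $\Delta I$ / $t_\mathrm{off}$ / $t_\mathrm{on}$ annotation, and sub-level
  segmentation for events that switch between intermediate levels.
- **`nanokin.kinetics`** — truncated-exponential dwell MLE
  ($\hat\tau = \bar t - t_\mathrm{min}$), weighted titration fits,
  statsmodels-style `BindingKineticsModel(...).fit()` returning rate
  constants with standard errors, Arrhenius temperature analysis, and the
  detection limit defined as the concentration yielding at least five
  events in a 10-minute recording.
- **`nanokin.discriminate`** — zero-phase Butterworth frequency split at
  100 Hz, per-event low-pass/high-pass SD features, support-vector event
  classification, confusion matrices and decision-boundary grids.
- **`nanokin.io` / CLI** — trace containers, TSV event tables, INI run
  configs and a `nanokin` command-line pipeline with deterministic
  seed-derived randomness.

## Worked example

Simulate a five-point titration (0.2–1.0 mM) of a two-state binder with
$k_\mathrm{on} = 10^4\,\mathrm{M^{-1}s^{-1}}$, $k_\mathrm{off} = 5\,
\mathrm{s^{-1}}$ and $\Delta I = -60$ pA at signal-to-noise 10, then
recover the kinetics from the traces alone:

```python
import nanokin as nk

scheme = nk.two_state_scheme(i_p=120.0, i_b=60.0, k_on=1e4, k_off=5.0)
noise = nk.NoiseModel(baseline_sd=6.0)
acq = nk.AcquisitionSettings(sampling_rate=25_000, analog_corner=1_000, duration=120.0)

concs = [2e-4, 4e-4, 6e-4, 8e-4, 1e-3]
traces = nk.simulate_concentration_series(scheme, concs, noise, acq, seed=11)

# baseline from a short analyte-free recording (static-blockage protocol)
cal = nk.simulate_trace(scheme, 0.0, noise, nk.AcquisitionSettings(duration=10.0), seed=12)
baseline = nk.estimate_baseline(cal)

tables = [nk.detect_events(tr, baseline, -60.0) for tr in traces]
res = nk.BindingKineticsModel.from_event_tables(tables, concs).fit()
print(res.summary())
```

prints

```
Two-state binding kinetics
============================================================
conditions            : 5
k_on  [1/(M s)]       : 9840.81 +/- 183
k_off [1/s]           : 4.93988 +/- 0.131
K_b   [1/M]           : 1992.12 +/- 64.6
titration intercept   : 0.1409 +/- 0.0822 1/s
1/tau_off vs c slope  : 107.4 (p = 0.568; ~0 expected)

 concentration_molar  tau_on_s  se_tau_on_s  n_on  tau_off_s  se_tau_off_s  n_off
              0.0002  0.481591     0.036509   174   0.203712      0.015399    175
              0.0004  0.240514     0.014719   267   0.207449      0.012672    268
              0.0006  0.163830     0.008991   332   0.196575      0.010772    333
              0.0008  0.123409     0.006451   366   0.203552      0.010625    367
              0.0010  0.102528     0.005165   394   0.201200      0.010123    395
```

The association constant comes back within 2% of the configured
$10^4\,\mathrm{M^{-1}s^{-1}}$, the dwell time $\tau_\mathrm{off} \approx
0.2$ s matches $1/k_\mathrm{off}$ at every concentration (the near-zero
slope diagnostic confirms unimolecular dissociation), and
`res.lod()` reports a detection limit of 0.85 µM for these kinetics.
A full mixed-analyte demonstration — simulation, idealization, kinetics,
100 Hz frequency-split features and SVC classification — runs with

```sh
nanokin run --config examples/demo_run.ini --out demo_out/
```

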