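# Methods

This note documents the models, algorithms and numerical choices behind
`nanokin`, in the order data flows through the pipeline.

## Kinetic model and simulator

A sensing site inside a nanopore is modelled as a continuous-time Markov
chain over named conductance states, each carrying a mean residual current
(pA). Rates are first-order (s⁻¹); association steps are marked
*concentration-coupled* and multiplied by the mobile-analyte concentration
(mol/L) at simulation time, making the canonical two-state instance

    baseline --k_on·c--> bound,   bound --k_off--> baseline

exactly the single-step bimolecular / unimolecular pair with
K_b = k_on/k_off. States may be absorbing (zero exit rate), representing
irreversible chemistry at the site.

Paths are sampled with the Gillespie algorithm: the dwell in a state is
exponential with the state's total exit rate, and the successor is chosen
with probability proportional to the competing rates. The path, with exact
segment boundaries and a per-segment measurement-cycle index, is retained as
ground truth on every synthetic trace, which is what makes the downstream
stages testable: closed-form oracles (equilibrium occupancy
cK_b/(1+cK_b), exponential dwell laws, competing-risks absorption times)
are checked against the sampler in the test suite, and the idealizer is
scored against the exact boundaries.

**Rendering.** Per-sample current = occupying state's mean + baseline white
noise + state-specific extra noise, then an emulation of the analog
acquisition chain. Defaults mirror a patch-clamp setup: 25 kHz sampling
with a causal 4-pole low-pass Bessel filter at a 1 kHz corner
(magnitude-normalised; type and order configurable, `analog_corner=None`
disables it). With all noise terms zero and the filter off, rendering is
bit-exact piecewise-constant — an invariant the tests rely on.

**Bound-state noise.** Real bound levels often carry characteristic extra
fluctuations whose spectral content is generally unknown, so two
interchangeable mechanisms are provided per state: extra broadband Gaussian
noise (SD in pA), and a secondary two-level telegraph flicker (zero-mean
square wave, peak-to-peak amplitude, exponential up/down dwell rates).
The defaults in the examples are chosen to be qualitatively similar to
recorded traces (flicker rates of tens of s⁻¹, amplitudes of ~10 pA on
60 pA events), not calibrated to any instrument.

**Irreversible runs.** After the path enters an absorbing state the trace
is a quiet baseline until a *reload*: the strand is ejected and recaptured,
the path restarts at baseline and the cycle index increments. Reloads
follow either a fixed schedule (k reload times → k+1 cycles) or an
absorption-triggered rule with a detection delay; a fixed dead time
(default 1 s) separates cycles and is recorded as a reserved `_reload`
state excluded from all event analysis. Voltage and temperature are
carried as metadata with linear scaling hooks on rates only — the package
deliberately does not model conductance physics.

**Mixtures.** For several analytes sharing one baseline, the waiting time
between events uses the proportion-weighted total association rate
Σ pₖ·k_on,k·c, and each event's class is drawn independently from the
proportions. True labels are recorded per event so classifiers can be
scored against ground truth.

**Determinism.** Every driver derives sub-seeds from a master seed via
`numpy.random.SeedSequence.spawn`; identical configuration + seed yields
bit-identical traces, event tables and reports.

## Idealization

**Baseline.** The static blockage level I_p is estimated from the
all-points histogram (256 bins): the dominant mode is located, its width
initialised from the mode's half-height extent, and a Gaussian is fitted by
least squares; the fit centre and width give mean and SD. A second
prominent mode at ≥ 80% of the dominant one raises an ambiguity error
rather than guessing. A segment-means variant fits a Gaussian to ≥ 500
static-capture level means, mirroring the experimental calibration
protocol; in the pipeline the baseline is calibrated on a short
analyte-free recording, since at high occupancy the bound level can
dominate the histogram of a titration trace.

**Detection.** Half-amplitude threshold crossing with hysteresis: an event
opens when the current crosses baseline + 0.5·ΔI_nominal (in the excursion
direction) and closes on recrossing 0.25·ΔI_nominal. Events shorter than
`min_duration` (default 3 samples = 0.12 ms at 25 kHz) are discarded — this
is also the left-truncation point handed to the dwell fits. Detection
refuses to run if the half-amplitude threshold sits within 3 baseline SDs.
When the trace metadata records that the causal analog filter was applied,
both boundaries are shifted back by the filter's DC group delay (computed
from the designed filter), keeping boundary errors at ~1 sample even on
filtered traces. Coordinates are 0-based, half-open sample intervals.
t_on is measured end-of-previous-event → start-of-current-event and resets
at cycle boundaries (undefined for the first event of a cycle).

**Annotation.** ΔI = (event mean level) − I_p, so positive-going events
(bound level above baseline) have ΔI > 0. One analog-filter time constant
(1/2πf_c) is trimmed from each event edge before level statistics to avoid
transition smearing; events too short for the guards use the full window
and carry a flag.

**Sub-levels.** For events that switch between intermediate levels, the
bound region is median-filtered (5 samples), clustered into 1–3 candidate
levels (k-means, fixed seed), adjacent levels closer than 2× a robust noise
estimate (from the median absolute first difference of the raw window,
which splitting a unimodal level cannot fool) are merged with a warning,
and samples are segmented by mid-level thresholds with runs < 3 samples
absorbed into their predecessor. The transition-count matrix includes
entry from and exit to the baseline, so each row sums to that level's
segment count. Whole events contribute a single t_off to dwell histograms
regardless of internal switching; per-sub-level dwell analysis is available
from the returned segments.

## Kinetics

**Dwell estimation.** The primary estimator is the left-truncated
exponential MLE: τ̂ = mean(t) − t_min with SE τ̂/√n, exact for data observed
only above the detector's minimum duration. A histogram route (linear or
log binning, least-squares fit of A·e^(−t/τ)) is retained for parity with
conventional time-histogram analysis; both are exposed and neither is
claimed to be "the" conventional method, since published analyses rarely
state one. MLE is the default for its small-n robustness.

**Rate constants.** k_on is the slope of 1/τ_on against concentration by
weighted least squares (weights from the propagated SEs of 1/τ_on), with a
free intercept reported as a diagnostic — it should be ≈ 0 under the
single-step bimolecular model; a forced-origin flag is available. k_off is
the unweighted mean of 1/τ_off across conditions (a weighted option exists),
with an OLS slope of 1/τ_off against c reported as the
concentration-independence diagnostic. K_b = k_on/k_off with first-order
error propagation. The statsmodels-style `BindingKineticsModel` wraps the
chain from event tables to a Results object with `params`, `bse` and
`summary()`.

**Temperature.** Rates across ≥ 3 temperatures spanning ≥ 5 K are fitted by
OLS of ln k on 1/T; E_a = −slope·R (kJ/mol) with R² reported.

**Detection limit.** Defined as the concentration giving at least
`n_min = 5` events in `t_obs = 600 s`. The default uses the expected-count
reading, lod = n_min/(k_on·t_obs), valid while the unbound fraction ≈ 1 at
such dilutions; because "at least five events" is ambiguous about
stochasticity, a Poisson variant returns the concentration at which
P(N ≥ n_min) reaches a configurable probability.

Units are mol/L, seconds and kelvin internally; conversions live at the
configuration boundary (key names carry units).

## Frequency-split discrimination

The trace is split at 100 Hz (configurable) with a zero-phase
(forward–backward) Butterworth low-pass — zero-phase so event shapes are
not skewed — and the high-pass portion is defined as the residual
x − lowpass(x), guaranteeing exact sample-wise reconstruction. A
separate-causal-filter reading is available via `zero_phase=False`.
Each event is summarised by the SDs of its low-pass and high-pass portions.
Because the zero-phase split filter rings for ~1.5/f_c around each level
transition, feature extraction trims 1.5/f_c (15 ms at 100 Hz) from each
event edge; events too short for that are flagged and, in the bundled
analyses, excluded from classification — they cannot carry meaningful
100 Hz-split features in any case.

Classification is a support-vector classifier on exactly (lp_sd, hp_sd),
z-scored on the training set; defaults RBF, C = 1, γ = "scale", with an
optional 5-fold cross-validated grid search. Published applications of
this kind rarely state the validation protocol, so the pipeline reports a
stratified 70/30 hold-out with a fixed seed; resubstitution accuracy can be
computed from the same objects. Confusion matrices use lexicographic label
order, per-class accuracy = recall, and include absent labels as zero
rows/columns. Decision regions are exported as a dense classified grid.

## Pipeline and formats

Traces are a JSON-sidecar + payload pair (little-endian float32 `.f32`, or
CSV for small traces) with a schema version, full acquisition metadata and
the generating seed; ground truth travels as a TSV interval table. Event
and feature tables are TSV with a comment header embedding the sampling
rate and the config hash; floats are written at 9 significant digits so
round trips are lossless at float32 precision. Run configuration is INI
with unit-suffixed keys; every artifact embeds the SHA-256 (truncated) hash
of the normalized config text. CLI exit codes: 0 success, 2 configuration
error, 3 data integrity, 4 insufficient data. Vendor amplifier formats are
not parsed; external traces enter through the documented container.

## Problem sizes and limitations

The bundled study-scale checks use five 600 s traces at 25 kHz for the
titration chain, 10⁶ samples for false-positive and noise-partition
checks, 10⁴ draws for dwell-MLE recovery, 200 × 600 s paths for the
detection-limit consistency and 900 synthetic events for the three-class
discrimination task — sizes at which Monte-Carlo error is comfortably
inside the asserted tolerances.

What the generator does not emulate: baseline drift and wander, 1/f and
capacitive instrumentation noise, open-pore ↔ docked transitions and
strand-capture dynamics, voltage- or charge-dependent conductance physics,
and amplitude distributions broader than the configured state means.
Passing tests therefore demonstrate correctness of the estimators and the
pipeline under the stated noise model, not robustness to every artefact of
recorded data. Known estimator limitations: dwells are single-exponential
(no mixtures, no Bayesian inference); events separated by gaps shorter than
the filter response merge, which slightly inflates τ̂_off and deflates event
counts at high occupancy; and the classifier is intentionally restricted to
the two frequency-split features for parity with the published feature set
(extras are opt-in).
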