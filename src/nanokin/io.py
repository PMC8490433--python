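"""File formats, run configuration and pipeline orchestration.

Traces are stored as a file pair: a JSON sidecar with acquisition metadata
(and schema version) plus a payload of little-endian IEEE-754 float32
samples in pA (``.f32``) or a two-column CSV for small traces.  Ground truth
travels alongside as an interval table (state, t_start_s, t_end_s, cycle).
Event and feature tables are TSV with a comment header embedding the
sampling rate and the config hash.  Run configuration is a plain-text INI
with unit-suffixed keys; :func:`run_pipeline` executes the requested stages
(simulate -> idealize -> kinetics -> features -> classify) reproducibly from
a master seed.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataIntegrityError
from .idealize import (
    BaselineEstimate,
    DetectionSettings,
    EventRecord,
    EventTable,
    detect_events,
    estimate_baseline,
)
from .schemes import (
    AcquisitionSettings,
    KineticScheme,
    NoiseModel,
    StateNoise,
    TelegraphNoise,
    two_state_scheme,
)
from .simulate import GroundTruthPath, SimulatedTrace, simulate_mixture, simulate_trace

__all__ = [
    "SCHEMA_VERSION",
    "write_trace",
    "read_trace",
    "write_events",
    "read_events",
    "RunConfig",
    "load_config",
    "config_hash",
    "run_pipeline",
]

SCHEMA_VERSION = 1

EVENT_COLUMNS = [
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


# ---------------------------------------------------------------------------
# Trace container
# ---------------------------------------------------------------------------


def write_trace(trace: SimulatedTrace, path, *, fmt: str = "binary",
                config_hash_value: str | None = None) -> tuple[Path, Path]:
    """Write a trace as a metadata JSON + payload file pair.

    ``path`` is the base path (no extension).  ``fmt`` is ``"binary"``
    (float32 little-endian ``.f32``) or ``"csv"`` (time_s, current_pA).
    Ground truth, if present, is written to ``<path>.truth.tsv``.
    """
    base = Path(path)
    base.parent.mkdir(parents=True, exist_ok=True)
    samples32 = trace.samples.astype("<f4")
    if fmt == "binary":
        payload = base.with_suffix(".f32")
        samples32.tofile(payload)
    elif fmt == "csv":
        payload = base.with_suffix(".csv")
        df = pd.DataFrame(
            {"time_s": trace.times, "current_pA": samples32.astype(float)}
        )
        df.to_csv(payload, index=False, float_format="%.9g")
    else:
        raise ConfigurationError("fmt must be 'binary' or 'csv'")

    acq = trace.acquisition
    meta = {
        "schema_version": SCHEMA_VERSION,
        "payload": payload.name,
        "payload_format": fmt,
        "units": "pA",
        "n_samples": int(trace.samples.size),
        "sampling_rate_hz": acq.sampling_rate,
        "duration_s": trace.samples.size / acq.sampling_rate,
        "analog_corner_hz": acq.analog_corner,
        "analog_filter_order": acq.analog_filter_order,
        "analog_filter_type": acq.analog_filter_type,
        "filter_applied": trace.filter_applied,
        "voltage_mV": trace.voltage,
        "concentration_molar": trace.concentration,
        "temperature_K": trace.temperature,
        "seed": trace.seed,
        "state_means_pA": trace.state_means,
        "config_hash": config_hash_value,
    }
    meta_path = base.with_suffix(".json")
    meta_path.write_text(json.dumps(meta, indent=2))
    if trace.truth is not None:
        trace.truth.to_frame().to_csv(
            base.with_suffix(".truth.tsv"), sep="\t", index=False, float_format="%.9g"
        )
    return meta_path, payload


def read_trace(path) -> SimulatedTrace:
    """Read a trace file pair back into a :class:`SimulatedTrace`.

    Raises :class:`DataIntegrityError` if the payload length disagrees with
    the metadata or the schema version is unsupported.
    """
    base = Path(path)
    meta_path = base if base.suffix == ".json" else base.with_suffix(".json")
    if not meta_path.exists():
        raise DataIntegrityError(f"missing trace metadata {meta_path}")
    meta = json.loads(meta_path.read_text())
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise DataIntegrityError(
            f"trace schema version {meta.get('schema_version')!r} requires migration "
            f"(this package reads version {SCHEMA_VERSION})"
        )
    payload = meta_path.with_name(meta["payload"])
    if not payload.exists():
        raise DataIntegrityError(f"missing trace payload {payload}")
    if meta["payload_format"] == "binary":
        samples = np.fromfile(payload, dtype="<f4").astype(np.float64)
    else:
        samples = pd.read_csv(payload)["current_pA"].to_numpy(dtype=np.float64)
    if samples.size != meta["n_samples"]:
        raise DataIntegrityError(
            f"payload has {samples.size} samples, metadata says {meta['n_samples']}"
        )
    acq = AcquisitionSettings(
        sampling_rate=meta["sampling_rate_hz"],
        analog_corner=meta["analog_corner_hz"],
        analog_filter_order=meta["analog_filter_order"],
        analog_filter_type=meta["analog_filter_type"],
        duration=max(meta["duration_s"], samples.size / meta["sampling_rate_hz"]),
    )
    truth = None
    truth_path = meta_path.with_suffix("").with_suffix(".truth.tsv")
    if truth_path.exists():
        truth = GroundTruthPath.from_frame(pd.read_csv(truth_path, sep="\t"))
    return SimulatedTrace(
        samples=samples,
        acquisition=acq,
        truth=truth,
        state_means=dict(meta.get("state_means_pA") or {}),
        concentration=meta.get("concentration_molar") or 0.0,
        temperature=meta.get("temperature_K") or 294.15,
        voltage=meta.get("voltage_mV") or 0.0,
        seed=meta.get("seed"),
        filter_applied=bool(meta.get("filter_applied")),
    )


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------


def write_events(table: EventTable, path, *, config_hash_value: str | None = None) -> Path:
    """Write an event table as TSV (9-significant-digit round trip)."""
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    header = (
        f"# nanokin-events v{SCHEMA_VERSION} "
        f"sampling_rate_hz={table.sampling_rate:.9g} "
        f"config_hash={config_hash_value or ''}\n"
    )
    with open(p, "w") as fh:
        fh.write(header)
        table.to_dataframe().to_csv(fh, sep="\t", index=False, float_format="%.9g")
    return p


def read_events(path) -> EventTable:
    """Read an event-table TSV, tolerant of column reordering."""
    p = Path(path)
    fs = 25_000.0
    with open(p) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for tok in first.split():
            if tok.startswith("sampling_rate_hz="):
                fs = float(tok.split("=", 1)[1])
    df = pd.read_csv(p, sep="\t", comment="#")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns and c != "label"]
    if missing:
        raise DataIntegrityError(f"event table missing required column(s): {missing}")
    records = []
    for r in df.itertuples():
        label = getattr(r, "label", "")
        label = None if (isinstance(label, float) and math.isnan(label)) or label == "" else str(label)
        records.append(
            EventRecord(
                start=int(round(r.start_s * fs)),
                end=int(round(r.end_s * fs)),
                t_off=float(r.t_off_s),
                t_on=float(r.t_on_s),
                cycle=int(r.cycle),
                delta_I=float(r.delta_I_pA),
                level_sd=float(r.level_sd_pA),
                label=label,
            )
        )
    return EventTable(records, baseline=None, sampling_rate=fs)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_STAGES = ("simulate", "idealize", "kinetics", "features", "classify")
_STAGE_DEPS = {
    "idealize": "simulate",
    "kinetics": "idealize",
    "features": "idealize",
    "classify": "features",
}


@dataclass
class RunConfig:
    """Parsed, validated pipeline run configuration."""

    stages: tuple[str, ...]
    seed: int
    scheme_type: str  # "two_state" | "mixture"
    i_p: float
    acquisition: AcquisitionSettings
    noise: NoiseModel
    concentrations: tuple[float, ...]
    nominal_delta_i: float
    detection: DetectionSettings
    dwell_method: str = "mle"
    force_origin: bool = False
    cutoff_hz: float = 100.0
    split_order: int = 4
    test_fraction: float = 0.3
    # two-state parameters
    i_b: float = math.nan
    k_on: float = math.nan
    k_off: float = math.nan
    # mixture parameters
    classes: dict[str, dict] = field(default_factory=dict)
    raw_text: str = ""

    def scheme(self) -> KineticScheme:
        if self.scheme_type != "two_state":
            raise ConfigurationError("scheme() is only defined for two_state runs")
        return two_state_scheme(self.i_p, self.i_b, self.k_on, self.k_off)

    def mixture_schemes(self) -> tuple[dict[str, KineticScheme], dict[str, float]]:
        schemes, props = {}, {}
        for label, params in self.classes.items():
            schemes[label] = two_state_scheme(
                self.i_p, params["i_b_pA"], params["k_on_per_M_s"], params["k_off_per_s"]
            )
            props[label] = params["proportion"]
        return schemes, props


def config_hash(text: str) -> str:
    """Stable short hash of the normalized config text."""
    norm = "\n".join(line.strip() for line in text.strip().splitlines() if line.strip())
    return hashlib.sha256(norm.encode()).hexdigest()[:16]


def _floats(s: str) -> tuple[float, ...]:
    return tuple(float(tok) for tok in s.replace(",", " ").split())


def load_config(path) -> RunConfig:
    """Parse and validate an INI run configuration."""
    p = Path(path)
    if not p.exists():
        raise ConfigurationError(f"config file {p} does not exist")
    text = p.read_text()
    cp = configparser.ConfigParser()
    try:
        cp.read_string(text)
    except configparser.Error as exc:
        raise ConfigurationError(f"malformed config: {exc}") from exc

    try:
        run = cp["run"]
        stages = tuple(s.strip() for s in run.get("stages", "simulate").split(",") if s.strip())
        for s in stages:
            if s not in _STAGES:
                raise ConfigurationError(f"unknown stage {s!r}")
        for s in stages:
            dep = _STAGE_DEPS.get(s)
            if dep and dep not in stages:
                raise ConfigurationError(f"stage {s!r} requires stage {dep!r}")
        seed = run.getint("seed", 0)

        acq_sec = cp["acquisition"] if cp.has_section("acquisition") else {}
        corner_raw = str(acq_sec.get("analog_corner_hz", "1000")).strip().lower()
        acq = AcquisitionSettings(
            sampling_rate=float(acq_sec.get("sampling_rate_hz", 25_000)),
            analog_corner=None if corner_raw in ("none", "off", "") else float(corner_raw),
            analog_filter_order=int(acq_sec.get("analog_filter_order", 4)),
            duration=float(acq_sec.get("duration_s", 60.0)),
        )

        sch = cp["scheme"]
        scheme_type = sch.get("type", "two_state")
        i_p = float(sch.get("i_p_pA"))

        noise_sec = cp["noise"] if cp.has_section("noise") else {}
        baseline_sd = float(noise_sec.get("baseline_sd_pA", 0.0))
        state_noise: dict[str, StateNoise] = {}

        classes: dict[str, dict] = {}
        i_b = k_on = k_off = math.nan
        if scheme_type == "two_state":
            i_b = float(sch.get("i_b_pA"))
            k_on = float(sch.get("k_on_per_M_s"))
            k_off = float(sch.get("k_off_per_s"))
            bb = float(noise_sec.get("bound_broadband_sd_pA", 0.0))
            ta = float(noise_sec.get("bound_telegraph_amp_pA", 0.0))
            tr = float(noise_sec.get("bound_telegraph_rate_per_s", 0.0))
            if bb > 0 or ta > 0:
                state_noise["bound"] = StateNoise(
                    broadband_sd=bb,
                    telegraph=TelegraphNoise(ta, tr, tr) if ta > 0 else None,
                )
        elif scheme_type == "mixture":
            for sec in cp.sections():
                if not sec.startswith("class:"):
                    continue
                label = sec.split(":", 1)[1]
                cls = cp[sec]
                classes[label] = {
                    "i_b_pA": float(cls.get("i_b_pA")),
                    "k_on_per_M_s": float(cls.get("k_on_per_M_s")),
                    "k_off_per_s": float(cls.get("k_off_per_s")),
                    "proportion": float(cls.get("proportion")),
                }
                bb = float(cls.get("broadband_sd_pA", 0.0))
                ta = float(cls.get("telegraph_amp_pA", 0.0))
                tr = float(cls.get("telegraph_rate_per_s", 0.0))
                if bb > 0 or ta > 0:
                    state_noise[f"bound:{label}"] = StateNoise(
                        broadband_sd=bb,
                        telegraph=TelegraphNoise(ta, tr, tr) if ta > 0 else None,
                    )
            if not classes:
                raise ConfigurationError("mixture scheme needs at least one [class:NAME] section")
        else:
            raise ConfigurationError(f"unknown scheme type {scheme_type!r}")

        tit = cp["titration"] if cp.has_section("titration") else {}
        concentrations = _floats(str(tit.get("concentrations_molar", "1e-3")))

        det_sec = cp["detection"] if cp.has_section("detection") else {}
        nominal = float(det_sec.get("nominal_delta_i_pA", 0.0)) if det_sec else 0.0
        if not det_sec and scheme_type == "two_state":
            nominal = i_b - i_p
        detection = DetectionSettings(
            enter_frac=float(det_sec.get("enter_frac", 0.5)),
            exit_frac=float(det_sec.get("exit_frac", 0.25)),
            min_duration_s=float(det_sec.get("min_duration_s", 1.2e-4)),
        )

        fit_sec = cp["fitting"] if cp.has_section("fitting") else {}
        cls_sec = cp["classification"] if cp.has_section("classification") else {}
        return RunConfig(
            stages=stages,
            seed=seed,
            scheme_type=scheme_type,
            i_p=i_p,
            acquisition=acq,
            noise=NoiseModel(baseline_sd=baseline_sd, state_noise=state_noise),
            concentrations=concentrations,
            nominal_delta_i=nominal,
            detection=detection,
            dwell_method=str(fit_sec.get("dwell_method", "mle")),
            force_origin=str(fit_sec.get("force_origin", "false")).lower() == "true",
            cutoff_hz=float(cls_sec.get("cutoff_hz", 100.0)),
            split_order=int(cls_sec.get("filter_order", 4)),
            test_fraction=float(cls_sec.get("test_fraction", 0.3)),
            i_b=i_b,
            k_on=k_on,
            k_off=k_off,
            classes=classes,
            raw_text=text,
        )
    except ConfigurationError:
        raise
    except (KeyError, TypeError, ValueError, configparser.Error) as exc:
        raise ConfigurationError(f"invalid config: {exc}") from exc


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the configured stages and write all artifacts to ``out_dir``.

    Identical config + seed produces identical artifacts.  Returns a
    manifest dict (also written as ``run_log.json``) recording every seed,
    parameter and artifact path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config.raw_text)
    master = np.random.SeedSequence(config.seed)
    trace_seeds = master.spawn(max(len(config.concentrations), 1))
    manifest: dict = {
        "config_hash": chash,
        "seed": config.seed,
        "stages": list(config.stages),
        "artifacts": {},
        "results": {},
    }

    traces: list[SimulatedTrace] = []
    labels_per_trace: list[list[str] | None] = []
    if "simulate" in config.stages:
        for i, (c, ss) in enumerate(zip(config.concentrations, trace_seeds)):
            if config.scheme_type == "two_state":
                tr = simulate_trace(config.scheme(), c, config.noise, config.acquisition, ss)
                labs = None
            else:
                schemes, props = config.mixture_schemes()
                tr, labs = simulate_mixture(
                    schemes, props, c, config.noise, config.acquisition, ss
                )
            traces.append(tr)
            labels_per_trace.append(labs)
            meta_p, _ = write_trace(tr, out / f"trace_{i:02d}", config_hash_value=chash)
            manifest["artifacts"][f"trace_{i:02d}"] = str(meta_p)

    tables: list[EventTable] = []
    if "idealize" in config.stages:
        # baseline calibration mirrors the static-blockage protocol: a short
        # analyte-free recording, fitted on its all-points histogram
        if config.noise.baseline_sd > 0:
            from dataclasses import replace as _dc_replace

            cal_acq = _dc_replace(config.acquisition,
                                  duration=min(config.acquisition.duration, 10.0))
            cal_scheme = (
                config.scheme()
                if config.scheme_type == "two_state"
                else next(iter(config.mixture_schemes()[0].values()))
            )
            cal_trace = simulate_trace(
                cal_scheme, 0.0, config.noise, cal_acq, master.spawn(1)[0]
            )
            baseline = estimate_baseline(cal_trace)
        else:
            baseline = BaselineEstimate(config.i_p, 0.0)
        for i, tr in enumerate(traces):
            nominal = config.nominal_delta_i
            if nominal == 0 and config.classes:
                db = [c["i_b_pA"] - config.i_p for c in config.classes.values()]
                nominal = db[int(np.argmax(np.abs(db)))]
            table = detect_events(tr, baseline, nominal, config.detection)
            if labels_per_trace[i]:
                truth_events = tr.truth.events("baseline")
                table = _label_events_from_truth(table, truth_events, tr.sampling_rate)
            tables.append(table)
            p = write_events(table, out / f"events_{i:02d}.tsv", config_hash_value=chash)
            manifest["artifacts"][f"events_{i:02d}"] = str(p)

    if "kinetics" in config.stages:
        from .kinetics import BindingKineticsModel

        model = BindingKineticsModel.from_event_tables(tables, config.concentrations)
        res = model.fit(dwell_method=config.dwell_method, force_origin=config.force_origin)
        (out / "kinetics_report.txt").write_text(
            f"# config_hash={chash}\n" + res.summary() + "\n"
        )
        res.per_condition.to_csv(out / "kinetics_per_condition.tsv", sep="\t",
                                 index=False, float_format="%.9g")
        manifest["artifacts"]["kinetics_report"] = str(out / "kinetics_report.txt")
        rc = res.rate_constants
        manifest["results"]["rate_constants"] = {
            "k_on_per_M_s": rc.k_on,
            "k_off_per_s": rc.k_off,
            "K_b_per_M": rc.K_b,
        }

    feature_frames: list[pd.DataFrame] = []
    if "features" in config.stages:
        from .discriminate import extract_features, features_to_frame, frequency_split

        for i, (tr, table) in enumerate(zip(traces, tables)):
            split = frequency_split(tr, cutoff=config.cutoff_hz, order=config.split_order)
            feats = extract_features(split, table, trace=tr, settings=config.detection)
            df = features_to_frame(feats)
            feature_frames.append(df)
            with open(out / f"features_{i:02d}.tsv", "w") as fh:
                fh.write(f"# nanokin-features v{SCHEMA_VERSION} config_hash={chash}\n")
                df.to_csv(fh, sep="\t", index=False, float_format="%.9g")
            manifest["artifacts"][f"features_{i:02d}"] = str(out / f"features_{i:02d}.tsv")

    if "classify" in config.stages:
        from sklearn.model_selection import train_test_split

        from .discriminate import EventClassifier, confusion_matrix, decision_boundary_grid

        all_feats = pd.concat(feature_frames, ignore_index=True)
        labelled = all_feats[all_feats["label"] != ""]
        if labelled.empty:
            raise ConfigurationError("classify stage needs labelled events (mixture run)")
        X = labelled[["lp_sd_pA", "hp_sd_pA"]]
        y = labelled["label"].to_numpy()
        idx_train, idx_test = train_test_split(
            np.arange(len(y)), test_size=config.test_fraction, stratify=y,
            random_state=config.seed,
        )
        clf = EventClassifier(seed=config.seed).fit(X.iloc[idx_train], y[idx_train])
        pred = clf.predict(X.iloc[idx_test])
        cm = confusion_matrix(y[idx_test], pred)
        cm.to_tsv(out / "confusion_matrix.tsv")
        clf.save(out / "classifier.joblib")
        lp, hp = X["lp_sd_pA"], X["hp_sd_pA"]
        pad = lambda v: 0.1 * (v.max() - v.min() + 1e-9)  # noqa: E731
        grid_lp, grid_hp, grid_labels = decision_boundary_grid(
            clf,
            (float(lp.min() - pad(lp)), float(lp.max() + pad(lp))),
            (float(hp.min() - pad(hp)), float(hp.max() + pad(hp))),
            resolution=100,
        )
        pd.DataFrame(grid_labels, index=np.round(grid_hp, 9), columns=np.round(grid_lp, 9)).to_csv(
            out / "decision_grid.tsv", sep="\t"
        )
        manifest["artifacts"]["confusion_matrix"] = str(out / "confusion_matrix.tsv")
        manifest["artifacts"]["classifier"] = str(out / "classifier.joblib")
        manifest["artifacts"]["decision_grid"] = str(out / "decision_grid.tsv")
        manifest["results"]["overall_accuracy"] = cm.overall_accuracy
        manifest["results"]["per_class_accuracy"] = {
            k: (None if pd.isna(v) else float(v)) for k, v in cm.per_class_accuracy.items()
        }

    (out / "run_log.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _label_events_from_truth(table: EventTable, truth_events, fs: float) -> EventTable:
    """Attach ground-truth class labels to detected events by overlap."""
    from dataclasses import replace as _replace

    out = []
    for ev in table:
        t_mid = 0.5 * (ev.start + ev.end) / fs
        label = None
        for seg in truth_events:
            if seg.t_start <= t_mid < seg.t_end:
                label = seg.state.split(":", 1)[1] if ":" in seg.state else seg.state
                break
        out.append(_replace(ev, label=label))
    return EventTable(out, table.baseline, table.sampling_rate, dict(table.provenance))
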