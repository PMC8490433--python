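"""Frequency-split noise features and event classification.

Chemically similar analytes bound at the same sensing site differ in their
noise signatures: some bound levels carry slow secondary flicker, others
broadband high-frequency noise.  Splitting the trace at 100 Hz with a
zero-phase Butterworth filter and summarizing each event by the standard
deviation of its low-pass and high-pass portions yields a two-dimensional
feature space in which a support-vector classifier separates the analyte
classes; a confusion matrix and a decision-boundary grid summarize the
result.

The high-pass portion is defined as the residual ``x - lowpass(x)``, so the
split reconstructs the input exactly.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .errors import ConfigurationError, TrivialModelWarning
from .idealize import DetectionSettings, EventTable, _guard_samples
from .simulate import SimulatedTrace

__all__ = [
    "SplitTrace",
    "EventFeatures",
    "frequency_split",
    "extract_features",
    "features_to_frame",
    "EventClassifier",
    "train_classifier",
    "classify",
    "ConfusionMatrix",
    "confusion_matrix",
    "decision_boundary_grid",
]


@dataclass(frozen=True)
class SplitTrace:
    """Low-pass / high-pass decomposition of a trace (lp + hp = input)."""

    low_pass: np.ndarray
    high_pass: np.ndarray
    cutoff: float
    order: int
    zero_phase: bool = True
    sampling_rate: float = 25_000.0

    @property
    def total(self) -> np.ndarray:
        return self.low_pass + self.high_pass


def frequency_split(
    trace: SimulatedTrace | np.ndarray,
    cutoff: float = 100.0,
    order: int = 4,
    *,
    sampling_rate: float | None = None,
    zero_phase: bool = True,
) -> SplitTrace:
    """Split a trace into low-pass and high-pass portions at ``cutoff`` Hz.

    A Butterworth low-pass (zero-phase by default, i.e. forward-backward so
    event shapes are not skewed) produces the low-pass portion; the
    high-pass portion is the exact residual ``x - lp``.
    """
    if isinstance(trace, SimulatedTrace):
        x = trace.samples
        fs = trace.sampling_rate
    else:
        x = np.asarray(trace, dtype=float)
        if sampling_rate is None:
            raise ConfigurationError("sampling_rate required for a bare array")
        fs = sampling_rate
    if not (0 < cutoff < fs / 2):
        raise ConfigurationError("cutoff must lie in (0, Nyquist)")
    sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    if zero_phase:
        lp = signal.sosfiltfilt(sos, x)
    else:
        zi = signal.sosfilt_zi(sos) * x[0]
        lp, _ = signal.sosfilt(sos, x, zi=zi)
    return SplitTrace(
        low_pass=lp,
        high_pass=x - lp,
        cutoff=cutoff,
        order=order,
        zero_phase=zero_phase,
        sampling_rate=fs,
    )


@dataclass(frozen=True)
class EventFeatures:
    """Per-event frequency-split noise features (pA)."""

    event_id: int
    lp_sd: float
    hp_sd: float
    label: str | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.lp_sd < 0 or self.hp_sd < 0:
            raise ConfigurationError("feature SDs must be >= 0")


def extract_features(
    split: SplitTrace,
    events: EventTable,
    *,
    trace: SimulatedTrace | None = None,
    settings: DetectionSettings | None = None,
    labels=None,
    include_extras: bool = False,
    split_guard_factor: float = 1.5,
) -> list[EventFeatures]:
    """Per-event SD of the low-pass and high-pass portions.

    Edge guard bands of ``split_guard_factor / cutoff`` seconds (default
    1.5/fc, enough for the zero-phase split filter's step ringing to settle
    below ~0.5%) are trimmed from each event end so the blockade's own
    rise/fall does not masquerade as low-frequency noise.  Events too short
    for the guards use the full window and are flagged via a
    ``"short_for_guard"`` extra.
    """
    settings = settings or DetectionSettings()
    guard = _guard_samples(trace, settings) if trace is not None else 1
    guard = max(
        guard, int(np.ceil(split_guard_factor * split.sampling_rate / split.cutoff))
    )
    n = split.low_pass.size
    out: list[EventFeatures] = []
    for i, ev in enumerate(events):
        lo, hi = ev.start + guard, ev.end - guard
        flagged = False
        if hi - lo < 2:
            lo, hi = ev.start, ev.end
            flagged = True
        lo, hi = max(0, lo), min(n, hi)
        lp_sd = float(np.std(split.low_pass[lo:hi]))
        hp_sd = float(np.std(split.high_pass[lo:hi]))
        label = None
        if labels is not None:
            label = labels[i]
        elif ev.label is not None:
            label = ev.label
        extras = {}
        if include_extras:
            extras = {"delta_I": ev.delta_I, "t_off": ev.t_off}
        if flagged:
            extras["short_for_guard"] = True
        out.append(EventFeatures(i, lp_sd, hp_sd, label, extras))
    return out


def features_to_frame(features: list[EventFeatures]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "event_id": [f.event_id for f in features],
            "lp_sd_pA": [f.lp_sd for f in features],
            "hp_sd_pA": [f.hp_sd for f in features],
            "label": ["" if f.label is None else f.label for f in features],
        }
    )


def _feature_matrix(features) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        return features[["lp_sd_pA", "hp_sd_pA"]].to_numpy(dtype=float)
    if len(features) == 0:
        return np.empty((0, 2))
    if isinstance(features[0], EventFeatures):
        return np.array([[f.lp_sd, f.hp_sd] for f in features], dtype=float)
    return np.asarray(features, dtype=float).reshape(len(features), -1)


class EventClassifier:
    """Support-vector classification of events in (lp_sd, hp_sd) space.

    Features are z-scored on the training set; the default kernel is RBF
    with C = 1 and gamma = 'scale'.  ``tune=True`` selects C and gamma by
    5-fold cross-validated grid search.
    """

    def __init__(
        self,
        kernel: str = "rbf",
        C: float = 1.0,
        gamma="scale",
        seed: int = 0,
    ):
        self.kernel = kernel
        self.C = C
        self.gamma = gamma
        self.seed = seed
        self.pipeline_ = None
        self.classes_: np.ndarray | None = None
        self.training_hash_: str | None = None

    def fit(self, features, labels, *, tune: bool = False) -> "EventClassifier":
        from sklearn.model_selection import GridSearchCV
        from sklearn.pipeline import Pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVC

        X = _feature_matrix(features)
        y = np.asarray(labels)
        if X.shape[0] != y.shape[0]:
            raise ConfigurationError("features and labels differ in length")
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            warnings.warn(
                "single-class training set; the model will always predict it",
                TrivialModelWarning,
                stacklevel=2,
            )
            self.pipeline_ = None
            self.classes_ = classes
            self.training_hash_ = self._hash(X, y)
            return self
        if counts.min() < 10:
            raise ConfigurationError("need >= 10 events per class")

        pipe = Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "svc",
                    SVC(kernel=self.kernel, C=self.C, gamma=self.gamma,
                        random_state=self.seed),
                ),
            ]
        )
        if tune:
            grid = {"svc__C": [0.1, 1, 10, 100], "svc__gamma": ["scale", 0.01, 0.1, 1]}
            search = GridSearchCV(pipe, grid, cv=5)
            search.fit(X, y)
            pipe = search.best_estimator_
        else:
            pipe.fit(X, y)
        self.pipeline_ = pipe
        self.classes_ = classes
        self.training_hash_ = self._hash(X, y)
        return self

    @staticmethod
    def _hash(X: np.ndarray, y: np.ndarray) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(X).tobytes())
        h.update("|".join(map(str, y)).encode())
        return h.hexdigest()[:16]

    def predict(self, features) -> np.ndarray:
        if self.classes_ is None:
            raise ConfigurationError("classifier is not trained")
        X = _feature_matrix(features)
        if X.shape[0] == 0:
            return np.array([], dtype=self.classes_.dtype)
        if self.pipeline_ is None:  # trivial single-class model
            return np.full(X.shape[0], self.classes_[0])
        if X.shape[1] != self.pipeline_.named_steps["scale"].n_features_in_:
            raise ConfigurationError("feature dimension mismatch")
        return self.pipeline_.predict(X)

    @property
    def support_vectors_(self) -> np.ndarray:
        if self.pipeline_ is None:
            raise ConfigurationError("classifier is not trained")
        return self.pipeline_.named_steps["svc"].support_vectors_

    def save(self, path) -> None:
        import joblib

        joblib.dump(
            {
                "pipeline": self.pipeline_,
                "classes": self.classes_,
                "training_hash": self.training_hash_,
                "params": {"kernel": self.kernel, "C": self.C, "gamma": self.gamma,
                           "seed": self.seed},
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "EventClassifier":
        import joblib

        blob = joblib.load(path)
        obj = cls(**blob["params"])
        obj.pipeline_ = blob["pipeline"]
        obj.classes_ = blob["classes"]
        obj.training_hash_ = blob["training_hash"]
        return obj


def train_classifier(features, labels, *, seed: int = 0, tune: bool = False,
                     **hyperparams) -> EventClassifier:
    """Train an :class:`EventClassifier` (functional wrapper)."""
    return EventClassifier(seed=seed, **hyperparams).fit(features, labels, tune=tune)


def classify(model: EventClassifier, features) -> np.ndarray:
    """Predict one label per event (functional wrapper)."""
    return model.predict(features)


@dataclass(frozen=True)
class ConfusionMatrix:
    """True-by-predicted count matrix with per-class and overall accuracy."""

    counts: pd.DataFrame
    per_class_accuracy: pd.Series
    overall_accuracy: float

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t")


def confusion_matrix(true_labels, predicted_labels) -> ConfusionMatrix:
    """Confusion matrix over the union of labels, in lexicographic order.

    Per-class accuracy is the recall (diagonal over row sum); overall
    accuracy is trace over total.  Labels absent from truth or prediction
    appear as zero rows/columns.
    """
    y_true = np.asarray(true_labels)
    y_pred = np.asarray(predicted_labels)
    if y_true.shape[0] != y_pred.shape[0]:
        raise ConfigurationError("label lists differ in length")
    labels = sorted(set(map(str, y_true)) | set(map(str, y_pred)))
    from sklearn.metrics import confusion_matrix as _sk_cm

    cm = _sk_cm([str(v) for v in y_true], [str(v) for v in y_pred], labels=labels)
    counts = pd.DataFrame(cm, index=labels, columns=labels)
    row_sums = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class = pd.Series(np.diag(cm), index=labels) / row_sums.replace(0, np.nan)
    overall = float(np.trace(cm) / cm.sum()) if cm.sum() else float("nan")
    return ConfusionMatrix(counts, per_class, overall)


def decision_boundary_grid(
    model: EventClassifier,
    lp_range: tuple[float, float],
    hp_range: tuple[float, float],
    resolution: int = 200,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Classify a dense (lp_sd, hp_sd) grid for decision-region plotting.

    Returns ``(lp_values, hp_values, labels)`` where ``labels`` has shape
    ``(resolution, resolution)`` with rows indexed by hp and columns by lp.
    """
    if not (lp_range[0] < lp_range[1]) or not (hp_range[0] < hp_range[1]):
        raise ConfigurationError("grid ranges must have min < max")
    if resolution < 2:
        raise ConfigurationError("resolution must be >= 2")
    lp = np.linspace(*lp_range, resolution)
    hp = np.linspace(*hp_range, resolution)
    LP, HP = np.meshgrid(lp, hp)
    pts = np.column_stack([LP.ravel(), HP.ravel()])
    labels = model.predict(pts).reshape(resolution, resolution)
    return lp, hp, labels
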