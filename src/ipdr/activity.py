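"""Windowed activity classification: walk vs jog vs run.

The bout label selects the stride template and the zero-velocity strategy
downstream, so classification happens before segmentation.  The signal is
cut into 1 s windows (200 samples at 200 Hz) with 50% overlap; per window
and per axis the features are the trapezoidal integral of the accelerometer
(a velocity-like quantity, gravity left in as a shared offset), the
trapezoidal integral of the gyroscope (an angle), and the energy (sum of
squares) of both sensors — 12 features per window.  Windows are classified
independently and the bout label is the majority vote, ties resolved toward
the slower activity.

The default backend mirrors a support-vector classifier with a third-order
polynomial kernel; features are z-scored from the training set (required
for kernel stability).  Any estimator with fit/predict can be plugged in.
Training data comes from the synthetic gait generator unless the user
supplies labelled recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import DataError, IPDRError
from .imu_core import IMUSequence

WINDOW = 200
STEP = 100

#: slowest-first order used for majority-vote tie breaking
ACTIVITY_ORDER = ("walk", "jog", "run")

MODEL_FORMAT_VERSION = 1


@dataclass
class FeatureWindow:
    """One 200-sample analysis window and its 12-dimensional feature vector."""

    start: int
    features: np.ndarray
    label: str | None = None


def _window_features(acc: np.ndarray, gyr: np.ndarray, dt: float) -> np.ndarray:
    feats = [np.trapezoid(acc, dx=dt, axis=0),      # per-axis velocity, m/s
             np.trapezoid(gyr, dx=dt, axis=0),      # per-axis angle, deg
             np.sum(acc ** 2, axis=0),              # accelerometer energy
             np.sum(gyr ** 2, axis=0)]              # gyroscope energy
    return np.concatenate(feats)


def extract_features(seq: IMUSequence) -> list[FeatureWindow]:
    """Sliding-window feature extraction (window 200, step 100 samples)."""
    n = len(seq)
    if n < WINDOW:
        raise DataError(f"sequence of {n} samples shorter than one window "
                        f"({WINDOW})")
    dt = 1.0 / seq.rate_hz
    label = seq.meta.get("activity")
    out = []
    for start in range(0, n - WINDOW + 1, STEP):
        f = _window_features(seq.acc[start:start + WINDOW],
                             seq.gyr[start:start + WINDOW], dt)
        out.append(FeatureWindow(start=start, features=f, label=label))
    return out


def feature_matrix(windows: list[FeatureWindow]) -> np.ndarray:
    return np.stack([w.features for w in windows])


def majority_vote(labels) -> str:
    """Most frequent label; ties go to the slower activity."""
    labels = list(labels)
    if not labels:
        raise ValueError("no window predictions to vote over")
    counts = {a: labels.count(a) for a in set(labels)}
    best = max(counts.values())
    for a in ACTIVITY_ORDER:
        if counts.get(a, 0) == best:
            return a
    return max(counts, key=counts.get)  # non-standard labels


class ActivityClassifier:
    """Pluggable per-window classifier with majority-vote bout labelling."""

    def __init__(self, estimator=None):
        self.pipeline = Pipeline([
            ("scale", StandardScaler()),
            ("clf", estimator if estimator is not None
             else SVC(kernel="poly", degree=3, C=10.0)),
        ])
        self.fitted = False
        self.training_meta: dict = {}

    def fit(self, windows: list[FeatureWindow], labels=None) -> "ActivityClassifier":
        y = list(labels) if labels is not None else [w.label for w in windows]
        if any(v is None for v in y):
            raise DataError("every training window needs a label")
        X = feature_matrix(windows)
        self.pipeline.fit(X, y)
        self.fitted = True
        self.training_meta = {"n_windows": len(y),
                              "classes": sorted(set(y))}
        return self

    def predict(self, windows: list[FeatureWindow]) -> list[str]:
        if not self.fitted:
            raise IPDRError("classifier is not trained")
        return list(self.pipeline.predict(feature_matrix(windows)))

    def classify_bout(self, windows: list[FeatureWindow]) -> str:
        return majority_vote(self.predict(windows))

    # -- persistence --------------------------------------------------------
    def save(self, path: str | Path) -> None:
        joblib.dump({"format_version": MODEL_FORMAT_VERSION,
                     "pipeline": self.pipeline,
                     "training_meta": self.training_meta}, path)

    @classmethod
    def load(cls, path: str | Path) -> "ActivityClassifier":
        blob = joblib.load(path)
        if blob.get("format_version") != MODEL_FORMAT_VERSION:
            raise IPDRError("unsupported model file version")
        obj = cls()
        obj.pipeline = blob["pipeline"]
        obj.training_meta = blob.get("training_meta", {})
        obj.fitted = True
        return obj


def classify_bout(windows: list[FeatureWindow], model: ActivityClassifier) -> str:
    """Per-window prediction followed by majority vote."""
    return model.classify_bout(windows)


def train_synthetic_classifier(
    seed: int = 0, seconds_per_activity: float = 40.0, noisy: bool = True
) -> ActivityClassifier:
    """Train the default classifier on generated bouts of all activities."""
    from .synthetic_gait import GaitPlan, NoiseModel, plan_trajectory, synthesize_imu

    windows: list[FeatureWindow] = []
    for i, activity in enumerate(ACTIVITY_ORDER):
        stride_t = GaitPlan(activity=activity, n_strides=1).stride_times()[0]
        n = max(4, int(round(seconds_per_activity / stride_t)))
        plan = GaitPlan(activity=activity, n_strides=n,
                        lead_in_s=0.5, lead_out_s=0.5,
                        jitter_frac=0.05, jitter_seed=seed + i)
        gt = plan_trajectory(plan)
        noise = NoiseModel(seed=seed + 100 + i) if noisy else NoiseModel.zero()
        seq = synthesize_imu(gt, noise)
        windows.extend(extract_features(seq))
    return ActivityClassifier().fit(windows)
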