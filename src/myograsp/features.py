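"""Sliding-window segmentation and time-domain sEMG features.

A recording is cut into overlapped analysis frames (250 ms windows
advanced by 100 ms by default, the standard low-latency myoelectric
configuration) and each frame is summarised by per-channel time-domain
statistics: integrated EMG (iEMG), root mean square (RMS), mean absolute
value (MAV), thresholded zero crossings (ZC), sample variance (VAR) and
the raw minimum (MIN).  The default feature selection for gesture
recognition is {VAR, RMS, MIN}.

Feature columns are ordered channel-major, feature-minor:
``ch1_VAR, ch1_RMS, ch1_MIN, ch2_VAR, ...``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import WindowingError
from .recording import SignalRecording

DEFAULT_FEATURES = ("VAR", "RMS", "MIN")
ZC_DEFAULT_THRESHOLD = 0.01  # mV; suppresses baseline-noise crossings


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in milliseconds."""

    window_ms: float = 250.0
    step_ms: float = 100.0

    def __post_init__(self):
        if not (0 < self.step_ms <= self.window_ms):
            raise ValueError(
                f"need 0 < step_ms <= window_ms, got {self.step_ms}/{self.window_ms}"
            )

    def in_samples(self, sampling_rate: float) -> tuple[int, int]:
        """(window, step) as exact whole sample counts."""
        w = self.window_ms * sampling_rate / 1000.0
        s = self.step_ms * sampling_rate / 1000.0
        if abs(w - round(w)) > 1e-9 or abs(s - round(s)) > 1e-9:
            raise ValueError(
                f"window/step ({self.window_ms}/{self.step_ms} ms) do not "
                f"convert to whole samples at {sampling_rate} Hz"
            )
        return int(round(w)), int(round(s))


@dataclass
class WindowFrame:
    """One analysis frame: ``(n_channels, W)`` samples and its label."""

    start_index: int
    samples: np.ndarray
    label: str = "rest"


@dataclass
class LabeledFeatureSet:
    """Per-window feature matrix with gesture labels."""

    matrix: np.ndarray          # (n_windows, d)
    labels: np.ndarray          # (n_windows,) gesture strings
    feature_names: list         # d strings

    def __post_init__(self):
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        self.labels = np.asarray(self.labels, dtype=object)
        if self.matrix.shape[0] != len(self.labels):
            raise ValueError("matrix rows and labels disagree")
        if self.matrix.shape[1] != len(self.feature_names):
            raise ValueError("matrix columns and feature_names disagree")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_windows(self) -> int:
        return self.matrix.shape[0]

    def select(self, mask) -> "LabeledFeatureSet":
        return LabeledFeatureSet(self.matrix[mask], self.labels[mask],
                                 list(self.feature_names))

    def restrict_classes(self, classes) -> "LabeledFeatureSet":
        """Keep only windows whose label is in ``classes``."""
        keep = set(str(getattr(c, "value", c)) for c in classes)
        return self.select(np.isin(self.labels.astype(str), sorted(keep)))


def _majority_label(window_labels: np.ndarray) -> str:
    """Majority per-sample label; ties go to the earlier-starting gesture."""
    values, counts = np.unique(window_labels.astype(str), return_counts=True)
    top = counts.max()
    tied = values[counts == top]
    if len(tied) == 1:
        return str(tied[0])
    firsts = {v: int(np.argmax(window_labels.astype(str) == v)) for v in tied}
    return min(tied, key=lambda v: firsts[v])


def segment(rec: SignalRecording, spec: WindowSpec | None = None) -> list:
    """Cut a recording into left-aligned overlapped frames.

    Returns ``floor((N - W)/S) + 1`` frames.  Each frame's label is the
    majority of its per-sample labels (ties to the earlier-starting
    gesture); unlabeled recordings produce ``rest``-labelled frames.

    Raises
    ------
    WindowingError
        If the recording is shorter than one window.
    """
    spec = spec or WindowSpec()
    w, s = spec.in_samples(rec.sampling_rate)
    n = rec.n_samples
    if n < w:
        raise WindowingError(
            f"recording of {n} samples is shorter than one {w}-sample window"
        )
    frames = []
    for start in range(0, n - w + 1, s):
        sl = slice(start, start + w)
        label = ("rest" if rec.labels is None
                 else _majority_label(rec.labels[sl]))
        frames.append(WindowFrame(start, rec.samples[:, sl], label))
    return frames


def n_windows(n_samples: int, window: int, step: int) -> int:
    """Closed-form frame count for N samples, window W, step S."""
    if n_samples < window:
        return 0
    return (n_samples - window) // step + 1


# ---------------------------------------------------------------------------
# Per-channel features.  Each takes a 1-D window of W samples (mV).

def _as_window(x, min_len=1) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < min_len:
        raise ValueError(f"window must have >= {min_len} samples, got {x.size}")
    return x


def feature_iemg(window, dt: float) -> float:
    """Integrated EMG: sum of |x_n| * dt over the window (mV*s)."""
    x = _as_window(window)
    if dt <= 0:
        raise ValueError("dt must be > 0")
    return float(np.sum(np.abs(x)) * dt)


def feature_rms(window) -> float:
    """Root mean square: sqrt(mean(x^2)) (mV)."""
    x = _as_window(window)
    return float(np.sqrt(np.mean(x**2)))


def feature_mav(window) -> float:
    """Mean absolute value (mV)."""
    x = _as_window(window)
    return float(np.mean(np.abs(x)))


def feature_zc(window, threshold: float = ZC_DEFAULT_THRESHOLD,
               printed_rule: bool = False) -> int:
    """Thresholded zero-crossing count.

    Default rule (standard practice): count consecutive pairs with a
    sign change (``x_n * x_{n-1} < 0``) whose amplitude difference is at
    least ``threshold``.

    ``printed_rule=True`` selects an alternative literal rule sometimes
    seen in print, which counts pairs whose *product* is at or above the
    threshold (i.e. non-crossing pairs); it is retained for auditability
    only.
    """
    x = _as_window(window, min_len=2)
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    prod = x[1:] * x[:-1]
    big_step = np.abs(x[1:] - x[:-1]) >= threshold
    if printed_rule:
        return int(np.sum((prod >= threshold) & big_step))
    return int(np.sum((prod < 0) & big_step))


def feature_var(window) -> float:
    """Unbiased sample variance, (n-1) denominator (mV^2)."""
    x = _as_window(window, min_len=2)
    return float(np.var(x, ddof=1))


def feature_min(window) -> float:
    """Raw minimum sample value in the window (mV)."""
    x = _as_window(window)
    return float(np.min(x))


FEATURE_REGISTRY = {
    "iEMG": lambda x, fs: feature_iemg(x, 1.0 / fs),
    "RMS": lambda x, fs: feature_rms(x),
    "MAV": lambda x, fs: feature_mav(x),
    "ZC": lambda x, fs: float(feature_zc(x)),
    "VAR": lambda x, fs: feature_var(x),
    "MIN": lambda x, fs: feature_min(x),
}


def feature_names_for(n_channels: int, features=DEFAULT_FEATURES) -> list:
    return [f"ch{ch + 1}_{feat}" for ch in range(n_channels) for feat in features]


def extract_features(frames, feature_names=DEFAULT_FEATURES,
                     sampling_rate: float = 1000.0) -> LabeledFeatureSet:
    """Build a labelled feature matrix from a sequence of frames.

    One row per frame; columns are channel-major, feature-minor in the
    order of ``feature_names``.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("frames must be non-empty")
    unknown = [f for f in feature_names if f not in FEATURE_REGISTRY]
    if unknown:
        raise ValueError(
            f"unknown feature names {unknown}; "
            f"choose from {sorted(FEATURE_REGISTRY)}"
        )
    n_ch = frames[0].samples.shape[0]
    rows = np.empty((len(frames), n_ch * len(feature_names)))
    for i, frame in enumerate(frames):
        col = 0
        for ch in range(n_ch):
            for feat in feature_names:
                rows[i, col] = FEATURE_REGISTRY[feat](frame.samples[ch], sampling_rate)
                col += 1
    labels = np.asarray([f.label for f in frames], dtype=object)
    return LabeledFeatureSet(rows, labels, feature_names_for(n_ch, feature_names))
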