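"""Core signal containers: gesture labels and multi-channel sEMG recordings."""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np


class GestureLabel(str, Enum):
    """The three gesture states of the two-class grasp/open protocol.

    ``GRASP`` and ``OPEN`` are the classifier classes; ``REST`` occurs only
    between activation bouts and is excluded from training by default.
    """

    REST = "rest"
    OPEN = "open"
    GRASP = "grasp"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical label order used wherever classes must be ordered
#: deterministically (lexicographic, matching ``numpy.unique`` on the
#: string values): grasp < open < rest.
LABEL_VOCABULARY = tuple(sorted(g.value for g in GestureLabel))


def as_label_array(labels) -> np.ndarray:
    """Coerce a label sequence to a validated array of label strings."""
    arr = np.asarray([str(getattr(v, "value", v)) for v in labels], dtype=object)
    bad = set(arr) - set(LABEL_VOCABULARY)
    if bad:
        raise ValueError(f"unknown gesture labels: {sorted(bad)}")
    return arr


@dataclass
class SignalRecording:
    """A multi-channel sEMG time series in millivolts.

    Parameters
    ----------
    samples
        ``(n_channels, n_samples)`` array, mV.
    sampling_rate
        Samples per second (Hz).
    labels
        Optional per-sample gesture annotation, same length as the time
        axis.
    subject_id
        Free-form identifier carried through file I/O.
    """

    samples: np.ndarray
    sampling_rate: float
    labels: np.ndarray | None = None
    subject_id: str = ""

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.labels is not None:
            self.labels = as_label_array(self.labels)
            if len(self.labels) != self.n_samples:
                raise ValueError(
                    f"labels length {len(self.labels)} != n_samples {self.n_samples}"
                )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_samples) / self.sampling_rate
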