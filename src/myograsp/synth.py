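"""Seeded synthetic two-channel sEMG with gesture-dependent activation.

Surface EMG over a contracting muscle looks like band-limited noise whose
amplitude tracks neuromuscular drive.  The generator emulates the signal
envelope of a typical two-electrode acquisition chain — peak amplitude in
the 0-6 mV range, spectral content concentrated in 20-450 Hz, sampled at
1000 Hz — by amplitude-modulating band-pass-shaped Gaussian noise with a
smoothed per-gesture activation gate, then adding baseline sensor noise
and an optional 50 Hz powerline tone.  The two channels stand in for two
distinct forearm muscles: by default channel 1 responds more strongly to
grasping and channel 2 to hand opening, which is what gives downstream
classifiers a learnable structure.

All randomness flows from the single ``seed`` in :class:`SynthParams`;
identical parameters and schedule are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .recording import GestureLabel, SignalRecording, as_label_array

#: Hard amplitude bound (mV): the acquisition chain saturates here, which
#: also enforces the documented 0-6 mV peak envelope at any gain.
SATURATION_MV = 6.0


def _default_gains() -> dict:
    # mV noise scale per (gesture, channel); rest drives nothing.
    return {
        GestureLabel.REST.value: (0.0, 0.0),
        GestureLabel.GRASP.value: (1.5, 0.4),
        GestureLabel.OPEN.value: (0.4, 1.5),
    }


@dataclass
class SynthParams:
    """Generator configuration.

    Attributes
    ----------
    sampling_rate
        Hz; the acquisition chain samples at 1000 Hz by default.
    n_channels
        Number of electrode channels (default 2).
    baseline_noise_sd
        mV standard deviation of unmodulated sensor noise.
    activation_gain
        Mapping gesture value -> per-channel mV scale of the activity
        noise.  Missing gestures default to zero drive.
    envelope_rise_ms
        Time constant of the first-order lag smoothing the rectangular
        gesture gate (real neuromuscular drive has no discontinuities).
    powerline_amp
        mV amplitude of an additive 50 Hz mains tone (0 disables).
    bandwidth
        (low, high) Hz band of the activity noise shaping filter.
    seed
        Integer seed; the only source of randomness.
    """

    sampling_rate: float = 1000.0
    n_channels: int = 2
    baseline_noise_sd: float = 0.02
    activation_gain: dict = field(default_factory=_default_gains)
    envelope_rise_ms: float = 50.0
    powerline_amp: float = 0.05
    powerline_freq: float = 50.0
    bandwidth: tuple = (20.0, 450.0)
    seed: int = 0

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.baseline_noise_sd < 0 or self.powerline_amp < 0:
            raise ValueError("noise amplitudes must be >= 0")
        for g, gains in self.activation_gain.items():
            if np.any(np.asarray(gains, dtype=float) < 0):
                raise ValueError(f"activation_gain[{g!r}] must be >= 0")

    def gains_for(self, gesture: str) -> np.ndarray:
        g = self.activation_gain.get(str(getattr(gesture, "value", gesture)))
        if g is None:
            return np.zeros(self.n_channels)
        g = np.asarray(g, dtype=float)
        if g.size == 1:
            g = np.full(self.n_channels, float(g))
        if g.size != self.n_channels:
            raise ValueError(
                f"activation gain for {gesture!r} has {g.size} entries, "
                f"expected {self.n_channels}"
            )
        return g


def _schedule_labels(schedule, sampling_rate: float) -> np.ndarray:
    """Expand a (gesture, duration_s) schedule into per-sample labels."""
    if not schedule:
        raise ValueError("schedule must be non-empty")
    parts = []
    for gesture, duration in schedule:
        if duration <= 0:
            raise ValueError(f"schedule durations must be > 0, got {duration}")
        n = int(round(duration * sampling_rate))
        parts.append(np.repeat(str(getattr(gesture, "value", gesture)), n))
    return as_label_array(np.concatenate(parts))


def _shaped_noise(rng: np.random.Generator, n: int, band, fs: float) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to ``band``."""
    white = rng.standard_normal(n)
    low, high = band
    high = min(high, 0.499 * fs)
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    shaped = sps.sosfilt(sos, white)
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


def _smooth_gate(gate: np.ndarray, rise_ms: float, fs: float) -> np.ndarray:
    """First-order lag with time constant ``rise_ms`` applied to a gate."""
    if rise_ms <= 0:
        return gate
    alpha = 1.0 - np.exp(-1.0 / (fs * rise_ms / 1000.0))
    return sps.lfilter([alpha], [1.0, -(1.0 - alpha)], gate)


def generate_recording(schedule, params: SynthParams) -> SignalRecording:
    """Generate a labelled recording following a gesture schedule.

    Parameters
    ----------
    schedule
        Sequence of ``(GestureLabel, duration_s)`` pairs; durations must
        be positive.
    params
        :class:`SynthParams`; ``params.seed`` fully determines the output.

    Returns
    -------
    SignalRecording
        ``n_channels`` x ``n_samples`` mV samples with per-sample labels
        matching the schedule.
    """
    labels = _schedule_labels(schedule, params.sampling_rate)
    n = len(labels)
    fs = params.sampling_rate
    rng = np.random.default_rng(params.seed)

    # Per-channel target amplitude trace from the gesture schedule.
    gain_by_gesture = {g: params.gains_for(g) for g in np.unique(labels)}
    target = np.zeros((params.n_channels, n))
    for g, gains in gain_by_gesture.items():
        mask = labels == g
        target[:, mask] = gains[:, None]

    samples = np.zeros((params.n_channels, n))
    for ch in range(params.n_channels):
        envelope = _smooth_gate(target[ch], params.envelope_rise_ms, fs)
        activity = _shaped_noise(rng, n, params.bandwidth, fs) * envelope
        baseline = (
            rng.standard_normal(n) * params.baseline_noise_sd
            if params.baseline_noise_sd > 0
            else 0.0
        )
        if params.powerline_amp > 0:
            phase = rng.uniform(0, 2 * np.pi)
            t = np.arange(n) / fs
            powerline = params.powerline_amp * np.sin(
                2 * np.pi * params.powerline_freq * t + phase
            )
        else:
            powerline = 0.0
        samples[ch] = activity + baseline + powerline

    np.clip(samples, -SATURATION_MV, SATURATION_MV, out=samples)
    return SignalRecording(samples=samples, sampling_rate=fs, labels=labels)


def make_subject_dataset(
    params: SynthParams,
    n_reps: int = 10,
    hold_s: float = 5.0,
    rest_s: float = 2.0,
    subject_id: str = "",
) -> SignalRecording:
    """Emulate one subject's acquisition session.

    The session alternates grasp and open bouts of ``hold_s`` seconds,
    separated by ``rest_s`` of rest, repeating each gesture ``n_reps``
    times (default 10 repetitions of 5 s holds, the standard protocol for
    collecting a balanced two-gesture training set).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    schedule = []
    for _ in range(n_reps):
        schedule.append((GestureLabel.GRASP, hold_s))
        schedule.append((GestureLabel.REST, rest_s))
        schedule.append((GestureLabel.OPEN, hold_s))
        schedule.append((GestureLabel.REST, rest_s))
    rec = generate_recording(schedule, params)
    rec.subject_id = subject_id
    return rec


def make_cohort(
    n_subjects: int,
    base_params: SynthParams | None = None,
    n_reps: int = 10,
    hold_s: float = 5.0,
    seed: int = 0,
) -> list[SignalRecording]:
    """Generate a cohort of independent subjects with derived seeds."""
    params = base_params or SynthParams()
    root = np.random.SeedSequence(seed)
    subject_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(n_subjects)]
    return [
        make_subject_dataset(
            replace(params, seed=s), n_reps=n_reps, hold_s=hold_s,
            subject_id=f"S{i + 1}",
        )
        for i, s in enumerate(subject_seeds)
    ]
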