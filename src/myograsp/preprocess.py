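"""Signal conditioning: gain, band-pass, and powerline notch.

The conditioning chain mirrors a standard surface-EMG front end: a gain
stage (software default 1.0 — amplification is a hardware concern, so
units stay in mV), a Butterworth band-pass spanning the useful EMG band,
and a narrow notch at the mains frequency.  Both filters are applied
zero-phase (forward-backward) so gesture labels stay aligned with the
underlying activity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .recording import SignalRecording


@dataclass(frozen=True)
class FilterSpec:
    """Conditioning-chain parameters.

    Defaults are the standard surface-EMG choices consistent with signal
    content in 0-500 Hz at a 1000 Hz sampling rate: 4th-order band-pass
    20-450 Hz plus a 50 Hz notch (Q = 30).  The notch frequency is
    configurable to 60 Hz for other mains regions.
    """

    bandpass_low: float = 20.0
    bandpass_high: float = 450.0
    bandpass_order: int = 4
    notch_freq: float = 50.0
    notch_q: float = 30.0
    gain: float = 1.0

    def validate(self, sampling_rate: float) -> None:
        nyq = sampling_rate / 2.0
        if not (0 < self.bandpass_low < self.bandpass_high < nyq):
            raise ValueError(
                f"band edges must satisfy 0 < {self.bandpass_low} < "
                f"{self.bandpass_high} < Nyquist ({nyq} Hz)"
            )
        if not (0 < self.notch_freq < nyq):
            raise ValueError(f"notch_freq must lie in (0, {nyq}) Hz")
        if self.notch_q <= 0:
            raise ValueError("notch_q must be > 0")
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.bandpass_order < 1:
            raise ValueError("bandpass_order must be >= 1")

    def _sos(self, fs: float):
        return sps.butter(
            self.bandpass_order,
            [self.bandpass_low, self.bandpass_high],
            btype="bandpass", fs=fs, output="sos",
        )

    def _notch_ba(self, fs: float):
        return sps.iirnotch(self.notch_freq, self.notch_q, fs=fs)

    def min_samples(self, fs: float) -> int:
        """Shortest recording the zero-phase chain can condition."""
        sos = self._sos(fs)
        b, a = self._notch_ba(fs)
        pad_bp = 3 * (2 * sos.shape[0] + 1)      # sosfiltfilt default padlen
        pad_notch = 3 * max(len(a), len(b))      # filtfilt default padlen
        return max(pad_bp, pad_notch, 3 * self.bandpass_order) + 1


def condition_signal(rec: SignalRecording, spec: FilterSpec | None = None) -> SignalRecording:
    """Apply the conditioning chain to every channel of a recording.

    Returns a new recording of identical shape, labels, and metadata.
    The operation is linear and zero-phase.
    """
    spec = spec or FilterSpec()
    spec.validate(rec.sampling_rate)
    if rec.n_samples < spec.min_samples(rec.sampling_rate):
        raise ValueError(
            f"recording of {rec.n_samples} samples is too short for the "
            f"filter chain (need >= {spec.min_samples(rec.sampling_rate)})"
        )
    y = rec.samples * spec.gain
    y = sps.sosfiltfilt(spec._sos(rec.sampling_rate), y, axis=-1)
    b, a = spec._notch_ba(rec.sampling_rate)
    y = sps.filtfilt(b, a, y, axis=-1)
    return SignalRecording(
        samples=y,
        sampling_rate=rec.sampling_rate,
        labels=None if rec.labels is None else rec.labels.copy(),
        subject_id=rec.subject_id,
    )


def filter_response(spec: FilterSpec, sampling_rate: float, freqs) -> np.ndarray:
    """Magnitude response (dB) of the conditioning chain as applied.

    Because both filters run forward-backward, the effective magnitude
    response is the squared single-pass magnitude; the returned gain in
    dB reflects that.
    """
    spec.validate(sampling_rate)
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size == 0:
        raise ValueError("freqs must be non-empty")
    nyq = sampling_rate / 2.0
    if np.any(freqs <= 0) or np.any(freqs >= nyq):
        raise ValueError(f"freqs must lie strictly inside (0, {nyq}) Hz")
    w = 2 * np.pi * freqs / sampling_rate
    _, h_bp = sps.sosfreqz(spec._sos(sampling_rate), worN=w)
    b, a = spec._notch_ba(sampling_rate)
    _, h_n = sps.freqz(b, a, worN=w)
    mag = spec.gain * np.abs(h_bp) ** 2 * np.abs(h_n) ** 2
    with np.errstate(divide="ignore"):
        return 20.0 * np.log10(mag)
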