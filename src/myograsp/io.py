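"""Delimited-text readers and writers for recordings and feature sets.

Recordings travel as plain CSV with a small commented metadata header:

    # myograsp-recording v1
    # sampling_rate_hz: 1000.0
    # subject_id: S1
    t_s,ch1_mV,ch2_mV,label
    0.000000,0.0123,-0.0045,rest
    ...

The ``label`` column is optional; the channel count is taken from the
``chN_mV`` headers, never hardcoded.  Values round-trip at full double
precision.
"""

from __future__ import annotations

import io as _io
import re

import numpy as np
import pandas as pd

from .errors import FormatError
from .features import LabeledFeatureSet
from .recording import SignalRecording

_CH_PATTERN = re.compile(r"^ch(\d+)_mV$")


def write_recording(rec: SignalRecording, path) -> None:
    with open(path, "w") as fh:
        fh.write("# myograsp-recording v1\n")
        fh.write(f"# sampling_rate_hz: {rec.sampling_rate!r}\n")
        fh.write(f"# subject_id: {rec.subject_id}\n")
        cols = ["t_s"] + [f"ch{i + 1}_mV" for i in range(rec.n_channels)]
        data = {"t_s": rec.times}
        for i in range(rec.n_channels):
            data[f"ch{i + 1}_mV"] = rec.samples[i]
        if rec.labels is not None:
            cols.append("label")
            data["label"] = rec.labels
        pd.DataFrame(data, columns=cols).to_csv(fh, index=False)


def read_recording(path) -> SignalRecording:
    """Read a recording CSV; raises :class:`FormatError` on bad input."""
    meta = {}
    body = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line.lstrip("#").strip()
                if ":" in stripped:
                    key, _, value = stripped.partition(":")
                    meta[key.strip()] = value.strip()
            else:
                body.append(line)
    if "sampling_rate_hz" not in meta:
        raise FormatError(
            f"{path}: missing required metadata field 'sampling_rate_hz'"
        )
    try:
        rate = float(meta["sampling_rate_hz"])
    except ValueError as exc:
        raise FormatError(f"{path}: bad sampling_rate_hz: {exc}") from exc
    try:
        df = pd.read_csv(_io.StringIO("".join(body)),
                         on_bad_lines="error",
                         float_precision="round_trip")
    except Exception as exc:
        raise FormatError(f"{path}: malformed CSV body: {exc}") from exc
    channels = sorted(
        (int(m.group(1)), c) for c in df.columns if (m := _CH_PATTERN.match(c))
    )
    if not channels:
        raise FormatError(f"{path}: no chN_mV channel columns found")
    samples = np.vstack([df[c].to_numpy(dtype=float) for _, c in channels])
    if df.isna().any().any():
        raise FormatError(f"{path}: missing values in CSV body")
    labels = df["label"].to_numpy() if "label" in df.columns else None
    return SignalRecording(samples=samples, sampling_rate=rate, labels=labels,
                           subject_id=meta.get("subject_id", ""))


def write_features(fs: LabeledFeatureSet, path) -> None:
    df = pd.DataFrame(fs.matrix, columns=fs.feature_names)
    df.insert(0, "label", fs.labels)
    df.to_csv(path, index=False)


def read_features(path) -> LabeledFeatureSet:
    try:
        df = pd.read_csv(path, on_bad_lines="error",
                         float_precision="round_trip")
    except Exception as exc:
        raise FormatError(f"{path}: malformed feature CSV: {exc}") from exc
    if "label" not in df.columns:
        raise FormatError(f"{path}: feature CSV lacks a 'label' column")
    names = [c for c in df.columns if c != "label"]
    if not names:
        raise FormatError(f"{path}: feature CSV has no feature columns")
    return LabeledFeatureSet(df[names].to_numpy(dtype=float),
                             df["label"].to_numpy(), names)
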