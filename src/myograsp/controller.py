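"""Simulated grasp controller: decision smoothing and the two control loops.

The prosthetic hand closes each finger with a linear actuator (10 mm
stroke).  Control runs two nested feedback loops: a *position loop*
advances the motor at a fixed rate per decision tick while contact force
— sensed as motor current — stays below a limit, and a *current loop*
freezes the motor the moment sensed current reaches the limit, which is
what lets the hand conform to objects of different shapes and sizes
without a force sensor.  An open command retracts the motor to zero and
returns the controller to idle.

Classifier decisions arrive once per analysis frame (every 100 ms by
default); a short majority vote over the last m frames rejects
single-frame flickers at the cost of (m - 1) frames of extra latency.
For a two-class grasp/open model that never saw rest data, a confidence
gate suppresses commands whose projection falls too far from every class
mean, so the hand does not actuate while the muscles are silent.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
import pandas as pd

from .features import DEFAULT_FEATURES, WindowSpec, extract_features, segment
from .lda import LdaModel, project
from .preprocess import FilterSpec, condition_signal
from .recording import GestureLabel, SignalRecording


class Mode(str, Enum):
    IDLE = "idle"
    CLOSING = "closing"
    OPENING = "opening"
    HOLDING = "holding"
    FAULT = "fault"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ObjectModel:
    """A graspable object: where contact starts, and how stiff it is.

    ``stiffness`` maps compression (mm past contact) to simulated motor
    current (A), the contact-force proxy the current loop monitors.
    """

    contact_position: float  # mm along the stroke where contact begins
    stiffness: float         # A per mm of compression

    def __post_init__(self):
        if self.contact_position < 0:
            raise ValueError("contact_position must be >= 0")
        if self.stiffness < 0:
            raise ValueError("stiffness must be >= 0")


#: "No object": contact never happens within any stroke.
FREE_SPACE = ObjectModel(contact_position=float("inf"), stiffness=0.0)


@dataclass(frozen=True)
class ControlState:
    """Controller mode plus simulated motor position and current."""

    mode: Mode = Mode.IDLE
    motor_position: float = 0.0   # mm in [0, stroke]
    motor_current: float = 0.0    # A
    stroke: float = 10.0          # mm, actuator travel limit
    current_limit: float = 1.0    # A, the current-loop threshold
    position_rate: float = 1.0    # mm advanced per decision tick

    def __post_init__(self):
        object.__setattr__(self, "mode", Mode(self.mode))
        if not 0 <= self.motor_position <= self.stroke:
            raise ValueError(
                f"motor_position {self.motor_position} outside [0, {self.stroke}]"
            )
        if self.stroke <= 0 or self.current_limit <= 0 or self.position_rate <= 0:
            raise ValueError("stroke, current_limit, position_rate must be > 0")


def _current_at(position: float, obj: ObjectModel) -> float:
    compression = max(0.0, position - obj.contact_position)
    return obj.stiffness * compression


def step_controller(state: ControlState, command,
                    obj: ObjectModel = FREE_SPACE) -> ControlState:
    """Advance the controller by one decision tick.

    ``command`` is a gesture label: grasp drives the position loop
    forward (current loop freezes it at contact force), open retracts
    toward zero, rest leaves the motor where it is.
    """
    if np.isfinite(obj.contact_position) and obj.contact_position > state.stroke:
        raise ValueError(
            f"object contact at {obj.contact_position} mm lies beyond the "
            f"{state.stroke} mm stroke"
        )
    cmd = str(getattr(command, "value", command))
    pos, mode = state.motor_position, state.mode

    if cmd == GestureLabel.GRASP.value:
        if mode != Mode.HOLDING:
            mode = Mode.CLOSING
            pos = min(pos + state.position_rate, state.stroke)
            current = _current_at(pos, obj)
            if current >= state.current_limit and obj.stiffness > 0:
                # Current loop: clamp at the position where current == limit.
                pos = min(pos, obj.contact_position
                          + state.current_limit / obj.stiffness)
                mode = Mode.HOLDING
            elif pos >= state.stroke:
                mode = Mode.HOLDING  # position-loop endpoint
    elif cmd == GestureLabel.OPEN.value:
        if pos > 0:
            mode = Mode.OPENING
            pos = max(pos - state.position_rate, 0.0)
        if pos <= 0:
            mode = Mode.IDLE
    # rest: no actuation; recompute current at the held position.

    current = min(_current_at(pos, obj), state.current_limit)
    return replace(state, mode=mode, motor_position=pos, motor_current=current)


def smooth_decisions(stream, m: int = 3):
    """Majority vote over the last ``m`` frame decisions.

    Before ``m`` frames have arrived the raw decision passes through.
    ``m`` must be odd; a three-way tie (possible with three labels)
    resolves to the most recent raw decision.
    """
    if m < 1 or m % 2 == 0:
        raise ValueError(f"m must be a positive odd count, got {m}")
    stream = [str(getattr(s, "value", s)) for s in stream]
    out = []
    window: deque = deque(maxlen=m)
    for i, raw in enumerate(stream):
        window.append(raw)
        if i < m - 1:
            out.append(raw)
            continue
        values, counts = np.unique(list(window), return_counts=True)
        top = counts.max()
        tied = values[counts == top]
        out.append(raw if len(tied) > 1 else str(tied[0]))
    return out


def gated_predict(model: LdaModel, features: np.ndarray,
                  gate: float = 0.5) -> list:
    """Classify feature rows, suppressing low-confidence commands to rest.

    A command is issued only when the projected sample's margin — the
    distance to its second-nearest projected class mean minus the
    distance to its nearest — is at least ``gate`` x (smallest
    inter-mean distance).  Silent muscles and gesture transitions
    project near the midpoint between class means, where the margin
    collapses to zero, so they yield ``rest`` instead of a spurious
    command.  ``gate=None`` disables the gate.
    """
    Y = project(model, features)
    dist = np.linalg.norm(
        Y[:, None, :] - model.projected_means[None, :, :], axis=2
    )
    labels = np.asarray(model.class_labels, dtype=object)
    idx = np.argmin(dist, axis=1)
    decisions = [str(labels[i]) for i in idx]
    if gate is None:
        return decisions
    c = len(labels)
    pair_d = [np.linalg.norm(model.projected_means[i] - model.projected_means[j])
              for i in range(c) for j in range(i + 1, c)]
    min_margin = gate * min(pair_d)
    two_nearest = np.sort(dist, axis=1)[:, :2]
    margins = two_nearest[:, 1] - two_nearest[:, 0]
    return [d if mg >= min_margin else GestureLabel.REST.value
            for d, mg in zip(decisions, margins)]


def run_session(rec: SignalRecording, model: LdaModel,
                filter_spec: FilterSpec | None = None,
                window_spec: WindowSpec | None = None,
                feature_names=DEFAULT_FEATURES,
                smoothing_m: int = 3,
                confidence_gate: float | None = 0.5,
                state: ControlState | None = None,
                obj: ObjectModel = FREE_SPACE) -> pd.DataFrame:
    """End-to-end replay: condition, segment, classify, smooth, actuate.

    Returns a log with one row per analysis frame: the raw and smoothed
    decisions, controller mode, motor position (mm) and current (A).
    """
    conditioned = condition_signal(rec, filter_spec or FilterSpec())
    frames = segment(conditioned, window_spec or WindowSpec())
    fs = extract_features(frames, feature_names, conditioned.sampling_rate)
    raw = gated_predict(model, fs.matrix, gate=confidence_gate)
    smoothed = smooth_decisions(raw, smoothing_m)
    state = state or ControlState()
    rows = []
    for i, (r, s) in enumerate(zip(raw, smoothed)):
        state = step_controller(state, s, obj)
        rows.append({
            "frame": i,
            "decision": r,
            "smoothed": s,
            "mode": state.mode.value,
            "position_mm": state.motor_position,
            "current_A": state.motor_current,
        })
    return pd.DataFrame(rows)
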