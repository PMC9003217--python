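"""Facial-expression attention detection.

Maps 8-class expression labels to active/passive moods (arousal axis only),
computes windowed activation levels normalized to a fixed scale, and
thresholds them into a per-second binary attention array.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import EMOTION_LABELS, EmotionStream

ACTIVE_LABELS = frozenset({"anger", "fear", "happiness", "surprise"})
PASSIVE_LABELS = frozenset({"contempt", "disgust", "sadness"})
NEUTRAL_LABELS = frozenset({"neutrality"})

ATTENTION = "Attention"
DISTRACTION = "Distraction"


def mood_of(label: str) -> str:
    """Return ``active``, ``passive`` or ``neutral`` for an emotion label.

    The mapping is total and fixed: high-arousal expressions (anger, fear,
    happiness, surprise) are active; low-arousal ones (contempt, disgust,
    sadness) are passive; neutrality is excluded from either mood.
    """
    if label in ACTIVE_LABELS:
        return "active"
    if label in PASSIVE_LABELS:
        return "passive"
    if label in NEUTRAL_LABELS:
        return "neutral"
    raise ValueError(f"unknown emotion label {label!r}")


@dataclass
class ActivationParams:
    """Parameters of the facial activation-level classifier.

    ``t_fe`` defaults to ``ws_nn / 3``; ``denominator`` selects whether the
    activation normalizes over non-neutral readouts only (default) or over
    the whole window.
    """

    ws_nn: float = 300.0
    window_s: int = 100
    t_fe: float | None = None
    denominator: str = "nonneutral"

    def __post_init__(self) -> None:
        if self.ws_nn <= 0:
            raise ValueError("ws_nn must be positive")
        if self.window_s < 1:
            raise ValueError("window_s must be >= 1")
        if self.denominator not in ("nonneutral", "window"):
            raise ValueError("denominator must be 'nonneutral' or 'window'")

    @property
    def threshold(self) -> float:
        return self.ws_nn / 3.0 if self.t_fe is None else self.t_fe


@dataclass
class AttentionArray:
    """Per-second binary attention labels from a single source.

    ``t[i]`` is the number of elapsed seconds at which the window ending
    there became full; labels are booleans (True = Attention). Defined only
    once a full window exists, i.e. ``t >= window length``.
    """

    t: np.ndarray
    attention: np.ndarray
    source: str
    subject_id: str

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=int)
        self.attention = np.asarray(self.attention, dtype=bool)
        if self.t.shape != self.attention.shape:
            raise ValueError("t and attention must have equal length")
        if self.source not in ("facial", "physio"):
            raise ValueError(f"source must be facial|physio, got {self.source!r}")

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def labels(self) -> np.ndarray:
        return np.where(self.attention, ATTENTION, DISTRACTION)

    def to_csv(self, path) -> None:
        lines = ["t_s,label"]
        lines += [f"{t},{lb}" for t, lb in zip(self.t, self.labels)]
        from pathlib import Path

        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _mood_counts(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    active = np.isin(labels, list(ACTIVE_LABELS)).astype(np.int64)
    passive = np.isin(labels, list(PASSIVE_LABELS)).astype(np.int64)
    return active, passive


def activation_level(window: Sequence[str], params: ActivationParams) -> float:
    """Activation score of one window of mood classes, in ``[0, ws_nn]``.

    With the default denominator the score is
    ``ws_nn * n_active / (n_active + n_passive)``; a window with no
    non-neutral readout scores 0. ``window`` may hold mood classes
    (``active``/``passive``/``neutral``) or raw emotion labels.
    """
    if len(window) != params.window_s:
        raise ValueError(
            f"window length {len(window)} != params.window_s {params.window_s}"
        )
    moods = [w if w in ("active", "passive", "neutral") else mood_of(w) for w in window]
    n_active = sum(m == "active" for m in moods)
    n_passive = sum(m == "passive" for m in moods)
    if params.denominator == "window":
        return params.ws_nn * n_active / len(moods)
    denom = n_active + n_passive
    if denom == 0:
        return 0.0
    return params.ws_nn * n_active / denom


def facial_attention_array(
    stream: EmotionStream,
    params: ActivationParams,
    subject_id: str = "",
) -> AttentionArray:
    """Threshold sliding-window activation levels into an attention array.

    The stream must already be on the 1 Hz grid (see
    :func:`attnfusion.io_formats.resample_emotion_to_1hz`) so the window
    size counts the same number of samples as for the physio source. A
    label is emitted for every second ``t`` from ``window_s`` to the stream
    length: Attention iff the activation of the window covering samples
    ``[t - window_s, t)`` is strictly greater than the threshold.
    """
    n = len(stream)
    ws = params.window_s
    if n < ws:
        raise ValueError(f"stream length {n} shorter than window {ws}")
    if n > 1:
        gaps = np.diff(stream.t)
        if np.any(np.abs(gaps - 1.0) > 1e-9):
            raise ValueError("stream is not on a 1 Hz grid; resample first")

    active, passive = _mood_counts(stream.labels)
    ca = np.concatenate(([0], np.cumsum(active)))
    cp = np.concatenate(([0], np.cumsum(passive)))
    n_act = ca[ws:] - ca[:-ws]
    n_pas = cp[ws:] - cp[:-ws]
    if params.denominator == "window":
        score = params.ws_nn * n_act / ws
    else:
        denom = n_act + n_pas
        with np.errstate(invalid="ignore", divide="ignore"):
            score = np.where(denom > 0, params.ws_nn * n_act / np.maximum(denom, 1), 0.0)
    t = np.arange(ws, n + 1)
    return AttentionArray(t, score > params.threshold, "facial", subject_id)
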