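"""Readers and writers for the canonical stream and log formats.

All timestamps are seconds since session start (0-based reals); wall-clock
alignment between sources is handled upstream by the session manifest.

Canonical CSV dialects (comma separator, dot decimal, UTF-8, mandatory
header):

* emotion stream  — ``t_s,label``
* physio stream   — ``t_s,hr_bpm,bb_ms``
* prompt log      — ``t_shown,t_answered,answer,delta_s``

Writers emit shortest-round-trip float representations so that
``write(read(x))`` is byte-identical for canonical-dialect files.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import yaml

EMOTION_LABELS: tuple[str, ...] = (
    "anger",
    "contempt",
    "disgust",
    "fear",
    "happiness",
    "neutrality",
    "sadness",
    "surprise",
)
_EMOTION_SET = frozenset(EMOTION_LABELS)

#: Gaps between consecutive physio samples longer than this are flagged.
GAP_THRESHOLD_S = 1.5

#: Tolerance when checking a logged prompt delta against its timestamps.
DELTA_TOLERANCE_S = 1e-3


class FormatError(ValueError):
    """Raised when a file violates its canonical dialect or an invariant."""


def _fmt(x: float) -> str:
    """Shortest round-trip decimal representation of a float."""
    return repr(float(x))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EmotionSample:
    """One facial-expression readout: time in seconds and an 8-class label."""

    t: float
    label: str

    def __post_init__(self) -> None:
        if self.label not in _EMOTION_SET:
            raise FormatError(f"unknown emotion label {self.label!r}")
        if self.t < 0:
            raise FormatError(f"negative timestamp {self.t}")


class EmotionStream:
    """A strictly time-ordered sequence of emotion labels.

    Parameters
    ----------
    t : array-like of float
        Sample times in seconds, strictly increasing.
    labels : sequence of str
        One of the 8 canonical labels per sample.
    filled : array-like of bool, optional
        Marks samples synthesised during 1 Hz resampling of seconds that
        had no source readout (defaulted to ``neutrality``).
    """

    def __init__(self, t, labels, filled=None) -> None:
        self.t = np.asarray(t, dtype=float)
        self.labels = np.asarray(labels, dtype=object)
        if self.t.shape != self.labels.shape:
            raise FormatError("t and labels must have equal length")
        if self.t.size and np.any(np.diff(self.t) <= 0):
            raise FormatError("timestamps must be strictly increasing")
        if self.t.size and self.t[0] < 0:
            raise FormatError("timestamps must be non-negative")
        bad = [lb for lb in self.labels if lb not in _EMOTION_SET]
        if bad:
            raise FormatError(f"unknown emotion label {bad[0]!r}")
        if filled is None:
            filled = np.zeros(self.t.shape, dtype=bool)
        self.filled = np.asarray(filled, dtype=bool)

    def __len__(self) -> int:
        return int(self.t.size)

    def __iter__(self) -> Iterator[EmotionSample]:
        for ti, lb in zip(self.t, self.labels):
            yield EmotionSample(float(ti), str(lb))

    def __eq__(self, other) -> bool:
        if not isinstance(other, EmotionStream):
            return NotImplemented
        return (
            np.array_equal(self.t, other.t)
            and np.array_equal(self.labels, other.labels)
        )

    @property
    def nominal_rate_hz(self) -> float:
        """Sampling rate estimated from the median inter-sample gap."""
        if len(self) < 2:
            return float("nan")
        return 1.0 / float(np.median(np.diff(self.t)))

    @property
    def duration_s(self) -> float:
        """Nominal covered duration: last timestamp plus one median gap."""
        if len(self) == 0:
            return 0.0
        if len(self) == 1:
            return float(self.t[0]) + 1.0
        return float(self.t[-1]) + float(np.median(np.diff(self.t)))

    def neutrality_fraction(self) -> float:
        """Fraction of samples labelled ``neutrality``."""
        if len(self) == 0:
            return 0.0
        return float(np.mean(self.labels == "neutrality"))


@dataclass(frozen=True)
class PhysioSample:
    t: float
    hr: float
    bb: float

    def __post_init__(self) -> None:
        if self.hr <= 0:
            raise FormatError(f"non-positive heart rate {self.hr}")
        if self.bb <= 0:
            raise FormatError(f"non-positive BB interval {self.bb}")


@dataclass(frozen=True)
class GapRecord:
    """A hole in a nominally 1 Hz physio stream."""

    t_before: float
    t_after: float

    @property
    def gap_s(self) -> float:
        return self.t_after - self.t_before


class PhysioStream:
    """1 Hz heart samples: heart rate (bpm) and beat-to-beat interval (ms)."""

    def __init__(self, t, hr, bb) -> None:
        self.t = np.asarray(t, dtype=float)
        self.hr = np.asarray(hr, dtype=float)
        self.bb = np.asarray(bb, dtype=float)
        if not (self.t.shape == self.hr.shape == self.bb.shape):
            raise FormatError("t, hr and bb must have equal length")
        if self.t.size and np.any(np.diff(self.t) <= 0):
            raise FormatError("timestamps must be strictly increasing")
        if np.any(self.hr <= 0):
            raise FormatError("heart rate must be positive")
        if np.any(self.bb <= 0):
            raise FormatError("BB interval must be positive")
        self.gaps: list[GapRecord] = [
            GapRecord(float(self.t[i]), float(self.t[i + 1]))
            for i in np.flatnonzero(np.diff(self.t) > GAP_THRESHOLD_S)
        ]

    def __len__(self) -> int:
        return int(self.t.size)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PhysioStream):
            return NotImplemented
        return (
            np.array_equal(self.t, other.t)
            and np.array_equal(self.hr, other.hr)
            and np.array_equal(self.bb, other.bb)
        )


@dataclass(frozen=True)
class PromptEvent:
    """One reaction-time prompt: shown, answered, yes/no, and the delay."""

    t_shown: float
    t_answered: float
    answer: str
    delta: float

    def __post_init__(self) -> None:
        if self.answer not in ("yes", "no"):
            raise FormatError(f"answer must be yes|no, got {self.answer!r}")
        if self.t_answered < self.t_shown:
            raise FormatError("answer precedes prompt")
        if abs(self.delta - (self.t_answered - self.t_shown)) > DELTA_TOLERANCE_S:
            raise FormatError("delta disagrees with timestamps by more than 1 ms")


@dataclass
class SubjectEntry:
    """Per-subject file bindings inside a session manifest."""

    subject_id: str
    emotion: Path | None = None
    physio: Path | None = None
    baseline: Path | None = None
    prompts: Path | None = None
    info: dict | None = None


@dataclass
class SessionManifest:
    """Binds subjects, per-source files and session timing together."""

    subjects: list[SubjectEntry]
    duration_s: float
    mode: str = "in-presence"

    def __post_init__(self) -> None:
        if not self.subjects:
            raise FormatError("manifest must list at least one subject")
        if self.mode not in ("in-presence", "remote"):
            raise FormatError(f"unknown lecture mode {self.mode!r}")


# ---------------------------------------------------------------------------
# emotion stream I/O
# ---------------------------------------------------------------------------


def read_emotion_csv(path: str | Path) -> EmotionStream:
    """Read a canonical emotion CSV (``t_s,label``) into an EmotionStream.

    Raises :class:`FormatError` naming the offending 1-based data row on
    unknown labels, unparsable values or non-monotone timestamps.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"label": str}, float_precision="round_trip")
    _require_columns(df, ("t_s", "label"), path)
    ts: list[float] = []
    labels: list[str] = []
    for row_no, (raw_t, label) in enumerate(
        zip(df["t_s"], df["label"]), start=1
    ):
        try:
            t = float(raw_t)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: row {row_no}: bad timestamp {raw_t!r}") from exc
        if not isinstance(label, str) or label not in _EMOTION_SET:
            raise FormatError(f"{path}: row {row_no}: unknown label {label!r}")
        if ts and t <= ts[-1]:
            raise FormatError(f"{path}: row {row_no}: non-monotone timestamp {t}")
        ts.append(t)
        labels.append(label)
    return EmotionStream(ts, labels)


def write_emotion_csv(stream: EmotionStream, path: str | Path) -> None:
    lines = ["t_s,label"]
    lines += [f"{_fmt(t)},{lb}" for t, lb in zip(stream.t, stream.labels)]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def resample_emotion_to_1hz(
    stream: EmotionStream, duration_s: float | None = None
) -> EmotionStream:
    """Collapse an arbitrary-rate emotion stream onto a 1 Hz grid.

    The label of second ``k`` is the modal label among samples with
    ``k <= t < k+1``; ties go to the earliest sample in the second. Seconds
    with no source sample take ``neutrality`` and are flagged via the
    returned stream's ``filled`` mask. Output length is
    ``ceil(duration_s)``; the duration defaults to the stream's nominal
    covered duration, so resampling a 1 Hz stream is the identity.
    """
    if len(stream) == 0:
        raise FormatError("cannot resample an empty stream")
    if duration_s is None:
        duration_s = stream.duration_s
    n = math.ceil(duration_s)
    seconds = np.floor(stream.t).astype(int)
    labels: list[str] = []
    filled = np.zeros(n, dtype=bool)
    for k in range(n):
        idx = np.flatnonzero(seconds == k)
        if idx.size == 0:
            labels.append("neutrality")
            filled[k] = True
            continue
        in_sec = [str(stream.labels[i]) for i in idx]
        counts = Counter(in_sec)
        best = max(counts.values())
        # earliest sample among the modal labels wins the tie
        labels.append(next(lb for lb in in_sec if counts[lb] == best))
    return EmotionStream(np.arange(n, dtype=float), labels, filled=filled)


# ---------------------------------------------------------------------------
# physio stream I/O
# ---------------------------------------------------------------------------


def read_physio_log(path: str | Path) -> PhysioStream:
    """Read a canonical physio CSV (``t_s,hr_bpm,bb_ms``).

    Gaps longer than 1.5 s between consecutive samples are flagged in the
    stream's ``gaps`` report rather than treated as errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ("t_s", "hr_bpm", "bb_ms"), path)
    t = df["t_s"].to_numpy(dtype=float)
    hr = df["hr_bpm"].to_numpy(dtype=float)
    bb = df["bb_ms"].to_numpy(dtype=float)
    if np.any(~np.isfinite(t)) or np.any(~np.isfinite(hr)) or np.any(~np.isfinite(bb)):
        row = int(
            np.flatnonzero(
                ~(np.isfinite(t) & np.isfinite(hr) & np.isfinite(bb))
            )[0]
        )
        raise FormatError(f"{path}: row {row + 1}: unparsable value")
    for name, col, check in (
        ("hr_bpm", hr, hr <= 0),
        ("bb_ms", bb, bb <= 0),
    ):
        if np.any(check):
            row = int(np.flatnonzero(check)[0])
            raise FormatError(
                f"{path}: row {row + 1}: non-positive {name} {col[row]}"
            )
    if t.size and np.any(np.diff(t) <= 0):
        row = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
        raise FormatError(f"{path}: row {row + 1}: non-monotone timestamp")
    return PhysioStream(t, hr, bb)


def write_physio_log(stream: PhysioStream, path: str | Path) -> None:
    lines = ["t_s,hr_bpm,bb_ms"]
    lines += [
        f"{_fmt(t)},{_fmt(hr)},{_fmt(bb)}"
        for t, hr, bb in zip(stream.t, stream.hr, stream.bb)
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# prompt log I/O
# ---------------------------------------------------------------------------


def read_prompt_log(path: str | Path) -> list[PromptEvent]:
    """Read a canonical prompt log (``t_shown,t_answered,answer,delta_s``).

    The delta is always recomputed from the two timestamps; if the stored
    value disagrees by more than 1 ms a warning is issued and the
    recomputed value is used (timestamps are the primary record). An empty
    log yields an empty list.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"answer": str}, float_precision="round_trip")
    _require_columns(df, ("t_shown", "t_answered", "answer", "delta_s"), path)
    events: list[PromptEvent] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        if pd.isna(row.t_answered) or pd.isna(row.answer):
            raise FormatError(f"{path}: row {row_no}: unpaired prompt event")
        t_shown = float(row.t_shown)
        t_answered = float(row.t_answered)
        if t_answered < t_shown:
            raise FormatError(f"{path}: row {row_no}: answer precedes prompt")
        answer = str(row.answer).strip().lower()
        if answer not in ("yes", "no"):
            raise FormatError(f"{path}: row {row_no}: bad answer {row.answer!r}")
        delta = t_answered - t_shown
        if not pd.isna(row.delta_s) and abs(float(row.delta_s) - delta) > DELTA_TOLERANCE_S:
            warnings.warn(
                f"{path}: row {row_no}: logged delta {row.delta_s} disagrees "
                f"with timestamps; using recomputed {delta:.6f}",
                stacklevel=2,
            )
        events.append(PromptEvent(t_shown, t_answered, answer, delta))
    return events


def write_prompt_log(events: Sequence[PromptEvent], path: str | Path) -> None:
    lines = ["t_shown,t_answered,answer,delta_s"]
    lines += [
        f"{_fmt(e.t_shown)},{_fmt(e.t_answered)},{e.answer},{_fmt(e.delta)}"
        for e in events
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# session manifest
# ---------------------------------------------------------------------------

_PATH_FIELDS = ("emotion", "physio", "baseline", "prompts")


def load_manifest(path: str | Path) -> SessionManifest:
    """Load a YAML session manifest; relative paths resolve against it.

    Every referenced file must exist at load time.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = yaml.safe_load(path.read_text(encoding="utf-8"))
    if not isinstance(data, dict) or "subjects" not in data:
        raise FormatError(f"{path}: manifest must contain a 'subjects' list")
    base = path.parent
    subjects = []
    for entry in data["subjects"]:
        kwargs: dict = {"subject_id": str(entry["id"])}
        for f in _PATH_FIELDS:
            if entry.get(f) is not None:
                p = (base / entry[f]).resolve()
                if not p.exists():
                    raise FormatError(f"{path}: missing referenced file {p}")
                kwargs[f] = p
        if entry.get("info") is not None:
            kwargs["info"] = dict(entry["info"])
        subjects.append(SubjectEntry(**kwargs))
    return SessionManifest(
        subjects=subjects,
        duration_s=float(data.get("duration_s", 0.0)),
        mode=str(data.get("mode", "in-presence")),
    )


def save_manifest(manifest: SessionManifest, path: str | Path) -> None:
    """Write a manifest YAML with paths stored relative to it when possible."""
    path = Path(path)
    base = path.parent.resolve()
    out: dict = {
        "duration_s": manifest.duration_s,
        "mode": manifest.mode,
        "subjects": [],
    }
    for s in manifest.subjects:
        entry: dict = {"id": s.subject_id}
        for f in _PATH_FIELDS:
            p = getattr(s, f)
            if p is not None:
                p = Path(p).resolve()
                try:
                    entry[f] = str(p.relative_to(base))
                except ValueError:
                    entry[f] = str(p)
        if s.info is not None:
            entry["info"] = dict(s.info)
        out["subjects"].append(entry)
    path.write_text(yaml.safe_dump(out, sort_keys=True), encoding="utf-8")


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
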