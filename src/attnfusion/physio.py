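"""Physiological attention detection from beat-to-beat interval streams.

Time-domain heart-rate-variability features are computed over short inner
windows sliding at 1 Hz, compared per-sample against per-subject calibrated
thresholds, accumulated into a grade of attention over the outer window, and
thresholded into a per-second binary attention array.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .facial import AttentionArray
from .io_formats import PhysioStream

__all__ = [
    "HRVFeatures",
    "SubjectInfo",
    "CalibrationProfile",
    "GAParams",
    "ClampRange",
    "sdnn",
    "sdsd",
    "rmssd",
    "pnn50",
    "hrv_features",
    "calibrate",
    "grade_of_attention",
    "physio_attention_array",
]


# ---------------------------------------------------------------------------
# time-domain HRV features
# ---------------------------------------------------------------------------


def sdnn(bb) -> float:
    """Sample standard deviation (n-1 denominator) of BB intervals, ms."""
    bb = np.asarray(bb, dtype=float)
    if bb.size < 2:
        raise ValueError("sdnn needs at least 2 intervals")
    return float(np.std(bb, ddof=1))


def sdsd(bb) -> float:
    """Sample standard deviation of successive BB differences, ms."""
    bb = np.asarray(bb, dtype=float)
    if bb.size < 3:
        raise ValueError("sdsd needs at least 3 intervals")
    return float(np.std(np.diff(bb), ddof=1))


def rmssd(bb) -> float:
    """Root mean square of successive BB differences, ms."""
    bb = np.asarray(bb, dtype=float)
    if bb.size < 2:
        raise ValueError("rmssd needs at least 2 intervals")
    return float(np.sqrt(np.mean(np.diff(bb) ** 2)))


def pnn50(bb) -> float:
    """Percentage of successive BB differences strictly larger than 50 ms."""
    bb = np.asarray(bb, dtype=float)
    if bb.size < 2:
        raise ValueError("pnn50 needs at least 2 intervals")
    d = np.abs(np.diff(bb))
    return 100.0 * float(np.mean(d > 50.0))


@dataclass(frozen=True)
class HRVFeatures:
    sdnn: float
    sdsd: float
    rmssd: float
    pnn50: float


def hrv_features(bb) -> HRVFeatures:
    """All four time-domain features of one window."""
    return HRVFeatures(sdnn(bb), sdsd(bb), rmssd(bb), pnn50(bb))


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubjectInfo:
    age: float
    gender: str
    weight: float
    height: float

    def __post_init__(self) -> None:
        if self.age <= 0 or self.weight <= 0 or self.height <= 0:
            raise ValueError("age, weight and height must be positive")


@dataclass(frozen=True)
class ClampRange:
    """Demographic plausibility bounds for one feature threshold (ms)."""

    lo: float
    hi: float
    default: float

    def clamp(self, x: float) -> float:
        return min(max(x, self.lo), self.hi)


# Age-banded plausibility ranges used as the first calibration level. They
# only clamp baseline-derived thresholds into a physiological range (and
# supply defaults when no baseline exists); bands are deliberately wide and
# editable via config.
DEFAULT_CLAMP_BANDS: list[tuple[float, float, dict[str, ClampRange]]] = [
    (
        0.0,
        200.0,
        {
            "sdnn": ClampRange(5.0, 300.0, 50.0),
            "rmssd": ClampRange(5.0, 300.0, 42.0),
            "sdsd": ClampRange(5.0, 300.0, 42.0),
        },
    ),
]


def _bands_for_age(age: float, bands) -> dict[str, ClampRange]:
    for lo, hi, ranges in bands:
        if lo <= age < hi:
            return ranges
    return bands[-1][2]


@dataclass
class CalibrationProfile:
    """Per-subject thresholds for the three HRV comparisons.

    ``direction`` states which side of each threshold counts toward
    attention; it is fixed for a whole session.
    """

    subject_id: str
    threshold_sdnn: float
    threshold_rmssd: float
    threshold_sdsd: float
    direction: str = "below"
    baseline_window_s: int = 120
    clamped: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.direction not in ("below", "above"):
            raise ValueError("direction must be 'below' or 'above'")
        for name in ("threshold_sdnn", "threshold_rmssd", "threshold_sdsd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {
                    "subject_id": self.subject_id,
                    "threshold_sdnn": self.threshold_sdnn,
                    "threshold_rmssd": self.threshold_rmssd,
                    "threshold_sdsd": self.threshold_sdsd,
                    "direction": self.direction,
                    "baseline_window_s": self.baseline_window_s,
                    "clamped": dict(self.clamped),
                },
                sort_keys=True,
            ),
            encoding="utf-8",
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CalibrationProfile":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(**data)


def calibrate(
    info: SubjectInfo,
    baseline: PhysioStream | None,
    direction: str = "below",
    subject_id: str = "",
    baseline_window_s: int = 120,
    clamp_bands=None,
    allow_defaults: bool = True,
) -> CalibrationProfile:
    """Two-level threshold calibration for one subject.

    Level 2 computes sdnn/rmssd/sdsd over the first ``baseline_window_s``
    samples of the baseline stream. Level 1 consists of age-banded
    plausibility ranges that clamp those values into a physiological range;
    when no (or too short a) baseline is supplied, the band defaults are
    used instead.
    """
    bands = _bands_for_age(info.age, clamp_bands or DEFAULT_CLAMP_BANDS)
    raw: dict[str, float]
    if baseline is not None and len(baseline) >= baseline_window_s:
        seg = baseline.bb[:baseline_window_s]
        raw = {"sdnn": sdnn(seg), "rmssd": rmssd(seg), "sdsd": sdsd(seg)}
    elif allow_defaults:
        raw = {k: r.default for k, r in bands.items()}
    else:
        raise ValueError("baseline too short and demographic defaults disabled")
    thresholds = {k: bands[k].clamp(v) for k, v in raw.items()}
    clamped = {k: thresholds[k] != raw[k] for k in raw}
    return CalibrationProfile(
        subject_id=subject_id,
        threshold_sdnn=thresholds["sdnn"],
        threshold_rmssd=thresholds["rmssd"],
        threshold_sdsd=thresholds["sdsd"],
        direction=direction,
        baseline_window_s=baseline_window_s,
        clamped=clamped,
    )


# ---------------------------------------------------------------------------
# grade of attention
# ---------------------------------------------------------------------------


@dataclass
class GAParams:
    """Outer/inner window sizes and the grade-of-attention threshold.

    ``t_p`` defaults to ``tp_factor * ws`` with ``tp_factor = 3/2`` (three
    feature comparisons, each able to contribute up to ``ws`` counts, put
    the threshold at the midpoint of the grade's ``[0, 3*ws]`` range).
    """

    ws: int = 100
    inner_len: int = 30
    tp_factor: float = 1.5
    t_p: float | None = None
    strict: bool = True

    def __post_init__(self) -> None:
        if self.inner_len < 2:
            raise ValueError("inner_len must be >= 2")
        if self.ws < self.inner_len:
            raise ValueError("ws must be >= inner_len")

    @property
    def threshold(self) -> float:
        return self.tp_factor * self.ws if self.t_p is None else self.t_p


def _rolling_inner_stats(bb: np.ndarray, inner_len: int) -> tuple[np.ndarray, ...]:
    """Punctual sdnn/rmssd/sdsd at every sample of a BB series.

    The stat at sample ``s`` covers the ``inner_len`` samples ending at
    ``s``; samples before the first full inner window reuse the first full
    window's values.
    """
    n = bb.size
    if n < inner_len:
        raise ValueError(f"series length {n} shorter than inner window {inner_len}")
    win = np.lib.stride_tricks.sliding_window_view(bb, inner_len)
    s_nn = np.std(win, axis=1, ddof=1)
    diffs = np.diff(win, axis=1)
    s_rms = np.sqrt(np.mean(diffs**2, axis=1))
    s_sd = np.std(diffs, axis=1, ddof=1)
    pad = inner_len - 1

    def _pad(a: np.ndarray) -> np.ndarray:
        return np.concatenate((np.full(pad, a[0]), a))

    return _pad(s_nn), _pad(s_rms), _pad(s_sd)


def _attention_side(
    stats: tuple[np.ndarray, ...], profile: CalibrationProfile, strict: bool
) -> np.ndarray:
    """Per-sample count (0..3) of features on the attention side."""
    s_nn, s_rms, s_sd = stats
    thresholds = (
        profile.threshold_sdnn,
        profile.threshold_rmssd,
        profile.threshold_sdsd,
    )
    comps = np.zeros(s_nn.size, dtype=np.int64)
    for stat, th in zip((s_nn, s_rms, s_sd), thresholds):
        if profile.direction == "below":
            hit = stat < th if strict else stat <= th
        else:
            hit = stat > th if strict else stat >= th
        comps += hit.astype(np.int64)
    return comps


def grade_of_attention(
    segment: PhysioStream | np.ndarray,
    profile: CalibrationProfile,
    params: GAParams,
) -> int:
    """Grade of attention of one full window of ``params.ws`` samples.

    For each sample the three features over the inner window ending there
    are compared with the calibrated thresholds; every comparison on the
    attention side adds one, so the grade lies in ``[0, 3*ws]``.
    """
    bb = segment.bb if isinstance(segment, PhysioStream) else np.asarray(segment, float)
    if bb.size != params.ws:
        raise ValueError(f"segment length {bb.size} != ws {params.ws}")
    comps = _attention_side(
        _rolling_inner_stats(bb, params.inner_len), profile, params.strict
    )
    return int(comps.sum())


def physio_attention_array(
    stream: PhysioStream,
    profile: CalibrationProfile,
    params: GAParams,
    subject_id: str = "",
    extra_delay_s: int = 0,
) -> AttentionArray:
    """Slide the grade-of-attention window over a stream at 1 Hz.

    One label is emitted per second from ``t = ws`` (plus any configured
    extra start-up delay) onward: Attention iff the window's grade is
    strictly greater than the threshold.
    """
    n = len(stream)
    ws = params.ws
    if n < ws:
        raise ValueError(f"stream length {n} shorter than window {ws}")
    comps = _attention_side(
        _rolling_inner_stats(stream.bb, params.inner_len), profile, params.strict
    )
    csum = np.concatenate(([0], np.cumsum(comps)))
    ga = csum[ws:] - csum[:-ws]  # grade per window end
    t = np.arange(ws, n + 1)
    attention = ga > params.threshold
    if extra_delay_s > 0:
        t = t[extra_delay_s:]
        attention = attention[extra_delay_s:]
    return AttentionArray(t, attention, "physio", subject_id)
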