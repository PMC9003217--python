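"""Classroom-level fusion of per-subject attention arrays.

Aggregates binary arrays across subjects into fraction series, applies the
trailing 5-minute counter to obtain the attention-behavior series, computes
the per-source attention gain, scores inter-source agreement with an RMSE
criterion, and selects the window size that minimizes it.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .facial import ActivationParams, AttentionArray, facial_attention_array
from .io_formats import EmotionStream, PhysioStream
from .physio import CalibrationProfile, GAParams, physio_attention_array

DEFAULT_AB_SPAN_S = 300
DEFAULT_WS_CANDIDATES = (25, 50, 75, 100, 150, 200, 300)


@dataclass
class FractionSeries:
    """Per-second fraction of subjects labelled Attention (1.0 = everyone)."""

    t: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.t.shape != self.values.shape:
            raise ValueError("t and values must have equal length")
        if self.values.size and (
            np.min(self.values) < -1e-12 or np.max(self.values) > 1 + 1e-12
        ):
            raise ValueError("fractions must lie in [0, 1]")

    def __len__(self) -> int:
        return int(self.t.size)


@dataclass
class AttentionBehavior:
    """Trailing moving average of a fraction series over a fixed span."""

    t: np.ndarray
    values: np.ndarray
    span_s: int = DEFAULT_AB_SPAN_S

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=int)
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return int(self.t.size)


def average_across_subjects(arrays: Sequence[AttentionArray]) -> FractionSeries:
    """Mean of binary labels (Attention = 1) over subjects, per second.

    All arrays must come from the same source and share some temporal
    overlap; at each second the mean runs over the subjects defined there.
    """
    if not arrays:
        raise ValueError("need at least one attention array")
    sources = {a.source for a in arrays}
    if len(sources) > 1:
        raise ValueError(f"arrays mix sources {sorted(sources)}")
    t_lo = max(int(a.t[0]) for a in arrays)
    t_hi = min(int(a.t[-1]) for a in arrays)
    if t_lo > t_hi:
        raise ValueError("attention arrays have no temporal overlap")
    t_min = min(int(a.t[0]) for a in arrays)
    t_max = max(int(a.t[-1]) for a in arrays)
    n = t_max - t_min + 1
    sums = np.zeros(n)
    counts = np.zeros(n)
    for a in arrays:
        idx = a.t - t_min
        sums[idx] += a.attention
        counts[idx] += 1
    present = counts > 0
    t = np.arange(t_min, t_max + 1)[present]
    return FractionSeries(t, sums[present] / counts[present])


def attention_behavior(
    series: FractionSeries, span_s: int = DEFAULT_AB_SPAN_S
) -> AttentionBehavior:
    """Trailing mean of the series over the half-open window ``(t-span, t]``.

    One value per second starting ``span_s`` seconds after the series
    begins; the series must be contiguous at 1 Hz and longer than the span.
    """
    if len(series) <= span_s:
        raise ValueError(f"series length {len(series)} must exceed span {span_s}")
    if np.any(np.diff(series.t) != 1):
        raise ValueError("series must be contiguous at 1 Hz")
    # exact per-window means (no running-sum drift); AB(t) covers the
    # half-open span (t - span_s, t], i.e. seconds t-span_s+1 .. t
    windows = np.lib.stride_tricks.sliding_window_view(series.values, span_s)
    vals = windows.mean(axis=1)[1:]
    t = series.t[span_s:]
    return AttentionBehavior(t, vals, span_s=span_s)


def attention_gain(series: FractionSeries) -> float:
    """Percentage of attention over the whole session: ``100 * mean``."""
    if len(series) == 0:
        raise ValueError("empty series")
    return 100.0 * float(np.mean(series.values))


def rmse_sources(ag_p: float, ag_fe: float) -> float:
    """Root mean square error between the two sources' attention gains.

    With the reference taken as the two-source mean this reduces
    algebraically to ``|ag_p - ag_fe| / 2``.
    """
    for name, v in (("ag_p", ag_p), ("ag_fe", ag_fe)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} out of [0, 100]: {v}")
    mean = (ag_p + ag_fe) / 2.0
    # hypot keeps the squared deviations from underflowing for tiny gaps
    return math.hypot(mean - ag_p, mean - ag_fe) / math.sqrt(2.0)


# ---------------------------------------------------------------------------
# session containers
# ---------------------------------------------------------------------------


@dataclass
class SubjectData:
    """Loaded per-subject inputs ready for windowing."""

    subject_id: str
    emotion_1hz: EmotionStream | None = None
    physio: PhysioStream | None = None
    profile: CalibrationProfile | None = None


@dataclass
class SessionData:
    subjects: list[SubjectData]
    mode: str = "in-presence"

    def __post_init__(self) -> None:
        if not self.subjects:
            raise ValueError("session needs at least one subject")


def _source_arrays(
    session: SessionData,
    activation: ActivationParams,
    ga: GAParams,
) -> tuple[list[AttentionArray], list[AttentionArray]]:
    facial_arrays: list[AttentionArray] = []
    physio_arrays: list[AttentionArray] = []
    for s in session.subjects:
        if s.emotion_1hz is not None and len(s.emotion_1hz) >= activation.window_s:
            facial_arrays.append(
                facial_attention_array(s.emotion_1hz, activation, s.subject_id)
            )
        if (
            s.physio is not None
            and s.profile is not None
            and len(s.physio) >= ga.ws
        ):
            physio_arrays.append(
                physio_attention_array(s.physio, s.profile, ga, s.subject_id)
            )
    return facial_arrays, physio_arrays


def _with_ws(activation: ActivationParams, ga: GAParams, ws: int):
    act = ActivationParams(
        ws_nn=activation.ws_nn,
        window_s=ws,
        t_fe=activation.t_fe,
        denominator=activation.denominator,
    )
    gap = GAParams(
        ws=ws,
        inner_len=min(ga.inner_len, ws),  # inner window cannot exceed the outer one
        tp_factor=ga.tp_factor,
        t_p=ga.t_p,
        strict=ga.strict,
    )
    return act, gap


def select_window_size(
    session: SessionData,
    candidates: Sequence[int],
    activation: ActivationParams | None = None,
    ga: GAParams | None = None,
) -> tuple[int, list[dict]]:
    """Pick the window size minimizing the inter-source RMSE.

    Both pipelines are recomputed for every candidate; candidates larger
    than the available streams are skipped with a warning. Ties break
    toward the smaller window. Returns the winner and the full per-window
    table (ws, ag_fe, ag_p, rmse) for plotting.
    """
    if len(candidates) < 1:
        raise ValueError("need at least one candidate window size")
    activation = activation or ActivationParams()
    ga = ga or GAParams()
    table: list[dict] = []
    for ws in sorted(set(int(w) for w in candidates)):
        act_ws, ga_ws = _with_ws(activation, ga, ws)
        try:
            fe_arrays, p_arrays = _source_arrays(session, act_ws, ga_ws)
            if not fe_arrays or not p_arrays:
                raise ValueError("a source has no stream long enough")
            ag_fe = attention_gain(average_across_subjects(fe_arrays))
            ag_p = attention_gain(average_across_subjects(p_arrays))
        except ValueError as exc:
            warnings.warn(f"skipping WS={ws}: {exc}", stacklevel=2)
            continue
        table.append(
            {"ws": ws, "ag_fe": ag_fe, "ag_p": ag_p, "rmse": rmse_sources(ag_p, ag_fe)}
        )
    if not table:
        raise ValueError("no candidate window size was computable")
    best = min(table, key=lambda row: (row["rmse"], row["ws"]))
    return best["ws"], table


# ---------------------------------------------------------------------------
# session report
# ---------------------------------------------------------------------------


@dataclass
class SessionReport:
    """Aggregated session outputs; never exposes per-subject labels."""

    subject_count: int
    ws: int
    span_s: int
    mode: str = "in-presence"
    ag_facial: float | None = None
    ag_physio: float | None = None
    rmse: float | None = None
    selected_ws: int | None = None
    ws_table: list[dict] = field(default_factory=list)
    ab_facial: dict | None = None
    ab_physio: dict | None = None
    neutrality_fraction: float | None = None
    flags: list[str] = field(default_factory=list)
    config_echo: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def _ab(ab):
            return ab and {
                "t_s": [int(t) for t in ab["t_s"]],
                "values": [float(v) for v in ab["values"]],
            }

        return {
            "subject_count": self.subject_count,
            "ws": self.ws,
            "span_s": self.span_s,
            "mode": self.mode,
            "ag_facial": self.ag_facial,
            "ag_physio": self.ag_physio,
            "rmse": self.rmse,
            "selected_ws": self.selected_ws,
            "ws_table": self.ws_table,
            "ab_facial": _ab(self.ab_facial),
            "ab_physio": _ab(self.ab_physio),
            "neutrality_fraction": self.neutrality_fraction,
            "flags": list(self.flags),
            "config_echo": dict(self.config_echo),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SessionReport":
        return cls(**data)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SessionReport":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def build_report(
    session: SessionData,
    ws: int = 100,
    span_s: int = DEFAULT_AB_SPAN_S,
    activation: ActivationParams | None = None,
    ga: GAParams | None = None,
    ws_candidates: Sequence[int] | None = None,
    config_echo: dict | None = None,
) -> SessionReport:
    """Run both sources at classroom level and assemble the session report.

    If ``ws_candidates`` is given the window size is selected first and the
    report is built at the winner. Missing sources degrade gracefully: a
    facial-only (or physio-only) report carries a ``no-redundancy`` flag
    instead of an RMSE.
    """
    activation = activation or ActivationParams(window_s=ws)
    ga = ga or GAParams(ws=ws)
    selected = None
    table: list[dict] = []
    if ws_candidates:
        selected, table = select_window_size(session, ws_candidates, activation, ga)
        ws = selected
    act_ws, ga_ws = _with_ws(activation, ga, ws)
    fe_arrays, p_arrays = _source_arrays(session, act_ws, ga_ws)
    if not fe_arrays and not p_arrays:
        raise ValueError("no usable source in session")

    flags: list[str] = []
    ag_fe = ag_p = rmse = None
    ab_fe = ab_p = None
    if fe_arrays:
        series_fe = average_across_subjects(fe_arrays)
        ag_fe = attention_gain(series_fe)
        if len(series_fe) > span_s:
            ab = attention_behavior(series_fe, span_s)
            ab_fe = {"t_s": ab.t.tolist(), "values": ab.values.tolist()}
        else:
            flags.append("facial-series-shorter-than-span")
    if p_arrays:
        series_p = average_across_subjects(p_arrays)
        ag_p = attention_gain(series_p)
        if len(series_p) > span_s:
            ab = attention_behavior(series_p, span_s)
            ab_p = {"t_s": ab.t.tolist(), "values": ab.values.tolist()}
        else:
            flags.append("physio-series-shorter-than-span")
    if ag_fe is not None and ag_p is not None:
        rmse = rmse_sources(ag_p, ag_fe)
    else:
        flags.append("no-redundancy")

    neutrality = None
    fracs = [
        s.emotion_1hz.neutrality_fraction()
        for s in session.subjects
        if s.emotion_1hz is not None
    ]
    if fracs:
        neutrality = float(np.mean(fracs))
        if neutrality > 0.5:
            flags.append("high-neutrality")

    return SessionReport(
        subject_count=len(session.subjects),
        ws=ws,
        span_s=span_s,
        mode=session.mode,
        ag_facial=ag_fe,
        ag_physio=ag_p,
        rmse=rmse,
        selected_ws=selected,
        ws_table=table,
        ab_facial=ab_fe,
        ab_physio=ab_p,
        neutrality_fraction=neutrality,
        flags=flags,
        config_echo=config_echo or {},
    )
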