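"""Regime-switching synthetic lecture sessions with known ground truth.

Generates multi-subject emotion-label streams, 1 Hz beat-to-beat/heart-rate
streams and prompt logs under an attentive/distracted schedule, so every
pipeline stage is testable without external recordings. All randomness runs
through ``numpy.random.default_rng`` seeded from one master seed, so bundles
are reproducible byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .facial import AttentionArray
from .fusion import FractionSeries
from .io_formats import (
    EMOTION_LABELS,
    EmotionStream,
    PhysioStream,
    PromptEvent,
    SessionManifest,
    SubjectEntry,
    save_manifest,
    write_emotion_csv,
    write_physio_log,
    write_prompt_log,
)
from .physio import SubjectInfo

ATTENTIVE = "attentive"
DISTRACTED = "distracted"
_STATES = (ATTENTIVE, DISTRACTED)


@dataclass(frozen=True)
class RegimeSegment:
    duration_s: int
    state: str

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("segment duration must be positive")
        if self.state not in _STATES:
            raise ValueError(f"state must be one of {_STATES}")


@dataclass
class RegimeSchedule:
    """Ordered attentive/distracted segments covering a whole session."""

    segments: list[RegimeSegment]

    @property
    def total_s(self) -> int:
        return sum(seg.duration_s for seg in self.segments)

    def per_second_states(self) -> np.ndarray:
        """State of every second ``0 .. total_s - 1``."""
        return np.concatenate(
            [np.full(seg.duration_s, seg.state, dtype=object) for seg in self.segments]
        )

    @classmethod
    def parse(cls, text: str) -> "RegimeSchedule":
        """Parse ``"1800:attentive,1800:distracted"`` style schedules."""
        segments = []
        for part in text.split(","):
            dur, state = part.strip().split(":")
            segments.append(RegimeSegment(int(dur), state.strip()))
        return cls(segments)


@dataclass(frozen=True)
class BBModel:
    """Stationary AR(1) model for the beat-to-beat interval series (ms).

    ``phi`` controls autocorrelation, which decouples successive-difference
    statistics (rmssd/sdsd scale as ``sd * sqrt(2 * (1 - phi))``) from the
    marginal spread ``sd`` (sdnn).
    """

    mean_ms: float = 800.0
    sd_ms: float = 15.0
    phi: float = 0.3

    def __post_init__(self) -> None:
        if self.mean_ms <= 0 or self.sd_ms < 0:
            raise ValueError("mean must be positive and sd non-negative")
        if not -1.0 < self.phi < 1.0:
            raise ValueError("phi must lie in (-1, 1)")

    @property
    def diff_sd_ms(self) -> float:
        return self.sd_ms * math.sqrt(2.0 * (1.0 - self.phi))


# Default per-state emotion distributions: attentive lectures show mostly
# active moods plus neutral frames; distracted stretches are passive-heavy.
DEFAULT_EMOTION_DISTS: dict[str, dict[str, float]] = {
    ATTENTIVE: {
        "happiness": 0.40,
        "surprise": 0.15,
        "anger": 0.02,
        "fear": 0.03,
        "neutrality": 0.30,
        "sadness": 0.06,
        "contempt": 0.02,
        "disgust": 0.02,
    },
    DISTRACTED: {
        "sadness": 0.38,
        "contempt": 0.14,
        "disgust": 0.10,
        "neutrality": 0.30,
        "happiness": 0.04,
        "fear": 0.02,
        "anger": 0.01,
        "surprise": 0.01,
    },
}

DEFAULT_BB_MODELS: dict[str, BBModel] = {
    ATTENTIVE: BBModel(mean_ms=800.0, sd_ms=15.0, phi=0.3),
    DISTRACTED: BBModel(mean_ms=800.0, sd_ms=50.0, phi=0.3),
}

#: Resting baseline used for calibration sits between the two regimes so
#: that its thresholds separate them.
DEFAULT_BASELINE_MODEL = BBModel(mean_ms=800.0, sd_ms=30.0, phi=0.3)


@dataclass
class SubjectSpec:
    """Generative model of one simulated subject."""

    subject_id: str = "s1"
    info: SubjectInfo = field(
        default_factory=lambda: SubjectInfo(age=22, gender="f", weight=65, height=172)
    )
    emotion_dists: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_EMOTION_DISTS.items()}
    )
    bb_models: dict[str, BBModel] = field(
        default_factory=lambda: dict(DEFAULT_BB_MODELS)
    )
    baseline_model: BBModel = DEFAULT_BASELINE_MODEL
    neutrality_inflation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.neutrality_inflation < 1.0:
            raise ValueError("neutrality_inflation must lie in [0, 1)")
        for state, dist in self.emotion_dists.items():
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{state} emotion distribution sums to {total}")
            if any(p < 0 for p in dist.values()):
                raise ValueError("emotion probabilities must be non-negative")
            unknown = set(dist) - set(EMOTION_LABELS)
            if unknown:
                raise ValueError(f"unknown labels in distribution: {unknown}")

    def effective_dist(self, state: str) -> np.ndarray:
        """Probability vector over the 8 labels after neutrality inflation."""
        dist = self.emotion_dists[state]
        p = np.array([dist.get(lb, 0.0) for lb in EMOTION_LABELS])
        f = self.neutrality_inflation
        if f > 0:
            i = EMOTION_LABELS.index("neutrality")
            pn = p[i]
            p = p * (1.0 - f)
            p[i] = pn * (1.0 - f) + f
        return p / p.sum()


def simulate_emotion_stream(
    schedule: RegimeSchedule,
    spec: SubjectSpec,
    rate_hz: float = 2.0,
    rng: np.random.Generator | None = None,
) -> EmotionStream:
    """Draw i.i.d. labels per sample from the active regime's distribution."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    n = int(round(schedule.total_s * rate_hz))
    t = np.arange(n) / rate_hz
    states = schedule.per_second_states()
    sec = np.minimum(np.floor(t).astype(int), states.size - 1)
    labels = np.empty(n, dtype=object)
    label_arr = np.array(EMOTION_LABELS, dtype=object)
    for state in _STATES:
        mask = states[sec] == state
        if mask.any():
            p = spec.effective_dist(state)
            labels[mask] = label_arr[rng.choice(len(label_arr), size=int(mask.sum()), p=p)]
    return EmotionStream(t, labels)


def _ar1(n: int, model: BBModel, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) path of length n (innovation sd keeps marginal sd)."""
    innov_sd = model.sd_ms * math.sqrt(1.0 - model.phi**2)
    x = np.empty(n)
    x[0] = model.mean_ms + rng.normal(0.0, model.sd_ms) if model.sd_ms > 0 else model.mean_ms
    eps = rng.normal(0.0, innov_sd, size=n) if innov_sd > 0 else np.zeros(n)
    for i in range(1, n):
        x[i] = model.mean_ms + model.phi * (x[i - 1] - model.mean_ms) + eps[i]
    return np.maximum(x, 100.0)  # keep BB physically positive


def simulate_bb_stream(
    schedule: RegimeSchedule,
    spec: SubjectSpec,
    rng: np.random.Generator | None = None,
) -> PhysioStream:
    """1 Hz BB/HR stream: AR(1) around the active regime's mean and sd."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    states = schedule.per_second_states()
    n = states.size
    bb = np.empty(n)
    prev = spec.bb_models[str(states[0])].mean_ms
    for i, state in enumerate(states):
        model = spec.bb_models[str(state)]
        innov_sd = model.sd_ms * math.sqrt(1.0 - model.phi**2)
        eps = rng.normal(0.0, innov_sd) if innov_sd > 0 else 0.0
        bb[i] = model.mean_ms + model.phi * (prev - model.mean_ms) + eps
        prev = bb[i]
    bb = np.maximum(bb, 100.0)
    hr = 60000.0 / bb
    return PhysioStream(np.arange(n, dtype=float), hr, bb)


def simulate_baseline_stream(
    spec: SubjectSpec,
    duration_s: int = 180,
    rng: np.random.Generator | None = None,
) -> PhysioStream:
    """Resting calibration recording drawn from the subject's baseline model."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    bb = _ar1(duration_s, spec.baseline_model, rng)
    return PhysioStream(np.arange(duration_s, dtype=float), 60000.0 / bb, bb)


def simulate_prompt_log(
    schedule: RegimeSchedule,
    spec: SubjectSpec,
    n_prompts: int = 5,
    max_rt: float = 10.0,
    rng: np.random.Generator | None = None,
) -> list[PromptEvent]:
    """Prompts at evenly spread times; answers follow the true regime.

    Attentive seconds answer yes quickly; distracted seconds answer no, or
    yes with an excessive delay (emulating an inattentive affirmative).
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    states = schedule.per_second_states()
    times = np.linspace(30, schedule.total_s - 30, n_prompts)
    events = []
    for t in times:
        state = states[int(t)]
        if state == ATTENTIVE:
            answer, rt = "yes", float(rng.uniform(0.5, max_rt * 0.5))
        elif rng.uniform() < 0.5:
            answer, rt = "no", float(rng.uniform(1.0, max_rt * 0.8))
        else:  # distracted but still claiming attention: slow yes
            answer, rt = "yes", float(rng.uniform(max_rt * 1.2, max_rt * 3.0))
        events.append(PromptEvent(float(t), float(t) + rt, answer, rt))
    return events


@dataclass
class ClassroomBundle:
    """On-disk layout of one simulated session."""

    out_dir: Path
    manifest_path: Path
    truth_path: Path
    truth_states: np.ndarray
    subject_ids: list[str]


def simulate_classroom(
    n_subjects: int,
    schedule: RegimeSchedule,
    base_spec: SubjectSpec | None = None,
    master_seed: int = 0,
    out_dir: str | Path = ".",
    mode: str = "in-presence",
    rate_hz: float = 2.0,
    baseline_s: int = 180,
    with_prompts: bool = False,
) -> ClassroomBundle:
    """Write a full multi-subject session bundle with ground truth.

    Per-subject generators are seeded by spawning the master seed, so two
    runs with the same seed produce byte-identical bundles. The bundle
    holds canonical CSVs per subject, a YAML manifest and a per-second
    truth CSV.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    base_spec = base_spec or SubjectSpec()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed_seqs = np.random.SeedSequence(master_seed).spawn(n_subjects)
    entries: list[SubjectEntry] = []
    ids: list[str] = []
    for i, ss in enumerate(seed_seqs, start=1):
        sid = f"s{i:02d}"
        ids.append(sid)
        spec = replace(base_spec, subject_id=sid)
        rng_emotion = np.random.default_rng(ss.spawn(1)[0])
        rng_bb = np.random.default_rng(ss.spawn(1)[0])
        rng_base = np.random.default_rng(ss.spawn(1)[0])
        emo = simulate_emotion_stream(schedule, spec, rate_hz=rate_hz, rng=rng_emotion)
        phys = simulate_bb_stream(schedule, spec, rng=rng_bb)
        base = simulate_baseline_stream(spec, duration_s=baseline_s, rng=rng_base)
        e_path = out_dir / f"{sid}_emotion.csv"
        p_path = out_dir / f"{sid}_physio.csv"
        b_path = out_dir / f"{sid}_baseline.csv"
        write_emotion_csv(emo, e_path)
        write_physio_log(phys, p_path)
        write_physio_log(base, b_path)
        entry = SubjectEntry(
            subject_id=sid,
            emotion=e_path,
            physio=p_path,
            baseline=b_path,
            info={
                "age": spec.info.age,
                "gender": spec.info.gender,
                "weight": spec.info.weight,
                "height": spec.info.height,
            },
        )
        if with_prompts:
            rng_prompt = np.random.default_rng(ss.spawn(1)[0])
            log_path = out_dir / f"{sid}_prompts.csv"
            write_prompt_log(
                simulate_prompt_log(schedule, spec, rng=rng_prompt), log_path
            )
            entry.prompts = log_path
        entries.append(entry)

    truth = schedule.per_second_states()
    truth_path = out_dir / "truth.csv"
    truth_path.write_text(
        "t_s,state\n" + "\n".join(f"{k},{s}" for k, s in enumerate(truth)) + "\n",
        encoding="utf-8",
    )
    manifest = SessionManifest(
        subjects=entries, duration_s=float(schedule.total_s), mode=mode
    )
    manifest_path = out_dir / "manifest.yaml"
    save_manifest(manifest, manifest_path)
    return ClassroomBundle(out_dir, manifest_path, truth_path, truth, ids)


def read_truth_csv(path: str | Path) -> np.ndarray:
    lines = Path(path).read_text(encoding="utf-8").strip().splitlines()[1:]
    return np.array([ln.split(",")[1] for ln in lines], dtype=object)


def evaluate_recovery(
    predicted: AttentionArray | FractionSeries,
    truth_states: np.ndarray,
    warmup_s: int | None = None,
) -> tuple[float, dict[str, dict[str, int]]]:
    """Agreement between a prediction and the per-second ground truth.

    Fraction series are binarized at 0.5. The label emitted at second ``t``
    describes the window ending there and is compared with the truth of
    second ``t - 1`` (the newest second inside the window). The warm-up —
    by default the larger of the prediction's start and 300 s — is
    excluded. Returns the agreement percentage and per-regime confusion
    counts.
    """
    if isinstance(predicted, FractionSeries):
        t = predicted.t
        attn = predicted.values > 0.5
    else:
        t = predicted.t
        attn = predicted.attention
    if warmup_s is None:
        warmup_s = max(int(t[0]), 300)
    keep = t > warmup_s
    t, attn = t[keep], attn[keep]
    if t.size == 0:
        raise ValueError("nothing left to evaluate after warm-up")
    if np.any(t - 1 >= truth_states.size):
        raise ValueError("prediction extends past the truth series")
    truth = truth_states[t - 1]
    expected_attn = truth == ATTENTIVE
    matches = attn == expected_attn
    confusion = {
        state: {
            "attention": int(np.sum(attn & (truth == state))),
            "distraction": int(np.sum(~attn & (truth == state))),
        }
        for state in _STATES
    }
    return 100.0 * float(np.mean(matches)), confusion
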