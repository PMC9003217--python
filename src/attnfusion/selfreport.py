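"""Self-reported attention from reaction-time prompt logs.

Affirmative answers given with an excessive reaction time are reclassified
as negative before computing the self-assessed attention level, which
serves as a comparison baseline for the sensor pipelines.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .io_formats import PromptEvent

#: Default reaction-time limit in seconds. Arbitrary: no quantitative limit
#: is established for "excessive" reaction times, so this is a required,
#: user-visible parameter everywhere it matters.
DEFAULT_MAX_RT_S = 10.0


@dataclass(frozen=True)
class SelfReportSummary:
    n_prompts: int
    n_yes_raw: int
    n_no_raw: int
    n_yes_reclassified: int
    max_rt: float

    @property
    def n_yes_effective(self) -> int:
        return self.n_yes_raw - self.n_yes_reclassified

    @property
    def n_no_effective(self) -> int:
        return self.n_prompts - self.n_yes_effective

    @property
    def attention_level(self) -> float:
        """Percentage of effective affirmative answers."""
        return 100.0 * self.n_yes_effective / self.n_prompts

    def to_dict(self) -> dict:
        return {
            "n_prompts": self.n_prompts,
            "n_yes_raw": self.n_yes_raw,
            "n_no_raw": self.n_no_raw,
            "n_yes_reclassified": self.n_yes_reclassified,
            "n_yes_effective": self.n_yes_effective,
            "n_no_effective": self.n_no_effective,
            "attention_level": self.attention_level,
            "max_rt": self.max_rt,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )


def reclassify(
    events: Sequence[PromptEvent], max_rt: float = DEFAULT_MAX_RT_S
) -> SelfReportSummary:
    """Count answers, demoting slow affirmatives to negatives.

    A yes-answer whose delay is strictly greater than ``max_rt`` counts as
    no (a delay exactly equal to the limit is kept as yes).
    """
    if max_rt <= 0:
        raise ValueError("max_rt must be positive")
    if not events:
        raise ValueError("empty prompt-event list")
    n_yes = sum(e.answer == "yes" for e in events)
    n_no = len(events) - n_yes
    n_recl = sum(e.answer == "yes" and e.delta > max_rt for e in events)
    return SelfReportSummary(
        n_prompts=len(events),
        n_yes_raw=n_yes,
        n_no_raw=n_no,
        n_yes_reclassified=n_recl,
        max_rt=max_rt,
    )


def pooled_attention_level(summaries: Sequence[SelfReportSummary]) -> float:
    """Prompt-weighted pooled attention percentage across volunteers."""
    if not summaries:
        raise ValueError("no summaries to pool")
    total = sum(s.n_prompts for s in summaries)
    yes = sum(s.n_yes_effective for s in summaries)
    return 100.0 * yes / total
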