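"""Rule-based quality scoring of cardiac cycles and videos.

A qualified cycle scores 5 points: gain (+1), depth (+1), cardiac-axis angle
(+1) and anatomical structures (+2), gated by cardiac-cycle completeness —
an incomplete cycle scores 0 outright.  Reasons name each failed criterion so
reports stay human-interpretable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Sequence

from .lvvc import CardiacCycle
from .obb import StructureCheck
from .quantify import CaaResult, DepthResult

__all__ = ["GainClass", "ScoreCard", "VideoReport", "score_cycle", "score_video"]

GainClass = Literal["low", "medium", "high"]

INCOMPLETE_REASON = "incomplete cardiac cycle"


@dataclass(frozen=True)
class ScoreCard:
    complete_cycle: bool
    gain_score: int
    depth_score: int
    caa_score: int
    structure_score: int
    total: int
    reasons: tuple
    cycle: CardiacCycle | None = None

    def __post_init__(self) -> None:
        if not self.complete_cycle:
            assert self.total == 0 and not any(
                (self.gain_score, self.depth_score, self.caa_score, self.structure_score)
            )
        else:
            assert self.total == (
                self.gain_score + self.depth_score + self.caa_score + self.structure_score
            )

    @property
    def standard(self) -> bool:
        return self.total == 5


@dataclass
class VideoReport:
    per_cycle: list = field(default_factory=list)
    video_total: int = 0
    standard: bool = False
    video_id: str = ""
    config_echo: dict = field(default_factory=dict)

    def to_json(self) -> str:
        cycles = []
        for card in self.per_cycle:
            entry = {
                "pattern": card.cycle.pattern.value if card.cycle else None,
                "ed_frame": None,
                "es_frame": None,
                "scores": {
                    "gain": card.gain_score,
                    "depth": card.depth_score,
                    "caa": card.caa_score,
                    "structure": card.structure_score,
                },
                "total": card.total,
                "reasons": list(card.reasons),
            }
            if card.cycle is not None:
                from .lvvc import select_qc_targets

                targets = select_qc_targets(card.cycle)
                entry["ed_frame"] = targets.ed_frame
                entry["es_frame"] = targets.es_frame
            cycles.append(entry)
        doc = {
            "video_id": self.video_id,
            "video_total": self.video_total,
            "standard": self.standard,
            "cycles": cycles,
            "config_echo": self.config_echo,
        }
        return json.dumps(doc, indent=1)


def score_cycle(
    complete: bool,
    gain_class: GainClass | None,
    structure: StructureCheck | None,
    depth: DepthResult | None,
    caa: CaaResult | None,
    cycle: CardiacCycle | None = None,
) -> ScoreCard:
    """Score one cardiac cycle against the five-point protocol.

    Inputs are produced on the cycle's QC target frames (depth/CAA/gain on
    the ES frame, structures on both ED and ES).  ``None`` criterion inputs
    mean "not computable" and score 0 with an explanatory reason.
    """
    if not complete:
        return ScoreCard(
            complete_cycle=False,
            gain_score=0, depth_score=0, caa_score=0, structure_score=0,
            total=0, reasons=(INCOMPLETE_REASON,), cycle=cycle,
        )

    reasons: list[str] = []

    gain_score = 1 if gain_class == "medium" else 0
    if gain_score == 0:
        reasons.append("gain" if gain_class is not None else "gain: not computable")

    if depth is None or not depth.computable:
        depth_score = 0
        reasons.append("depth: not computable")
    else:
        depth_score = 1 if depth.passed else 0
        if not depth_score:
            reasons.append("depth")

    if caa is None or not caa.computable:
        caa_score = 0
        reasons.append("caa: not computable")
    else:
        caa_score = 1 if caa.passed else 0
        if not caa_score:
            reasons.append("caa")

    if structure is None:
        structure_score = 0
        reasons.append("structure: not computable")
    else:
        structure_score = 2 if structure.passed else 0
        if not structure_score:
            reasons.append("structure")

    total = gain_score + depth_score + caa_score + structure_score
    return ScoreCard(
        complete_cycle=True,
        gain_score=gain_score, depth_score=depth_score,
        caa_score=caa_score, structure_score=structure_score,
        total=total, reasons=tuple(reasons), cycle=cycle,
    )


def score_video(
    cards: Sequence[ScoreCard],
    aggregation: Literal["max", "min", "first"] = "max",
    video_id: str = "",
    config_echo: dict | None = None,
) -> VideoReport:
    """Aggregate per-cycle scorecards into one video-level report.

    Default aggregation is ``max`` — a video is standard if at least one of
    its cycles scores 5.  An empty card list (no complete cycle) scores 0.
    """
    totals = [c.total for c in cards]
    if not totals:
        video_total = 0
    elif aggregation == "max":
        video_total = max(totals)
    elif aggregation == "min":
        video_total = min(totals)
    elif aggregation == "first":
        video_total = totals[0]
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    return VideoReport(
        per_cycle=list(cards),
        video_total=video_total,
        standard=video_total == 5,
        video_id=video_id,
        config_echo=dict(config_echo or {}),
    )
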