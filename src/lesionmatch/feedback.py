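"""Feedback aggregation: per-pathology percentages and color-coded lesion lists.

Mirrors the structure of the learning tool's feedback view: a general summary
over all four pathologies with the percentage of reference lesions the learner
found, plus categorized detail lists ("All", "Correct", "Missed", "False").
Correctly drawn lesions display green, falsely drawn ones yellow, missed ones
red.

The percentage is recall-style: ``100 * n_correct / n_reference``. False
marks are reported as counts alongside it, not folded into the percentage.
When the reference holds no lesion of a class, there is nothing to find and
the percentage is 100 by convention (false marks are still listed).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Any

from .geometry import AnnotationSet, PathologyClass
from .matching import MatchResult

__all__ = [
    "FeedbackCategory",
    "LesionRef",
    "PathologyFeedback",
    "FeedbackReport",
    "build_report",
    "filter_view",
    "CATEGORY_COLORS",
]


class FeedbackCategory(enum.Enum):
    ALL = "all"
    CORRECT = "correct"
    MISSED = "missed"
    FALSE = "false"

    def __str__(self) -> str:
        return self.value


CATEGORY_COLORS = {
    FeedbackCategory.CORRECT: "green",
    FeedbackCategory.FALSE: "yellow",
    FeedbackCategory.MISSED: "red",
}


@dataclass(frozen=True)
class LesionRef:
    """A display reference to one lesion in a feedback list.

    ``origin`` says which annotation set the index refers to: reference for
    missed lesions, marked for correct and false ones. ``paired_with`` carries
    the reference index a correct mark was matched to.
    """

    category: FeedbackCategory
    origin: str  # "reference" | "marked"
    index: int
    color: str
    iou: float | None = None
    paired_with: int | None = None


@dataclass
class PathologyFeedback:
    pathology: PathologyClass
    n_reference: int
    n_marked: int
    n_correct: int
    n_false: int
    n_missed: int
    percent_found: float
    lesion_lists: dict[FeedbackCategory, list[LesionRef]] = field(default_factory=dict)


@dataclass
class FeedbackReport:
    """Feedback for one image: exactly one entry per pathology class."""

    image_id: str
    pathologies: dict[PathologyClass, PathologyFeedback]
    config: dict[str, Any] = field(default_factory=dict)


def build_report(
    match: MatchResult,
    reference: AnnotationSet,
    marked: AnnotationSet,
    config: dict[str, Any] | None = None,
) -> FeedbackReport:
    """Aggregate a match result into the feedback structure.

    Raises a consistency error when match indices fall outside the annotation
    sets they were produced from.
    """
    pathologies: dict[PathologyClass, PathologyFeedback] = {}
    for pathology in PathologyClass:
        entry = match.per_pathology[pathology]
        n_ref = reference.n_lesions(pathology)
        n_mark = marked.n_lesions(pathology)

        for pair in entry.correct_pairs:
            if not (0 <= pair.detected_index < n_ref and 0 <= pair.marked_index < n_mark):
                raise ValueError(
                    f"match indices out of range for pathology {pathology}"
                )
        if any(i >= n_ref or i < 0 for i in entry.missed_detected) or any(
            i >= n_mark or i < 0 for i in entry.false_marked
        ):
            raise ValueError(f"match indices out of range for pathology {pathology}")

        n_correct = len(entry.correct_pairs)
        n_false = len(entry.false_marked)
        n_missed = len(entry.missed_detected)
        if n_ref > 0:
            percent = 100.0 * n_correct / n_ref
        else:
            percent = 100.0  # nothing to find

        correct_refs = [
            LesionRef(
                category=FeedbackCategory.CORRECT,
                origin="marked",
                index=p.marked_index,
                color=CATEGORY_COLORS[FeedbackCategory.CORRECT],
                iou=p.iou,
                paired_with=p.detected_index,
            )
            for p in entry.correct_pairs
        ]
        missed_refs = [
            LesionRef(
                category=FeedbackCategory.MISSED,
                origin="reference",
                index=i,
                color=CATEGORY_COLORS[FeedbackCategory.MISSED],
            )
            for i in entry.missed_detected
        ]
        false_refs = [
            LesionRef(
                category=FeedbackCategory.FALSE,
                origin="marked",
                index=i,
                color=CATEGORY_COLORS[FeedbackCategory.FALSE],
            )
            for i in entry.false_marked
        ]
        lists = {
            FeedbackCategory.CORRECT: correct_refs,
            FeedbackCategory.MISSED: missed_refs,
            FeedbackCategory.FALSE: false_refs,
        }
        lists[FeedbackCategory.ALL] = correct_refs + missed_refs + false_refs

        pathologies[pathology] = PathologyFeedback(
            pathology=pathology,
            n_reference=n_ref,
            n_marked=n_mark,
            n_correct=n_correct,
            n_false=n_false,
            n_missed=n_missed,
            percent_found=percent,
            lesion_lists=lists,
        )

    return FeedbackReport(
        image_id=reference.image_id,
        pathologies=pathologies,
        config=dict(config or {}),
    )


def filter_view(
    report: FeedbackReport,
    pathology: PathologyClass,
    category: FeedbackCategory,
) -> list[LesionRef]:
    """The detail view: lesion references of one category for one pathology."""
    return list(report.pathologies[pathology].lesion_lists[category])
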