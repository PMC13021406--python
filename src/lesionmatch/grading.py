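"""Rule-based diabetic-retinopathy severity grading.

Maps per-pathology lesion counts (plus an explicit proliferative flag) to a
severity grade 0-4 through an ordered rule table: the first matching rule
wins, with a default of grade 0. The shipped default table is inspired by the
International Clinical Diabetic Retinopathy (ICDR) scale:

* 0 - no lesions of any class,
* 1 - microaneurysms only,
* 2 - any hemorrhage or exudate below the severe thresholds,
* 3 - 20 or more hemorrhages, or soft exudates together with hemorrhages,
* 4 - proliferative flag set, or extreme hemorrhage counts.

It is a configurable stand-in for a severity classifier, not a clinical
instrument: lesion *locations* (the quadrant-based 4-2-1 rule) are not
modeled and the thresholds carry no diagnostic claim.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping

import numpy as np

from .geometry import AnnotationSet, PathologyClass, Source

__all__ = [
    "SeverityGrade",
    "GradingRule",
    "GradingRuleTable",
    "default_rule_table",
    "grade_severity",
    "grade_counts",
    "grade_grid",
    "enumerate_reachable_grades",
    "GRADE_LABELS",
]

GRADE_LABELS = {
    0: "no DR",
    1: "mild",
    2: "moderate",
    3: "severe",
    4: "proliferative",
}


@dataclass(frozen=True)
class SeverityGrade:
    grade: int
    label: str
    matched_rule: str = "default"

    def __post_init__(self) -> None:
        if self.grade not in GRADE_LABELS:
            raise ValueError("grade must be an integer in 0..4")


@dataclass(frozen=True)
class GradingRule:
    """One ordered rule: an ANDed predicate over lesion counts -> grade.

    ``min_counts`` requires each named pathology to reach its count;
    ``require_proliferative`` requires the flag; ``only`` (when given)
    requires every pathology *outside* the listed set to have count zero.
    """

    name: str
    grade: int
    min_counts: Mapping[PathologyClass, int] = field(default_factory=dict)
    require_proliferative: bool = False
    only: frozenset[PathologyClass] | None = None

    def __post_init__(self) -> None:
        if self.grade not in GRADE_LABELS:
            raise ValueError(f"rule {self.name!r}: grade must be in 0..4")
        for pathology, n in self.min_counts.items():
            if n < 0:
                raise ValueError(f"rule {self.name!r}: negative min_count")

    def matches(
        self, counts: Mapping[PathologyClass, int], proliferative: bool
    ) -> bool:
        if self.require_proliferative and not proliferative:
            return False
        for pathology, n in self.min_counts.items():
            if counts.get(pathology, 0) < n:
                return False
        if self.only is not None:
            for pathology in PathologyClass:
                if pathology not in self.only and counts.get(pathology, 0) > 0:
                    return False
        return True


@dataclass(frozen=True)
class GradingRuleTable:
    """Ordered first-match rule table with implicit default grade 0."""

    rules: tuple[GradingRule, ...]
    default_grade: int = 0

    def __post_init__(self) -> None:
        if self.default_grade not in GRADE_LABELS:
            raise ValueError("default_grade must be in 0..4")
        names = [r.name for r in self.rules]
        if len(names) != len(set(names)):
            raise ValueError("rule names must be unique")

    def evaluate(
        self, counts: Mapping[PathologyClass, int], proliferative: bool = False
    ) -> SeverityGrade:
        for rule in self.rules:
            if rule.matches(counts, proliferative):
                return SeverityGrade(
                    grade=rule.grade,
                    label=GRADE_LABELS[rule.grade],
                    matched_rule=rule.name,
                )
        return SeverityGrade(
            grade=self.default_grade,
            label=GRADE_LABELS[self.default_grade],
            matched_rule="default",
        )


MA = PathologyClass.MICROANEURYSM
HEM = PathologyClass.HEMORRHAGE
SE = PathologyClass.SOFT_EXUDATE
HE = PathologyClass.HARD_EXUDATE

SEVERE_HEMORRHAGE_COUNT = 20
EXTREME_HEMORRHAGE_COUNT = 40


def default_rule_table() -> GradingRuleTable:
    """The shipped ICDR-inspired default table (see module docstring)."""
    return GradingRuleTable(
        rules=(
            GradingRule(name="proliferative_flag", grade=4, require_proliferative=True),
            GradingRule(
                name="extreme_hemorrhages",
                grade=4,
                min_counts={HEM: EXTREME_HEMORRHAGE_COUNT},
            ),
            GradingRule(
                name="severe_hemorrhages",
                grade=3,
                min_counts={HEM: SEVERE_HEMORRHAGE_COUNT},
            ),
            GradingRule(
                name="soft_exudates_with_hemorrhages",
                grade=3,
                min_counts={SE: 1, HEM: 1},
            ),
            GradingRule(name="any_hemorrhage", grade=2, min_counts={HEM: 1}),
            GradingRule(name="any_soft_exudate", grade=2, min_counts={SE: 1}),
            GradingRule(name="any_hard_exudate", grade=2, min_counts={HE: 1}),
            GradingRule(
                name="microaneurysms_only",
                grade=1,
                min_counts={MA: 1},
                only=frozenset({MA}),
            ),
        ),
        default_grade=0,
    )


def grade_counts(
    counts: Mapping[PathologyClass, int],
    table: GradingRuleTable | None = None,
    proliferative: bool = False,
) -> SeverityGrade:
    """Grade a per-pathology lesion-count vector."""
    table = table or default_rule_table()
    return table.evaluate(counts, proliferative)


def grade_severity(
    reference: AnnotationSet,
    table: GradingRuleTable | None = None,
    proliferative: bool = False,
) -> SeverityGrade:
    """Grade a reference annotation set from its lesion counts."""
    if reference.source is not Source.REFERENCE:
        raise ValueError("severity grading expects a reference annotation set")
    return grade_counts(reference.counts(), table, proliferative)


def grade_grid(
    table: GradingRuleTable, count_cap: int, proliferative: bool
) -> np.ndarray:
    """Vectorized table evaluation over the full count lattice.

    Returns a 4-dimensional integer array ``g`` (one axis per pathology, in
    :class:`PathologyClass` declaration order) where ``g[a, b, c, d]`` is the
    grade assigned to the count vector ``(a, b, c, d)`` under the given
    proliferative-flag state. First-match semantics are reproduced exactly.
    """
    if count_cap < 1:
        raise ValueError("count_cap must be >= 1")
    n = count_cap + 1
    axes = np.indices((n, n, n, n), dtype=np.int32)
    counts = {p: axes[i] for i, p in enumerate(PathologyClass)}

    grades = np.full((n, n, n, n), table.default_grade, dtype=np.int8)
    assigned = np.zeros((n, n, n, n), dtype=bool)
    for rule in table.rules:
        if rule.require_proliferative and not proliferative:
            continue
        mask = ~assigned
        for pathology, m in rule.min_counts.items():
            mask &= counts[pathology] >= m
        if rule.only is not None:
            for pathology in PathologyClass:
                if pathology not in rule.only:
                    mask &= counts[pathology] == 0
        grades[mask] = rule.grade
        assigned |= mask
    return grades


def enumerate_reachable_grades(
    table: GradingRuleTable, count_cap: int = 50
) -> set[int]:
    """Exhaustively evaluate the table over all count vectors up to a cap.

    Every combination of per-pathology counts in ``[0, count_cap]`` and both
    proliferative-flag states is graded; the set of produced grades is
    returned. Used to validate that a configured table can actually emit the
    grades it promises.
    """
    reachable: set[int] = set()
    for flag in (False, True):
        reachable.update(int(g) for g in np.unique(grade_grid(table, count_cap, flag)))
    return reachable
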