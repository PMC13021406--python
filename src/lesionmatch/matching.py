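"""Greedy IOU matching of learner-marked lesions against reference detections.

For each pathology class independently, detected (reference) lesions are
visited in canonical order. Each computes its intersection-over-union against
every still-unassigned marked lesion; if the best IOU reaches the threshold
(0.5 by default, inclusive), the pair is recorded as *correct* and the marked
lesion is removed from the pool. Marked lesions that never pair are *falsely
input*; detected lesions that never pair are *missed*.

Assignment-and-deletion is conditional on the threshold: a marked lesion whose
best overlap with the current detected lesion is sub-threshold stays available
for later detected lesions, so weak overlaps cannot consume lesions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .geometry import AnnotationSet, Lesion, PathologyClass, Source

__all__ = [
    "MatchConfig",
    "LesionPair",
    "PathologyMatch",
    "MatchResult",
    "iou",
    "match_pathology",
    "match_all",
    "optimal_match_oracle",
]

DEFAULT_IOU_THRESHOLD = 0.5


@dataclass(frozen=True)
class MatchConfig:
    """Matching parameters: the IOU correctness threshold (inclusive)."""

    iou_threshold: float = DEFAULT_IOU_THRESHOLD

    def __post_init__(self) -> None:
        if not 0.0 <= self.iou_threshold <= 1.0:
            raise ValueError("iou_threshold must lie in [0, 1]")


@dataclass(frozen=True)
class LesionPair:
    """A correct detected/marked pair and its IOU score."""

    detected_index: int
    marked_index: int
    iou: float


@dataclass
class PathologyMatch:
    """Match outcome for one pathology class.

    Every marked index appears in exactly one of ``correct_pairs`` /
    ``false_marked``; every detected index in exactly one of ``correct_pairs``
    / ``missed_detected``.
    """

    correct_pairs: list[LesionPair] = field(default_factory=list)
    false_marked: list[int] = field(default_factory=list)
    missed_detected: list[int] = field(default_factory=list)


@dataclass
class MatchResult:
    """Per-pathology match outcomes for one image."""

    per_pathology: dict[PathologyClass, PathologyMatch] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pathology in PathologyClass:
            self.per_pathology.setdefault(pathology, PathologyMatch())


def iou(a: frozenset[tuple[int, int]], b: frozenset[tuple[int, int]]) -> float:
    """Intersection over union of two pixel sets.

    Undefined (and rejected) when both sets are empty.
    """
    if not a and not b:
        raise ValueError("IOU of two empty pixel sets is undefined")
    inter = len(a & b)
    if inter == 0:
        return 0.0
    return inter / len(a | b)


def _canonical_ranks(lesions: list[Lesion]) -> list[int]:
    """Indices into ``lesions`` ordered canonically (area desc, top-left)."""
    return sorted(range(len(lesions)), key=lambda i: lesions[i].sort_key())


def match_pathology(
    detected: list[Lesion],
    marked: list[Lesion],
    cfg: MatchConfig | None = None,
) -> PathologyMatch:
    """Greedy one-to-one matching within a single pathology class.

    Detected lesions are visited in canonical order; ties between marked
    lesions with equal maximal IOU break toward the lower canonical index.
    Indices in the result refer to positions in the input lists.
    """
    cfg = cfg or MatchConfig()
    if detected and marked:
        p = detected[0].pathology
        g = detected[0].grid
        for lesion in itertools.chain(detected, marked):
            if lesion.pathology is not p:
                raise ValueError("all lesions must share one pathology class")
            if lesion.grid != g:
                raise ValueError("all lesions must share one grid")

    result = PathologyMatch()
    marked_rank = {idx: rank for rank, idx in enumerate(_canonical_ranks(marked))}
    unassigned = set(range(len(marked)))

    for d_idx in _canonical_ranks(detected):
        best: tuple[float, int] | None = None  # (iou, marked index)
        for m_idx in unassigned:
            score = iou(detected[d_idx].pixels, marked[m_idx].pixels)
            if best is None or score > best[0] or (
                score == best[0] and marked_rank[m_idx] < marked_rank[best[1]]
            ):
                best = (score, m_idx)
        if best is not None and best[0] >= cfg.iou_threshold:
            result.correct_pairs.append(
                LesionPair(detected_index=d_idx, marked_index=best[1], iou=best[0])
            )
            unassigned.discard(best[1])
        else:
            result.missed_detected.append(d_idx)

    result.false_marked = sorted(unassigned)
    result.missed_detected.sort()
    return result


def match_all(
    reference: AnnotationSet,
    marked: AnnotationSet,
    cfg: MatchConfig | None = None,
) -> MatchResult:
    """Match a learner's annotation against the reference, per pathology.

    Matching never crosses pathology classes. Both sets must describe the
    same image and grid.
    """
    cfg = cfg or MatchConfig()
    if reference.source is not Source.REFERENCE:
        raise ValueError("first argument must be the reference annotation set")
    if marked.source is not Source.MARKED:
        raise ValueError("second argument must be the learner-marked set")
    if reference.image_id != marked.image_id:
        raise ValueError(
            f"image_id mismatch: {reference.image_id!r} vs {marked.image_id!r}"
        )
    if reference.grid != marked.grid:
        raise ValueError("grid mismatch between reference and marked sets")

    result = MatchResult()
    for pathology in PathologyClass:
        result.per_pathology[pathology] = match_pathology(
            reference.lesions[pathology], marked.lesions[pathology], cfg
        )
    return result


def optimal_match_oracle(
    detected: list[Lesion],
    marked: list[Lesion],
    threshold: float = DEFAULT_IOU_THRESHOLD,
) -> PathologyMatch:
    """Brute-force assignment oracle for small instances (test-only).

    Enumerates every one-to-one assignment of marked to detected lesions and
    returns one maximizing the number of pairs with IOU >= threshold, breaking
    ties by total IOU and then by canonical order of the pairing. Limited to
    seven lesions per side.
    """
    if len(detected) > 7 or len(marked) > 7:
        raise ValueError("oracle instances are limited to 7 lesions per side")

    scores = [[iou(d.pixels, m.pixels) for m in marked] for d in detected]
    d_order = _canonical_ranks(detected)
    m_order = _canonical_ranks(marked)

    best_pairs: list[tuple[int, int]] = []
    best_key: tuple[int, float, tuple] | None = None

    # Every one-to-one pairing is a sub-assignment of some maximal-size
    # assignment (sub-threshold pairs are simply discarded), so enumerating
    # maximal-size assignments covers the whole search space.
    n_d, n_m = len(detected), len(marked)
    k = min(n_d, n_m)
    for d_subset in itertools.combinations(range(n_d), k):
        for m_perm in itertools.permutations(range(n_m), k):
            pairs = [
                (d, m)
                for d, m in zip(d_subset, m_perm)
                if scores[d][m] >= threshold
            ]
            total = sum(scores[d][m] for d, m in pairs)
            canon = tuple(
                sorted((d_order.index(d), m_order.index(m)) for d, m in pairs)
            )
            key = (len(pairs), total, tuple(-x for pair in canon for x in pair))
            if best_key is None or key > best_key:
                best_key = key
                best_pairs = pairs

    paired_d = {d for d, _ in best_pairs}
    paired_m = {m for _, m in best_pairs}
    return PathologyMatch(
        correct_pairs=[
            LesionPair(detected_index=d, marked_index=m, iou=scores[d][m])
            for d, m in sorted(best_pairs)
        ],
        false_marked=sorted(set(range(n_m)) - paired_m),
        missed_detected=sorted(set(range(n_d)) - paired_d),
    )
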