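"""Seeded synthetic annotation generator with construction-guaranteed outcomes.

Stands in for both the lesion detector (reference annotations) and the human
learner (marked annotations). Reference lesions are random filled ellipses,
sized to caricature the four pathology classes (microaneurysms smallest, soft
exudates largest) and placed far enough apart that distinct lesions can never
merge under the default morphology, and that any lesion overlaps at most one
lesion of the other annotation set.

The learner is emulated by perturbing each reference lesion independently:

* *keep* - exact copy, guaranteed CORRECT (IOU 1);
* *small shift* - translation bounded by 25% of the lesion's minor diameter
  and verified to keep IOU at or above the matching threshold, guaranteed
  CORRECT;
* *large shift* - the copy is relocated far from every reference lesion
  (IOU 0 everywhere), so the copy is FALSE and the original MISSED;
* *drop* - no copy, the original is MISSED;

plus spurious extra lesions placed clear of everything (FALSE). Because every
kept/shifted copy overlaps exactly one reference lesion (its own source) and
relocated/spurious lesions overlap none, the expected per-lesion labels are
certain, not probabilistic — the generator's bookkeeping is an exact oracle
for the matching pipeline.

Everything is deterministic given the spec and its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.draw import ellipse as _draw_ellipse

from .geometry import (
    AnnotationSet,
    ImageGrid,
    Lesion,
    PathologyClass,
    Source,
    canonical_sort,
)
from .matching import DEFAULT_IOU_THRESHOLD, iou

__all__ = [
    "SyntheticCaseSpec",
    "PerturbationSpec",
    "ExpectedEntry",
    "SyntheticCase",
    "DEFAULT_RADIUS_RANGES",
    "DEFAULT_COUNT_RANGES",
    "generate_reference",
    "perturb_annotation",
    "generate_case",
]

# Semi-axis ranges (pixels) caricaturing the four classes; synthetic, not
# clinical morphometry.
DEFAULT_RADIUS_RANGES: dict[PathologyClass, tuple[int, int]] = {
    PathologyClass.MICROANEURYSM: (1, 3),
    PathologyClass.HEMORRHAGE: (3, 8),
    PathologyClass.SOFT_EXUDATE: (4, 10),
    PathologyClass.HARD_EXUDATE: (2, 6),
}

DEFAULT_COUNT_RANGES: dict[PathologyClass, tuple[int, int]] = {
    PathologyClass.MICROANEURYSM: (2, 6),
    PathologyClass.HEMORRHAGE: (1, 4),
    PathologyClass.SOFT_EXUDATE: (1, 3),
    PathologyClass.HARD_EXUDATE: (1, 5),
}

_MAX_RADIUS = max(hi for _, hi in DEFAULT_RADIUS_RANGES.values())
_PLACEMENT_RETRIES = 1000


class CapacityError(RuntimeError):
    """Raised when lesions cannot be packed under the separation constraint."""


@dataclass(frozen=True)
class SyntheticCaseSpec:
    """Parameters of a synthetic reference annotation.

    ``min_separation`` is the guaranteed pixel gap between any two lesions;
    the default (2 x max radius + 2) keeps lesions from merging after the
    default dilation and keeps match outcomes unambiguous.
    """

    grid: ImageGrid = ImageGrid(256, 256)
    count_ranges: dict[PathologyClass, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_COUNT_RANGES)
    )
    radius_ranges: dict[PathologyClass, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_RADIUS_RANGES)
    )
    min_separation: int = 2 * _MAX_RADIUS + 2
    seed: int = 0

    def __post_init__(self) -> None:
        for p in PathologyClass:
            lo, hi = self.count_ranges[p]
            if not (0 <= lo <= hi):
                raise ValueError(f"bad count range for {p}")
            rlo, rhi = self.radius_ranges[p]
            if not (1 <= rlo <= rhi):
                raise ValueError(f"bad radius range for {p}")
        if self.min_separation < 1:
            raise ValueError("min_separation must be >= 1")


@dataclass(frozen=True)
class PerturbationSpec:
    """How the synthetic learner deviates from the reference.

    The four probabilities must sum to at most 1; leftover mass falls back to
    an exact keep. ``n_spurious`` extra lesions (random pathology) are added
    clear of all reference and marked lesions.
    """

    p_keep_exact: float = 0.35
    p_small_shift: float = 0.25
    p_large_shift: float = 0.2
    p_drop: float = 0.2
    n_spurious: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (self.p_keep_exact, self.p_small_shift, self.p_large_shift, self.p_drop)
        if any(p < 0 for p in probs):
            raise ValueError("probabilities must be non-negative")
        if sum(probs) > 1.0 + 1e-12:
            raise ValueError("perturbation probabilities must sum to <= 1")
        if self.n_spurious < 0:
            raise ValueError("n_spurious must be >= 0")


@dataclass
class ExpectedEntry:
    """Construction-guaranteed outcome for one pathology.

    Indices refer to the canonical lesion ordering of the case's annotation
    sets, i.e. exactly the indices the matching engine reports.
    """

    correct_pairs: list[tuple[int, int]] = field(default_factory=list)
    false_marked: list[int] = field(default_factory=list)
    missed_detected: list[int] = field(default_factory=list)

    @property
    def counts(self) -> tuple[int, int, int]:
        """(n_correct, n_false, n_missed)."""
        return (
            len(self.correct_pairs),
            len(self.false_marked),
            len(self.missed_detected),
        )


@dataclass
class SyntheticCase:
    reference: AnnotationSet
    marked: AnnotationSet
    expected: dict[PathologyClass, ExpectedEntry]

    def expected_counts(self) -> dict[PathologyClass, tuple[int, int, int]]:
        return {p: self.expected[p].counts for p in PathologyClass}


def _ellipse_pixels(
    center: tuple[int, int],
    radii: tuple[int, int],
    rotation: float,
    grid: ImageGrid,
) -> frozenset[tuple[int, int]]:
    rr, cc = _draw_ellipse(
        center[0],
        center[1],
        radii[0],
        radii[1],
        shape=(grid.height, grid.width),
        rotation=rotation,
    )
    return frozenset(zip(rr.tolist(), cc.tolist()))


def _far_enough(
    center: tuple[int, int],
    max_radius: int,
    others: list[tuple[tuple[int, int], int]],
    min_separation: int,
) -> bool:
    """Conservative separation test on bounding circles."""
    for (r, c), other_rad in others:
        d = math.hypot(center[0] - r, center[1] - c)
        if d < max_radius + other_rad + min_separation:
            return False
    return True


def _place_ellipse(
    rng: np.random.Generator,
    radius_range: tuple[int, int],
    grid: ImageGrid,
    occupied: list[tuple[tuple[int, int], int]],
    min_separation: int,
) -> tuple[frozenset[tuple[int, int]], tuple[int, int], int]:
    """Sample a fully-in-grid ellipse respecting the separation constraint."""
    lo, hi = radius_range
    for _ in range(_PLACEMENT_RETRIES):
        a = int(rng.integers(lo, hi + 1))
        b = int(rng.integers(lo, a + 1))  # minor axis <= major axis
        max_rad = a
        r = int(rng.integers(max_rad, grid.height - max_rad))
        c = int(rng.integers(max_rad, grid.width - max_rad))
        if not _far_enough((r, c), max_rad, occupied, min_separation):
            continue
        rotation = float(rng.uniform(0, math.pi))
        pixels = _ellipse_pixels((r, c), (a, b), rotation, grid)
        if pixels:
            return pixels, (r, c), max_rad
    raise CapacityError(
        "could not place a lesion under the separation constraint; "
        "enlarge the grid or reduce counts"
    )


def generate_reference(spec: SyntheticCaseSpec, image_id: str = "synthetic") -> AnnotationSet:
    """Generate a reference annotation set of separated elliptical lesions.

    Deterministic given the spec (including its seed). Raises
    :class:`CapacityError` when the requested counts cannot be packed.
    """
    rng = np.random.default_rng(spec.seed)
    occupied: list[tuple[tuple[int, int], int]] = []
    lesions: dict[PathologyClass, list[Lesion]] = {}
    for pathology in PathologyClass:
        lo, hi = spec.count_ranges[pathology]
        n = int(rng.integers(lo, hi + 1))
        items = []
        for _ in range(n):
            pixels, center, max_rad = _place_ellipse(
                rng, spec.radius_ranges[pathology], spec.grid, occupied,
                spec.min_separation,
            )
            occupied.append((center, max_rad))
            items.append(Lesion(pathology=pathology, pixels=pixels, grid=spec.grid))
        lesions[pathology] = canonical_sort(items)
    return AnnotationSet(
        image_id=image_id, grid=spec.grid, source=Source.REFERENCE, lesions=lesions
    )


def _shift_pixels(
    pixels: frozenset[tuple[int, int]], dr: int, dc: int, grid: ImageGrid
) -> frozenset[tuple[int, int]] | None:
    shifted = frozenset((r + dr, c + dc) for r, c in pixels)
    for r, c in shifted:
        if not grid.contains(r, c):
            return None
    return shifted


def _lesion_geometry(lesion: Lesion) -> tuple[tuple[int, int], int, int]:
    """(approx center, bounding radius, minor diameter) from the bbox."""
    r0, c0, r1, c1 = lesion.bbox
    center = ((r0 + r1) // 2, (c0 + c1) // 2)
    height, width = r1 - r0 + 1, c1 - c0 + 1
    bounding_radius = int(math.ceil(math.hypot(height, width) / 2))
    return center, bounding_radius, min(height, width)


def _small_shift(
    rng: np.random.Generator,
    lesion: Lesion,
    threshold: float,
) -> frozenset[tuple[int, int]]:
    """Translate by <= 25% of the minor diameter, certifying IOU >= threshold.

    The analytic bound (a quarter-diameter shift of a convex shape keeps IOU
    above 0.5) is conservative in the continuum but can fray for few-pixel
    lesions, so the achieved IOU is verified on the actual pixel sets; the
    shift shrinks toward zero until the certificate holds (zero shift is an
    exact copy, IOU 1).
    """
    _, _, minor_diameter = _lesion_geometry(lesion)
    max_shift = int(minor_diameter * 0.25)
    for magnitude in range(max_shift, -1, -1):
        if magnitude == 0:
            return lesion.pixels
        angle = float(rng.uniform(0, 2 * math.pi))
        dr = int(round(magnitude * math.sin(angle)))
        dc = int(round(magnitude * math.cos(angle)))
        if dr == 0 and dc == 0:
            dr = magnitude
        shifted = _shift_pixels(lesion.pixels, dr, dc, lesion.grid)
        if shifted is not None and iou(lesion.pixels, shifted) >= threshold:
            return shifted
    return lesion.pixels


def perturb_annotation(
    reference: AnnotationSet,
    pspec: PerturbationSpec | None = None,
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
) -> SyntheticCase:
    """Derive a learner annotation from the reference with known outcomes.

    Requires a reference generated under the separation guarantees (each
    relocated or spurious lesion is re-placed with the same constraint).
    """
    pspec = pspec or PerturbationSpec()
    rng = np.random.default_rng(pspec.seed)
    grid = reference.grid

    # Bounding circles of every reference lesion, shared across pathologies so
    # relocated and spurious lesions stay clear of everything.
    occupied: list[tuple[tuple[int, int], int]] = []
    for pathology in PathologyClass:
        for lesion in reference.lesions[pathology]:
            center, bounding_radius, _ = _lesion_geometry(lesion)
            occupied.append((center, bounding_radius))

    min_separation = 2 * _MAX_RADIUS + 2
    cum = np.cumsum(
        [pspec.p_keep_exact, pspec.p_small_shift, pspec.p_large_shift, pspec.p_drop]
    )

    marked_lesions: dict[PathologyClass, list[Lesion]] = {}
    # provenance per pathology: list of (marked lesion, ref index or None)
    provenance: dict[PathologyClass, list[tuple[Lesion, int | None]]] = {}

    for pathology in PathologyClass:
        items: list[tuple[Lesion, int | None]] = []
        for ref_idx, lesion in enumerate(reference.lesions[pathology]):
            u = float(rng.random())
            if u < cum[0]:  # keep exact
                items.append((replace(lesion), ref_idx))
            elif u < cum[1]:  # small shift, still correct
                pixels = _small_shift(rng, lesion, iou_threshold)
                items.append(
                    (Lesion(pathology=pathology, pixels=pixels, grid=grid), ref_idx)
                )
            elif u < cum[2]:  # large shift: relocate far away -> false + missed
                _, _, minor = _lesion_geometry(lesion)
                radius_range = (max(1, minor // 2), max(1, minor // 2))
                pixels, center, max_rad = _place_ellipse(
                    rng, radius_range, grid, occupied, min_separation
                )
                occupied.append((center, max_rad))
                items.append(
                    (Lesion(pathology=pathology, pixels=pixels, grid=grid), None)
                )
            elif u < cum[3]:  # drop -> missed
                pass
            else:  # leftover probability mass: keep exact
                items.append((replace(lesion), ref_idx))
        provenance[pathology] = items

    # Spurious additions, random pathology each.
    classes = list(PathologyClass)
    for _ in range(pspec.n_spurious):
        pathology = classes[int(rng.integers(0, len(classes)))]
        pixels, center, max_rad = _place_ellipse(
            rng,
            DEFAULT_RADIUS_RANGES[pathology],
            grid,
            occupied,
            min_separation,
        )
        occupied.append((center, max_rad))
        provenance[pathology].append(
            (Lesion(pathology=pathology, pixels=pixels, grid=grid), None)
        )

    expected: dict[PathologyClass, ExpectedEntry] = {}
    for pathology in PathologyClass:
        items = provenance[pathology]
        order = sorted(range(len(items)), key=lambda i: items[i][0].sort_key())
        marked_lesions[pathology] = [items[i][0] for i in order]
        entry = ExpectedEntry()
        matched_refs: set[int] = set()
        for marked_idx, orig_idx in enumerate(order):
            ref_idx = items[orig_idx][1]
            if ref_idx is None:
                entry.false_marked.append(marked_idx)
            else:
                entry.correct_pairs.append((ref_idx, marked_idx))
                matched_refs.add(ref_idx)
        entry.missed_detected = [
            i for i in range(len(reference.lesions[pathology])) if i not in matched_refs
        ]
        entry.correct_pairs.sort()
        expected[pathology] = entry

    marked = AnnotationSet(
        image_id=reference.image_id,
        grid=grid,
        source=Source.MARKED,
        lesions=marked_lesions,
    )
    return SyntheticCase(reference=reference, marked=marked, expected=expected)


def generate_case(
    spec: SyntheticCaseSpec | None = None,
    pspec: PerturbationSpec | None = None,
    image_id: str = "synthetic",
) -> SyntheticCase:
    """Convenience: generate a reference and perturb it in one call."""
    spec = spec or SyntheticCaseSpec()
    pspec = pspec or PerturbationSpec(seed=spec.seed)
    reference = generate_reference(spec, image_id=image_id)
    return perturb_annotation(reference, pspec)
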