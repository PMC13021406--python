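"""Lesion geometry: contours, binary masks, morphology and connected components.

Drawn lesion outlines (from a detector or from a learner's freehand strokes)
live in the pixel space of a fundus image. Before two annotations can be
compared by intersection-over-union, each outline has to become a *filled*
pixel region: the polyline is rasterized onto a binary plane, dilated and
morphologically closed so small drawing gaps seal, interior holes are filled,
and connected components are extracted as :class:`Lesion` objects.

Coordinates are 0-based ``(row, col)`` pairs throughout, matching the pixel
indices of the underlying image raster.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage
from skimage.draw import line as _draw_line
from skimage.morphology import disk as _disk

__all__ = [
    "ImageGrid",
    "PathologyClass",
    "Source",
    "MorphologyConfig",
    "Lesion",
    "AnnotationSet",
    "rasterize_contours",
    "close_and_fill",
    "extract_lesions",
    "lesions_to_mask",
    "canonical_sort",
]


class PathologyClass(enum.Enum):
    """The four diabetic-retinopathy lesion classes the tool distinguishes."""

    MICROANEURYSM = "microaneurysm"
    HEMORRHAGE = "hemorrhage"
    SOFT_EXUDATE = "soft_exudate"
    HARD_EXUDATE = "hard_exudate"

    def __str__(self) -> str:  # stable serialization name
        return self.value


class Source(enum.Enum):
    """Origin of an annotation set: detector reference or learner-marked."""

    REFERENCE = "reference"
    MARKED = "marked"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class ImageGrid:
    """Pixel dimensions of the image plane annotations are drawn on."""

    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError(
                f"grid dimensions must be >= 1, got {self.height}x{self.width}"
            )

    def contains(self, row: int, col: int) -> bool:
        return 0 <= row < self.height and 0 <= col < self.width


@dataclass(frozen=True)
class MorphologyConfig:
    """Parameters of the contour-sealing morphology.

    ``dilation_radius`` is the radius (pixels) of the structuring element used
    for both the dilation and the closing step; radius 1 with a disk is the
    smallest element that bridges 1-pixel gaps left by freehand drawing.
    Foreground connectivity is 8 by default, with the complementary
    4-connectivity used for the background flood during hole filling.
    """

    dilation_radius: int = 1
    connectivity: int = 8
    structuring_element: str = "disk"

    def __post_init__(self) -> None:
        if self.dilation_radius < 0:
            raise ValueError("dilation_radius must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.structuring_element not in ("disk", "square"):
            raise ValueError("structuring_element must be 'disk' or 'square'")

    def footprint(self) -> np.ndarray:
        r = self.dilation_radius
        if self.structuring_element == "disk":
            return _disk(r).astype(bool)
        return np.ones((2 * r + 1, 2 * r + 1), dtype=bool)

    def label_structure(self) -> np.ndarray:
        # 8-connectivity: full 3x3; 4-connectivity: cross.
        return ndimage.generate_binary_structure(2, 2 if self.connectivity == 8 else 1)


@dataclass(frozen=True)
class Lesion:
    """One connected pixel region of a single pathology class.

    The atomic unit of matching, counting and color-coding. ``pixels`` is the
    complete filled region, not just its outline.
    """

    pathology: PathologyClass
    pixels: frozenset[tuple[int, int]]
    grid: ImageGrid

    def __post_init__(self) -> None:
        if not self.pixels:
            raise ValueError("a lesion must contain at least one pixel")
        for r, c in self.pixels:
            if not self.grid.contains(r, c):
                raise ValueError(f"pixel ({r}, {c}) outside {self.grid}")

    @property
    def area(self) -> int:
        return len(self.pixels)

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        rows = [p[0] for p in self.pixels]
        cols = [p[1] for p in self.pixels]
        return (min(rows), min(cols), max(rows), max(cols))

    @property
    def centroid(self) -> tuple[float, float]:
        rows = [p[0] for p in self.pixels]
        cols = [p[1] for p in self.pixels]
        return (sum(rows) / len(rows), sum(cols) / len(cols))

    def sort_key(self) -> tuple[int, int, int]:
        """Canonical ordering key: area descending, then top-left bbox corner."""
        b = self.bbox
        return (-self.area, b[0], b[1])

    def to_mask(self) -> np.ndarray:
        mask = np.zeros((self.grid.height, self.grid.width), dtype=bool)
        rows, cols = zip(*self.pixels)
        mask[list(rows), list(cols)] = True
        return mask


def canonical_sort(lesions: Iterable[Lesion]) -> list[Lesion]:
    """Order lesions by descending area, ties by (min_row, min_col).

    This ordering makes the greedy matcher deterministic across runs and
    platforms.
    """
    return sorted(lesions, key=Lesion.sort_key)


@dataclass
class AnnotationSet:
    """All lesions for one image, grouped by pathology class.

    Holds either the detector's reference lesions or the learner-marked ones.
    Every pathology key is always present (possibly with an empty list) and
    lesion pixel sets within one pathology are pairwise disjoint.
    """

    image_id: str
    grid: ImageGrid
    source: Source
    lesions: dict[PathologyClass, list[Lesion]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pathology in PathologyClass:
            self.lesions.setdefault(pathology, [])
        for pathology, items in self.lesions.items():
            seen: set[tuple[int, int]] = set()
            for lesion in items:
                if lesion.pathology is not pathology:
                    raise ValueError(
                        f"lesion of class {lesion.pathology} filed under {pathology}"
                    )
                if lesion.grid != self.grid:
                    raise ValueError("lesion grid differs from annotation grid")
                if seen & lesion.pixels:
                    raise ValueError(
                        f"overlapping lesions within pathology {pathology}"
                    )
                seen |= lesion.pixels

    def n_lesions(self, pathology: PathologyClass) -> int:
        return len(self.lesions[pathology])

    def counts(self) -> dict[PathologyClass, int]:
        return {p: len(self.lesions[p]) for p in PathologyClass}


def rasterize_contours(
    contours: Sequence[Sequence[tuple[int, int]]], grid: ImageGrid
) -> np.ndarray:
    """Draw contour polylines onto a binary plane.

    Each contour is an ordered list of ``(row, col)`` vertices. Consecutive
    vertices are joined by discrete line segments; contours with three or more
    vertices are closed (last vertex joined back to the first). A single-point
    contour sets exactly that pixel.

    Raises
    ------
    ValueError
        If any coordinate falls outside the grid; the message names the
        offending contour index.
    """
    mask = np.zeros((grid.height, grid.width), dtype=bool)
    for idx, contour in enumerate(contours):
        if len(contour) == 0:
            raise ValueError(f"contour {idx} is empty")
        for r, c in contour:
            if not grid.contains(r, c):
                raise ValueError(
                    f"contour {idx}: coordinate ({r}, {c}) outside "
                    f"{grid.height}x{grid.width} grid"
                )
        pts = [(int(r), int(c)) for r, c in contour]
        if len(pts) == 1:
            mask[pts[0]] = True
            continue
        segments = list(zip(pts[:-1], pts[1:]))
        if len(pts) >= 3:
            segments.append((pts[-1], pts[0]))
        for (r0, c0), (r1, c1) in segments:
            rr, cc = _draw_line(r0, c0, r1, c1)
            mask[rr, cc] = True
    return mask


def close_and_fill(mask: np.ndarray, cfg: MorphologyConfig | None = None) -> np.ndarray:
    """Seal and fill a drawn outline: dilation, closing, then hole filling.

    The returned mask is always a superset of the input (the image is padded
    internally so the closing never erodes at the border) and contains no
    holes: every background region not connected to the grid border is set.
    An all-zero mask maps to an all-zero mask.
    """
    cfg = cfg or MorphologyConfig()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    r = cfg.dilation_radius
    if r > 0:
        pad = 2 * r + 1
        work = np.pad(mask, pad)
        footprint = cfg.footprint()
        work = ndimage.binary_dilation(work, structure=footprint)
        work = ndimage.binary_closing(work, structure=footprint)
        work = work[pad:-pad, pad:-pad]
    else:
        work = mask.copy()
    # binary_fill_holes with the cross structure floods the background with
    # 4-connectivity, the standard dual of 8-connected foreground.
    work = ndimage.binary_fill_holes(
        work, structure=ndimage.generate_binary_structure(2, 1)
    )
    return work | mask


def extract_lesions(
    mask: np.ndarray,
    pathology: PathologyClass,
    cfg: MorphologyConfig | None = None,
) -> list[Lesion]:
    """Split a binary mask into one :class:`Lesion` per connected component.

    Components are found under the configured connectivity and returned in
    canonical order (area descending, then top-left corner).
    """
    cfg = cfg or MorphologyConfig()
    mask = np.asarray(mask, dtype=bool)
    grid = ImageGrid(*mask.shape)
    labeled, n = ndimage.label(mask, structure=cfg.label_structure())
    lesions = []
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labeled == lab)
        pixels = frozenset(zip(rows.tolist(), cols.tolist()))
        lesions.append(Lesion(pathology=pathology, pixels=pixels, grid=grid))
    return canonical_sort(lesions)


def lesions_to_mask(lesions: Iterable[Lesion], grid: ImageGrid) -> np.ndarray:
    """Paint lesion pixel sets back onto a binary plane (union)."""
    mask = np.zeros((grid.height, grid.width), dtype=bool)
    for lesion in lesions:
        rows, cols = zip(*lesion.pixels)
        mask[list(rows), list(cols)] = True
    return mask
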