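from __future__ import annotations

import numpy as np
import pytest

from lesionmatch import ImageGrid, Lesion, PathologyClass


def make_lesion(
    pixels,
    grid: ImageGrid | None = None,
    pathology: PathologyClass = PathologyClass.HEMORRHAGE,
) -> Lesion:
    """Build a lesion straight from a pixel collection (test helper)."""
    pixels = frozenset((int(r), int(c)) for r, c in pixels)
    if grid is None:
        max_r = max(p[0] for p in pixels)
        max_c = max(p[1] for p in pixels)
        grid = ImageGrid(max_r + 2, max_c + 2)
    return Lesion(pathology=pathology, pixels=pixels, grid=grid)


def block(r0: int, c0: int, height: int, width: int) -> set[tuple[int, int]]:
    """Axis-aligned rectangle of pixels."""
    return {(r, c) for r in range(r0, r0 + height) for c in range(c0, c0 + width)}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
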