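"""Independent brute-force oracles for the morphology and matching tests.

Everything here is deliberately naive — explicit loops, set arithmetic and
breadth-first flood fills — and shares no code path with the package
implementation it checks.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def disk_offsets(radius: int) -> list[tuple[int, int]]:
    return [
        (dr, dc)
        for dr in range(-radius, radius + 1)
        for dc in range(-radius, radius + 1)
        if dr * dr + dc * dc <= radius * radius
    ]


def square_offsets(radius: int) -> list[tuple[int, int]]:
    return [
        (dr, dc)
        for dr in range(-radius, radius + 1)
        for dc in range(-radius, radius + 1)
    ]


def brute_dilate(pixels: set[tuple[int, int]], offsets) -> set[tuple[int, int]]:
    return {(r + dr, c + dc) for r, c in pixels for dr, dc in offsets}


def brute_erode(pixels: set[tuple[int, int]], offsets) -> set[tuple[int, int]]:
    return {
        (r, c)
        for r, c in pixels
        if all((r + dr, c + dc) in pixels for dr, dc in offsets)
    }


def flood_fill_holes(
    pixels: set[tuple[int, int]], height: int, width: int
) -> set[tuple[int, int]]:
    """Set every background pixel not 4-connected to the grid border."""
    outside: set[tuple[int, int]] = set()
    queue: deque[tuple[int, int]] = deque()
    for r in range(height):
        for c in (0, width - 1):
            if (r, c) not in pixels:
                outside.add((r, c))
                queue.append((r, c))
    for c in range(width):
        for r in (0, height - 1):
            if (r, c) not in pixels and (r, c) not in outside:
                outside.add((r, c))
                queue.append((r, c))
    while queue:
        r, c = queue.popleft()
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nr, nc = r + dr, c + dc
            if 0 <= nr < height and 0 <= nc < width:
                if (nr, nc) not in pixels and (nr, nc) not in outside:
                    outside.add((nr, nc))
                    queue.append((nr, nc))
    return {
        (r, c)
        for r in range(height)
        for c in range(width)
        if (r, c) not in outside
    }


def brute_close_and_fill(
    mask: np.ndarray, radius: int, element: str = "disk"
) -> np.ndarray:
    """Reference for the sealing morphology: dilate, close, fill holes.

    Operates on an unbounded pixel-set plane (so border erosion artifacts
    cannot occur), then clips back to the grid and unions the input.
    """
    height, width = mask.shape
    pixels = {(int(r), int(c)) for r, c in zip(*np.nonzero(mask))}
    if not pixels:
        return mask.astype(bool).copy()
    offsets = disk_offsets(radius) if element == "disk" else square_offsets(radius)
    if radius > 0:
        work = brute_dilate(pixels, offsets)
        work = brute_erode(brute_dilate(work, offsets), offsets)
        work = {(r, c) for r, c in work if 0 <= r < height and 0 <= c < width}
    else:
        work = set(pixels)
    work = flood_fill_holes(work, height, width) | pixels
    out = np.zeros((height, width), dtype=bool)
    for r, c in work:
        out[r, c] = True
    return out


def brute_components(
    pixels: set[tuple[int, int]], connectivity: int = 8
) -> list[set[tuple[int, int]]]:
    """Connected components by breadth-first search."""
    if connectivity == 8:
        neighbors = [
            (dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)
        ]
    else:
        neighbors = [(1, 0), (-1, 0), (0, 1), (0, -1)]
    remaining = set(pixels)
    components = []
    while remaining:
        start = next(iter(remaining))
        comp = {start}
        remaining.discard(start)
        queue = deque([start])
        while queue:
            r, c = queue.popleft()
            for dr, dc in neighbors:
                p = (r + dr, c + dc)
                if p in remaining:
                    remaining.discard(p)
                    comp.add(p)
                    queue.append(p)
        components.append(comp)
    return components
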