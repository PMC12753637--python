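"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest


def chebyshev_dilate(binary: np.ndarray, radius: int) -> np.ndarray:
    """Brute-force dilation: a pixel is set when any set pixel lies within
    the given Chebyshev radius."""
    h, w = binary.shape
    out = np.zeros_like(binary, dtype=bool)
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            ys = slice(max(0, dy), min(h, h + dy))
            yt = slice(max(0, -dy), min(h, h - dy))
            xs = slice(max(0, dx), min(w, w + dx))
            xt = slice(max(0, -dx), min(w, w - dx))
            out[yt, xt] |= binary[ys, xs]
    return out


def flood_fill_components(binary: np.ndarray) -> list[set[tuple[int, int]]]:
    """4-connectivity components by explicit stack-based flood fill."""
    h, w = binary.shape
    seen = np.zeros_like(binary, dtype=bool)
    comps = []
    for sy in range(h):
        for sx in range(w):
            if not binary[sy, sx] or seen[sy, sx]:
                continue
            stack = [(sy, sx)]
            seen[sy, sx] = True
            comp = set()
            while stack:
                y, x = stack.pop()
                comp.add((y, x))
                for ny, nx in ((y - 1, x), (y + 1, x), (y, x - 1), (y, x + 1)):
                    if 0 <= ny < h and 0 <= nx < w and binary[ny, nx] \
                            and not seen[ny, nx]:
                        seen[ny, nx] = True
                        stack.append((ny, nx))
            comps.append(comp)
    return comps


def oracle_label_cells(mask: np.ndarray, class_label: int,
                       merge_radius: int = 4) -> list[set[tuple[int, int]]]:
    """Independent oracle: brute-force dilation then flood fill, with the
    original pixels assigned to the component of their dilated pixel."""
    binary = mask == class_label
    if not binary.any():
        return []
    dilated = chebyshev_dilate(binary, merge_radius) if merge_radius else binary
    cells = []
    for comp in flood_fill_components(dilated):
        orig = {(y, x) for (y, x) in comp if binary[y, x]}
        if orig:
            cells.append(orig)
    return cells


def random_cellish_mask(rng: np.random.Generator, size: int = 64,
                        n_blobs: int = 8) -> np.ndarray:
    """Random label mask with a mix of blobs and isolated pixels."""
    mask = np.zeros((size, size), dtype=np.uint8)
    for _ in range(n_blobs):
        cy, cx = rng.integers(0, size, 2)
        r = int(rng.integers(1, 5))
        lab = int(rng.integers(1, 3))
        yy, xx = np.mgrid[max(0, cy - r):min(size, cy + r + 1),
                          max(0, cx - r):min(size, cx + r + 1)]
        mask[yy, xx] = lab
    # salt noise of single pixels
    for _ in range(10):
        mask[rng.integers(0, size), rng.integers(0, size)] = rng.integers(0, 3)
    return mask


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
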