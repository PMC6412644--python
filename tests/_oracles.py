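"""Independent brute-force oracles used to validate the morphology stack.

Everything here is deliberately naive (shift-and-compare, iterate to a
fixed point, exhaustive scans) and shares no code path with the package
implementation.
"""

from __future__ import annotations

import numpy as np

_SHIFTS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 0), (0, 1), (1, -1), (1, 0), (1, 1)]


def _shifted_stack(img: np.ndarray, offsets, pad_value: float) -> np.ndarray:
    h, w = img.shape
    padded = np.pad(img, 1, constant_values=pad_value)
    return np.stack(
        [padded[1 + dy : 1 + dy + h, 1 + dx : 1 + dx + w] for dy, dx in offsets]
    )


def brute_dilate8(img: np.ndarray) -> np.ndarray:
    """Grayscale dilation with the full 3x3 neighbourhood."""
    return _shifted_stack(img, _SHIFTS8, -np.inf).max(axis=0)


def brute_erode8(img: np.ndarray) -> np.ndarray:
    return _shifted_stack(img, _SHIFTS8, np.inf).min(axis=0)


def brute_dilate_fp(img: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Grayscale dilation by an arbitrary centred footprint, direct loops."""
    r = footprint.shape[0] // 2
    h, w = img.shape
    padded = np.pad(img, r, constant_values=-np.inf)
    out = np.empty_like(img, dtype=float)
    offs = [
        (dy - r, dx - r)
        for dy in range(footprint.shape[0])
        for dx in range(footprint.shape[1])
        if footprint[dy, dx]
    ]
    for y in range(h):
        for x in range(w):
            out[y, x] = max(padded[y + r + dy, x + r + dx] for dy, dx in offs)
    return out


def brute_erode_fp(img: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    return -brute_dilate_fp(-img, footprint)


def brute_open_fp(img: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    return brute_dilate_fp(brute_erode_fp(img, footprint), footprint)


def brute_close_fp(img: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    return brute_erode_fp(brute_dilate_fp(img, footprint), footprint)


def brute_reconstruct_dilation(seed: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Geodesic dilation (8-connected) iterated to its fixed point."""
    cur = np.minimum(seed, mask).astype(float)
    while True:
        nxt = np.minimum(brute_dilate8(cur), mask)
        if np.array_equal(nxt, cur):
            return cur
        cur = nxt


def brute_reconstruct_erosion(seed: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Geodesic erosion (8-connected) iterated to its fixed point."""
    cur = np.maximum(seed, mask).astype(float)
    while True:
        nxt = np.maximum(brute_erode8(cur), mask)
        if np.array_equal(nxt, cur):
            return cur
        cur = nxt


def brute_open_reconstruction(g, r, footprint):
    opened = brute_open_fp(np.asarray(g, float), footprint)
    return brute_reconstruct_dilation(opened, np.asarray(r, float))


def brute_close_reconstruction(g, r, footprint):
    closed = brute_close_fp(np.asarray(g, float), footprint)
    return brute_reconstruct_erosion(closed, np.asarray(r, float))


def brute_regional_minima(img: np.ndarray) -> np.ndarray:
    """Exhaustive regional-minima scan: an 8-connected plateau is a
    regional minimum iff no neighbour of the plateau is lower."""
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    out = np.zeros((h, w), dtype=bool)
    seen = np.zeros((h, w), dtype=bool)
    for sy in range(h):
        for sx in range(w):
            if seen[sy, sx]:
                continue
            v = img[sy, sx]
            stack = [(sy, sx)]
            plateau = []
            is_min = True
            seen[sy, sx] = True
            while stack:
                y, x = stack.pop()
                plateau.append((y, x))
                for dy, dx in _SHIFTS8:
                    if dy == 0 and dx == 0:
                        continue
                    ny, nx = y + dy, x + dx
                    if not (0 <= ny < h and 0 <= nx < w):
                        continue
                    if img[ny, nx] < v:
                        is_min = False
                    elif img[ny, nx] == v and not seen[ny, nx]:
                        seen[ny, nx] = True
                        stack.append((ny, nx))
            if is_min:
                for y, x in plateau:
                    out[y, x] = True
    return out


def brute_mean_boundary_distance(candidate: np.ndarray, reference: np.ndarray) -> float:
    """Mean distance of mismatched pixels to the nearest 4-boundary pixel
    of the reference foreground, by exhaustive pairwise search."""
    candidate = np.asarray(candidate, bool)
    reference = np.asarray(reference, bool)
    h, w = reference.shape
    boundary = []
    for y in range(h):
        for x in range(w):
            if not reference[y, x]:
                continue
            for dy, dx in ((-1, 0), (0, -1), (0, 1), (1, 0)):
                ny, nx = y + dy, x + dx
                if not (0 <= ny < h and 0 <= nx < w) or not reference[ny, nx]:
                    boundary.append((y, x))
                    break
    mism = np.argwhere(candidate ^ reference)
    if len(mism) == 0:
        return 0.0
    dists = [
        min(np.hypot(y - by, x - bx) for by, bx in boundary) for y, x in mism
    ]
    return float(np.mean(dists))
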