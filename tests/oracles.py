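"""Brute-force reference implementations used only by the test suite.

Each oracle states the operation's definition directly (exhaustive
per-pixel scans, explicit floods), independently of the library's
implementation strategy, so agreement is meaningful.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def disk_offsets(radius: float) -> np.ndarray:
    """All integer offsets with Euclidean norm <= radius."""
    n = int(np.floor(radius))
    offs = [(dy, dx)
            for dy in range(-n, n + 1) for dx in range(-n, n + 1)
            if dy * dy + dx * dx <= radius * radius]
    return np.array(offs, dtype=int)


def erode_labels(labels: np.ndarray, n_px: float) -> np.ndarray:
    """Keep a pixel iff every pixel within distance n_px lies inside the
    image and carries the same label."""
    h, w = labels.shape
    out = labels.copy()
    offs = disk_offsets(n_px)
    for dy, dx in offs:
        ys = np.arange(h) + dy
        xs = np.arange(w) + dx
        inside_y = (ys >= 0) & (ys < h)
        inside_x = (xs >= 0) & (xs < w)
        shifted = np.zeros_like(labels)
        shifted[np.ix_(inside_y, inside_x)] = \
            labels[np.ix_(ys[inside_y], xs[inside_x])]
        valid = np.outer(inside_y, inside_x)
        out[(shifted != labels) | ~valid] = 0
    return out


def grow_labels(labels: np.ndarray, n_px: float) -> np.ndarray:
    """Nearest-label assignment within distance n_px; ties to smallest id."""
    out = labels.copy()
    pts = np.argwhere(labels > 0)
    if pts.size == 0:
        return out
    vals = labels[pts[:, 0], pts[:, 1]]
    limit = n_px * n_px
    for r in range(labels.shape[0]):
        for c in range(labels.shape[1]):
            if labels[r, c]:
                continue
            d2 = (pts[:, 0] - r) ** 2 + (pts[:, 1] - c) ** 2
            m = d2.min()
            if m <= limit:
                out[r, c] = vals[d2 == m].min()
    return out


def _rank_filter(image: np.ndarray, radius: float, op) -> np.ndarray:
    h, w = image.shape
    out = np.empty_like(image, dtype=float)
    offs = disk_offsets(radius)
    for r in range(h):
        for c in range(w):
            ys = r + offs[:, 0]
            xs = c + offs[:, 1]
            ok = (ys >= 0) & (ys < h) & (xs >= 0) & (xs < w)
            out[r, c] = op(image[ys[ok], xs[ok]])
    return out


def closing(image: np.ndarray, radius: float) -> np.ndarray:
    """Grey closing: max filter then min filter over the clipped disk."""
    return _rank_filter(_rank_filter(image, radius, np.max), radius, np.min)


def bottom_hat(image: np.ndarray, radius: float) -> np.ndarray:
    return closing(image, radius) - np.asarray(image, dtype=float)


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Foreground plus background regions unreachable from the border by an
    8-connected flood."""
    h, w = mask.shape
    reach = np.zeros_like(mask, dtype=bool)
    queue: deque = deque()
    for r in range(h):
        for c in (0, w - 1):
            if not mask[r, c] and not reach[r, c]:
                reach[r, c] = True
                queue.append((r, c))
    for c in range(w):
        for r in (0, h - 1):
            if not mask[r, c] and not reach[r, c]:
                reach[r, c] = True
                queue.append((r, c))
    while queue:
        r, c = queue.popleft()
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                rr, cc = r + dy, c + dx
                if 0 <= rr < h and 0 <= cc < w and not mask[rr, cc] \
                        and not reach[rr, cc]:
                    reach[rr, cc] = True
                    queue.append((rr, cc))
    return mask | ~reach


def random_label_image(rng: np.random.Generator, shape=(64, 64),
                       max_objects: int = 5) -> np.ndarray:
    """A few random disks/rectangles with distinct labels for oracle runs."""
    labels = np.zeros(shape, dtype=np.int32)
    yy, xx = np.ogrid[:shape[0], :shape[1]]
    n = int(rng.integers(1, max_objects + 1))
    for i in range(1, n + 1):
        r, c = rng.integers(4, shape[0] - 4), rng.integers(4, shape[1] - 4)
        if rng.random() < 0.5:
            rad = int(rng.integers(1, 7))
            obj = (yy - r) ** 2 + (xx - c) ** 2 <= rad * rad
        else:
            hh, ww = rng.integers(2, 9, 2)
            obj = (abs(yy - r) <= hh) & (abs(xx - c) <= ww)
        labels[obj & (labels == 0)] = i
    return labels
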