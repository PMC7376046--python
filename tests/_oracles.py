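"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (BFS, explicit offset sets, O(n^2)
pair counting, exhaustive threshold scans) and shares no code with the
package's own implementations.
"""

from collections import deque

import numpy as np


def fill_holes_bruteforce(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """BFS border-connectivity labeling of the background; unreached
    background pixels are holes and become foreground."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    if connectivity == 4:
        neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        neigh = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                 if (dr, dc) != (0, 0)]
    reached = np.zeros_like(mask)
    q = deque()
    for r in range(h):
        for c in range(w):
            if (r in (0, h - 1) or c in (0, w - 1)) and not mask[r, c]:
                if not reached[r, c]:
                    reached[r, c] = True
                    q.append((r, c))
    while q:
        r, c = q.popleft()
        for dr, dc in neigh:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and not mask[rr, cc] \
                    and not reached[rr, cc]:
                reached[rr, cc] = True
                q.append((rr, cc))
    return mask | ~reached


def disk_offsets(radius: int):
    return [(dr, dc) for dr in range(-radius, radius + 1)
            for dc in range(-radius, radius + 1)
            if dr * dr + dc * dc <= radius * radius]


def erode_bruteforce(mask: np.ndarray, radius: int) -> np.ndarray:
    """Pixel survives iff every disk offset lands on in-image foreground
    (outside the image counts as background)."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    out = np.zeros_like(mask)
    offs = disk_offsets(radius)
    for r in range(h):
        for c in range(w):
            out[r, c] = all(0 <= r + dr < h and 0 <= c + dc < w
                            and mask[r + dr, c + dc] for dr, dc in offs)
    return out


def dilate_bruteforce(mask: np.ndarray, radius: int) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    out = np.zeros_like(mask)
    offs = disk_offsets(radius)
    for r in range(h):
        for c in range(w):
            if mask[r, c]:
                for dr, dc in offs:
                    if 0 <= r + dr < h and 0 <= c + dc < w:
                        out[r + dr, c + dc] = True
    return out


def open_bruteforce(mask: np.ndarray, radius: int) -> np.ndarray:
    return dilate_bruteforce(erode_bruteforce(mask, radius), radius)


def otsu_bruteforce(values: np.ndarray) -> float:
    """Exhaustive scan of all 256 candidate thresholds maximizing
    between-class variance; first (lowest) maximizer wins."""
    v = np.asarray(values, dtype=float).ravel()
    lo, hi = v.min(), v.max()
    counts, edges = np.histogram(v, bins=256, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    best_t, best_var = None, -1.0
    n = counts.sum()
    for t in range(255):
        n0 = counts[:t + 1].sum()
        n1 = n - n0
        if n0 == 0 or n1 == 0:
            continue
        mu0 = (counts[:t + 1] * centers[:t + 1]).sum() / n0
        mu1 = (counts[t + 1:] * centers[t + 1:]).sum() / n1
        var = (n0 / n) * (n1 / n) * (mu0 - mu1) ** 2
        # thresholds inside an empty-bin gap are exact ties up to float
        # noise; keep the first (lowest) per the tie-break convention
        if var > best_var * (1 + 1e-9) + 1e-12:
            best_var = var
            best_t = t
    return float(centers[best_t])


def auc_pair_counting(scores, truths) -> float:
    """(concordant + 0.5 * tied) / (n_pos * n_neg) over all +/- pairs."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(truths, dtype=bool)
    pos = scores[y]
    neg = scores[~y]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def fscore_direct(tp: int, fp: int, fn: int) -> float:
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    return 2 * prec * rec / (prec + rec) if prec + rec else 0.0


def convex_hull_area(points: np.ndarray) -> float:
    """Monotone-chain hull + shoelace area of a pixel point set."""
    pts = sorted(map(tuple, points))
    if len(pts) < 3:
        return 0.0

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower, upper = [], []
    for p in pts:
        while len(lower) > 1 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    for p in reversed(pts):
        while len(upper) > 1 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    hull = lower[:-1] + upper[:-1]
    area = 0.0
    for i in range(len(hull)):
        x0, y0 = hull[i]
        x1, y1 = hull[(i + 1) % len(hull)]
        area += x0 * y1 - x1 * y0
    return abs(area) / 2.0
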