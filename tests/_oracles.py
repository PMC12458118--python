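"""Independent brute-force oracles for derived expected values.

Everything here is deliberately naive — exhaustive grid searches and
plain-Python loops — and shares no code with the package implementation
it checks.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# T2 fitting: exhaustive grid search over (S0, T2) with S0 profiled out


def grid_search_t2(signals: np.ndarray, te: np.ndarray, t2_grid: np.ndarray) -> np.ndarray:
    """Least-squares T2 per voxel by exhaustive search over a T2 grid."""
    signals = np.atleast_2d(signals)
    best_sse = np.full(signals.shape[0], np.inf)
    best_t2 = np.full(signals.shape[0], np.nan)
    for t2 in t2_grid:
        decay = np.exp(-te / t2)
        s0 = signals @ decay / float(decay @ decay)
        resid = signals - s0[:, None] * decay[None, :]
        sse = (resid**2).sum(axis=1)
        better = sse < best_sse
        best_sse[better] = sse[better]
        best_t2[better] = t2
    return best_t2


# ---------------------------------------------------------------------------
# Hierarchical region split: plain-loop recursion of the stated rules


def _hist(values: list[float], bin_width: float) -> tuple[list[float], list[int]]:
    lo, hi = min(values), max(values)
    nb = max(1, math.ceil((hi - lo) / bin_width + 0.5))
    if lo + (nb - 0.5) * bin_width < hi:
        nb += 1
    edges = [lo - bin_width / 2.0 + bin_width * i for i in range(nb + 1)]
    counts = [0] * nb
    for v in values:
        i = 0
        while i < nb - 1 and v >= edges[i + 1]:
            i += 1
        counts[i] += 1
    return edges, counts


def _smooth(counts: list[int], bin_width: float, bandwidth: float) -> list[float]:
    if bandwidth <= 0:
        return [float(c) for c in counts]
    r = math.ceil(4.0 * bandwidth / bin_width)
    kernel = [math.exp(-0.5 * ((i * bin_width) / bandwidth) ** 2) for i in range(-r, r + 1)]
    total = sum(kernel)
    kernel = [k / total for k in kernel]
    out = []
    for i in range(len(counts)):
        acc = 0.0
        for j, w in enumerate(kernel):
            idx = i + j - r
            if 0 <= idx < len(counts):
                acc += counts[idx] * w
        out.append(acc)
    return out


def _peaks_with_prominence(s: list[float]) -> list[tuple[int, float]]:
    peaks = []
    n = len(s)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and s[j + 1] == s[i]:
            j += 1
        left = s[i - 1] if i > 0 else -math.inf
        right = s[j + 1] if j + 1 < n else -math.inf
        if s[i] > left and s[i] > right:
            peaks.append((i + j) // 2)
        i = j + 1
    result = []
    for p in peaks:
        h = s[p]
        lmin = None
        for k in range(p - 1, -1, -1):
            if s[k] > h:
                break
            lmin = s[k] if lmin is None else min(lmin, s[k])
        rmin = None
        for k in range(p + 1, n):
            if s[k] > h:
                break
            rmin = s[k] if rmin is None else min(rmin, s[k])
        bases = [m for m in (lmin, rmin) if m is not None]
        result.append((p, h - max(bases) if bases else h))
    return result


def _centers(edges: list[float]) -> list[float]:
    return [(a + b) / 2.0 for a, b in zip(edges[:-1], edges[1:])]


def oracle_valley(values: list[float], bin_width: float, bandwidth: float,
                  min_prom_frac: float) -> tuple[float | None, float]:
    """(valley T2 or None, mode T2) by the exhaustive scan of the rules."""
    edges, counts = _hist(values, bin_width)
    s = _smooth(counts, bin_width, bandwidth)
    centers = _centers(edges)
    mode_idx = max(range(len(s)), key=lambda i: (s[i], -i))
    mode = centers[mode_idx]
    smax = max(s)
    cand = [(p, prom) for p, prom in _peaks_with_prominence(s)
            if s[p] > 0 and prom >= min_prom_frac * smax]
    cand.sort(key=lambda m: (-m[1], -s[m[0]], m[0]))
    if len(cand) < 2:
        return None, mode
    p1, p2 = sorted(p for p, _ in cand[:2])
    if p2 - p1 < 2:
        return None, mode
    best = p1 + 1
    for k in range(p1 + 1, p2):
        if s[k] < s[best]:
            best = k
    return centers[best], mode


def oracle_segment(
    ids: list[int],
    values: list[float],
    bin_width: float,
    bandwidth: float,
    min_prom_frac: float,
    min_region: int,
    max_depth: int,
    core_threshold: float,
    uninjured_threshold: float,
) -> dict[int, int]:
    """Voxel id -> label {1 uninjured, 2 penumbra, 3 core} by hand recursion."""
    labels: dict[int, int] = {}

    def recurse(ids: list[int], values: list[float], depth: int) -> None:
        valley, mode = oracle_valley(values, bin_width, bandwidth, min_prom_frac)
        if valley is not None and depth < max_depth:
            left = [(i, v) for i, v in zip(ids, values) if v <= valley]
            right = [(i, v) for i, v in zip(ids, values) if v > valley]
            if len(left) >= min_region and len(right) >= min_region:
                recurse([i for i, _ in left], [v for _, v in left], depth + 1)
                recurse([i for i, _ in right], [v for _, v in right], depth + 1)
                return
        code = 3 if mode > core_threshold else 2
        for i in ids:
            labels[i] = code

    recurse(list(ids), list(values), 0)
    for i, v in zip(ids, values):
        if v < uninjured_threshold:
            labels[i] = 1
    return labels


# ---------------------------------------------------------------------------
# point-in-ellipsoid voxel counting


def count_ellipsoid_voxels(center, semiaxes, grid_shape) -> int:
    n = 0
    for r in range(grid_shape[0]):
        for c in range(grid_shape[1]):
            for s in range(grid_shape[2]):
                q = (
                    ((r - center[0]) / semiaxes[0]) ** 2
                    + ((c - center[1]) / semiaxes[1]) ** 2
                    + ((s - center[2]) / semiaxes[2]) ** 2
                )
                if q <= 1.0:
                    n += 1
    return n
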