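"""Hierarchical region split of a masked T2 map into ischemic core and penumbra.

The edematous region of a quantitative T2 map (supplied as a manually
outlined lesion mask) is segmented by recursive histogram splitting: the
region's T2-time histogram is smoothed, its two most prominent modes are
located, and the region is split at the valley between them; each half is
split again until a region is unimodal, too small, or too deep.  Terminal
regions ("leaves") are classified by the T2 at their histogram peak:

* leaf mode  > 56 ms  ->  ischemic core
* leaf mode <= 56 ms  ->  penumbra

and finally any voxel with T2 below 33 ms is relabelled as uninjured
tissue, whatever leaf it fell in.  Both thresholds are strict
inequalities and both are exposed in :class:`SegmentationParams`.

The mode/valley detector is deliberately specified to the letter so that
an independent re-implementation must agree exactly:

* histogram: fixed-width bins covering the region values, centered on a
  grid anchored at the region minimum (the first bin's center is the
  minimum value);
* smoothing: discrete Gaussian kernel (truncated at 4 bandwidths,
  normalized to unit sum) convolved with the raw counts, zero-padded;
* modes: plateau-aware local maxima (boundary bins are eligible, with
  out-of-range neighbours treated as -inf; a plateau contributes its
  middle bin), kept when their side-scan prominence is at least
  ``bimodality_min_prominence`` times the smoothed maximum;
* valley: the first (lowest-T2) global minimum of the smoothed counts
  strictly between the two most prominent modes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

__all__ = [
    "OUTSIDE",
    "UNINJURED",
    "PENUMBRA",
    "CORE",
    "LABEL_NAMES",
    "LesionMask",
    "T2Histogram",
    "RegionNode",
    "SegmentationParams",
    "TissueLabels",
    "build_histogram",
    "find_valley",
    "hierarchical_split",
    "classify_leaves",
    "segment_lesion",
    "format_tree",
]

OUTSIDE, UNINJURED, PENUMBRA, CORE = 0, 1, 2, 3
LABEL_NAMES = {OUTSIDE: "outside", UNINJURED: "uninjured", PENUMBRA: "penumbra", CORE: "core"}


@dataclass
class LesionMask:
    """Binary mask of the manually outlined edematous region."""

    mask: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("lesion mask must be 3-D")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)


@dataclass
class TissueLabels:
    """Per-voxel tissue class: 0 outside, 1 uninjured, 2 penumbra, 3 core."""

    labels: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3-D")
        if not np.isin(np.unique(self.labels), [OUTSIDE, UNINJURED, PENUMBRA, CORE]).all():
            raise ValueError("label codes must be within {0,1,2,3}")
        self.labels = self.labels.astype(np.uint8)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))


@dataclass
class T2Histogram:
    """Fixed-width T2-time histogram with optional smoothed counts."""

    bin_edges: np.ndarray      # ms, ascending, len = nbins + 1
    counts: np.ndarray         # raw integer counts per bin
    smoothed: np.ndarray       # Gaussian-smoothed counts (== counts if bandwidth 0)

    @property
    def centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0


@dataclass
class SegmentationParams:
    """Knobs of the hierarchical region split.

    Defaults implement the published regime: core if the leaf's histogram
    mode exceeds 56 ms, uninjured below 33 ms (both strict), 1 ms bins
    smoothed with a 2 ms Gaussian, recursion stopped by unimodality, a
    30-voxel minimum region, or depth 6.
    """

    core_mode_threshold: float = 56.0
    uninjured_t2_threshold: float = 33.0
    bin_width: float = 1.0
    smoothing_bandwidth: float = 2.0
    min_region_voxels: int = 30
    max_depth: int = 6
    bimodality_min_prominence: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.uninjured_t2_threshold < self.core_mode_threshold:
            raise ValueError("need 0 < uninjured_t2_threshold < core_mode_threshold")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.smoothing_bandwidth < 0:
            raise ValueError("smoothing_bandwidth must be non-negative")
        if self.min_region_voxels < 1 or self.max_depth < 0:
            raise ValueError("min_region_voxels >= 1 and max_depth >= 0 required")
        if not 0 <= self.bimodality_min_prominence <= 1:
            raise ValueError("bimodality_min_prominence must be a fraction in [0,1]")


@dataclass
class RegionNode:
    """A node of the recursive split tree over voxel flat-indices."""

    voxel_ids: np.ndarray
    mode_t2: float
    split_threshold: float | None
    children: tuple["RegionNode", ...]
    depth: int

    @property
    def is_leaf(self) -> bool:
        return self.split_threshold is None

    def leaves(self) -> Iterator["RegionNode"]:
        if self.is_leaf:
            yield self
        else:
            for child in self.children:
                yield from child.leaves()


def _gaussian_smooth(counts: np.ndarray, bin_width: float, bandwidth: float) -> np.ndarray:
    if bandwidth <= 0:
        return counts.astype(float)
    radius = int(np.ceil(4.0 * bandwidth / bin_width))
    x = np.arange(-radius, radius + 1) * bin_width
    kernel = np.exp(-0.5 * (x / bandwidth) ** 2)
    kernel /= kernel.sum()
    # sliding dot product with zero padding (np.convolve 'same' misbehaves
    # when the kernel outgrows a small region's histogram)
    n = counts.size
    padded = np.zeros(n + 2 * radius)
    padded[radius : radius + n] = counts
    return np.array([float(np.dot(padded[i : i + 2 * radius + 1], kernel)) for i in range(n)])


def build_histogram(
    t2_values: np.ndarray, bin_width: float = 1.0, smoothing_bandwidth: float = 2.0
) -> T2Histogram:
    """Histogram a set of T2 values into fixed-width bins and smooth it.

    Bin centers sit on the grid ``min + k*bin_width``, so the first bin is
    centered on the minimum value and a degenerate (single-value) region's
    mode is that value exactly (a single bin when all values coincide).
    Raw counts always sum to the number of values; smoothing (a normalized
    Gaussian kernel, zero-padded) applies only to the ``smoothed`` field.
    """
    values = np.asarray(t2_values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("cannot histogram an empty set of T2 values")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo = float(values.min())
    hi = float(values.max())
    # bins centered on the value grid anchored at the minimum, so a
    # degenerate (single-value) region's mode is that value exactly
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width + 0.5)))
    if lo + (n_bins - 0.5) * bin_width < hi:  # guard against float round-down
        n_bins += 1
    edges = lo - bin_width / 2.0 + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    smoothed = _gaussian_smooth(counts, bin_width, smoothing_bandwidth)
    return T2Histogram(bin_edges=edges, counts=counts, smoothed=smoothed)


def _local_maxima(s: np.ndarray) -> list[int]:
    """Plateau-aware local maxima; boundary neighbours count as -inf."""
    peaks: list[int] = []
    n = s.size
    i = 0
    while i < n:
        j = i
        while j + 1 < n and s[j + 1] == s[i]:
            j += 1
        left = s[i - 1] if i > 0 else -np.inf
        right = s[j + 1] if j + 1 < n else -np.inf
        if s[i] > left and s[i] > right:
            peaks.append((i + j) // 2)
        i = j + 1
    return peaks


def _prominence(s: np.ndarray, peak: int) -> float:
    """Side-scan prominence: height above the higher of the two bases.

    Each base is the minimum encountered walking away from the peak until
    a strictly higher bin or the array edge; a side with no bins at all
    (boundary peak) contributes no base.
    """
    h = s[peak]
    left_min = None
    for i in range(peak - 1, -1, -1):
        if s[i] > h:
            break
        left_min = s[i] if left_min is None else min(left_min, s[i])
    right_min = None
    for i in range(peak + 1, s.size):
        if s[i] > h:
            break
        right_min = s[i] if right_min is None else min(right_min, s[i])
    bases = [m for m in (left_min, right_min) if m is not None]
    return float(h - max(bases)) if bases else float(h)


def _qualifying_modes(hist: T2Histogram, min_prominence_frac: float) -> list[int]:
    """Modes of the smoothed histogram passing the prominence filter, by index."""
    s = hist.smoothed
    if s.size == 0 or s.max() <= 0:
        return []
    threshold = min_prominence_frac * float(s.max())
    modes = [
        (p, _prominence(s, p))
        for p in _local_maxima(s)
        if s[p] > 0
    ]
    modes = [(p, prom) for p, prom in modes if prom >= threshold]
    # two most prominent; ties broken by height then by lower T2
    modes.sort(key=lambda m: (-m[1], -s[m[0]], m[0]))
    return [p for p, _ in modes]


def find_valley(hist: T2Histogram, min_prominence_frac: float = 0.05) -> float | None:
    """T2 at the valley between the histogram's two principal modes.

    Returns the bin-centre T2 of the global minimum of the smoothed
    counts strictly between the two highest-prominence modes (first bin
    on ties, i.e. toward lower T2), or ``None`` when the histogram is
    unimodal under the prominence criterion — a valid outcome that makes
    the region a leaf.
    """
    modes = _qualifying_modes(hist, min_prominence_frac)
    if len(modes) < 2:
        return None
    p1, p2 = sorted(modes[:2])
    if p2 - p1 < 2:  # no interior bin between adjacent modes
        return None
    interior = hist.smoothed[p1 + 1 : p2]
    valley_idx = p1 + 1 + int(np.argmin(interior))
    return float(hist.centers[valley_idx])


def _region_mode(hist: T2Histogram) -> float:
    return float(hist.centers[int(np.argmax(hist.smoothed))])


def hierarchical_split(
    t2_map, domain: np.ndarray, params: SegmentationParams | None = None
) -> RegionNode:
    """Recursively split a region of a T2 map at histogram valleys.

    Parameters
    ----------
    t2_map : T2Map
        Fitted map; every domain voxel must be a valid fit.
    domain : ndarray
        Boolean volume or flat voxel indices defining the region to
        split (typically lesion mask ∩ valid fits).
    params : SegmentationParams, optional

    Returns
    -------
    RegionNode
        Root of the split tree.  A node is split only when a qualifying
        valley exists, both halves hold at least ``min_region_voxels``,
        and the depth limit is not reached; children partition the parent
        as {T2 <= valley} / {T2 > valley}.
    """
    params = params or SegmentationParams()
    domain = np.asarray(domain)
    if domain.dtype == bool:
        ids = np.flatnonzero(domain.ravel())
    else:
        ids = np.asarray(domain, dtype=np.int64).ravel()
    if ids.size == 0:
        raise ValueError("empty domain")
    valid = t2_map.valid.ravel()[ids]
    if not np.all(valid):
        raise ValueError("domain contains invalid-fit voxels; pre-filter with t2_map.valid")
    values = t2_map.t2.ravel()[ids]

    def split(ids: np.ndarray, values: np.ndarray, depth: int) -> RegionNode:
        hist = build_histogram(values, params.bin_width, params.smoothing_bandwidth)
        mode = _region_mode(hist)
        if depth < params.max_depth:
            valley = find_valley(hist, params.bimodality_min_prominence)
        else:
            valley = None
        if valley is not None:
            left = values <= valley
            n_left = int(left.sum())
            if (
                n_left >= params.min_region_voxels
                and ids.size - n_left >= params.min_region_voxels
            ):
                children = (
                    split(ids[left], values[left], depth + 1),
                    split(ids[~left], values[~left], depth + 1),
                )
                return RegionNode(ids, mode, valley, children, depth)
        return RegionNode(ids, mode, None, (), depth)

    return split(ids, values, 0)


def classify_leaves(
    tree: RegionNode, t2_map, params: SegmentationParams | None = None
) -> TissueLabels:
    """Label the tree's voxels: leaf mode > 56 ms -> core, else penumbra;
    then any voxel with T2 < 33 ms is overridden to uninjured.

    Both comparisons are strict: a leaf whose mode is exactly at the core
    threshold stays penumbra, a voxel exactly at the uninjured threshold
    keeps its leaf class.
    """
    params = params or SegmentationParams()
    labels = np.zeros(t2_map.t2.shape, dtype=np.uint8)
    flat = labels.ravel()
    for leaf in tree.leaves():
        code = CORE if leaf.mode_t2 > params.core_mode_threshold else PENUMBRA
        flat[leaf.voxel_ids] = code
    t2_flat = t2_map.t2.ravel()
    domain = tree.voxel_ids
    low = domain[t2_flat[domain] < params.uninjured_t2_threshold]
    flat[low] = UNINJURED
    return TissueLabels(labels=labels, voxel_size=t2_map.voxel_size)


def segment_lesion(
    t2_map, lesion_mask: LesionMask, params: SegmentationParams | None = None
) -> TissueLabels:
    """Full segmentation of the outlined edematous region.

    Restricts the analysis domain to lesion-mask voxels with valid fits
    (the manual outline exists precisely to keep skull-stripping errors
    and CSF out of the histogram), runs the hierarchical split, and
    classifies leaves.  Voxels outside the mask are labelled 0.
    """
    params = params or SegmentationParams()
    if lesion_mask.mask.shape != t2_map.t2.shape:
        raise ValueError("lesion mask grid does not match the T2 map")
    domain = lesion_mask.mask & t2_map.valid
    n_masked = int(lesion_mask.mask.sum())
    n_domain = int(domain.sum())
    if n_domain == 0:
        raise ValueError(
            f"no usable voxels: lesion mask holds {n_masked} voxels, "
            f"none with a valid T2 fit"
        )
    tree = hierarchical_split(t2_map, domain, params)
    return classify_leaves(tree, t2_map, params)


def format_tree(node: RegionNode, params: SegmentationParams | None = None) -> str:
    """Indented text dump of a split tree (depth, size, mode, split)."""
    lines: list[str] = []

    def walk(n: RegionNode) -> None:
        pad = "  " * n.depth
        split = f" split@{n.split_threshold:.2f}ms" if not n.is_leaf else " leaf"
        lines.append(f"{pad}depth={n.depth} n={n.voxel_ids.size} mode={n.mode_t2:.2f}ms{split}")
        for child in n.children:
            walk(child)

    walk(node)
    return "\n".join(lines)
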