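"""Multi-echo MRI phantoms with known core/penumbra geometry.

The phantom emulates a neonatal mouse brain scanned with a multi-echo
spin-echo sequence: two mirror-image ellipsoidal hemispheres, an
ellipsoidal ischemic core wrapped in a concentric penumbra shell inside
the ipsilateral hemisphere, per-class T2 times drawn from truncated
Gaussians (uninjured below the 33 ms convention, penumbra intermediate,
core above 56 ms), mono-exponential echo decay, and Rician noise — the
magnitude-reconstruction noise model sqrt((S+n1)^2 + n2^2) with
independent Gaussian n1, n2.

"Lost tissue" (post-injury atrophy) is emulated by deleting a posterior
wedge of ipsilateral brain voxels: the simplest geometry for which the
hemisphere-subtraction volumetric contract is exact.  Default scale
mirrors the scan this emulates: 0.12x0.12x0.5 mm voxels and 10 echoes at
TE = 10..100 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ..relaxometry import MultiEchoVolume
from ..segmentation import CORE, LesionMask, OUTSIDE, PENUMBRA, TissueLabels, UNINJURED

__all__ = ["Ellipsoid", "PhantomSpec", "PhantomTruth", "make_phantom"]


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid in voxel coordinates."""

    center: tuple[float, float, float]
    semiaxes: tuple[float, float, float]

    def mask(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        r, c, s = np.ogrid[: grid_shape[0], : grid_shape[1], : grid_shape[2]]
        q = (
            ((r - self.center[0]) / self.semiaxes[0]) ** 2
            + ((c - self.center[1]) / self.semiaxes[1]) ** 2
            + ((s - self.center[2]) / self.semiaxes[2]) ** 2
        )
        return q <= 1.0


def _default_geometry(
    grid_shape: tuple[int, int, int], midline_col: int
) -> tuple[Ellipsoid, Ellipsoid, Ellipsoid, Ellipsoid]:
    """Mirror-symmetric hemispheres and an anterior ipsilateral lesion."""
    nr, nc, ns = grid_shape
    cr, cs = (nr - 1) / 2.0, (ns - 1) / 2.0
    c_left = (midline_col - 1) / 2.0
    c_right = midline_col + (nc - midline_col - 1) / 2.0
    hemi_axes = (0.41 * nr, 0.45 * (nc / 2.0), 0.46 * ns)
    contra = Ellipsoid((cr, c_left, cs), hemi_axes)
    ipsi = Ellipsoid((cr, c_right, cs), hemi_axes)
    # lesion sits slightly anterior so the posterior atrophy wedge misses it
    core_center = (cr - 0.08 * nr, c_right, cs)
    core_axes = (0.09 * nr, 0.16 * (nc / 2.0), 0.21 * ns)
    core = Ellipsoid(core_center, core_axes)
    penumbra = Ellipsoid(core_center, tuple(1.8 * a for a in core_axes))
    return contra, ipsi, core, penumbra


@dataclass
class PhantomSpec:
    """Everything needed to synthesize one multi-echo phantom.

    Geometry fields left as ``None`` are filled with mirror-symmetric
    defaults derived from ``grid_shape``/``midline_col``.  Class T2 means
    must follow the injury regime uninjured < penumbra < core.
    ``noise_sigma`` is the Gaussian scale of the Rician channels in
    signal units (2% of ``s0`` by default, i.e. SNR 50 at TE→0);
    ``lost_fraction`` is the fraction of ipsilateral brain voxels deleted
    as a posterior wedge.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 12)
    voxel_size: tuple[float, float, float] = (0.12, 0.12, 0.5)
    echo_times: tuple[float, ...] = tuple(float(te) for te in range(10, 101, 10))
    midline_col: int | None = None
    ipsi_side: str = "right"
    contra_hemisphere: Ellipsoid | None = None
    ipsi_hemisphere: Ellipsoid | None = None
    core: Ellipsoid | None = None
    penumbra: Ellipsoid | None = None
    class_t2: dict[str, float] = field(
        default_factory=lambda: {"uninjured": 30.0, "penumbra": 45.0, "core": 70.0}
    )
    class_t2_sd: dict[str, float] = field(
        default_factory=lambda: {"uninjured": 1.5, "penumbra": 2.5, "core": 3.0}
    )
    s0: float = 1000.0
    noise_sigma: float = 20.0
    lost_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        te = np.asarray(self.echo_times, dtype=float)
        if te.size < 3 or not (np.all(np.diff(te) > 0) and te[0] > 0):
            raise ValueError("echo_times must be >=3 values, strictly increasing, positive")
        self.echo_times = tuple(float(t) for t in te)
        if self.midline_col is None:
            self.midline_col = self.grid_shape[1] // 2
        if not 0 < self.midline_col < self.grid_shape[1]:
            raise ValueError("midline_col must lie strictly inside the grid")
        if self.ipsi_side not in ("left", "right"):
            raise ValueError("ipsi_side must be 'left' or 'right'")
        if not 0.0 <= self.lost_fraction <= 1.0:
            raise ValueError("lost_fraction must be within [0, 1]")
        t2 = self.class_t2
        if not t2["uninjured"] < t2["penumbra"] < t2["core"]:
            raise ValueError("class T2 must be ordered uninjured < penumbra < core")
        if any(sd < 0 for sd in self.class_t2_sd.values()):
            raise ValueError("class_t2_sd must be non-negative")
        if self.s0 <= 0 or self.noise_sigma < 0:
            raise ValueError("s0 must be positive and noise_sigma non-negative")
        contra, ipsi, core, penumbra = _default_geometry(self.grid_shape, self.midline_col)
        if self.ipsi_side == "left":
            contra, ipsi = ipsi, contra
        self.contra_hemisphere = self.contra_hemisphere or contra
        self.ipsi_hemisphere = self.ipsi_hemisphere or ipsi
        self.core = self.core or core
        self.penumbra = self.penumbra or penumbra

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))


@dataclass
class PhantomTruth:
    """Ground truth accompanying a phantom, for recovery tests."""

    labels: TissueLabels
    true_volumes_mm3: dict[str, float]   # per class, label count x voxel volume
    true_lost_mm3: float                 # deleted-wedge volume
    true_t2: np.ndarray                  # per-voxel generating T2 (NaN outside brain)
    brain_mask: np.ndarray               # post-deletion tissue mask
    removed_mask: np.ndarray             # the deleted wedge
    midline_col: int
    ipsi_side: str


def _side_mask(grid_shape: tuple[int, int, int], midline_col: int, side: str) -> np.ndarray:
    cols = np.arange(grid_shape[1])
    sel = cols >= midline_col if side == "right" else cols < midline_col
    return np.broadcast_to(sel[None, :, None], grid_shape)


def make_phantom(spec: PhantomSpec) -> tuple[MultiEchoVolume, PhantomTruth, LesionMask]:
    """Synthesize a multi-echo phantom with known tissue-class geometry.

    Every in-brain voxel's noiseless signal is ``s0*exp(-TE/T2)`` with T2
    drawn once per voxel from its class's truncated Gaussian (lower bound
    1 ms); Rician noise is then applied independently per voxel and echo.
    The returned lesion mask is the union of the core and penumbra labels
    — the stand-in for a manual edema outline.  Identical spec and seed
    give bit-identical output.
    """
    shape = spec.grid_shape
    ipsi_half = _side_mask(shape, spec.midline_col, spec.ipsi_side)
    contra_half = ~ipsi_half
    ipsi = spec.ipsi_hemisphere.mask(shape) & ipsi_half
    contra = spec.contra_hemisphere.mask(shape) & contra_half
    core = spec.core.mask(shape)
    penumbra_ell = spec.penumbra.mask(shape)
    if np.any(core & ~penumbra_ell):
        raise ValueError("core ellipsoid must be contained in the penumbra ellipsoid")
    if np.any(penumbra_ell & ~ipsi):
        raise ValueError("lesion extends outside the ipsilateral hemisphere")

    labels = np.zeros(shape, dtype=np.uint8)
    labels[ipsi | contra] = UNINJURED
    labels[penumbra_ell & ~core] = PENUMBRA
    labels[core] = CORE

    # posterior atrophy wedge: delete the requested fraction of ipsilateral
    # brain voxels, highest row index (most posterior) first
    removed = np.zeros(shape, dtype=bool)
    n_ipsi = int(np.count_nonzero(ipsi))
    k = int(round(spec.lost_fraction * n_ipsi))
    if k > 0:
        rows, cols, slcs = np.nonzero(ipsi)
        order = np.lexsort((slcs, cols, -rows))
        sel = (rows[order[:k]], cols[order[:k]], slcs[order[:k]])
        removed[sel] = True
        labels[removed] = OUTSIDE

    rng = np.random.default_rng(spec.seed)
    true_t2 = np.full(shape, np.nan)
    for code, name in ((UNINJURED, "uninjured"), (PENUMBRA, "penumbra"), (CORE, "core")):
        sel = labels == code
        n = int(sel.sum())
        if n == 0:
            continue
        mean, sd = spec.class_t2[name], spec.class_t2_sd[name]
        if sd == 0:
            draws = np.full(n, mean)
        else:
            a = (1.0 - mean) / sd  # truncate at 1 ms: T2 stays physical
            draws = stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)
        true_t2[sel] = draws

    te = np.asarray(spec.echo_times)
    signal = np.zeros(shape + (te.size,))
    in_brain = labels != OUTSIDE
    signal[in_brain] = spec.s0 * np.exp(-te[None, :] / true_t2[in_brain][:, None])
    if spec.noise_sigma > 0:
        n1 = rng.normal(0.0, spec.noise_sigma, signal.shape)
        n2 = rng.normal(0.0, spec.noise_sigma, signal.shape)
        signal = np.sqrt((signal + n1) ** 2 + n2**2)

    vv = spec.voxel_volume_mm3
    tissue_labels = TissueLabels(labels=labels, voxel_size=spec.voxel_size)
    truth = PhantomTruth(
        labels=tissue_labels,
        true_volumes_mm3={
            name: float(np.count_nonzero(labels == code)) * vv
            for code, name in ((UNINJURED, "uninjured"), (PENUMBRA, "penumbra"), (CORE, "core"))
        },
        true_lost_mm3=k * vv,
        true_t2=true_t2,
        brain_mask=labels != OUTSIDE,
        removed_mask=removed,
        midline_col=spec.midline_col,
        ipsi_side=spec.ipsi_side,
    )
    vol = MultiEchoVolume(signal=signal, echo_times=te, voxel_size=spec.voxel_size)
    lesion = LesionMask(mask=(labels == PENUMBRA) | (labels == CORE), voxel_size=spec.voxel_size)
    return vol, truth, lesion
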