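"""Longitudinal lesion volumetrics.

Turns segmented label volumes into the study's outcome measures: per-class
volumes (core, penumbra, uninjured-within-mask) and the lost-tissue volume
obtained by hemisphere subtraction.  Lost tissue — injury not explained by
the core and penumbra classes — is the amount by which the injured
(ipsilateral) hemisphere falls short of the intact (contralateral) one,
clipped at zero so that edema swelling does not read as negative loss.

All volumes are exact voxel counts times the voxel volume, in mm³.
Tables are emitted tidy/long so they can be fed straight into external
repeated-measures ANOVA tooling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .segmentation import CORE, LABEL_NAMES, OUTSIDE, PENUMBRA, TissueLabels, UNINJURED

__all__ = [
    "ClassVolumes",
    "HemisphereVolumes",
    "class_volumes",
    "hemisphere_volumes",
    "longitudinal_table",
    "group_summary",
]


@dataclass
class ClassVolumes:
    """Per-class tissue volumes for one subject at one timepoint."""

    subject_id: str
    timepoint_h: float
    group: str
    volumes_mm3: dict[str, float]

    def with_lost(self, hemi: "HemisphereVolumes") -> "ClassVolumes":
        """Return a copy with the hemisphere-subtraction 'lost' class added."""
        merged = dict(self.volumes_mm3)
        merged["lost"] = hemi.lost_mm3
        return replace(self, volumes_mm3=merged)


@dataclass
class HemisphereVolumes:
    """Hemisphere tissue volumes and the clipped subtraction result.

    ``swelling`` flags scans where the ipsilateral hemisphere exceeded the
    contralateral one, in which case the raw subtraction was negative and
    ``lost_mm3`` was clipped to 0.
    """

    ipsilateral_mm3: float
    contralateral_mm3: float
    lost_mm3: float
    swelling: bool = False


def class_volumes(
    labels: TissueLabels,
    subject_id: str = "",
    timepoint_h: float = 0.0,
    group: str = "",
) -> ClassVolumes:
    """Volumes of the uninjured/penumbra/core classes from a label volume.

    Volume of each class is its voxel count times the voxel volume
    (mm³); unknown label codes are rejected.
    """
    arr = labels.labels
    codes = np.unique(arr)
    known = {OUTSIDE, UNINJURED, PENUMBRA, CORE}
    if not set(int(c) for c in codes) <= known:
        raise ValueError(f"unknown label codes {sorted(set(codes.tolist()) - known)}")
    vv = labels.voxel_volume_mm3
    volumes = {
        LABEL_NAMES[code]: float(np.count_nonzero(arr == code)) * vv
        for code in (UNINJURED, PENUMBRA, CORE)
    }
    return ClassVolumes(subject_id=subject_id, timepoint_h=timepoint_h, group=group, volumes_mm3=volumes)


def hemisphere_volumes(
    brain_mask: np.ndarray,
    voxel_size: tuple[float, float, float],
    midline_col: int,
    ipsilateral_side: str = "right",
    labels: TissueLabels | None = None,
) -> HemisphereVolumes:
    """Hemisphere tissue volumes split by a sagittal midline plane.

    Columns strictly below ``midline_col`` are one hemisphere, columns at
    or above it the other; ``ipsilateral_side`` says which side carries
    the injury.  ``lost_mm3 = max(0, contralateral - ipsilateral)``.  If
    ``labels`` is given, any voxel holding a nonzero tissue class is
    counted as present tissue even where the brain mask omits it, so a
    mask that excluded the lesion cannot inflate the loss estimate.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if brain_mask.ndim != 3:
        raise ValueError("brain mask must be 3-D")
    n_cols = brain_mask.shape[1]
    if not 0 < midline_col < n_cols:
        raise ValueError(f"midline_col {midline_col} outside grid with {n_cols} columns")
    if ipsilateral_side not in ("left", "right"):
        raise ValueError("ipsilateral_side must be 'left' or 'right'")
    tissue = brain_mask
    if labels is not None:
        if labels.labels.shape != brain_mask.shape:
            raise ValueError("labels grid does not match the brain mask")
        tissue = tissue | (labels.labels != OUTSIDE)
    vv = float(np.prod([float(v) for v in voxel_size]))
    left = float(np.count_nonzero(tissue[:, :midline_col, :])) * vv
    right = float(np.count_nonzero(tissue[:, midline_col:, :])) * vv
    ipsi, contra = (right, left) if ipsilateral_side == "right" else (left, right)
    raw = contra - ipsi
    return HemisphereVolumes(
        ipsilateral_mm3=ipsi,
        contralateral_mm3=contra,
        lost_mm3=max(0.0, raw),
        swelling=raw < 0,
    )


def longitudinal_table(records: list[ClassVolumes]) -> pd.DataFrame:
    """Tidy long-format volume table: one row per (subject, timepoint, class).

    Sorted by subject, timepoint, class; duplicate (subject, timepoint,
    class) entries are rejected.  This is the table external
    repeated-measures ANOVA consumes.
    """
    rows = [
        {
            "subject": r.subject_id,
            "group": r.group,
            "timepoint_h": r.timepoint_h,
            "tissue_class": cls,
            "volume_mm3": vol,
        }
        for r in records
        for cls, vol in r.volumes_mm3.items()
    ]
    if not rows:
        raise ValueError("no volume records supplied")
    df = pd.DataFrame(rows)
    dup = df.duplicated(subset=["subject", "timepoint_h", "tissue_class"])
    if dup.any():
        offending = df.loc[dup, ["subject", "timepoint_h", "tissue_class"]]
        raise ValueError(f"duplicate volume records:\n{offending.to_string(index=False)}")
    return df.sort_values(["subject", "timepoint_h", "tissue_class"]).reset_index(drop=True)


def group_summary(long_table: pd.DataFrame) -> pd.DataFrame:
    """Per-(group, timepoint, class) mean ± SD of volumes.

    SD is the sample standard deviation (ddof=1; 0 for singleton groups),
    matching the mean ± SD presentation of longitudinal volumetry.
    """
    def sd(x: pd.Series) -> float:
        return float(x.std(ddof=1)) if len(x) > 1 else 0.0

    out = (
        long_table.groupby(["group", "timepoint_h", "tissue_class"])["volume_mm3"]
        .agg(mean_mm3="mean", sd_mm3=sd, n="size")
        .reset_index()
    )
    return out
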