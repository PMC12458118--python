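"""End-to-end orchestration: configuration, MRI pipeline, demo workspace.

Chains the library stages (T2 fitting → lesion segmentation → volumetrics)
over a cohort described by a plain-text (YAML) config, isolates per-scan
failures so one bad scan cannot kill a cohort run, and stamps every run
with a provenance sidecar (config hash + stage parameters).  Also holds
the small stimulation-protocol arithmetic (pulse counts of a repetitive
TMS session, e.g. 1 Hz for 20 minutes = 1200 pulses).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .ephys import build_io_curve, hltp_contrast, paired_pulse_facilitation
from .expression import delta_delta_ct, fold_table, group_geometric_means
from .relaxometry import fit_t2_map
from .segmentation import SegmentationParams, segment_lesion
from .synthetic import (
    EphysSpec,
    PhantomSpec,
    make_ct_table,
    make_io_series,
    make_paired_pulse,
    make_phantom,
)
from .volumetrics import class_volumes, group_summary, hemisphere_volumes, longitudinal_table

__all__ = ["StimProtocol", "ScanInput", "RunConfig", "pulse_count", "run_mri_pipeline", "run_demo"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StimProtocol:
    """A repetitive-stimulation protocol (frequency, duration, intensity)."""

    frequency_hz: float
    duration_s: float
    intensity_percent_max: float = 80.0

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0 or self.duration_s <= 0:
            raise ValueError("frequency and duration must be positive")
        if not 0 < self.intensity_percent_max <= 100:
            raise ValueError("intensity must be in (0, 100] percent")

    @property
    def pulse_count(self) -> int:
        return pulse_count(self.frequency_hz, self.duration_s)


def pulse_count(frequency_hz: float, duration_s: float) -> int:
    """Total pulses delivered: floor(frequency x duration)."""
    if frequency_hz <= 0 or duration_s <= 0:
        raise ValueError("frequency and duration must be positive")
    return math.floor(frequency_hz * duration_s)


@dataclass
class ScanInput:
    """One scan of one subject: file paths plus cohort metadata."""

    subject: str
    group: str
    timepoint_h: float
    volume: str
    echoes: str
    lesion_mask: str
    brain_mask: str | None = None
    midline_col: int | None = None
    ipsi_side: str = "right"


@dataclass
class RunConfig:
    """Cohort-level configuration for the MRI pipeline."""

    scans: list[ScanInput] = field(default_factory=list)
    method: str = "nonlinear"
    omit_first_echo: bool = False
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    seed: int = 0
    log_level: str = "INFO"
    #: directory against which relative scan paths resolve; not serialized,
    #: so configs (and provenance hashes) stay location-independent
    base_dir: Path | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        seg = SegmentationParams(**raw.get("segmentation", {}))
        scans = [ScanInput(**s) for s in raw.get("scans", [])]
        return cls(
            scans=scans,
            method=raw.get("method", "nonlinear"),
            omit_first_echo=bool(raw.get("omit_first_echo", False)),
            segmentation=seg,
            seed=int(raw.get("seed", 0)),
            log_level=raw.get("log_level", "INFO"),
            base_dir=Path(path).resolve().parent,
        )

    def resolve(self, path: str) -> Path:
        p = Path(path)
        if p.is_absolute() or self.base_dir is None:
            return p
        return self.base_dir / p

    def to_dict(self) -> dict:
        return {
            "scans": [dataclasses.asdict(s) for s in self.scans],
            "method": self.method,
            "omit_first_echo": self.omit_first_echo,
            "segmentation": dataclasses.asdict(self.segmentation),
            "seed": self.seed,
            "log_level": self.log_level,
        }


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_provenance(out_dir: Path, config: RunConfig, extra: dict | None = None) -> None:
    payload = {"config_hash": _config_hash(config), "parameters": config.to_dict()}
    if extra:
        payload.update(extra)
    (out_dir / "provenance.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def run_mri_pipeline(config: RunConfig, out_dir: str | Path) -> pd.DataFrame:
    """Fit, segment, and measure every scan of a cohort.

    Writes per-scan label volumes (``labels_<subject>_<timepoint>.nii``),
    the tidy ``volumes.csv``, the per-group ``summary.csv`` and a
    provenance sidecar into ``out_dir``; returns the long table.  A
    failing scan is logged with its subject/timepoint context and
    skipped; the run continues.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    failures: list[str] = []
    for scan in config.scans:
        try:
            vol = hio.load_multi_echo(config.resolve(scan.volume), config.resolve(scan.echoes))
            mask = hio.load_mask(config.resolve(scan.lesion_mask))
            t2_map = fit_t2_map(
                vol,
                brain_mask=mask.mask,
                method=config.method,
                omit_first_echo=config.omit_first_echo,
            )
            labels = segment_lesion(t2_map, mask, config.segmentation)
            rec = class_volumes(labels, scan.subject, scan.timepoint_h, scan.group)
            if scan.brain_mask and scan.midline_col is not None:
                brain, vox = hio.load_nifti(config.resolve(scan.brain_mask))
                hemi = hemisphere_volumes(
                    brain.astype(bool), vox, scan.midline_col, scan.ipsi_side, labels
                )
                rec = rec.with_lost(hemi)
            label_path = out / f"labels_{scan.subject}_{scan.timepoint_h:g}h.nii"
            hio.save_labels(labels, label_path)
            records.append(rec)
        except Exception as exc:  # noqa: BLE001 - per-scan isolation is the contract
            logger.error(
                "scan failed (subject=%s, timepoint=%sh): %s", scan.subject, scan.timepoint_h, exc
            )
            failures.append(f"{scan.subject}@{scan.timepoint_h}h: {exc}")
    if not records:
        raise RuntimeError("every scan failed; nothing to tabulate: " + "; ".join(failures))
    long = longitudinal_table(records)
    long.to_csv(out / "volumes.csv", index=False)
    group_summary(long).to_csv(out / "summary.csv", index=False)
    _write_provenance(out, config, {"failures": failures})
    return long


# --------------------------------------------------------------------------
# demo workspace


def _demo_phantom_spec(seed: int, core_scale: float = 1.0) -> PhantomSpec:
    spec = PhantomSpec(grid_shape=(48, 48, 10), seed=seed, lost_fraction=0.05)
    if core_scale != 1.0:
        # shrink the core ellipsoid isotropically (treatment effect on volume)
        per_axis = core_scale ** (1.0 / 3.0)
        spec.core = dataclasses.replace(
            spec.core, semiaxes=tuple(per_axis * a for a in spec.core.semiaxes)
        )
    return spec


def run_demo(seed: int = 0, out_dir: str | Path = "demo_out") -> dict:
    """Generate a full synthetic study and run every stage on it.

    Simulates a two-group cohort (sham-treated vs low-frequency TMS) with
    two imaging timepoints, runs fit → segment → volumes, simulates the
    slice-electrophysiology arm (border-site potentiation present in the
    untreated group, restored to contralateral level by the treatment
    flag), computes paired-pulse facilitation, and builds a ΔΔCt table.
    One seed drives every stage; outputs are bit-identical across runs.
    Returns the headline summary (also written to ``summary.json``).
    """
    out = Path(out_dir)
    (out / "mri").mkdir(parents=True, exist_ok=True)
    (out / "ephys").mkdir(parents=True, exist_ok=True)

    def child_seed(i: int) -> int:
        return (seed * 10007 + i) % (2**31)

    # ---- MRI arm: 2 groups x 2 subjects x 2 timepoints -------------------
    scans: list[ScanInput] = []
    truths = {}
    i = 0
    for group, core_scales in (("sham_tms", {24.0: 1.0, 48.0: 1.0}),
                               ("lf_tms", {24.0: 1.0, 48.0: 0.7})):
        for subj_idx in (1, 2):
            subject = f"{group}_m{subj_idx}"
            for tp, core_scale in core_scales.items():
                spec = _demo_phantom_spec(child_seed(i), core_scale)
                i += 1
                vol, truth, lesion = make_phantom(spec)
                rel = f"mri/{subject}_{tp:g}h"  # config stores workspace-relative paths
                base = out / rel
                hio.save_multi_echo(vol, f"{base}_echo.nii", f"{base}_te.txt")
                hio.save_nifti(lesion.mask.astype(np.uint8), spec.voxel_size, f"{base}_mask.nii")
                hio.save_nifti(
                    truth.brain_mask.astype(np.uint8), spec.voxel_size, f"{base}_brain.nii"
                )
                truths[(subject, tp)] = truth
                scans.append(
                    ScanInput(
                        subject=subject,
                        group=group,
                        timepoint_h=tp,
                        volume=f"{rel}_echo.nii",
                        echoes=f"{rel}_te.txt",
                        lesion_mask=f"{rel}_mask.nii",
                        brain_mask=f"{rel}_brain.nii",
                        midline_col=spec.midline_col,
                        ipsi_side=spec.ipsi_side,
                    )
                )
    config = RunConfig(scans=scans, seed=seed, base_dir=out)
    config_path = out / "run_config.yaml"
    config_path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    long = run_mri_pipeline(config, out / "mri_results")

    core = long[long["tissue_class"] == "core"]
    core_by_group = (
        core.groupby(["group", "timepoint_h"])["volume_mm3"].mean().unstack("timepoint_h")
    )

    # ---- ephys arm: border vs contralateral I-O curves per group ---------
    n_slices = 4
    contrast = {}
    ppf = {}
    rows = []
    for g_idx, (group, border_potentiation) in enumerate(
        (("sham_tms", 1.5), ("lf_tms", 1.0))
    ):
        sides = {}
        for s_idx, (site, factor) in enumerate(
            (("border", border_potentiation), ("contralateral", 1.0))
        ):
            curves = []
            for k in range(n_slices):
                spec = EphysSpec(
                    potentiation_factor=factor,
                    seed=child_seed(100 + 10 * g_idx + 5 * s_idx + k),
                )
                curve = build_io_curve(make_io_series(spec))
                curves.append(curve)
                rows.append(
                    {
                        "group": group,
                        "site": site,
                        "slice": k + 1,
                        "auc_fp1_mv_ua": curve.auc_fp1,
                        "auc_fp2_mv_ua": curve.auc_fp2,
                    }
                )
            sides[site] = curves
        result = hltp_contrast(sides["border"], sides["contralateral"])
        contrast[group] = result.auc_ratio
        pp_spec = EphysSpec(
            potentiation_factor=border_potentiation, seed=child_seed(200 + g_idx)
        )
        ppf[group] = paired_pulse_facilitation(make_paired_pulse(pp_spec)).ppf_percent
    pd.DataFrame(rows).to_csv(out / "ephys" / "curves.csv", index=False)

    # ---- expression arm --------------------------------------------------
    records = make_ct_table(
        n_per_group=8,
        group_effects={"sham": 0.0, "hi": 1.0, "hi_tms": 1.0},
        seed=child_seed(300),
    )
    folds = delta_delta_ct(records, "Gria2", "Gapdh", reference_group="sham")
    fold_table(folds).to_csv(out / "folds.csv", index=False)
    geo = group_geometric_means(folds)

    summary = {
        "tms_protocol_pulses": StimProtocol(1.0, 20 * 60.0).pulse_count,
        "mean_core_volume_mm3": {
            g: {f"{tp:g}h": float(v) for tp, v in row.items()}
            for g, row in core_by_group.iterrows()
        },
        "core_reduction_lf_tms_48h_pct": float(
            100.0 * (1.0 - core_by_group.loc["lf_tms", 48.0] / core_by_group.loc["sham_tms", 48.0])
        ),
        "border_auc_ratio": {g: float(r) for g, r in contrast.items()},
        "ppf_percent": {g: float(p) for g, p in ppf.items()},
        "gria2_fold_geomean": {g: float(v) for g, v in geo.items()},
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
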