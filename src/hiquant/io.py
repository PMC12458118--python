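"""File formats: NIfTI volumes, echo-time sidecars, sweep CSVs, tables.

Volumes travel as NIfTI with the voxel size on the affine diagonal; the
echo times of a 4-D multi-echo stack live in a plain-text sidecar (one ms
value per line).  Sweeps are CSV with ``# key: value`` metadata header
lines followed by ``time_ms,voltage_mv`` rows.  Label volumes get a small
JSON legend sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .ephys import FieldTrace
from .relaxometry import MultiEchoVolume, T2Map
from .segmentation import LABEL_NAMES, LesionMask, TissueLabels

__all__ = [
    "save_nifti",
    "load_nifti",
    "write_echo_times",
    "read_echo_times",
    "load_multi_echo",
    "save_multi_echo",
    "save_t2_map",
    "load_t2_map",
    "save_labels",
    "load_labels",
    "load_mask",
    "write_trace",
    "read_trace",
]


def save_nifti(data: np.ndarray, voxel_size, path: str | Path) -> None:
    affine = np.diag(list(voxel_size)[:3] + [1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    nib.save(img, str(path))


def load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    vox = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), vox


def write_echo_times(echo_times, path: str | Path) -> None:
    Path(path).write_text("".join(f"{float(te):g}\n" for te in echo_times))


def read_echo_times(path: str | Path) -> np.ndarray:
    values = [float(line) for line in Path(path).read_text().split() if line.strip()]
    return np.asarray(values)


def save_multi_echo(vol: MultiEchoVolume, nifti_path: str | Path, te_path: str | Path) -> None:
    save_nifti(vol.signal, vol.voxel_size, nifti_path)
    write_echo_times(vol.echo_times, te_path)


def load_multi_echo(nifti_path: str | Path, te_path: str | Path) -> MultiEchoVolume:
    data, vox = load_nifti(nifti_path)
    return MultiEchoVolume(signal=data, echo_times=read_echo_times(te_path), voxel_size=vox)


def save_t2_map(t2_map: T2Map, out_dir: str | Path) -> dict[str, Path]:
    """Write t2/s0/r2/valid as separate 3-D NIfTI maps; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, data in (
        ("t2", t2_map.t2),
        ("s0", t2_map.s0),
        ("r2", t2_map.r2),
        ("valid", t2_map.valid.astype(np.uint8)),
    ):
        p = out / f"{name}.nii"
        save_nifti(data, t2_map.voxel_size, p)
        paths[name] = p
    return paths


def load_t2_map(map_dir: str | Path) -> T2Map:
    d = Path(map_dir)
    t2, vox = load_nifti(d / "t2.nii")
    s0, _ = load_nifti(d / "s0.nii")
    r2, _ = load_nifti(d / "r2.nii")
    valid, _ = load_nifti(d / "valid.nii")
    return T2Map(t2=t2, s0=s0, r2=r2, valid=valid.astype(bool), voxel_size=vox)


def save_labels(labels: TissueLabels, path: str | Path) -> None:
    """Write the uint8 label volume plus a JSON legend sidecar."""
    save_nifti(labels.labels, labels.voxel_size, path)
    legend = {str(code): name for code, name in LABEL_NAMES.items()}
    Path(str(path) + ".json").write_text(json.dumps({"legend": legend}, indent=2) + "\n")


def load_labels(path: str | Path) -> TissueLabels:
    data, vox = load_nifti(path)
    return TissueLabels(labels=data.astype(np.uint8), voxel_size=vox)


def load_mask(path: str | Path) -> LesionMask:
    data, vox = load_nifti(path)
    return LesionMask(mask=data.astype(bool), voxel_size=vox)


def write_trace(trace: FieldTrace, path: str | Path) -> None:
    lines = [
        f"# sampling_rate: {trace.sampling_rate:g}",
        f"# stim_times_ms: {','.join(f'{t:g}' for t in trace.stim_times_ms)}",
        f"# stim_current_ua: {trace.stim_current_ua:g}",
        "time_ms,voltage_mv",
    ]
    lines += [f"{t:.6f},{v:.8f}" for t, v in zip(trace.time_ms, trace.voltage_mv)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_trace(path: str | Path) -> FieldTrace:
    meta: dict[str, str] = {}
    times: list[float] = []
    volts: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
            elif line[0].isdigit() or line[0] in "-+.":
                t, _, v = line.partition(",")
                times.append(float(t))
                volts.append(float(v))
    return FieldTrace(
        time_ms=np.asarray(times),
        voltage_mv=np.asarray(volts),
        sampling_rate=float(meta["sampling_rate"]),
        stim_times_ms=tuple(float(x) for x in meta["stim_times_ms"].split(",")),
        stim_current_ua=float(meta["stim_current_ua"]),
    )
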