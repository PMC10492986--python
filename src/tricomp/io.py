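"""File I/O: NIfTI stacks and label maps, waveform and cohort CSVs."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from tricomp.segmentation import FatFractionStack, SegmentationResult

__all__ = [
    "write_stack_nifti",
    "read_stack_nifti",
    "write_label_map",
    "write_waveform_csv",
    "read_waveform_csv",
    "write_truth_sidecar",
]

LABEL_BACKGROUND, LABEL_NAT, LABEL_SAT, LABEL_VAT = 0, 1, 2, 3


def _affine(voxel_dims: tuple[float, float, float]) -> np.ndarray:
    return np.diag([*voxel_dims, 1.0])


def write_stack_nifti(stack: FatFractionStack, out_dir: Path, prefix: str = "phantom") -> dict[str, Path]:
    """Write one NIfTI file per channel; arrays stored as (x, y, z)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    affine = _affine(stack.voxel_dims)
    for channel, data in (
        ("fat_fraction", stack.fat_fraction),
        ("combined_signal", stack.combined_signal),
    ):
        # (slice, row, col) -> (col, row, slice) = (x, y, z)
        vol = np.transpose(data, (2, 1, 0)).astype(np.float32)
        path = out_dir / f"{prefix}_{channel}.nii"
        nib.save(nib.Nifti1Image(vol, affine), path)
        paths[channel] = path
    return paths


def read_stack_nifti(
    fat_fraction_path: Path, combined_signal_path: Path,
    slab_convention: str = "neck-to-knees, arms excluded",
) -> FatFractionStack:
    ff_img = nib.load(str(fat_fraction_path))
    cs_img = nib.load(str(combined_signal_path))
    ff = np.transpose(np.asarray(ff_img.dataobj, dtype=float), (2, 1, 0))
    cs = np.transpose(np.asarray(cs_img.dataobj, dtype=float), (2, 1, 0))
    zooms = ff_img.header.get_zooms()[:3]
    return FatFractionStack(
        fat_fraction=ff,
        combined_signal=cs,
        voxel_dims=(float(zooms[0]), float(zooms[1]), float(zooms[2])),
        slab_convention=slab_convention,
    )


def write_label_map(result: SegmentationResult, voxel_dims, path: Path) -> Path:
    """Label map: 0 background, 1 NAT, 2 SAT, 3 VAT."""
    slices = []
    for sm in result.slices:
        lab = np.zeros(sm.tissue_mask.shape, dtype=np.uint8)
        lab[sm.tissue_mask] = LABEL_NAT
        lab[sm.sat_mask] = LABEL_SAT
        lab[sm.vat_mask] = LABEL_VAT
        slices.append(lab)
    vol = np.transpose(np.stack(slices), (2, 1, 0))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(vol, _affine(tuple(voxel_dims))), path)
    return path


def write_waveform_csv(frame: pd.DataFrame, path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    return path


def read_waveform_csv(path: Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = {"t_ms", "Q_ml_s", "A_mm2"} - set(frame.columns)
    if missing:
        raise ValueError(f"waveform CSV missing columns: {sorted(missing)}")
    return frame


def write_truth_sidecar(truth: dict, path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return path
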