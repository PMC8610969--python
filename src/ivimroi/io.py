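"""NIfTI, sidecar and table input/output.

Conventions
-----------
* In memory, volumes are indexed ``(slice, row, column[, b])``; on disk
  NIfTI-1 stores ``(column, row, slice[, b])`` with a diagonal affine
  built from the voxel size, so files round-trip through other viewers.
* b-values travel in a plain-text sidecar (whitespace-separated s/mm²,
  order matching the 4th dimension), lesion ROIs as integer label
  volumes (0 background) plus a JSON sidecar carrying slice quality
  labels, the reference slice and the CDA mask filename.
* Parameter maps are written in report units (coefficients ×10⁻⁶ mm²/s,
  fractions ×10⁻³) with one uint8 defined-mask volume per parameter.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .bvalues import BValueScheme
from .maps import PARAMETERS, ParameterMaps
from .roi import LesionROISet, SliceROI
from .study import DWIStudy


def _affine(voxel_size) -> np.ndarray:
    # (slice, row, col) mm -> NIfTI (x=col, y=row, z=slice)
    return np.diag([voxel_size[2], voxel_size[1], voxel_size[0], 1.0])


def _to_nifti_order(arr: np.ndarray) -> np.ndarray:
    axes = (2, 1, 0) if arr.ndim == 3 else (2, 1, 0, 3)
    return np.ascontiguousarray(np.transpose(arr, axes))


def _from_nifti_order(arr: np.ndarray) -> np.ndarray:
    return _to_nifti_order(arr)  # the transpose is its own inverse


def save_volume(arr: np.ndarray, path, voxel_size=(7.7, 3.4, 3.4)) -> None:
    img = nib.Nifti1Image(_to_nifti_order(np.asarray(arr)), _affine(voxel_size))
    nib.save(img, str(path))


def load_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    voxel_size = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return _from_nifti_order(np.asarray(img.get_fdata())), voxel_size


def save_study(study: DWIStudy, prefix) -> tuple[Path, Path]:
    """Write ``<prefix>.nii.gz`` (4D) and ``<prefix>.bval``."""
    prefix = Path(prefix)
    nii = prefix.with_suffix(".nii.gz")
    bval = prefix.with_suffix(".bval")
    save_volume(study.signal, nii, study.voxel_size)
    bval.write_text(study.scheme.to_sidecar())
    return nii, bval


def load_study(prefix) -> DWIStudy:
    prefix = Path(prefix)
    nii = prefix.with_suffix(".nii.gz")
    if not nii.exists():
        nii = prefix.with_suffix(".nii")
    bval = prefix.with_suffix(".bval")
    if not nii.exists() or not bval.exists():
        raise FileNotFoundError(f"missing study files for prefix {prefix}")
    signal, voxel_size = load_volume(nii)
    scheme = BValueScheme.from_sidecar(bval.read_text())
    return DWIStudy(signal=signal, scheme=scheme, voxel_size=voxel_size)


def save_maps(maps: ParameterMaps, out_dir, stem: str) -> dict[str, Path]:
    """One report-unit NIfTI per parameter plus its defined mask."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for p in PARAMETERS:
        vals = maps.report_values(p)
        vpath = out_dir / f"{stem}_{p}.nii.gz"
        mpath = out_dir / f"{stem}_{p}_defined.nii.gz"
        save_volume(np.nan_to_num(vals, nan=0.0), vpath, maps.voxel_size)
        save_volume(maps.defined_mask(p).astype(np.uint8), mpath, maps.voxel_size)
        written[p] = vpath
        written[f"{p}_defined"] = mpath
    return written


def save_roiset(roiset: LesionROISet, prefix, grid_shape, voxel_size=(7.7, 3.4, 3.4)) -> None:
    """Write the ROI label volume, JSON sidecar and optional CDA mask."""
    prefix = Path(prefix)
    label = np.zeros(grid_shape, dtype=np.int16)
    for s in roiset.slices:
        label[s.slice_index, s.coords[:, 0], s.coords[:, 1]] = 1
    save_volume(label, prefix.with_suffix(".nii.gz"), voxel_size)
    cda_file = None
    if roiset.cda_coords is not None:
        cda = np.zeros(grid_shape, dtype=np.int16)
        cda[tuple(roiset.cda_coords.T)] = 1
        cda_file = prefix.name + "_cda.nii.gz"
        save_volume(cda, prefix.parent / cda_file, voxel_size)
    sidecar = {
        "lesion_id": roiset.lesion_id,
        "class": roiset.class_label,
        "reference_slice": int(roiset.reference_slice.slice_index),
        "slice_quality": {str(s.slice_index): s.quality for s in roiset.slices},
        "cda_mask": cda_file,
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def load_roiset(prefix) -> LesionROISet:
    prefix = Path(prefix)
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    label, _ = load_volume(prefix.with_suffix(".nii.gz"))
    label = np.rint(label).astype(int)
    slices = []
    for sl in np.flatnonzero(label.any(axis=(1, 2))):
        rows, cols = np.nonzero(label[sl])
        quality = sidecar["slice_quality"].get(str(int(sl)), "good")
        slices.append(
            SliceROI(
                slice_index=int(sl),
                coords=np.column_stack([rows, cols]),
                quality=quality,
                reference=int(sl) == int(sidecar["reference_slice"]),
            )
        )
    cda_coords = None
    if sidecar.get("cda_mask"):
        cda, _ = load_volume(prefix.parent / sidecar["cda_mask"])
        cda_coords = np.argwhere(np.rint(cda).astype(int) > 0)
    return LesionROISet(
        lesion_id=sidecar["lesion_id"],
        class_label=sidecar["class"],
        slices=slices,
        cda_coords=cda_coords,
    )
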