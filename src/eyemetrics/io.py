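"""Reading and writing volumes, truth files and tables.

Volumes travel as multi-page TIFF stacks (one page per z slice) or HDF5
datasets; the voxel size and grid origin ride along as JSON in the TIFF
ImageDescription tag or as HDF5 attributes, so a written volume round-trips
with its physical calibration.  Tables are plain CSV with unit-suffixed
column names (``D_um``, ``delta_phi_deg``, ...).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .segmentation import LabeledConeVolume
from .synthetic import SyntheticEyeSpec, SyntheticEyeTruth

__all__ = [
    "read_volume",
    "write_volume",
    "read_labeled_volume",
    "write_labeled_volume",
    "save_truth_h5",
    "load_truth_h5",
]

_TIFF_EXTS = {".tif", ".tiff"}


def write_volume(
    path,
    array: np.ndarray,
    voxel_size_um: float | None = None,
    origin_um=(0.0, 0.0, 0.0),
) -> Path:
    """Write a 3D array as a multi-page TIFF (or HDF5 if *.h5) with metadata."""
    path = Path(path)
    arr = np.asarray(array)
    if arr.ndim != 3:
        raise ValueError("volume must be 3D")
    meta = {"voxel_size_um": voxel_size_um, "origin_um": list(map(float, origin_um))}
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as f:
            d = f.create_dataset("volume", data=arr, compression="gzip")
            if voxel_size_um is not None:
                d.attrs["voxel_size_um"] = voxel_size_um
            d.attrs["origin_um"] = list(map(float, origin_um))
    else:
        tifffile.imwrite(
            path, arr, photometric="minisblack", description=json.dumps(meta)
        )
    return path


def _read_tiff(path: Path):
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].description or ""
    voxel, origin = None, (0.0, 0.0, 0.0)
    try:
        meta = json.loads(desc)
        voxel = meta.get("voxel_size_um")
        origin = tuple(meta.get("origin_um", origin))
    except (json.JSONDecodeError, AttributeError, TypeError):
        pass
    return arr, voxel, origin


def _read_h5(path: Path, dataset: str | None):
    with h5py.File(path, "r") as f:
        if dataset is None:
            names = []
            f.visititems(
                lambda n, o: names.append(n) if isinstance(o, h5py.Dataset) else None
            )
            candidates = [n for n in names if f[n].ndim == 3]
            if len(candidates) != 1:
                raise ValueError(
                    f"{path}: specify a dataset; found 3D datasets {candidates}"
                )
            dataset = candidates[0]
        d = f[dataset]
        arr = d[()]
        voxel = d.attrs.get("voxel_size_um", f.attrs.get("voxel_size_um", None))
        origin = tuple(d.attrs.get("origin_um", (0.0, 0.0, 0.0)))
    return arr, (float(voxel) if voxel is not None else None), origin


def read_volume(path, dataset: str | None = None):
    """Read a 3D volume from TIFF, a directory of TIFF slices, or HDF5.

    Returns ``(array, voxel_size_um_or_None, origin_um)``.  A directory is
    stacked in lexicographic filename order (z order); inconsistent slice
    shapes raise.
    """
    path = Path(path)
    if path.is_dir():
        slices = sorted(p for p in path.iterdir() if p.suffix.lower() in _TIFF_EXTS)
        if not slices:
            raise ValueError(f"{path}: no TIFF slices found")
        arrays = [tifffile.imread(p) for p in slices]
        shapes = {a.shape for a in arrays}
        if len(shapes) != 1:
            raise ValueError(f"{path}: inconsistent slice shapes {sorted(shapes)}")
        return np.stack(arrays, axis=0), None, (0.0, 0.0, 0.0)
    if path.suffix in {".h5", ".hdf5"}:
        return _read_h5(path, dataset)
    arr, voxel, origin = _read_tiff(path)
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 3D stack, got shape {arr.shape}")
    return arr, voxel, origin


def write_labeled_volume(path, volume: LabeledConeVolume) -> Path:
    return write_volume(path, volume.labels, volume.voxel_size_um, volume.origin_um)


def read_labeled_volume(path, voxel_size_um: float | None = None) -> LabeledConeVolume:
    """Read a labeled volume; voxel size from metadata, else the argument."""
    arr, voxel, origin = read_volume(path)
    voxel = voxel if voxel is not None else voxel_size_um
    if voxel is None:
        raise ValueError(f"{path}: no voxel size in metadata and none supplied")
    return LabeledConeVolume(arr.astype(np.int32), voxel, origin)


def save_truth_h5(path, truth: SyntheticEyeTruth) -> Path:
    """Persist phantom ground truth: arrays as datasets, the spec as attributes."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("true_centers_um", data=truth.true_centers_um)
        f.create_dataset("true_axes", data=truth.true_axes)
        f.create_dataset("true_sphere_center_um", data=truth.true_sphere_center_um)
        f.create_dataset(
            "per_cone_true_spacing_um", data=truth.per_cone_true_spacing_um
        )
        f.attrs["true_interommatidial_angle_deg"] = truth.true_interommatidial_angle_deg
        for key, val in asdict(truth.spec).items():
            f.attrs[f"spec_{key}"] = val
    return path


def load_truth_h5(path) -> SyntheticEyeTruth:
    with h5py.File(path, "r") as f:
        spec = SyntheticEyeSpec(
            **{
                k[len("spec_") :]: (
                    int(f.attrs[k]) if k in ("spec_seed",) else float(f.attrs[k])
                )
                for k in f.attrs
                if k.startswith("spec_")
            }
        )
        return SyntheticEyeTruth(
            spec=spec,
            true_centers_um=f["true_centers_um"][()],
            true_axes=f["true_axes"][()],
            true_sphere_center_um=f["true_sphere_center_um"][()],
            per_cone_true_spacing_um=f["per_cone_true_spacing_um"][()],
            true_interommatidial_angle_deg=float(
                f.attrs["true_interommatidial_angle_deg"]
            ),
        )
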