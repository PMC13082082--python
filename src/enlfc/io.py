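"""File formats: NIfTI scans and masks, the HDF5 FC store, map export.

Voxel column order is the package-wide contract: ascending linear index
over the mask with x fastest (Fortran ravel order), 0-based. Every array
written next to a mask records this order via the ``voxel_index``
coordinate table.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import FormatError
from .fc import FCMatrix, TimeSeriesMatrix, zscore_timeseries

__all__ = [
    "read_mask",
    "read_scan",
    "write_fc_store",
    "read_fc_store",
    "write_component_maps",
]


def read_mask(mask_path: str | Path) -> tuple[np.ndarray, np.ndarray, nib.Nifti1Image]:
    """Load a binary 3-D mask; returns (bool grid, v x 3 coordinates in
    ascending x-fastest linear order, the nibabel image for grid checks)."""
    img = nib.load(str(mask_path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"mask must be 3-D, got shape {data.shape}")
    vals = np.unique(data)
    if not np.all(np.isin(vals, (0, 1))):
        raise FormatError("mask must be binary (0/1)")
    mask = data.astype(bool)
    if not mask.any():
        raise FormatError("mask selects no voxels")
    lin = np.flatnonzero(mask.ravel(order="F"))
    coords = np.column_stack(np.unravel_index(lin, mask.shape, order="F"))
    return mask, coords, img


def read_scan(nii_path: str | Path, mask_path: str | Path) -> TimeSeriesMatrix:
    """Load a 4-D scan restricted to the mask and Z-score per voxel.

    The scan and mask must share grid shape and affine. Column order
    follows the mask's ascending linear index (x-fastest, 0-based).
    """
    mask, coords, mimg = read_mask(mask_path)
    img = nib.load(str(nii_path))
    data = np.asarray(img.dataobj)
    if data.ndim != 4:
        raise FormatError(f"scan must be 4-D, got shape {data.shape}")
    if data.shape[:3] != mask.shape:
        raise FormatError(f"scan grid {data.shape[:3]} does not match mask grid {mask.shape}")
    if not np.allclose(img.affine, mimg.affine, atol=1e-6):
        raise FormatError("scan and mask affines differ")
    flat = data.reshape(-1, data.shape[3], order="F")
    raw = flat[np.flatnonzero(mask.ravel(order="F"))].T  # timepoints x voxels
    return zscore_timeseries(raw, voxel_index=coords)


def write_fc_store(
    store_path: str | Path,
    matrices: dict[str, FCMatrix],
    scan_id: str,
    mode: str = "a",
) -> None:
    """Append one scan's FC matrices to a chunked HDF5 store, one group per
    kind, with voxel_index and n_timepoints attached as attributes."""
    import h5py

    with h5py.File(str(store_path), mode) as f:
        for kind, m in matrices.items():
            grp = f.require_group(kind)
            if scan_id in grp:
                del grp[scan_id]
            v = m.values.shape[0]
            chunk = min(64, v)
            ds = grp.create_dataset(scan_id, data=m.values, chunks=(chunk, chunk))
            ds.attrs["n_timepoints"] = m.n_timepoints
            ds.attrs["kind"] = m.kind
            if m.voxel_index is not None:
                ds.attrs["voxel_index"] = m.voxel_index


def read_fc_store(store_path: str | Path, kind: str) -> dict[str, FCMatrix]:
    """Read all scans' matrices of one kind from an FC store."""
    import h5py

    out: dict[str, FCMatrix] = {}
    with h5py.File(str(store_path), "r") as f:
        if kind not in f:
            raise FormatError(f"store has no group {kind!r}")
        for scan_id, ds in f[kind].items():
            out[scan_id] = FCMatrix(
                values=ds[()],
                kind=ds.attrs.get("kind", kind),
                n_timepoints=int(ds.attrs.get("n_timepoints", 0)),
                voxel_index=np.asarray(ds.attrs["voxel_index"]) if "voxel_index" in ds.attrs else None,
            )
    return out


def write_component_maps(
    out_path: str | Path,
    maps: np.ndarray,
    mask: np.ndarray,
    affine: np.ndarray | None = None,
    sidecar: "object | None" = None,
) -> None:
    """Write component x voxel maps as 4-D NIfTI (component axis last) plus
    an optional sidecar table (CSV next to the image)."""
    maps = np.atleast_2d(maps)
    vol = np.zeros((*mask.shape, maps.shape[0]), dtype=np.float32)
    lin = np.flatnonzero(mask.ravel(order="F"))
    for c in range(maps.shape[0]):
        flat = np.zeros(mask.size, dtype=np.float32)
        flat[lin] = maps[c]
        vol[..., c] = flat.reshape(mask.shape, order="F")
    nib.save(nib.Nifti1Image(vol, affine if affine is not None else np.eye(4)), str(out_path))
    if sidecar is not None:
        sidecar.to_csv(str(Path(out_path).with_suffix("").with_suffix("")) + "_info.csv", index=False)
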