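"""NIfTI and delimited-table I/O for the deconvolution pipeline."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = ["read_bold", "write_bold", "write_mask", "write_hrf_table",
           "read_hrf_table"]


def read_bold(path, mask_path):
    """Load a 4D BOLD image and a 3D mask into a time x voxels matrix.

    Returns ``(data, coords)`` where ``data`` is N x V (time-major) and
    ``coords`` is the V x 3 integer voxel coordinates inside the mask,
    retained so results can be written back onto the grid.
    """
    img = nib.load(str(path))
    mask_img = nib.load(str(mask_path))
    if img.ndim != 4:
        raise ValueError(f"expected a 4D BOLD image, got shape {img.shape}")
    if img.shape[:3] != mask_img.shape:
        raise ValueError(
            f"grid mismatch: BOLD spatial shape {img.shape[:3]} vs mask shape "
            f"{mask_img.shape}"
        )
    mask = np.asanyarray(mask_img.dataobj) > 0
    data = np.asanyarray(img.dataobj)[mask].T.astype(float)  # N x V
    bad = ~np.all(np.isfinite(data), axis=0)
    if bad.any():
        raise ValueError(f"{int(bad.sum())} of {data.shape[1]} masked voxels "
                         "contain non-finite values")
    coords = np.column_stack(np.nonzero(mask))
    return data, coords


def _grid_shape(n_voxels: int):
    side = int(np.ceil(n_voxels ** (1.0 / 3.0)))
    return (side, side, max(1, int(np.ceil(n_voxels / side ** 2))))


def write_bold(path, data: np.ndarray, tr: float, coords=None, shape=None):
    """Write an N x V matrix as a 4D NIfTI (synthetic grid if no coords).

    Returns ``(coords, shape)`` so a matching mask can be written on the
    identical grid.
    """
    N, V = data.shape
    if coords is None:
        shape = shape or _grid_shape(V)
        vol = np.zeros(shape + (N,))
        flat = vol.reshape(-1, N)
        flat[:V] = data.T
        vol = flat.reshape(shape + (N,))
        coords = np.column_stack(
            np.unravel_index(np.arange(V), shape)
        )
    else:
        shape = shape or tuple(coords.max(axis=0) + 1)
        vol = np.zeros(shape + (N,))
        vol[coords[:, 0], coords[:, 1], coords[:, 2]] = data.T
    aff = np.eye(4)
    img = nib.Nifti1Image(vol, aff)
    img.header.set_zooms((1.0, 1.0, 1.0, tr))
    nib.save(img, str(path))
    return coords, shape


def write_mask(path, coords, shape=None):
    shape = shape or tuple(coords.max(axis=0) + 1)
    vol = np.zeros(shape, dtype=np.uint8)
    vol[coords[:, 0], coords[:, 1], coords[:, 2]] = 1
    nib.save(nib.Nifti1Image(vol, np.eye(4)), str(path))


def write_hrf_table(path, hrfs: np.ndarray, method: str, deltas, gammas,
                    voxel_ids=None):
    """Per-voxel HRF table: voxel id, method, delta, gamma, h(0..L-1)."""
    L, V = hrfs.shape
    if voxel_ids is None:
        voxel_ids = np.arange(V)
    df = pd.DataFrame({"voxel_id": voxel_ids, "method": method,
                       "delta": np.broadcast_to(deltas, V),
                       "gamma": np.broadcast_to(gammas, V)})
    for i in range(L):
        df[f"h{i}"] = hrfs[i]
    df.to_csv(path, sep="\t", index=False)
    return df


def read_hrf_table(path):
    df = pd.read_csv(path, sep="\t")
    hcols = [c for c in df.columns if c.startswith("h") and c[1:].isdigit()]
    hcols.sort(key=lambda c: int(c[1:]))
    return df[hcols].to_numpy().T, df
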