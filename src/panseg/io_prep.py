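"""Volume I/O and preprocessing for pancreas subregion segmentation.

The pipeline operates on a pre-delineated pancreas: a CT intensity volume
plus a binary pancreas mask (and, for training, an integer label volume
with 0 = background, 1 = head, 2 = body, 3 = tail).  Preprocessing crops
the volume to a padded bounding box of the mask, zeroes every non-pancreas
voxel and linearly rescales the pancreas intensities to [0, 1].
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy import ndimage

HEAD, BODY, TAIL = 1, 2, 3
SUBREGIONS = (HEAD, BODY, TAIL)
SUBREGION_NAMES = {HEAD: "head", BODY: "body", TAIL: "tail"}

#: 26-connectivity structuring element.
CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class PancreasVolume:
    """A CT volume restricted to a delineated pancreas.

    Attributes
    ----------
    intensities : ndarray
        3D scalar grid.  After :func:`normalize_intensities` the pancreas
        voxels lie in [0, 1] and background voxels are exactly 0.
    mask : ndarray of bool
        Binary pancreas mask, same shape as ``intensities``.
    spacing : tuple of float
        Physical voxel size per axis, in mm.
    affine : ndarray
        4x4 voxel-to-world matrix (axis order and patient-side convention).
    """

    intensities: np.ndarray
    mask: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.intensities.shape != self.mask.shape:
            raise ValueError(
                f"intensity shape {self.intensities.shape} != mask shape {self.mask.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self):
        return self.mask.shape

    @property
    def n_pancreas_voxels(self) -> int:
        return int(self.mask.sum())


def check_mask_connectivity(mask: np.ndarray, keep_largest: bool = False) -> np.ndarray:
    """Require a single 26-connected pancreas component.

    The anatomical model assumes one whole pancreas; a fragmented mask is a
    hard error unless ``keep_largest`` is set, in which case all but the
    largest component are dropped.
    """
    lab, n = ndimage.label(mask, structure=CONN26)
    if n == 0:
        raise ValueError("empty pancreas mask")
    if n == 1:
        return mask.astype(bool)
    if not keep_largest:
        raise ValueError(
            f"pancreas mask has {n} connected components (expected 1); "
            "pass keep_largest=True to keep the largest"
        )
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return lab == (int(np.argmax(sizes)) + 1)


def _load_nifti(path):
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(data), spacing, np.asarray(img.affine)


def _validate_labels(labels: np.ndarray) -> np.ndarray:
    arr = np.asarray(labels)
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.round(arr)):
            raise ValueError("non-integer label values in label volume")
        arr = arr.astype(np.int64)
    bad = np.setdiff1d(np.unique(arr), [0, HEAD, BODY, TAIL])
    if bad.size:
        raise ValueError(f"unknown label value(s) {bad.tolist()} (expected 0..3)")
    return arr.astype(np.uint8)


def read_volume(path, mask_path=None, label_path=None, keep_largest=False,
                check_connectivity=True):
    """Read a CT volume with its pancreas mask and optional subregion labels.

    Parameters
    ----------
    path : str
        NIfTI image volume.
    mask_path : str, optional
        NIfTI binary pancreas mask.  If omitted, ``label_path`` must be given
        and the mask is derived as ``labels > 0``.
    label_path : str, optional
        NIfTI integer subregion label volume (0/1/2/3).

    Returns
    -------
    (PancreasVolume, labels or None)
    """
    intensities, spacing, affine = _load_nifti(path)
    labels = None
    if label_path is not None:
        lab_data, _, _ = _load_nifti(label_path)
        if lab_data.shape != intensities.shape:
            raise ValueError(
                f"image shape {intensities.shape} != label shape {lab_data.shape}"
            )
        labels = _validate_labels(lab_data)
    if mask_path is not None:
        mask_data, _, _ = _load_nifti(mask_path)
        if mask_data.shape != intensities.shape:
            raise ValueError(
                f"image shape {intensities.shape} != mask shape {mask_data.shape}"
            )
        mask = mask_data > 0
    elif labels is not None:
        mask = labels > 0
    else:
        raise ValueError("either mask_path or label_path is required")
    if labels is not None and np.any((labels > 0) != mask):
        raise ValueError("labels must be nonzero exactly on the pancreas mask")
    if check_connectivity:
        mask = check_mask_connectivity(mask, keep_largest=keep_largest)
        if labels is not None:
            labels = np.where(mask, labels, 0).astype(np.uint8)
    vol = PancreasVolume(intensities, mask, spacing, affine)
    return vol, labels


def write_volume(vol: PancreasVolume, image_path, mask_path=None):
    """Write intensities (and optionally the mask) as NIfTI."""
    nib.save(nib.Nifti1Image(vol.intensities.astype(np.float32), vol.affine), image_path)
    if mask_path is not None:
        nib.save(nib.Nifti1Image(vol.mask.astype(np.uint8), vol.affine), mask_path)


def write_labels(labels: np.ndarray, affine, path):
    nib.save(nib.Nifti1Image(np.asarray(labels).astype(np.uint8), np.asarray(affine)), path)


def crop_to_pancreas(vol: PancreasVolume, labels=None, padding: int = 8):
    """Crop to the padded bounding box of the pancreas mask.

    The crop never removes a pancreas voxel; padding is clipped at the
    volume bounds.  Returns ``(cropped_vol, cropped_labels, offset)`` where
    ``offset`` is the low corner of the crop in the original volume, which
    together with the original shape allows exact uncropping.
    """
    if not vol.mask.any():
        raise ValueError("empty pancreas mask")
    idx = np.argwhere(vol.mask)
    lo = np.maximum(idx.min(axis=0) - padding, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + padding, vol.mask.shape)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    cropped = PancreasVolume(vol.intensities[sl], vol.mask[sl], vol.spacing, vol.affine)
    cropped_labels = None if labels is None else np.asarray(labels)[sl]
    return cropped, cropped_labels, tuple(int(a) for a in lo)


def uncrop(array: np.ndarray, offset, original_shape, fill=0):
    """Paste a cropped array back at ``offset`` into ``original_shape``."""
    out = np.full(original_shape, fill, dtype=np.asarray(array).dtype)
    sl = tuple(slice(o, o + s) for o, s in zip(offset, array.shape))
    out[sl] = array
    return out


def normalize_intensities(vol: PancreasVolume) -> PancreasVolume:
    """Linear min-max rescaling of pancreas intensities to [0, 1].

    Statistics are computed over pancreas voxels only; every background
    voxel is set to exactly 0.  A constant-valued pancreas maps to all
    zeros (convention for degenerate inputs).  The operation is idempotent
    and invariant to affine rescaling a*I + b (a > 0) of the input.
    """
    if not vol.mask.any():
        raise ValueError("empty pancreas mask")
    vals = vol.intensities[vol.mask]
    lo, hi = float(vals.min()), float(vals.max())
    out = np.zeros_like(vol.intensities)
    if hi > lo:
        out[vol.mask] = (vol.intensities[vol.mask] - lo) / (hi - lo)
    return replace(vol, intensities=out)


def preprocess(vol: PancreasVolume, labels=None, padding: int = 8,
               keep_largest: bool = False):
    """Full preparation path: connectivity check -> crop -> normalize."""
    mask = check_mask_connectivity(vol.mask, keep_largest=keep_largest)
    vol = replace(vol, mask=mask)
    if labels is not None:
        labels = np.where(mask, labels, 0).astype(np.uint8)
    cropped, cropped_labels, offset = crop_to_pancreas(vol, labels, padding=padding)
    return normalize_intensities(cropped), cropped_labels, offset


def save_sidecar(path, **entries):
    """Persist crop offsets / preprocessing parameters as a JSON sidecar."""

    def _clean(v):
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, (np.integer, np.floating)):
            return v.item()
        if isinstance(v, (tuple, list)):
            return [_clean(x) for x in v]
        return v

    with open(path, "w") as fh:
        json.dump({k: _clean(v) for k, v in entries.items()}, fh, indent=2)
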