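"""NIfTI volume I/O and voxel/world coordinate arithmetic.

All public coordinates are world millimetres in the subject's native RAS
frame; voxel indices are 0-based and continuous (sub-voxel positions are
meaningful).  Volumes are never resampled: electrode localization depends on
keeping the CT at its native resolution, since down-sampling to typical MRI
resolution can erase small contacts entirely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import BoundsError, FormatError, HeaderError

logger = logging.getLogger(__name__)


@dataclass
class Volume:
    """A 3D scalar volume with a voxel-to-world affine.

    Parameters
    ----------
    data
        3D array of intensities (CT units are arbitrary; no Hounsfield
        calibration is assumed).
    affine
        4x4 voxel-to-world matrix mapping 0-based continuous voxel indices to
        world mm (RAS).  Must be invertible.
    """

    data: np.ndarray
    affine: np.ndarray
    _inv_affine: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise HeaderError(f"expected a 3D volume, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise HeaderError(f"affine must be 4x4, got {self.affine.shape}")
        try:
            self._inv_affine = np.linalg.inv(self.affine)
        except np.linalg.LinAlgError as exc:
            raise HeaderError("voxel-to-world affine is not invertible") from exc

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Length of each voxel edge in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)


def read_volume(path) -> Volume:
    """Read a NIfTI-1/NIfTI-2 file at full resolution.

    The affine is taken from the header following the usual precedence
    (sform when set, else qform, else pixdim-scaled identity).  Voxel data
    are loaded as-is; no resampling, reorientation, or scaling beyond the
    header's scl slope/intercept ever occurs.
    """
    import nibabel as nib

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise FormatError(f"not a readable NIfTI file: {path}") from exc
    if not isinstance(img, (nib.Nifti1Image, nib.Nifti2Image)):
        raise FormatError(f"not a NIfTI-1/NIfTI-2 file: {path}")
    # nibabel's best-affine already applies sform > qform > base precedence
    affine = img.affine
    hdr = img.header
    logger.info(
        "read %s: shape=%s sform_code=%d qform_code=%d",
        path, img.shape, int(hdr["sform_code"]), int(hdr["qform_code"]),
    )
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    try:
        return Volume(np.asarray(data, dtype=np.float64), affine)
    except HeaderError:
        raise HeaderError(f"non-invertible affine in {path}")


def write_volume(vol: Volume, path) -> None:
    """Write a Volume as NIfTI-1 (.nii or .nii.gz), setting both sform and qform."""
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), vol.affine)
    img.set_sform(vol.affine, code=1)
    img.set_qform(vol.affine, code=1)
    nib.save(img, str(path))


def voxel_to_world(vol: Volume, v) -> np.ndarray:
    """Map continuous voxel indices to world mm.  Accepts a triple or (n, 3)."""
    v = np.asarray(v, dtype=float)
    single = v.ndim == 1
    v = np.atleast_2d(v)
    out = v @ vol.affine[:3, :3].T + vol.affine[:3, 3]
    return out[0] if single else out


def world_to_voxel(vol: Volume, p) -> np.ndarray:
    """Map world mm to continuous (unrounded) voxel indices."""
    p = np.asarray(p, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    out = p @ vol._inv_affine[:3, :3].T + vol._inv_affine[:3, 3]
    return out[0] if single else out


def sample_intensity(vol: Volume, p, mode: str = "trilinear") -> float:
    """Sample the volume at a world point.

    ``nearest`` returns the value at the rounded voxel; ``trilinear`` the
    standard 8-neighbour interpolation.  Raises :class:`BoundsError` when the
    point maps outside the voxel grid.
    """
    if mode not in ("nearest", "trilinear"):
        raise ValueError(f"unknown sampling mode {mode!r}")
    v = world_to_voxel(vol, p)
    shape = np.array(vol.shape)
    if np.any(v < -0.5) or np.any(v > shape - 0.5):
        raise BoundsError(f"world point {tuple(np.asarray(p, float))} maps outside the volume")
    if mode == "nearest":
        idx = np.clip(np.rint(v).astype(int), 0, shape - 1)
        return float(vol.data[tuple(idx)])
    lo = np.floor(v).astype(int)
    frac = v - lo
    acc = 0.0
    for corner in range(8):
        offs = np.array([(corner >> a) & 1 for a in range(3)])
        idx = np.clip(lo + offs, 0, shape - 1)
        w = np.prod(np.where(offs == 1, frac, 1.0 - frac))
        acc += w * float(vol.data[tuple(idx)])
    return float(acc)
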