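"""Anatomic labeling of electrodes from an integer parcellation volume.

Each electrode receives the modal label over the 3x3x3 cube of parcellation
voxels centered on it; on a tie the center voxel's own label wins.  Voting
over the cube makes the assignment robust to sub-voxel electrode shifts,
which single-voxel lookup is not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import BoundsError, FormatError
from .table import ElectrodeTable
from .volume import Volume, world_to_voxel

logger = logging.getLogger(__name__)

UNKNOWN_ID = 0
UNKNOWN_NAME = "unknown"


@dataclass
class LabelVolume:
    """Integer parcellation with a voxel-to-world affine and an id->name LUT.

    Ids absent from the LUT resolve to "unknown" (FreeSurfer convention:
    id 0 is out-of-brain).
    """

    labels: np.ndarray
    affine: np.ndarray
    lut: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = np.rint(self.labels).astype(np.int64)
        self._vol = Volume(self.labels, self.affine)  # affine checks + coords
        self.lut.setdefault(UNKNOWN_ID, UNKNOWN_NAME)

    def name(self, label_id: int) -> str:
        return self.lut.get(int(label_id), UNKNOWN_NAME)


def read_lut(path) -> dict[int, str]:
    """Parse a FreeSurfer-style color LUT: whitespace-delimited
    ``id name r g b a`` lines, ``#`` comments; color columns ignored."""
    lut: dict[int, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"malformed LUT line: {line!r}")
            try:
                lut[int(parts[0])] = parts[1]
            except ValueError as exc:
                raise FormatError(f"malformed LUT line: {line!r}") from exc
    return lut


def read_label_volume(nifti_path, lut_path=None) -> LabelVolume:
    from .volume import read_volume

    vol = read_volume(nifti_path)
    lut = read_lut(lut_path) if lut_path else {}
    return LabelVolume(labels=vol.data, affine=vol.affine, lut=lut)


def majority_label(lv: LabelVolume, p) -> tuple[int, str]:
    """Modal label over the 3x3x3 voxel cube centered on a world point.

    The center voxel is the rounded voxel index of ``p``; cube neighbours
    falling outside the volume are skipped (not padded).  If the maximal
    count is shared by several labels the center voxel's label is returned —
    applied literally, even when the center label is not itself among the
    tied maxima.  Raises :class:`BoundsError` for points outside the volume.
    """
    v = world_to_voxel(lv._vol, p)
    center = np.rint(v).astype(int)
    shape = np.array(lv.labels.shape)
    if np.any(center < 0) or np.any(center >= shape):
        raise BoundsError(f"point {tuple(np.asarray(p, float))} outside the label volume")
    lo = np.maximum(center - 1, 0)
    hi = np.minimum(center + 1, shape - 1)
    cube = lv.labels[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
    ids, counts = np.unique(cube, return_counts=True)
    top = counts.max()
    winners = ids[counts == top]
    if len(winners) > 1:
        label_id = int(lv.labels[tuple(center)])
    else:
        label_id = int(winners[0])
    return label_id, lv.name(label_id)


def label_table(table: ElectrodeTable, lv: LabelVolume) -> ElectrodeTable:
    """Fill anat_label_id/name for every localized record, in place.

    Unlocalized records are untouched; electrodes outside the label volume
    get "unknown" with a warning rather than an error.
    """
    for rec in table.records:
        if rec.coord_native is None:
            continue
        try:
            rec.anat_label_id, rec.anat_label_name = majority_label(lv, rec.coord_native)
        except BoundsError:
            logger.warning("electrode %s (%s) outside the label volume; labelled unknown",
                           rec.number, rec.channel)
            rec.anat_label_id, rec.anat_label_name = UNKNOWN_ID, UNKNOWN_NAME
    return table
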