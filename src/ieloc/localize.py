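"""CT metal-contact detection and sub-voxel centroid refinement.

Metal electrode contacts appear as bright blooming densities in post-implant
CT.  This module thresholds the CT, finds connected high-intensity clusters,
and refines a contact estimate to the intensity-weighted center of the
nearby density — the step that places the reported coordinate at the
physical center of the contact rather than at the clicked voxel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DetectionError, NoDensityError
from .volume import Volume, voxel_to_world, world_to_voxel


@dataclass(frozen=True)
class ThresholdSpec:
    """Detection threshold: an absolute intensity, or a percentile of the
    finite intensities (default 99.5, which isolates metal from tissue and
    bone in typical post-implant CT)."""

    absolute: float | None = None
    percentile: float = 99.5

    def resolve(self, vol: Volume) -> float:
        if self.absolute is not None:
            return float(self.absolute)
        if not 0.0 < self.percentile < 100.0:
            raise ValueError(f"percentile must be in (0, 100), got {self.percentile}")
        finite = vol.data[np.isfinite(vol.data)]
        if finite.size == 0 or np.min(finite) == np.max(finite):
            raise DetectionError("volume is constant; no threshold separates metal")
        return float(np.percentile(finite, self.percentile))


@dataclass
class DensityCandidate:
    """One connected high-intensity cluster: a putative contact."""

    centroid: np.ndarray  # world mm
    peak_intensity: float
    voxel_count: int


def ct_threshold(vol: Volume, spec: ThresholdSpec | float = ThresholdSpec()) -> np.ndarray:
    """Boolean mask of voxels strictly above the threshold."""
    if not isinstance(spec, ThresholdSpec):
        spec = ThresholdSpec(absolute=float(spec))
    thr = spec.resolve(vol)
    mask = vol.data > thr
    if isinstance(spec.absolute, type(None)) and not mask.any():
        # percentile of a non-constant volume always leaves something above
        raise DetectionError("threshold leaves no voxels; volume may be degenerate")
    return mask

# 26-connectivity: metal blooming makes diagonal voxels contiguous at
# sub-millimetre CT resolution
_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def detect_clusters(vol: Volume, mask: np.ndarray) -> list[DensityCandidate]:
    """Connected components of the mask as candidate contacts.

    Each 26-connected component yields its intensity-weighted centroid in
    world mm, its peak intensity, and its voxel count; candidates are sorted
    by descending peak.
    """
    if mask.shape != vol.shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {vol.shape}")
    labels, n = ndimage.label(mask, structure=_STRUCT26)
    out: list[DensityCandidate] = []
    if n == 0:
        return out
    idx = np.arange(1, n + 1)
    peaks = ndimage.maximum(vol.data, labels=labels, index=idx)
    counts = ndimage.sum_labels(mask, labels=labels, index=idx)
    # intensity-weighted voxel centroid per component, then map to world
    coms = ndimage.center_of_mass(vol.data * mask, labels=labels, index=idx)
    for k in range(n):
        centroid = voxel_to_world(vol, np.asarray(coms[k], dtype=float))
        out.append(DensityCandidate(centroid=centroid,
                                    peak_intensity=float(peaks[k]),
                                    voxel_count=int(counts[k])))
    out.sort(key=lambda c: -c.peak_intensity)
    return out


def _in_radius_voxels(vol: Volume, center_world: np.ndarray, radius: float):
    """Voxel indices and world centers within a world-mm radius of a point."""
    vc = world_to_voxel(vol, center_world)
    half = radius / vol.voxel_sizes + 1.0
    lo = np.maximum(np.floor(vc - half).astype(int), 0)
    hi = np.minimum(np.ceil(vc + half).astype(int), np.array(vol.shape) - 1)
    if np.any(lo > hi):
        return (np.empty((0, 3), int), np.empty((0, 3)), np.empty(0))
    grids = np.meshgrid(*(np.arange(lo[a], hi[a] + 1) for a in range(3)), indexing="ij")
    vox = np.stack([g.ravel() for g in grids], axis=1)
    world = voxel_to_world(vol, vox.astype(float))
    d = np.linalg.norm(world - center_world, axis=1)
    keep = d <= radius
    return vox[keep], world[keep], d[keep]


def refine_contact(vol: Volume, seed, radius: float = 2.0,
                   spec: ThresholdSpec | float = ThresholdSpec(),
                   tol: float = 0.01, max_iter: int = 10) -> np.ndarray:
    """Refine a contact estimate to the intensity-weighted density center.

    Starting from ``seed`` (world mm), repeatedly replace the estimate with
    the centroid of above-threshold voxels within ``radius`` of the current
    estimate, weighted by intensity above threshold (w = I - thr, clipped at
    0, so background never biases the result), until the estimate moves less
    than ``tol`` mm or ``max_iter`` iterations.

    Raises :class:`NoDensityError` when no above-threshold voxel lies within
    ``radius`` of the current estimate.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not isinstance(spec, ThresholdSpec):
        spec = ThresholdSpec(absolute=float(spec))
    thr = spec.resolve(vol)
    p = np.asarray(seed, dtype=float)
    for _ in range(max_iter):
        vox, world, _ = _in_radius_voxels(vol, p, radius)
        if len(vox) == 0:
            raise NoDensityError(p)
        inten = vol.data[vox[:, 0], vox[:, 1], vox[:, 2]]
        w = np.clip(inten - thr, 0.0, None)
        if not np.any(w > 0):
            raise NoDensityError(p)
        new_p = (world * w[:, None]).sum(axis=0) / w.sum()
        moved = float(np.linalg.norm(new_p - p))
        p = new_p
        if moved < tol:
            break
    return p
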