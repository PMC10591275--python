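"""Automatic shaft/strip localization from two clicked contacts.

Given the first two contacts of an sEEG shaft (extrapolation) or the two end
contacts (interpolation), the remaining contacts are predicted geometrically
one step at a time and snapped to the nearest CT density within a small
search window.  Because real shafts bend and subdural strips follow cortical
curvature, each step re-measures the local inter-contact vector, so the
march tracks the physical trajectory instead of a straight line; voxels near
already-placed contacts are excluded so two predictions can never claim the
same density.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import SnapFailure
from .localize import ThresholdSpec, _in_radius_voxels, refine_contact
from .volume import Volume

logger = logging.getLogger(__name__)

PROV_REFINED = "refined"
PROV_EXTRAPOLATED = "extrapolated"
PROV_INTERPOLATED = "interpolated"
PROV_FALLBACK = "geometric-fallback"


@dataclass(frozen=True)
class SnapConfig:
    """Snapping parameters.

    search_radius : mm, candidates are sought within this distance of the
        predicted position (default 2.0 — contacts rarely deviate further
        from the local linear prediction).
    exclusion_radius : mm, candidates this close to an already-placed contact
        are rejected to avoid duplicate selection (default 1.5, about half
        the common 3-3.5 mm contact pitch).
    """

    search_radius: float = 2.0
    exclusion_radius: float = 1.5
    threshold: ThresholdSpec = field(default_factory=ThresholdSpec)

    def __post_init__(self) -> None:
        if self.search_radius <= 0 or self.exclusion_radius <= 0:
            raise ValueError("search and exclusion radii must be positive")


def snap_to_density(vol: Volume, predicted, cfg: SnapConfig = SnapConfig(),
                    used: list | None = None) -> np.ndarray:
    """Snap a predicted contact position to the best nearby CT density.

    Among above-threshold voxels within ``search_radius`` of ``predicted``
    and farther than ``exclusion_radius`` from every point in ``used``, the
    highest-intensity voxel wins (ties broken by distance to the prediction,
    then by flat voxel index for determinism); the refined density centroid
    seeded there is returned.  Raises :class:`SnapFailure` when no admissible
    voxel exists.
    """
    predicted = np.asarray(predicted, dtype=float)
    thr = cfg.threshold.resolve(vol)
    vox, world, dist = _in_radius_voxels(vol, predicted, cfg.search_radius)
    if len(vox) == 0:
        raise SnapFailure(predicted)
    inten = vol.data[vox[:, 0], vox[:, 1], vox[:, 2]]
    ok = inten > thr
    if used:
        upts = np.atleast_2d(np.asarray(used, dtype=float))
        dmin = np.min(np.linalg.norm(world[:, None, :] - upts[None, :, :], axis=2), axis=1)
        ok &= dmin > cfg.exclusion_radius
    if not np.any(ok):
        raise SnapFailure(predicted)
    flat = np.ravel_multi_index((vox[:, 0], vox[:, 1], vox[:, 2]), vol.shape)
    order = np.lexsort((flat[ok], dist[ok], -inten[ok]))
    best = world[ok][order[0]]
    return refine_contact(vol, best, radius=cfg.search_radius, spec=cfg.threshold)


def extrapolate_shaft(vol: Volume, c1, c2, n_total: int,
                      cfg: SnapConfig = SnapConfig()) -> tuple[np.ndarray, list[str]]:
    """Localize a whole shaft from its first two contacts.

    Contacts 1 and 2 are the refined seeds.  Each further contact is
    predicted by stepping the vector between the two most recently placed
    contacts, then snapped to the CT; a failed snap falls back to the
    geometric prediction with provenance ``geometric-fallback`` and a
    warning, so one ambiguous CT region does not discard the shaft.

    Returns ``(points, provenance)`` with ``points`` shaped (n_total, 3) in
    shaft order.
    """
    if n_total < 2:
        raise ValueError("n_total must be >= 2")
    c1 = np.asarray(c1, float)
    c2 = np.asarray(c2, float)
    if np.allclose(c1, c2):
        raise ValueError("the two seed contacts must differ")
    pts = [refine_contact(vol, c1, radius=cfg.search_radius, spec=cfg.threshold),
           refine_contact(vol, c2, radius=cfg.search_radius, spec=cfg.threshold)]
    prov = [PROV_REFINED, PROV_REFINED]
    for _ in range(2, n_total):
        predicted = pts[-1] + (pts[-1] - pts[-2])
        try:
            p = snap_to_density(vol, predicted, cfg, used=pts)
            prov.append(PROV_EXTRAPOLATED)
        except SnapFailure:
            logger.warning("snap failed at predicted %s; using geometric fallback",
                           np.round(predicted, 2))
            p = predicted
            prov.append(PROV_FALLBACK)
        pts.append(p)
    return np.array(pts), prov


def interpolate_shaft(vol: Volume, c_first, c_last, n_total: int,
                      cfg: SnapConfig = SnapConfig()) -> tuple[np.ndarray, list[str]]:
    """Localize a shaft/strip from its two end contacts.

    Both endpoints are refined first.  Interior contacts are then placed by a
    forward march: at each step the prediction is the current contact plus
    the remaining straight-line vector to the refined far endpoint divided by
    the number of gaps still to fill, snapped to the CT.  Re-aiming at every
    step keeps the march on course around bends (including strips curving 90°
    over the occipital pole) without accumulating error.
    """
    if n_total < 2:
        raise ValueError("n_total must be >= 2")
    first = refine_contact(vol, np.asarray(c_first, float),
                           radius=cfg.search_radius, spec=cfg.threshold)
    last = refine_contact(vol, np.asarray(c_last, float),
                          radius=cfg.search_radius, spec=cfg.threshold)
    pts = [first]
    prov = [PROV_REFINED]
    for i in range(1, n_total - 1):
        gaps_left = n_total - i  # gaps from pts[-1] to the far endpoint
        predicted = pts[-1] + (last - pts[-1]) / gaps_left
        try:
            p = snap_to_density(vol, predicted, cfg, used=pts + [last])
            prov.append(PROV_INTERPOLATED)
        except SnapFailure:
            logger.warning("snap failed at predicted %s; using geometric fallback",
                           np.round(predicted, 2))
            p = predicted
            prov.append(PROV_FALLBACK)
        pts.append(p)
    pts.append(last)
    prov.append(PROV_REFINED)
    return np.array(pts), prov


def geometric_interpolate(c_first, c_last, n_total: int) -> np.ndarray:
    """Evenly spaced collinear contacts between two endpoints (no-CT mode)."""
    if n_total < 2:
        raise ValueError("n_total must be >= 2")
    c_first = np.asarray(c_first, float)
    c_last = np.asarray(c_last, float)
    t = np.linspace(0.0, 1.0, n_total)[:, None]
    return c_first * (1 - t) + c_last * t
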