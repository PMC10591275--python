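"""Deterministic synthetic fixtures with known ground truth.

Every downstream test runs on data produced here: CT volumes in which metal
contacts are rendered as bright isotropic Gaussian blobs along straight or
arced trajectories over a noisy background, integer label volumes built from
half-spaces and boxes, icosphere stand-ins for the pial envelope, and
grid-of-contacts fixtures displaced inward to emulate post-craniotomy brain
shift.  All generators are pure functions of their arguments including the
seed, so identical calls produce bit-identical outputs.

Defaults — 0.5 mm voxels, blob sigma 0.6 mm, amplitude 1000, noise SD 20 —
give a blob/background contrast at which percentile thresholding cleanly
separates contacts, comparable to metal against soft tissue in real CT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .anatomy import LabelVolume
from .brainshift import SurfaceMesh, is_inside
from .errors import PlacementError
from .volume import Volume, voxel_to_world, world_to_voxel


def make_trajectory(start, direction, n: int, spacing: float,
                    curvature_radius: float = np.inf,
                    plane_normal=None) -> np.ndarray:
    """Contact centers along a straight line or a circular arc.

    Points are spaced exactly ``spacing`` mm apart in arc length; for a
    finite ``curvature_radius`` the arc lies in the plane orthogonal to
    ``plane_normal`` (required), starting at ``start`` with initial tangent
    ``direction``.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    start = np.asarray(start, dtype=float)
    direction = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(direction)
    if norm < 1e-12:
        raise ValueError("direction must be a nonzero vector")
    t_hat = direction / norm
    if not np.isfinite(curvature_radius):
        return start + spacing * np.arange(n)[:, None] * t_hat
    if curvature_radius <= 0:
        raise ValueError("curvature_radius must be positive or infinite")
    if plane_normal is None:
        raise ValueError("an arc trajectory requires plane_normal")
    n_vec = np.asarray(plane_normal, dtype=float)
    n_vec = n_vec - np.dot(n_vec, t_hat) * t_hat  # orthogonalize
    if np.linalg.norm(n_vec) < 1e-12:
        raise ValueError("plane_normal must not be parallel to direction")
    n_hat = n_vec / np.linalg.norm(n_vec)
    m_hat = np.cross(n_hat, t_hat)  # in-plane normal, points toward the center
    center = start + curvature_radius * m_hat
    theta = spacing * np.arange(n) / curvature_radius
    pts = (center[None, :]
           - curvature_radius * np.cos(theta)[:, None] * m_hat[None, :]
           + curvature_radius * np.sin(theta)[:, None] * t_hat[None, :])
    return pts


def render_ct(points, shape=(96, 96, 96), voxel_size: float = 0.5,
              amplitude: float = 1000.0, sigma: float = 0.6,
              noise_sd: float = 20.0, seed: int = 0,
              origin=None) -> Volume:
    """Render contacts as Gaussian blobs over pseudo-random background noise.

    Each point becomes an isotropic Gaussian of peak ``amplitude`` and width
    ``sigma`` mm; blobs sum where they overlap.  Every point must sit at
    least 3 sigma inside the field of view; violating points raise
    :class:`PlacementError`.  The background is iid normal noise from
    ``seed``; the same arguments always yield a bit-identical volume.
    """
    shape = tuple(int(s) for s in shape)
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if origin is None:
        origin = np.zeros(3)
    affine = np.diag([voxel_size] * 3 + [1.0])
    affine[:3, 3] = np.asarray(origin, dtype=float)
    vol = Volume(np.zeros(shape, dtype=np.float64), affine)
    lo = voxel_to_world(vol, np.zeros(3)) + 3 * sigma
    hi = voxel_to_world(vol, np.array(shape, float) - 1) - 3 * sigma
    for p in points:
        if np.any(p < lo) or np.any(p > hi):
            raise PlacementError(
                f"point {tuple(p)} closer than 3*sigma to the field-of-view edge")
    rng = np.random.default_rng(seed)
    data = rng.normal(0.0, noise_sd, size=shape) if noise_sd > 0 else np.zeros(shape)
    # add each blob over a local 4-sigma window only
    half = int(np.ceil(4 * sigma / voxel_size))
    for p in points:
        vc = world_to_voxel(vol, p)
        c = np.rint(vc).astype(int)
        lo_i = np.maximum(c - half, 0)
        hi_i = np.minimum(c + half, np.array(shape) - 1)
        grids = np.meshgrid(*(np.arange(lo_i[a], hi_i[a] + 1) for a in range(3)),
                            indexing="ij")
        vox = np.stack([g.ravel() for g in grids], axis=1)
        world = voxel_to_world(vol, vox.astype(float))
        d2 = np.sum((world - p) ** 2, axis=1)
        data[vox[:, 0], vox[:, 1], vox[:, 2]] += amplitude * np.exp(-d2 / (2 * sigma ** 2))
    vol.data[...] = data
    return vol


@dataclass
class TrajectoryFixture:
    """Ground-truth contact centers paired with the CT rendered from them."""

    truth: np.ndarray  # (n, 3) world mm
    volume: Volume
    spacing: float
    curvature_radius: float
    sigma: float
    amplitude: float
    noise_sd: float
    seed: int


def make_shaft_fixture(n: int = 8, spacing: float = 3.5,
                       curvature_radius: float = np.inf,
                       start=None, direction=(1.0, 0.0, 0.0),
                       plane_normal=(0.0, 0.0, 1.0),
                       shape=(96, 96, 96), voxel_size: float = 0.5,
                       amplitude: float = 1000.0, sigma: float = 0.6,
                       noise_sd: float = 20.0, seed: int = 0) -> TrajectoryFixture:
    """A complete shaft fixture: trajectory, rendered CT, and ground truth.

    The default start centers the shaft in the field of view.
    """
    pn = plane_normal if np.isfinite(curvature_radius) else None
    if start is None:
        fov = np.array(shape, float) * voxel_size
        d = np.asarray(direction, float)
        d = d / np.linalg.norm(d)
        length = spacing * (n - 1)
        start = fov / 2 - d * length / 2
    truth = make_trajectory(start, direction, n, spacing, curvature_radius, pn)
    vol = render_ct(truth, shape=shape, voxel_size=voxel_size, amplitude=amplitude,
                    sigma=sigma, noise_sd=noise_sd, seed=seed)
    return TrajectoryFixture(truth=truth, volume=vol, spacing=spacing,
                             curvature_radius=float(curvature_radius), sigma=sigma,
                             amplitude=amplitude, noise_sd=noise_sd, seed=seed)


def make_random_shaft_fixture(seed: int) -> TrajectoryFixture:
    """A randomized shaft for recovery studies: random 3D orientation,
    straight or arced (curvature radius 60-150 mm, the range of clinically
    plausible shaft bends), 8-12 contacts at 3.5 mm pitch, background noise
    up to 10% of the blob amplitude.  Fully determined by ``seed``."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(8, 13))
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    if rng.random() < 0.5:
        radius = np.inf
        plane_normal = None
    else:
        radius = float(rng.uniform(60.0, 150.0))
        plane_normal = rng.normal(size=3)
    noise_sd = float(rng.uniform(0.0, 100.0))
    pts = make_trajectory(np.zeros(3), direction, n, 3.5, radius, plane_normal)
    shape = (96, 96, 96)
    voxel_size = 0.5
    fov_center = np.array(shape) * voxel_size / 2
    pts = pts + (fov_center - (pts.min(axis=0) + pts.max(axis=0)) / 2)
    vol = render_ct(pts, shape=shape, voxel_size=voxel_size, amplitude=1000.0,
                    sigma=0.6, noise_sd=noise_sd, seed=int(rng.integers(2**31)))
    return TrajectoryFixture(truth=pts, volume=vol, spacing=3.5,
                             curvature_radius=radius, sigma=0.6, amplitude=1000.0,
                             noise_sd=noise_sd, seed=seed)


def make_label_volume(shape, affine, regions) -> LabelVolume:
    """Build an integer parcellation from geometric region specs.

    ``regions`` is a list of dicts with keys ``id``, ``name`` and either
    ``halfspace: (normal, offset)`` — world points with normal . p > offset —
    or ``box: (lo, hi)`` — an axis-aligned world box.  Voxels claimed by no
    region get id 0 ("unknown"); a voxel claimed by two regions is an error.
    """
    shape = tuple(int(s) for s in shape)
    vol = Volume(np.zeros(shape, dtype=np.int32), affine)
    grids = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    vox = np.stack([g.ravel() for g in grids], axis=1).astype(float)
    world = voxel_to_world(vol, vox)
    labels = np.zeros(len(world), dtype=np.int32)
    claimed = np.zeros(len(world), dtype=bool)
    lut = {0: "unknown"}
    for reg in regions:
        rid = int(reg["id"])
        if rid == 0:
            raise ValueError("region id 0 is reserved for 'unknown'")
        if "halfspace" in reg:
            normal, offset = reg["halfspace"]
            normal = np.asarray(normal, dtype=float)
            inside = world @ normal > float(offset)
        elif "box" in reg:
            lo, hi = (np.asarray(v, dtype=float) for v in reg["box"])
            inside = np.all((world >= lo) & (world <= hi), axis=1)
        else:
            raise ValueError(f"region {reg.get('name')} has no halfspace/box spec")
        if np.any(claimed & inside):
            raise ValueError(f"region {reg['name']!r} overlaps a previous region")
        labels[inside] = rid
        claimed |= inside
        lut[rid] = str(reg["name"])
    return LabelVolume(labels=labels.reshape(shape), affine=np.asarray(affine, float),
                       lut=lut)


def make_icosphere(center=(0.0, 0.0, 0.0), radius: float = 50.0,
                   subdivisions: int = 2) -> SurfaceMesh:
    """Closed triangulated sphere (icosahedron subdivision); the pial-envelope
    stand-in.  subdivisions=0 gives the 12-vertex icosahedron."""
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    verts = np.asarray(tm.vertices, dtype=float) + np.asarray(center, dtype=float)
    return SurfaceMesh(vertices=verts, faces=np.asarray(tm.faces, dtype=int))


def make_grid_fixture(rows: int, cols: int, spacing: float, mesh: SurfaceMesh,
                      inward_offset: float = 8.0) -> tuple[np.ndarray, np.ndarray]:
    """Grid contacts on a spherical cap, displaced inward by ``inward_offset``.

    The mesh is assumed spherical (center and radius estimated from its
    vertices).  Grid points are laid out by the exponential map from the top
    pole, so geodesic spacing equals ``spacing`` along the two axes; the
    on-surface positions are returned as ground-truth targets alongside the
    inward-displaced contact positions.

    Returns ``(contacts, surface_targets)``, each (rows*cols, 3), row-major.
    """
    center = mesh.vertices.mean(axis=0)
    radius = float(np.mean(np.linalg.norm(mesh.vertices - center, axis=1)))
    half_extent = max((rows - 1), (cols - 1)) / 2 * spacing
    if half_extent / radius > np.pi / 2:
        raise ValueError("grid is larger than the upper hemisphere cap")
    pts = []
    for r in range(rows):
        for c in range(cols):
            u = (r - (rows - 1) / 2) * spacing
            v = (c - (cols - 1) / 2) * spacing
            rho = np.hypot(u, v)
            theta = rho / radius  # geodesic angle from the pole
            if rho < 1e-12:
                d = np.array([0.0, 0.0, 1.0])
            else:
                t = np.array([u / rho, v / rho, 0.0])
                d = np.cos(theta) * np.array([0.0, 0.0, 1.0]) + np.sin(theta) * t
            pts.append(center + radius * d)
    targets = np.array(pts)
    directions = (targets - center) / radius
    contacts = targets - inward_offset * directions
    return contacts, targets
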