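"""Brain-shift correction for subdural (ECoG) electrodes.

A craniotomy can displace the brain by a centimetre or more, so subdural
contacts localized on the post-implant CT may fall inside the brain of the
pre-implant MRI.  Since subdural electrodes by definition sit on the pial
surface, any ECoG contact found interior to the pial envelope is moved to
the nearest point on that envelope, while a topology penalty keeps the
projected grid/strip from folding: neighbouring contacts are pulled toward
their original inter-contact distances.  sEEG contacts, inserted through
burr holes, do not shift and are never touched.  Both the original and the
shifted coordinates are kept in the electrode table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh

from .errors import TopologyError
from .table import ElectrodePlan, ElectrodeTable

logger = logging.getLogger(__name__)


@dataclass
class SurfaceMesh:
    """Triangle mesh: vertices in world mm, faces as vertex-index triples."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=int).reshape(-1, 3)
        if len(self.faces) and (self.faces.min() < 0
                                or self.faces.max() >= len(self.vertices)):
            raise TopologyError("face indices out of range")

    def is_closed(self) -> bool:
        """True when every undirected edge is shared by exactly two faces."""
        if len(self.faces) == 0:
            return False
        edges = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                           self.faces[:, [2, 0]]])
        edges = np.sort(edges, axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def _trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces,
                               process=False)


def read_surface(path) -> SurfaceMesh:
    """Read a GIfTI (.gii) or FreeSurfer binary surface file."""
    import nibabel as nib

    path = Path(path)
    if path.suffix.lower() == ".gii":
        img = nib.load(str(path))
        verts = faces = None
        for arr in img.darrays:
            code = arr.intent
            if code in (1008, "NIFTI_INTENT_POINTSET"):
                verts = np.asarray(arr.data, dtype=float)
            elif code in (1009, "NIFTI_INTENT_TRIANGLE"):
                faces = np.asarray(arr.data, dtype=int)
        if verts is None or faces is None:
            raise TopologyError(f"GIfTI file {path} lacks pointset/triangle arrays")
        return SurfaceMesh(verts, faces)
    verts, faces = nib.freesurfer.read_geometry(str(path))
    return SurfaceMesh(np.asarray(verts, float), np.asarray(faces, int))


def write_surface_gifti(mesh: SurfaceMesh, path) -> None:
    import nibabel as nib
    from nibabel.gifti import GiftiDataArray, GiftiImage

    img = GiftiImage(darrays=[
        GiftiDataArray(mesh.vertices.astype(np.float32),
                       intent="NIFTI_INTENT_POINTSET"),
        GiftiDataArray(mesh.faces.astype(np.int32),
                       intent="NIFTI_INTENT_TRIANGLE"),
    ])
    nib.save(img, str(path))


def winding_number(mesh: SurfaceMesh, points) -> np.ndarray:
    """Generalized winding number of each point with respect to the mesh.

    Sum of signed solid angles over all triangles divided by 4*pi
    (van Oosterom & Strackee's formula); exactly 1 inside a closed surface,
    0 outside, and robust to glancing intersections that break ray-parity
    tests on coarse meshes.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    tri = mesh.vertices[mesh.faces]  # (m, 3, 3)
    w = np.empty(len(pts))
    for i, p in enumerate(pts):
        a = tri[:, 0] - p
        b = tri[:, 1] - p
        c = tri[:, 2] - p
        la = np.linalg.norm(a, axis=1)
        lb = np.linalg.norm(b, axis=1)
        lc = np.linalg.norm(c, axis=1)
        num = np.einsum("ij,ij->i", a, np.cross(b, c))
        den = (la * lb * lc + np.einsum("ij,ij->i", a, b) * lc
               + np.einsum("ij,ij->i", b, c) * la
               + np.einsum("ij,ij->i", c, a) * lb)
        w[i] = np.sum(2.0 * np.arctan2(num, den)) / (4.0 * np.pi)
    return w


def is_inside(mesh: SurfaceMesh, p) -> bool | np.ndarray:
    """Interior test by generalized winding number (> 0.5).

    Requires a closed mesh; raises :class:`TopologyError` otherwise.
    """
    if not mesh.is_closed():
        raise TopologyError("interior test requires a closed mesh")
    p = np.asarray(p, dtype=float)
    w = winding_number(mesh, p)
    inside = np.abs(w) > 0.5
    return bool(inside[0]) if p.ndim == 1 else inside


def project_to_surface(mesh: SurfaceMesh, p) -> np.ndarray:
    """Exact nearest point on the triangulated surface.

    The minimiser may lie in a face interior, on an edge, or at a vertex;
    this is a true point-to-triangle projection, not a nearest-vertex lookup.
    """
    if len(mesh.faces) == 0:
        raise TopologyError("cannot project onto an empty mesh")
    p = np.asarray(p, dtype=float)
    single = p.ndim == 1
    pts = np.atleast_2d(p)
    closest, _, _ = trimesh.proximity.closest_point_naive(mesh._trimesh(), pts)
    closest = np.asarray(closest, dtype=float)
    return closest[0] if single else closest


def _grid_adjacency(grid_dims: tuple[int, int]) -> list[tuple[int, int]]:
    """4-neighbourhood pairs over a row-major rows x cols grid (0-based)."""
    rows, cols = grid_dims
    pairs = []
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            if c + 1 < cols:
                pairs.append((i, i + 1))
            if r + 1 < rows:
                pairs.append((i, i + cols))
    return pairs


def _regularized_projection(orig: np.ndarray, mesh: SurfaceMesh,
                            adjacency: list[tuple[int, int]],
                            lambda_topo: float,
                            max_sweeps: int = 100,
                            rel_tol: float = 1e-6) -> np.ndarray:
    """Project points to the surface while preserving inter-point distances.

    Minimizes  sum_i ||s_i - proj_i||^2
             + lambda * sum_(i,j) (||s_i - s_j|| - ||o_i - o_j||)^2
    by coordinate-wise fixed-point sweeps: each s_i moves to the weighted
    mean of its anchor projection and the points at original distance from
    each neighbour along the current direction, and every sweep ends with a
    re-projection of all points onto the surface so the constraint
    "shifted contacts lie on the pial envelope" holds exactly.
    """
    proj = project_to_surface(mesh, orig)
    if lambda_topo == 0.0 or not adjacency:
        return proj
    d0 = {(i, j): float(np.linalg.norm(orig[i] - orig[j])) for i, j in adjacency}
    nbrs: dict[int, list[int]] = {}
    for i, j in adjacency:
        nbrs.setdefault(i, []).append(j)
        nbrs.setdefault(j, []).append(i)
    s = proj.copy()
    prev = s.copy()
    scale = max(float(np.abs(orig).max()), 1.0)
    for _ in range(max_sweeps):
        for i in range(len(orig)):
            acc = proj[i].copy()
            wsum = 1.0
            for j in nbrs.get(i, []):
                dij = d0[(i, j)] if (i, j) in d0 else d0[(j, i)]
                delta = s[i] - s[j]
                norm = np.linalg.norm(delta)
                direction = delta / norm if norm > 1e-12 else np.zeros(3)
                acc += lambda_topo * (s[j] + dij * direction)
                wsum += lambda_topo
            s[i] = acc / wsum
        s = project_to_surface(mesh, s)
        change = float(np.max(np.linalg.norm(s - prev, axis=1)))
        if change / scale < rel_tol:
            break
        prev = s.copy()
    return s


def topology_term(orig: np.ndarray, shifted: np.ndarray,
                  adjacency: list[tuple[int, int]]) -> float:
    """Sum of squared adjacent-distance changes (diagnostic for the penalty)."""
    total = 0.0
    for i, j in adjacency:
        total += (np.linalg.norm(shifted[i] - shifted[j])
                  - np.linalg.norm(orig[i] - orig[j])) ** 2
    return float(total)


def correct_brain_shift(table: ElectrodeTable, plan: ElectrodePlan,
                        mesh: SurfaceMesh, lambda_topo: float = 1.0) -> ElectrodeTable:
    """Project interior ECoG contacts onto the pial envelope, in place.

    Only contacts whose plan group is of ECoG type are considered; among
    those, only contacts strictly inside the closed mesh are moved.  The
    corrected position goes to ``coord_shifted``; ``coord_native`` is always
    retained.  Grid adjacency is the 4-neighbourhood given by ``grid_dims``;
    strips use chain order.  An ECoG group without adjacency information
    falls back to pure nearest-point projection with a warning.
    """
    if lambda_topo < 0:
        raise ValueError("lambda_topo must be >= 0")
    if not mesh.is_closed():
        raise TopologyError("brain-shift correction requires a closed pial envelope")
    for group in plan.groups:
        if not group.is_ecog:
            continue
        recs = sorted((r for r in table.records if r.group == group.label
                       and r.coord_native is not None),
                      key=lambda r: r.within_group_index)
        if not recs:
            continue
        coords = np.array([r.coord_native for r in recs])
        interior = is_inside(mesh, coords)
        if not np.any(interior):
            continue
        if group.kind == "ECoG-grid" and group.grid_dims is not None:
            idx_of = {r.within_group_index - 1: k for k, r in enumerate(recs)}
            adjacency = [(idx_of[i], idx_of[j])
                         for i, j in _grid_adjacency(group.grid_dims)
                         if i in idx_of and j in idx_of]
        elif group.kind == "ECoG-strip":
            adjacency = [(k, k + 1) for k in range(len(recs) - 1)]
        else:
            logger.warning("group %s lacks adjacency info; pure projection used",
                           group.label)
            adjacency = []
        # regularize over the interior subset only; exterior contacts stay put
        sub = np.where(interior)[0]
        sub_index = {g: k for k, g in enumerate(sub)}
        sub_adj = [(sub_index[i], sub_index[j]) for i, j in adjacency
                   if i in sub_index and j in sub_index]
        shifted = _regularized_projection(coords[sub], mesh, sub_adj, lambda_topo)
        for k, g in enumerate(sub):
            recs[g].coord_shifted = shifted[k]
        logger.info("group %s: %d of %d contacts shifted to the pial envelope",
                    group.label, len(sub), len(recs))
    return table
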