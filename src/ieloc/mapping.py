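"""Electrode-to-surface value mapping for visualization export.

A per-electrode scalar (power, a stimulation-mapping category, one frame of
a time series) is spread onto nearby cortical-surface vertices with an
exponential fall-off:

    vertex_value = electrode_value * exp(-d * decay_factor / max_radius)

where d is the Euclidean electrode-to-vertex distance in mm; vertices
farther than ``max_radius`` from every electrode stay unassigned.  A vertex
near several electrodes averages their contributions with inverse-distance
weights, so nearer electrodes dominate.  For categorical data, where
averaging is meaningless, discrete mode assigns the raw value of the nearest
in-radius electrode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import MappingError
from .brainshift import SurfaceMesh

EPS_MM = 1e-6  # floor on inverse-distance weights at d = 0


@dataclass(frozen=True)
class MappingParams:
    decay_factor: float = 1.5
    max_radius: float = 1.0  # mm
    mode: str = "continuous"

    def __post_init__(self) -> None:
        if self.max_radius <= 0:
            raise ValueError("max_radius must be positive")
        if self.decay_factor < 0:
            raise ValueError("decay_factor must be >= 0")
        if self.mode not in ("continuous", "discrete"):
            raise ValueError(f"unknown mapping mode {self.mode!r}")


@dataclass
class VertexValues:
    """Per-vertex values with an explicit unassigned mask."""

    values: np.ndarray  # float for continuous, object for discrete
    assigned: np.ndarray  # bool, same length as mesh vertices

    def __len__(self) -> int:
        return len(self.values)


def _is_unset(v) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v))


def map_values(mesh: SurfaceMesh, electrodes, params: MappingParams = MappingParams()
               ) -> VertexValues:
    """Map per-electrode values onto mesh vertices.

    ``electrodes`` is a sequence of (world point, value); entries with unset
    values (None/NaN) are skipped.  Raises :class:`MappingError` when no
    electrode has a value.
    """
    usable = [(np.asarray(p, float), v) for p, v in electrodes if not _is_unset(v)]
    if not usable:
        raise MappingError("no electrode has a set value")
    pos = np.array([p for p, _ in usable])
    vals = [v for _, v in usable]
    d = cdist(mesh.vertices, pos)  # (n_vertices, n_electrodes)
    in_radius = d <= params.max_radius
    assigned = in_radius.any(axis=1)
    if params.mode == "discrete":
        values = np.full(len(mesh.vertices), None, dtype=object)
        d_masked = np.where(in_radius, d, np.inf)
        nearest = np.argmin(d_masked, axis=1)
        for vi in np.where(assigned)[0]:
            values[vi] = vals[nearest[vi]]
        return VertexValues(values=values, assigned=assigned)
    varr = np.asarray(vals, dtype=float)
    decayed = varr[None, :] * np.exp(-d * params.decay_factor / params.max_radius)
    w = np.where(in_radius, 1.0 / np.maximum(d, EPS_MM), 0.0)
    wsum = w.sum(axis=1)
    values = np.full(len(mesh.vertices), np.nan)
    values[assigned] = (w * decayed).sum(axis=1)[assigned] / wsum[assigned]
    return VertexValues(values=values, assigned=assigned)


def map_timeseries(mesh: SurfaceMesh, electrodes, params: MappingParams = MappingParams()
                   ) -> list[VertexValues]:
    """Map a (point, value-vector) series frame by frame.

    All electrodes must share the same number of timepoints; each frame is
    an independent :func:`map_values` call.
    """
    lengths = {len(np.atleast_1d(v)) for _, v in electrodes}
    if len(lengths) > 1:
        raise ValueError(f"electrodes carry ragged timeseries lengths: {sorted(lengths)}")
    T = lengths.pop() if lengths else 0
    frames = []
    for t in range(T):
        frame_elec = [(p, np.atleast_1d(v)[t]) for p, v in electrodes]
        frames.append(map_values(mesh, frame_elec, params))
    return frames


def threshold_values(electrodes, threshold: float):
    """Mask electrodes with value below the display threshold.

    Returns the same (point, value) list with below-threshold values unset,
    so they behave as missing in downstream mapping — the standard
    "show only significant responses" display mode.
    """
    out = []
    for p, v in electrodes:
        if _is_unset(v) or float(v) < threshold:
            out.append((p, None))
        else:
            out.append((p, v))
    return out


def write_vertex_values_csv(values: VertexValues, path) -> None:
    """Write assigned vertices as CSV rows (vertex_index, value)."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["vertex_index", "value"])
        for i in np.where(values.assigned)[0]:
            writer.writerow([int(i), values.values[i]])


def write_vertex_values_gifti(values: VertexValues, path) -> None:
    """Write a continuous vertex map as a functional GIfTI (.func.gii);
    unassigned vertices are NaN."""
    import nibabel as nib
    from nibabel.gifti import GiftiDataArray, GiftiImage

    arr = np.asarray(values.values, dtype=np.float32)
    img = GiftiImage(darrays=[GiftiDataArray(arr, intent="NIFTI_INTENT_NONE")])
    nib.save(img, str(path))
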