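"""Electrode plan and results-table data model, value import, and export.

The electrode plan declares how contacts are grouped into sEEG shafts and
ECoG grids/strips; the electrode table holds one row per contact with
coordinates (native, voxel, brain-shift-corrected, template), anatomic
labels, provenance, and any number of user-supplied value columns.  Export
follows the BIDS-iEEG electrodes.tsv / coordsystem.json conventions:
tab-separated, UTF-8, literal ``n/a`` for missing cells.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ExportError, PlanError, TableImportError

logger = logging.getLogger(__name__)

KINDS = ("sEEG", "ECoG-grid", "ECoG-strip")
NA = "n/a"


@dataclass
class ContactGroup:
    """One shaft, grid, or strip in the implantation plan.

    ``grid_dims`` (rows, cols) is required for grids and must multiply to
    ``n_contacts``; contacts are numbered row-major within a grid and in
    insertion order along a shaft or strip.
    """

    label: str
    kind: str
    n_contacts: int
    grid_dims: tuple[int, int] | None = None
    nominal_spacing: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise PlanError(f"group {self.label!r}: unknown kind {self.kind!r}")
        if self.n_contacts < 1:
            raise PlanError(f"group {self.label!r}: n_contacts must be >= 1")
        if self.kind == "ECoG-grid":
            if self.grid_dims is None:
                raise PlanError(f"grid group {self.label!r} requires grid_dims")
            r, c = self.grid_dims
            if r * c != self.n_contacts:
                raise PlanError(
                    f"group {self.label!r}: grid_dims {r}x{c} != n_contacts {self.n_contacts}"
                )

    @property
    def is_ecog(self) -> bool:
        return self.kind in ("ECoG-grid", "ECoG-strip")


@dataclass
class ElectrodePlan:
    groups: list[ContactGroup]

    def __post_init__(self) -> None:
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise PlanError(f"duplicate group labels: {dupes}")

    def group(self, label: str) -> ContactGroup:
        for g in self.groups:
            if g.label == label:
                return g
        raise PlanError(f"no group labelled {label!r} in plan")

    @property
    def n_total(self) -> int:
        return sum(g.n_contacts for g in self.groups)


@dataclass
class ElectrodeRecord:
    """One contact: identity, coordinates, anatomy, provenance, extra values.

    Coordinates are world mm RAS; ``coord_shifted`` is the brain-shift
    corrected position (ECoG only), ``coord_template`` a caller-supplied
    template-space position.  ``provenance`` records how the native
    coordinate was obtained.
    """

    number: int
    channel: str
    group: str
    within_group_index: int  # 1-based
    coord_native: np.ndarray | None = None
    coord_voxel: np.ndarray | None = None
    coord_shifted: np.ndarray | None = None
    coord_template: np.ndarray | None = None
    anat_label_id: int | None = None
    anat_label_name: str | None = None
    provenance: str | None = None
    extra: dict = field(default_factory=dict)


@dataclass
class ElectrodeTable:
    records: list[ElectrodeRecord]
    coordinate_frame: str = "subject-native scanner RAS, mm"

    def __post_init__(self) -> None:
        nums = [r.number for r in self.records]
        if nums != list(range(1, len(nums) + 1)):
            raise PlanError("record numbers must be unique and dense from 1")

    def __len__(self) -> int:
        return len(self.records)

    def extra_columns(self) -> list[str]:
        cols: list[str] = []
        for r in self.records:
            for k in r.extra:
                if k not in cols:
                    cols.append(k)
        return cols


def table_from_plan(plan: ElectrodePlan) -> ElectrodeTable:
    """Create the template table: one row per planned contact, no coordinates.

    Channel labels default to group label + within-group index ("LA3"),
    following clinical shaft-code conventions.
    """
    records = []
    n = 0
    for g in plan.groups:
        for i in range(1, g.n_contacts + 1):
            n += 1
            records.append(
                ElectrodeRecord(number=n, channel=f"{g.label}{i}", group=g.label,
                                within_group_index=i)
            )
    return ElectrodeTable(records=records)


def _is_blank(x) -> bool:
    if x is None:
        return True
    if isinstance(x, float) and np.isnan(x):
        return True
    s = str(x).strip()
    return s == "" or s.lower() in ("n/a", "na", "nan")


def read_delimited(path) -> pd.DataFrame:
    """Read a TSV/CSV value table, auto-detecting the delimiter by extension."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def import_values(table: ElectrodeTable, values: pd.DataFrame) -> list:
    """Merge per-electrode value columns into the table, in place.

    Rows are keyed by a ``number`` or ``channel`` column (``name`` is accepted
    as a synonym for channel, matching the BIDS electrodes.tsv header).  Blank
    and ``n/a`` cells are ignored — the record's value stays unset.  Keys that
    match no electrode are returned as a warning list, never raised.
    """
    cols = list(values.columns)
    key_col = next((c for c in ("number", "channel", "name") if c in cols), None)
    if key_col is None:
        raise TableImportError(
            "value table needs a 'number', 'channel' or 'name' key column"
        )
    by_number = {r.number: r for r in table.records}
    by_channel = {r.channel: r for r in table.records}
    unmatched = []
    data_cols = [c for c in cols if c != key_col]
    for _, row in values.iterrows():
        key = row[key_col]
        if key_col == "number":
            try:
                rec = by_number.get(int(float(key)))
            except (TypeError, ValueError):
                rec = None
        else:
            rec = by_channel.get(str(key).strip())
        if rec is None:
            unmatched.append(key)
            continue
        for c in data_cols:
            if not _is_blank(row[c]):
                rec.extra[c] = row[c]
    if unmatched:
        logger.warning("import_values: %d unmatched keys: %s", len(unmatched), unmatched)
    return unmatched


def _fmt_coord(c) -> tuple[str, str, str]:
    if c is None:
        return (NA, NA, NA)
    return tuple(f"{float(x):.6f}" for x in c)


def _to_dataframe(table: ElectrodeTable) -> pd.DataFrame:
    rows = []
    for r in table.records:
        x, y, z = _fmt_coord(r.coord_native)
        row = {
            "number": r.number, "name": r.channel, "group": r.group,
            "within_group_index": r.within_group_index,
            "x": x, "y": y, "z": z, "size": NA,
        }
        for prefix, coord in (("shifted", r.coord_shifted),
                              ("template", r.coord_template)):
            cx, cy, cz = _fmt_coord(coord)
            row[f"{prefix}_x"], row[f"{prefix}_y"], row[f"{prefix}_z"] = cx, cy, cz
        row["anat_label_id"] = NA if r.anat_label_id is None else r.anat_label_id
        row["anat_label_name"] = NA if r.anat_label_name is None else r.anat_label_name
        row["provenance"] = NA if r.provenance is None else r.provenance
        for c in table.extra_columns():
            row[c] = r.extra.get(c, NA)
        rows.append(row)
    return pd.DataFrame(rows)


def export_bids(table: ElectrodeTable, out_dir, subject_tag: str) -> tuple[Path, Path]:
    """Write ``<tag>_electrodes.tsv`` and ``<tag>_coordsystem.json``.

    The TSV carries name/x/y/z (native mm; unset -> ``n/a``), a ``size``
    column, and every extra value column.  Template coordinates, when any
    record has them, go to a separate ``<tag>_space-template`` sidecar pair so
    they never overwrite native ones.
    """
    if not any(r.coord_native is not None for r in table.records):
        raise ExportError("no record has coordinates; nothing to export")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = _to_dataframe(table)
    bids_cols = ["name", "x", "y", "z", "size", "group"] + table.extra_columns()
    tsv_path = out_dir / f"{subject_tag}_electrodes.tsv"
    df[bids_cols].to_csv(tsv_path, sep="\t", index=False, encoding="utf-8")
    json_path = out_dir / f"{subject_tag}_coordsystem.json"
    meta = {
        "iEEGCoordinateSystem": "Other",
        "iEEGCoordinateSystemDescription": table.coordinate_frame,
        "iEEGCoordinateUnits": "mm",
    }
    json_path.write_text(json.dumps(meta, indent=2) + "\n", encoding="utf-8")
    if any(r.coord_template is not None for r in table.records):
        tdf = df[["name", "template_x", "template_y", "template_z", "size", "group"]]
        tdf = tdf.rename(columns={"template_x": "x", "template_y": "y", "template_z": "z"})
        tdf.to_csv(out_dir / f"{subject_tag}_space-template_electrodes.tsv",
                   sep="\t", index=False, encoding="utf-8")
        (out_dir / f"{subject_tag}_space-template_coordsystem.json").write_text(
            json.dumps({"iEEGCoordinateSystem": "Other",
                        "iEEGCoordinateSystemDescription": "caller-supplied template space",
                        "iEEGCoordinateUnits": "mm"}, indent=2) + "\n",
            encoding="utf-8")
    return tsv_path, json_path


def export_plaintext(table: ElectrodeTable, path) -> Path:
    """Write the full table (every field, one row per electrode) as one TSV."""
    if not any(r.coord_native is not None for r in table.records):
        raise ExportError("no record has coordinates; nothing to export")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _to_dataframe(table).to_csv(path, sep="\t", index=False, encoding="utf-8")
    return path


def _parse_coord(row, cx, cy, cz):
    vals = [row.get(c, NA) for c in (cx, cy, cz)]
    if any(_is_blank(v) for v in vals):
        return None
    return np.array([float(v) for v in vals])


def read_plaintext(path) -> ElectrodeTable:
    """Read a table written by :func:`export_plaintext` (round-trip inverse)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    known = {"number", "name", "group", "within_group_index", "x", "y", "z", "size",
             "shifted_x", "shifted_y", "shifted_z",
             "template_x", "template_y", "template_z",
             "anat_label_id", "anat_label_name", "provenance"}
    records = []
    for _, row in df.iterrows():
        rec = ElectrodeRecord(
            number=int(row["number"]), channel=row["name"], group=row["group"],
            within_group_index=int(row["within_group_index"]),
            coord_native=_parse_coord(row, "x", "y", "z"),
            coord_shifted=_parse_coord(row, "shifted_x", "shifted_y", "shifted_z"),
            coord_template=_parse_coord(row, "template_x", "template_y", "template_z"),
        )
        if not _is_blank(row.get("anat_label_id", NA)):
            rec.anat_label_id = int(float(row["anat_label_id"]))
            rec.anat_label_name = row.get("anat_label_name") or None
        if not _is_blank(row.get("provenance", NA)):
            rec.provenance = row["provenance"]
        for c in df.columns:
            if c not in known and not _is_blank(row[c]):
                rec.extra[c] = row[c]
        records.append(rec)
    return ElectrodeTable(records=records)


def read_bids_electrodes(path) -> pd.DataFrame:
    """Read a BIDS electrodes.tsv; coordinates come back as floats, n/a -> NaN."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for c in ("x", "y", "z"):
        df[c] = pd.to_numeric(df[c].replace(NA, np.nan), errors="coerce")
    return df


def read_plan(path) -> ElectrodePlan:
    """Read an electrode plan from JSON (list of group dicts) or TSV."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text())
        groups_raw = raw["groups"] if isinstance(raw, dict) else raw
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        groups_raw = df.to_dict("records")
    groups = []
    for g in groups_raw:
        dims = g.get("grid_dims")
        if isinstance(dims, str) and dims.strip() and not _is_blank(dims):
            r, c = dims.lower().replace("x", " ").split()
            dims = (int(r), int(c))
        elif isinstance(dims, (list, tuple)):
            dims = (int(dims[0]), int(dims[1]))
        else:
            dims = None
        spacing = g.get("nominal_spacing")
        spacing = None if _is_blank(spacing) else float(spacing)
        groups.append(ContactGroup(
            label=str(g["label"]), kind=str(g["kind"]),
            n_contacts=int(g["n_contacts"]), grid_dims=dims,
            nominal_spacing=spacing,
        ))
    return ElectrodePlan(groups=groups)


def write_plan(plan: ElectrodePlan, path) -> None:
    groups = []
    for g in plan.groups:
        groups.append({
            "label": g.label, "kind": g.kind, "n_contacts": g.n_contacts,
            "grid_dims": list(g.grid_dims) if g.grid_dims else None,
            "nominal_spacing": g.nominal_spacing,
        })
    Path(path).write_text(json.dumps({"groups": groups}, indent=2) + "\n")
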