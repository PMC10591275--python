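"""Run configuration shared by the CLI subcommands.

A :class:`RunConfig` collects every path and tunable the pipeline uses, with
defaults equal to the documented module defaults.  Values can come from a
YAML or JSON config file with individual CLI flags taking precedence, so a
complete localization run is reproducible from one file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # input/output paths
    ct: str | None = None
    parcellation: str | None = None
    lut: str | None = None
    surface: str | None = None
    plan: str | None = None
    seeds: str | None = None
    table: str | None = None
    values: str | None = None
    out_dir: str = "."
    subject_tag: str = "sub-01"
    # snapping / refinement
    search_radius: float = 2.0
    exclusion_radius: float = 1.5
    threshold_percentile: float = 99.5
    threshold_absolute: float | None = None
    # value mapping
    decay_factor: float = 1.5
    max_radius: float = 1.0
    mapping_mode: str = "continuous"
    value_column: str | None = None
    # brain shift
    lambda_topo: float = 1.0
    # misc
    log_level: str = "INFO"
    seed: int = 0

    def validate(self) -> None:
        if self.search_radius <= 0 or self.exclusion_radius <= 0:
            raise ValueError("search and exclusion radii must be positive")
        if self.max_radius <= 0 or self.decay_factor < 0:
            raise ValueError("max_radius must be > 0 and decay_factor >= 0")
        if self.lambda_topo < 0:
            raise ValueError("lambda_topo must be >= 0")
        if not 0 < self.threshold_percentile < 100:
            raise ValueError("threshold_percentile must be in (0, 100)")

    def provenance(self) -> dict:
        """Serializable record of every parameter, for the per-run log."""
        from . import __version__

        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["ieloc_version"] = __version__
        return d


def load_config(path=None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML/JSON file plus overrides.

    Overrides with value None are ignored, so absent CLI flags never mask
    file-supplied values.
    """
    data: dict = {}
    if path is not None:
        path = Path(path)
        text = path.read_text()
        data = (json.loads(text) if path.suffix.lower() == ".json"
                else yaml.safe_load(text)) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for k, v in overrides.items():
        if v is not None:
            data[k] = v
    cfg = RunConfig(**data)
    cfg.validate()
    return cfg
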