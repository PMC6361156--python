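"""Run configuration: one YAML document of record per pipeline run."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, is_dataclass
from pathlib import Path
from typing import Any, Dict, Optional

import yaml

from enumap.assoc.qc import QcThresholds
from enumap.exome.cascade import CascadeThresholds
from enumap.pedsim.cohort import SimParams


def _coerce(cls, data: Dict[str, Any]):
    """Build a dataclass from a plain mapping, converting lists to tuples
    where the default is a tuple (YAML has no tuple type)."""
    kwargs = {}
    defaults = cls()
    for f in fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        current = getattr(defaults, f.name)
        if isinstance(current, tuple) and isinstance(value, list):
            value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        kwargs[f.name] = value
    return cls(**kwargs)


@dataclass
class RunConfig:
    """Everything a full run needs; serialisable to/from YAML."""

    seed: int = 1
    sim: SimParams = field(default_factory=SimParams)
    qc: QcThresholds = field(default_factory=QcThresholds)
    qc_population: str = "founders"
    n_perm: int = 1000
    alpha: float = 0.05
    merge_gap_bp: int = 10_000_000
    cascade: CascadeThresholds = field(default_factory=CascadeThresholds)
    min_coverage_depth: int = 20
    matrix_path: Optional[str] = None  # external weight-matrix TSV
    outdir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.merge_gap_bp < 0:
            raise ValueError("merge_gap_bp must be >= 0")

    def to_dict(self) -> Dict[str, Any]:
        out = {}
        for f in fields(self):
            value = getattr(self, f.name)
            out[f.name] = asdict(value) if is_dataclass(value) else value
        return out

    def to_yaml(self, path: Path) -> Path:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return Path(path)

    @classmethod
    def from_dict(cls, data: Dict[str, Any]) -> "RunConfig":
        data = dict(data)
        if "sim" in data and isinstance(data["sim"], dict):
            data["sim"] = _coerce(SimParams, data["sim"])
        if "qc" in data and isinstance(data["qc"], dict):
            data["qc"] = _coerce(QcThresholds, data["qc"])
        if "cascade" in data and isinstance(data["cascade"], dict):
            data["cascade"] = _coerce(CascadeThresholds, data["cascade"])
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)
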