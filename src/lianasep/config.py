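"""Pipeline configuration: every tunable with its standard default.

The defaults are the operating point of the published pipeline: 0.04 m
voxel grid, neighborhood radii 0.1/0.25/0.5/0.75/1.0 m, 10% majority
under-sampling, a 50-tree forest with all features available at each
split, a 0.5 probability threshold, SOR with 6 neighbors and 1 sigma, and
DBSCAN with eps 0.05 m and minPts 5.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml

from .cloud import ValidationError
from .features import ScaleSet
from .model import RFParams
from .postprocess import DBSCANParams
from .preprocess import SORParams

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    voxel_size: float = 0.04
    scales: tuple[float, ...] = (0.1, 0.25, 0.5, 0.75, 1.0)
    undersample_fraction: float = 0.10
    n_trees: int = 50
    n_features_per_split: int | str = "all"
    threshold: float = 0.5
    sor_n_points: int = 6
    sor_n_sigma: float = 1.0
    dbscan_eps: float = 0.05
    dbscan_min_pts: int = 5
    chunk_size: int = 2048
    seed: int = 0

    @property
    def scale_set(self) -> ScaleSet:
        return ScaleSet(tuple(self.scales))

    @property
    def rf_params(self) -> RFParams:
        return RFParams(
            n_trees=self.n_trees,
            n_features_per_split=self.n_features_per_split,
            seed=self.seed,
        )

    @property
    def sor_params(self) -> SORParams:
        return SORParams(n_points=self.sor_n_points, n_sigma=self.sor_n_sigma)

    @property
    def dbscan_params(self) -> DBSCANParams:
        return DBSCANParams(eps=self.dbscan_eps, min_pts=self.dbscan_min_pts)

    def to_dict(self) -> dict:
        out = asdict(self)
        out["scales"] = list(self.scales)
        return out

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "scales" in data:
            data = {**data, "scales": tuple(data["scales"])}
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"{path}: config must be a YAML mapping")
        return cls.from_dict(data)
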