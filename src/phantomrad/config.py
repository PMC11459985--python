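"""Run configuration: one serializable object drives the whole pipeline."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .phantom import (DEFAULT_SETTING, NECROTIC, TABLE1_VARIATIONS,
                      InsertConfig, NoiseModel, PhantomGeometry, ReconSetting,
                      default_insert_configs)

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Everything needed to reproduce one phantom stability study.

    Defaults reproduce the study conditions: the four insert shapes, the
    21-setting one-at-a-time reconstruction grid around the clinical
    default, 64-bin discretization at 2 mm spacing, stability thresholds
    (5, 10, 20)% and alpha = 0.05 over the 6 shape pairs.
    """

    geometry: PhantomGeometry = field(default_factory=PhantomGeometry)
    inserts: tuple[InsertConfig, ...] = field(
        default_factory=default_insert_configs)
    variations: dict = field(
        default_factory=lambda: {k: list(v) for k, v in TABLE1_VARIATIONS.items()})
    default_setting: ReconSetting = DEFAULT_SETTING
    noise: NoiseModel = field(default_factory=NoiseModel)
    ng: int = 64
    spacing: float = 2.0
    glcm_distance: int = 1
    thresholds: tuple[float, float, float] = (5.0, 10.0, 20.0)
    alpha: float = 0.05
    overall_cov: str = "family-mean"   # or "pooled"
    p_method: str = "chisq"            # or "exact"
    seed: int = 0
    write_images: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["inserts"] = [
            {"shape_id": c.shape_id,
             "syringe_activities": list(c.syringe_activities)}
            for c in self.inserts]
        d["thresholds"] = list(self.thresholds)
        d["geometry"]["insert_centers"] = [
            list(c) for c in self.geometry.insert_centers]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        geo = dict(d.pop("geometry", {}))
        if "insert_centers" in geo:
            geo["insert_centers"] = tuple(tuple(c) for c in geo["insert_centers"])
        inserts = tuple(
            InsertConfig(c["shape_id"],
                         tuple(a if a == NECROTIC else float(a)
                               for a in c["syringe_activities"]))
            for c in d.pop("inserts", []))
        ds = d.pop("default_setting", None)
        cfg = cls(
            geometry=PhantomGeometry(**geo),
            inserts=inserts or default_insert_configs(),
            default_setting=ReconSetting(**ds) if ds else DEFAULT_SETTING,
            noise=NoiseModel(**d.pop("noise", {})),
            **{k: v for k, v in d.items()
               if k in {f.name for f in dataclasses.fields(cls)}},
        )
        cfg.thresholds = tuple(cfg.thresholds)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def load_config(path: str | Path) -> RunConfig:
    return RunConfig.from_dict(yaml.safe_load(Path(path).read_text()))
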