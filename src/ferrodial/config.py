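"""YAML configuration round-trip for geometry, design and generator
parameters."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .core import DialysisGeometry
from .design import Diet, StudyDesign, default_design, design_from_dict, \
    design_to_dict
from .synth import (BLANK_CONCENTRATION_DEFAULT, DIET_IRON_MG_DEFAULT,
                    GroupParams, RECOVERY_FRACTION_DEFAULT)

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    design: StudyDesign = field(default_factory=default_design)
    geometry: DialysisGeometry = field(default_factory=DialysisGeometry)
    diet_iron_mg: float = DIET_IRON_MG_DEFAULT
    recovery_fraction: float = RECOVERY_FRACTION_DEFAULT
    blank_concentration: float = BLANK_CONCENTRATION_DEFAULT
    group_params: Optional[list[GroupParams]] = None  # None = defaults


def _params_to_list(params: Sequence[GroupParams]) -> list[dict]:
    return [
        {
            "product_id": p.product_id,
            "diet": p.diet.value,
            "target_mean": p.target_mean,
            "target_sd": p.target_sd,
            "total_iron": p.total_iron,
            "recovery_fraction": p.recovery_fraction,
            "dr_share": p.dr_share,
        }
        for p in params
    ]


def _params_from_list(data: Sequence[dict]) -> list[GroupParams]:
    return [
        GroupParams(
            product_id=(None if row.get("product_id") is None
                        else int(row["product_id"])),
            diet=Diet(row["diet"]),
            target_mean=float(row["target_mean"]),
            target_sd=float(row["target_sd"]),
            total_iron=float(row["total_iron"]),
            recovery_fraction=float(row.get("recovery_fraction",
                                            RECOVERY_FRACTION_DEFAULT)),
            dr_share=(None if row.get("dr_share") is None
                      else float(row["dr_share"])),
        )
        for row in data
    ]


def save_config(config: PipelineConfig, path: str | Path) -> None:
    data = {
        "design": design_to_dict(config.design),
        "geometry": {
            "tube_volume_ml": config.geometry.tube_volume,
            "bath_volume_ml": config.geometry.bath_volume,
            "dr_dilution_factor": config.geometry.dr_dilution_factor,
        },
        "diet_iron_mg": config.diet_iron_mg,
        "recovery_fraction": config.recovery_fraction,
        "blank_concentration": config.blank_concentration,
        "group_params": (None if config.group_params is None
                         else _params_to_list(config.group_params)),
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_config(path: str | Path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text())
    geometry = data.get("geometry", {})
    return PipelineConfig(
        design=(design_from_dict(data["design"]) if "design" in data
                else default_design()),
        geometry=DialysisGeometry(
            tube_volume=float(geometry.get("tube_volume_ml", 50.0)),
            bath_volume=float(geometry.get("bath_volume_ml", 500.0)),
            dr_dilution_factor=float(geometry.get("dr_dilution_factor", 2.0)),
        ),
        diet_iron_mg=float(data.get("diet_iron_mg", DIET_IRON_MG_DEFAULT)),
        recovery_fraction=float(data.get("recovery_fraction",
                                         RECOVERY_FRACTION_DEFAULT)),
        blank_concentration=float(data.get("blank_concentration",
                                           BLANK_CONCENTRATION_DEFAULT)),
        group_params=(None if data.get("group_params") is None
                      else _params_from_list(data["group_params"])),
    )
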