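"""Pipeline configuration: a single YAML file validated with pydantic.

Unknown keys are rejected everywhere so a typo cannot silently fall back
to a default.  All lengths are mm, forces N, moduli GPa.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict
from pydantic import ValidationError as PydanticValidationError

from .errors import ValidationError
from .fem import Material, default_materials
from .geometry import ToothParams
from .meshes import Region


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Strict):
    crown_height: float = 8.0
    buccal_cusp_height: float = 8.0
    lingual_cusp_height: float = 6.5
    buccal_cusp_slope: float = 50.0
    cervix_radius: float = 3.5
    root_length: float = 10.0
    enamel_thickness: float = 1.2
    pulp_radius: float = 1.0
    pdl_thickness: float = 0.25
    bone_block: tuple[float, float, float] = (10.5, 11.5, 16.0)
    wear_depth: float = 0.0
    mesh_size: float = 1.0
    seed: int = 0

    def to_params(self) -> ToothParams:
        return ToothParams(**self.model_dump())


class ContactConfig(_Strict):
    epsilon: float = 0.05
    direction: tuple[float, float, float] = (0.0, -1.0, 0.0)


class LoadsConfig(_Strict):
    total_force: float = 100.0


class MaterialConfig(_Strict):
    E: float  # GPa
    nu: float


class MaterialsConfig(_Strict):
    enamel: MaterialConfig | None = None
    dentine: MaterialConfig | None = None
    pulp: MaterialConfig | None = None
    pdl: MaterialConfig | None = None
    bone: MaterialConfig | None = None

    def to_materials(self) -> dict[Region, Material]:
        mats = default_materials()
        for name, region in (
            ("enamel", Region.ENAMEL), ("dentine", Region.DENTINE),
            ("pulp", Region.PULP), ("pdl", Region.PDL), ("bone", Region.BONE),
        ):
            override = getattr(self, name)
            if override is not None:
                mats[region] = Material(override.E, override.nu)
        return mats


class AnalysisConfig(_Strict):
    n_cervical: int = 10


class PipelineConfig(_Strict):
    geometry: GeometryConfig = GeometryConfig()
    contact: ContactConfig = ContactConfig()
    loads: LoadsConfig = LoadsConfig()
    materials: MaterialsConfig = MaterialsConfig()
    analysis: AnalysisConfig = AnalysisConfig()
    wear_depths: list[float] | None = None  # default: one depth per wear stage
    output_dir: str = "runs"
    seed: int = 0


def load_config(path: str | Path) -> PipelineConfig:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ValidationError(f"malformed YAML in {path}: {exc}") from exc
    return parse_config(raw)


def parse_config(raw: dict) -> PipelineConfig:
    try:
        return PipelineConfig.model_validate(raw)
    except PydanticValidationError as exc:
        raise ValidationError(f"invalid configuration: {exc}") from exc
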