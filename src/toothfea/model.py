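"""Model/Results interface over the occlusal-wear pipeline.

:class:`ToothWearModel` bundles a parametric tooth with the loading and
solver configuration; ``fit()`` runs geometry -> contact -> loads ->
solve -> stress recovery -> cervical sampling and returns a
:class:`ToothWearResults` carrying every intermediate product and a
``summary()`` table.  :class:`WearStudy` fits the same tooth across a
grid of wear depths and exposes the wear trends (contact area, load
obliquity, buccal cervical sigma1) that the abfraction hypothesis is
about.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import analysis as _analysis
from .contact import DEFAULT_EPSILON, ContactResult, contact_at_intercuspation
from .errors import ValidationError
from .fem import (
    ConstraintSet,
    DisplacementField,
    Material,
    StressField,
    default_materials,
    recover_stress,
    solve,
    tooth_constraints,
)
from .geometry import (
    SURFACE_SPACING,
    ToothParams,
    WearStage,
    apply_wear,
    crown_surface,
    generate_tooth,
    wear_stage,
)
from .loads import DEFAULT_TOTAL_FORCE, LoadCase, build_load_case
from .meshes import Region, SurfaceMesh, VolumeMesh


@dataclass
class ToothWearResults:
    """Everything produced by one fitted wear state."""

    params: ToothParams
    stage: WearStage
    mesh: VolumeMesh
    lower_surface: SurfaceMesh
    antagonist: SurfaceMesh  # translated to maximum intercuspation
    contacts: ContactResult
    load_case: LoadCase
    displacement: DisplacementField
    stress: StressField
    cervical: _analysis.CervicalSample
    zones: pd.DataFrame

    @property
    def mean_cervical_sigma1(self) -> float:
        return float(self.cervical.sigma1.mean())

    @property
    def max_cervical_sigma1(self) -> float:
        return float(self.cervical.sigma1.max())

    @property
    def load_obliquity_deg(self) -> float:
        return self.load_case.obliquity_deg()

    @property
    def total_contact_area(self) -> float:
        return self.contacts.total_area

    def summary(self) -> str:
        p = self.params
        r = self.load_case.resultant
        lines = [
            "Tooth wear FE results",
            "=" * 70,
            f"wear depth:            {p.wear_depth:.3f} mm (stage {self.stage.stage},"
            f" dentine {'exposed' if self.stage.dentine_exposed else 'covered'})",
            f"mesh:                  {self.mesh.n_elements} TET10 elements, "
            f"{self.mesh.n_nodes} nodes",
            f"contact patches:       {self.contacts.n_patches} "
            f"(total area {self.total_contact_area:.2f} mm^2)",
            f"load resultant:        ({r[0]:.2f}, {r[1]:.2f}, {r[2]:.2f}) N, "
            f"|R| = {np.linalg.norm(r):.2f} N",
            f"load obliquity:        {self.load_obliquity_deg:.1f} deg from tooth axis",
            f"equilibrium residual:  {self.displacement.equilibrium_residual:.2e}",
            f"buccal cervix sigma1:  mean {self.mean_cervical_sigma1:.3f} MPa, "
            f"max {self.max_cervical_sigma1:.3f} MPa ({self.cervical.n} nodes)",
            "",
            "Zone summary (MPa):",
            self.zones.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
        ]
        return "\n".join(lines)


class ToothWearModel:
    """One parametric tooth at one wear state, ready to solve.

    Parameters
    ----------
    params : ToothParams
        Geometry/wear parameters of the synthetic premolar.
    materials : optional mapping Region -> Material, defaults to the
        literature dental/bone properties.
    epsilon : contact proximity tolerance, mm.
    total_force : prescribed occlusal resultant magnitude, N.
    approach_direction : antagonist approach direction (unit not required).
    n_cervical : number of homologous cervical sampling nodes.
    """

    def __init__(
        self,
        params: ToothParams,
        materials: dict[Region, Material] | None = None,
        epsilon: float = DEFAULT_EPSILON,
        total_force: float = DEFAULT_TOTAL_FORCE,
        approach_direction: tuple[float, float, float] = (0.0, -1.0, 0.0),
        n_cervical: int = _analysis.DEFAULT_N_CERVICAL,
        surface_spacing: float = SURFACE_SPACING,
        smoothing_radius: float | None = None,
    ):
        self.params = params
        self.materials = dict(materials) if materials is not None else default_materials()
        self.epsilon = float(epsilon)
        self.total_force = float(total_force)
        self.approach_direction = np.asarray(approach_direction, dtype=float)
        self.n_cervical = int(n_cervical)
        self.surface_spacing = float(surface_spacing)
        # surface patch-recovery radius; default spans adjacent voxel corners
        self.smoothing_radius = (
            float(smoothing_radius) if smoothing_radius is not None
            else 1.25 * params.mesh_size
        )

    @classmethod
    def from_config(cls, config) -> "ToothWearModel":
        """Build from a validated :class:`~toothfea.config.PipelineConfig`."""
        return cls(
            params=config.geometry.to_params(),
            materials=config.materials.to_materials(),
            epsilon=config.contact.epsilon,
            total_force=config.loads.total_force,
            approach_direction=tuple(config.contact.direction),
            n_cervical=config.analysis.n_cervical,
        )

    def constraints_for(self, mesh: VolumeMesh) -> ConstraintSet:
        return tooth_constraints(mesh)

    def fit(self) -> ToothWearResults:
        """Run the full static maximum-intercuspation analysis."""
        mesh, antagonist = generate_tooth(self.params)
        lower = crown_surface(self.params, spacing=self.surface_spacing)
        contacts, moved = contact_at_intercuspation(
            lower, antagonist, direction=self.approach_direction, epsilon=self.epsilon
        )
        load_case = build_load_case(
            mesh, contacts, total=self.total_force,
            match_distance=self.params.mesh_size,
        )
        constraints = self.constraints_for(mesh)
        displacement = solve(mesh, self.materials, load_case.nodal_forces, constraints)
        stress = recover_stress(mesh, self.materials, displacement)
        smoothed = _analysis.surface_smoothed_sigma1(stress, mesh, self.smoothing_radius)
        cervical = _analysis.sample_cervical_nodes(mesh, self.n_cervical).with_stress(
            stress, sigma1=smoothed
        )
        zones = _analysis.pattern_report(stress, mesh, self.params, sigma1=smoothed)
        return ToothWearResults(
            params=self.params,
            stage=wear_stage(self.params),
            mesh=mesh,
            lower_surface=lower,
            antagonist=moved,
            contacts=contacts,
            load_case=load_case,
            displacement=displacement,
            stress=stress,
            cervical=cervical,
            zones=zones,
        )


def default_wear_depths(params: ToothParams) -> list[float]:
    """One representative wear depth per ordinal stage (1, 2, 3)."""
    cap = params.enamel_cap_vertical
    return [0.2 * cap, 0.7 * cap, 1.3 * cap]


@dataclass
class WearStudyResults:
    """Fitted wear-state series of one parametric tooth."""

    results: list[ToothWearResults]
    trends: pd.DataFrame
    comparison: _analysis.WearComparison  # least vs most worn state

    def summary(self) -> str:
        c = self.comparison
        lines = [
            "Wear study: occlusal wear vs buccal cervical tensile stress",
            "=" * 70,
            self.trends.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
            "",
            f"mean cervical sigma1, least worn:  {c.sigma1_a.mean():.3f} MPa",
            f"mean cervical sigma1, most worn:   {c.sigma1_b.mean():.3f} MPa",
            f"mean delta (least - most):         {c.mean_delta:.3f} MPa",
            f"load obliquity, least worn:        {c.load_obliquity_a:.1f} deg",
            f"load obliquity, most worn:         {c.load_obliquity_b:.1f} deg",
        ]
        return "\n".join(lines)


class WearStudy:
    """Fit one parametric tooth across a grid of wear depths."""

    def __init__(
        self,
        params: ToothParams,
        wear_depths: list[float] | None = None,
        **model_kwargs,
    ):
        self.base_params = params
        self.wear_depths = (
            list(wear_depths) if wear_depths is not None else default_wear_depths(params)
        )
        if len(self.wear_depths) < 2:
            raise ValidationError("a wear study needs at least two wear depths")
        if sorted(self.wear_depths) != self.wear_depths:
            raise ValidationError("wear depths must be given in increasing order")
        self.model_kwargs = model_kwargs

    def fit(self) -> WearStudyResults:
        results = []
        for depth in self.wear_depths:
            params = apply_wear(self.base_params, depth)
            results.append(ToothWearModel(params, **self.model_kwargs).fit())
        rows = []
        for res in results:
            apex = res.zones.set_index("zone").loc["root_apex"]
            rows.append({
                "wear_depth_mm": res.params.wear_depth,
                "stage": res.stage.stage,
                "dentine_exposed": res.stage.dentine_exposed,
                "n_patches": res.contacts.n_patches,
                "contact_area_mm2": res.total_contact_area,
                "load_obliquity_deg": res.load_obliquity_deg,
                "mean_cervical_sigma1_mpa": res.mean_cervical_sigma1,
                "max_cervical_sigma1_mpa": res.max_cervical_sigma1,
                "apex_mean_trace_mpa": float(apex["mean_trace_mpa"]),
            })
        trends = pd.DataFrame(rows)
        comparison = _analysis.compare_wear_states(
            results[0].cervical, results[-1].cervical,
            load_a=results[0].load_case, load_b=results[-1].load_case,
        )
        return WearStudyResults(results=results, trends=trends, comparison=comparison)
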