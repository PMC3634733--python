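"""End-to-end pipeline runner: config in, run directory out.

Executes geometry -> contact -> loads -> solve -> analysis for every
requested wear state and writes all artifacts plus a machine-readable
manifest (config hash, seed, library versions).  Outputs contain no
timestamps, so a rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .contact import contact_summary
from .io import write_abaqus_inp, write_surface, write_volume
from .model import ToothWearModel, WearStudy, WearStudyResults, default_wear_depths


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.model_dump(), sort_keys=True, default=list)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, output_dir: str | Path | None = None) -> Path:
    """Run every wear state and write artifacts; returns the run directory."""
    out = Path(output_dir if output_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    params = config.geometry.to_params()
    depths = config.wear_depths if config.wear_depths is not None else default_wear_depths(params)
    model_kwargs = dict(
        materials=config.materials.to_materials(),
        epsilon=config.contact.epsilon,
        total_force=config.loads.total_force,
        approach_direction=tuple(config.contact.direction),
        n_cervical=config.analysis.n_cervical,
    )
    study = WearStudy(params, wear_depths=list(depths), **model_kwargs)
    results = study.fit()
    write_study(results, out)

    manifest = {
        "config": config.model_dump(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "wear_depths": [float(d) for d in depths],
        "versions": _versions(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=list))
    return out


def _versions() -> dict[str, str]:
    import scipy
    import trimesh

    return {
        "toothfea": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "trimesh": trimesh.__version__,
    }


def write_study(results: WearStudyResults, out: Path) -> None:
    """Write per-state artifacts and the cross-state tables."""
    cervical_rows = []
    contact_rows = []
    zone_rows = []
    for res in results.results:
        tag = f"d{res.params.wear_depth:.3f}".replace(".", "p")
        state_dir = out / f"state_{tag}"
        state_dir.mkdir(parents=True, exist_ok=True)
        write_surface(res.lower_surface, state_dir / "crown_surface.ply")
        write_surface(res.antagonist, state_dir / "antagonist_surface.ply")
        write_volume(
            res.mesh,
            state_dir / "model.vtu",
            point_data={
                "displacement_mm": res.displacement.u,
                "force_n": res.load_case.nodal_forces,
                "stress_mpa": res.stress.sigma,
                "principal_mpa": res.stress.principal,
            },
        )
        write_abaqus_inp(
            res.mesh, state_dir / "model.inp",
            nodal_forces=res.load_case.nodal_forces,
        )
        contact_summary(res.contacts).to_csv(state_dir / "contact_summary.csv", index=False)
        for k in range(res.cervical.n):
            cervical_rows.append({
                "wear_depth_mm": res.params.wear_depth,
                "stage": res.stage.stage,
                "arc_position": res.cervical.arc_positions[k],
                "node_id": int(res.cervical.node_ids[k]),
                "sigma1_mpa": float(res.cervical.sigma1[k]),
            })
        df = contact_summary(res.contacts)
        df.insert(0, "wear_depth_mm", res.params.wear_depth)
        contact_rows.append(df)
        z = res.zones.copy()
        z.insert(0, "wear_depth_mm", res.params.wear_depth)
        zone_rows.append(z)

    pd.DataFrame(cervical_rows).to_csv(out / "cervical_sample.csv", index=False)
    pd.concat(zone_rows, ignore_index=True).to_csv(out / "zones.csv", index=False)
    pd.concat(contact_rows, ignore_index=True).to_csv(out / "contacts.csv", index=False)
    results.trends.to_csv(out / "trends.csv", index=False)
    (out / "summary.txt").write_text(results.summary() + "\n")


def run_single(config: PipelineConfig, wear_depth: float | None = None):
    """Fit a single wear state from a pipeline config (CLI plumbing)."""
    params = config.geometry.to_params()
    if wear_depth is not None:
        from .geometry import apply_wear

        params = apply_wear(params, wear_depth)
    model = ToothWearModel(
        params,
        materials=config.materials.to_materials(),
        epsilon=config.contact.epsilon,
        total_force=config.loads.total_force,
        approach_direction=tuple(config.contact.direction),
        n_cervical=config.analysis.n_cervical,
    )
    return model.fit()
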