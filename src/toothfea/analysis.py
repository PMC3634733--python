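"""Comparison stage: cervical stress sampling and wear-state contrasts.

The abfraction question is answered here: maximum principal (tensile)
stress is read at homologous nodes along the buccal cervical margin and
compared between wear states of the same parametric tooth.  Homology is
parametric — nodes are picked nearest to fixed fractions of the buccal
cervix arc, and because the voxel grid does not move with wear the
sub-cervical nodes coincide exactly across states.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ValidationError
from .fem import StressField
from .geometry import ToothParams
from .loads import LoadCase
from .meshes import Region, VolumeMesh

#: Number of homologous cervical sampling nodes.
DEFAULT_N_CERVICAL = 10


@dataclass(frozen=True)
class CervicalSample:
    """Homologous nodes along the buccal cervical margin."""

    node_ids: np.ndarray  # (n,)
    arc_positions: np.ndarray  # (n,) fraction in [0, 1] along the buccal arc
    sigma1: np.ndarray | None = None  # (n,) MPa once a solve is attached

    @property
    def n(self) -> int:
        return len(self.node_ids)

    def with_stress(
        self, stress: StressField, sigma1: np.ndarray | None = None
    ) -> "CervicalSample":
        """Attach sigma1 values: raw nodal by default, or a caller-supplied
        per-node array (e.g. surface-smoothed recovery)."""
        field = stress.sigma1 if sigma1 is None else np.asarray(sigma1)
        return replace(self, sigma1=field[self.node_ids].copy())


@dataclass(frozen=True)
class WearComparison:
    """Per-position sigma1 pairs between two wear states (deltas = a - b)."""

    arc_positions: np.ndarray
    sigma1_a: np.ndarray  # MPa, state a (e.g. unworn)
    sigma1_b: np.ndarray  # MPa, state b (e.g. worn)
    mean_delta: float
    max_delta: float
    load_obliquity_a: float | None = None  # degrees to the tooth axis
    load_obliquity_b: float | None = None

    @property
    def deltas(self) -> np.ndarray:
        return self.sigma1_a - self.sigma1_b


def sample_cervical_nodes(
    mesh: VolumeMesh, n: int = DEFAULT_N_CERVICAL
) -> CervicalSample:
    """Pick ``n`` nodes nearest to equally spaced positions on the buccal arc.

    The buccal cervix arc is parametrized by azimuth about the tooth axis,
    from the mesial to the distal end of the buccal half.  Selection is
    deterministic: candidates are ranked by azimuth mismatch, then distance
    from the cervix plane, then lowest node id, and chosen azimuths must
    increase strictly so arc positions are strictly ordered.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    if "BUCCAL_CERVIX" not in mesh.node_sets or len(mesh.node_sets["BUCCAL_CERVIX"]) == 0:
        raise ValidationError("mesh has no BUCCAL_CERVIX nodes")
    ids = np.sort(np.asarray(mesh.node_sets["BUCCAL_CERVIX"]))
    if len(ids) < n:
        raise ValidationError(
            f"only {len(ids)} buccal cervix nodes available, need {n}"
        )
    pts = mesh.nodes[ids]
    theta = np.arctan2(pts[:, 2], pts[:, 0])  # in (-pi/2, pi/2) since x > 0
    targets = np.linspace(-np.pi / 2.0, np.pi / 2.0, n + 2)[1:-1]
    chosen: list[int] = []
    prev_theta = -np.inf
    for target in targets:
        best = None
        best_key = None
        for k in range(len(ids)):
            if k in chosen or theta[k] <= prev_theta:
                continue
            key = (abs(theta[k] - target), abs(pts[k, 1]), ids[k])
            if best_key is None or key < best_key:
                best, best_key = k, key
        if best is None:
            raise ValidationError(
                "cannot select strictly ordered cervical nodes; refine the mesh"
            )
        chosen.append(best)
        prev_theta = theta[best]
    chosen = np.asarray(chosen)
    return CervicalSample(
        node_ids=ids[chosen],
        arc_positions=(theta[chosen] + np.pi / 2.0) / np.pi,
    )


def compare_wear_states(
    sample_a: CervicalSample,
    sample_b: CervicalSample,
    load_a: LoadCase | None = None,
    load_b: LoadCase | None = None,
) -> WearComparison:
    """Pair homologous cervical stresses of two states (deltas = a - b)."""
    if sample_a.sigma1 is None or sample_b.sigma1 is None:
        raise ValidationError("both samples need sigma1 attached (run a solve first)")
    if sample_a.n != sample_b.n:
        raise ValidationError("cervical samples have different sizes")
    if not np.allclose(sample_a.arc_positions, sample_b.arc_positions, atol=1e-6):
        raise ValidationError("cervical arc positions do not match between states")
    deltas = sample_a.sigma1 - sample_b.sigma1
    return WearComparison(
        arc_positions=sample_a.arc_positions.copy(),
        sigma1_a=sample_a.sigma1.copy(),
        sigma1_b=sample_b.sigma1.copy(),
        mean_delta=float(deltas.mean()),
        max_delta=float(deltas.max()),
        load_obliquity_a=None if load_a is None else load_a.obliquity_deg(),
        load_obliquity_b=None if load_b is None else load_b.obliquity_deg(),
    )


#: Anatomical zone order of the pattern report.
ZONES = ("buccal_cervix", "lingual_cervix", "mesial_side", "distal_side", "root_apex")


def tooth_surface_nodes(mesh: VolumeMesh) -> np.ndarray:
    """Nodes on the external surface of the tooth proper (enamel + dentine).

    Uses the boundary of the enamel/dentine element subset, so it includes
    the root surface where the tooth meets the periodontal ligament, not
    just the exposed crown.  Faces on the pulp-chamber wall (the internal
    dentine/pulp interface) are excluded: the stress maps of interest are
    the external ones.
    """
    on_tooth = np.isin(mesh.region, [int(Region.ENAMEL), int(Region.DENTINE)])
    sub = VolumeMesh(
        nodes=mesh.nodes,
        elements=mesh.elements[on_tooth],
        region=mesh.region[on_tooth],
    )
    faces, _ = sub.boundary_faces()
    pulp_elems = mesh.elements[mesh.region == int(Region.PULP)]
    if len(pulp_elems):
        from .meshes import TET10_FACES

        pulp_faces = np.concatenate(
            [pulp_elems[:, list(corners)] for corners, _ in TET10_FACES], axis=0
        )
        pulp_keys = {tuple(k) for k in np.sort(pulp_faces, axis=1)}
        keep = [
            tuple(k) not in pulp_keys for k in np.sort(faces[:, :3], axis=1)
        ]
        faces = faces[np.asarray(keep, dtype=bool)]
    return np.unique(faces)


def surface_smoothed_sigma1(
    stress: StressField, mesh: VolumeMesh, radius: float
) -> np.ndarray:
    """Patch-averaged maximum principal stress on the tooth surface.

    Voxel meshes carry stair-step corners whose nodal stresses oscillate
    about the smooth-surface solution; averaging sigma1 over the surface
    nodes within ``radius`` of each surface node (a surface analog of
    patch recovery) removes this single-node noise while preserving the
    regional pattern.  Returns a full-length per-node array that is NaN
    off the tooth surface.
    """
    if radius <= 0:
        raise ValidationError(f"smoothing radius must be positive, got {radius}")
    ids = tooth_surface_nodes(mesh)
    pts = mesh.nodes[ids]
    tree = cKDTree(pts)
    s1 = stress.sigma1[ids]
    out = np.full(mesh.n_nodes, np.nan)
    neighborhoods = tree.query_ball_point(pts, r=radius)
    out[ids] = [s1[nb].mean() for nb in neighborhoods]
    return out


def _zone_masks(mesh: VolumeMesh, params: ToothParams, node_ids: np.ndarray):
    pts = mesh.nodes[node_ids]
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    az = np.degrees(np.arctan2(z, x))
    band = params.cervical_band
    near_cervix = np.abs(y) <= band
    # lateral sides: upper root to mid-crown, below the loaded occlusal table
    side_band = (y >= -0.5 * params.root_length) & (y <= 0.35 * params.truncation_height)
    return {
        "buccal_cervix": (np.abs(az) <= 45.0) & near_cervix,
        "lingual_cervix": (np.abs(az) >= 135.0) & near_cervix,
        "mesial_side": (az < -45.0) & (az > -135.0) & side_band,
        "distal_side": (az > 45.0) & (az < 135.0) & side_band,
        "root_apex": y <= -0.85 * params.root_length,
    }


def pattern_report(
    stress: StressField,
    mesh: VolumeMesh,
    params: ToothParams,
    sigma1: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-zone tensile/compressive summary of the tooth surface.

    Zones are defined by azimuth quadrants about the tooth axis and height
    bands; statistics cover external boundary nodes of enamel/dentine
    elements.  ``sigma1`` may supply a per-node override for the tensile
    statistics (e.g. the surface-smoothed recovery); sigma3/trace
    statistics always use the raw nodal field.

    The ``highest_tension`` column flags the zone with the largest mean
    sigma1.  On a voxel boundary the pointwise maximum rides stair-step
    corner concentrations and does not converge under refinement, so the
    zone comparison uses the mean as its ranking statistic.
    """
    node_ids = tooth_surface_nodes(mesh)
    masks = _zone_masks(mesh, params, node_ids)
    s1_field = stress.sigma1 if sigma1 is None else np.asarray(sigma1)
    rows = []
    for zone in ZONES:
        sel = node_ids[masks[zone]]
        if len(sel) == 0:
            rows.append({"zone": zone, "n_nodes": 0, "mean_sigma1_mpa": np.nan,
                         "max_sigma1_mpa": np.nan, "mean_sigma3_mpa": np.nan,
                         "min_sigma3_mpa": np.nan, "mean_trace_mpa": np.nan})
            continue
        s1 = s1_field[sel]
        s3 = stress.sigma3[sel]
        tr = stress.trace()[sel]
        rows.append({
            "zone": zone,
            "n_nodes": int(len(sel)),
            "mean_sigma1_mpa": float(s1.mean()),
            "max_sigma1_mpa": float(s1.max()),
            "mean_sigma3_mpa": float(s3.mean()),
            "min_sigma3_mpa": float(s3.min()),
            "mean_trace_mpa": float(tr.mean()),
        })
    df = pd.DataFrame(rows)
    flags = np.zeros(len(df), dtype=bool)
    if df["mean_sigma1_mpa"].notna().any():
        flags[int(df["mean_sigma1_mpa"].idxmax())] = True
    df["highest_tension"] = flags
    return df


def nccl_prevalence(cases: int, individuals: int) -> float:
    """Prevalence of cervical lesions as a percentage at one decimal.

    E.g. the Neolithic Mehrgarh sample — 10 affected individuals out of
    225 — computes to 4.4%.
    """
    if individuals <= 0:
        raise ValidationError("individuals must be positive")
    if cases < 0 or cases > individuals:
        raise ValidationError("cases must lie in [0, individuals]")
    return round(100.0 * cases / individuals, 1)
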