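"""Synthetic pseudo-anatomical thigh models.

Real anatomically based volume conductors are segmented from MRI; this
module generates *pseudo-anatomical* stand-ins (representation
``PSEUDO_AM``) that reproduce the structural features such models add over
a concentric cylinder stack:

* smooth low-harmonic radial perturbation of the fat–muscle and skin–fat
  boundaries ("tissue irregularities"),
* a non-concentric bone,
* an embedded blood-vessel inclusion on the medial ray and a nerve-trunk
  (sciatic) inclusion on the posterior ray.

Default inclusion sizes follow the bone-size ratios of the thigh (vessel
cross-section 16 % and nerve 6 % of the bone cross-section disk), and the
default surface-to-boundary distances are 20.17 mm (vessel, medial) and
30.07 mm (nerve trunk, posterior) from the fat–muscle boundary.  These are
exact placement parameters of a synthetic phantom, not anatomical claims.

Everything is deterministic for a fixed seed; each generated spec embeds
its seed and a parameter digest in ``provenance``.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .geometry import (
    SITE_ANGLES_RAD,
    ElectrodePair,
    FiberPlacement,
    InclusionSpec,
    PerturbationHarmonic,
    VolumeModelSpec,
    build_model,
    fiber_axis_xy,
    standard_layers,
)
from .tissues import conductivity_of

__all__ = ["AnatomyParams", "DepthPlacement", "generate_pseudo_anatomy", "depth_series"]

#: Inclusion cross-section as a fraction of the bone cross-section disk.
VESSEL_BONE_AREA_RATIO = 0.16
NERVE_BONE_AREA_RATIO = 0.06

#: Distance from the fat–muscle boundary to the inclusion surface, mm.
VESSEL_BOUNDARY_DISTANCE_MM = 20.17
NERVE_BOUNDARY_DISTANCE_MM = 30.07

#: Minimum clearance between an inclusion and any other boundary, mm.
INCLUSION_CLEARANCE_MM = 2.0


@dataclass(frozen=True)
class AnatomyParams:
    """Parameters of one generated pseudo-anatomy.

    ``vessel_radius_mm`` / ``nerve_radius_mm`` default to the bone-ratio
    values computed from the layer stack; ``*_distance_mm`` measure from
    the fat–muscle boundary to the inclusion *surface* along the medial
    (vessel) and posterior (nerve) rays.
    """

    seed: int = 0
    stack: str = "1"
    fat_perturbation_amplitude_mm: float = 3.0
    fat_harmonics: int = 4
    bone_offset_mm: tuple[float, float] = (2.0, 2.0)
    vessel_radius_mm: float | None = None
    vessel_distance_mm: float = VESSEL_BOUNDARY_DISTANCE_MM
    nerve_radius_mm: float | None = None
    nerve_distance_mm: float = NERVE_BOUNDARY_DISTANCE_MM
    include_vessel: bool = True
    include_nerve: bool = True
    axial_length_cm: float = 40.0

    def __post_init__(self) -> None:
        if self.fat_harmonics < 0 or self.fat_harmonics > 4:
            raise ValueError("boundary perturbation uses at most 4 angular harmonics")
        if self.fat_perturbation_amplitude_mm < 0:
            raise ValueError("perturbation amplitude must be >= 0")

    def digest(self) -> str:
        payload = {k: list(v) if isinstance(v, tuple) else v
                   for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass(frozen=True)
class DepthPlacement:
    """One fibre depth of a depth series, with its validity flag."""

    placement: FiberPlacement
    valid: bool
    reason: str | None = None


def _default_radii_mm(layers) -> tuple[float, float]:
    import numpy as _np

    r_bone_mm = float(_np.cumsum([l.thickness_cm for l in layers])[1]) * 10.0
    r_vessel = r_bone_mm * math.sqrt(VESSEL_BONE_AREA_RATIO)
    r_nerve = r_bone_mm * math.sqrt(NERVE_BONE_AREA_RATIO)
    return r_vessel, r_nerve


def generate_pseudo_anatomy(params: AnatomyParams) -> VolumeModelSpec:
    """Generate a pseudo-anatomical volume model from seeded parameters.

    Deterministic: the same parameters (including seed) give byte-identical
    specifications.  Setting ``include_vessel``/``include_nerve`` to False
    yields the inclusion-ablated variant with *identical* boundaries, bone
    position and mesh hints, so omission studies compare like with like.
    """
    layers = standard_layers(params.stack)
    rng = np.random.default_rng(params.seed)
    # boundary perturbation: low angular harmonics with seeded phases.
    # the skin-fat boundary moves at 30% amplitude so the thin skin layer
    # is never pinched against the (circular) outer surface.
    muscle_h, fat_h = [], []
    amp = params.fat_perturbation_amplitude_mm
    for k in range(1, params.fat_harmonics + 1):
        a_k = amp / params.fat_harmonics * float(rng.uniform(0.5, 1.0))
        phase = float(rng.uniform(0.0, 2.0 * math.pi))
        muscle_h.append(PerturbationHarmonic(a_k, theta_order=k, theta_phase=phase))
        fat_h.append(PerturbationHarmonic(0.3 * a_k, theta_order=k, theta_phase=phase))
    perturbation = {}
    if muscle_h:
        perturbation = {"muscle_outer": tuple(muscle_h), "fat_outer": tuple(fat_h)}

    r_vessel_default, r_nerve_default = _default_radii_mm(layers)
    r_vessel = params.vessel_radius_mm or r_vessel_default
    r_nerve = params.nerve_radius_mm or r_nerve_default

    # probe model without inclusions to evaluate perturbed boundary radii
    probe = build_model(
        "PSEUDO_AM", layers, params.axial_length_cm,
        perturbation=perturbation, bone_offset_mm=params.bone_offset_mm,
    )
    inclusions = []
    specs = [
        ("blood_vessel", params.include_vessel, "medial",
         r_vessel, params.vessel_distance_mm, "blood"),
        ("nerve_trunk", params.include_nerve, "posterior",
         r_nerve, params.nerve_distance_mm, "nerve"),
    ]
    mesh_hints = []
    for kind, include, site, radius, dist, tissue in specs:
        th = SITE_ANGLES_RAD[site]
        r_boundary_mm = float(probe.boundary_radius_m("muscle_outer", th, 0.0)) * 1e3
        r_center = r_boundary_mm - dist - radius
        cx, cy = r_center * math.cos(th), r_center * math.sin(th)
        _check_clearance(probe, kind, (cx, cy), radius)
        mesh_hints.append((cx, cy, radius))
        if include:
            inclusions.append(InclusionSpec(
                kind=kind, axis_offset_mm=(cx, cy), radius_mm=radius,
                conductivity=conductivity_of(tissue),
            ))
    return build_model(
        "PSEUDO_AM", layers, params.axial_length_cm,
        inclusions=inclusions, perturbation=perturbation,
        bone_offset_mm=params.bone_offset_mm,
        provenance={
            "generator": "generate_pseudo_anatomy",
            "seed": params.seed,
            "params_digest": params.digest(),
            "mesh_hint_inclusions": mesh_hints,
        },
    )


def _check_clearance(probe: VolumeModelSpec, kind: str, center_mm, radius_mm) -> None:
    cx, cy = center_mm
    c = np.array([cx, cy])
    theta = np.linspace(0.0, 2.0 * math.pi, 721)
    r_b = probe.boundary_radius_m("muscle_outer", theta, 0.0) * 1e3
    boundary = np.column_stack([r_b * np.cos(theta), r_b * np.sin(theta)])
    gap_boundary = float(np.min(np.linalg.norm(boundary - c, axis=1))) - radius_mm
    bx, by = probe.bone_offset_mm
    r_bone = probe.base_boundary_radius_cm("bone_outer") * 10.0
    gap_bone = math.hypot(cx - bx, cy - by) - r_bone - radius_mm
    for name, gap in (("fat-muscle boundary", gap_boundary), ("bone", gap_bone)):
        if gap < INCLUSION_CLEARANCE_MM:
            raise ValueError(
                f"{kind} inclusion violates the {INCLUSION_CLEARANCE_MM} mm "
                f"clearance to the {name} (gap {gap:.2f} mm)"
            )


def depth_series(
    model: VolumeModelSpec,
    site: str,
    depths_mm,
    diameter_um: float,
    electrodes: ElectrodePair,
    clearance_mm: float = 0.5,
) -> list[DepthPlacement]:
    """Fibre placements at several depths along the site's inward ray.

    Depths outside the muscle or passing within ``clearance_mm`` of an
    inclusion (including the inclusions recorded in the mesh hints of an
    ablated variant) are flagged with a reason, never silently moved.
    """
    out = []
    inclusion_geoms = [
        (inc.axis_offset_mm[0], inc.axis_offset_mm[1], inc.radius_mm)
        for inc in model.inclusions
    ] or list(model.provenance.get("mesh_hint_inclusions", ()))
    for depth in depths_mm:
        placement = FiberPlacement(site=site, depth_mm=float(depth),
                                   diameter_um=diameter_um)
        try:
            x, y = fiber_axis_xy(model, placement, electrodes)
        except ValueError as exc:
            out.append(DepthPlacement(placement, False, str(exc)))
            continue
        labels = model.tissue_at(np.array([[x, y, electrodes.cathode_center_z_cm * 1e-2]]))
        if labels[0] != "muscle":
            out.append(DepthPlacement(
                placement, False,
                f"depth {depth} mm leaves the muscle domain (tissue {labels[0]!r})",
            ))
            continue
        flagged = None
        for cx, cy, r in inclusion_geoms:
            gap = math.hypot(x * 1e3 - cx, y * 1e3 - cy) - r
            if gap < clearance_mm:
                flagged = (f"depth {depth} mm passes within {gap:.2f} mm of an "
                           f"inclusion (clearance {clearance_mm} mm)")
                break
        out.append(DepthPlacement(placement, flagged is None, flagged))
    return out
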