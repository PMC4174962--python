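"""Volume-conductor geometry for a layered human thigh.

Three geometric representations are supported:

* ``CM`` — concentric finite cylinders (bone marrow, cortical bone, muscle,
  subcutaneous fat, skin from the axis outward);
* ``PM`` — a stack of rectangular slabs with the same layer thicknesses,
  skin on top;
* ``PSEUDO_AM`` — a cylinder stack whose fat and muscle boundaries carry
  smooth low-harmonic radial perturbations, whose bone may be off-centre,
  and which may embed blood-vessel and nerve-trunk inclusions.  It stands
  in for an anatomically based model in representation-comparison studies.

Coordinate convention: z runs along the limb axis with the origin at model
mid-length; the transverse plane is x (medial → lateral) and y
(posterior → anterior).  Scalar fields on the dataclasses carry their units
in the field name (cm / mm / μm); every 3-D point array exchanged between
modules is in metres.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .tissues import ConductivityTensor, conductivity_of

__all__ = [
    "CANONICAL_LAYER_ORDER",
    "SITE_ANGLES_RAD",
    "TissueLayer",
    "InclusionSpec",
    "PerturbationHarmonic",
    "VolumeModelSpec",
    "ElectrodePair",
    "FiberPlacement",
    "compute_layer_radii",
    "build_model",
    "standard_layers",
    "cm_model",
    "pm_model",
    "place_electrodes",
    "fiber_axis_xy",
    "fiber_trajectory",
    "FIBER_SAMPLING_STEP_MM",
]

CANONICAL_LAYER_ORDER = ("bone_marrow", "cortical_bone", "muscle", "fat", "skin")

#: Site azimuths on the cylindrical representations (radians from +x).
SITE_ANGLES_RAD = {
    "lateral": 0.0,
    "anterior": 0.5 * math.pi,
    "medial": math.pi,
    "posterior": 1.5 * math.pi,
}

#: Sampling step for voltage profiles along a fibre, mm.
FIBER_SAMPLING_STEP_MM = 0.1

#: Table-1 layer thicknesses (cm), innermost first.
_STANDARD_THICKNESS_CM = {
    "1": (0.87, 0.63, 4.32, 1.24, 0.20),
    "2": (0.94, 0.57, 5.02, 1.73, 0.20),
}


@dataclass(frozen=True)
class TissueLayer:
    """One concentric (or stacked) tissue layer."""

    name: str
    thickness_cm: float
    conductivity: ConductivityTensor

    def __post_init__(self) -> None:
        if self.name not in CANONICAL_LAYER_ORDER:
            raise ValueError(
                f"layer tissue {self.name!r} not in the closed vocabulary "
                f"{CANONICAL_LAYER_ORDER}"
            )
        if not self.thickness_cm > 0.0:
            raise ValueError(
                f"layer {self.name!r}: thickness must be > 0, got {self.thickness_cm} cm"
            )


@dataclass(frozen=True)
class InclusionSpec:
    """A cylindrical inclusion (blood vessel or nerve trunk) parallel to z.

    ``axis_offset_mm`` is the (x, y) position of the inclusion axis in the
    transverse plane, relative to the model axis.
    """

    kind: str
    axis_offset_mm: tuple[float, float]
    radius_mm: float
    conductivity: ConductivityTensor

    def __post_init__(self) -> None:
        if self.kind not in ("blood_vessel", "nerve_trunk"):
            raise ValueError(f"unknown inclusion kind {self.kind!r}")
        if not self.radius_mm > 0.0:
            raise ValueError("inclusion radius must be > 0")

    @property
    def tissue(self) -> str:
        return "blood" if self.kind == "blood_vessel" else "nerve"


@dataclass(frozen=True)
class PerturbationHarmonic:
    """One term of a smooth radial boundary perturbation.

    The perturbed boundary radius is

        r(θ, z) = r0 + amplitude · cos(theta_order·θ + theta_phase)
                        · cos(2π·z_order·z/L + z_phase)

    with the z factor equal to 1 when ``z_order`` is 0 and the θ factor
    equal to 1 when ``theta_order`` is 0.
    """

    amplitude_mm: float
    theta_order: int = 0
    theta_phase: float = 0.0
    z_order: int = 0
    z_phase: float = 0.0

    def evaluate_mm(self, theta: np.ndarray, z_m: np.ndarray, length_m: float) -> np.ndarray:
        out = np.full(np.broadcast(theta, z_m).shape, self.amplitude_mm, dtype=float)
        if self.theta_order:
            out = out * np.cos(self.theta_order * theta + self.theta_phase)
        if self.z_order:
            out = out * np.cos(2.0 * math.pi * self.z_order * z_m / length_m + self.z_phase)
        return out


# Boundaries that may be perturbed in a PSEUDO_AM: the fat–muscle interface
# ("muscle_outer") and the skin–fat interface ("fat_outer").  The outer skin
# surface stays circular so that electrode placement is well defined.
_PERTURBABLE = ("muscle_outer", "fat_outer")


@dataclass(frozen=True)
class VolumeModelSpec:
    """Complete geometric + electrical description of one volume conductor.

    ``layers`` runs innermost (bone marrow) to outermost (skin).  For the PM
    the same thicknesses are stacked along y with the skin face on top and
    ``slab_width_cm`` as the lateral (x) extent.  ``bone_offset_mm`` moves
    the marrow + cortical-bone pair in the transverse plane (used by the
    bone-location adjustment study); it is permitted on any representation
    that keeps the bone inside the muscle.
    """

    representation: str
    layers: tuple[TissueLayer, ...]
    axial_length_cm: float
    inclusions: tuple[InclusionSpec, ...] = ()
    perturbation: dict[str, tuple[PerturbationHarmonic, ...]] = field(default_factory=dict)
    bone_offset_mm: tuple[float, float] = (0.0, 0.0)
    slab_width_cm: float | None = None
    provenance: dict = field(default_factory=dict)

    # -- validation -------------------------------------------------------
    def __post_init__(self) -> None:
        if self.representation not in ("PM", "CM", "PSEUDO_AM"):
            raise ValueError(f"unknown representation {self.representation!r}")
        names = tuple(l.name for l in self.layers)
        if names != CANONICAL_LAYER_ORDER:
            raise ValueError(
                f"layer order must be {CANONICAL_LAYER_ORDER}, got {names}"
            )
        if self.representation in ("PM", "CM"):
            if self.inclusions:
                raise ValueError(f"{self.representation} must be inclusion-free")
            if self.perturbation:
                raise ValueError(f"{self.representation} must have no boundary perturbation")
        if self.representation == "PM" and self.bone_offset_mm != (0.0, 0.0):
            raise ValueError("bone offset is not supported on the PM slab stack")
        for key in self.perturbation:
            if key not in _PERTURBABLE:
                raise ValueError(
                    f"perturbable boundaries are {_PERTURBABLE}, got {key!r}"
                )
        # Electrode extents up to 5 cm side each plus the 6.3 cm fibre must fit.
        if self.axial_length_cm <= 16.3:
            raise ValueError(
                "axial length must exceed the fibre length plus both electrode "
                f"extents (> 16.3 cm); got {self.axial_length_cm} cm"
            )
        self._validate_bone_and_inclusions()

    def _validate_bone_and_inclusions(self) -> None:
        if self.representation == "PM":
            return
        r_bone = self.layer_radii_cm[1] * 10.0  # mm
        r_muscle_min = self._min_boundary_radius_mm("muscle_outer")
        off = math.hypot(*self.bone_offset_mm)
        if off + r_bone >= r_muscle_min:
            raise ValueError(
                f"bone offset {self.bone_offset_mm} mm pushes the bone outside "
                f"the muscle domain (bone radius {r_bone:.1f} mm, "
                f"muscle boundary ≥ {r_muscle_min:.1f} mm)"
            )
        bc = np.asarray(self.bone_offset_mm)
        for inc in self.inclusions:
            c = np.asarray(inc.axis_offset_mm)
            if np.hypot(*c) + inc.radius_mm >= r_muscle_min:
                raise ValueError(
                    f"{inc.kind} inclusion at {inc.axis_offset_mm} mm with radius "
                    f"{inc.radius_mm} mm crosses the muscle–fat boundary "
                    f"(≥ {r_muscle_min:.1f} mm)"
                )
            if np.hypot(*(c - bc)) <= r_bone + inc.radius_mm:
                raise ValueError(f"{inc.kind} inclusion overlaps the bone")

    # -- derived geometry -------------------------------------------------
    @property
    def layer_radii_cm(self) -> np.ndarray:
        """Outer radius (CM) / cumulative stack height (PM) per layer, cm."""
        return compute_layer_radii(self.layers)

    @property
    def outer_radius_cm(self) -> float:
        return float(self.layer_radii_cm[-1])

    @property
    def width_cm(self) -> float:
        """Lateral (x) extent of the PM slab, cm."""
        if self.slab_width_cm is not None:
            return self.slab_width_cm
        # Half the equivalent cylinder circumference, so surface area is
        # comparable and edge truncation stays small.
        return math.pi * self.outer_radius_cm

    def base_boundary_radius_cm(self, boundary: str) -> float:
        radii = self.layer_radii_cm
        idx = {"bone_outer": 1, "muscle_outer": 2, "fat_outer": 3, "skin_outer": 4}
        return float(radii[idx[boundary]])

    def boundary_radius_m(self, boundary: str, theta, z_m) -> np.ndarray:
        """Radius of a tissue interface at azimuth θ and axial position z, metres."""
        theta = np.asarray(theta, dtype=float)
        z_m = np.asarray(z_m, dtype=float)
        r = np.full(np.broadcast(theta, z_m).shape, self.base_boundary_radius_cm(boundary) * 1e-2)
        for h in self.perturbation.get(boundary, ()):
            r = r + 1e-3 * h.evaluate_mm(theta, z_m, self.axial_length_cm * 1e-2)
        return r

    def _min_boundary_radius_mm(self, boundary: str) -> float:
        theta = np.linspace(0.0, 2.0 * math.pi, 721)
        z = np.linspace(-self.axial_length_cm / 200.0, self.axial_length_cm / 200.0, 41)
        r = self.boundary_radius_m(boundary, theta[:, None], z[None, :])
        return float(r.min() * 1e3)

    def layer_by_name(self, name: str) -> TissueLayer:
        for l in self.layers:
            if l.name == name:
                return l
        raise KeyError(name)

    def conductivity_for(self, tissue: str) -> ConductivityTensor:
        for l in self.layers:
            if l.name == tissue:
                return l.conductivity
        for inc in self.inclusions:
            if inc.tissue == tissue:
                return inc.conductivity
        return conductivity_of(tissue)

    # -- tissue classification -------------------------------------------
    def tissue_at(self, points_m: np.ndarray) -> np.ndarray:
        """Classify 3-D points (metres) into tissue labels.

        Points outside the conductor are labelled ``"outside"``.  This is the
        single source of truth used both by the discretizer (cell centres)
        and by fibre-trajectory validation.
        """
        p = np.atleast_2d(np.asarray(points_m, dtype=float))
        if self.representation == "PM":
            return self._tissue_at_slab(p)
        return self._tissue_at_cylinder(p)

    def _tissue_at_slab(self, p: np.ndarray) -> np.ndarray:
        y = p[:, 1]
        x = p[:, 0]
        z = p[:, 2]
        bounds = self.layer_radii_cm * 1e-2
        half_w = self.width_cm * 1e-2 / 2.0
        half_l = self.axial_length_cm * 1e-2 / 2.0
        out = np.full(len(p), "outside", dtype=object)
        inside = (
            (np.abs(x) <= half_w) & (np.abs(z) <= half_l) & (y >= 0) & (y <= bounds[-1])
        )
        edges = np.concatenate(([0.0], bounds))
        for i, layer in enumerate(self.layers):
            sel = inside & (y >= edges[i]) & (y <= edges[i + 1])
            out[sel] = layer.name
        return out

    def _tissue_at_cylinder(self, p: np.ndarray) -> np.ndarray:
        x, y, z = p[:, 0], p[:, 1], p[:, 2]
        r = np.hypot(x, y)
        theta = np.mod(np.arctan2(y, x), 2.0 * math.pi)
        half_l = self.axial_length_cm * 1e-2 / 2.0
        out = np.full(len(p), "outside", dtype=object)
        r_skin = self.base_boundary_radius_cm("skin_outer") * 1e-2
        inside = (r <= r_skin) & (np.abs(z) <= half_l)
        out[inside] = "muscle"
        r_fat = self.boundary_radius_m("fat_outer", theta, z)
        r_mus = self.boundary_radius_m("muscle_outer", theta, z)
        out[inside & (r > r_fat)] = "skin"
        out[inside & (r <= r_fat) & (r > r_mus)] = "fat"
        # inclusions carve the muscle
        for inc in self.inclusions:
            cx, cy = (v * 1e-3 for v in inc.axis_offset_mm)
            hit = inside & (np.hypot(x - cx, y - cy) <= inc.radius_mm * 1e-3)
            out[hit] = inc.tissue
        # bone (possibly off-centre) carves the core
        bx, by = (v * 1e-3 for v in self.bone_offset_mm)
        rb = np.hypot(x - bx, y - by)
        r_bone = self.base_boundary_radius_cm("bone_outer") * 1e-2
        r_marrow = self.layer_radii_cm[0] * 1e-2
        out[inside & (rb <= r_bone)] = "cortical_bone"
        out[inside & (rb <= r_marrow)] = "bone_marrow"
        return out


@dataclass(frozen=True)
class ElectrodePair:
    """Two square surface patches straddling a fixed axial centreline.

    The patch at more negative z is "proximal"; by default it carries the
    cathode (the stimulation pulse is cathodic at the proximal patch).
    Swapping the roles leaves the geometry untouched.
    """

    site: str
    area_cm2: float
    gap_cm: float
    centerline_z_cm: float = 0.0
    cathode: str = "proximal"

    def __post_init__(self) -> None:
        if self.site not in SITE_ANGLES_RAD:
            raise ValueError(f"unknown site {self.site!r}")
        if self.cathode not in ("proximal", "distal"):
            raise ValueError("cathode must be 'proximal' or 'distal'")
        if not self.area_cm2 > 0.0:
            raise ValueError("electrode area must be > 0")
        if self.gap_cm < 0.0:
            raise ValueError("edge-to-edge gap must be >= 0")

    @property
    def side_cm(self) -> float:
        return math.sqrt(self.area_cm2)

    @property
    def patch_center_z_cm(self) -> tuple[float, float]:
        """(proximal, distal) patch centre axial coordinates, cm."""
        half = (self.side_cm + self.gap_cm) / 2.0
        return (self.centerline_z_cm - half, self.centerline_z_cm + half)

    @property
    def cathode_center_z_cm(self) -> float:
        prox, dist = self.patch_center_z_cm
        return prox if self.cathode == "proximal" else dist

    @property
    def anode_center_z_cm(self) -> float:
        prox, dist = self.patch_center_z_cm
        return dist if self.cathode == "proximal" else prox

    def swapped(self) -> "ElectrodePair":
        other = "distal" if self.cathode == "proximal" else "proximal"
        return replace(self, cathode=other)


@dataclass(frozen=True)
class FiberPlacement:
    """A straight axial myelinated fibre below one stimulation site.

    ``depth_mm`` is measured inward from the local fat–muscle boundary; the
    fibre midpoint sits below the centre of the proximal (cathode) patch.
    """

    site: str
    depth_mm: float
    diameter_um: float
    length_mm: float = 63.0

    def __post_init__(self) -> None:
        if self.site not in SITE_ANGLES_RAD:
            raise ValueError(f"unknown site {self.site!r}")
        if self.depth_mm < 0.0:
            raise ValueError("depth must be >= 0")
        if not (self.diameter_um > 0.0 and self.length_mm > 0.0):
            raise ValueError("diameter and length must be > 0")


# ---------------------------------------------------------------------------


def compute_layer_radii(layers) -> np.ndarray:
    """Cumulative outer radius per layer (cm), innermost first."""
    for l in layers:
        if not l.thickness_cm > 0.0:
            raise ValueError(f"layer {l.name!r} has non-positive thickness {l.thickness_cm} cm")
    return np.cumsum([l.thickness_cm for l in layers])


def standard_layers(stack: str = "1") -> tuple[TissueLayer, ...]:
    """The layer stack of subject 1 ("1", used by CM1/PM1) or subject 2 ("2")."""
    thick = _STANDARD_THICKNESS_CM[str(stack)]
    return tuple(
        TissueLayer(name, t, conductivity_of(name))
        for name, t in zip(CANONICAL_LAYER_ORDER, thick)
    )


def build_model(
    representation: str,
    layers,
    axial_length_cm: float = 40.0,
    inclusions=(),
    perturbation=None,
    bone_offset_mm=(0.0, 0.0),
    slab_width_cm: float | None = None,
    provenance: dict | None = None,
) -> VolumeModelSpec:
    """Construct and validate a :class:`VolumeModelSpec`."""
    return VolumeModelSpec(
        representation=representation,
        layers=tuple(layers),
        axial_length_cm=float(axial_length_cm),
        inclusions=tuple(inclusions),
        perturbation={k: tuple(v) for k, v in (perturbation or {}).items()},
        bone_offset_mm=tuple(bone_offset_mm),
        slab_width_cm=slab_width_cm,
        provenance=dict(provenance or {}),
    )


def cm_model(stack: str = "1", axial_length_cm: float = 40.0) -> VolumeModelSpec:
    """Concentric-cylinder model with the standard layer stack."""
    return build_model("CM", standard_layers(stack), axial_length_cm)


def pm_model(stack: str = "1", axial_length_cm: float = 40.0) -> VolumeModelSpec:
    """Parallel-slab model with the standard layer stack."""
    return build_model("PM", standard_layers(stack), axial_length_cm)


def place_electrodes(
    model: VolumeModelSpec,
    site: str,
    area_cm2: float,
    gap_cm: float,
    centerline_z_cm: float = 0.0,
) -> ElectrodePair:
    """Place a square electrode pair on the skin surface at one site.

    On the cylindrical representations the square is geodesic (wrapped on
    the skin cylinder, side measured on the surface); on the PM it is a
    planar square on the top face.  Areas outside [1, 25] cm² or gaps
    outside [0, 6] cm are accepted with a warning.
    """
    pair = ElectrodePair(site=site, area_cm2=area_cm2, gap_cm=gap_cm,
                         centerline_z_cm=centerline_z_cm)
    if not 1.0 <= area_cm2 <= 25.0:
        warnings.warn(
            f"electrode area {area_cm2} cm² outside the studied range [1, 25] cm²",
            stacklevel=2,
        )
    if not 0.0 <= gap_cm <= 6.0:
        warnings.warn(
            f"interelectrode distance {gap_cm} cm outside the studied range [0, 6] cm",
            stacklevel=2,
        )
    side = pair.side_cm
    if model.representation in ("CM", "PSEUDO_AM"):
        arc = side / model.outer_radius_cm  # radians subtended on the skin
        if arc > math.pi / 2.0:
            raise ValueError(
                f"electrode side {side:.2f} cm subtends {math.degrees(arc):.0f}° "
                "on the skin cylinder (more than one quadrant)"
            )
    else:
        if side > model.width_cm:
            raise ValueError("electrode side exceeds the slab width")
    z_extent = abs(centerline_z_cm) + gap_cm / 2.0 + side
    if z_extent > model.axial_length_cm / 2.0:
        raise ValueError("electrode pair extends beyond the model ends")
    return pair


def fiber_axis_xy(
    model: VolumeModelSpec,
    placement: FiberPlacement,
    electrodes: ElectrodePair,
) -> tuple[float, float]:
    """Transverse (x, y) position of the fibre axis, metres.

    The fibre runs parallel to z at ``placement.depth_mm`` below the local
    fat–muscle boundary of the placement site, evaluated under the cathode
    patch centre.
    """
    if placement.site != electrodes.site:
        raise ValueError("fibre placement and electrode pair must share a site")
    if model.representation == "PM":
        y = model.layer_radii_cm[2] * 1e-2 - placement.depth_mm * 1e-3
        return (0.0, y)
    th = SITE_ANGLES_RAD[placement.site]
    z_c = electrodes.cathode_center_z_cm * 1e-2
    r_b = float(model.boundary_radius_m("muscle_outer", th, z_c))
    r_f = r_b - placement.depth_mm * 1e-3
    return (r_f * math.cos(th), r_f * math.sin(th))


def fiber_trajectory(
    model: VolumeModelSpec,
    placement: FiberPlacement,
    electrodes: ElectrodePair,
    step_mm: float = FIBER_SAMPLING_STEP_MM,
) -> np.ndarray:
    """Sample points along the fibre at fixed axial spacing, metres.

    Points are spaced ``step_mm`` along z, centred under the cathode patch
    centre, at ``placement.depth_mm`` below the local fat–muscle boundary.
    The trajectory must lie entirely inside the muscle; the first offending
    arclength is reported otherwise.
    """
    n = round(placement.length_mm / step_mm) + 1
    z_c = electrodes.cathode_center_z_cm * 1e-2
    z = z_c + (np.arange(n) - (n - 1) / 2.0) * step_mm * 1e-3
    x, y = fiber_axis_xy(model, placement, electrodes)
    pts = np.column_stack([np.full(n, x), np.full(n, y), z])
    labels = model.tissue_at(pts)
    bad = np.nonzero(labels != "muscle")[0]
    if bad.size:
        s_mm = bad[0] * step_mm
        raise ValueError(
            f"fibre trajectory leaves the muscle domain at arclength {s_mm:.1f} mm "
            f"(tissue {labels[bad[0]]!r})"
        )
    return pts
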