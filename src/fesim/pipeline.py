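"""Model-representation comparison experiments.

Drives the two-step pipeline (field solve → fibre activation threshold)
over sweeps of electrode size, interelectrode distance, stimulation site,
fibre diameter and depth, for several volume-conductor representations;
tabulates activation thresholds and activation errors against a flagged
reference model; and provides the projection-based geometry metrics
(average fat thickness, bone-to-muscle distance) together with the
geometry-adjustment operation used in the fat/bone matching study.

Tables are tidy :class:`pandas.DataFrame` objects with a stable column
schema (see :data:`THRESHOLD_COLUMNS` / :data:`ERROR_COLUMNS`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import (
    SITE_ANGLES_RAD,
    FiberPlacement,
    TissueLayer,
    VolumeModelSpec,
    place_electrodes,
)
from .field import SolveCounter, discretize, solve_unit_field
from .fiber import StimulusWaveform, build_fiber, node_positions_m
from .threshold import find_threshold

__all__ = [
    "SweepSpec",
    "run_sweep",
    "activation_error",
    "error_table",
    "cross_correlate",
    "average_fat_thickness",
    "average_bone_to_muscle_distance",
    "adjust_geometry",
    "THRESHOLD_COLUMNS",
    "ERROR_COLUMNS",
]

THRESHOLD_COLUMNS = [
    "model", "site", "area_cm2", "gap_cm", "diameter_um", "depth_mm",
    "threshold_mA", "out_of_range", "status", "reason",
    "n_field_solves", "n_fiber_sims", "dof", "solve_seconds", "solve_iterations",
]

ERROR_COLUMNS = [
    "site", "area_cm2", "gap_cm", "diameter_um", "depth_mm", "model",
    "threshold_mA", "reference_mA", "error_pct", "signed_error_pct",
]

#: Key columns identifying one sweep configuration.
KEY_COLUMNS = ["model", "site", "area_cm2", "gap_cm", "diameter_um", "depth_mm"]


@dataclass(frozen=True)
class SweepSpec:
    """A full sweep definition over models × electrode/fibre parameters.

    ``models`` maps a name to a :class:`VolumeModelSpec`; ``reference``
    names exactly one of them as the reference for activation errors.
    """

    models: dict
    reference: str | None
    sites: tuple = ("anterior",)
    electrode_areas_cm2: tuple = (9.0,)
    gaps_cm: tuple = (4.0,)
    fiber_diameters_um: tuple = (12.0,)
    depths_mm: tuple = (5.0,)
    waveform: StimulusWaveform = field(default_factory=StimulusWaveform)
    electrode_mode: str = "equipotential"
    resolution_level: int = 0
    mesh: dict | None = None

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("need at least one model")
        if self.reference is not None and self.reference not in self.models:
            raise ValueError(f"reference {self.reference!r} not among the models")
        for name, vals in (
            ("sites", self.sites),
            ("electrode_areas_cm2", self.electrode_areas_cm2),
            ("gaps_cm", self.gaps_cm),
            ("fiber_diameters_um", self.fiber_diameters_um),
            ("depths_mm", self.depths_mm),
        ):
            if len(tuple(vals)) == 0:
                raise ValueError(f"{name} must be non-empty")


def run_sweep(spec: SweepSpec, counter: SolveCounter | None = None,
              verbose: bool = False) -> pd.DataFrame:
    """Compute one activation threshold per sweep configuration.

    One field solve is performed per (model, site, area, gap) geometry and
    reused across fibre diameters and depths (amplitude scaling is exact by
    linearity).  Individual failures are recorded as rows with
    ``status="failed"`` and a reason; they never abort the sweep.  Row order
    is deterministic.
    """
    counter = counter if counter is not None else SolveCounter()
    rows = []
    for model_name, model in spec.models.items():
        for site in spec.sites:
            for area in spec.electrode_areas_cm2:
                for gap in spec.gaps_cm:
                    rows.extend(_sweep_one_geometry(
                        spec, model_name, model, site, area, gap, counter,
                        verbose=verbose,
                    ))
    df = pd.DataFrame(rows, columns=THRESHOLD_COLUMNS)
    dup = df.duplicated(subset=KEY_COLUMNS)
    if dup.any():
        raise RuntimeError("duplicate sweep keys generated")
    return df


def _sweep_one_geometry(spec, model_name, model, site, area, gap, counter,
                        verbose=False):
    rows = []
    base = dict(model=model_name, site=site, area_cm2=area, gap_cm=gap,
                n_field_solves=0, n_fiber_sims=0, dof=0,
                solve_seconds=np.nan, solve_iterations=0)

    def failed_rows(reason):
        for diam in spec.fiber_diameters_um:
            for depth in spec.depths_mm:
                rows.append({**base, "diameter_um": diam, "depth_mm": depth,
                             "threshold_mA": np.nan, "out_of_range": None,
                             "status": "failed", "reason": reason})
        return rows

    try:
        electrodes = place_electrodes(model, site, area, gap)
        domain = discretize(model, electrodes,
                            resolution_level=spec.resolution_level,
                            mesh=spec.mesh)
        solution = solve_unit_field(domain, mode=spec.electrode_mode,
                                    counter=counter)
    except Exception as exc:  # recorded, never aborts the sweep
        return failed_rows(f"{type(exc).__name__}: {exc}")
    solves_for_geometry = 1
    base.update(solve_seconds=round(solution.solve_seconds, 3),
                solve_iterations=solution.iterations)
    for diam in spec.fiber_diameters_um:
        fiber = build_fiber(diam)
        for depth in spec.depths_mm:
            row = {**base, "diameter_um": diam, "depth_mm": depth,
                   "n_field_solves": solves_for_geometry, "dof": domain.n_dof}
            try:
                placement = FiberPlacement(site=site, depth_mm=depth,
                                           diameter_um=diam)
                nodes = node_positions_m(model, placement, electrodes, fiber)
                profile = solution.sample_fiber_profile(nodes)
                res = find_threshold(profile, fiber, spec.waveform)
                row.update(threshold_mA=res.threshold_mA,
                           out_of_range=res.out_of_range,
                           n_fiber_sims=res.n_fiber_sims,
                           status="ok" if res.in_range else "out_of_range",
                           reason=None)
            except Exception as exc:
                row.update(threshold_mA=np.nan, out_of_range=None,
                           status="failed", reason=f"{type(exc).__name__}: {exc}")
            rows.append(row)
            if verbose:
                print(f"[sweep] {row['model']} {site} {area}cm2 {gap}cm "
                      f"{diam}um {depth}mm -> {row['threshold_mA']}")
    return rows


def activation_error(threshold_test_mA: float, threshold_ref_mA: float,
                     signed: bool = False) -> float:
    """Relative activation error of a model against the reference, percent.

    Unsigned by default: 100·|I_test − I_ref| / I_ref.  The signed variant
    is positive when the model under study overestimates the reference.
    """
    if not threshold_ref_mA > 0.0:
        raise ValueError("reference threshold must be positive")
    if not threshold_test_mA > 0.0:
        raise ValueError("test threshold must be positive")
    err = 100.0 * (threshold_test_mA - threshold_ref_mA) / threshold_ref_mA
    return err if signed else abs(err)


def error_table(thresholds: pd.DataFrame, reference: str) -> pd.DataFrame:
    """Activation errors of every non-reference model against the reference.

    Deterministic and idempotent: regenerating from the same threshold
    table gives an identical result.  Configurations missing a usable
    threshold on either side appear with NaN error (the threshold table
    carries the reason); reference rows are absent.
    """
    if reference not in set(thresholds["model"]):
        raise ValueError(f"reference model {reference!r} not in table")
    keys = [c for c in KEY_COLUMNS if c != "model"]
    ref = thresholds[thresholds["model"] == reference]
    ref = ref.set_index(keys)["threshold_mA"]
    rows = []
    test = thresholds[thresholds["model"] != reference]
    for _, r in test.iterrows():
        key = tuple(r[k] for k in keys)
        ref_thr = ref.get(key, np.nan)
        t_thr = r["threshold_mA"]
        if np.isfinite(t_thr) and np.isfinite(ref_thr) and ref_thr > 0:
            signed = activation_error(t_thr, ref_thr, signed=True)
            err = abs(signed)
        else:
            signed = err = np.nan
        rows.append(dict(
            **{k: r[k] for k in keys}, model=r["model"],
            threshold_mA=t_thr, reference_mA=ref_thr,
            error_pct=err, signed_error_pct=signed,
        ))
    return pd.DataFrame(rows, columns=ERROR_COLUMNS)


def cross_correlate(curve_a, curve_b) -> float:
    """Zero-lag normalized (Pearson) correlation of two threshold curves.

    The curves must live on the identical parameter grid (length ≥ 3).
    Constant curves have no defined correlation → NaN.
    """
    a = np.asarray(curve_a, dtype=float)
    b = np.asarray(curve_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("curves must be 1-D and share the same grid")
    if len(a) < 3:
        raise ValueError("need at least 3 points")
    da, db = a - a.mean(), b - b.mean()
    na, nb = np.linalg.norm(da), np.linalg.norm(db)
    if na == 0.0 or nb == 0.0:
        return float("nan")
    return float(np.dot(da, db) / (na * nb))


# ---------------------------------------------------------------------------
# projection-based geometry metrics and the adjustment study
# ---------------------------------------------------------------------------


def _z_samples(model: VolumeModelSpec, z_range_cm) -> np.ndarray:
    z_lo, z_hi = (z * 1e-2 for z in z_range_cm)
    half = model.axial_length_cm * 1e-2 / 2.0
    if z_lo > z_hi:
        raise ValueError("empty z range")
    if z_lo < -half - 1e-12 or z_hi > half + 1e-12:
        raise ValueError(
            f"z range ({z_range_cm[0]}, {z_range_cm[1]}) cm outside the model "
            f"(±{half * 100:.0f} cm)"
        )
    if z_hi == z_lo:
        return np.array([z_lo])
    return np.linspace(z_lo, z_hi, 201)


def average_fat_thickness(model: VolumeModelSpec, site: str,
                          z_range_cm=(-5.0, 5.0)) -> float:
    """Mean radial fat-layer thickness along the site's projection ray, mm.

    The fat boundaries are projected on the plane containing the limb axis
    and the site direction; the thickness profile is averaged over z within
    ``z_range_cm`` (the window covered by the electrode variations).
    """
    if site not in SITE_ANGLES_RAD:
        raise ValueError(f"unknown site {site!r}")
    if model.representation == "PM":
        return model.layer_by_name("fat").thickness_cm * 10.0
    z = _z_samples(model, z_range_cm)
    th = SITE_ANGLES_RAD[site]
    outer = model.boundary_radius_m("fat_outer", th, z)
    inner = model.boundary_radius_m("muscle_outer", th, z)
    return float(np.mean(outer - inner) * 1e3)


def average_bone_to_muscle_distance(model: VolumeModelSpec, site: str,
                                    z_range_cm=(-5.0, 5.0)) -> float:
    """Mean distance from the bone surface to the fat–muscle boundary along
    the site's projection ray, mm."""
    if site not in SITE_ANGLES_RAD:
        raise ValueError(f"unknown site {site!r}")
    if model.representation == "PM":
        return model.layer_by_name("muscle").thickness_cm * 10.0
    z = _z_samples(model, z_range_cm)
    th = SITE_ANGLES_RAD[site]
    u = np.array([math.cos(th), math.sin(th)])
    c = np.asarray(model.bone_offset_mm) * 1e-3
    r_bone = model.base_boundary_radius_cm("bone_outer") * 1e-2
    along = float(np.dot(c, u))
    perp2 = float(np.dot(c, c)) - along * along
    if r_bone * r_bone <= perp2:
        raise ValueError("bone does not intersect the site's projection ray")
    t_bone = along + math.sqrt(r_bone * r_bone - perp2)
    boundary = model.boundary_radius_m("muscle_outer", th, z)
    return float(np.mean(boundary - t_bone) * 1e3)


def adjust_geometry(model: VolumeModelSpec, site: str,
                    target_fat_mm: float | None = None,
                    target_bone_mm: float | None = None,
                    z_range_cm=(-5.0, 5.0)) -> VolumeModelSpec:
    """Adjust fat thickness and/or bone position to match target metrics.

    Fat: the fat layer thickness changes uniformly, compensated in the
    muscle layer so the outer radius is preserved.  Bone: the marrow +
    cortical bone pair translates along the site direction.  The returned
    specification re-measures to the targets (within numerical tolerance);
    infeasible targets are rejected by model validation.
    """
    out = model
    if target_fat_mm is not None:
        current = average_fat_thickness(out, site, z_range_cm)
        delta_cm = (target_fat_mm - current) / 10.0
        new_layers = []
        for layer in out.layers:
            if layer.name == "fat":
                new_layers.append(replace(layer, thickness_cm=layer.thickness_cm + delta_cm))
            elif layer.name == "muscle":
                new_layers.append(replace(layer, thickness_cm=layer.thickness_cm - delta_cm))
            else:
                new_layers.append(layer)
        out = replace(out, layers=tuple(new_layers))
    if target_bone_mm is not None:
        current = average_bone_to_muscle_distance(out, site, z_range_cm)
        shift = current - target_bone_mm  # move toward the site to reduce
        th = SITE_ANGLES_RAD[site]
        off = (out.bone_offset_mm[0] + shift * math.cos(th),
               out.bone_offset_mm[1] + shift * math.sin(th))
        out = replace(out, bone_offset_mm=off)
    return out
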