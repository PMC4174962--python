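"""Structured text configuration for models, electrodes, fibres and runs.

The on-disk format is YAML (key/value with nested sections).  A run
configuration has up to four sections::

    model:        # or `anatomy:` to generate a PSEUDO_AM from parameters
      representation: CM
      stack: "1"              # Table-stack shortcut; or explicit `layers:`
      axial_length_cm: 40.0
    electrodes:
      site: anterior
      area_cm2: 9.0
      gap_cm: 4.0
    fiber:
      diameter_um: 12.0
      depth_mm: 5.0
    waveform:
      pulse_width_ms: 0.5

Parse errors report the YAML line; validation errors name the offending
key path.  ``model_to_dict``/``model_from_dict`` round-trip a full
:class:`VolumeModelSpec` including perturbation harmonics and inclusions.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

from .anatomy import AnatomyParams, generate_pseudo_anatomy
from .fiber import StimulusWaveform
from .geometry import (
    CANONICAL_LAYER_ORDER,
    ElectrodePair,
    FiberPlacement,
    InclusionSpec,
    PerturbationHarmonic,
    TissueLayer,
    VolumeModelSpec,
    build_model,
    place_electrodes,
    standard_layers,
)
from .tissues import ConductivityTensor, conductivity_of

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_run_config",
    "parse_run_config",
    "model_from_dict",
    "model_to_dict",
    "save_model",
    "load_model",
]


class ConfigError(ValueError):
    """A configuration problem, carrying the key path it was found at."""

    def __init__(self, path: str, message: str):
        super().__init__(f"{path}: {message}")
        self.path = path


@dataclass
class RunConfig:
    model: VolumeModelSpec
    electrodes: ElectrodePair | None
    placement: FiberPlacement | None
    waveform: StimulusWaveform


def _require(mapping: dict, key: str, path: str):
    if key not in mapping:
        raise ConfigError(path, f"missing required key {key!r}")
    return mapping[key]


def _check_keys(mapping: dict, allowed: set, path: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(path, f"unknown keys {sorted(unknown)}; "
                                f"allowed: {sorted(allowed)}")


def _conductivity_from(d, path: str) -> ConductivityTensor:
    if isinstance(d, (int, float)):
        return ConductivityTensor.iso(float(d))
    _check_keys(d, {"transverse_mS_per_m", "longitudinal_mS_per_m"}, path)
    t = float(_require(d, "transverse_mS_per_m", path))
    l = float(d.get("longitudinal_mS_per_m", t))
    return ConductivityTensor(t, l)


def model_from_dict(d: dict, path: str = "model") -> VolumeModelSpec:
    _check_keys(d, {"representation", "stack", "layers", "axial_length_cm",
                    "inclusions", "perturbation", "bone_offset_mm",
                    "slab_width_cm"}, path)
    rep = _require(d, "representation", path)
    if "layers" in d:
        layers = []
        for i, ld in enumerate(d["layers"]):
            lp = f"{path}.layers[{i}]"
            _check_keys(ld, {"name", "thickness_cm", "conductivity"}, lp)
            name = _require(ld, "name", lp)
            if name not in CANONICAL_LAYER_ORDER:
                raise ConfigError(lp, f"unknown tissue {name!r}")
            cond = (_conductivity_from(ld["conductivity"], lp + ".conductivity")
                    if "conductivity" in ld else conductivity_of(name))
            layers.append(TissueLayer(name, float(_require(ld, "thickness_cm", lp)),
                                      cond))
    else:
        layers = list(standard_layers(str(d.get("stack", "1"))))
    inclusions = []
    for i, idict in enumerate(d.get("inclusions", []) or []):
        ip = f"{path}.inclusions[{i}]"
        _check_keys(idict, {"kind", "axis_offset_mm", "radius_mm", "conductivity"}, ip)
        kind = _require(idict, "kind", ip)
        default_tissue = "blood" if kind == "blood_vessel" else "nerve"
        cond = (_conductivity_from(idict["conductivity"], ip + ".conductivity")
                if "conductivity" in idict else conductivity_of(default_tissue))
        inclusions.append(InclusionSpec(
            kind=kind,
            axis_offset_mm=tuple(float(v) for v in _require(idict, "axis_offset_mm", ip)),
            radius_mm=float(_require(idict, "radius_mm", ip)),
            conductivity=cond,
        ))
    perturbation = {}
    for boundary, harmonics in (d.get("perturbation") or {}).items():
        hs = []
        for i, hd in enumerate(harmonics):
            hp = f"{path}.perturbation.{boundary}[{i}]"
            _check_keys(hd, {"amplitude_mm", "theta_order", "theta_phase",
                             "z_order", "z_phase"}, hp)
            hs.append(PerturbationHarmonic(
                amplitude_mm=float(_require(hd, "amplitude_mm", hp)),
                theta_order=int(hd.get("theta_order", 0)),
                theta_phase=float(hd.get("theta_phase", 0.0)),
                z_order=int(hd.get("z_order", 0)),
                z_phase=float(hd.get("z_phase", 0.0)),
            ))
        perturbation[boundary] = tuple(hs)
    try:
        return build_model(
            representation=rep,
            layers=layers,
            axial_length_cm=float(d.get("axial_length_cm", 40.0)),
            inclusions=inclusions,
            perturbation=perturbation,
            bone_offset_mm=tuple(float(v) for v in d.get("bone_offset_mm", (0.0, 0.0))),
            slab_width_cm=d.get("slab_width_cm"),
        )
    except ValueError as exc:
        raise ConfigError(path, str(exc)) from exc


def model_to_dict(model: VolumeModelSpec) -> dict:
    d = {
        "representation": model.representation,
        "axial_length_cm": model.axial_length_cm,
        "layers": [
            {"name": l.name, "thickness_cm": l.thickness_cm,
             "conductivity": {"transverse_mS_per_m": l.conductivity.transverse,
                              "longitudinal_mS_per_m": l.conductivity.longitudinal}}
            for l in model.layers
        ],
    }
    if model.inclusions:
        d["inclusions"] = [
            {"kind": inc.kind, "axis_offset_mm": list(inc.axis_offset_mm),
             "radius_mm": inc.radius_mm,
             "conductivity": {"transverse_mS_per_m": inc.conductivity.transverse,
                              "longitudinal_mS_per_m": inc.conductivity.longitudinal}}
            for inc in model.inclusions
        ]
    if model.perturbation:
        d["perturbation"] = {
            boundary: [
                {"amplitude_mm": h.amplitude_mm, "theta_order": h.theta_order,
                 "theta_phase": h.theta_phase, "z_order": h.z_order,
                 "z_phase": h.z_phase}
                for h in harmonics
            ]
            for boundary, harmonics in model.perturbation.items()
        }
    if model.bone_offset_mm != (0.0, 0.0):
        d["bone_offset_mm"] = list(model.bone_offset_mm)
    if model.slab_width_cm is not None:
        d["slab_width_cm"] = model.slab_width_cm
    return d


def save_model(model: VolumeModelSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"model": model_to_dict(model)}, fh, sort_keys=False)


def load_model(path) -> VolumeModelSpec:
    return parse_run_config(_load_yaml(path)).model


def _load_yaml(path) -> dict:
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.MarkedYAMLError as exc:
            mark = exc.problem_mark
            where = f"line {mark.line + 1}" if mark else "unknown location"
            raise ConfigError(str(path), f"YAML parse error at {where}: "
                                         f"{exc.problem}") from exc
    if not isinstance(data, dict):
        raise ConfigError(str(path), "top level must be a mapping")
    return data


def parse_run_config(data: dict) -> RunConfig:
    _check_keys(data, {"model", "anatomy", "electrodes", "fiber", "waveform"}, "$")
    if ("model" in data) == ("anatomy" in data):
        raise ConfigError("$", "exactly one of 'model' or 'anatomy' is required")
    if "model" in data:
        model = model_from_dict(data["model"])
    else:
        ad = dict(data["anatomy"])
        path = "anatomy"
        allowed = set(AnatomyParams.__dataclass_fields__)
        _check_keys(ad, allowed, path)
        if "bone_offset_mm" in ad:
            ad["bone_offset_mm"] = tuple(float(v) for v in ad["bone_offset_mm"])
        try:
            model = generate_pseudo_anatomy(AnatomyParams(**ad))
        except ValueError as exc:
            raise ConfigError(path, str(exc)) from exc

    electrodes = None
    if "electrodes" in data:
        ed = data["electrodes"]
        _check_keys(ed, {"site", "area_cm2", "gap_cm", "centerline_z_cm"},
                    "electrodes")
        try:
            electrodes = place_electrodes(
                model,
                _require(ed, "site", "electrodes"),
                float(_require(ed, "area_cm2", "electrodes")),
                float(_require(ed, "gap_cm", "electrodes")),
                centerline_z_cm=float(ed.get("centerline_z_cm", 0.0)),
            )
        except ValueError as exc:
            raise ConfigError("electrodes", str(exc)) from exc

    placement = None
    if "fiber" in data:
        fd = data["fiber"]
        _check_keys(fd, {"site", "diameter_um", "depth_mm", "length_mm"}, "fiber")
        site = fd.get("site") or (electrodes.site if electrodes else None)
        if site is None:
            raise ConfigError("fiber", "no site given and no electrodes section")
        try:
            placement = FiberPlacement(
                site=site,
                depth_mm=float(fd.get("depth_mm", 5.0)),
                diameter_um=float(_require(fd, "diameter_um", "fiber")),
                length_mm=float(fd.get("length_mm", 63.0)),
            )
        except ValueError as exc:
            raise ConfigError("fiber", str(exc)) from exc

    wd = data.get("waveform", {})
    _check_keys(wd, {"amplitude_mA", "pulse_width_ms", "total_duration_ms",
                     "polarity"}, "waveform")
    try:
        waveform = StimulusWaveform(
            amplitude_mA=float(wd.get("amplitude_mA", 0.0)),
            pulse_width_ms=float(wd.get("pulse_width_ms", 0.5)),
            total_duration_ms=float(wd.get("total_duration_ms", 2.0)),
            polarity=wd.get("polarity", "cathodic"),
        )
    except ValueError as exc:
        raise ConfigError("waveform", str(exc)) from exc
    return RunConfig(model=model, electrodes=electrodes, placement=placement,
                     waveform=waveform)


def load_run_config(path) -> RunConfig:
    """Load and validate a run configuration file."""
    return parse_run_config(_load_yaml(path))
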