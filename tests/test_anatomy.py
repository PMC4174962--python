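"""Pseudo-anatomy generator: determinism, ratios, clearances, depth series."""

import math

import numpy as np
import pytest

import fesim as f
from fesim.anatomy import AnatomyParams, depth_series, generate_pseudo_anatomy
from fesim.config import model_to_dict


class TestGenerator:
    def test_same_seed_identical_specs(self):
        a = generate_pseudo_anatomy(AnatomyParams(seed=11))
        b = generate_pseudo_anatomy(AnatomyParams(seed=11))
        assert model_to_dict(a) == model_to_dict(b)
        assert a.provenance["params_digest"] == b.provenance["params_digest"]

    def test_different_seed_different_boundaries(self):
        a = generate_pseudo_anatomy(AnatomyParams(seed=11))
        b = generate_pseudo_anatomy(AnatomyParams(seed=12))
        assert model_to_dict(a) != model_to_dict(b)

    def test_ablated_variant_differs_only_by_inclusions(self, pseudo_am_pair):
        full, ablated = pseudo_am_pair
        assert ablated.inclusions == ()
        d_full = model_to_dict(full)
        d_abl = model_to_dict(ablated)
        d_full.pop("inclusions")
        assert d_full == d_abl
        assert (full.provenance["mesh_hint_inclusions"]
                == ablated.provenance["mesh_hint_inclusions"])

    def test_vessel_area_is_16_percent_of_bone_disk(self, pseudo_am_pair):
        full, _ = pseudo_am_pair
        r_bone_mm = full.base_boundary_radius_cm("bone_outer") * 10.0
        vessel = next(i for i in full.inclusions if i.kind == "blood_vessel")
        nerve = next(i for i in full.inclusions if i.kind == "nerve_trunk")
        assert math.pi * vessel.radius_mm ** 2 == pytest.approx(
            0.16 * math.pi * r_bone_mm ** 2, rel=1e-9)
        assert math.pi * nerve.radius_mm ** 2 == pytest.approx(
            0.06 * math.pi * r_bone_mm ** 2, rel=1e-9)

    def test_inclusion_surface_distances(self, pseudo_am_pair):
        full, _ = pseudo_am_pair
        for kind, site_angle, dist in (
            ("blood_vessel", math.pi, 20.17),
            ("nerve_trunk", 1.5 * math.pi, 30.07),
        ):
            inc = next(i for i in full.inclusions if i.kind == kind)
            r_b = float(full.boundary_radius_m("muscle_outer", site_angle, 0.0)) * 1e3
            r_centre = math.hypot(*inc.axis_offset_mm)
            assert r_b - r_centre - inc.radius_mm == pytest.approx(dist, abs=1e-9)

    def test_conductivities_from_tissue_table(self, pseudo_am_pair):
        full, _ = pseudo_am_pair
        vessel = next(i for i in full.inclusions if i.kind == "blood_vessel")
        nerve = next(i for i in full.inclusions if i.kind == "nerve_trunk")
        assert vessel.conductivity.transverse == pytest.approx(700.0)
        assert nerve.conductivity.transverse == pytest.approx(29.89)

    def test_infeasible_clearance_rejected(self):
        # pushing the vessel deep makes it collide with the bone
        with pytest.raises(ValueError, match="clearance"):
            generate_pseudo_anatomy(AnatomyParams(seed=1, vessel_distance_mm=32.0))

    def test_boundaries_stay_nested(self, pseudo_am_pair):
        full, _ = pseudo_am_pair
        theta = np.linspace(0, 2 * math.pi, 720)
        r_mus = full.boundary_radius_m("muscle_outer", theta, 0.0)
        r_fat = full.boundary_radius_m("fat_outer", theta, 0.0)
        r_skin = full.base_boundary_radius_cm("skin_outer") * 1e-2
        assert np.all(r_mus < r_fat)
        assert np.all(r_fat < r_skin)


class TestDepthSeries:
    def test_valid_depths_on_cm1(self, cm1, cm1_electrodes):
        el = f.place_electrodes(cm1, "medial", 9.0, 4.0)
        series = depth_series(cm1, "medial", (5.0, 10.0, 15.0, 20.0), 12.0, el)
        assert len(series) == 4
        assert all(d.valid for d in series)

    def test_depth_beyond_muscle_flagged(self, cm1):
        el = f.place_electrodes(cm1, "medial", 9.0, 4.0)
        series = depth_series(cm1, "medial", (50.0,), 12.0, el)
        assert not series[0].valid
        assert "muscle" in series[0].reason

    def test_depth_grazing_vessel_flagged(self, pseudo_am_pair):
        full, _ = pseudo_am_pair
        el = f.place_electrodes(full, "medial", 9.0, 4.0)
        vessel = next(i for i in full.inclusions if i.kind == "blood_vessel")
        r_b = float(full.boundary_radius_m(
            "muscle_outer", math.pi, el.cathode_center_z_cm * 1e-2)) * 1e3
        graze_depth = r_b - math.hypot(*vessel.axis_offset_mm) - vessel.radius_mm - 0.2
        series = depth_series(full, "medial", (graze_depth,), 12.0, el)
        assert not series[0].valid
        assert "inclusion" in series[0].reason

    def test_ablated_variant_flags_via_mesh_hints(self, pseudo_am_pair):
        # the (VN)' variant carries no inclusions but remembers where they
        # were, so depth series stay comparable between the two models
        full, ablated = pseudo_am_pair
        el = f.place_electrodes(ablated, "medial", 9.0, 4.0)
        vessel_hint = ablated.provenance["mesh_hint_inclusions"][0]
        r_b = float(ablated.boundary_radius_m(
            "muscle_outer", math.pi, el.cathode_center_z_cm * 1e-2)) * 1e3
        graze = r_b - math.hypot(vessel_hint[0], vessel_hint[1]) - vessel_hint[2] - 0.2
        series = depth_series(ablated, "medial", (graze,), 12.0, el)
        assert not series[0].valid
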