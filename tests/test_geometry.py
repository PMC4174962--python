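"""Geometry construction: layer stacks, electrodes, fibre trajectories."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import fesim as f
from fesim.geometry import compute_layer_radii, standard_layers
from fesim.tissues import ConductivityTensor, conductivity_of


class TestLayerRadii:
    @pytest.mark.parametrize("stack, expected", [
        ("1", (0.87, 1.50, 5.82, 7.06, 7.26)),
        ("2", (0.94, 1.51, 6.53, 8.26, 8.46)),
    ])
    def test_standard_stacks_cumulative_radii(self, stack, expected):
        radii = compute_layer_radii(standard_layers(stack))
        assert radii == pytest.approx(expected, abs=1e-12)

    def test_single_layer_is_identity(self):
        layer = f.TissueLayer("muscle", 4.32, conductivity_of("muscle"))
        assert compute_layer_radii([layer]) == pytest.approx([4.32])

    def test_non_positive_thickness_names_offender(self):
        layers = list(standard_layers("1"))
        object.__setattr__(layers[2], "thickness_cm", -1.0)  # bypass ctor check
        with pytest.raises(ValueError, match="muscle"):
            compute_layer_radii(layers)

    @given(st.lists(st.floats(0.05, 5.0), min_size=1, max_size=5))
    def test_radii_increase_and_sum(self, thicknesses):
        names = ("bone_marrow", "cortical_bone", "muscle", "fat", "skin")
        layers = [f.TissueLayer(n, t, ConductivityTensor.iso(10.0))
                  for n, t in zip(names, thicknesses)]
        radii = compute_layer_radii(layers)
        assert np.all(np.diff(radii) > 0) or len(radii) == 1
        assert radii[-1] == pytest.approx(sum(thicknesses), rel=1e-12)


class TestConductivities:
    def test_skin_is_isotropic_low(self):
        t = conductivity_of("skin")
        assert t.isotropic and t.transverse == pytest.approx(0.790)

    def test_muscle_is_anisotropic_along_z(self):
        t = conductivity_of("muscle")
        assert not t.isotropic
        assert t.transverse == pytest.approx(82.38)
        assert t.longitudinal == pytest.approx(329.53)

    def test_blood_value(self):
        assert conductivity_of("blood").transverse == pytest.approx(700.0)

    def test_unknown_tissue_rejected(self):
        with pytest.raises(KeyError, match="cartilage"):
            conductivity_of("cartilage")

    def test_non_positive_conductivity_rejected(self):
        with pytest.raises(ValueError):
            ConductivityTensor(0.0, 100.0)


class TestBuildModel:
    def test_cm1_is_valid(self, cm1):
        assert cm1.representation == "CM"
        assert cm1.outer_radius_cm == pytest.approx(7.26)

    def test_cm_with_inclusion_rejected(self):
        inc = f.InclusionSpec("blood_vessel", (-30.0, 0.0), 6.0,
                              conductivity_of("blood"))
        with pytest.raises(ValueError, match="inclusion-free"):
            f.build_model("CM", standard_layers("1"), inclusions=[inc])

    def test_inclusion_crossing_muscle_boundary_rejected(self):
        # a vessel reaching past the fat-muscle boundary is not in muscle
        inc = f.InclusionSpec("blood_vessel", (-54.0, 0.0), 8.0,
                              conductivity_of("blood"))
        with pytest.raises(ValueError, match="muscle"):
            f.build_model("PSEUDO_AM", standard_layers("1"), inclusions=[inc])

    def test_wrong_layer_order_rejected(self):
        layers = standard_layers("1")[::-1]
        with pytest.raises(ValueError, match="order"):
            f.build_model("CM", layers)

    def test_pm_slab_width_matches_half_circumference(self, pm1, cm1):
        assert pm1.width_cm == pytest.approx(math.pi * cm1.outer_radius_cm)


class TestElectrodes:
    def test_side_is_sqrt_of_area(self, cm1):
        el = f.place_electrodes(cm1, "anterior", 25.0, 4.0)
        assert el.side_cm == pytest.approx(5.0)

    def test_patch_centres_separated_by_side_plus_gap(self, cm1):
        el = f.place_electrodes(cm1, "anterior", 9.0, 4.0)
        prox, dist = el.patch_center_z_cm
        assert dist - prox == pytest.approx(3.0 + 4.0)

    def test_out_of_range_area_warns_but_accepts(self, cm1):
        with pytest.warns(UserWarning, match="outside the studied range"):
            el = f.place_electrodes(cm1, "anterior", 26.0, 4.0)
        assert el.area_cm2 == 26.0

    def test_patch_exceeding_quadrant_rejected(self):
        thin = [f.TissueLayer(n, t, conductivity_of(n)) for n, t in zip(
            ("bone_marrow", "cortical_bone", "muscle", "fat", "skin"),
            (0.3, 0.3, 1.5, 0.4, 0.1))]
        small = f.build_model("CM", thin, axial_length_cm=40.0)
        with pytest.raises(ValueError, match="quadrant"):
            f.place_electrodes(small, "anterior", 25.0, 4.0)

    def test_role_swap_leaves_geometry_unchanged(self, cm1_electrodes):
        swapped = cm1_electrodes.swapped()
        assert swapped.patch_center_z_cm == cm1_electrodes.patch_center_z_cm
        assert swapped.cathode_center_z_cm == cm1_electrodes.anode_center_z_cm


class TestFiberTrajectory:
    def test_63mm_at_0p1mm_gives_631_points(self, cm1, cm1_electrodes):
        pl = f.FiberPlacement("anterior", 5.0, 12.0)
        traj = f.fiber_trajectory(cm1, pl, cm1_electrodes)
        assert traj.shape == (631, 3)

    @pytest.mark.parametrize("length_mm", [10.0, 25.3, 63.0])
    def test_point_count_rule(self, cm1, cm1_electrodes, length_mm):
        pl = f.FiberPlacement("anterior", 5.0, 12.0, length_mm=length_mm)
        traj = f.fiber_trajectory(cm1, pl, cm1_electrodes)
        assert len(traj) == round(length_mm / 0.1) + 1

    def test_depth_zero_sits_on_muscle_boundary(self, cm1, cm1_electrodes):
        pl = f.FiberPlacement("anterior", 0.0, 12.0)
        traj = f.fiber_trajectory(cm1, pl, cm1_electrodes)
        radii = np.hypot(traj[:, 0], traj[:, 1])
        assert radii == pytest.approx(5.82e-2, abs=1e-12)

    def test_midpoint_under_cathode_centre(self, cm1, cm1_electrodes):
        pl = f.FiberPlacement("anterior", 5.0, 12.0)
        traj = f.fiber_trajectory(cm1, pl, cm1_electrodes)
        mid_z = traj[len(traj) // 2, 2]
        assert mid_z == pytest.approx(cm1_electrodes.cathode_center_z_cm * 1e-2)

    def test_excessive_depth_rejected_with_arclength(self, cm1, cm1_electrodes):
        pl = f.FiberPlacement("anterior", 50.0, 12.0)
        with pytest.raises(ValueError, match="arclength"):
            f.fiber_trajectory(cm1, pl, cm1_electrodes)

    def test_site_mismatch_rejected(self, cm1, cm1_electrodes):
        pl = f.FiberPlacement("medial", 5.0, 12.0)
        with pytest.raises(ValueError, match="site"):
            f.fiber_trajectory(cm1, pl, cm1_electrodes)
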