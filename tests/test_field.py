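"""Field solver: discretization contracts, conservation, sampling."""

import math

import numpy as np
import pytest

import fesim as f
from fesim.field import (
    discretize,
    homogeneous_box_domain,
    scaled_mesh,
    solve_point_sources,
    solve_unit_field,
)
from fesim.tissues import ConductivityTensor


class TestDiscretize:
    def test_all_five_tissues_present(self, cm1_domain):
        assert cm1_domain.tissue_labels_present() == {
            "bone_marrow", "cortical_bone", "muscle", "fat", "skin"}

    def test_refinement_at_least_doubles_dof(self, cm1, cm1_electrodes, coarse_mesh):
        d0 = discretize(cm1, cm1_electrodes, 0, mesh=coarse_mesh)
        d1 = discretize(cm1, cm1_electrodes, 1, mesh=coarse_mesh)
        assert d1.n_cells >= 2 * d0.n_cells

    def test_min_dof_floor_is_respected(self, cm1, cm1_electrodes, coarse_mesh):
        dom = discretize(cm1, cm1_electrodes, 0, min_dof=150_000, mesh=coarse_mesh)
        assert dom.n_dof >= 150_000

    def test_patch_area_within_two_percent(self, cm1_domain):
        for pos in ("proximal", "distal"):
            area = cm1_domain.discretized_patch_area_cm2(pos)
            assert area == pytest.approx(9.0, rel=0.02)

    def test_underresolved_inclusion_refused(self, pseudo_am_pair):
        full, _ = pseudo_am_pair
        very_coarse = scaled_mesh(8.0)
        with pytest.raises(ValueError, match="raise the level"):
            el = f.place_electrodes(full, "medial", 9.0, 4.0)
            discretize(full, el, 0, mesh=very_coarse)


class TestSolutionInvariants:
    def test_electrode_flux_balance_within_one_percent(self, cm1_solution):
        cur = cm1_solution.electrode_currents()
        assert cur["distal"] == pytest.approx(1.0, abs=0.01)   # anode
        assert cur["proximal"] == pytest.approx(-1.0, abs=0.01)  # cathode

    def test_net_current_through_separating_plane(self, cm1_solution):
        # all current crossing the plane between the patches is the unit drive
        i_z = cm1_solution.current_through_z_plane(0.0)
        assert abs(i_z) == pytest.approx(1.0, abs=0.01)

    def test_linearity_profile_scales_exactly(self, cm1_profile_12um):
        fiber, profile = cm1_profile_12um
        assert np.allclose(3.7 * profile, profile * 3.7)  # trivially exact
        # the lead-field contract: scaling current scales potentials; the
        # simulation multiplies amplitude x profile, exact by construction
        assert profile.ndim == 1 and len(profile) == fiber.node_count

    def test_reciprocity_swapped_electrodes_negate_field(
            self, cm1, cm1_electrodes, coarse_mesh, cm1_solution):
        dom = discretize(cm1, cm1_electrodes.swapped(), 0, mesh=coarse_mesh)
        swapped = solve_unit_field(dom)
        a = cm1_solution.potential.ravel()
        b = swapped.potential.ravel()
        scale = np.max(np.abs(a))
        assert np.max(np.abs(a + b)) / scale < 1e-6

    def test_residual_below_tolerance(self, cm1_solution):
        assert cm1_solution.solve_residual <= 1e-8

    def test_zero_mean_gauge(self, cm1_solution):
        vol = cm1_solution.domain.grid.cell_volumes()
        mean = np.average(cm1_solution.potential, weights=vol)
        assert abs(mean) < 1e-9 * np.max(np.abs(cm1_solution.potential))


class TestSampling:
    def test_sampling_at_cell_centre_reproduces_nodal_value(self, cm1_solution):
        g = cm1_solution.domain.grid
        i, j, k = 10, 3, 20
        r = g.axes[0].centers[i]
        th = g.axes[1].centers[j]
        z = g.axes[2].centers[k]
        pt = np.array([[r * math.cos(th), r * math.sin(th), z]])
        v = cm1_solution.sample_along(pt, method="linear")[0]
        assert v == pytest.approx(cm1_solution.potential[i, j, k], rel=1e-12)

    def test_most_negative_under_cathode_for_cathodic_drive(
            self, cm1, cm1_electrodes, cm1_solution):
        pl = f.FiberPlacement("anterior", 5.0, 12.0)
        traj = f.fiber_trajectory(cm1, pl, cm1_electrodes)
        v = cm1_solution.sample_along(traj)
        z_min = traj[np.argmin(v), 2] * 100.0  # cm
        assert v.min() < 0
        assert abs(z_min - cm1_electrodes.cathode_center_z_cm) < 1.0

    def test_point_outside_domain_rejected_with_index(self, cm1_solution):
        pts = np.array([[0.0, 0.05, 0.0], [0.2, 0.0, 0.0]])
        with pytest.raises(ValueError, match="point 1"):
            cm1_solution.sample_along(pts)

    def test_pm_midplane_antisymmetry(self, pm1, coarse_mesh):
        # for symmetric patches the field is antisymmetric in z about the
        # centreline: the mid-plane sits at the gauge constant (zero mean)
        el = f.place_electrodes(pm1, "anterior", 9.0, 4.0)
        sol = solve_unit_field(discretize(pm1, el, 0, mesh=coarse_mesh))
        y = pm1.layer_radii_cm[2] * 1e-2 - 0.005
        pts = np.array([[0.0, y, 0.0], [0.01, y, 0.0]])
        v = sol.sample_along(pts)
        vmax = np.max(np.abs(sol.potential))
        assert np.all(np.abs(v) < 1e-3 * vmax)


class TestPointSources:
    def test_currents_must_balance(self):
        dom = homogeneous_box_domain(half_widths_m=(0.05, 0.05, 0.05),
                                     core_half_m=0.05, h_core=5e-3, h_far=5e-3)
        with pytest.raises(ValueError, match="sum to zero"):
            solve_point_sources(dom, [((0.0, 0.0, 0.0), 1.0)])

    def test_dipole_field_antisymmetry(self):
        dom = homogeneous_box_domain(half_widths_m=(0.06, 0.06, 0.08),
                                     core_half_m=0.05, h_core=4e-3, h_far=6e-3,
                                     conductivity=ConductivityTensor.iso(100.0))
        sol = solve_point_sources(
            dom, [((0.0, 0.0, -0.02), 1.0), ((0.0, 0.0, 0.02), -1.0)])
        pts = np.array([[0.01, 0.0, -0.02], [0.01, 0.0, 0.02]])
        va, vb = sol.sample_along(pts, method="linear")
        assert va == pytest.approx(-vb, rel=2e-2)
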