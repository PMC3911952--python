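import numpy as np
import pytest

from ureteroflow.cfd2d import (
    CFDError,
    ConvergenceError,
    SolverControls,
    advect_particles,
    build_domain,
    centerline_minima,
    centerline_speed,
    detect_eddies,
    mesh_domain,
    solve_simple,
    write_field_csv,
    write_vtk,
)
from ureteroflow.hydraulics import FluidSpec
from ureteroflow.synthetic import synth_vortex_field


class TestDomain:
    def test_default_hole_position(self):
        dom = build_domain()
        assert dom.hole_left_mm == pytest.approx(5.0)
        assert dom.hole_right_mm == pytest.approx(5.8)
        assert dom.gap_height_mm == 1.5
        assert dom.channel_length_mm == 10.8

    def test_distance_to_center_alternative(self):
        dom = build_domain(distance_to="center")
        assert dom.hole_center_x_mm == pytest.approx(5.0)

    def test_override_is_identity(self):
        dom = build_domain(gap_height_mm=1.5)
        assert dom.gap_height_mm == 1.5

    def test_hole_beyond_channel_end_rejected(self):
        with pytest.raises(CFDError):
            build_domain(occlusion_hole_distance_mm=11.0)


class TestMesh:
    def test_cell_counts(self):
        mesh = mesh_domain(build_domain(), 0.05)
        assert (mesh.nx, mesh.ny) == (216, 30)
        assert mesh.nx * mesh.ny == 6480

    def test_too_coarse_for_hole_rejected(self):
        with pytest.raises(CFDError, match="hole"):
            mesh_domain(build_domain(), 0.75)

    def test_non_divisible_spacing_rejected(self):
        with pytest.raises(CFDError):
            mesh_domain(build_domain(), 0.07)

    def test_inlet_faces_cover_hole(self):
        mesh = mesh_domain(build_domain(), 0.1)
        xc = mesh.x_centers_mm[mesh.inlet_mask]
        assert xc.min() > 5.0 and xc.max() < 5.8
        assert mesh.inlet_mask.sum() == 8  # 0.8 mm / 0.1 mm

    def test_boundary_tags(self):
        tags = mesh_domain(build_domain(), 0.1).boundary_tags()
        assert tags["left"] == "PS" and tags["right"] == "OUT"


class TestSolver:
    def test_zero_inflow_gives_quiescent_field(self):
        mesh = mesh_domain(build_domain(inlet_speed_m_s=0.0), 0.1)
        res = solve_simple(mesh)
        assert res.converged
        assert np.all(res.u == 0.0) and np.all(res.v == 0.0)

    def test_reynolds_cap_refuses_turbulent_regime(self):
        mesh = mesh_domain(build_domain(), 0.1)
        with pytest.raises(CFDError, match="Re"):
            solve_simple(mesh, v_h_m_s=5.0)

    def test_non_convergence_carries_residual_history(self):
        mesh = mesh_domain(build_domain(), 0.1)
        with pytest.raises(ConvergenceError) as exc:
            solve_simple(mesh, v_h_m_s=0.01, controls=SolverControls(max_iter=3))
        assert len(exc.value.residual_history) == 3

    def test_mass_conservation(self, coarse_flow):
        assert coarse_flow.mass_defect() < 1e-6

    def test_recirculation_in_dead_end_region(self, coarse_flow):
        eddies = detect_eddies(coarse_flow)
        dead_end = [e for e in eddies if 0.0 < e.center_x_mm < 5.0]
        assert len(dead_end) >= 1
        senses = [e.sense for e in eddies]
        assert any(a != b for a, b in zip(senses, senses[1:]))  # counter-rotating

    def test_plane_poiseuille_profile(self):
        # uniform inlet on the left develops into the parabolic closed form
        U = 0.01
        dom = build_domain(inlet_on="left", inlet_speed_m_s=U)
        mesh = mesh_domain(dom, 0.1)
        res = solve_simple(mesh)
        H = dom.gap_height_mm * 1e-3
        y = mesh.y_centers_mm * 1e-3
        exact = 6 * U * (y / H) * (1 - y / H)
        err = np.abs(res.u[-1, :] - exact).max() / exact.max()
        assert err < 0.02

    def test_poiseuille_symmetric_about_midline(self):
        dom = build_domain(inlet_on="left", inlet_speed_m_s=0.01)
        res = solve_simple(mesh_domain(dom, 0.1))
        outlet = res.u[-1, :]
        assert np.abs(outlet - outlet[::-1]).max() < 1e-3 * outlet.max()


class TestCenterline:
    def test_zero_field_gives_zero_speeds(self):
        mesh = mesh_domain(build_domain(inlet_speed_m_s=0.0), 0.1)
        res = solve_simple(mesh)
        assert all(s == 0.0 for _, s in centerline_speed(res))

    def test_poiseuille_centerline_is_peak_speed(self):
        U = 0.01
        dom = build_domain(inlet_on="left", inlet_speed_m_s=U)
        res = solve_simple(mesh_domain(dom, 0.1))
        speeds = [s for x, s in centerline_speed(res) if x > 3.0]
        assert np.allclose(speeds, 1.5 * U, rtol=0.02)

    def test_minima_mark_eddy_centres(self, coarse_flow):
        eddies = detect_eddies(coarse_flow)
        minima = centerline_minima(coarse_flow, x_max_mm=5.0)
        h = coarse_flow.mesh.spacing_mm
        for e in eddies:
            if 0 < e.center_x_mm < 5.0:
                assert min(abs(e.center_x_mm - m) for m in minima) <= 3 * h

    def test_refuses_unconverged_input(self, coarse_flow):
        import copy

        bad = copy.copy(coarse_flow)
        bad.converged = False
        with pytest.raises(CFDError):
            centerline_speed(bad)


class TestEddyDetection:
    def test_uniform_flow_has_no_eddies(self):
        dom = build_domain(inlet_on="left", inlet_speed_m_s=0.01)
        res = solve_simple(mesh_domain(dom, 0.1))
        assert detect_eddies(res) == []

    def test_recovers_synthetic_vortex_pair(self):
        mesh = mesh_domain(build_domain(), 0.05)
        field = synth_vortex_field([(2.0, 0.75), (4.0, 0.75)], [1e-6, -1e-6], mesh)
        eddies = detect_eddies(field)
        assert len(eddies) == 2
        assert eddies[0].center_x_mm == pytest.approx(2.0, abs=mesh.spacing_mm)
        assert eddies[1].center_x_mm == pytest.approx(4.0, abs=mesh.spacing_mm)
        assert eddies[0].sense == +1 and eddies[1].sense == -1

    def test_eddy_speeds_increase_with_hole_velocity(self, coarse_flow):
        from ureteroflow.cfd2d import match_eddies

        fast = solve_simple(mesh_domain(build_domain(), 0.1), v_h_m_s=0.1)
        pairs = match_eddies(detect_eddies(coarse_flow), detect_eddies(fast))
        assert pairs
        for slow_eddy, fast_eddy in pairs:
            assert fast_eddy.peak_speed_m_s > slow_eddy.peak_speed_m_s


class TestPathlines:
    def test_uniform_field_gives_straight_paths(self):
        mesh = mesh_domain(build_domain(), 0.1)
        field = synth_vortex_field([(5.4, 0.75)], [0.0], mesh)
        field.u[:, :] = 0.01  # impose a uniform stream
        paths = advect_particles(field, [(1.0, 0.75)])
        path = paths[0]
        assert np.allclose(path[:, 1], 0.75, atol=1e-9)
        assert path[-1, 0] > 10.0

    def test_seed_outside_domain_raises(self, coarse_flow):
        with pytest.raises(CFDError, match="outside"):
            advect_particles(coarse_flow, [(50.0, 0.75)])

    def test_inlet_seed_reaches_outflow(self, coarse_flow):
        paths = advect_particles(coarse_flow, [(5.4, 0.1)])
        assert paths[0][-1, 0] > 10.7

    def test_eddy_seed_stays_on_its_streamline(self, coarse_flow):
        # streamfunction level-set oracle: a closed orbit keeps psi constant
        from scipy.interpolate import RegularGridInterpolator

        eddies = [e for e in detect_eddies(coarse_flow) if 0 < e.center_x_mm < 5]
        e = max(eddies, key=lambda e: abs(e.streamfunction_m2_s))
        mesh = coarse_flow.mesh
        psi = coarse_flow.streamfunction()
        interp = RegularGridInterpolator(
            (mesh.x_faces_mm, mesh.y_faces_mm), psi
        )
        seed = (e.center_x_mm + 2 * mesh.spacing_mm, e.center_y_mm)
        path = advect_particles(coarse_flow, [seed])[0]
        values = interp(path)
        scale = abs(e.streamfunction_m2_s)
        assert np.abs(values - values[0]).max() < 0.2 * scale


class TestOutput:
    def test_vtk_and_csv_writers(self, coarse_flow, tmp_path):
        vtk = tmp_path / "f.vtk"
        csv = tmp_path / "f.csv"
        write_vtk(coarse_flow, vtk)
        write_field_csv(coarse_flow, csv)
        text = vtk.read_text()
        assert "STRUCTURED_POINTS" in text and "VECTORS velocity" in text
        header = csv.read_text().splitlines()[0]
        assert header == "x_mm,y_mm,u,v,p"
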