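import math
import random

import numpy as np
import pytest
from scipy.integrate import quad

from ureteroflow import units
from ureteroflow.geometry import ObstructionSpec, StentSpec, UreterProfile, circle_area
from ureteroflow.hydraulics import (
    FluidSpec,
    HydraulicNetwork,
    NetworkError,
    annulus_resistance,
    build_network,
    classify_pressure,
    hydraulic_resistance,
    orifice_resistance,
    pipe_resistance,
    pressure_map,
    solve_network,
    tapered_pipe_resistance,
)


def cmh2o_per_ml_min(r_si: float) -> float:
    return r_si * units.M3S_PER_ML_MIN / units.PA_PER_CMH2O


class TestPipeResistance:
    def test_stent_lumen_value(self):
        r = pipe_resistance(1.28e-3, 0.41, 1e-3)
        assert r == pytest.approx(6.223e9, rel=1e-3)
        # the slope the bench measured for complete obstruction
        assert cmh2o_per_ml_min(r) == pytest.approx(1.057, abs=0.002)

    def test_linear_in_length_and_viscosity(self):
        base = pipe_resistance(1.28e-3, 0.41, 1e-3)
        assert pipe_resistance(1.28e-3, 0.82, 1e-3) == pytest.approx(2 * base)
        assert pipe_resistance(1.28e-3, 0.41, 6e-3) == pytest.approx(6 * base)

    def test_rejects_non_positive(self):
        with pytest.raises(NetworkError):
            pipe_resistance(0.0, 0.41, 1e-3)

    def test_tapered_reduces_to_uniform(self):
        assert tapered_pipe_resistance(2e-3, 2e-3, 0.1, 1e-3) == pytest.approx(
            pipe_resistance(2e-3, 0.1, 1e-3), rel=1e-9
        )

    def test_tapered_matches_quadrature(self):
        d1, d2, L, mu = 2e-3, 5e-3, 0.1, 1e-3
        integral, _ = quad(lambda x: 1.0 / (d1 + (d2 - d1) * x / L) ** 4, 0, L)
        assert tapered_pipe_resistance(d1, d2, L, mu) == pytest.approx(
            128 * mu / math.pi * integral, rel=1e-9
        )


class TestAnnulusResistance:
    def test_small_core_approaches_pipe(self):
        # the core's drag vanishes only logarithmically, so the approach to
        # the open-pipe value is slow but strictly monotone from above
        pipe = pipe_resistance(4e-3, 0.1, 1e-3)
        gaps = [
            annulus_resistance(4e-3, d_i, 0.1, 1e-3) / pipe - 1.0
            for d_i in (1e-4, 1e-6, 1e-9)
        ]
        assert all(g > 0 for g in gaps)
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[-1] < 0.08

    def test_matches_velocity_profile_quadrature(self):
        # independent oracle: integrate the annular velocity profile
        ro, ri, L, mu = 2e-3, 1.04e-3, 0.1, 1e-3
        dp = 1.0

        def u(r):
            return (
                dp
                / (4 * mu * L)
                * (ro**2 - r**2 + (ro**2 - ri**2) * math.log(r / ro) / math.log(ro / ri))
            )

        q, _ = quad(lambda r: 2 * math.pi * r * u(r), ri, ro)
        assert annulus_resistance(2 * ro, 2 * ri, L, mu) == pytest.approx(
            dp / q, rel=1e-6
        )

    def test_resistance_diverges_as_gap_closes(self):
        values = [
            annulus_resistance(4e-3, d_i, 0.1, 1e-3)
            for d_i in (1e-3, 2e-3, 3e-3, 3.9e-3)
        ]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_rejects_inner_geq_outer(self):
        with pytest.raises(NetworkError):
            annulus_resistance(2e-3, 2e-3, 0.1, 1e-3)


class TestOrificeResistance:
    def test_side_hole_value(self):
        assert orifice_resistance(0.8e-3, 0.4e-3, 1e-3) == pytest.approx(
            3.98e7, rel=1e-2
        )

    def test_zero_thickness_is_free(self):
        assert orifice_resistance(0.8e-3, 0.0, 1e-3) == 0.0

    def test_fourth_power_scaling(self):
        r1 = orifice_resistance(0.8e-3, 0.4e-3, 1e-3)
        r4 = orifice_resistance(3.2e-3, 0.4e-3, 1e-3)
        assert r1 / r4 == pytest.approx(256.0, rel=1e-9)


class TestBuildNetwork:
    def test_bare_conduit_is_series_of_section_pipes(self, profile):
        net = build_network(profile)
        assert len(net.branches) == profile.n_sections - 1
        assert all(b.kind == "lumen" for b in net.branches)
        total = sum(b.resistance_pa_s_m3 for b in net.branches)
        m = hydraulic_resistance(net)
        assert m == pytest.approx(cmh2o_per_ml_min(total), rel=1e-12)

    def test_complete_obstruction_severs_extraluminal_path(self, profile, stent):
        obstruction = ObstructionSpec(hole_area_mm2=stent.cross_section_mm2)
        net = build_network(profile, stent, obstruction).pruned()
        x_ob = 0.5 * (
            profile.section_positions_mm[0] + profile.section_positions_mm[1]
        )
        for br in net.branches:
            assert br.kind != "obstruction_gap"
        # no annulus branch spans the obstruction plane
        def span(b):
            def coord(n):
                if n == "pelvis":
                    return 0.0
                if n == "bladder":
                    return profile.length_mm
                return float(n.split("@")[1].replace("ob_up", "nan").replace("ob_dn", "nan"))
            return coord(b.node_a), coord(b.node_b)
        for br in net.branches:
            if br.kind == "annulus":
                a, b = span(br)
                if not (math.isnan(a) or math.isnan(b)):
                    assert not (min(a, b) < x_ob < max(a, b))

    def test_lumen_only_limit_matches_poiseuille(self, profile, stent):
        # holes disabled + complete occlusion: all flow through the lumen
        obstruction = ObstructionSpec(hole_area_mm2=stent.cross_section_mm2)
        net = build_network(profile, stent, obstruction, side_holes=False)
        m = hydraulic_resistance(net)
        lumen = pipe_resistance(1.28e-3, 0.41, 1e-3)
        assert m == pytest.approx(cmh2o_per_ml_min(lumen), rel=1e-12)

    def test_obstruction_requires_stent(self, profile):
        with pytest.raises(NetworkError):
            build_network(profile, None, ObstructionSpec())

    def test_stent_must_fit_profile(self, stent):
        narrow = UreterProfile((6.0, 1.5, 6.0), length_mm=289.0)
        with pytest.raises(Exception, match="fit"):
            build_network(narrow, stent)


class TestSolveNetwork:
    def test_single_branch_is_ohms_law(self):
        net = HydraulicNetwork()
        net.add("pelvis", "bladder", 1e9, "lumen")
        sol = solve_network(net, 10.0)
        expected = 1e9 * units.ml_min_to_m3s(10.0) / units.PA_PER_CMH2O
        assert sol.pelvic_pressure_cmh2o == pytest.approx(expected, rel=1e-12)

    def test_parallel_branches_halve_resistance(self):
        net = HydraulicNetwork()
        net.add("pelvis", "bladder", 1e9, "lumen")
        net.add("pelvis", "bladder", 1e9, "annulus")
        assert hydraulic_resistance(net) == pytest.approx(
            cmh2o_per_ml_min(0.5e9), rel=1e-12
        )

    def test_zero_inflow_gives_zero_pressures(self, profile):
        sol = solve_network(build_network(profile), 0.0)
        assert all(p == 0.0 for p in sol.nodal_pressures_pa.values())

    def test_disconnected_network_raises(self):
        net = HydraulicNetwork()
        net.add("pelvis", "a", 1e9, "lumen")
        net.add("b", "bladder", 1e9, "lumen")
        with pytest.raises(NetworkError, match="connected"):
            solve_network(net, 1.0)

    def test_flow_conservation(self, profile, stent):
        net = build_network(profile, stent, ObstructionSpec())
        sol = solve_network(net, 20.0)
        assert sol.max_conservation_defect() < 1e-10

    def test_pressure_linear_in_flow(self, profile, stent):
        net = build_network(profile, stent)
        two = [solve_network(net, q).pelvic_pressure_cmh2o for q in (5.0, 20.0)]
        slope2 = (two[1] - two[0]) / 15.0
        qs = np.linspace(2, 20, 10)
        ps = [solve_network(net, q).pelvic_pressure_cmh2o for q in qs]
        slope10 = np.polyfit(qs, ps, 1)[0]
        assert slope10 == pytest.approx(slope2, rel=1e-12)

    def test_random_series_parallel_against_reduction_oracle(self):
        rng = random.Random(7)

        def compose(depth):
            # returns (network-fragment builder, equivalent resistance)
            if depth == 0 or rng.random() < 0.3:
                r = rng.uniform(1e8, 1e10)
                def build(net, a, b):
                    net.add(a, b, r, "lumen")
                return build, r
            left, rl = compose(depth - 1)
            right, rr = compose(depth - 1)
            if rng.random() < 0.5:  # series
                def build(net, a, b, left=left, right=right):
                    mid = f"n{id(build)}_{rng.random()}"
                    left(net, a, mid)
                    right(net, mid, b)
                return build, rl + rr
            def build(net, a, b, left=left, right=right):  # parallel
                left(net, a, b)
                right(net, a, b)
            return build, rl * rr / (rl + rr)

        for _ in range(20):
            builder, r_eq = compose(3)
            net = HydraulicNetwork()
            builder(net, "pelvis", "bladder")
            assert hydraulic_resistance(net) == pytest.approx(
                cmh2o_per_ml_min(r_eq), rel=1e-9
            )


class TestMonotonicity:
    """The bench observed pressure rising with Q, viscosity and OB%."""

    def test_non_decreasing_in_viscosity(self, profile, stent):
        ms = [
            hydraulic_resistance(
                build_network(profile, stent, ObstructionSpec(), FluidSpec.from_cp(mu))
            )
            for mu in (1.0, 1.3, 1.7, 2.5, 3.7, 6.0)
        ]
        assert all(b >= a for a, b in zip(ms, ms[1:]))

    def test_non_decreasing_in_obstruction(self, profile, stent):
        from ureteroflow.geometry import hole_area_for_severity

        sphere = circle_area(6.07)
        ms = []
        for ob in (81, 88, 94, 99, 100):
            hole = hole_area_for_severity(ob, sphere, stent.cross_section_mm2)
            net = build_network(
                profile, stent, ObstructionSpec(6.07, hole), FluidSpec()
            )
            ms.append(hydraulic_resistance(net))
        assert all(b >= a for a, b in zip(ms, ms[1:]))

    def test_stent_insertion_raises_resistance(self, profile, stent):
        assert hydraulic_resistance(build_network(profile, stent)) > (
            hydraulic_resistance(build_network(profile))
        )


class TestClassifyPressure:
    @pytest.mark.parametrize(
        "p, expected",
        [
            (10.0, "safe"),
            (17.0, "warning"),
            (25.0, "dangerous"),
            (15.0, "warning"),
            (20.0, "warning"),
            (0.0, "safe"),
        ],
    )
    def test_bands(self, p, expected):
        assert classify_pressure(p) == expected

    def test_rejects_negative(self):
        with pytest.raises(NetworkError):
            classify_pressure(-1.0)


class TestPressureMap:
    def test_single_cell_equals_single_solve(self, profile, stent):
        pmap = pressure_map(profile, stent, None, [10.0], [1.0])
        net = build_network(profile, stent, None, FluidSpec.from_cp(1.0))
        direct = solve_network(net, 10.0).pelvic_pressure_cmh2o
        assert pmap.pressure_grid_cmh2o[0, 0] == pytest.approx(direct, rel=1e-12)

    def test_bare_conduit_stays_safe_at_extremes(self, profile):
        pmap = pressure_map(profile, None, None, [20.0], [6.0])
        assert pmap.class_grid[0, 0] == "safe"

    def test_monotone_along_both_axes(self, profile, stent):
        pmap = pressure_map(
            profile, stent, ObstructionSpec(), [5, 10, 15, 20], [1, 1.7, 3.7, 6]
        )
        grid = pmap.pressure_grid_cmh2o
        assert np.all(np.diff(grid, axis=0) >= -1e-12)
        assert np.all(np.diff(grid, axis=1) >= -1e-12)

    def test_dangerous_region_grows_with_obstruction(self, profile, stent):
        from ureteroflow.geometry import hole_area_for_severity

        sphere = circle_area(6.07)
        hole88 = hole_area_for_severity(88, sphere, stent.cross_section_mm2)
        q, mu = [5, 10, 15, 20], [1, 1.3, 1.7, 2.5, 3.7, 6]
        m88 = pressure_map(profile, stent, ObstructionSpec(6.07, hole88), q, mu)
        m100 = pressure_map(profile, stent, ObstructionSpec(), q, mu)
        d88 = m88.class_grid == "dangerous"
        d100 = m100.class_grid == "dangerous"
        assert np.all(d100 | ~d88)  # superset
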