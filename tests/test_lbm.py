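"""Lattice-Boltzmann solver: boundary laws, oracles and conservation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stentflow import geometry as geom
from stentflow import lbm
from stentflow.porous import pressure_drop


class TestMurraySplit:
    def test_symmetric_outlets(self):
        assert lbm.murray_outlet_split([2, 2]) == pytest.approx([0.5, 0.5])

    def test_cube_law_normalization(self):
        assert lbm.murray_outlet_split([1, 2]) == pytest.approx([1 / 9, 8 / 9])

    def test_single_outlet(self):
        assert lbm.murray_outlet_split([3]) == [1.0]

    def test_empty_and_invalid(self):
        with pytest.raises(ValueError):
            lbm.murray_outlet_split([])
        with pytest.raises(ValueError):
            lbm.murray_outlet_split([2, 0])

    @given(st.lists(st.floats(0.5, 6.0), min_size=1, max_size=5))
    @settings(max_examples=50, deadline=None)
    def test_fractions_sum_to_one(self, diams):
        fr = lbm.murray_outlet_split(diams)
        assert sum(fr) == pytest.approx(1.0)
        assert all(f > 0 for f in fr)


class TestInletVelocityScaling:
    def test_exponent_one_gives_area_independence(self):
        v1 = lbm.inlet_mean_velocity_from_area(10.0, a=0.3, b=1.0)
        v2 = lbm.inlet_mean_velocity_from_area(25.0, a=0.3, b=1.0)
        assert v1 == pytest.approx(v2) == pytest.approx(0.3)

    def test_flow_rate_power_law(self):
        a, b = 2.0, 1.5
        q1 = lbm.inlet_mean_velocity_from_area(10.0, a, b) * 10e-6
        q2 = lbm.inlet_mean_velocity_from_area(20.0, a, b) * 20e-6
        assert q2 / q1 == pytest.approx(2**1.5)

    def test_default_gives_physiological_velocity_on_4mm_inlet(self):
        v = lbm.inlet_mean_velocity_from_area(np.pi * 2.0**2)
        assert 0.2 < v < 0.3

    def test_nonpositive_area(self):
        with pytest.raises(ValueError):
            lbm.inlet_mean_velocity_from_area(0.0)


class TestWaveform:
    def test_packaged_waveform_unit_mean_and_peak(self):
        wf = lbm.WaveformSpec.ica(0.25)
        assert abs(wf.w.mean() - 1.0) < 1e-6
        assert wf.peak == pytest.approx(1.8, abs=0.05)
        assert wf.w.min() > 0

    def test_non_normalized_waveform_rejected(self):
        with pytest.raises(ValueError):
            lbm.WaveformSpec(period=1.0, t_frac=np.array([0.0, 0.5]),
                             w=np.array([1.0, 2.0]), v_mean=0.1)

    def test_periodic_interpolation(self):
        wf = lbm.WaveformSpec.ica(0.1, period=2.0)
        assert wf(0.3) == pytest.approx(wf(2.3))


def test_time_step_magnitude_at_reference_conditions():
    """At 0.1 mm and physiological inflow the physical time step is of
    order 1e-4 s (within one order of magnitude)."""
    conv = lbm._make_conversion(0.1, lbm.FluidProps(), u_peak=0.5,
                                cfg=lbm.SolverConfig(tau_min=0.0))
    assert 1e-5 <= conv.dt <= 1e-3
    assert conv.tau > 0.505


def test_conversion_respects_stability_envelope():
    cfg = lbm.SolverConfig()
    conv = lbm._make_conversion(0.3, lbm.FluidProps(), u_peak=0.036, cfg=cfg)
    assert cfg.tau_floor < conv.tau <= cfg.tau_max
    # peak lattice velocity at the Mach budget
    assert 0.036 * conv.dt / conv.dx <= cfg.ma_max / np.sqrt(3) + 1e-12


class TestPoiseuille:
    def test_profile_matches_analytic_parabola(self, poiseuille_flow, blood):
        grid, flow = poiseuille_flow["grid"], poiseuille_flow["flow"]
        R, g = poiseuille_flow["R"], poiseuille_flow["g"]
        centers = grid.origin + (flow.cell_pos + 0.5) * grid.h
        r = np.hypot(centers[:, 1], centers[:, 2])
        ux = flow.u[0][:, 0]
        ana = g * ((R * 1e-3) ** 2 - (r * 1e-3) ** 2) / (4 * blood.viscosity)
        assert np.max(np.abs(ux - ana)) / ana.max() < 0.02

    def test_centerline_is_twice_the_mean(self, poiseuille_flow):
        ux = poiseuille_flow["flow"].u[0][:, 0]
        assert ux.max() / ux.mean() == pytest.approx(2.0, rel=0.02)


class TestPorousPlug:
    def test_pressure_drop_matches_areal_law(self, plug_flows):
        """Channel Δp across a porous plug reproduces Δp = l_c v + q_c v²
        within 5% for three measured coefficient pairs."""
        for lc, qc, v, grid, flow in plug_flows:
            x = (flow.cell_pos[:, 0] + 0.5) * grid.h
            p = flow.pressure[0]
            dp = p[(x > 1.5) & (x < 3.2)].mean() - p[(x > 5.0) & (x < 6.7)].mean()
            assert dp == pytest.approx(pressure_drop(lc, qc, v), rel=0.05)

    def test_plug_flow_stays_uniform(self, plug_flows):
        _, _, v, _, flow = plug_flows[0]
        ux = flow.u[0][:, 0]
        assert ux.mean() == pytest.approx(v, rel=0.02)


class TestSteadySolver:
    def test_zero_inflow_gives_zero_field(self, blood):
        g = geom.make_sidewall_aneurysm(3, 0, 0, 9)
        grid = geom.voxelize(g, 0.3)
        flow = lbm.run_steady(grid, None, blood, v_mean=0.0,
                              config=lbm.SolverConfig(max_steps=2000,
                                                      steady_tol=1e-9))
        assert np.abs(flow.u).max() < 1e-12

    def test_no_porous_equals_zero_resistance_porous(self, reference_case,
                                                     zero_resistance_flow):
        pre = reference_case["pre"]
        diff = np.abs(zero_resistance_flow.u - pre.u).max()
        assert diff / np.abs(pre.u).max() < 0.01

    def test_mass_conservation_on_reference_run(self, reference_case):
        assert reference_case["pre"].mass_balance_error() < 0.01

    def test_warm_start_reproduces_cold_start(self, blood):
        g = geom.make_sidewall_aneurysm(3, 0, 0, 9)
        grid = geom.voxelize(g, 0.3)
        cfg = lbm.SolverConfig(steady_tol=1e-8)
        cold = lbm.run_steady(grid, None, blood, v_mean=0.01, config=cfg)
        warm = lbm.run_steady(grid, None, blood, v_mean=0.01, config=cfg,
                              init=cold)
        assert np.abs(warm.u - cold.u).max() / np.abs(cold.u).max() < 5e-3


@pytest.fixture(scope="module")
def t_junction(blood):
    """Two-outlet junction: Murray fractions via velocity-flux outlets."""
    prims = [
        {"type": "cylinder", "p0": [0, 0, 0], "p1": [30, 0, 0], "radius": 2.0},
        {"type": "cylinder", "p0": [15, 0, 0], "p1": [15, 0, 12], "radius": 1.4},
    ]
    bbox = np.array([[0, -2, -2], [30, 2, 14.0]])
    corners = np.array([[x, y, z] for x in bbox[:, 0] for y in bbox[:, 1]
                        for z in bbox[:, 2]])
    g = geom.SurfaceGeometry(
        corners, np.zeros((0, 3), dtype=int),
        [geom.Opening("inlet", [0, 0, 0], [-1, 0, 0], 4.0),
         geom.Opening("outlet_0", [30, 0, 0], [1, 0, 0], 4.0),
         geom.Opening("outlet_1", [15, 0, 12], [0, 0, 1], 2.8)],
        {"primitives": prims},
    )
    grid = geom.voxelize(g, 0.3)
    flow = lbm.run_steady(grid, None, blood, v_mean=0.018,
                          config=lbm.SolverConfig(steady_tol=1e-6))
    return grid, flow


class TestMurrayOutflow:
    def test_realized_split_matches_cube_law(self, t_junction):
        _, flow = t_junction
        target = lbm.murray_outlet_split([4.0, 2.8])
        realized = flow.outlet_fractions()
        assert realized["outlet_0"] == pytest.approx(target[0], abs=0.02)
        assert realized["outlet_1"] == pytest.approx(target[1], abs=0.02)

    def test_mass_conservation_with_two_outlets(self, t_junction):
        _, flow = t_junction
        assert flow.mass_balance_error() < 0.01


@pytest.fixture(scope="module")
def pulsatile_pair(blood):
    """Steady vs pulsatile on a small sidewall case at low Womersley."""
    g = geom.make_sidewall_aneurysm(3, 5, 3, 12)
    grid = geom.voxelize(geom.extend_openings(g, 3), 0.3)
    from stentflow.neck import detect_ostium_plane

    sac = detect_ostium_plane(g, grid)
    steady = lbm.run_steady(grid, None, blood, v_mean=0.018,
                            config=lbm.SolverConfig(steady_tol=1e-6))
    wf = lbm.WaveformSpec.ica(0.018, period=2.0)
    puls = lbm.run_pulsatile(grid, None, blood, wf, n_export=50,
                             config=lbm.SolverConfig())
    return sac, steady, puls


class TestPulsatile:
    def test_exports_fifty_instants(self, pulsatile_pair):
        _, _, puls = pulsatile_pair
        assert puls.n_instants == 50

    def test_quasi_steady_limit(self, pulsatile_pair):
        """At Womersley ≈ 1.5 the cycle-mean sac velocity approaches the
        steady solution at the cycle-mean inflow."""
        from stentflow.neck import stav

        sac, steady, puls = pulsatile_pair
        assert stav(puls, sac) == pytest.approx(stav(steady, sac), rel=0.10)

    def test_cycle_mean_mass_conservation(self, pulsatile_pair):
        _, _, puls = pulsatile_pair
        assert puls.cycle_mean_mass_error() < 0.01

    def test_zero_velocity_on_walls_everywhere(self, pulsatile_pair):
        # solid voxels are excluded from the active set entirely
        _, _, puls = pulsatile_pair
        lab = puls.grid.labels[puls.cell_pos[:, 0], puls.cell_pos[:, 1],
                               puls.cell_pos[:, 2]]
        assert (lab > 0).all()


def test_flowfield_vtk_export(tmp_path, reference_case):
    out = tmp_path / "speed.vtk"
    reference_case["pre"].save_vtk(str(out))
    assert out.read_text().startswith("# vtk DataFile")


def test_load_yaml_config(tmp_path):
    from stentflow import lbm

    cfg_file = tmp_path / "sim.yaml"
    cfg_file.write_text(
        "fluid:\n  density: 1060\n  viscosity: 0.0035\n"
        "solver:\n  steady_tol: 1.0e-7\n  check_every: 100\n"
        "resolution: 0.25\nmode: steady\nv_mean: 0.02\n"
        "cebral:\n  b: 1.9\n"
    )
    cfg = lbm.load_config(str(cfg_file))
    assert cfg["fluid"].density == 1060
    assert cfg["solver"].steady_tol == 1e-7
    assert cfg["resolution"] == 0.25
    assert cfg["mode"] == "steady"
    assert cfg["cebral"]["b"] == 1.9
    wf = cfg["waveform"](0.1)
    assert abs(wf.w.mean() - 1.0) < 1e-6
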