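"""Shared fixtures: expensive simulations are run once per session.

The heavy fixtures mirror the desk-scale study conditions (coarse steady
fast mode); individual tests assert different properties of the same
flow solutions rather than recomputing them.
"""

import numpy as np
import pytest

from stentflow import geometry as geom
from stentflow import lbm
from stentflow.deployment import TubeSpec, build_braid, deploy
from stentflow.neck import detect_ostium_plane, stav
from stentflow.porous import map_stent_to_porous_voxels, porous_slab_field
from stentflow.study import StudyConfig, run_study


@pytest.fixture(scope="session")
def blood():
    return lbm.FluidProps()


@pytest.fixture(scope="session")
def reference_case(blood):
    """Reference sidewall aneurysm: grid, sac, deployed layer, pre-flow."""
    g = geom.make_sidewall_aneurysm(4, 8, 4, 20)
    ge = geom.extend_openings(g, 5)
    grid = geom.voxelize(ge, 0.3)
    sac = detect_ostium_plane(g, grid)
    tube = TubeSpec(radius=2.0, axis_point=g.metadata["parent_axis_point"],
                    axis_dir=g.metadata["parent_axis_dir"])
    stent = deploy(build_braid(48, 4, 20, 75), tube, release_position=0.0)
    layer = map_stent_to_porous_voxels(stent, grid, 0.45)
    cfg = lbm.SolverConfig(steady_tol=1e-6, check_every=250)
    pre = lbm.run_steady(grid, None, blood, v_mean=0.018, config=cfg)
    return {
        "geometry": g,
        "grid": grid,
        "sac": sac,
        "layer": layer,
        "pre": pre,
        "stav_pre": stav(pre, sac),
        "config": cfg,
        "v_mean": 0.018,
    }


@pytest.fixture(scope="session")
def zero_resistance_flow(reference_case, blood):
    """Treated run with a resistance-free layer (l_c = q_c = 0)."""
    rc = reference_case
    return lbm.run_steady(rc["grid"], rc["layer"].with_coefficients(0.0, 0.0),
                          blood, v_mean=rc["v_mean"], config=rc["config"],
                          init=rc["pre"])


@pytest.fixture(scope="session")
def fixed_qc_sweep(reference_case, blood):
    """AMVR at increasing l_c with q_c held fixed (similarity-scaled)."""
    rc = reference_case
    lc_values = [4.3, 19.3, 66.8, 186.0]
    scale = 0.018 / 0.25  # fast-mode similarity factor, as in the study
    amvrs = []
    prev = rc["pre"]
    for lc in lc_values:
        flow = lbm.run_steady(
            rc["grid"], rc["layer"].with_coefficients(lc * scale, 200.0),
            blood, v_mean=rc["v_mean"], config=rc["config"], init=prev,
        )
        prev = flow
        amvrs.append(1.0 - stav(flow, rc["sac"]) / rc["stav_pre"])
    return lc_values, amvrs


@pytest.fixture(scope="session")
def study_results():
    """Fast-mode study: all 16 measured scenarios on one sidewall geometry."""
    g = geom.make_sidewall_aneurysm(4, 8, 4, 20)
    return run_study([g], config=StudyConfig(mode="fast", t_layer=0.45))


@pytest.fixture(scope="session")
def poiseuille_flow(blood):
    """Body-force-driven periodic circular tube at 30 voxels per radius."""
    R, h = 2.0, 0.0667
    grid, periodic = lbm.make_periodic_tube_grid(R, h, nx=3)
    u_target = 0.02
    g_force = u_target * 4 * blood.viscosity / (R * 1e-3) ** 2
    flow = lbm.run_steady(
        grid, None, blood, v_mean=0.0, body_force=[g_force, 0.0, 0.0],
        periodic=periodic, u_ref=u_target,
        config=lbm.SolverConfig(steady_tol=1e-8, check_every=500,
                                max_steps=200000),
    )
    return {"grid": grid, "flow": flow, "R": R, "g": g_force}


@pytest.fixture(scope="session")
def plug_flows(blood):
    """Porous-plug channel runs for three measured coefficient pairs."""
    h = 0.2
    grid, periodic = lbm.make_duct_grid(8.0, 0.8, h)
    v = 0.1
    cfg = lbm.SolverConfig(profile="flat", steady_tol=3e-8, check_every=200)
    out = []
    prev = None
    for lc, qc in [(66.8, 170.0), (114.0, 464.0), (5.6, 239.0)]:
        plug = porous_slab_field(grid, axis=0, position_mm=3.6,
                                 thickness_mm=1.0, l_c=lc, q_c=qc)
        with np.errstate(all="ignore"):
            flow = lbm.run_steady(grid, plug, blood, v_mean=v, config=cfg,
                                  periodic=periodic, init=prev)
        prev = flow
        out.append((lc, qc, v, grid, flow))
    return out


@pytest.fixture(scope="session")
def tensile_net():
    """Small braid for calibration tests; the moderate braid angle gives a
    tensile response with pronounced necking, so both spring types are
    well engaged by the test protocol."""
    return build_braid(16, 4, 8, 55)


@pytest.fixture(scope="session")
def tensile_samples(tensile_net):
    """Noise-free tensile responses (force, necking) from the model itself."""
    from stentflow.deployment import mid_braid_diameter, simulate_tensile

    true_ks, true_kr = 0.08, 0.02
    elong = np.array([0.5, 1.0, 2.0, 3.0, 4.0])
    forces = []
    diams = []
    x0 = None
    for e in elong:
        f, x0 = simulate_tensile(tensile_net, e, k_s=true_ks, k_r=true_kr, x0=x0)
        forces.append(f)
        diams.append(mid_braid_diameter(tensile_net, x0))
    return {"elongation": elong, "force": np.array(forces),
            "diameter": np.array(diams), "k_s": true_ks, "k_r": true_kr}
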