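"""Flexion-angle measurement, configuration, validation and the CLI."""

import numpy as np
import pytest
import yaml
from click.testing import CliRunner
from scipy.spatial.transform import Rotation

from myoflex import scenarios as sc
from myoflex.cli import main as cli_main
from myoflex.geometry_fixtures import make_cylinder, write_mesh
from myoflex.materials import ActivationPair, MuscleParams


# ---------------------------------------------------------------------------
# Elbow flexion angle
# ---------------------------------------------------------------------------

def test_angle_zero_for_identity():
    assert sc.elbow_flexion_angle([0, 0, 0], [250, 0, 0], [0, 0, 0], [250, 0, 0]) == 0.0


@pytest.mark.parametrize("deg", [5.0, 30.0, 65.0, -20.0])
def test_angle_recovers_rigid_rotation(deg):
    """Rotation about +Y by -deg lifts the tip toward +Z (flexion)."""
    R = Rotation.from_euler("y", -deg, degrees=True).as_matrix()
    tip = R @ np.array([250.0, 0, 0])
    ang = sc.elbow_flexion_angle([0, 0, 0], [250, 0, 0], [0, 0, 0], tip)
    assert ang == pytest.approx(deg, abs=1e-12)


def test_angle_insensitive_to_out_of_plane_perturbation():
    base = sc.elbow_flexion_angle([0, 0, 0], [250, 0, 0], [0, 0, 0],
                                  [240, 0, 40])
    pert = sc.elbow_flexion_angle([0, 0, 0], [250, 0, 0], [0, 0, 0],
                                  [240, 2.5, 40])
    assert abs(pert - base) < 0.2


def test_angle_rejects_coincident_markers():
    with pytest.raises(ValueError):
        sc.elbow_flexion_angle([0, 0, 0], [0, 1, 0], [0, 0, 0], [0, 2, 0])


# ---------------------------------------------------------------------------
# OLS fits
# ---------------------------------------------------------------------------

def test_ols_exact_line():
    slope, r2 = sc._ols([1, 2, 3, 4], [2.0, 4.0, 6.0, 8.0])
    assert slope == pytest.approx(2.0)
    assert r2 == pytest.approx(1.0)


def test_ols_r2_below_one_with_noise():
    slope, r2 = sc._ols([1, 2, 3, 4], [2.0, 4.5, 5.5, 8.0])
    assert 0.9 < r2 < 1.0


# ---------------------------------------------------------------------------
# Configuration files
# ---------------------------------------------------------------------------

def test_scenario_config_yaml(tmp_path):
    path = tmp_path / "cfg.yaml"
    path.write_text(yaml.safe_dump({
        "geometry": {"edge_length": 20.0},
        "muscle": {"t0m": 0.4},
        "dt": 0.02, "t_end": 0.5, "load_n": 50.0,
    }))
    cfg = sc.load_scenario_config(path)
    assert cfg.geometry.edge_length == 20.0
    assert cfg.muscle.t0m == 0.4
    assert cfg.dt == 0.02 and cfg.t_end == 0.5 and cfg.load_n == 50.0


def test_material_params_yaml(tmp_path):
    path = tmp_path / "mat.yaml"
    path.write_text(yaml.safe_dump({
        "biceps": {"type": "muscle", "t0m": 0.3},
        "radius": {"type": "bone"},
        "strap": {"type": "tendon", "lame_mu": 70.0},
    }))
    mats = sc.load_material_params(path)
    assert isinstance(mats["biceps"], MuscleParams)
    assert mats["biceps"].t0m == 0.3
    assert mats["radius"].lame_mu == 6154.0
    assert mats["strap"].lame_mu == 70.0


def test_material_params_unknown_tissue(tmp_path):
    path = tmp_path / "mat.yaml"
    path.write_text("thing: {type: cartilage}\n")
    with pytest.raises(ValueError, match="cartilage"):
        sc.load_material_params(path)


# ---------------------------------------------------------------------------
# Uniaxial oracle sanity
# ---------------------------------------------------------------------------

def test_oracle_zero_at_rest(params):
    assert sc.uniaxial_oracle(1.0, ActivationPair.uniform(0.0), params) == pytest.approx(0.0, abs=1e-14)


def test_oracle_isometric_equals_t0m_alpha(params):
    assert sc.uniaxial_oracle(1.0, ActivationPair.uniform(0.91), params) == pytest.approx(0.535 * 0.91)


def test_single_element_fe_matches_oracle_with_activation(params):
    from myoflex.geometry_fixtures import make_unit_fixture

    mesh = make_unit_fixture("single_tet")
    act = ActivationPair.uniform(0.5)
    fe = sc._uniaxial_fe(mesh, params, 1.1, act)
    assert fe == pytest.approx(sc.uniaxial_oracle(1.1, act, params), rel=0.01)


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def test_cli_unknown_subcommand_exit_2():
    result = CliRunner().invoke(cli_main, ["frobnicate"])
    assert result.exit_code == 2


def test_cli_mesh_and_fibers(tmp_path):
    runner = CliRunner()
    mesh_path = tmp_path / "cyl.msh"
    write_mesh(make_cylinder(60.0, 8.0, 4), mesh_path)
    out = tmp_path / "fibers.vtk"
    result = runner.invoke(cli_main, ["fibers", "--mesh", str(mesh_path),
                                      "--out", str(out),
                                      "--source", "end0", "--sink", "end1"])
    assert result.exit_code == 0, result.output
    assert out.exists()

    result = runner.invoke(cli_main, ["mesh", "--kind", "unit_cube",
                                      "--out", str(tmp_path / "cube.msh")])
    assert result.exit_code == 0
    assert (tmp_path / "cube.msh").exists()


def test_cli_fibers_missing_mesh_exit_1(tmp_path):
    result = CliRunner().invoke(
        cli_main, ["fibers", "--mesh", str(tmp_path / "missing.msh"),
                   "--out", str(tmp_path / "o.vtk")])
    assert result.exit_code == 1
    assert "missing.msh" in result.output


def test_cli_run_missing_mesh_exit_1(tmp_path):
    cfg = tmp_path / "cfg.yaml"
    cfg.write_text(yaml.safe_dump({"mesh_path": str(tmp_path / "gone.msh")}))
    result = CliRunner().invoke(cli_main, ["run", "--study", "velocity",
                                           "--config", str(cfg),
                                           "--out", str(tmp_path / "res")])
    assert result.exit_code == 1
    assert "gone.msh" in result.output


def test_cli_validate(tmp_path):
    report = tmp_path / "val.csv"
    result = CliRunner().invoke(cli_main, ["validate", "--report", str(report)])
    assert result.exit_code == 0, result.output
    assert report.exists()
    assert "validation passed" in result.output


# ---------------------------------------------------------------------------
# Determinism of study runs
# ---------------------------------------------------------------------------

def test_flexion_case_deterministic(params):
    """Identical configuration reproduces the trajectory bitwise."""
    config = sc.ScenarioConfig(t_end=0.03)
    mesh, fibers = sc.forearm_model_inputs(config)
    runs = []
    for _ in range(2):
        traj = sc._run_flexion_case(
            config, mesh, fibers, params, sc._ode_profiles(params, 0.5),
            sc._constant_load_schedule, t_end=0.03, dt=0.01, case_label="det")
        runs.append(traj.angles.copy())
    assert np.array_equal(runs[0], runs[1])
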