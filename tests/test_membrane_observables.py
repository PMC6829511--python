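"""SASA, insertion detection, macrodipole, density maps and lateral MSD."""

import numpy as np
import pytest

from mempsn.exceptions import MissingChargeError
from mempsn.membrane_observables import (
    SASASeries,
    density_map,
    detect_insertion,
    lateral_msd,
    macrodipole_z,
    sasa_series,
    shrake_rupley,
)
from mempsn.synthetic_data import GeneratorConfig, generate_membrane_patch
from mempsn.trajectory_io import AtomRecord, Residue, Topology, Trajectory

SPHERE_R = 1.9
PROBE = 1.4
ANALYTIC = 4 * np.pi * (SPHERE_R + PROBE) ** 2


def test_sasa_isolated_sphere_analytic():
    area = shrake_rupley(np.zeros((1, 3)), np.array([SPHERE_R]),
                         probe_radius=PROBE)
    assert area[0] == pytest.approx(ANALYTIC, rel=0.02)


def test_sasa_additivity_when_disjoint():
    coords = np.array([[0.0, 0, 0], [100.0, 0, 0]])
    areas = shrake_rupley(coords, np.array([SPHERE_R, SPHERE_R]),
                          probe_radius=PROBE)
    assert areas.sum() == pytest.approx(2 * ANALYTIC, rel=1e-12)


def test_sasa_buried_by_occluder_cage():
    from mempsn.synthetic_data import _icosahedron

    cage = _icosahedron() * 3.0
    coords = np.vstack([[0.0, 0.0, 0.0], cage])
    radii = np.full(len(coords), 1.7)
    areas = shrake_rupley(coords, radii, selection=np.array([0]),
                          probe_radius=PROBE)
    assert areas[0] == 0.0


def test_sasa_monotone_under_added_occluders():
    rng = np.random.default_rng(0)
    center = np.zeros((1, 3))
    occluders = rng.uniform(-4, 4, (6, 3))
    radii = np.full(7, 1.7)
    alone = shrake_rupley(center, radii[:1], probe_radius=PROBE)[0]
    prev = alone
    for k in range(1, 7):
        coords = np.vstack([center, occluders[:k]])
        area = shrake_rupley(coords, radii[:k + 1],
                             selection=np.array([0]), probe_radius=PROBE)[0]
        assert area <= prev + 1e-9
        prev = area


def test_sasa_sphere_point_convergence():
    a1 = shrake_rupley(np.zeros((1, 3)), np.array([SPHERE_R]),
                       probe_radius=PROBE, n_sphere_points=960)[0]
    a2 = shrake_rupley(np.zeros((1, 3)), np.array([SPHERE_R]),
                       probe_radius=PROBE, n_sphere_points=1920)[0]
    assert abs(a2 - a1) / a1 < 0.005


def _synthetic_series(values, dt=1.0):
    values = np.asarray(values, dtype=float)
    return SASASeries(np.arange(len(values)) * dt, values, PROBE)


def test_detect_insertion_on_analytic_trace():
    rng = np.random.default_rng(1)
    t = np.arange(200.0)
    trace = np.full(200, 320.0) + rng.normal(0, 6, 200)
    # burial drops fast at onset (contact with the head-group region), then
    # grinds down to the buried level
    trace[142:164] = np.linspace(200.0, 90.0, 22)
    trace[t >= 164] = 25.0 + rng.normal(0, 2, (t >= 164).sum())
    event = detect_insertion(_synthetic_series(trace))
    assert event is not None and event.completed
    assert event.start_time == pytest.approx(141, abs=2)
    assert event.end_time == pytest.approx(164, abs=2)


def test_detect_insertion_flat_trace_none():
    rng = np.random.default_rng(2)
    trace = 300 + rng.normal(0, 8, 150)
    assert detect_insertion(_synthetic_series(trace)) is None


def test_detect_insertion_dip_and_recover_none():
    trace = np.full(200, 320.0)
    trace[90:96] = 20.0  # short dip, recovers
    assert detect_insertion(_synthetic_series(trace)) is None


def test_detect_insertion_scale_invariant():
    rng = np.random.default_rng(3)
    t = np.arange(200.0)
    trace = np.full(200, 320.0) + rng.normal(0, 5, 200)
    trace[t >= 150] = 20.0
    e1 = detect_insertion(_synthetic_series(trace))
    e2 = detect_insertion(_synthetic_series(trace * 7.3))
    assert e1 is not None and e2 is not None
    assert (e1.start_time, e1.end_time) == (e2.start_time, e2.end_time)


def _two_charge_system(q=(1.0, -1.0)):
    atoms = [
        AtomRecord(0, "NZ", "N", 1, "LYS", "A", frozenset(), q[0]),
        AtomRecord(1, "OD1", "O", 2, "ASP", "A", frozenset(), q[1]),
    ]
    residues = [
        Residue(0, 1, "LYS", "A", np.array([0]), "protein"),
        Residue(1, 2, "ASP", "A", np.array([1]), "protein"),
    ]
    return Topology(atoms, residues)


def test_macrodipole_two_point_charge():
    top = _two_charge_system()
    coords = np.array([[[0, 0, 1.0], [0, 0, -1.0]]])
    trj = Trajectory(coords, np.array([[100.0, 100, 100]]), np.array([0.0]))
    series = macrodipole_z(trj, top)
    assert series.mu_z[0] == pytest.approx(2 * 4.8032, rel=1e-6)  # ~9.61 D


def test_macrodipole_symmetric_system_zero():
    top = _two_charge_system(q=(0.5, 0.5))
    coords = np.array([[[0, 0, 3.0], [0, 0, -3.0]]])
    trj = Trajectory(coords, np.array([[100.0, 100, 100]]), np.array([0.0]))
    assert macrodipole_z(trj, top).mu_z[0] == pytest.approx(0.0, abs=1e-12)


def test_macrodipole_translation_invariant():
    top = _two_charge_system()
    coords = np.array([[[0, 0, 1.0], [0, 0, -1.0]]])
    shifted = coords + np.array([0.0, 0.0, 42.0])
    box = np.array([[1000.0, 1000, 1000]])
    t = np.array([0.0])
    a = macrodipole_z(Trajectory(coords, box, t), top).mu_z[0]
    b = macrodipole_z(Trajectory(shifted, box, t), top).mu_z[0]
    assert a == pytest.approx(b, abs=1e-9)


def test_macrodipole_missing_charges():
    top = _two_charge_system()
    top.atoms[0].charge = None
    coords = np.array([[[0, 0, 1.0], [0, 0, -1.0]]])
    trj = Trajectory(coords, np.array([[100.0, 100, 100]]), np.array([0.0]))
    with pytest.raises(MissingChargeError):
        macrodipole_z(trj, top)
    # formal-charge fallback restores the Lys +1
    series = macrodipole_z(trj, top, formal_charge_fallback=True)
    assert series.mu_z[0] == pytest.approx(2 * 4.8032, rel=1e-6)


def test_sign_reversal_count():
    top = _two_charge_system()
    coords = np.array([
        [[0, 0, 1.0], [0, 0, -1.0]],
        [[0, 0, -1.0], [0, 0, 1.0]],
        [[0, 0, 1.0], [0, 0, -1.0]],
    ])
    trj = Trajectory(coords, np.tile([100.0, 100, 100], (3, 1)),
                     np.arange(3.0))
    assert macrodipole_z(trj, top).sign_reversals == 2


def test_density_conservation_static(small_patch):
    _, top, trj = small_patch
    sel = np.arange(top.n_atoms)
    dm = density_map(trj[0], top, sel, z_slab=(0.0, 160.0), cell_edge=2.0)
    assert dm.total_observations == pytest.approx(top.n_atoms, abs=1e-9)


def test_density_single_cell():
    atoms = [AtomRecord(i, "P", "P", 1, "DGPC", "M") for i in range(5)]
    res = [Residue(0, 1, "DGPC", "M", np.arange(5), "lipid_PC",
                   np.arange(5))]
    top = Topology(atoms, res)
    coords = np.tile(np.array([10.2, 10.4, 50.0]), (1, 5, 1))
    trj = Trajectory(coords, np.array([[40.0, 40.0, 100.0]]),
                     np.array([0.0]))
    dm = density_map(trj, top, np.arange(5), z_slab=(40.0, 60.0),
                     cell_edge=1.0)
    assert (dm.density > 0).sum() == 1
    assert dm.density.max() == pytest.approx(5 / (1.0 * 1.0 * 20.0))


def test_density_enrichment_near_anchor(small_patch, role_map):
    _, top, base = small_patch
    rng = np.random.default_rng(5)
    anchor = np.array([45.0, 45.0])
    coords = np.repeat(base.coords[:1], 40, axis=0).copy()
    ps = top.select_atoms(molecule_class="lipid_PS")
    for f in range(40):
        jitter = rng.normal(0.0, 6.0, size=(len(ps), 2))
        coords[f, ps, 0] = np.mod(anchor[0] + jitter[:, 0], 90.0)
        coords[f, ps, 1] = np.mod(anchor[1] + jitter[:, 1], 90.0)
    trj = Trajectory(coords, np.tile([90.0, 90, 160], (40, 1)),
                     np.arange(40.0))
    dm = density_map(trj, top, ps, z_slab=(0.0, 160.0), cell_edge=2.0)
    assert np.linalg.norm(dm.maximum_position() - anchor) <= 10.0


def test_msd_brownian_parameter_recovery(role_map):
    cfg = GeneratorConfig(seed=0, n_lipids=200, composition=(1.0, 0.0, 0.0),
                          n_frames=500)
    top, trj = generate_membrane_patch(cfg, role_map)
    curve = lateral_msd(trj, top)["PS"]
    assert curve.diffusion_coefficient == pytest.approx(5e-7, rel=0.10)
    assert curve.msd[0] == 0.0
    assert np.all(curve.msd >= 0)
    assert not curve.super_diffusive


def test_msd_immobile_beads_zero(small_patch):
    _, top, trj = small_patch
    frozen = Trajectory(
        np.repeat(trj.coords[:1], 10, axis=0),
        np.repeat(trj.box[:1], 10, axis=0), np.arange(10.0),
    )
    for curve in lateral_msd(frozen, top).values():
        assert np.allclose(curve.msd, 0.0)
        assert curve.diffusion_coefficient == 0.0


def test_msd_ballistic_flagged_super_diffusive(small_patch):
    _, top, trj = small_patch
    v = np.array([0.8, 0.3])
    coords = np.repeat(trj.coords[:1], 60, axis=0).copy()
    lipid_atoms = np.concatenate(
        [r.atom_indices for r in top.lipid_residues]
    )
    for f in range(60):
        coords[f, lipid_atoms, :2] = np.mod(
            trj.coords[0][lipid_atoms, :2] + f * v, 90.0
        )
    moving = Trajectory(coords, np.tile([90.0, 90, 160], (60, 1)),
                        np.arange(60.0))
    for curve in lateral_msd(moving, top).values():
        speed2 = float(v @ v)
        mid = len(curve.lag_times) // 2
        assert curve.msd[mid] == pytest.approx(
            speed2 * curve.lag_times[mid] ** 2, rel=1e-6
        )
        assert curve.super_diffusive


def test_sasa_series_occluders_modes(role_map):
    from mempsn.synthetic_data import generate_insertion_trajectory

    cfg = GeneratorConfig(seed=5, n_lipids=20, n_frames=3, dt=1.0,
                          insertion=(0.5, 1.5))
    top, trj = generate_insertion_trajectory(cfg, role_map)
    sel = top.select_atoms(molecule_class="myristoyl")
    with_lipids = sasa_series(trj, top, sel, n_sphere_points=240)
    protein_only = sasa_series(trj, top, sel, n_sphere_points=240,
                               occluders="protein")
    # lipid occluders can only reduce the area
    assert np.all(with_lipids.values <= protein_only.values + 1e-9)
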