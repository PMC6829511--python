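"""Generator contracts: composition, determinism, schedule realisation."""

import numpy as np
import pytest

from mempsn.exceptions import ConfigError
from mempsn.interactions import PROTEIN_LIPID, scan_trajectory
from mempsn.synthetic_data import (
    ContactScheduleEntry,
    GeneratorConfig,
    expected_persistence_table,
    generate_contact_trajectory,
    generate_insertion_trajectory,
    generate_membrane_patch,
    generate_threshold_fixture,
    generate_toy_graph,
    largest_remainder,
)
from mempsn.trajectory_io import assign_leaflets


def test_default_composition_counts(role_map):
    cfg = GeneratorConfig(seed=0, n_frames=2)
    top, _ = generate_membrane_patch(cfg, role_map)
    counts = {}
    for r in top.lipid_residues:
        counts[r.molecule_class] = counts.get(r.molecule_class, 0) + 1
    assert counts == {"lipid_PS": 52, "lipid_PE": 104, "lipid_PC": 104}
    assert len(top.lipid_residues) == 260


@pytest.mark.parametrize("total,fracs,expected", [
    (260, (0.20, 0.40, 0.40), [52, 104, 104]),
    (10, (0.21, 0.39, 0.40), [2, 4, 4]),
    (7, (1 / 3, 1 / 3, 1 / 3), [3, 2, 2]),
])
def test_largest_remainder_exact_totals(total, fracs, expected):
    counts = largest_remainder(total, fracs)
    assert sum(counts) == total
    assert counts == expected


def test_bad_composition_rejected():
    with pytest.raises(ConfigError):
        GeneratorConfig(composition=(0.5, 0.3, 0.3))


def test_same_seed_bit_identical(role_map):
    cfg = GeneratorConfig(seed=42, n_lipids=20, n_frames=10)
    _, t1 = generate_membrane_patch(cfg, role_map)
    _, t2 = generate_membrane_patch(cfg, role_map)
    assert np.array_equal(t1.coords, t2.coords)
    _, t3 = generate_membrane_patch(
        GeneratorConfig(seed=43, n_lipids=20, n_frames=10), role_map
    )
    assert not np.array_equal(t1.coords, t3.coords)


def test_leaflets_stay_separated_while_diffusing(role_map):
    cfg = GeneratorConfig(seed=1, n_lipids=30, n_frames=30)
    top, trj = generate_membrane_patch(cfg, role_map)
    for f in (0, 15, 29):
        leaf = assign_leaflets(top, trj.coords[f])
        assert leaf.well_separated
        assert len(leaf.residues("upper")) == 15


def test_contact_schedule_exact_realisation(contact_fixture, contact_table):
    cfg, _, _ = contact_fixture
    expected = expected_persistence_table(cfg)
    assert contact_table.counts == expected.counts


def test_empty_schedule_no_contacts(role_map):
    cfg = GeneratorConfig(seed=2, n_lipids=12, n_frames=10)
    top, trj = generate_contact_trajectory(cfg, role_map)
    table = scan_trajectory(trj, top, PROTEIN_LIPID)
    assert table.counts == {}


def test_conflicting_schedule_rejected():
    entries = [
        ContactScheduleEntry("R43", "PS_1", "saltbridge", 0.25),
        ContactScheduleEntry("R43", "PS_1", "saltbridge", 0.75),
    ]
    with pytest.raises(ConfigError):
        GeneratorConfig(contact_schedule=entries)


def test_schedule_validation_errors(role_map):
    with pytest.raises(ConfigError):
        GeneratorConfig(contact_schedule=[
            ContactScheduleEntry("R43", "PS_1", "saltbridge", 1.5)
        ])
    # lower-leaflet lipid node
    cfg = GeneratorConfig(seed=0, n_lipids=10, n_frames=5, contact_schedule=[
        ContactScheduleEntry("R43", "PS_9", "saltbridge", 0.5)
    ])
    with pytest.raises(ConfigError):
        generate_contact_trajectory(cfg, role_map)
    # hydrophobic schedule on a charged residue
    cfg = GeneratorConfig(seed=0, n_lipids=10, n_frames=5, contact_schedule=[
        ContactScheduleEntry("R43", "PS_1", "hydrophobic", 0.5)
    ])
    with pytest.raises(ConfigError):
        generate_contact_trajectory(cfg, role_map)


def test_random_schedule_round_trips(role_map):
    """Detected persistence equals the scheduled value within 1/n_frames."""
    rng = np.random.default_rng(17)
    residues = ["R", "K", "S", "L", "D"]
    classes = {"R": ["saltbridge", "hbond"], "K": ["saltbridge", "hbond"],
               "S": ["hbond"], "L": ["hydrophobic"], "D": ["saltbridge"]}
    for trial in range(3):
        schedule, used = [], set()
        for j in range(4):
            res = residues[int(rng.integers(len(residues)))]
            node = f"{res}{10 + j}"
            lipid = f"{['PS', 'PE', 'PC'][int(rng.integers(3))]}_{j + 1}"
            cls = classes[res][int(rng.integers(len(classes[res])))]
            if (node, lipid, cls) in used:
                continue
            used.add((node, lipid, cls))
            schedule.append(ContactScheduleEntry(
                node, lipid, cls, float(rng.uniform(0.05, 0.95))
            ))
        cfg = GeneratorConfig(seed=100 + trial, n_lipids=16, n_frames=80,
                              contact_schedule=schedule)
        top, trj = generate_contact_trajectory(cfg, role_map)
        table = scan_trajectory(trj, top, PROTEIN_LIPID)
        for e in schedule:
            got = table.persistence(e.protein_node, e.lipid_node,
                                    e.interaction_class)
            assert abs(got - e.persistence) <= 1.0 / cfg.n_frames


def test_insertion_window_validation(role_map):
    cfg = GeneratorConfig(seed=0, n_lipids=10, n_frames=50, dt=1.0,
                          insertion=(40.0, 60.0))
    with pytest.raises(ConfigError):
        generate_insertion_trajectory(cfg, role_map)


def test_toy_graph_contracts():
    star = generate_toy_graph("star", 9)
    assert star.degree("N0") == 8
    cycle = generate_toy_graph("cycle", 4)
    assert cycle.number_of_edges() == 4
    r1 = generate_toy_graph("random", 30, seed=5)
    r2 = generate_toy_graph("random", 30, seed=5)
    assert set(r1.edges) == set(r2.edges)
    assert all("max_persistence" in d for _, _, d in r1.edges(data=True))
    with pytest.raises(ValueError):
        generate_toy_graph("cycle", 1)
    with pytest.raises(ValueError):
        generate_toy_graph("nope", 5)


def test_threshold_fixture_curve_shape():
    table = generate_threshold_fixture(30.0, seed=3)
    persists = sorted(p for _, p in table.items())
    assert persists[0] >= 0.0 and persists[-1] <= 1.0
    # half the edges should survive at the inflection
    above = sum(1 for p in persists if p >= 0.30)
    assert abs(above - len(persists) / 2) <= 2


def test_generated_trajectory_io_round_trip(tmp_path, role_map,
                                            contact_fixture):
    from mempsn.trajectory_io import (
        load_topology,
        load_trajectory,
        write_structure,
        write_trajectory,
    )

    _, top, trj = contact_fixture
    sub = trj[:3]
    gro, pdb = tmp_path / "s.gro", tmp_path / "t.pdb"
    write_structure(top, sub, gro)
    write_trajectory(top, sub, pdb)
    top2 = load_topology(gro, role_map)
    assert top2.n_atoms == top.n_atoms
    assert [r.node_key for r in top2.residues] == \
        [r.node_key for r in top.residues]
    trj2 = load_trajectory(top2, pdb)
    assert np.abs(trj2.coords - sub.coords).max() <= 1e-3
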