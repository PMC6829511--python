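import numpy as np
import pytest

from mempsn.interactions import PROTEIN_LIPID, scan_trajectory
from mempsn.synthetic_data import (
    ContactScheduleEntry,
    GeneratorConfig,
    generate_contact_trajectory,
    generate_membrane_patch,
)
from mempsn.trajectory_io import load_role_map


@pytest.fixture(scope="session")
def role_map():
    return load_role_map()


@pytest.fixture(scope="session")
def small_patch(role_map):
    cfg = GeneratorConfig(seed=11, n_lipids=30, n_frames=12)
    return cfg, *generate_membrane_patch(cfg, role_map)


@pytest.fixture(scope="session")
def contact_fixture(role_map):
    schedule = [
        ContactScheduleEntry("R43", "PS_1", "saltbridge", 0.25),
        ContactScheduleEntry("R43", "PS_1", "hbond", 0.40),
        ContactScheduleEntry("L50", "PE_3", "hydrophobic", 0.60),
        ContactScheduleEntry("D12", "PC_5", "saltbridge", 0.10),
        ContactScheduleEntry("S77", "PS_2", "hbond", 0.90),
    ]
    cfg = GeneratorConfig(seed=3, n_lipids=20, n_frames=100,
                          contact_schedule=schedule)
    top, trj = generate_contact_trajectory(cfg, role_map)
    return cfg, top, trj


@pytest.fixture(scope="session")
def contact_table(contact_fixture):
    _, top, trj = contact_fixture
    return scan_trajectory(trj, top, PROTEIN_LIPID)
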