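"""Contact-detector geometry gates and persistence accounting."""

import math

import numpy as np
import pytest

from mempsn.exceptions import NoHydrogensError
from mempsn.interactions import (
    DEFAULT_CUTOFFS,
    HBOND,
    HYDROPHOBIC_CLASS,
    INTRA_PROTEIN,
    PROTEIN_LIPID,
    SALTBRIDGE,
    Cutoffs,
    PersistenceTable,
    canonical_pair,
    classify_frame_interactions,
    scan_trajectory,
)
from mempsn.trajectory_io import (
    AtomRecord,
    HYDROPHOBIC_RESIDUES,
    Residue,
    Topology,
    Trajectory,
    assign_leaflets,
)


def _tiny_protein(atoms_spec):
    """Build a Topology from [(resname, resid, [(name, element, roles)])]."""
    atoms, residues = [], []
    i = 0
    for ridx, (resname, resid, beads) in enumerate(atoms_spec):
        idxs = []
        for name, element, roles in beads:
            atoms.append(AtomRecord(i, name, element, resid, resname, "A",
                                    frozenset(roles)))
            idxs.append(i)
            i += 1
        residues.append(Residue(ridx, resid, resname, "A",
                                np.array(idxs), "protein"))
    return Topology(atoms, residues)


def test_saltbridge_distance_gate():
    top = _tiny_protein([
        ("ARG", 5, [("NH1", "N", {"charged_positive"})]),
        ("ASP", 9, [("OD1", "O", {"charged_negative"})]),
    ])
    inside = np.array([[0, 0, 0], [0, 0, 4.0]], dtype=float)
    recs = classify_frame_interactions(inside, top, INTRA_PROTEIN)
    assert {(r.node_a, r.node_b, r.interaction_class) for r in recs} == {
        canonical_pair("R5", "D9") + (SALTBRIDGE,)
    }
    outside = np.array([[0, 0, 0], [0, 0, 4.6]], dtype=float)
    assert classify_frame_interactions(outside, top, INTRA_PROTEIN) == set()


def test_hbond_angle_gate():
    def geom(angle_deg):
        # donor at origin, H at 1 Å along +z, acceptor at 3.4 Å from donor
        # positioned to give the requested donor-H-acceptor angle
        h = np.array([0.0, 0.0, 1.0])
        d_ha = None
        # numerically place acceptor: rotate around H
        theta = math.radians(angle_deg)
        # direction from H making angle theta with (donor-H) = -z
        direction = np.array([math.sin(theta), 0.0, -math.cos(theta)])
        # find acceptor along `direction` from H with |D-A| = 3.4
        lo, hi = 0.0, 10.0
        for _ in range(60):
            mid = (lo + hi) / 2
            a = h + mid * direction
            if np.linalg.norm(a) < 3.4:
                lo = mid
            else:
                hi = mid
        return np.array([[0.0, 0.0, 0.0], h, h + lo * direction])

    top = _tiny_protein([
        ("SER", 2, [("OG", "O", {"hbond_donor"}), ("HG1", "H", set())]),
        ("ASN", 7, [("OD1", "O", {"hbond_acceptor"})]),
    ])
    good = classify_frame_interactions(geom(150.0), top, INTRA_PROTEIN)
    assert {r.interaction_class for r in good} == {HBOND}
    bad = classify_frame_interactions(geom(100.0), top, INTRA_PROTEIN)
    assert bad == set()


def test_hbond_requires_hydrogens():
    top = _tiny_protein([
        ("SER", 2, [("OG", "O", {"hbond_donor"})]),
        ("ASN", 7, [("OD1", "O", {"hbond_acceptor"})]),
    ])
    coords = np.array([[0, 0, 0], [0, 0, 3.0]], dtype=float)
    with pytest.raises(NoHydrogensError):
        classify_frame_interactions(coords, top, INTRA_PROTEIN)


def test_hydrophobic_com_gate():
    top = _tiny_protein([
        ("LEU", 3, [("CB", "C", {"hydrophobic"})]),
        ("VAL", 8, [("CB", "C", {"hydrophobic"})]),
    ])
    near = np.array([[0, 0, 0], [0, 0, 4.9]], dtype=float)
    recs = classify_frame_interactions(near, top, INTRA_PROTEIN)
    assert {r.interaction_class for r in recs} == {HYDROPHOBIC_CLASS}
    far = np.array([[0, 0, 0], [0, 0, 5.5]], dtype=float)
    assert classify_frame_interactions(far, top, INTRA_PROTEIN) == set()


def test_sequence_neighbours_excluded_intra_protein():
    top = _tiny_protein([
        ("ARG", 5, [("NH1", "N", {"charged_positive"})]),
        ("ASP", 6, [("OD1", "O", {"charged_negative"})]),
    ])
    coords = np.array([[0, 0, 0], [0, 0, 3.0]], dtype=float)
    assert classify_frame_interactions(coords, top, INTRA_PROTEIN) == set()


def test_scheduled_persistence_counts(contact_fixture, contact_table):
    cfg, _, _ = contact_fixture
    for e in cfg.contact_schedule:
        assert contact_table.persistence(
            e.protein_node, e.lipid_node, e.interaction_class
        ) == pytest.approx(e.persistence, abs=1e-12)


def test_pairs_never_in_contact_absent(contact_table):
    observed_pairs = {(a, b) for (a, b, _), _ in contact_table.items()}
    assert ("D12", "PS_1") not in observed_pairs
    for (a, b, _), p in contact_table.items():
        assert p > 0


def test_persistence_frame_reordering_invariance(contact_fixture):
    cfg, top, trj = contact_fixture
    rng = np.random.default_rng(0)
    perm = rng.permutation(trj.n_frames)
    shuffled = Trajectory(trj.coords[perm], trj.box[perm],
                          np.sort(trj.times))
    a = scan_trajectory(trj, top, PROTEIN_LIPID)
    b = scan_trajectory(shuffled, top, PROTEIN_LIPID)
    assert a.counts == b.counts


def test_persistence_concatenation(contact_fixture):
    cfg, top, trj = contact_fixture
    t1, t2 = trj[:40], trj[40:]
    p1 = scan_trajectory(t1, top, PROTEIN_LIPID)
    p2 = scan_trajectory(t2, top, PROTEIN_LIPID)
    whole = scan_trajectory(trj, top, PROTEIN_LIPID)
    pooled = p1 + p2
    assert pooled.n_frames == whole.n_frames
    assert pooled.counts == whole.counts


def test_persistence_symmetry(contact_table):
    for (a, b, cls), _ in contact_table.items():
        assert (a, b) == canonical_pair(b, a)
        assert contact_table.persistence(a, b, cls) == \
            contact_table.persistence(b, a, cls)


def test_cutoff_monotonicity(contact_fixture):
    _, top, trj = contact_fixture
    short = scan_trajectory(trj[:25], top, PROTEIN_LIPID, DEFAULT_CUTOFFS)
    wide = scan_trajectory(trj[:25], top, PROTEIN_LIPID,
                           DEFAULT_CUTOFFS.scaled(2.0))
    for key, k in short.counts.items():
        assert wide.counts.get(key, 0) >= k


def test_table_tsv_round_trip(tmp_path, contact_table):
    path = tmp_path / "table.tsv"
    contact_table.to_tsv(path)
    back = PersistenceTable.from_tsv(path)
    assert back.counts == contact_table.counts
    assert back.n_frames == contact_table.n_frames



def test_scan_matches_brute_force_recount(contact_fixture):
    """Full table equals an independent O(N²) frame-by-frame recount."""
    from oracles import brute_force_recount

    _, top, trj = contact_fixture
    sub = trj[:30]
    fast = scan_trajectory(sub, top, PROTEIN_LIPID)
    slow = brute_force_recount(sub, top, PROTEIN_LIPID)
    assert fast.counts == slow.counts
    assert fast.n_frames == slow.n_frames
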