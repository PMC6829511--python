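"""Frame-wise detection of noncovalent contacts and persistence accumulation.

Three interaction classes are detected with the geometric criteria standard in
residue-interaction-network analysis:

* hydrogen bond — donor-acceptor distance ≤ 3.5 Å and donor-H-acceptor angle
  ≥ 120°;
* salt bridge — any-atom distance ≤ 4.5 Å between oppositely charged groups;
* hydrophobic — distance ≤ 5.0 Å between the centres of mass of apolar
  side-chain groups (apolar residue set, lipid acyl carbons, myristoyl chain).

Persistence of a contact is the fraction of analyzed frames in which its
geometric criterion is fulfilled; a pair may carry the three classes
independently.  Hydrogens are associated to donors geometrically (element H,
same residue, within 1.3 Å of the donor in the frame) since coarse-grained
topologies carry no bond table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import NoHydrogensError
from .trajectory_io import (
    CHARGED_NEGATIVE,
    CHARGED_POSITIVE,
    HBOND_ACCEPTOR,
    HBOND_DONOR,
    HYDROPHOBIC,
    HYDROPHOBIC_RESIDUES,
    LIPID_CLASSES,
    LeafletAssignment,
    Topology,
    Trajectory,
    assign_leaflets,
    minimum_image,
)

HBOND = "hbond"
SALTBRIDGE = "saltbridge"
HYDROPHOBIC_CLASS = "hydrophobic"
CLASSES = (HBOND, SALTBRIDGE, HYDROPHOBIC_CLASS)

INTRA_PROTEIN = "intra_protein"
PROTEIN_LIPID = "protein_lipid"

_H_ATTACH_DIST = 1.3  # Å, donor-hydrogen association radius


@dataclass(frozen=True)
class Cutoffs:
    """Geometric criteria; defaults follow the residue-interaction-network
    convention (all overridable)."""

    hbond_distance: float = 3.5       # Å donor-acceptor
    hbond_angle: float = 120.0        # degrees, donor-H-acceptor minimum
    saltbridge_distance: float = 4.5  # Å any-atom between charged groups
    hydrophobic_distance: float = 5.0  # Å between group centres of mass

    def scaled(self, factor: float) -> "Cutoffs":
        return Cutoffs(
            self.hbond_distance * factor, self.hbond_angle,
            self.saltbridge_distance * factor,
            self.hydrophobic_distance * factor,
        )


DEFAULT_CUTOFFS = Cutoffs()


@dataclass(frozen=True)
class ContactRecord:
    node_a: str
    node_b: str
    interaction_class: str
    frame_index: int


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


class PersistenceTable:
    """Per (node pair, class) contact counts over a number of frames."""

    def __init__(self, counts: dict | None = None, n_frames: int = 0):
        self.counts: dict[tuple[str, str, str], int] = dict(counts or {})
        self.n_frames = int(n_frames)

    def persistence(self, node_a: str, node_b: str, cls: str) -> float:
        a, b = canonical_pair(node_a, node_b)
        return self.counts.get((a, b, cls), 0) / self.n_frames

    def items(self):
        for (a, b, cls), k in self.counts.items():
            yield (a, b, cls), k / self.n_frames

    def class_table(self, cls: str) -> dict[tuple[str, str], float]:
        return {
            (a, b): k / self.n_frames
            for (a, b, c), k in self.counts.items() if c == cls
        }

    def concatenate(self, other: "PersistenceTable") -> "PersistenceTable":
        """Pool counts from a second replica: persistence on the concatenated
        trajectory is (k1+k2)/(n1+n2)."""
        merged = dict(self.counts)
        for key, k in other.counts.items():
            merged[key] = merged.get(key, 0) + k
        return PersistenceTable(merged, self.n_frames + other.n_frames)

    __add__ = concatenate

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"node_a": a, "node_b": b, "class": c, "count": k,
             "n_frames": self.n_frames, "persistence": k / self.n_frames}
            for (a, b, c), k in sorted(self.counts.items())
        ]
        return pd.DataFrame(
            rows, columns=["node_a", "node_b", "class", "count",
                           "n_frames", "persistence"]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PersistenceTable":
        n = int(df["n_frames"].iloc[0]) if len(df) else 0
        counts = {
            (str(a), str(b), str(c)): int(k)
            for a, b, c, k in zip(df["node_a"], df["node_b"],
                                  df["class"], df["count"])
        }
        return cls(counts, n)

    @classmethod
    def from_tsv(cls, path) -> "PersistenceTable":
        return cls.from_frame(pd.read_csv(path, sep="\t"))

    @classmethod
    def from_persistences(cls, pairs: dict, n_frames: int,
                          interaction_class: str) -> "PersistenceTable":
        """Build a single-class table from {(a, b): persistence} fractions."""
        counts = {}
        for (a, b), p in pairs.items():
            a, b = canonical_pair(a, b)
            counts[(a, b, interaction_class)] = int(round(p * n_frames))
        return cls(counts, n_frames)


# -- geometry groups -------------------------------------------------------

class _InteractionGroups:
    """Precomputed atom/group index sets for one topology + scope."""

    def __init__(self, topology: Topology, scope: str):
        if scope not in (INTRA_PROTEIN, PROTEIN_LIPID):
            raise ValueError(f"unknown scope {scope!r}")
        self.scope = scope
        self.top = topology
        res = topology.residues
        self.node_key = np.array([r.node_key for r in res])
        self.mol_class = np.array([r.molecule_class for r in res])
        self.resid = np.array([r.resid for r in res])
        self.chain = np.array([r.chain for r in res])
        self.is_protein_side = np.isin(self.mol_class, ["protein", "myristoyl"])
        self.is_lipid = np.isin(self.mol_class, list(LIPID_CLASSES))

        resindex = topology.atom_resindex
        donor_mask = topology.role_mask(HBOND_DONOR)
        acc_mask = topology.role_mask(HBOND_ACCEPTOR)
        pos_mask = topology.role_mask(CHARGED_POSITIVE)
        neg_mask = topology.role_mask(CHARGED_NEGATIVE)
        hyd_mask = topology.role_mask(HYDROPHOBIC)
        self.h_mask = topology.elements == "H"

        side_a = self.is_protein_side[resindex]
        if scope == INTRA_PROTEIN:
            side_b = side_a
        else:
            side_b = self.is_lipid[resindex]

        self.donors_a = np.flatnonzero(donor_mask & side_a)
        self.acceptors_a = np.flatnonzero(acc_mask & side_a)
        self.donors_b = np.flatnonzero(donor_mask & side_b)
        self.acceptors_b = np.flatnonzero(acc_mask & side_b)
        self.pos_a = np.flatnonzero(pos_mask & side_a)
        self.neg_a = np.flatnonzero(neg_mask & side_a)
        self.pos_b = np.flatnonzero(pos_mask & side_b)
        self.neg_b = np.flatnonzero(neg_mask & side_b)
        self.hydrogens = np.flatnonzero(self.h_mask)

        # hydrophobic groups: apolar protein residues, myristoyl, lipid acyl
        self.hyd_groups_a, self.hyd_groups_b = [], []
        for r in res:
            atoms = r.atom_indices[hyd_mask[r.atom_indices]]
            if len(atoms) == 0:
                continue
            if r.molecule_class == "protein" and \
                    r.resname not in HYDROPHOBIC_RESIDUES:
                continue
            if self.is_protein_side[r.index]:
                self.hyd_groups_a.append((r.index, atoms))
            if scope == INTRA_PROTEIN and self.is_protein_side[r.index]:
                self.hyd_groups_b.append((r.index, atoms))
            elif scope == PROTEIN_LIPID and self.is_lipid[r.index]:
                self.hyd_groups_b.append((r.index, atoms))

    def pair_allowed(self, ra: int, rb: int) -> bool:
        """Exclude self-pairs and, intra-protein, sequence neighbours i, i±1."""
        if ra == rb:
            return False
        if self.scope == INTRA_PROTEIN:
            if (self.mol_class[ra] == "protein"
                    and self.mol_class[rb] == "protein"
                    and self.chain[ra] == self.chain[rb]
                    and abs(int(self.resid[ra]) - int(self.resid[rb])) <= 1):
                return False
        return True


def _pair_distances(coords, idx_a, idx_b, box):
    """Min-image distance matrix between two atom index sets."""
    if len(idx_a) == 0 or len(idx_b) == 0:
        return np.empty((len(idx_a), len(idx_b)))
    diff = coords[idx_a][:, None, :] - coords[idx_b][None, :, :]
    diff = minimum_image(diff, box)
    return np.linalg.norm(diff, axis=-1)


def _emit(records, groups, ra, rb, cls, frame_index, upper_set):
    if not groups.pair_allowed(ra, rb):
        return
    if groups.scope == PROTEIN_LIPID:
        # orient: node_a protein side, node_b lipid; require upper leaflet
        if groups.is_lipid[ra]:
            ra, rb = rb, ra
        if upper_set is not None and rb not in upper_set:
            return
    a, b = groups.node_key[ra], groups.node_key[rb]
    a, b = canonical_pair(a, b)
    records.add((a, b, cls, frame_index))


def classify_frame_interactions(
    frame_coords: np.ndarray,
    topology: Topology,
    scope: str,
    cutoffs: Cutoffs = DEFAULT_CUTOFFS,
    box: np.ndarray | None = None,
    leaflets: LeafletAssignment | None = None,
    frame_index: int = 0,
    _groups: _InteractionGroups | None = None,
) -> set[ContactRecord]:
    """Detect every qualifying contact in one frame.

    Returns one :class:`ContactRecord` per (pair, class); a pair satisfying
    several criteria in the same frame yields one record per class.
    """
    g = _groups or _InteractionGroups(topology, scope)
    if box is None:
        box = np.array([1e6, 1e6, 1e6])
    upper_set = None
    if scope == PROTEIN_LIPID:
        if leaflets is None:
            leaflets = assign_leaflets(topology, frame_coords)
        upper_set = set(leaflets.residues("upper"))
    resindex = topology.atom_resindex
    found: set[tuple] = set()

    # --- salt bridges -----------------------------------------------------
    for idx_a, idx_b in ((g.pos_a, g.neg_b), (g.neg_a, g.pos_b)):
        d = _pair_distances(frame_coords, idx_a, idx_b, box)
        for i, j in zip(*np.nonzero(d <= cutoffs.saltbridge_distance)):
            _emit(found, g, resindex[idx_a[i]], resindex[idx_b[j]],
                  SALTBRIDGE, frame_index, upper_set)

    # --- hydrogen bonds ---------------------------------------------------
    for donors, acceptors in ((g.donors_a, g.acceptors_b),
                              (g.donors_b, g.acceptors_a)):
        if len(donors) == 0 or len(acceptors) == 0:
            continue
        if len(g.hydrogens) == 0:
            raise NoHydrogensError(
                "H-bond detection requires hydrogen atoms; none present"
            )
        d_da = _pair_distances(frame_coords, donors, acceptors, box)
        cand = np.nonzero(d_da <= cutoffs.hbond_distance)
        if len(cand[0]) == 0:
            continue
        d_dh = _pair_distances(frame_coords, donors, g.hydrogens, box)
        for i, j in zip(*cand):
            di, aj = donors[i], acceptors[j]
            if resindex[di] == resindex[aj]:
                continue
            hs = g.hydrogens[
                (d_dh[i] <= _H_ATTACH_DIST)
                & (resindex[g.hydrogens] == resindex[di])
            ]
            for h in hs:
                v1 = minimum_image(frame_coords[di] - frame_coords[h], box)
                v2 = minimum_image(frame_coords[aj] - frame_coords[h], box)
                cosang = np.dot(v1, v2) / (
                    np.linalg.norm(v1) * np.linalg.norm(v2) + 1e-30
                )
                angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                if angle >= cutoffs.hbond_angle:
                    _emit(found, g, resindex[di], resindex[aj],
                          HBOND, frame_index, upper_set)
                    break

    # --- hydrophobic ------------------------------------------------------
    if g.hyd_groups_a and g.hyd_groups_b:
        com_a = np.array([frame_coords[at].mean(axis=0)
                          for _, at in g.hyd_groups_a])
        com_b = np.array([frame_coords[at].mean(axis=0)
                          for _, at in g.hyd_groups_b])
        diff = minimum_image(com_a[:, None, :] - com_b[None, :, :], box)
        d = np.linalg.norm(diff, axis=-1)
        for i, j in zip(*np.nonzero(d <= cutoffs.hydrophobic_distance)):
            _emit(found, g, g.hyd_groups_a[i][0], g.hyd_groups_b[j][0],
                  HYDROPHOBIC_CLASS, frame_index, upper_set)

    return {ContactRecord(a, b, c, f) for (a, b, c, f) in found}


def scan_trajectory(
    trajectory: Trajectory,
    topology: Topology,
    scope: str,
    cutoffs: Cutoffs = DEFAULT_CUTOFFS,
    leaflet_mode: str = "per_frame",
) -> PersistenceTable:
    """Accumulate frame-wise contacts into a persistence table.

    ``leaflet_mode``: ``per_frame`` recomputes leaflet membership every frame
    (default); ``initial`` fixes it at the first frame.
    """
    if trajectory.n_frames == 0:
        raise ValueError("empty trajectory")
    groups = _InteractionGroups(topology, scope)
    leaflets = None
    if scope == PROTEIN_LIPID and leaflet_mode == "initial":
        leaflets = assign_leaflets(topology, trajectory.coords[0])
    counts: dict[tuple[str, str, str], int] = {}
    for f in range(trajectory.n_frames):
        frame_leaflets = leaflets
        if scope == PROTEIN_LIPID and leaflet_mode == "per_frame":
            frame_leaflets = assign_leaflets(topology, trajectory.coords[f])
        records = classify_frame_interactions(
            trajectory.coords[f], topology, scope, cutoffs,
            box=trajectory.box[f], leaflets=frame_leaflets,
            frame_index=f, _groups=groups,
        )
        for rec in records:
            key = (rec.node_a, rec.node_b, rec.interaction_class)
            counts[key] = counts.get(key, 0) + 1
    return PersistenceTable(counts, trajectory.n_frames)
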