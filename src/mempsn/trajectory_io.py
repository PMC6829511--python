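"""Topology/trajectory loading, chemical-role assignment and leaflet analysis.

File parsing is delegated to MDAnalysis; this module converts parsed systems
into the package's lightweight data model (numpy-backed :class:`Topology` and
:class:`Trajectory`), assigns chemical roles from an editable YAML lookup and
classifies lipids into bilayer leaflets.

Internal units are Å for length, ns for time and elementary charges for
charge.  MDAnalysis already reports lengths in Å; times arrive in ps and are
converted at the boundary.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

from .exceptions import (
    EmptyTrajectoryError,
    FormatError,
    NoMembraneError,
    TopologyMismatchError,
    UnknownResidueError,
)

# Role labels
HBOND_DONOR = "hbond_donor"
HBOND_ACCEPTOR = "hbond_acceptor"
CHARGED_POSITIVE = "charged_positive"
CHARGED_NEGATIVE = "charged_negative"
HYDROPHOBIC = "hydrophobic"

LIPID_CLASSES = ("lipid_PS", "lipid_PE", "lipid_PC")

#: Residues whose side chains enter the hydrophobic-contact criterion.
HYDROPHOBIC_RESIDUES = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO"}
)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "HSP": "H",
    "ILE": "I", "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F",
    "PRO": "P", "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y",
    "VAL": "V",
}

_MAP_KEYS = {
    "donors": HBOND_DONOR,
    "acceptors": HBOND_ACCEPTOR,
    "positive": CHARGED_POSITIVE,
    "negative": CHARGED_NEGATIVE,
    "hydrophobic": HYDROPHOBIC,
}


class RoleMap:
    """Lookup of molecule class and per-atom roles keyed by residue name."""

    def __init__(self, mapping: dict):
        self.backbone_donors = set(mapping.get("backbone", {}).get("donors", []))
        self.backbone_acceptors = set(
            mapping.get("backbone", {}).get("acceptors", [])
        )
        self.residues = mapping.get("residues", {})

    def __contains__(self, resname: str) -> bool:
        return resname in self.residues

    def molecule_class(self, resname: str) -> str:
        return self.residues[resname]["class"]

    def atom_roles(self, resname: str, atom_name: str) -> frozenset:
        """Roles for one atom; a pure function of (residue_name, atom_name)."""
        entry = self.residues[resname]
        roles = set()
        for key, role in _MAP_KEYS.items():
            if atom_name in entry.get(key, []):
                roles.add(role)
        # acyl carbons of lipids join the hydrophobic group
        if atom_name in entry.get("acyl", []):
            roles.add(HYDROPHOBIC)
        if entry["class"] == "protein":
            if atom_name in self.backbone_donors:
                roles.add(HBOND_DONOR)
            if atom_name in self.backbone_acceptors:
                roles.add(HBOND_ACCEPTOR)
        return frozenset(roles)

    def headgroup_atoms(self, resname: str) -> set:
        return set(self.residues[resname].get("headgroup", []))

    def formal_charge(self, resname: str):
        return self.residues[resname].get("formal_charge")


def load_role_map(path=None) -> RoleMap:
    """Load the role lookup; the packaged default covers the 20 amino acids,
    PS/PE/PC lipids and the myristoyl group."""
    if path is None:
        ref = importlib.resources.files("mempsn.data") / "role_map.yaml"
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return RoleMap(yaml.safe_load(text))


def load_vdw_radii(path=None) -> dict:
    if path is None:
        ref = importlib.resources.files("mempsn.data") / "vdw_radii.yaml"
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return {str(k).upper(): float(v) for k, v in yaml.safe_load(text).items()}


@dataclass
class AtomRecord:
    atom_id: int
    name: str
    element: str
    residue_id: int
    residue_name: str
    chain: str
    roles: frozenset = frozenset()
    charge: float | None = None
    radius: float | None = None


@dataclass
class Residue:
    index: int              # position in Topology.residues
    resid: int
    resname: str
    chain: str
    atom_indices: np.ndarray
    molecule_class: str
    headgroup_indices: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=int)
    )

    @property
    def node_key(self) -> str:
        """Network node key: one-letter code + resid for protein residues
        (e.g. ``R43``), ``MYR`` for the myristoyl group, ``PS_17``-style keys
        for lipids."""
        if self.molecule_class == "protein":
            one = THREE_TO_ONE.get(self.resname, "X")
            return f"{one}{self.resid}"
        if self.molecule_class == "myristoyl":
            return "MYR"
        if self.molecule_class in LIPID_CLASSES:
            return f"{self.molecule_class.split('_')[1]}_{self.resid}"
        return f"{self.resname}_{self.resid}"


class Topology:
    """Atoms grouped into residues, with roles and molecule classes assigned."""

    def __init__(self, atoms: list[AtomRecord], residues: list[Residue]):
        self.atoms = atoms
        self.residues = residues
        self.n_atoms = len(atoms)
        # cached arrays
        self._names = np.array([a.name for a in atoms])
        self._elements = np.array([a.element for a in atoms])
        self._resindex = np.empty(self.n_atoms, dtype=int)
        for res in residues:
            self._resindex[res.atom_indices] = res.index
        self._role_masks: dict[str, np.ndarray] = {}

    # -- selections -------------------------------------------------------
    def role_mask(self, role: str) -> np.ndarray:
        if role not in self._role_masks:
            self._role_masks[role] = np.array(
                [role in a.roles for a in self.atoms], dtype=bool
            )
        return self._role_masks[role]

    @property
    def elements(self) -> np.ndarray:
        return self._elements

    @property
    def atom_resindex(self) -> np.ndarray:
        return self._resindex

    def residues_of_class(self, *classes: str) -> list[Residue]:
        return [r for r in self.residues if r.molecule_class in classes]

    @property
    def lipid_residues(self) -> list[Residue]:
        return self.residues_of_class(*LIPID_CLASSES)

    @property
    def protein_residues(self) -> list[Residue]:
        return self.residues_of_class("protein")

    @property
    def myristoyl_residues(self) -> list[Residue]:
        return self.residues_of_class("myristoyl")

    def select_atoms(self, *, molecule_class=None, atom_names=None,
                     node_keys=None) -> np.ndarray:
        """Atom indices matching all given filters."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if molecule_class is not None:
            classes = (
                {molecule_class} if isinstance(molecule_class, str)
                else set(molecule_class)
            )
            res_ok = np.array(
                [r.molecule_class in classes for r in self.residues]
            )
            mask &= res_ok[self._resindex]
        if node_keys is not None:
            keys = {node_keys} if isinstance(node_keys, str) else set(node_keys)
            res_ok = np.array([r.node_key in keys for r in self.residues])
            mask &= res_ok[self._resindex]
        if atom_names is not None:
            names = {atom_names} if isinstance(atom_names, str) else set(atom_names)
            mask &= np.isin(self._names, list(names))
        return np.flatnonzero(mask)

    def charges(self) -> np.ndarray:
        """Per-atom charge array with NaN for unknown charges."""
        return np.array(
            [np.nan if a.charge is None else a.charge for a in self.atoms]
        )


@dataclass
class Trajectory:
    """Ordered frames: coordinates (Å), orthorhombic box lengths (Å), times (ns)."""

    coords: np.ndarray   # (n_frames, n_atoms, 3)
    box: np.ndarray      # (n_frames, 3)
    times: np.ndarray    # (n_frames,)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3:
            raise ValueError("coords must be (n_frames, n_atoms, 3)")
        if len(self.times) != len(self.coords):
            raise ValueError("times length must equal frame count")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("frame times must be nondecreasing")

    @property
    def n_frames(self) -> int:
        return len(self.coords)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def __getitem__(self, idx) -> "Trajectory":
        idx = np.atleast_1d(np.arange(self.n_frames)[idx])
        return Trajectory(self.coords[idx], self.box[idx], self.times[idx])

    def concatenate(self, other: "Trajectory") -> "Trajectory":
        """Concatenate replicas; mirrors joining independent runs into one
        analysis trajectory.  Times of the second block are shifted to keep
        monotonicity."""
        if other.n_atoms != self.n_atoms:
            raise TopologyMismatchError("atom counts differ between replicas")
        shift = self.times[-1] - other.times[0]
        dt = np.median(np.diff(self.times)) if self.n_frames > 1 else 1.0
        return Trajectory(
            np.concatenate([self.coords, other.coords]),
            np.concatenate([self.box, other.box]),
            np.concatenate([self.times, other.times + shift + dt]),
        )


@dataclass
class LeafletAssignment:
    """Per-lipid leaflet labels plus a bimodality diagnostic."""

    labels: dict            # residue index -> "upper" | "lower"
    midplane_z: float
    well_separated: bool
    separation_score: float

    def residues(self, leaflet: str) -> list[int]:
        return [ri for ri, lab in self.labels.items() if lab == leaflet]


def minimum_image(vectors: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors
    (orthorhombic box)."""
    vectors = np.asarray(vectors, dtype=float)
    box = np.asarray(box, dtype=float)
    return vectors - box * np.round(vectors / box)


def _element_from_name(name: str) -> str:
    stripped = name.lstrip("0123456789")
    if not stripped:
        return "X"
    if len(stripped) >= 2 and stripped[:2].upper() in ("CL", "NA", "MG", "BR"):
        return stripped[:2].capitalize()
    return stripped[0].upper()


def _universe(structure_path, *traj, **kw):
    import MDAnalysis as mda

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return mda.Universe(str(structure_path), *map(str, traj), **kw)
    except (OSError, ValueError, EOFError) as exc:
        raise FormatError(f"cannot parse {structure_path}: {exc}") from exc


def load_topology(structure_path, role_map: RoleMap | None = None,
                  on_unknown: str = "error") -> Topology:
    """Read a PDB or GRO file into a :class:`Topology`.

    Unknown residue names are reported: ``on_unknown='error'`` raises
    :class:`UnknownResidueError`; ``'warn'`` emits a warning and labels the
    residue class ``unknown`` (never silently dropped).
    """
    if role_map is None:
        role_map = load_role_map()
    u = _universe(structure_path)
    return topology_from_universe(u, role_map, on_unknown=on_unknown)


def topology_from_universe(u, role_map: RoleMap,
                           on_unknown: str = "error") -> Topology:
    unknown = sorted(
        {str(r) for r in set(u.residues.resnames) if str(r) not in role_map}
    )
    if unknown:
        if on_unknown == "error":
            raise UnknownResidueError(unknown)
        warnings.warn(
            "residues not in role map treated as class 'unknown': "
            + ", ".join(unknown)
        )

    atoms: list[AtomRecord] = []
    residues: list[Residue] = []
    for ridx, res in enumerate(u.residues):
        resname = str(res.resname)
        known = resname in role_map
        mol_class = role_map.molecule_class(resname) if known else "unknown"
        head_names = role_map.headgroup_atoms(resname) if known else set()
        idxs, head_idxs = [], []
        for atom in res.atoms:
            name = str(atom.name)
            try:
                element = str(atom.element).capitalize() or _element_from_name(name)
            except Exception:
                element = _element_from_name(name)
            try:
                chain = str(atom.segid) or "A"
            except Exception:
                chain = "A"
            roles = role_map.atom_roles(resname, name) if known else frozenset()
            atoms.append(AtomRecord(
                atom_id=int(atom.ix), name=name, element=element,
                residue_id=int(res.resid), residue_name=resname,
                chain=chain, roles=roles,
            ))
            idxs.append(int(atom.ix))
            if name in head_names:
                head_idxs.append(int(atom.ix))
        residues.append(Residue(
            index=ridx, resid=int(res.resid), resname=resname,
            chain=atoms[idxs[0]].chain if idxs else "A",
            atom_indices=np.array(idxs, dtype=int),
            molecule_class=mol_class,
            headgroup_indices=np.array(head_idxs, dtype=int),
        ))
    atoms.sort(key=lambda a: a.atom_id)
    return Topology(atoms, residues)


def _frame_box(ts):
    if ts.dimensions is None or not np.all(ts.dimensions[:3] > 0):
        return np.array([1e6, 1e6, 1e6])  # effectively non-periodic
    return np.array(ts.dimensions[:3], dtype=float)


def load_trajectory(topology: Topology, trajectory_path,
                    structure_path=None) -> Trajectory:
    """Read XTC/DCD/multi-model-PDB/GRO frames; coordinates in Å, times in ns.

    ``structure_path`` may supply the topology file MDAnalysis needs to pair
    with a coordinate-only format; by default the trajectory file itself is
    opened standalone (works for PDB/GRO).
    """
    import MDAnalysis as mda

    path = str(trajectory_path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if structure_path is not None:
                u = mda.Universe(str(structure_path), path)
            else:
                u = mda.Universe(path)
        except (OSError, ValueError, EOFError, IndexError) as exc:
            raise FormatError(f"cannot parse {path}: {exc}") from exc

    if len(u.atoms) != topology.n_atoms:
        raise TopologyMismatchError(
            f"trajectory has {len(u.atoms)} atoms, topology {topology.n_atoms}"
        )
    coords, boxes, times = [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ts in u.trajectory:
            coords.append(ts.positions.astype(float).copy())
            boxes.append(_frame_box(ts))
            # MDAnalysis times are ps
            times.append(float(ts.time) / 1000.0)
    if not coords:
        raise EmptyTrajectoryError(f"{path} contains no frames")
    times = np.array(times)
    if np.any(np.diff(times) < 0):  # writers without time metadata
        times = np.arange(len(coords), dtype=float)
    return Trajectory(np.array(coords), np.array(boxes), times)


def assign_leaflets(topology: Topology, frame_coords: np.ndarray,
                    ) -> LeafletAssignment:
    """Split lipids into upper/lower leaflets by head-group centroid z.

    The midplane is the mean z over all lipid head-group centroids; lipids at
    or above it are ``upper`` (documented tie-break).  The separation score is
    the between-class fraction of the z-variance explained by the midplane
    split: ~1 for a true bilayer, ≤ ~0.75 for unimodal (micelle-like) z
    distributions, flagged below 0.85.
    """
    lipids = topology.lipid_residues
    if not lipids:
        raise NoMembraneError("no lipid residues in topology")
    if len(lipids) < 2:
        raise NoMembraneError("need at least 2 lipids for leaflet assignment")
    z = np.array([
        frame_coords[r.headgroup_indices
                     if len(r.headgroup_indices) else r.atom_indices, 2].mean()
        for r in lipids
    ])
    midplane = float(z.mean())
    labels = {
        r.index: ("upper" if zi >= midplane else "lower")
        for r, zi in zip(lipids, z)
    }
    upper = z[z >= midplane]
    lower = z[z < midplane]
    total_var = z.var()
    if len(lower) == 0 or len(upper) == 0 or total_var < 1e-12:
        score = 0.0
    else:
        between = (
            len(upper) / len(z) * (upper.mean() - midplane) ** 2
            + len(lower) / len(z) * (lower.mean() - midplane) ** 2
        )
        score = float(between / total_var)
    return LeafletAssignment(
        labels=labels, midplane_z=midplane,
        well_separated=bool(score > 0.85), separation_score=score,
    )


# -- writers ---------------------------------------------------------------

def to_universe(topology: Topology, trajectory: Trajectory | None = None):
    """Build an MDAnalysis Universe from the internal data model (for writing)."""
    import MDAnalysis as mda

    n_res = len(topology.residues)
    u = mda.Universe.empty(
        topology.n_atoms, n_residues=n_res,
        atom_resindex=topology.atom_resindex,
        residue_segindex=np.zeros(n_res, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("name", [a.name for a in topology.atoms])
    u.add_TopologyAttr("element", [a.element for a in topology.atoms])
    u.add_TopologyAttr("resname", [r.resname for r in topology.residues])
    u.add_TopologyAttr("resid", [r.resid for r in topology.residues])
    u.add_TopologyAttr("segid", ["SYS"])
    if trajectory is not None:
        from MDAnalysis.coordinates.memory import MemoryReader

        dims = np.column_stack([
            trajectory.box,
            np.full((trajectory.n_frames, 3), 90.0),
        ])
        u.load_new(
            trajectory.coords.astype(np.float32), format=MemoryReader,
            dimensions=dims, dt=float(
                np.median(np.diff(trajectory.times)) * 1000.0
            ) if trajectory.n_frames > 1 else 1000.0,
        )
    return u


def write_structure(topology: Topology, trajectory: Trajectory, path) -> None:
    """Write frame 0 as PDB or GRO (by extension)."""
    u = to_universe(topology, trajectory[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def write_trajectory(topology: Topology, trajectory: Trajectory, path) -> None:
    """Write all frames (multi-model PDB, XTC or DCD by extension)."""
    import MDAnalysis as mda

    u = to_universe(topology, trajectory)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=topology.n_atoms) as w:
            for _ in u.trajectory:
                w.write(u.atoms)
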