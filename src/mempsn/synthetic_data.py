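"""Seeded generators for coarse-grained test systems.

All fixtures are bead models, not all-atom lipids: the analysis chain operates
on chemical roles and geometry, so one charged/polar bead per functional group
and a couple of acyl beads per lipid exercise every detector while keeping
generation in milliseconds.  Every generator is a pure function of its
configuration (seed included).

Generators:

* a two-leaflet bilayer patch with the disc-membrane composition
  (260 lipids, 20% PS / 40% PE / 40% PC by default) whose head groups perform
  independent 2D Brownian motion at a configurable diffusion coefficient;
* a protein-like chain above the patch whose residues make geometric contacts
  with named upper-leaflet lipids according to a prescribed persistence
  schedule (each scheduled contact holds in exactly round(p·n_frames) frames
  and is violated by ≥ 1 Å otherwise);
* a scripted myristoyl-chain descent whose computed SASA falls from the
  solvated plateau to a buried level between configurable start/end times —
  burial is enforced by cage beads (scripted acyl packing of the nearest
  lipids) that fully enclose below-plane chain beads;
* deterministic toy graphs and a persistence table whose largest-cluster-size
  curve follows a logistic with a prescribed inflection, for threshold-
  selection tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .exceptions import ConfigError
from .interactions import (
    HBOND,
    HYDROPHOBIC_CLASS,
    SALTBRIDGE,
    PersistenceTable,
    canonical_pair,
)
from .trajectory_io import (
    HYDROPHOBIC_RESIDUES,
    THREE_TO_ONE,
    AtomRecord,
    Residue,
    RoleMap,
    Topology,
    Trajectory,
    load_role_map,
)

ONE_TO_THREE: dict[str, str] = {}
for _three, _one in THREE_TO_ONE.items():
    ONE_TO_THREE.setdefault(_one, _three)

LIPID_RESNAMES = {"PS": "DGPS", "PE": "DGPE", "PC": "DGPC"}

CM2_PER_S_TO_A2_PER_NS = 1e7

# bilayer geometry (Å): head-group planes of the two leaflets
BILAYER_CENTER_Z = 50.0
LEAFLET_HALF_THICKNESS = 18.5


@dataclass
class ContactScheduleEntry:
    protein_node: str       # e.g. "R43" or "MYR"
    lipid_node: str         # e.g. "PS_17" (upper-leaflet lipid)
    interaction_class: str  # hbond | saltbridge | hydrophobic
    persistence: float      # target fraction of frames in contact


@dataclass
class GeneratorConfig:
    """Study conditions for the fixture generators.

    Defaults mirror the simulated disc-membrane system: 260 lipids at
    20/40/40 PS/PE/PC in a 90 × 90 × 160 Å box.  The default lateral
    diffusion coefficient (5×10⁻⁷ cm²/s for every type) gives head-group
    displacements resolvable within short fixture trajectories.
    """

    seed: int = 0
    n_lipids: int = 260
    composition: tuple[float, float, float] = (0.20, 0.40, 0.40)  # PS, PE, PC
    box: tuple[float, float, float] = (90.0, 90.0, 160.0)
    diffusion: dict = field(
        default_factory=lambda: {"PS": 5e-7, "PE": 5e-7, "PC": 5e-7}
    )  # cm²/s
    n_frames: int = 500
    dt: float = 0.1  # ns
    contact_schedule: list[ContactScheduleEntry] = field(default_factory=list)
    insertion: tuple[float, float] | None = None   # (start, end) ns
    insertion_mode: str = "complete"               # or "dip"

    def __post_init__(self):
        if abs(sum(self.composition) - 1.0) > 1e-6:
            raise ConfigError("composition fractions must sum to 1")
        if self.n_frames < 1 or self.dt <= 0:
            raise ConfigError("need n_frames >= 1 and dt > 0")
        for e in self.contact_schedule:
            if not 0.0 <= e.persistence <= 1.0:
                raise ConfigError(
                    f"schedule persistence {e.persistence} outside [0, 1]"
                )
        seen = set()
        for e in self.contact_schedule:
            key = (e.protein_node, e.lipid_node, e.interaction_class)
            if key in seen:
                raise ConfigError(f"conflicting schedule entries for {key}")
            seen.add(key)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt


def largest_remainder(total: int, fractions) -> list[int]:
    """Integer counts proportional to ``fractions`` summing exactly to
    ``total`` (largest-remainder apportionment)."""
    raw = np.asarray(fractions, dtype=float) * total
    counts = np.floor(raw).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(raw - counts))
    for i in range(remainder):
        counts[order[i]] += 1
    return counts.tolist()


# -- bead construction -----------------------------------------------------

_LIPID_BEADS = {
    # name, dz from head plane (sign flipped for lower leaflet), charge
    "DGPS": [("P", 0.0, -1.0), ("O11", 0.9, 0.0), ("OC", 1.8, -1.0),
             ("N", 2.7, 1.0), ("HN1", 3.6, 0.0),
             ("CA1", -6.0, 0.0), ("CA2", -12.0, 0.0)],
    "DGPE": [("P", 0.0, -1.0), ("O11", 0.9, 0.0),
             ("N", 2.7, 1.0), ("HN1", 3.6, 0.0),
             ("CA1", -6.0, 0.0), ("CA2", -12.0, 0.0)],
    "DGPC": [("P", 0.0, -1.0), ("O11", 0.9, 0.0), ("N", 2.7, 1.0),
             ("CA1", -6.0, 0.0), ("CA2", -12.0, 0.0)],
}

_PROTEIN_BEADS = {
    # functional bead(s) per residue: (name, dz, charge)
    "ARG": [("NH1", 0.0, 1.0), ("HH11", -1.0, 0.0)],
    "LYS": [("NZ", 0.0, 1.0), ("HZ1", -1.0, 0.0)],
    "ASP": [("OD1", 0.0, -1.0)],
    "GLU": [("OE1", 0.0, -1.0)],
    "SER": [("OG", 0.0, 0.0), ("HG1", -1.0, 0.0)],
    "THR": [("OG1", 0.0, 0.0), ("HG1", -1.0, 0.0)],
    "ASN": [("ND2", 0.0, 0.0), ("HD21", -1.0, 0.0), ("OD1", 1.5, 0.0)],
    "GLN": [("NE2", 0.0, 0.0), ("HE21", -1.0, 0.0), ("OE1", 1.5, 0.0)],
}


def _protein_beads_for(resname: str):
    if resname in _PROTEIN_BEADS:
        return _PROTEIN_BEADS[resname]
    if resname in HYDROPHOBIC_RESIDUES:
        return [("CB", 0.0, 0.0)]
    return [("CB", 0.0, 0.0)]


class _SystemBuilder:
    """Accumulates beads into AtomRecord/Residue lists plus a static
    coordinate template."""

    def __init__(self, role_map: RoleMap):
        self.role_map = role_map
        self.atoms: list[AtomRecord] = []
        self.residues: list[Residue] = []
        self.coords: list[np.ndarray] = []

    def add_residue(self, resname: str, resid: int, beads, chain="A") -> Residue:
        known = resname in self.role_map
        mol_class = (self.role_map.molecule_class(resname)
                     if known else "unknown")
        head_names = (self.role_map.headgroup_atoms(resname)
                      if known else set())
        idxs, head_idxs = [], []
        for name, xyz, charge in beads:
            i = len(self.atoms)
            element = ("H" if name.startswith("H") else
                       name.lstrip("0123456789")[0].upper())
            roles = (self.role_map.atom_roles(resname, name)
                     if known else frozenset())
            self.atoms.append(AtomRecord(
                atom_id=i, name=name, element=element, residue_id=resid,
                residue_name=resname, chain=chain, roles=roles,
                charge=charge,
            ))
            self.coords.append(np.asarray(xyz, dtype=float))
            idxs.append(i)
            if name in head_names:
                head_idxs.append(i)
        res = Residue(
            index=len(self.residues), resid=resid, resname=resname,
            chain=chain, atom_indices=np.array(idxs, dtype=int),
            molecule_class=mol_class,
            headgroup_indices=np.array(head_idxs, dtype=int),
        )
        self.residues.append(res)
        return res

    def build(self) -> tuple[Topology, np.ndarray]:
        return Topology(self.atoms, self.residues), np.array(self.coords)


def _leaflet_type_assignment(config: GeneratorConfig):
    """Exact composition counts split between leaflets; returns the per-lipid
    type list, upper leaflet first."""
    counts = largest_remainder(config.n_lipids, config.composition)
    n_upper = config.n_lipids // 2
    upper_counts = [c // 2 for c in counts]
    deficit = n_upper - sum(upper_counts)
    i = 0
    while deficit > 0:
        if upper_counts[i] < counts[i]:
            upper_counts[i] += 1
            deficit -= 1
        i = (i + 1) % len(counts)
    types = ["PS", "PE", "PC"]
    upper = [t for t, c in zip(types, upper_counts) for _ in range(c)]
    lower = [t for t, c, u in zip(types, counts, upper_counts)
             for _ in range(c - u)]
    return upper, lower, counts


def _grid_positions(n: int, box_x: float, box_y: float,
                    rng: np.random.Generator) -> np.ndarray:
    cols = int(np.ceil(np.sqrt(n)))
    rows = int(np.ceil(n / cols))
    xs = (np.arange(cols) + 0.5) * box_x / cols
    ys = (np.arange(rows) + 0.5) * box_y / rows
    grid = np.array([(x, y) for y in ys for x in xs])[:n]
    return grid + rng.uniform(-0.5, 0.5, size=grid.shape)


def _brownian_xy(start: np.ndarray, n_frames: int, dt: float,
                 d_a2ns: np.ndarray, box_xy: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """(frames, beads, 2) wrapped 2D Brownian paths; per-bead D in Å²/ns."""
    sigma = np.sqrt(2.0 * d_a2ns * dt)[None, :, None]
    steps = rng.standard_normal((n_frames - 1, len(start), 2)) * sigma
    paths = np.concatenate([start[None], start[None] + np.cumsum(steps, 0)])
    return np.mod(paths, box_xy[None, None, :])


def _build_membrane(config: GeneratorConfig, builder: _SystemBuilder,
                    rng: np.random.Generator, start_resid: int = 1,
                    type_override=None):
    """Add all lipid residues; returns per-lipid metadata and head paths."""
    if type_override is None:
        upper_types, lower_types, _ = _leaflet_type_assignment(config)
    else:
        upper_types, lower_types = type_override
    all_types = upper_types + lower_types
    leaflets = ["upper"] * len(upper_types) + ["lower"] * len(lower_types)
    z_head = {
        "upper": BILAYER_CENTER_Z + LEAFLET_HALF_THICKNESS,
        "lower": BILAYER_CENTER_Z - LEAFLET_HALF_THICKNESS,
    }
    box_xy = np.array(config.box[:2])
    pos_upper = _grid_positions(len(upper_types), *box_xy, rng)
    pos_lower = _grid_positions(len(lower_types), *box_xy, rng)
    positions = np.concatenate([pos_upper, pos_lower])
    records = []
    for k, (ltype, leaf) in enumerate(zip(all_types, leaflets)):
        resname = LIPID_RESNAMES[ltype]
        sign = 1.0 if leaf == "upper" else -1.0
        beads = [
            (name, np.array([positions[k, 0], positions[k, 1],
                             z_head[leaf] + sign * dz]), q)
            for name, dz, q in _LIPID_BEADS[resname]
        ]
        res = builder.add_residue(resname, start_resid + k, beads, chain="M")
        records.append({
            "residue": res, "type": ltype, "leaflet": leaf,
            "xy0": positions[k],
        })
    d_a2ns = np.array([
        config.diffusion.get(r["type"], 5e-7) * CM2_PER_S_TO_A2_PER_NS
        for r in records
    ])
    paths = _brownian_xy(positions, config.n_frames, config.dt,
                         d_a2ns, box_xy, rng)
    return records, paths


def _membrane_coords(template: np.ndarray, records, paths,
                     n_frames: int) -> np.ndarray:
    """Propagate each lipid's lateral Brownian path to all its beads."""
    coords = np.repeat(template[None], n_frames, axis=0)
    for k, rec in enumerate(records):
        idx = rec["residue"].atom_indices
        offset = paths[:, k, :] - rec["xy0"][None, :]
        coords[:, idx, 0] += offset[:, 0:1]
        coords[:, idx, 1] += offset[:, 1:2]
    return coords


def generate_membrane_patch(
    config: GeneratorConfig | None = None,
    role_map: RoleMap | None = None,
) -> tuple[Topology, Trajectory]:
    """Two-leaflet bead bilayer with exact composition counts and laterally
    diffusing head groups (leaflet z-levels fixed)."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    builder = _SystemBuilder(role_map or load_role_map())
    records, paths = _build_membrane(config, builder, rng)
    topology, template = builder.build()
    coords = _membrane_coords(template, records, paths, config.n_frames)
    box = np.tile(np.asarray(config.box, dtype=float), (config.n_frames, 1))
    return topology, Trajectory(coords, box, config.times)


# -- scheduled-contact fixture --------------------------------------------

_CONTACT_GEOMETRY = {
    # class -> (lipid bead name resolver, contact distance Å)
    HBOND: 3.0,
    SALTBRIDGE: 4.0,
    HYDROPHOBIC_CLASS: 4.0,
}

_PROTEIN_Z = BILAYER_CENTER_Z + LEAFLET_HALF_THICKNESS + 16.5
_PROTEIN_SPACING = 15.0


def _parse_protein_node(node: str) -> tuple[str, int]:
    if node == "MYR":
        return "MYR", 9999
    one, resid = node[0], node[1:]
    if one not in ONE_TO_THREE or not resid.isdigit():
        raise ConfigError(f"cannot parse protein node {node!r}")
    return ONE_TO_THREE[one], int(resid)


def _parse_lipid_node(node: str) -> tuple[str, int]:
    try:
        ltype, resid = node.split("_")
        assert ltype in LIPID_RESNAMES
        return ltype, int(resid)
    except (ValueError, AssertionError) as exc:
        raise ConfigError(f"cannot parse lipid node {node!r}") from exc


def _contact_beads(entry: ContactScheduleEntry, resname: str):
    """(protein bead, lipid bead) names realising one scheduled class."""
    cls = entry.interaction_class
    if cls == SALTBRIDGE:
        if resname in ("ARG", "LYS"):
            return ("NH1" if resname == "ARG" else "NZ"), "P"
        if resname in ("ASP", "GLU"):
            return ("OD1" if resname == "ASP" else "OE1"), "N"
        raise ConfigError(
            f"{entry.protein_node}: residue {resname} carries no charged bead"
        )
    if cls == HBOND:
        donors = {"ARG": "NH1", "LYS": "NZ", "SER": "OG", "THR": "OG1",
                  "ASN": "ND2", "GLN": "NE2"}
        if resname not in donors:
            raise ConfigError(
                f"{entry.protein_node}: residue {resname} has no donor bead"
            )
        return donors[resname], "O11"
    if cls == HYDROPHOBIC_CLASS:
        if resname != "MYR" and resname not in HYDROPHOBIC_RESIDUES:
            raise ConfigError(
                f"{entry.protein_node}: residue {resname} is not in the "
                "hydrophobic set"
            )
        return ("C1" if resname == "MYR" else "CB"), "CA1"
    raise ConfigError(f"unknown interaction class {cls!r}")


def generate_contact_trajectory(
    config: GeneratorConfig,
    role_map: RoleMap | None = None,
) -> tuple[Topology, Trajectory]:
    """Membrane patch plus a protein-like chain realising the contact
    schedule exactly.

    For every scheduled (pair, class, p) the class geometry is satisfied in
    exactly ``round(p · n_frames)`` seeded-random frames and violated by at
    least 1 Å in all others.  Scheduled lipid nodes must name upper-leaflet
    lipids; the generator retypes lipids (swapping within the leaflet) so the
    named nodes exist.
    """
    rng = np.random.default_rng(config.seed)
    builder = _SystemBuilder(role_map or load_role_map())

    # protein chain first (resids must not collide with lipids)
    prot_nodes = sorted(
        {e.protein_node for e in config.contact_schedule},
        key=lambda n: _parse_protein_node(n)[1],
    )
    n_lip = config.n_lipids
    lipid_start_resid = 1
    prot_positions = {}
    for j, node in enumerate(prot_nodes):
        resname, resid = _parse_protein_node(node)
        x = 10.0 + j * _PROTEIN_SPACING
        y = config.box[1] / 2.0
        if x > config.box[0] - 5:
            raise ConfigError("too many scheduled residues for the box width")
        if resname == "MYR":
            beads = [(f"C{i + 1}",
                      np.array([x, y, _PROTEIN_Z + 2.0 * i]), 0.0)
                     for i in range(3)]
            builder.add_residue("MYR", resid, beads, chain="P")
        else:
            beads = [
                (name, np.array([x, y, _PROTEIN_Z + dz]), q)
                for name, dz, q in _protein_beads_for(resname)
            ]
            builder.add_residue(resname, resid, beads, chain="P")
        prot_positions[node] = np.array([x, y, _PROTEIN_Z])

    # retype upper-leaflet lipids (swaps within the leaflet preserve the
    # composition counts) so the scheduled lipid nodes exist
    upper_types, lower_types, _ = _leaflet_type_assignment(config)
    scheduled_pos = {}
    for entry in config.contact_schedule:
        ltype, resid = _parse_lipid_node(entry.lipid_node)
        pos = resid - 1  # lipid resids start at 1, upper leaflet first
        if not 0 <= pos < n_lip:
            raise ConfigError(f"lipid resid {resid} outside 1..{n_lip}")
        if pos >= len(upper_types):
            raise ConfigError(
                f"{entry.lipid_node}: scheduled lipids must be in the upper "
                f"leaflet (resids 1..{len(upper_types)})"
            )
        if pos in scheduled_pos and scheduled_pos[pos] != ltype:
            raise ConfigError(
                f"lipid resid {resid} scheduled with two different types"
            )
        scheduled_pos[pos] = ltype
    for pos, want in scheduled_pos.items():
        if upper_types[pos] == want:
            continue
        swap = next(
            (q for q, t in enumerate(upper_types)
             if t == want and q not in scheduled_pos),
            None,
        )
        if swap is None:
            raise ConfigError(
                f"no free upper-leaflet {want} lipid available for retyping"
            )
        upper_types[pos], upper_types[swap] = \
            upper_types[swap], upper_types[pos]

    records, paths = _build_membrane(
        config, builder, rng, start_resid=1,
        type_override=(upper_types, lower_types),
    )
    topology, template = builder.build()
    coords = _membrane_coords(template, records, paths, config.n_frames)
    box = np.tile(np.asarray(config.box, dtype=float), (config.n_frames, 1))

    name_index = {
        (r.resid, builder.atoms[i].name, r.chain): i
        for r in builder.residues for i in r.atom_indices
    }
    for entry in config.contact_schedule:
        resname, presid = _parse_protein_node(entry.protein_node)
        _, lresid = _parse_lipid_node(entry.lipid_node)
        pbead, lbead = _contact_beads(entry, resname)
        pi = name_index[(presid, pbead, "P")]
        li = name_index[(lresid, lbead, "M")]
        k = int(round(entry.persistence * config.n_frames))
        contact_frames = rng.choice(config.n_frames, size=k, replace=False)
        d_contact = _CONTACT_GEOMETRY[entry.interaction_class]
        target = coords[:, pi, :].copy()
        if entry.interaction_class == HYDROPHOBIC_CLASS and resname == "MYR":
            # pair to the chain's hydrophobic centre of mass
            myr_res = next(r for r in builder.residues if r.resname == "MYR")
            target = coords[:, myr_res.atom_indices, :].mean(axis=1)
        coords[contact_frames, li, :] = (
            target[contact_frames] + np.array([0.0, 0.0, -d_contact])
        )
        if entry.interaction_class == HYDROPHOBIC_CLASS:
            # the class criterion uses the acyl-group centre of mass: move
            # the second acyl bead alongside the first
            li2 = name_index[(lresid, "CA2", "M")]
            coords[contact_frames, li2, :] = coords[contact_frames, li, :] + \
                np.array([0.0, 0.0, -0.5])
        if entry.interaction_class == HBOND:
            # point the donor hydrogen at the acceptor (angle 180°)
            hname = {"ARG": "HH11", "LYS": "HZ1", "SER": "HG1",
                     "THR": "HG1", "ASN": "HD21", "GLN": "HE21"}[resname]
            hi = name_index[(presid, hname, "P")]
            coords[contact_frames, hi, :] = (
                coords[contact_frames, pi, :] + np.array([0.0, 0.0, -1.0])
            )
    return topology, Trajectory(coords, box, config.times)


def expected_persistence_table(config: GeneratorConfig) -> PersistenceTable:
    """The persistence table a correct detector must report for a
    contact-schedule fixture."""
    counts = {}
    for e in config.contact_schedule:
        a, b = canonical_pair(e.protein_node, e.lipid_node)
        counts[(a, b, e.interaction_class)] = int(
            round(e.persistence * config.n_frames)
        )
    return PersistenceTable(counts, config.n_frames)


# -- insertion fixture -----------------------------------------------------

_CHAIN_BEADS = 14
_CHAIN_SPACING = 4.0
_CAGE_DISTANCE = 3.0


def _icosahedron() -> np.ndarray:
    phi = (1 + 5 ** 0.5) / 2
    v = np.array([
        [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
        [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
        [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
    ], dtype=float)
    return v / np.linalg.norm(v[0])


def _burial_schedule(config: GeneratorConfig) -> np.ndarray:
    """Buried-bead count per frame implementing the configured window.

    Immediately after the start the count jumps to 4 of 14 (SASA drops well
    below the 75%-of-baseline start criterion, so the configured start is the
    last plateau time), climbs to 9 through the window (SASA stays above the
    25% end criterion) and reaches 11 at the end (SASA falls decisively below
    25%), ramping to full burial afterwards.  A ``dip`` fixture rises briefly
    and recovers (no stable low state).
    """
    t = config.times
    k = np.zeros(config.n_frames, dtype=int)
    if config.insertion is None:
        return k
    start, end = config.insertion
    if not (t[0] <= start < end <= t[-1]):
        raise ConfigError(
            f"insertion window ({start}, {end}) outside trajectory span "
            f"({t[0]}, {t[-1]})"
        )
    if config.insertion_mode == "dip":
        dip = (t > start) & (t <= start + 5.0)
        k[dip] = 11
        return k
    window = (t > start) & (t < end)
    u = (t[window] - start) / (end - start)
    k[window] = 4 + np.floor(6 * u).astype(int)
    after = t >= end
    ramp = np.minimum(
        11 + np.round((t[after] - end) / max(config.dt, 1e-9)).astype(int), 14
    )
    k[after] = ramp
    return k


def generate_insertion_trajectory(
    config: GeneratorConfig,
    role_map: RoleMap | None = None,
) -> tuple[Topology, Trajectory]:
    """Membrane patch plus a 14-bead myristoyl chain that descends through
    the upper head-group plane between the configured start/end times.

    Chain beads below the plane are enclosed by 12-bead icosahedral cages of
    acyl beads hosted by the nearest upper-leaflet lipids (scripted chain
    packing), so their SASA vanishes; beads above the plane stay solvated.
    Before the start the chain diffuses laterally above the patch without
    burial.
    """
    config_rng = np.random.default_rng(config.seed)
    builder = _SystemBuilder(role_map or load_role_map())

    cx, cy = config.box[0] / 2.0, config.box[1] / 2.0
    z_plane = BILAYER_CENTER_Z + LEAFLET_HALF_THICKNESS
    k_schedule = _burial_schedule(config)

    # myristoyl chain, bead 0 = methyl tip (descends first)
    tip_z0 = z_plane + 2.0
    chain_beads = [
        (f"C{i + 1}", np.array([cx, cy, tip_z0 + i * _CHAIN_SPACING]), 0.0)
        for i in range(_CHAIN_BEADS)
    ]
    myr = builder.add_residue("MYR", 1, chain_beads, chain="P")

    records, paths = _build_membrane(
        config, builder, rng=config_rng, start_resid=2
    )
    # cage beads: hosted by the 4 upper-leaflet lipids nearest the chain
    upper = [r for r in records if r["leaflet"] == "upper"]
    upper.sort(key=lambda r: np.sum((r["xy0"] - [cx, cy]) ** 2))
    n_cage = _CHAIN_BEADS * 12
    cage_hosts = upper[:4]
    park = np.array([cx, cy, BILAYER_CENTER_Z - 40.0])
    cage_ids = []
    for m in range(n_cage):
        host = cage_hosts[m % len(cage_hosts)]["residue"]
        i = len(builder.atoms)
        builder.atoms.append(AtomRecord(
            atom_id=i, name="CA2", element="C", residue_id=host.resid,
            residue_name=host.resname, chain="M",
            roles=builder.role_map.atom_roles(host.resname, "CA2"),
            charge=0.0,
        ))
        builder.coords.append(park + [0.0, 0.0, 0.1 * m])
        host.atom_indices = np.append(host.atom_indices, i)
        cage_ids.append(i)
    cage_ids = np.array(cage_ids)

    topology, template = builder.build()
    coords = _membrane_coords(template, records, paths, config.n_frames)
    box = np.tile(np.asarray(config.box, dtype=float), (config.n_frames, 1))

    ico = _icosahedron() * _CAGE_DISTANCE
    jitter = config_rng.normal(0.0, 0.15,
                               size=(config.n_frames, 2))  # lateral wiggle
    chain_idx = myr.atom_indices
    for f in range(config.n_frames):
        k = int(k_schedule[f])
        base_z = tip_z0 - k * _CHAIN_SPACING
        xy = np.array([cx, cy]) + jitter[f]
        for i in range(_CHAIN_BEADS):
            coords[f, chain_idx[i], :2] = xy
            coords[f, chain_idx[i], 2] = base_z + i * _CHAIN_SPACING
        for i in range(_CHAIN_BEADS):
            cage = cage_ids[i * 12:(i + 1) * 12]
            if i < k:  # buried bead: wrap its cage around it
                coords[f, cage, :] = coords[f, chain_idx[i], :] + ico
            else:
                coords[f, cage, :] = template[cage]
    return topology, Trajectory(coords, box, config.times)


# -- toy graphs and threshold fixtures ------------------------------------

def generate_toy_graph(kind: str, size: int, seed: int = 0) -> nx.Graph:
    """Deterministic named topologies or a seeded Erdős–Rényi graph, with
    persistence attributes on every edge."""
    if size < 2:
        raise ValueError("size must be >= 2")
    if kind == "cycle":
        g = nx.cycle_graph(size)
    elif kind == "path":
        g = nx.path_graph(size)
    elif kind == "star":
        g = nx.star_graph(size - 1)
    elif kind == "random":
        g = nx.gnp_random_graph(size, 0.15, seed=seed)
        while g.number_of_edges() == 0:
            seed += 1
            g = nx.gnp_random_graph(size, 0.15, seed=seed)
    else:
        raise ValueError(f"unknown graph kind {kind!r}")
    g = nx.relabel_nodes(g, {n: f"N{n}" for n in g.nodes})
    rng = np.random.default_rng(seed)
    for a, b in g.edges:
        p = float(rng.uniform(0.2, 1.0))
        g[a][b]["max_persistence"] = p
        g[a][b]["persistence_hydrophobic"] = p
        g[a][b]["classes"] = "hydrophobic"
    g.graph["p_t"] = 20.0
    return g


def generate_threshold_fixture(
    inflection: float,
    width: float = 3.0,
    n_edges: int = 120,
    seed: int = 0,
    n_frames: int = 20000,
) -> PersistenceTable:
    """Hydrophobic persistence table whose largest-cluster-size curve follows
    a logistic with the given inflection (percent scale).

    The edges form a chain with persistences decreasing along it, so at
    cutoff c the largest component is the contiguous surviving prefix; edge
    persistences are placed on the inverse logistic so the prefix length
    tracks ``n_edges / (1 + exp((c − inflection)/width))``.
    """
    rng = np.random.default_rng(seed)
    i = np.arange(1, n_edges + 1)
    with np.errstate(divide="ignore"):
        p_percent = inflection + width * np.log(n_edges / i - 1.0)
    p_percent[~np.isfinite(p_percent)] = 0.05
    p_percent = p_percent + rng.normal(0.0, 0.05, size=n_edges)
    p_percent = np.clip(p_percent, 0.05, 99.5)
    p_percent = np.sort(p_percent)[::-1]
    pairs = {
        (f"N{j}", f"N{j + 1}"): p_percent[j] / 100.0
        for j in range(n_edges)
    }
    return PersistenceTable.from_persistences(pairs, n_frames, "hydrophobic")
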